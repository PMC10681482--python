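# Methods

`sylvagen` couples an individual-based stand dynamics model with a
finite-loci quantitative genetic model, so that natural selection on a
growth trait emerges from — and feeds back on — competition, mortality and
mating success. This note records the model, its parameters and the design
choices behind them.

## State and spatial structure

A simulation holds one rectangular, environmentally homogeneous stand
(default 210 m × 210 m = 4.41 ha; site index 20 m at 50 years) tiled by
square pixels (15 m default). Each pixel is treated as an independent
even-aged sub-stand: growth, competition and mortality read only the
pixel's own trees, and the only coupling between pixels is seed and pollen
flow during regeneration. Trees carry continuous coordinates (half-open
pixel intervals [k·15, (k+1)·15)), age, diameter at breast height (dbh),
derived height/crown/volume, a diploid multi-locus genotype, the identities
of both parents, and a status flag whose transitions are one-way from
`alive` (dead by self-thinning, dead by disturbance, removed by thinning,
removed by harvest). All trees ever created are kept in a struct-of-arrays
registry, which makes the pedigree and the production ledger exactly
reconstructible and lets the annual processes run vectorized.

The annual order of operations is fixed: growth → self-thinning →
disturbance → regeneration (while the window is open) → scheduled
intervention → record.

## Growth

Dominant height follows a Chapman–Richards curve
H(t) = A(1 − e^(−kt))^c with the asymptote solved so that H(50) equals the
site index. Defaults k = 0.02, c = 1.4 give H(100) ≈ 1.55·H(50), the
late-age behavior expected of a long-lived conifer; steeper defaults
saturate growth unrealistically early and let the trait term dominate old
stands.

Each pixel receives an annual basal-area increment
ΔG = η·ΔH_dom·G^γ·s(RDI) (per-ha basis, scaled to the pixel), with
s(RDI) = 1 − e^(−RDI/0.1) a smooth damping in nearly empty pixels. The
increment is allocated to trees as circumference increments
max(0, m·(c_i − σ) + π·(v_i − v̄)), where v_i is individual phenotypic
vigor and v̄ the pixel mean: the threshold σ is re-solved by bisection
every pixel-year so that the implied basal-area increments sum *exactly* to
ΔG. The pixel mean vigor v̄ is then added to every tree's diameter
increment, floored at zero. This split encodes two properties of the
underlying biology: variation *around* the mean redistributes a
site-determined stand increment (so phenotypic variation does not change
the predicted mean growth before selective mortality begins), while a
population whose genetic *mean* has risen genuinely grows faster, which is
what makes tree size and timber production improve across generations.
With all vigor zero the scheme reduces to the plain threshold allocation
with exact conservation.

Tree height is a power curve anchored so trees at the pixel dominant
diameter reach the dominant height; crown height is a fixed fraction (0.6)
of height; stem volume is form factor (0.5) × basal area × height. Trees
younger than the recruitment age (25 y) neither grow nor express their
phenotype.

Calibration: the species-level growth coefficients are not published as a
usable set, so the defaults are anchored to three features of the simulated
system — H(50) = site index exactly; first self-thinning death at stand age
43 ± 2 in the unthinned 2800 stems/ha stand without variation (anchors η,
γ, and the Reineke intercept jointly; defaults η = 1.7, γ = 0.25,
k = 1.26·10⁶ on a circumference-cm basis with slope b = 1.6); and seed
trees comfortably above the 15 cm fertility threshold by age 60. The
allocation slope m = 0.03 yr⁻¹ sets how fast size differences amplify
(spread doubling time ≈ 23 y at full stocking).

## Mortality

Self-thinning: whenever a pixel's relative density index
RDI = N_ha / (k·Cg^(−b)) exceeds 1 (Cg the quadratic mean circumference),
the smallest trees die one at a time, Cg and RDI being recomputed after
each removal, until the pixel fits under the line. The sequential rule is
evaluated in closed form as a prefix search over the size order (ties by
tree id); this is exactly equivalent for b < 2 because removing the
smallest tree decreases both the stem count and the remaining sum of
squared circumferences. Self-thinning is the model's soft selection: it
targets relative size, and size integrates vigor, so indirect selection on
vigor strengthens as the vigor–size correlation builds with age.

Disturbance: each year one potential whole-stand mortality rate is drawn —
`none` (0), `medium` (Weibull, shape 1.5, scale 0.0222, long-run mean
≈ 2 %/yr) or `severe` (mixture of a low component, shape 1.5/scale 0.0443,
drawn five times more often than a high component, shape 3/scale 0.582;
long-run mean ≈ 12 %/yr). The rate is damped per pixel by the ratio of the
pixel's summed crown height to the maximum across pixels (exponent θ = 1),
and each tree then dies independently with the damped rate — death is
independent of size and genotype within a pixel, so disturbance removes
trees from the selection arena without selecting.

A run is flagged as a population collapse when no alive recruited tree
remains outside a regeneration window, when a seeding cut finds fewer
fertile trees than 10 % of its seed-tree target (a stand that cannot field
its regeneration system has failed demographically; setting the fraction
to 0 keeps only the strict no-fertile-tree rule), or when no seedling
exists at recruitment.

## Regeneration and inheritance

Trees are fertile when strictly older than 25 y with dbh strictly above
15 cm. Female fecundity is an ordinal cone-class model: a latent score
linear in dbh (0.25 per cm above the threshold) and crown height (0.05 per
m) plus a lifetime tree effect (SD 0.5) and an annual draw (SD 0.5), cut at
{0.5, 1.5, 2.5, 3.5} into classes with midpoint cone counts
{0, 10, 50, 200, 500}, times 10 viable seeds per cone. Released seed trees
sit deep in the top class, so female fecundity differentials among them are
modest; male fertility is dbh², giving fathers a size-proportional mating
advantage. Together these generate the model's fecundity selection, which
is deliberately weak next to viability selection.

Seeds and pollen are not simulated individually. Each regeneration year,
every pixel receives an expected seed density at its center: the sum over
mothers of (viable seeds) × f(distance), with f a 2D exponential-power
kernel, shape 0.5 (fat-tailed), scale solved from the mean dispersal
distance of 240 m (closed form a = mean·Γ(2/s)/Γ(3/s), verified by
quadrature in the tests). The number of seedlings established is
round(density × 1 m² × multiplier); each seedling draws its mother
proportionally to her contribution and its father among all fertile trees
proportionally to male fertility, selfing allowed. Genotypes are one
recombinant gamete per parent: independent assortment across the 10 default
linkage groups, Haldane recombination within groups, no mutation. The
default multiplier (6) is chosen so that regeneration saturates the
2800 stems/ha recruitment reset even for stands of about 1 ha; seeds
dispersing beyond the stand are lost (closed system), so small stands
intercept a smaller share of the fat-tailed rain and the test suite raises
the multiplier further on its 0.56 ha stand.

Each cycle ends with a seeding cut (random thinning to 110 seed trees/ha)
that opens a 3-year regeneration window, then a final harvest that removes
the seed trees. The 25-year pre-recruitment wait is a single bookkeeping
transition: accumulated seedlings are set to age 25, receive diameters
drawn from the recruitment-age distribution (truncated normal, mean 7 cm,
CV 0.25, floor 0.5 cm) *independently of genotype* — the genotype only
starts to matter through subsequent growth — then the cohort is
self-thinned and randomly reduced to 2800 stems/ha, so demographic
stochasticity of regeneration does not blur the scenario comparisons.

## Genetics

Genotypic value = Σ over loci and haplotypes of ±a_l; no dominance, no
epistasis. A locus at frequency p contributes 8·p(1−p)·a² to the additive
variance at Hardy–Weinberg/linkage equilibrium (the homozygotes are ±2a).
Phenotype = genotypic value + a lifetime environmental deviation
N(0, V_E) with V_E = V_A(1−h²)/h² (an annually redrawn inter-step
component is supported but zero by default, so phenotypes are constant over
a tree's life).

The founder initializer draws per-locus variance contributions from a
Gamma(0.5) (few QTL of large contribution), allele frequencies from a
Gamma(2) draw mapped through its own CDF into (0.05, 0.95), deduces
a_l = sqrt(c_l / (8 p_l q_l)), samples founder haplotypes as independent
Bernoulli(p_l) alleles, and repeats until the realized founder variance is
within 2 % of the target and the realized mean within 0.05·sqrt(V_A) of
zero (at most 1000 restarts; failure returns the best draw, flagged). The
same targets with different optimizer seeds give different architectures —
the study design runs several setups per architecture for that reason.

## Outputs and metrics

Annual records carry stems/ha, genetic mean and variance of vigor, Nei's
expected heterozygosity over the QTL, cumulative timber production per
hectare within the cycle (standing + dead volume; thinned and harvested
volume included by default, configurable), quadratic mean diameter, and
per-cycle death counts by cause. The evolutionary rate
H0 = |Δmean| / pooled SD / n_gen is computed on *phenotypic* vigor by
default (a genotypic variant is also reported), between the founders at
age 25 and the generation-5 recruits at age 25 — equivalent life stages,
because within-generation fluctuations do not represent the signal passed
between generations. The per-cycle selection differential is the genetic
mean of the seed trees minus that of the cycle-start population.

Randomness is scoped by three named seeds — genetic setup, inventory,
dynamics — so replicate runs can share founders while varying demographic
stochasticity. Identical configuration and seeds replay bit-identically.

## Problem sizes

The acceptance script (`scripts/acceptance.py`) runs the study on a
105 m × 105 m (1.1 ha) stand with 16 replicate dynamics seeds per
scenario-regime cell and five optimizer seeds per QTL architecture; the
test suite's scenario batch uses the same 1.1 ha conditions with 10
replicates, and cheaper checks a 0.56 ha stand. These sizes keep a full
factorial re-run in the minutes range while leaving the per-hectare
dynamics (densities, carrying capacity, dispersal) at the study's scale;
the main scale sensitivity is drift — fewer seed trees per stand widen the
replicate spread of H0.

## What the generator does and does not emulate

The synthetic stand reproduces the study conditions: even-aged monospecific
structure, homogeneous site, uniform random stem placement, the stated
density/site-index/genetic targets. It does not emulate spatial
autocorrelation of site quality or of disturbance, inter-pixel competition,
asymmetric neighborhood effects, juvenile selection before recruitment,
inbreeding depression, mutation, or immigration of external seed or pollen.
Passing tests therefore demonstrate the internal consistency of the coupled
model and the robustness of the scenario *comparisons*, not the absolute
calibration of any dendrometric output for a real stand.

## Known limitations

- The species calibration of the growth, self-thinning and fecundity
  submodels is anchored to a handful of printed values, not to the original
  (unpublished) coefficient sets; absolute productivity and size outputs
  should be read as internally consistent rather than species-accurate.
  The anchors pin the *relative* scenario comparisons, which are the
  intended use.
- The split between redistribution and net addition of vigor in the growth
  allocation controls how strongly phenotypic variation inflates
  end-of-cycle tree size and cumulative production; the implemented choice
  reproduces the qualitative mechanisms, but the magnitude of those two
  feedback numbers is sensitive to it.
- Fecundity selection strength rests entirely on the cone-class model's
  slope and saturation behavior; it sets the floor of the evolutionary
  rate in heavily thinned scenarios.
- Single trait, single parcel, even-aged cycles only; uneven-aged systems
  and multi-trait architectures are out of scope.
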