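# sylvagen

A demo-genetic agent-based simulator of even-aged forest stands, for
studying how silviculture and disturbance modulate natural
density-dependent selection on a heritable growth trait.

Individual trees carry a quantitative trait, **vigor**: the deviation of a
tree's annual diameter increment from the baseline prediction of a
stand-level growth model (cm·yr⁻¹). Vigor is controlled by a configurable
number of diallelic QTL with purely additive effects (each allele
contributes ±a_l, heterozygotes are neutral) plus a lifetime environmental
deviation; narrow-sense heritability is h² = V_A / (V_A + V_E). Every
simulated year the stand grows (a dominant-height-driven basal-area
increment allocated linearly to trees above a size threshold), the smallest
trees die where stem density exceeds a Reineke-type carrying capacity
N_max(Cg) = k·Cg⁻ᵇ (self-thinning), random disturbance kills trees
irrespective of size or genotype, and — at the end of each management cycle
— seed trees reproduce through explicit seed and pollen dispersal with
Mendelian inheritance and recombination. Because survival and mating
success depend on size, and size integrates vigor over decades, *indirect*
selection on vigor emerges from the coupled dynamics rather than being
imposed.

The headline statistic is the evolutionary rate in haldanes,

    H0 = |z̄_end − z̄_start| / sqrt((s²_start + s²_end)/2) / n_gen,

the change of mean vigor between the founders and the recruits produced
after the last management cycle, in units of pooled phenotypic standard
deviations per generation. Non-selective thinning and disturbance lower the
stand density, which weakens competition-driven selection and therefore
lowers H0 — a management "regulator" of natural selection.

## Worked example

Simulate four 103-year management cycles of an unthinned stand (seeding cut
at stand age 100 leaving 110 seed trees/ha, final harvest 3 years later,
recruitment reset to 2800 stems/ha), with the default genetic architecture
(50 QTL, V_A = 0.0042 cm²·yr⁻², h² = 0.3):

```python
import sylvagen as sg

cfg = sg.SimulationConfig()
cfg.stand = sg.Stand(width_m=105, depth_m=105)   # 1.1 ha
cfg.scenario = sg.scenario_library("U-long")
records, summary = sg.run_simulation(cfg)

print(f"H0 = {summary.h0:.3f} haldanes over {summary.n_gen} generations")
print(f"selection differentials: "
      f"{[round(s, 3) for s in summary.selection_differentials]}")
print(records[records.stand_age == 100]
      [["cycle", "Nha", "muG.Vig", "VA(Vig)", "He", "QMD"]]
      .to_string(index=False))
```

prints (seeds are fixed by default, so this is reproducible):

```
H0 = 0.538 haldanes over 4 generations
selection differentials: [0.047, 0.058, 0.057, 0.063]
 cycle        Nha  muG.Vig  VA(Vig)       He       QMD
     1 109.750567 0.044958 0.004179 0.343280 47.511370
     2 109.750567 0.111997 0.005057 0.333473 54.341738
     3 109.750567 0.175142 0.004282 0.322906 62.926251
     4 109.750567 0.243647 0.002630 0.314322 67.294592
```

Reading this: after each seeding cut 110 trees/ha remain; the genetic mean
of vigor (`muG.Vig`, cm·yr⁻¹) climbs by roughly one genetic standard
deviation (√0.0042 ≈ 0.065) per generation under competition-driven
selection; the genetic variance `VA(Vig)` erodes only slowly across
generations (reproduction restores the variance that within-generation
selection removes via linkage disequilibrium); gene diversity `He` declines
little; and the quadratic mean diameter of the survivors grows cycle over
cycle as the stand's genetic quality improves. Annual records also carry
stem density (`Nha`), cumulative timber production including dead and
removed trees (`VhaProd`, m³·ha⁻¹ per cycle) and per-cycle death counts by
cause (`DeadS-T`, `DeadD`).

The same experiment through the CLI:

```
sylvagen run --scenario U-long --disturbance none --out out/
sylvagen batch --scenarios U-long,B-long --disturbances none,medium --replicates 5
sylvagen metrics out/batch_summaries.json
```

Seven named scenarios are built in (`U-long`, `U-short`, `B-long`,
`B-short`, `E-low`, `E-delayed`, `E-relaxed`): unthinned, baseline and
exploratory thinning schedules on 60- or 100-year cycles, all ending with a
seeding cut and a final harvest. Disturbance regimes `none`, `medium`
(≈2 %/yr) and `severe` (≈12 %/yr, bimodal) add non-selective stochastic
mortality; the severe regime collapses the population during the first
cycle.

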