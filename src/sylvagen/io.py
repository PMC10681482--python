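"""Plain-text input/output: inventories, QTL maps, pedigrees, records.

The inventory CSV stores one tree per row with the genotype as a per-locus
allele-dosage digit string (count of the increasing allele); a phased
haplotype sidecar CSV allows exact replay of meiosis.  All files are
ordinary CSVs handled through pandas.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core_state import TreePopulation
from .genetics import QTLMap

INVENTORY_COLUMNS = ["id", "x", "y", "age", "dbh", "mother_id", "father_id",
                     "genotype"]


def write_qtl_map(qmap: QTLMap, path: str | Path) -> None:
    pd.DataFrame({
        "locus": np.arange(qmap.n_loci),
        "linkage_group": qmap.linkage_group,
        "position_cM": qmap.position_cM,
        "effect": qmap.effect,
        "init_freq": qmap.init_freq,
    }).to_csv(path, index=False)


def read_qtl_map(path: str | Path) -> QTLMap:
    df = pd.read_csv(path)
    return QTLMap(df["effect"].to_numpy(), df["init_freq"].to_numpy(),
                  df["linkage_group"].to_numpy(), df["position_cM"].to_numpy())


def _dosage_strings(geno: np.ndarray) -> list[str]:
    dosage = geno.sum(axis=2)
    return ["".join(map(str, row)) for row in dosage]


def write_inventory(pop: TreePopulation, path: str | Path,
                    haplotypes_path: str | Path | None = None) -> None:
    """Write the tree inventory; optionally a phased-haplotype sidecar."""
    df = pd.DataFrame({
        "id": pop.id, "x": pop.x, "y": pop.y, "age": pop.age, "dbh": pop.dbh,
        "mother_id": pop.mother, "father_id": pop.father,
        "genotype": (_dosage_strings(pop.geno) if pop.geno is not None
                     else [""] * pop.n),
    })
    df.to_csv(path, index=False)
    if haplotypes_path is not None and pop.geno is not None:
        hap = pd.DataFrame({
            "id": pop.id,
            "hap1": ["".join(map(str, h)) for h in pop.geno[:, :, 0]],
            "hap2": ["".join(map(str, h)) for h in pop.geno[:, :, 1]],
        })
        hap.to_csv(haplotypes_path, index=False)


def read_inventory(path: str | Path,
                   haplotypes_path: str | Path | None = None,
                   stand=None) -> TreePopulation:
    """Load an inventory CSV (phased sidecar preferred for genotypes;
    without it heterozygous phase is arbitrary).  When a stand is given the
    trees are assigned to their containing pixels."""
    df = pd.read_csv(path, dtype={"genotype": str}, keep_default_na=False)
    geno = None
    gstrings = df["genotype"].astype(str)
    n_loci = len(gstrings.iloc[0]) if len(df) and gstrings.iloc[0] else 0
    if haplotypes_path is not None:
        hap = pd.read_csv(haplotypes_path, dtype=str)
        n_loci = len(hap["hap1"].iloc[0])
        geno = np.zeros((len(df), n_loci, 2), dtype=np.uint8)
        for k, col in enumerate(("hap1", "hap2")):
            geno[:, :, k] = np.array(
                [[int(c) for c in s] for s in hap[col]], dtype=np.uint8)
    elif n_loci:
        dosage = np.array([[int(c) for c in s] for s in gstrings],
                          dtype=np.uint8)
        geno = np.zeros((len(df), n_loci, 2), dtype=np.uint8)
        geno[:, :, 0] = dosage >= 1
        geno[:, :, 1] = dosage == 2
    x = df["x"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    pop = TreePopulation(n_loci=n_loci)
    pop.append(x=x, y=y,
               pixel=stand.pixel_of(x, y) if stand is not None else 0,
               age=df["age"].to_numpy(), dbh=df["dbh"].to_numpy(),
               mother=df["mother_id"].to_numpy(),
               father=df["father_id"].to_numpy(),
               cohort=1, recruited=True, geno=geno)
    return pop


def write_pedigree(pop: TreePopulation, path: str | Path) -> None:
    pd.DataFrame({
        "id": pop.id, "cohort": pop.cohort,
        "mother_id": pop.mother, "father_id": pop.father,
    }).to_csv(path, index=False)
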