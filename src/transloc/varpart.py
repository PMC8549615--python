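"""Partition morphological variance into genomic and epigenomic parts.

Three constrained ordinations on the first few PCs of each data block:
morpho ~ gen + epi (joint), morpho ~ gen | epi (partial) and
morpho ~ epi | gen.  Fractions are adjusted-R^2 differences in the usual
variance-partitioning convention:

    [gen|epi] = R2adj(gen+epi) - R2adj(epi)
    [epi|gen] = R2adj(gen+epi) - R2adj(gen)
    overlap   = R2adj(gen) + R2adj(epi) - R2adj(gen+epi)

so [gen+epi] = [gen|epi] + [epi|gen] + overlap exactly.  The overlap has
no permutation test and may be negative (suppression); it is reported,
not clipped.  Cohort splits (per system, source+young, source+old)
repeat the decomposition on row subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ordination import rda

__all__ = ["VarPartResult", "varpart", "varpart_morphology"]


@dataclass
class VarPartResult:
    cohort: str
    n: int
    adj_r2_joint: float
    adj_r2_gen: float
    adj_r2_epi: float
    gen_unique: float
    epi_unique: float
    overlap: float
    residual: float
    p_joint: float | None
    p_gen_conditional: float | None
    p_epi_conditional: float | None

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort, "n": self.n,
            "adj_r2_joint": self.adj_r2_joint, "adj_r2_gen": self.adj_r2_gen,
            "adj_r2_epi": self.adj_r2_epi, "gen_unique": self.gen_unique,
            "epi_unique": self.epi_unique, "overlap": self.overlap,
            "residual": self.residual, "p_joint": self.p_joint,
            "p_gen_conditional": self.p_gen_conditional,
            "p_epi_conditional": self.p_epi_conditional,
        }


def varpart(
    morpho: np.ndarray,
    gen: np.ndarray,
    epi: np.ndarray,
    n_perm: int = 1000,
    seed=None,
    cohort: str = "all",
) -> VarPartResult:
    """One variance-partitioning decomposition on aligned score matrices."""
    morpho = np.asarray(morpho, float)
    gen = np.atleast_2d(np.asarray(gen, float))
    epi = np.atleast_2d(np.asarray(epi, float))
    if gen.shape[0] == 1:
        gen = gen.T
    if epi.shape[0] == 1:
        epi = epi.T
    n = morpho.shape[0]
    k = gen.shape[1] + epi.shape[1]
    if n <= k + 4:
        raise ValueError(f"cohort {cohort!r} has n={n}, too few rows for {k} predictors")

    joint = rda(morpho, np.hstack([gen, epi]), n_perm=n_perm, seed=seed)
    only_gen = rda(morpho, gen, n_perm=0)
    only_epi = rda(morpho, epi, n_perm=0)
    p_gen = rda(morpho, gen, condition=epi, n_perm=n_perm, seed=seed)
    p_epi = rda(morpho, epi, condition=gen, n_perm=n_perm, seed=seed)

    a_joint, a_gen, a_epi = joint.adj_r2, only_gen.adj_r2, only_epi.adj_r2
    gen_unique = a_joint - a_epi
    epi_unique = a_joint - a_gen
    overlap = a_gen + a_epi - a_joint
    return VarPartResult(
        cohort=cohort, n=n,
        adj_r2_joint=a_joint, adj_r2_gen=a_gen, adj_r2_epi=a_epi,
        gen_unique=gen_unique, epi_unique=epi_unique, overlap=overlap,
        residual=1.0 - a_joint,
        p_joint=joint.perm_p, p_gen_conditional=p_gen.perm_p,
        p_epi_conditional=p_epi.perm_p,
    )


def varpart_morphology(
    morpho_pcs: np.ndarray,
    gen_pcs: np.ndarray,
    epi_pcs: np.ndarray,
    cohorts: dict[str, np.ndarray] | None = None,
    n_perm: int = 1000,
    seed=None,
) -> pd.DataFrame:
    """Variance partitioning per cohort; rows must be aligned individuals.

    ``cohorts`` maps cohort name to a boolean row mask; the full data set
    ("all") is always included.  Cohorts too small for the predictor
    count are skipped with a note in the ``skipped`` attrs.
    """
    results = []
    skipped = {}
    cohort_masks = {"all": np.ones(morpho_pcs.shape[0], dtype=bool)}
    if cohorts:
        cohort_masks.update(cohorts)
    for name, mask in cohort_masks.items():
        mask = np.asarray(mask, dtype=bool)
        try:
            res = varpart(morpho_pcs[mask], gen_pcs[mask], epi_pcs[mask],
                          n_perm=n_perm, seed=seed, cohort=name)
        except ValueError as err:
            skipped[name] = str(err)
            continue
        results.append(res.to_dict())
    out = pd.DataFrame(results)
    out.attrs["skipped"] = skipped
    return out
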