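"""Outlier detection for genotype-environment association.

Two evidence lines are combined: (1) SNP loadings on the lake-type axis
of a redundancy analysis, z-scored across SNPs and thresholded at
|z| > 2.5 (equivalent to a two-tailed standard-normal p of 0.01), and
(2) the z-score of the absolute major-allele frequency change between
the source-population group and the refuge-population group.  The shared
outlier set is the intersection of the two callers.  A multi-set overlap
excess test (hypergeometric for two sets, Monte-Carlo for more) measures
sharing of outlier/differentially methylated sets beyond chance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, MISSING
from .ordination import OrdinationResult
from .utils import as_rng

__all__ = ["rda_outliers", "af_change_z", "combine_outlier_calls", "overlap_test"]


def rda_outliers(
    ord_result: OrdinationResult, axis: int = 0, z_threshold: float = 2.5
) -> pd.DataFrame:
    """Flag variables whose axis loading lies beyond ``z_threshold`` SDs.

    z = (loading - mean) / SD across all variables on the axis.
    """
    if axis >= ord_result.loadings.shape[1]:
        raise ValueError(f"axis {axis} not present")
    loadings = ord_result.loadings[:, axis]
    sd = loadings.std()
    if sd == 0:
        raise ValueError("zero-variance loadings; outlier z-scores undefined")
    z = (loadings - loadings.mean()) / sd
    return pd.DataFrame({
        "loading": loadings, "z": z, "outlier": np.abs(z) > z_threshold,
    })


def af_change_z(
    matrix: GenotypeMatrix,
    source_pops,
    refuge_pops,
    weighting: str = "population",
) -> pd.DataFrame:
    """Per-SNP z-score of the absolute major-allele frequency change.

    The major allele is defined in the pooled sample.  Group frequencies
    average population frequencies with equal weight per population
    (``weighting="population"``) or pool allele counts
    (``weighting="pooled"``).  z = (|delta| - mean|delta|) / SD(|delta|).
    SNPs missing in an entire group are excluded (NaN rows).
    """
    if weighting not in ("population", "pooled"):
        raise ValueError("weighting must be 'population' or 'pooled'")
    pooled_af = matrix.allele_freq()
    major_is_alt = pooled_af >= 0.5

    def group_freq(pops) -> np.ndarray:
        if weighting == "population":
            freqs = []
            for pop in pops:
                mask = (matrix.samples["population"] == pop).to_numpy()
                freqs.append(matrix.allele_freq(mask))
            return np.nanmean(np.vstack(freqs), axis=0)
        mask = matrix.samples["population"].isin(list(pops)).to_numpy()
        return matrix.allele_freq(mask)

    f_src = group_freq(source_pops)
    f_ref = group_freq(refuge_pops)
    # convert alt-allele to major-allele frequency
    f_src_major = np.where(major_is_alt, f_src, 1 - f_src)
    f_ref_major = np.where(major_is_alt, f_ref, 1 - f_ref)
    delta = f_src_major - f_ref_major
    abs_delta = np.abs(delta)
    ok = np.isfinite(abs_delta)
    z = np.full_like(abs_delta, np.nan)
    sd = np.nanstd(abs_delta[ok])
    if ok.sum() and sd > 0:
        z[ok] = (abs_delta[ok] - np.nanmean(abs_delta[ok])) / sd
    return pd.DataFrame({
        "delta_major_af": delta, "abs_delta": abs_delta, "z": z,
    }, index=matrix.snps.index)


def combine_outlier_calls(
    rda_table: pd.DataFrame, afz_table: pd.DataFrame, z_threshold: float = 2.5
) -> pd.DataFrame:
    """Merge the two callers; ``shared`` marks SNPs flagged by both."""
    out = pd.DataFrame({
        "rda_z": rda_table["z"].to_numpy(),
        "afz_z": afz_table["z"].to_numpy(),
    })
    out["rda"] = np.abs(out["rda_z"]) > z_threshold
    out["afz"] = np.abs(out["afz_z"]) > z_threshold
    out["shared"] = out["rda"] & out["afz"]
    return out


def overlap_test(
    sets: list[set],
    universe_size: int,
    method: str = "auto",
    n_draws: int = 100_000,
    seed=None,
) -> dict[str, float]:
    """Observed vs expected intersection size of k sets from one universe.

    Two sets: exact hypergeometric upper-tail p of the intersection.
    More sets: Monte-Carlo resampling of uniform random sets of the
    observed sizes with a plus-one p-value.  Expected overlap under
    independence is prod(|S_i|) / universe^(k-1).
    """
    sets = [set(s) for s in sets]
    sizes = [len(s) for s in sets]
    if any(sz > universe_size for sz in sizes):
        raise ValueError("a set is larger than the universe")
    k = len(sets)
    if k < 2:
        raise ValueError("need >= 2 sets")
    observed = len(set.intersection(*sets))
    expected = float(np.prod([s / universe_size for s in sizes]) * universe_size)
    if method == "auto":
        method = "exact2" if k == 2 else "montecarlo"
    if method == "exact2":
        if k != 2:
            raise ValueError("exact2 requires exactly 2 sets")
        p = float(stats.hypergeom.sf(observed - 1, universe_size, sizes[0], sizes[1]))
    elif method == "montecarlo":
        rng = as_rng(seed)
        count = 0
        universe = np.arange(universe_size)
        for _ in range(n_draws):
            inter = set(rng.choice(universe, size=sizes[0], replace=False))
            for sz in sizes[1:]:
                inter &= set(rng.choice(universe, size=sz, replace=False))
                if not inter:
                    break
            if len(inter) >= observed:
                count += 1
        p = (count + 1) / (n_draws + 1)
    else:
        raise ValueError("method must be 'auto', 'exact2' or 'montecarlo'")
    return {"observed": observed, "expected": expected, "p": p,
            "n_sets": k, "universe": universe_size}
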