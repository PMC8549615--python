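"""SNP matrix quality control.

Filters follow the reduced-representation workflow the package models:
global missingness, minor allele frequency, maximum observed
heterozygosity (paralog screen), per-individual missingness, a
per-population exact Hardy-Weinberg screen, per-population missingness,
and one SNP per RAD locus.  Also provided: greedy LD pruning on dosage
r^2, a PCA-based blacklist of SNPs correlated with library batch, and
k-nearest-neighbour genotype imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import GenotypeMatrix, MISSING

__all__ = ["QCParams", "FilterReport", "filter_genotypes", "hwe_exact_test",
           "ld_prune", "pca_batch_blacklist", "knn_impute"]


@dataclass
class QCParams:
    maf: float = 0.05
    max_missing_global: float = 0.33
    max_missing_per_pop: float = 0.33
    max_obs_het: float = 0.6
    max_ind_missing: float = 0.30
    hwe_alpha: float = 0.001
    hwe_pop_fraction: float = 0.5
    one_snp_per_locus: bool = True


@dataclass
class FilterReport:
    """Ordered log of filter steps with before/after counts."""

    steps: list[dict] = field(default_factory=list)

    def add(self, name: str, params: dict, snps_before: int, snps_after: int,
            individuals_removed: int = 0) -> None:
        self.steps.append({
            "filter": name, "params": params, "snps_before": snps_before,
            "snps_after": snps_after, "individuals_removed": individuals_removed,
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the probabilities of configurations no more likely
    than the observed one.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be >= 0")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("need at least one genotype")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n_rare == 0:
        return 1.0
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # log P(het = h | allele counts) up to a constant, via factorials
    n_common = 2 * n - n_rare
    logp = (hets * np.log(2.0)
            + gammaln(n + 1)
            - gammaln(hets + 1)
            - gammaln((n_rare - hets) / 2 + 1)
            - gammaln((n_common - hets) / 2 + 1))
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[hets == n_het][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def _obs_het(matrix: GenotypeMatrix) -> np.ndarray:
    called = matrix.called()
    n_called = called.sum(axis=0)
    n_het = ((matrix.genotypes == 1) & called).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_called > 0, n_het / n_called, np.nan)


def filter_genotypes(
    matrix: GenotypeMatrix, params: QCParams | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the full SNP/individual filter chain; returns matrix + report.

    An all-filtered result is returned as an empty matrix with the report
    describing where everything went, rather than raising.
    """
    p = params or QCParams()
    report = FilterReport()
    m = matrix

    # 1. global missingness
    before = m.n_snps
    keep = m.missing_rate_snps() <= p.max_missing_global
    m = m.take_snps(np.flatnonzero(keep))
    report.add("max_missing_global", {"threshold": p.max_missing_global}, before, m.n_snps)

    # 2. minor allele frequency
    before = m.n_snps
    af = m.allele_freq()
    maf = np.minimum(af, 1 - af)
    keep = maf >= p.maf
    m = m.take_snps(np.flatnonzero(keep & np.isfinite(maf)))
    report.add("maf", {"threshold": p.maf}, before, m.n_snps)

    # 3. maximum observed heterozygosity
    before = m.n_snps
    keep = _obs_het(m) <= p.max_obs_het
    m = m.take_snps(np.flatnonzero(keep))
    report.add("max_obs_het", {"threshold": p.max_obs_het}, before, m.n_snps)

    # 4. individual missingness
    ind_keep = m.missing_rate_individuals() <= p.max_ind_missing
    removed = int((~ind_keep).sum())
    m = m.take_individuals(np.flatnonzero(ind_keep))
    report.add("max_ind_missing", {"threshold": p.max_ind_missing},
               m.n_snps, m.n_snps, individuals_removed=removed)

    pops = m.samples["population"].unique() if "population" in m.samples else []

    # 5. per-population HWE
    before = m.n_snps
    if len(pops) and m.n_snps:
        out_count = np.zeros(m.n_snps, dtype=int)
        for pop in pops:
            sub = m.subset_population(pop)
            g = sub.genotypes
            for j in range(m.n_snps):
                col = g[:, j]
                col = col[col != MISSING]
                if col.size == 0:
                    continue
                counts = [(col == 0).sum(), (col == 1).sum(), (col == 2).sum()]
                if hwe_exact_test(*counts) < p.hwe_alpha:
                    out_count[j] += 1
        keep = out_count <= p.hwe_pop_fraction * len(pops)
        m = m.take_snps(np.flatnonzero(keep))
    report.add("hwe_per_pop", {"alpha": p.hwe_alpha, "pop_fraction": p.hwe_pop_fraction},
               before, m.n_snps)

    # 6. per-population missingness
    before = m.n_snps
    if len(pops) and m.n_snps:
        keep = np.ones(m.n_snps, dtype=bool)
        for pop in pops:
            sub = m.subset_population(pop)
            keep &= sub.missing_rate_snps() <= p.max_missing_per_pop
        m = m.take_snps(np.flatnonzero(keep))
    report.add("max_missing_per_pop", {"threshold": p.max_missing_per_pop}, before, m.n_snps)

    # 7. one SNP per RAD locus (first by position)
    before = m.n_snps
    if p.one_snp_per_locus and "locus_id" in m.snps.columns and m.n_snps:
        order = m.snps.sort_values(["locus_id", "pos"]).index
        first = m.snps.loc[order].drop_duplicates("locus_id").index.to_numpy()
        first.sort()
        m = m.take_snps(first)
    report.add("one_snp_per_locus", {}, before, m.n_snps)

    return m, report


def ld_prune(
    matrix: GenotypeMatrix, r2_max: float = 0.2, window_bp: int = 1_000_000
) -> np.ndarray:
    """Greedy LD pruning on dosage correlation; returns kept SNP indices.

    Scans each chromosome left to right; a SNP is dropped when its squared
    dosage correlation with any *retained* SNP within ``window_bp``
    upstream reaches ``r2_max``.  Missing genotypes are pairwise-deleted.
    """
    g = matrix.genotypes.astype(float)
    g[matrix.genotypes == MISSING] = np.nan
    snps = matrix.snps
    kept: list[int] = []
    for chrom in pd.unique(snps["chrom"]):
        idx = snps.index[snps["chrom"] == chrom].to_numpy()
        idx = idx[np.argsort(snps.loc[idx, "pos"].to_numpy(), kind="stable")]
        kept_chr: list[int] = []
        for j in idx:
            pos_j = snps.at[j, "pos"]
            drop = False
            for i in reversed(kept_chr):
                if pos_j - snps.at[i, "pos"] > window_bp:
                    break
                both = ~(np.isnan(g[:, i]) | np.isnan(g[:, j]))
                if both.sum() < 3:
                    continue
                a, b = g[both, i], g[both, j]
                if a.std() == 0 or b.std() == 0:
                    continue
                r = np.corrcoef(a, b)[0, 1]
                if r * r >= r2_max:
                    drop = True
                    break
            if not drop:
                kept_chr.append(j)
        kept.extend(kept_chr)
    return np.array(sorted(kept), dtype=int)


def pca_batch_blacklist(
    matrix: GenotypeMatrix,
    batch_labels,
    threshold: float = 0.3,
    n_axes: int = 10,
) -> tuple[np.ndarray, dict]:
    """SNPs whose genotypes track the library batch axis of a PCA.

    Runs a genotype PCA (mean-imputed), picks the axis with the largest
    point-biserial correlation with batch membership, and blacklists SNPs
    whose |genotype-score correlation| or |correlation-scaled loading|
    exceeds ``threshold``.  When no axis correlates with batch beyond the
    threshold there is no batch axis to clean and nothing is blacklisted.
    Returns (blacklisted indices, info dict); the info dict carries a
    confounding warning when batch is nested within population.
    """
    batch = np.asarray(batch_labels)
    levels = np.unique(batch)
    if levels.size < 2:
        raise ValueError("need >= 2 batches")
    g = matrix.genotypes.astype(float)
    g[matrix.genotypes == MISSING] = np.nan
    mu = np.nanmean(g, axis=0)
    gf = np.where(np.isnan(g), mu[None, :], g)
    gc = gf - gf.mean(axis=0)
    n = gc.shape[0]
    U, s, Vt = np.linalg.svd(gc, full_matrices=False)
    n_axes = int(min(n_axes, s.size))
    scores = (U * s)[:, :n_axes]

    # strongest batch axis: max point-biserial over one-vs-rest indicators
    best_axis, best_r = 0, -1.0
    for ax in range(n_axes):
        for lv in levels:
            ind = (batch == lv).astype(float)
            r = abs(np.corrcoef(scores[:, ax], ind)[0, 1])
            if r > best_r:
                best_r, best_axis = r, ax

    if best_r < threshold:
        # no axis meaningfully tracks batch: nothing to blacklist
        return np.array([], dtype=int), {
            "axis": int(best_axis), "batch_axis_corr": float(best_r),
            "no_batch_axis": True, "confounded": False,
        }

    sc = scores[:, best_axis]
    sd_g = gc.std(axis=0)
    sd_g[sd_g == 0] = np.inf
    corr = (gc * (sc - sc.mean())[:, None]).mean(axis=0) / (sd_g * sc.std())
    loading = Vt[best_axis] * s[best_axis] / (sd_g * np.sqrt(n))
    flagged = (np.abs(corr) > threshold) | (np.abs(loading) > threshold)

    info = {"axis": int(best_axis), "batch_axis_corr": float(best_r),
            "corr": corr, "loading": loading, "confounded": False}
    if "population" in matrix.samples:
        pops = matrix.samples["population"].to_numpy()
        tab = pd.crosstab(pops, batch)
        if ((tab > 0).sum(axis=1) == 1).all():
            info["confounded"] = True
    return np.flatnonzero(flagged), info


def knn_impute(
    matrix: GenotypeMatrix, k: int = 10, system_column: str = "system"
) -> GenotypeMatrix:
    """Distance-weighted k-nearest-neighbour genotype imputation.

    Neighbours are restricted to the same system partition (when a system
    label exists); the metric is the mean absolute dosage difference over
    shared non-missing SNPs.  Each missing call takes the distance-
    weighted modal dosage among neighbours genotyped there; if no
    neighbour is genotyped, the cohort major-allele dosage is used.
    Observed genotypes are never altered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    g = matrix.genotypes.astype(float)
    g[matrix.genotypes == MISSING] = np.nan
    out = matrix.genotypes.copy()
    n = matrix.n_individuals
    systems = (matrix.samples[system_column].to_numpy()
               if system_column in matrix.samples else np.zeros(n))

    af = matrix.allele_freq()
    major_dosage = np.where(np.isnan(af), 0, np.where(af >= 0.5, 2, 0)).astype(np.int8)

    for sys_lv in np.unique(systems):
        part = np.flatnonzero(systems == sys_lv)
        sub = g[part]
        obs = ~np.isnan(sub)
        # pairwise mean |dosage difference| over shared sites
        diff = np.abs(sub[:, None, :] - sub[None, :, :])
        shared = obs[:, None, :] & obs[None, :, :]
        n_shared = shared.sum(axis=2)
        with np.errstate(invalid="ignore"):
            dist = np.where(n_shared > 0,
                            np.nansum(np.where(shared, diff, 0.0), axis=2) / n_shared,
                            np.inf)
        np.fill_diagonal(dist, np.inf)
        for ii, i_glob in enumerate(part):
            miss_j = np.flatnonzero(np.isnan(sub[ii]))
            if miss_j.size == 0:
                continue
            order = np.argsort(dist[ii], kind="stable")[:k]
            w = 1.0 / (dist[ii, order] + 1e-6)
            for j in miss_j:
                neigh = obs[order, j]
                if not neigh.any():
                    out[i_glob, j] = major_dosage[j]
                    continue
                votes = np.zeros(3)
                for o, wt in zip(order[neigh], w[neigh]):
                    votes[int(sub[o, j])] += wt
                out[i_glob, j] = int(np.argmax(votes))
    return GenotypeMatrix(out, matrix.samples.copy(), matrix.snps.copy())
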