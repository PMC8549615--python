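"""Population-genomic summary statistics.

Per-population diversity (He, Ho, pi over variant sites, private alleles,
rarefied allelic richness), individual inbreeding from excess
homozygosity (F_H), pairwise genomic relatedness (R_xy), Weir-Cockerham
FST with permutation significance, genotype PCA, Kolmogorov-Smirnov
distribution comparisons, and the founder-size regressions.

F_H uses allele frequencies from a designated outbred reference (the
source population): F_H = (O_hom - E_hom) / (L - E_hom) with E_hom =
sum_j (1 - 2 p_j q_j).  R_xy is the genomic-relationship-matrix form,
R_xy = (1/M) sum_j (x_i - 2p_j)(x_j - 2p_j) / (2 p_j q_j).

The multilocus FST is the ratio-of-sums estimator theta = sum a /
sum(a + b + c) over the Weir & Cockerham (1984) variance components for
two populations with unequal sample sizes; negative estimates are
retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .containers import GenotypeMatrix, MISSING
from .ordination import OrdinationResult, pca
from .utils import as_rng

__all__ = [
    "DiversityStats", "KinshipResult", "FstResult",
    "diversity_stats", "inbreeding_relatedness", "wc_components", "wc_theta",
    "wc_fst", "genotype_pca", "ks_compare", "founder_regression",
]


@dataclass
class DiversityStats:
    table: pd.DataFrame  # per-population He, Ho, pi, private alleles, rarefied AR


@dataclass
class KinshipResult:
    f_h: pd.Series                # per individual
    r_xy: pd.DataFrame            # symmetric individuals x individuals
    n_snps_used: int


@dataclass
class FstResult:
    theta: pd.DataFrame           # pairwise multilocus ratio-of-sums theta
    theta_mean_loci: pd.DataFrame  # pairwise mean of per-locus theta (secondary)
    p_values: pd.DataFrame


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _rarefied_ar(alt_copies: np.ndarray, total_copies: np.ndarray, g_copies: int) -> np.ndarray:
    """Expected allele count per SNP when subsampling ``g_copies`` gene copies."""
    ar = np.zeros(alt_copies.shape, dtype=float)
    for copies in (alt_copies, total_copies - alt_copies):
        with np.errstate(invalid="ignore"):
            absent = np.where(
                total_copies - copies >= g_copies,
                np.exp(_log_comb(total_copies - copies, g_copies)
                       - _log_comb(total_copies, g_copies)),
                0.0,
            )
        ar += np.where(copies > 0, 1.0 - absent, 0.0)
    return ar


def diversity_stats(
    matrix: GenotypeMatrix, populations=None, rarefaction_g: int = 8
) -> DiversityStats:
    """Per-population He, Ho, pi, private alleles and rarefied richness.

    He uses the unbiased estimator 2 p q n/(n-1); pi is averaged over
    variant sites only (proportional to, not identical with, per-
    nucleotide diversity).  Rarefaction is to ``2 * rarefaction_g`` gene
    copies.  SNPs rarefied below the target copy number contribute their
    observed allele count.
    """
    pops = (matrix.samples["population"].unique() if populations is None
            else list(populations))
    missing_pops = set(pops) - set(matrix.samples["population"])
    if missing_pops:
        raise ValueError(f"populations absent from matrix: {sorted(missing_pops)}")

    per_pop = {}
    alt_presence = {}
    ref_presence = {}
    for pop in pops:
        sub = matrix.subset_population(pop)
        g = sub.genotypes
        called = g != MISSING
        n_called = called.sum(axis=0)
        ok = n_called >= 2
        alt = np.where(called, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_hat = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
            het = np.where(n_called > 0,
                           ((g == 1) & called).sum(axis=0) / n_called, np.nan)
        n_dip = n_called.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            he = 2 * p_hat * (1 - p_hat) * (2 * n_dip) / (2 * n_dip - 1)
        variant = ok & (alt > 0) & (alt < 2 * n_called)
        per_pop[pop] = {
            "He": float(np.nanmean(he[ok])),
            "Ho": float(np.nanmean(het[ok])),
            "pi": float(np.nanmean(he[variant])) if variant.any() else 0.0,
        }
        alt_presence[pop] = alt > 0
        ref_presence[pop] = (2 * n_called - alt) > 0
        ar = _rarefied_ar(alt, 2 * n_called, 2 * rarefaction_g)
        small = 2 * n_called < 2 * rarefaction_g
        if small.any():
            obs_alleles = (alt_presence[pop].astype(int) + ref_presence[pop].astype(int))
            ar = np.where(small, obs_alleles, ar)
        per_pop[pop]["rarefied_AR"] = float(np.mean(ar[ok]))

    # private alleles: allele present in exactly one population
    for pop in pops:
        others_alt = np.any([alt_presence[q] for q in pops if q != pop], axis=0)
        others_ref = np.any([ref_presence[q] for q in pops if q != pop], axis=0)
        private = (alt_presence[pop] & ~others_alt).sum() + \
                  (ref_presence[pop] & ~others_ref).sum()
        per_pop[pop]["private_alleles"] = int(private)

    table = pd.DataFrame(per_pop).T
    table.index.name = "population"
    return DiversityStats(table)


# ---------------------------------------------------------------------------
# inbreeding & relatedness
# ---------------------------------------------------------------------------


def inbreeding_relatedness(
    matrix: GenotypeMatrix, ref_freqs: np.ndarray
) -> KinshipResult:
    """F_H per individual and the R_xy relatedness matrix.

    ``ref_freqs`` must come from the outbred source population.  SNPs
    fixed in the reference (p in {0, 1}) are excluded.  Missing calls are
    handled per individual (F_H) and pairwise (R_xy).
    """
    p = np.asarray(ref_freqs, dtype=float)
    usable = np.isfinite(p) & (p > 0) & (p < 1)
    g = matrix.genotypes[:, usable].astype(float)
    g[g == MISSING] = np.nan
    p = p[usable]
    q = 1 - p
    het_exp = 2 * p * q

    obs = ~np.isnan(g)
    o_hom = ((g == 0) | (g == 2)).sum(axis=1)
    e_hom = (obs * (1 - het_exp)[None, :]).sum(axis=1)
    l_total = obs.sum(axis=1)
    denom = l_total - e_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        f_h = np.where(denom != 0, (o_hom - e_hom) / denom, np.nan)

    z = (g - 2 * p[None, :]) / np.sqrt(het_exp)[None, :]
    z_filled = np.where(np.isnan(z), 0.0, z)
    pair_m = obs.astype(float) @ obs.astype(float).T
    r = (z_filled @ z_filled.T) / np.maximum(pair_m, 1)

    ids = matrix.samples["id"].tolist() if "id" in matrix.samples else list(range(len(g)))
    return KinshipResult(
        f_h=pd.Series(f_h, index=ids, name="F_H"),
        r_xy=pd.DataFrame(r, index=ids, columns=ids),
        n_snps_used=int(usable.sum()),
    )


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------


def wc_components(g1: np.ndarray, g2: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir & Cockerham (1984) a, b, c for two populations.

    ``g1``/``g2`` are dosage matrices (individuals x loci) with -1 missing.
    Loci without at least one genotyped diploid per population give NaN.
    """
    comps = []
    ns, ps, hs = [], [], []
    for g in (g1, g2):
        called = g != MISSING
        n_i = called.sum(axis=0).astype(float)
        alt = np.where(called, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(n_i > 0, alt / (2 * n_i), np.nan)
            h_i = np.where(n_i > 0, ((g == 1) & called).sum(axis=0) / n_i, np.nan)
        ns.append(n_i)
        ps.append(p_i)
        hs.append(h_i)
    n1, n2 = ns
    p1, p2 = ps
    h1, h2 = hs
    r = 2.0
    nbar = (n1 + n2) / r
    valid = (n1 >= 1) & (n2 >= 1) & (nbar > 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


def wc_theta(g1: np.ndarray, g2: np.ndarray) -> tuple[float, float]:
    """(ratio-of-sums theta, mean per-locus theta) for one population pair.

    Loci monomorphic across the pair (a+b+c = 0) are skipped.
    """
    a, b, c = wc_components(g1, g2)
    denom = a + b + c
    ok = np.isfinite(denom) & (np.abs(denom) > 1e-300) & (denom != 0)
    informative = ok & (denom > 0)
    if not informative.any():
        return np.nan, np.nan
    theta_sum = float(np.nansum(a[informative]) / np.nansum(denom[informative]))
    per_locus = a[informative] / denom[informative]
    return theta_sum, float(np.mean(per_locus))


def wc_fst(
    matrix: GenotypeMatrix, populations=None, n_perm: int = 10_000, seed=None
) -> FstResult:
    """Pairwise multilocus Weir-Cockerham theta with permutation p-values.

    For each pair, individuals are permuted across the two populations;
    p = (#{theta_perm >= theta_obs} + 1)/(n_perm + 1).
    """
    pops = (list(matrix.samples["population"].unique()) if populations is None
            else list(populations))
    rng = as_rng(seed)
    k = len(pops)
    theta = np.full((k, k), np.nan)
    theta_ml = np.full((k, k), np.nan)
    pvals = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            gi = matrix.subset_population(pops[i]).genotypes
            gj = matrix.subset_population(pops[j]).genotypes
            if len(gi) < 2 or len(gj) < 2:
                raise ValueError("each population needs >= 2 individuals")
            t, tm = wc_theta(gi, gj)
            theta[i, j] = theta[j, i] = t
            theta_ml[i, j] = theta_ml[j, i] = tm
            if n_perm:
                pool = np.vstack([gi, gj])
                n1 = len(gi)
                count = 0
                for _ in range(n_perm):
                    perm = rng.permutation(len(pool))
                    tp, _ = wc_theta(pool[perm[:n1]], pool[perm[n1:]])
                    if tp >= t:
                        count += 1
                p = (count + 1) / (n_perm + 1)
                pvals[i, j] = pvals[j, i] = p
    np.fill_diagonal(theta, 0.0)
    np.fill_diagonal(theta_ml, 0.0)
    return FstResult(
        theta=pd.DataFrame(theta, index=pops, columns=pops),
        theta_mean_loci=pd.DataFrame(theta_ml, index=pops, columns=pops),
        p_values=pd.DataFrame(pvals, index=pops, columns=pops),
    )


# ---------------------------------------------------------------------------
# PCA / KS / regressions
# ---------------------------------------------------------------------------


def genotype_pca(matrix: GenotypeMatrix, scale: bool = False) -> OrdinationResult:
    """PCA of dosages centred by 2*p-hat (optionally scaled by sqrt(2pq)).

    Missing calls are mean-imputed; zero-variance SNPs are dropped.
    """
    g = matrix.genotypes.astype(float)
    g[matrix.genotypes == MISSING] = np.nan
    af = matrix.allele_freq()
    g = np.where(np.isnan(g), (2 * af)[None, :], g)
    keep = np.nanstd(g, axis=0) > 0
    g = g[:, keep]
    af = af[keep]
    gc = g - 2 * af[None, :]
    if scale:
        gc = gc / np.sqrt(2 * af * (1 - af))[None, :]
    return pca(gc)


def ks_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov D and asymptotic p."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need >= 3 values per group")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def founder_regression(founder_families, response_deltas) -> dict[str, float]:
    """OLS of a diversity response change on founder family count."""
    x = np.asarray(founder_families, dtype=float)
    y = np.asarray(response_deltas, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 refuge populations")
    res = stats.linregress(x, y)
    n = x.size
    r2 = res.rvalue**2
    f = r2 / (1 - r2) * (n - 2) if r2 < 1 else np.inf
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r2": float(r2), "F": float(f), "p": float(res.pvalue), "n": int(n)}
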