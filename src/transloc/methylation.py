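"""epiRADseq count analysis.

Read counts at methylation-sensitive RAD loci proxy methylation state: a
methylated cut site yields fewer reads.  The workflow is (in order)
library-batch blacklisting, informative-locus filtering, TMM
normalization, and per-locus negative-binomial GLM likelihood-ratio
tests of a source-vs-refuge contrast, with BH FDR control.  Loci at
FDR < 0.05 are called differentially methylated (DM); the reported
methylation direction is minus the sign of the count log2 fold change.

The NB GLM machinery is vectorized across loci: means follow a log link
with an offset for the effective library size, dispersion phi gives
variance mu + phi mu^2, and the common dispersion maximizes the adjusted
profile likelihood (Cox-Reid style 0.5 log det penalty) on a log-grid,
with empirical-Bayes shrinkage of per-locus dispersions toward it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .containers import CountMatrix
from .utils import bh_adjust

__all__ = [
    "DMResult", "filter_informative", "batch_blacklist", "tmm_normalize",
    "estimate_dispersion", "dm_test", "log_transform", "annotate_loci",
    "nb_glm_fit", "nb_loglik",
]


# ---------------------------------------------------------------------------
# filtering & normalization
# ---------------------------------------------------------------------------


def filter_informative(counts: CountMatrix, min_nonzero_frac: float = 0.33) -> CountMatrix:
    """Keep loci with a nonzero count in >= ceil(frac * n) individuals."""
    if not 0 < min_nonzero_frac <= 1:
        raise ValueError("min_nonzero_frac must be in (0, 1]")
    n = counts.n_individuals
    need = int(np.ceil(min_nonzero_frac * n))
    keep = (counts.counts > 0).sum(axis=0) >= need
    return counts.take_loci(np.flatnonzero(keep))


def tmm_normalize(
    counts: CountMatrix,
    ref: int | None = None,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors (mean log factor 0).

    The reference sample is the one whose upper-quartile count/library
    ratio is closest to the mean (unless ``ref`` is given).  Per sample,
    the factor is the precision-weighted mean of per-locus log2 ratios
    after trimming ``logratio_trim`` from each tail of the M values and
    ``sum_trim`` from each tail of the A values.
    """
    Y = counts.counts.astype(float)
    N = counts.lib_sizes
    if np.any(N <= 0):
        raise ValueError("every sample needs a positive library size")
    n_samp = Y.shape[0]
    if n_samp < 2:
        raise ValueError("need >= 2 samples")
    if ref is None:
        f75 = np.array([np.quantile(Y[i] / N[i], 0.75) for i in range(n_samp)])
        ref = int(np.argmin(np.abs(f75 - f75.mean())))

    log_factors = np.zeros(n_samp)
    yr, nr = Y[ref], N[ref]
    for i in range(n_samp):
        if i == ref:
            continue
        yi, ni = Y[i], N[i]
        both = (yi > 0) & (yr > 0)
        if both.sum() < 10:
            continue
        pi, pr = yi[both] / ni, yr[both] / nr
        M = np.log2(pi / pr)
        A = 0.5 * np.log2(pi * pr)
        w = (ni - yi[both]) / (ni * yi[both]) + (nr - yr[both]) / (nr * yr[both])
        nn = M.size
        rM = stats.rankdata(M, method="ordinal")
        rA = stats.rankdata(A, method="ordinal")
        loM, hiM = np.floor(nn * logratio_trim) + 1, nn - np.floor(nn * logratio_trim)
        loA, hiA = np.floor(nn * sum_trim) + 1, nn - np.floor(nn * sum_trim)
        keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        if keep.any():
            log_factors[i] = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


# ---------------------------------------------------------------------------
# NB GLM core (vectorized across loci)
# ---------------------------------------------------------------------------


def nb_loglik(Y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Per-locus NB log-likelihood summed over samples (Poisson as phi->0)."""
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (Y.shape[0],))[:, None]
    mu = np.maximum(mu, 1e-10)
    small = phi[:, 0] < 1e-8
    ll = np.empty(Y.shape[0])
    if np.any(~small):
        p, y, m = phi[~small], Y[~small], mu[~small]
        inv = 1.0 / p
        ll[~small] = np.sum(
            gammaln(y + inv) - gammaln(inv) - gammaln(y + 1)
            + y * np.log(p * m) - (y + inv) * np.log1p(p * m), axis=1)
    if np.any(small):
        y, m = Y[small], mu[small]
        ll[small] = np.sum(y * np.log(m) - m - gammaln(y + 1), axis=1)
    return ll


def nb_glm_fit(
    Y: np.ndarray,
    X: np.ndarray,
    offsets: np.ndarray,
    phi,
    max_iter: int = 50,
    tol: float = 1e-8,
):
    """IRLS fit of per-locus NB GLMs with log link.

    Parameters
    ----------
    Y : (L, n) counts; X : (n, p) design; offsets : (n,) log effective
    library sizes; phi : scalar or (L,) dispersions.

    Returns
    -------
    beta (L, p), mu (L, n), loglik (L,), converged (L,), xtwx (L, p, p)
    """
    Y = np.asarray(Y, dtype=float)
    L, n = Y.shape
    p = X.shape[1]
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), (L,)).copy()

    z0 = np.log(Y + 0.5) - offsets[None, :]
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T  # (L, p)

    eye = np.eye(p)[None, :, :] * 1e-8
    ll_old = np.full(L, -np.inf)
    converged = np.zeros(L, dtype=bool)
    xtwx = None
    for _ in range(max_iter):
        eta = offsets[None, :] + beta @ X.T
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        W = mu / (1.0 + phi_arr[:, None] * mu)
        z = (eta - offsets[None, :]) + (Y - mu) / mu
        xtwx = np.einsum("ln,np,nq->lpq", W, X, X)
        xtwz = np.einsum("ln,np->lp", W * z, X)
        beta_new = np.linalg.solve(xtwx + eye, xtwz[:, :, None])[:, :, 0]
        beta = beta_new
        ll = nb_loglik(Y, np.exp(np.clip(offsets[None, :] + beta @ X.T, -30, 30)), phi_arr)
        converged = np.abs(ll - ll_old) < tol * (np.abs(ll) + 1)
        if converged.all():
            break
        ll_old = ll
    eta = np.clip(offsets[None, :] + beta @ X.T, -30, 30)
    mu = np.exp(eta)
    ll = nb_loglik(Y, mu, phi_arr)
    W = mu / (1.0 + phi_arr[:, None] * mu)
    xtwx = np.einsum("ln,np,nq->lpq", W, X, X)
    return beta, mu, ll, converged, xtwx


def _apl(Y, X, offsets, phi) -> np.ndarray:
    """Adjusted profile likelihood per locus at a fixed dispersion."""
    _, _, ll, _, xtwx = nb_glm_fit(Y, X, offsets, phi)
    sign, logdet = np.linalg.slogdet(xtwx + np.eye(X.shape[1])[None] * 1e-10)
    return ll - 0.5 * logdet


def estimate_dispersion(
    Y: np.ndarray,
    X: np.ndarray,
    offsets: np.ndarray,
    grid: np.ndarray | None = None,
    prior_df: float = 10.0,
) -> tuple[float, np.ndarray]:
    """(common, tagwise) NB dispersions by adjusted profile likelihood.

    The common dispersion maximizes the summed APL over a log-spaced
    grid (with quadratic interpolation); tagwise estimates maximize the
    per-locus APL plus ``prior_df`` times the average APL, shrinking
    noisy per-locus values toward the common one.
    """
    if Y.shape[1] - X.shape[1] < 2:
        raise ValueError("need >= 2 residual degrees of freedom")
    if grid is None:
        grid = np.logspace(-4, 0.7, 18)
    log_grid = np.log(grid)
    apl = np.stack([_apl(Y, X, offsets, g) for g in grid], axis=1)  # (L, G)

    def _argmax_interp(vals: np.ndarray) -> float:
        j = int(np.argmax(vals))
        if 0 < j < len(vals) - 1:
            y0, y1, y2 = vals[j - 1], vals[j], vals[j + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                dx = 0.5 * (y0 - y2) / denom
                x = log_grid[j] + dx * (log_grid[j + 1] - log_grid[j])
                return float(np.exp(x))
        return float(grid[j])

    common = _argmax_interp(apl.sum(axis=0))
    mean_apl = apl.mean(axis=0)
    shrunk = apl + prior_df * mean_apl[None, :]
    tagwise = np.array([_argmax_interp(shrunk[l]) for l in range(Y.shape[0])])
    return common, tagwise


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------


@dataclass
class DMResult:
    """Per-locus differential-methylation calls for one contrast."""

    table: pd.DataFrame  # locus_id, log2fc, lrt, p, fdr, dm, methylation_direction
    contrast: tuple[str, str]
    dispersion_common: float

    @property
    def dm_locus_ids(self) -> np.ndarray:
        return self.table.loc[self.table["dm"], "locus_id"].to_numpy()


def _design_matrix(labels: np.ndarray) -> np.ndarray:
    levels = np.unique(labels)
    return np.column_stack([np.ones(labels.size)] +
                           [(labels == lv).astype(float) for lv in levels[1:]])


def _lrt_vs_null(Y, X, offsets, phi) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """LRT of a design against intercept-only; returns (lrt, p, beta_full)."""
    beta_f, _, ll_f, conv_f, _ = nb_glm_fit(Y, X, offsets, phi)
    X0 = X[:, :1]
    _, _, ll_0, conv_0, _ = nb_glm_fit(Y, X0, offsets, phi)
    lrt = np.maximum(2.0 * (ll_f - ll_0), 0.0)
    df = X.shape[1] - 1
    p = stats.chi2.sf(lrt, df)
    p[~(conv_f & conv_0)] = np.nan
    return lrt, p, beta_f


def batch_blacklist(
    counts: CountMatrix,
    batch_column: str = "batch",
    fdr: float = 0.05,
    dispersion: float | np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Loci whose counts depend on a library batch factor (NB GLM LRT).

    Fits count ~ batch with a log effective-library-size offset, tests
    each locus against intercept-only, and blacklists loci at BH FDR
    below ``fdr``.  Returns (blacklisted locus indices, per-locus table).
    Re-runnable for successive batch factors (e.g. library, then adapter
    barcode).  Warns via the table attrs when batch is confounded with
    population.
    """
    batch = counts.samples[batch_column].to_numpy()
    levels = np.unique(batch)
    if levels.size < 2:
        tab = pd.DataFrame({"p": [], "fdr": []})
        tab.attrs["warning"] = "single batch level; no-op"
        return np.array([], dtype=int), tab
    X = _design_matrix(batch)
    offsets = np.log(counts.effective_lib_sizes())
    Y = counts.counts.T.astype(float)
    if dispersion is None:
        common, tagwise = estimate_dispersion(Y, X, offsets)
        dispersion = tagwise
    lrt, p, _ = _lrt_vs_null(Y, X, offsets, dispersion)
    q = bh_adjust(p)
    tab = pd.DataFrame({"lrt": lrt, "p": p, "fdr": q}, index=counts.loci.index)
    if "population" in counts.samples:
        ct = pd.crosstab(counts.samples["population"], batch)
        if ((ct > 0).sum(axis=1) == 1).all():
            tab.attrs["warning"] = "batch confounded with population"
    return np.flatnonzero(q < fdr), tab


def dm_test(
    counts: CountMatrix,
    group_a: str,
    group_b: str,
    group_column: str = "population",
    fdr: float = 0.05,
    dispersion: float | np.ndarray | None = None,
) -> DMResult:
    """NB GLM LRT of differential methylation between two groups.

    log2fc is the count fold change of ``group_b`` relative to
    ``group_a``; the methylation direction is its negated sign (fewer
    reads = more methylation).  Loci failing IRLS get p = NaN and are
    excluded from FDR control.
    """
    labels = counts.samples[group_column].to_numpy()
    keep = np.isin(labels, [group_a, group_b])
    sub = counts.take_individuals(np.flatnonzero(keep))
    labels = sub.samples[group_column].to_numpy()
    ind = (labels == group_b).astype(float)
    X = np.column_stack([np.ones(ind.size), ind])
    offsets = np.log(sub.effective_lib_sizes())
    Y = sub.counts.T.astype(float)
    if dispersion is None:
        common, tagwise = estimate_dispersion(Y, X, offsets)
        dispersion = tagwise
    else:
        common = float(np.mean(dispersion))
    lrt, p, beta = _lrt_vs_null(Y, X, offsets, dispersion)
    if group_a == group_b:  # self-contrast: no information, p = 1
        p = np.ones_like(p)
        lrt = np.zeros_like(lrt)
    q = bh_adjust(p)
    log2fc = beta[:, 1] / np.log(2.0)
    table = pd.DataFrame({
        "locus_id": sub.loci["locus_id"].to_numpy()
        if "locus_id" in sub.loci else sub.loci.index.to_numpy(),
        "log2fc": log2fc,
        "lrt": lrt,
        "p": p,
        "fdr": q,
        "dm": q < fdr,
        "methylation_direction": -np.sign(log2fc),
    })
    return DMResult(table=table, contrast=(group_a, group_b),
                    dispersion_common=float(common))


def log_transform(counts: CountMatrix) -> np.ndarray:
    """log2(normalized count + 1) for ordination and heatmaps.

    Normalized count = count / (library size x TMM factor) x mean library
    size, so equal-library-size data are left on the raw count scale.
    """
    eff = counts.effective_lib_sizes()
    norm = counts.counts / eff[:, None] * counts.lib_sizes.mean()
    return np.log2(norm + 1.0)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def annotate_loci(
    loci: pd.DataFrame, gene_intervals: pd.DataFrame, flank: int = 3000
) -> pd.DataFrame:
    """Label loci genic / near-gene / intergenic relative to gene intervals.

    Both tables use 0-based half-open (chrom, start, end).  A locus is
    genic when it overlaps a gene, near-gene when within ``flank`` bp of
    one (but not overlapping), else intergenic; loci on chromosomes
    absent from the annotation are labelled unplaced.
    """
    labels = []
    by_chrom = {c: df for c, df in gene_intervals.groupby("chrom")}
    for _, row in loci.iterrows():
        genes = by_chrom.get(row["chrom"])
        if genes is None:
            labels.append("unplaced")
            continue
        gs = genes["start"].to_numpy()
        ge = genes["end"].to_numpy()
        s, e = row["start"], row["end"]
        if np.any((s < ge) & (e > gs)):
            labels.append("genic")
        elif np.any((s <= ge + flank) & (e >= gs - flank)):
            # a locus whose end sits exactly `flank` bp from a gene start
            # (gap measured between half-open coordinates) still counts
            labels.append("near_gene")
        else:
            labels.append("intergenic")
    out = loci.copy()
    out["context"] = labels
    out.attrs["fractions"] = pd.Series(labels).value_counts(normalize=True).to_dict()
    return out
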