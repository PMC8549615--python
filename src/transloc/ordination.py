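"""Principal component and (partial) redundancy analysis.

A single constrained-ordination engine shared by the genomic, epigenomic
and morphological analyses.  RDA regresses a multivariate centred
response ``Y`` on predictors ``X`` (optionally after removing
conditioning covariates), extracts constrained axes by SVD of the fitted
values, and assesses the model by free row permutation of the
(residualized) response.  Explained variance is summarized as R^2 =
SS(fit)/SS(total) with the Ezekiel small-sample adjustment
``1 - (1 - R^2)(n - 1)/(n - k - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .utils import as_rng, perm_pvalue

__all__ = ["OrdinationResult", "pca", "rda"]


@dataclass
class OrdinationResult:
    """Axes, loadings and fit summaries for a PCA or (p)RDA.

    ``site_scores`` are sample coordinates (weighted-average scores for
    RDA), ``fitted_scores`` the model-fitted (linear-combination) sample
    coordinates, and ``loadings`` the per-variable axis weights used for
    outlier calling.  For an unconstrained PCA ``constrained_axes`` is 0
    and the fit summaries are None.
    """

    site_scores: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    prop_explained: np.ndarray
    constrained_axes: int = 0
    fitted_scores: np.ndarray | None = None
    total_inertia: float = 0.0
    constrained_inertia: float | None = None
    r2: float | None = None
    adj_r2: float | None = None
    perm_p: float | None = None
    pseudo_f: float | None = None
    rank_x: int | None = None

    @property
    def percent_constrained(self) -> np.ndarray | None:
        """Each constrained axis as a percent of constrained variance."""
        if self.constrained_axes == 0:
            return None
        ev = self.eigenvalues[: self.constrained_axes]
        return 100.0 * ev / ev.sum()


def _center(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    return Y - Y.mean(axis=0)


def pca(Y: np.ndarray, scale: bool = False) -> OrdinationResult:
    """PCA of a samples x variables matrix via SVD of the centred data."""
    Yc = _center(Y)
    if Yc.shape[0] < 3:
        raise ValueError("PCA needs at least 3 samples")
    if scale:
        sd = Yc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Yc = Yc / sd
    n = Yc.shape[0]
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    eig = s**2 / (n - 1)
    total = eig.sum()
    prop = eig / total if total > 0 else np.zeros_like(eig)
    return OrdinationResult(
        site_scores=U * s,
        loadings=Vt.T,
        eigenvalues=eig,
        prop_explained=prop,
        constrained_axes=0,
        total_inertia=total,
    )


def _hat_fit(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, int]:
    """Least-squares fitted values of Y on X and the rank of X."""
    B, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    return X @ B, rank


def rda(
    Y: np.ndarray,
    X: np.ndarray,
    condition: np.ndarray | None = None,
    n_perm: int = 1000,
    seed=None,
) -> OrdinationResult:
    """Redundancy analysis of ``Y`` on ``X`` (partial on ``condition``).

    Parameters
    ----------
    Y : (n, m) response matrix; centred internally.
    X : (n, k) explanatory variables; centred internally.
    condition : optional (n, c) conditioning covariates.  Both Y and X are
        residualized on them before fitting (partial RDA).
    n_perm : permutations for the global significance test (0 disables).
    seed : int or Generator for the permutation stream.

    Notes
    -----
    A rank-deficient design is handled by least squares on the pseudo-
    inverse; the effective rank is reported in ``rank_x``.
    """
    Y = _center(Y)
    X = _center(np.atleast_2d(np.asarray(X, dtype=float)))
    if X.ndim == 1:
        X = X[:, None]
    n, m = Y.shape
    if X.shape[0] != n:
        raise ValueError("Y and X must have aligned rows")
    total_inertia = float(np.sum(Y**2))
    n_cond = 0
    if condition is not None:
        C = _center(np.asarray(condition, dtype=float))
        if C.ndim == 1:
            C = C[:, None]
        fitY, rank_c = _hat_fit(C, Y)
        Yr = Y - fitY
        fitX, _ = _hat_fit(C, X)
        Xr = X - fitX
        # predictors numerically absorbed by the condition carry no signal
        scale = np.linalg.norm(X, axis=0)
        keep = np.linalg.norm(Xr, axis=0) > 1e-9 * np.maximum(scale, 1.0)
        Xr = Xr[:, keep] if keep.any() else np.zeros((n, 0))
        n_cond = rank_c
    else:
        Yr, Xr = Y, X

    Yhat, rank_x = _hat_fit(Xr, Yr)
    ss_fit = float(np.sum(Yhat**2))
    ss_work = float(np.sum(Yr**2))
    ss_res = ss_work - ss_fit

    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    n_axes = int(min(rank_x, m))
    s = s[:n_axes]
    V = Vt[:n_axes].T
    eig_c = s**2 / (n - 1)

    # unconstrained axes from the residual matrix
    resid = Yr - Yhat
    s_r = np.linalg.svd(resid, compute_uv=False)
    eig_u = (s_r[s_r > 1e-12] ** 2) / (n - 1)

    eig = np.concatenate([eig_c, eig_u])
    prop = eig / (total_inertia / (n - 1)) if total_inertia > 0 else np.zeros_like(eig)

    r2 = ss_fit / total_inertia if total_inertia > 0 else 0.0
    k = rank_x
    denom = n - k - 1 - n_cond
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1 - n_cond) / denom if denom > 0 else np.nan

    df_res = n - k - n_cond - 1
    if k == 0:
        pseudo_f = np.nan
    elif df_res > 0 and ss_res > 0:
        pseudo_f = (ss_fit / k) / (ss_res / df_res)
    else:
        pseudo_f = np.inf

    perm_p = None
    if n_perm and n_perm > 0 and k > 0:
        rng = as_rng(seed)
        stats_perm = np.empty(n_perm)
        for i in range(n_perm):
            Yp = Yr[rng.permutation(n)]
            Yhat_p, _ = _hat_fit(Xr, Yp)
            ssf = float(np.sum(Yhat_p**2))
            ssr = float(np.sum(Yp**2)) - ssf
            stats_perm[i] = (ssf / k) / (ssr / df_res) if ssr > 0 else np.inf
        perm_p = perm_pvalue(stats_perm, pseudo_f)

    return OrdinationResult(
        site_scores=Yr @ V,
        loadings=V,
        eigenvalues=eig,
        prop_explained=prop,
        constrained_axes=n_axes,
        fitted_scores=Yhat @ V,
        total_inertia=total_inertia / (n - 1),
        constrained_inertia=float(eig_c.sum()),
        r2=r2,
        adj_r2=adj_r2,
        perm_p=perm_p,
        pseudo_f=pseudo_f,
        rank_x=rank_x,
    )
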