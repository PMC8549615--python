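"""Geometric morphometrics: Procrustes superimposition, shape PCA,
allometry ANOVA and phenotypic trajectory analysis.

Body shape is captured as 14 fixed 2-D landmarks per fish.  Generalized
Procrustes analysis (GPA) removes location, scale and orientation;
reflections are disallowed because fish are photographed on one side.
Shape models are fitted as multivariate linear models and assessed with
the randomized residual permutation procedure (RRPP): the residuals of
the reduced model are permuted and the term statistic recomputed, which
respects the sequential (Type I) decomposition.

Trajectory analysis compares the source-to-refuge shape-change vector of
each translocation system: a difference in magnitude (delta L_P) and the
angle between directions (theta_P, degrees), both with permutation
p-values obtained by shuffling the source/refuge labels within systems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ordination import OrdinationResult, pca
from .utils import as_rng, bh_adjust, perm_pvalue

__all__ = [
    "LandmarkConfiguration", "AlignedShapes", "TrajectoryResult",
    "centroid_size", "generalized_procrustes", "shape_pca",
    "allometry_anova", "pairwise_group_tests", "trajectory_analysis",
]

N_LANDMARKS = 14


@dataclass
class LandmarkConfiguration:
    """One individual's landmark configuration.

    ``coords`` are in image units; multiplying by ``scale`` converts to
    millimetres.  ``population`` is the lake label.
    """

    individual_id: str
    coords: np.ndarray
    scale: float = 1.0
    population: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (k, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for {self.individual_id}")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    @property
    def coords_mm(self) -> np.ndarray:
        return self.coords * self.scale

    @property
    def centroid_size(self) -> float:
        return centroid_size(self.coords_mm)


@dataclass
class AlignedShapes:
    """GPA output: unit-size, consensus-aligned configurations.

    ``procrustes_coords`` has shape (n, k, 2); every configuration is
    centred at the origin with unit centroid size.  ``centroid_sizes``
    keeps the pre-alignment sizes in mm.
    """

    procrustes_coords: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    ids: list[str] | None = None

    @property
    def n(self) -> int:
        return self.procrustes_coords.shape[0]

    def flat(self) -> np.ndarray:
        """(n, 2k) flattened coordinates for multivariate models."""
        return self.procrustes_coords.reshape(self.n, -1)


@dataclass
class TrajectoryResult:
    delta_l: float
    theta: float
    p_delta_l: float
    p_theta: float
    trajectories: dict[str, np.ndarray]
    lengths: dict[str, float]


def centroid_size(coords: np.ndarray) -> float:
    """Square root of summed squared landmark distances from the centroid."""
    c = coords - coords.mean(axis=0)
    return float(np.sqrt(np.sum(c**2)))


def _optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimizing ||A R - B||_F."""
    H = A.T @ B
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    return U @ np.diag([1.0, d]) @ Vt


def _as_array(configs) -> tuple[np.ndarray, np.ndarray, list[str] | None]:
    if isinstance(configs, np.ndarray):
        arr = np.asarray(configs, dtype=float)
        sizes = np.array([centroid_size(c) for c in arr])
        return arr, sizes, None
    arr = np.stack([c.coords_mm for c in configs])
    sizes = np.array([c.centroid_size for c in configs])
    ids = [c.individual_id for c in configs]
    return arr, sizes, ids


def generalized_procrustes(
    configs, tol: float = 1e-10, max_iter: int = 100
) -> AlignedShapes:
    """Generalized Procrustes superimposition.

    Each configuration is translated to its centroid, scaled to unit
    centroid size, and iteratively rotated to the evolving consensus
    until the consensus change drops below ``tol``.
    """
    arr, sizes, ids = _as_array(configs)
    n, k, _ = arr.shape
    if n < 2:
        raise ValueError("GPA needs at least 2 configurations")
    if np.any(sizes <= 0):
        bad = int(np.argmax(sizes <= 0))
        raise ValueError(f"degenerate configuration at index {bad} (zero centroid size)")

    X = arr - arr.mean(axis=1, keepdims=True)
    cs = np.sqrt((X**2).sum(axis=(1, 2)))
    X = X / cs[:, None, None]

    consensus = X[0].copy()
    for _ in range(max_iter):
        for i in range(n):
            X[i] = X[i] @ _optimal_rotation(X[i], consensus)
        new = X.mean(axis=0)
        new = new - new.mean(axis=0)
        new = new / np.sqrt(np.sum(new**2))
        if np.sqrt(np.sum((new - consensus) ** 2)) < tol:
            consensus = new
            break
        consensus = new
    # final alignment onto the converged consensus
    for i in range(n):
        X[i] = X[i] @ _optimal_rotation(X[i], consensus)
    return AlignedShapes(X, sizes, X.mean(axis=0), ids)


def shape_pca(aligned: AlignedShapes) -> OrdinationResult:
    """PCA of the flattened, centred Procrustes coordinates."""
    if aligned.n < 3:
        raise ValueError("shape PCA needs at least 3 specimens")
    return pca(aligned.flat())


# ---------------------------------------------------------------------------
# linear shape models with RRPP
# ---------------------------------------------------------------------------


def _group_dummies(groups) -> tuple[np.ndarray, np.ndarray]:
    groups = np.asarray(groups)
    levels = np.unique(groups)
    G = (groups[:, None] == levels[None, 1:]).astype(float)
    return G, levels


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def _model_frames(log_size: np.ndarray, groups) -> list[np.ndarray]:
    """Nested design matrices: intercept, +size, +group, +interaction."""
    n = log_size.size
    one = np.ones((n, 1))
    ls = log_size[:, None]
    G, _ = _group_dummies(groups)
    inter = ls * G
    return [one, np.hstack([one, ls]), np.hstack([one, ls, G]),
            np.hstack([one, ls, G, inter])]


def allometry_anova(
    aligned, sizes, groups, n_perm: int = 1000, seed=None, permutations=None
) -> pd.DataFrame:
    """Sequential multivariate ANOVA for ``Shape ~ log(Size) * Group``.

    Sums of squares are Type I (sequential); the F of each term is tested
    by RRPP with ``n_perm`` iterations.  ``aligned`` may be an
    :class:`AlignedShapes` or any (n, p) response matrix.  An explicit
    array of row permutations may be supplied instead of random draws
    (e.g. the complete enumeration for a tiny sample).
    """
    Y = aligned.flat() if isinstance(aligned, AlignedShapes) else np.asarray(aligned, float)
    sizes = np.asarray(sizes, dtype=float)
    if np.allclose(sizes, sizes[0]):
        raise ValueError("size vector is constant; allometry model is undefined")
    if np.any(sizes <= 0):
        raise ValueError("centroid sizes must be > 0")
    groups = np.asarray(groups)
    _, levels = _group_dummies(groups)
    counts = pd.Series(groups).value_counts()
    if (counts < 3).any():
        raise ValueError("every group needs >= 3 members")
    if permutations is None and n_perm < 99:
        raise ValueError("n_perm must be >= 99")

    log_size = np.log(sizes)
    Xs = _model_frames(log_size, groups)
    hats = [_hat(X) for X in Xs]
    ranks = [np.linalg.matrix_rank(X) for X in Xs]
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0)
    ss_total = float(np.sum(Yc**2))

    def term_stats(Ymat: np.ndarray) -> tuple[np.ndarray, float]:
        proj_ss = np.array([float(np.sum((H @ Ymat) ** 2)) for H in hats])
        ss_terms = np.diff(proj_ss)  # size, group, interaction
        ss_res = float(np.sum(Ymat**2)) - proj_ss[-1]
        return ss_terms, ss_res

    ss_terms, ss_res = term_stats(Y)
    df_terms = np.diff(ranks)
    df_res = n - ranks[-1]
    ms_terms = ss_terms / df_terms
    ms_res = ss_res / df_res
    f_obs = ms_terms / ms_res

    rng = as_rng(seed)
    if permutations is None:
        permutations = [rng.permutation(n) for _ in range(n_perm)]
    else:
        permutations = [np.asarray(p) for p in permutations]
        n_perm = len(permutations)
    exceed = np.zeros(3)
    for perm in permutations:
        for t in range(3):
            fitted = hats[t] @ Y
            resid = Y - fitted
            Yp = fitted + resid[perm]
            ssp, ssrp = term_stats(Yp)
            fp = (ssp[t] / df_terms[t]) / (ssrp / df_res)
            if fp >= f_obs[t]:
                exceed[t] += 1
    pvals = (exceed + 1) / (n_perm + 1)

    rows = []
    for name, df, ss, ms, f, p in zip(
        ["log(Size)", "Group", "log(Size):Group"], df_terms, ss_terms, ms_terms, f_obs, pvals
    ):
        rows.append({"term": name, "df": int(df), "SS": ss, "MS": ms, "F": f, "p": p})
    rows.append({"term": "Residuals", "df": int(df_res), "SS": ss_res, "MS": ms_res,
                 "F": np.nan, "p": np.nan})
    rows.append({"term": "Total", "df": int(n - 1), "SS": ss_total, "MS": np.nan,
                 "F": np.nan, "p": np.nan})
    return pd.DataFrame(rows)


def _group_slopes(Y: np.ndarray, log_size: np.ndarray, groups: np.ndarray) -> dict:
    slopes = {}
    for g in np.unique(groups):
        m = groups == g
        X = np.column_stack([np.ones(m.sum()), log_size[m]])
        B, *_ = np.linalg.lstsq(X, Y[m], rcond=None)
        slopes[g] = B[1]
    return slopes


def _angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    c = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def pairwise_group_tests(
    aligned, sizes, groups, mode: str = "means", n_perm: int = 999, seed=None
) -> pd.DataFrame:
    """Pairwise group comparisons of mean shape or allometric slope.

    mode="means": Procrustes distance between group mean shapes, tested by
    permuting group labels.  mode="slopes": angle (degrees) between group
    allometric vectors, tested by RRPP under the common-slope model.
    BH correction is applied across pairs.
    """
    if mode not in ("means", "slopes"):
        raise ValueError("mode must be 'means' or 'slopes'")
    Y = aligned.flat() if isinstance(aligned, AlignedShapes) else np.asarray(aligned, float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    counts = pd.Series(groups).value_counts()
    if (counts < 3).any():
        raise ValueError("every group needs >= 3 members")
    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
    rng = as_rng(seed)
    n = Y.shape[0]

    if mode == "means":
        def stat_all(Ym, grp):
            means = {g: Ym[grp == g].mean(axis=0) for g in levels}
            return {pr: float(np.linalg.norm(means[pr[0]] - means[pr[1]])) for pr in pairs}

        obs = stat_all(Y, groups)
        exceed = {pr: 0 for pr in pairs}
        for _ in range(n_perm):
            gp = rng.permutation(groups)
            st = stat_all(Y, gp)
            for pr in pairs:
                if st[pr] >= obs[pr]:
                    exceed[pr] += 1
    else:
        sizes = np.asarray(sizes, dtype=float)
        log_size = np.log(sizes)
        X_common = _model_frames(log_size, groups)[2]  # intercept + size + group
        H = _hat(X_common)
        fitted = H @ Y
        resid = Y - fitted

        def stat_all(Ym):
            sl = _group_slopes(Ym, log_size, groups)
            return {pr: _angle_deg(sl[pr[0]], sl[pr[1]]) for pr in pairs}

        obs = stat_all(Y)
        exceed = {pr: 0 for pr in pairs}
        for _ in range(n_perm):
            Yp = fitted + resid[rng.permutation(n)]
            st = stat_all(Yp)
            for pr in pairs:
                if st[pr] >= obs[pr]:
                    exceed[pr] += 1

    raw = np.array([(exceed[pr] + 1) / (n_perm + 1) for pr in pairs])
    adj = bh_adjust(raw)
    return pd.DataFrame({
        "group1": [a for a, _ in pairs],
        "group2": [b for _, b in pairs],
        "statistic": [obs[pr] for pr in pairs],
        "p": raw,
        "p_adj": adj,
    })


def trajectory_analysis(
    aligned, system_labels, type_labels, n_perm: int = 1000, seed=None
) -> TrajectoryResult:
    """Phenotypic trajectory analysis between two translocation systems.

    Per system the trajectory is the mean refuge shape minus the mean
    source shape in the full Procrustes coordinate space.  delta L_P is
    the absolute difference of trajectory lengths and theta_P the angle
    between trajectories in degrees; both are tested by permuting
    source/refuge labels within each system.
    """
    Y = aligned.flat() if isinstance(aligned, AlignedShapes) else np.asarray(aligned, float)
    system_labels = np.asarray(system_labels)
    type_labels = np.asarray(type_labels)
    systems = np.unique(system_labels)
    if systems.size != 2:
        raise ValueError("trajectory analysis compares exactly 2 systems")
    for s in systems:
        present = set(type_labels[system_labels == s])
        if not {"source", "refuge"} <= present:
            raise ValueError(f"system {s!r} is missing a source or refuge level")

    def trajectories(tlab):
        vs = {}
        for s in systems:
            m = system_labels == s
            vs[s] = (Y[m & (tlab == "refuge")].mean(axis=0)
                     - Y[m & (tlab == "source")].mean(axis=0))
        return vs

    def stats(tlab):
        vs = trajectories(tlab)
        vA, vB = vs[systems[0]], vs[systems[1]]
        dl = abs(float(np.linalg.norm(vA)) - float(np.linalg.norm(vB)))
        return dl, _angle_deg(vA, vB), vs

    dl_obs, th_obs, vs_obs = stats(type_labels)
    rng = as_rng(seed)
    dl_perm = np.empty(n_perm)
    th_perm = np.empty(n_perm)
    for i in range(n_perm):
        tlab = type_labels.copy()
        for s in systems:
            m = np.flatnonzero(system_labels == s)
            tlab[m] = tlab[m[rng.permutation(m.size)]]
        dl_perm[i], th_perm[i], _ = stats(tlab)

    return TrajectoryResult(
        delta_l=dl_obs,
        theta=th_obs,
        p_delta_l=perm_pvalue(dl_perm, dl_obs),
        p_theta=perm_pvalue(th_perm, th_obs),
        trajectories={str(s): vs_obs[s] for s in systems},
        lengths={str(s): float(np.linalg.norm(vs_obs[s])) for s in systems},
    )
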