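"""Inter-landmark linear traits, allometric standardization and
nonparametric group comparison.

Linear traits (body depths, head length, fin lengths, ...) are Euclidean
distances between landmark pairs in mm.  Because they scale with body
length, each trait Y is adjusted to a common fork length L_st with the
log-linear common-slope formula

    log10 Y_st = log10 Y_obs + b (log10 L_st - log10 L_obs)

where b is the pooled within-group slope of log10(trait) on log10(length)
from the ANCOVA ``Trait ~ Group * Size`` and L_st is the arithmetic mean
of the measured fork lengths.  Group divergence is then tested trait by
trait with Kruskal-Wallis plus Dunn post hoc tests (BH-corrected).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .utils import bh_adjust

__all__ = [
    "DEFAULT_TRAIT_DEFINITIONS", "interlandmark_traits",
    "allometric_standardize", "kw_dunn_bh",
]

# Default landmark-pair endpoints (0-based indices into the 14-landmark
# scheme).  Users digitizing their own scheme should remap these.
DEFAULT_TRAIT_DEFINITIONS: dict[str, tuple[int, int]] = {
    "head_length": (0, 1),
    "body_depth_anterior": (2, 11),
    "body_depth_posterior": (4, 9),
    "caudal_peduncle_length": (5, 6),
    "caudal_peduncle_depth": (6, 7),
    "dorsal_fin_base": (2, 3),
    "anal_fin_base": (9, 10),
    "pre_pelvic_length": (0, 11),
    "snout_to_dorsal": (0, 2),
    "fork_length": (0, 6),
}


def interlandmark_traits(configs, trait_definitions: dict | None = None) -> pd.DataFrame:
    """Euclidean inter-landmark distances (mm) per individual."""
    defs = DEFAULT_TRAIT_DEFINITIONS if trait_definitions is None else trait_definitions
    rows = []
    for cfg in configs:
        coords = cfg.coords_mm
        k = coords.shape[0]
        row = {"individual_id": cfg.individual_id, "population": cfg.population}
        for name, (i, j) in defs.items():
            if not (0 <= i < k and 0 <= j < k):
                raise ValueError(f"trait {name!r} references missing landmark ({i}, {j})")
            row[name] = float(np.linalg.norm(coords[i] - coords[j]))
        rows.append(row)
    return pd.DataFrame(rows)


def _pooled_slope(log_y: np.ndarray, log_l: np.ndarray, groups: np.ndarray) -> float:
    """Size coefficient of the log10 ANCOVA Trait ~ Group * Size.

    The pooled (common) slope is the Size main effect with groups coded as
    centred contrasts, i.e. the average within-group slope.
    """
    levels = np.unique(groups)
    slopes = []
    weights = []
    for g in levels:
        m = groups == g
        if m.sum() < 2:
            continue
        x = log_l[m] - log_l[m].mean()
        y = log_y[m] - log_y[m].mean()
        sxx = np.dot(x, x)
        if sxx > 0:
            slopes.append(np.dot(x, y) / sxx)
            weights.append(sxx)
    if not slopes:
        raise ValueError("cannot estimate a slope (constant lengths within groups)")
    return float(np.average(slopes, weights=weights))


def allometric_standardize(
    trait_table: pd.DataFrame,
    lengths: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
    trait_columns: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Standardize traits to the mean body length; returns (table, slopes).

    Every trait and length must be strictly positive.
    """
    lengths = np.asarray(lengths, dtype=float)
    groups = np.asarray(groups)
    if np.any(lengths <= 0):
        raise ValueError("lengths must be > 0")
    if trait_columns is None:
        trait_columns = [c for c in trait_table.columns
                         if c not in ("individual_id", "population")]
    if np.unique(groups).size < 2:
        raise ValueError("need >= 2 groups for the ANCOVA")
    log_l = np.log10(lengths)
    l_st = float(lengths.mean())  # average length of all fish examined
    out = trait_table.copy()
    slopes = {}
    for col in trait_columns:
        y = np.asarray(trait_table[col], dtype=float)
        if np.any(y <= 0):
            raise ValueError(f"non-positive values in trait {col!r}")
        b = _pooled_slope(np.log10(y), log_l, groups)
        slopes[col] = b
        out[col] = 10 ** (np.log10(y) + b * (np.log10(l_st) - log_l))
    return out, pd.Series(slopes, name="common_slope")


def _dunn_z(ranks: np.ndarray, groups: np.ndarray, tie_term: float) -> pd.DataFrame:
    levels = np.unique(groups)
    n = ranks.size
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            na, nb = (groups == a).sum(), (groups == b).sum()
            diff = ranks[groups == a].mean() - ranks[groups == b].mean()
            se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb))
            z = diff / se if se > 0 else 0.0
            rows.append({"group1": a, "group2": b, "z": z,
                         "p": 2 * stats.norm.sf(abs(z))})
    return pd.DataFrame(rows)


def kw_dunn_bh(
    traits: pd.DataFrame,
    groups: np.ndarray | pd.Series,
    trait_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Kruskal-Wallis per trait with Dunn post hoc tests, BH across pairs.

    Returns a long table with one row per (trait, pair) carrying the KW H
    and p alongside each Dunn z and BH-adjusted p.  An all-tied trait is
    flagged with p = 1.
    """
    groups = np.asarray(groups)
    levels, counts = np.unique(groups, return_counts=True)
    if levels.size < 2 or np.any(counts < 3):
        raise ValueError("need >= 2 groups with >= 3 observations each")
    if trait_columns is None:
        trait_columns = [c for c in traits.columns
                         if c not in ("individual_id", "population")]
    out = []
    for col in trait_columns:
        y = np.asarray(traits[col], dtype=float)
        if np.all(y == y[0]):
            out.append(pd.DataFrame([{
                "trait": col, "H": 0.0, "kw_p": 1.0, "group1": None, "group2": None,
                "z": np.nan, "p": np.nan, "p_adj": np.nan, "all_tied": True,
            }]))
            continue
        h, kw_p = stats.kruskal(*[y[groups == g] for g in levels])
        ranks = stats.rankdata(y)
        _, tie_counts = np.unique(y, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (y.size - 1))
        dunn = _dunn_z(ranks, groups, tie_term)
        dunn["p_adj"] = bh_adjust(dunn["p"])
        dunn.insert(0, "trait", col)
        dunn.insert(1, "H", h)
        dunn.insert(2, "kw_p", kw_p)
        dunn["all_tied"] = False
        out.append(dunn)
    return pd.concat(out, ignore_index=True)
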