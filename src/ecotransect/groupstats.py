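"""Non-parametric comparison of transition metrics across groups.

Slopes and widths of the detected transitions are compared across boundary
types, months or seasons with the Kruskal-Wallis rank-sum test, followed by
Dunn's test for pairwise contrasts with Bonferroni adjustment, summarised as
a compact letter display.  Mid-ranks are used for ties throughout and the
chi-square approximation is applied even at the small group sizes typical of
a six-month transect study (a documented caveat).
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

__all__ = [
    "kruskal_wallis",
    "dunn_test",
    "compact_letter_display",
    "compare_boundaries",
    "season_of",
]

# southern-hemisphere seasons
_SEASONS = {
    "Dec": "summer", "Jan": "summer", "Feb": "summer",
    "Mar": "autumn", "Apr": "autumn", "May": "autumn",
    "Jun": "winter", "Jul": "winter", "Aug": "winter",
    "Sep": "spring", "Oct": "spring", "Nov": "spring",
}


def season_of(month: str) -> str:
    key = month[:3].capitalize()
    if key not in _SEASONS:
        raise ConfigurationError(f"unknown month label: {month!r}")
    return _SEASONS[key]


def _check_groups(groups: dict) -> dict:
    if len(groups) < 2:
        raise ConfigurationError("need at least 2 groups")
    clean = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size == 0:
            raise ConfigurationError(f"group {name!r} is empty")
        clean[name] = arr
    return clean


def kruskal_wallis(groups: dict) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    clean = _check_groups(groups)
    if sum(a.size for a in clean.values()) < 5:
        warnings.warn("chi-square approximation unreliable for N < 5")
    H, p = stats.kruskal(*clean.values())
    return float(H), float(p)


def dunn_test(groups: dict, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise rank-sum z tests after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt([N(N+1)/12 - sum(t^3 - t)/(12(N-1))] *
    (1/n_i + 1/n_j)), two-sided p from the normal, Bonferroni multiplies by
    the number of pairs (capped at 1).
    """
    if adjust not in ("bonferroni", "none"):
        raise ConfigurationError("adjust must be 'bonferroni' or 'none'")
    clean = _check_groups(groups)
    names = list(clean)
    pooled = np.concatenate([clean[g] for g in names])
    N = pooled.size
    ranks = stats.rankdata(pooled)  # mid-ranks
    mean_rank = {}
    i = 0
    for g in names:
        n_g = clean[g].size
        mean_rank[g] = ranks[i : i + n_g].mean()
        i += n_g
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(tie_counts**3 - tie_counts))
    var_term = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))
    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in combinations(names, 2):
        se = np.sqrt(var_term * (1.0 / clean[a].size + 1.0 / clean[b].size))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, n_pairs * p_raw) if adjust == "bonferroni" else p_raw
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p_raw, "p_adj": p_adj})
    return pd.DataFrame(rows)


def compact_letter_display(
    names: list, pairwise: pd.DataFrame, alpha: float = 0.05, order_by: dict | None = None
) -> dict:
    """Letters such that groups sharing a letter are not significantly different.

    Greedy insert-and-absorb: groups (sorted by ``order_by``, e.g. median)
    join every existing letter class whose members they do not significantly
    differ from; otherwise they open a new class.
    """
    sig = {}
    for _, r in pairwise.iterrows():
        sig[frozenset((r["group_a"], r["group_b"]))] = r["p_adj"] < alpha
    ordered = sorted(names, key=lambda g: -order_by[g]) if order_by else list(names)
    classes: list[set] = []
    for g in ordered:
        placed = False
        for cls in classes:
            if all(not sig.get(frozenset((g, h)), False) for h in cls):
                cls.add(g)
                placed = True
        if not placed:
            classes.append({g})
    letters = {g: "" for g in names}
    for i, cls in enumerate(classes):
        ch = chr(ord("a") + i)
        for g in cls:
            letters[g] += ch
    return letters


def compare_boundaries(
    records: pd.DataFrame,
    metric: str,
    grouping: str = "boundary_type",
    alpha: float = 0.05,
) -> dict:
    """KW + Dunn + letters for one transition metric.

    ``records`` must carry columns ``pair`` (boundary type), ``month`` and the
    metric (``slope_per_km`` or ``transition_width_km``); ``grouping`` is one
    of boundary_type / month / season.  Singleton groups trigger a warning and
    an empty result instead of a test.
    """
    if grouping == "boundary_type":
        key = records["pair"]
    elif grouping == "month":
        key = records["month"]
    elif grouping == "season":
        key = records["month"].map(season_of)
    else:
        raise ConfigurationError(f"unknown grouping: {grouping!r}")
    df = records.dropna(subset=[metric])
    groups = {g: sub[metric].to_numpy() for g, sub in df.groupby(key.loc[df.index])}
    if len(groups) < 2 or any(v.size < 2 for v in groups.values()):
        warnings.warn(f"grouping {grouping!r} has singleton/missing groups; test skipped")
        return {"H": np.nan, "p": np.nan, "dunn": pd.DataFrame(), "letters": {}}
    H, p = kruskal_wallis(groups)
    dunn = dunn_test(groups)
    medians = {g: float(np.median(v)) for g, v in groups.items()}
    letters = compact_letter_display(list(groups), dunn, alpha=alpha, order_by=medians)
    return {"H": H, "p": p, "dunn": dunn, "letters": letters, "medians": medians}
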