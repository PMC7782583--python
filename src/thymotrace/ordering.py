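"""Ordering coreceptor states along a developmental axis.

The headline analysis: do Cd4+Cd8a- selection intermediates appear before
Cd4-Cd8a+ intermediates along the maturation axis (oriented PC1 or a
principal-curve pseudotime)? Per-state positions are summarised as
max-normalised frequency curves and compared with a one-sided two-sample
Kolmogorov-Smirnov test whose direction is fixed a priori
(CD4_state-before-CD8_state). Conditions (wild type versus MHC class
II-deficient) are compared by their verdicts at a significance level.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb, exp
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .embedding import Embedding

_EXACT_MAX_GROUP = 8
_EXACT_MAX_COMB = 50_000


@dataclass
class KSResult:
    d: float
    p: float
    alternative: str
    n_a: int
    n_b: int
    method: str  # "exact" or "asymptotic"


@dataclass
class OrderingResult:
    axis_name: str
    per_state_values: dict[str, np.ndarray]
    curves: dict[str, tuple[np.ndarray, np.ndarray]]
    ks: dict[str, KSResult]
    n_per_state: dict[str, int]


def frequency_curves(
    axis: np.ndarray,
    states: np.ndarray,
    n_bins: int = 20,
    include: Sequence[str] = ("DP_state", "CD4_state", "CD8_state"),
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-state histograms along the axis, normalised to each state's own
    maximal bin count (every curve peaks at exactly 1).

    Bins are equal-width over the pooled range of the included states.
    States with no cells are omitted with a warning.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    axis = np.asarray(axis, dtype=float)
    states = np.asarray(states)
    pool = np.isin(states, include)
    if not pool.any():
        raise ValueError("no cells in any of the included states")
    lo, hi = axis[pool].min(), axis[pool].max()
    if lo == hi:
        hi = lo + 1e-12
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    curves = {}
    for st in include:
        vals = axis[states == st]
        if vals.size == 0:
            warnings.warn(f"state {st} has no cells; omitted from curves", stacklevel=2)
            continue
        hist, _ = np.histogram(vals, bins=edges)
        curves[st] = (centers, hist / hist.max())
    return curves


def _ks_direction_stat(a: np.ndarray, b: np.ndarray, grid: np.ndarray) -> float:
    """sup_x (F_a(x) - F_b(x)) evaluated on the pooled value grid."""
    fa = np.searchsorted(np.sort(a), grid, side="right") / a.size
    fb = np.searchsorted(np.sort(b), grid, side="right") / b.size
    return float(np.max(fa - fb))


def ks_order_test(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "A_before_B",
) -> KSResult:
    """One-sided two-sample KS test of temporal order along an axis.

    ``A_before_B``: the alternative is that sample a sits earlier (is
    stochastically smaller), with statistic D = sup_x (F_a(x) - F_b(x)).
    The p-value is exact (enumeration of all group assignments of the
    pooled values) when the smaller sample has <= 8 observations, and the
    one-sided asymptotic tail exp(-2 D^2 nm/(n+m)) otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("A_before_B", "B_before_A"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if alternative == "B_before_A":
        res = ks_order_test(b, a, "A_before_B")
        return KSResult(res.d, res.p, alternative, a.size, b.size, res.method)
    na, nb = a.size, b.size
    grid = np.unique(np.concatenate([a, b]))
    d_obs = _ks_direction_stat(a, b, grid)

    if min(na, nb) <= _EXACT_MAX_GROUP and comb(na + nb, na) <= _EXACT_MAX_COMB:
        pooled = np.concatenate([a, b])
        n = na + nb
        hits = total = 0
        all_idx = frozenset(range(n))
        for idx in combinations(range(n), na):
            pa = pooled[list(idx)]
            pb = pooled[list(all_idx - set(idx))]
            dp = _ks_direction_stat(pa, pb, grid)
            total += 1
            if dp >= d_obs - 1e-12:
                hits += 1
        return KSResult(d_obs, hits / total, alternative, na, nb, "exact")

    p = min(1.0, exp(-2.0 * d_obs**2 * na * nb / (na + nb)))
    return KSResult(d_obs, p, alternative, na, nb, "asymptotic")


def order_states(
    axis: np.ndarray,
    states: np.ndarray,
    axis_name: str,
    n_bins: int = 20,
    include: Sequence[str] = ("DP_state", "CD4_state", "CD8_state"),
) -> OrderingResult:
    """Summarise and test the order of coreceptor states along an axis.

    The one-sided KS direction is fixed a priori as CD4_state before
    CD8_state (the sequential-expression hypothesis); DN_state cells are
    excluded. Cells of states absent from ``include`` are ignored.
    """
    axis = np.asarray(axis, dtype=float)
    states = np.asarray(states)
    per_state = {st: axis[states == st] for st in include}
    n_per_state = {st: int(v.size) for st, v in per_state.items()}
    curves = frequency_curves(axis, states, n_bins=n_bins, include=include)
    ks = {}
    if n_per_state.get("CD4_state", 0) >= 2 and n_per_state.get("CD8_state", 0) >= 2:
        ks["CD4_before_CD8"] = ks_order_test(
            per_state["CD4_state"], per_state["CD8_state"], "A_before_B"
        )
    else:
        warnings.warn(
            "too few CD4_state/CD8_state cells for the ordering test", stacklevel=2
        )
    return OrderingResult(axis_name, per_state, curves, ks, n_per_state)


def peak_bin(curve: tuple[np.ndarray, np.ndarray]) -> int:
    """Index of the first maximal bin of a normalised frequency curve."""
    centers, freq = curve
    return int(np.argmax(freq))


def centroid_distances(
    emb: Embedding,
    groups: Mapping[str, np.ndarray],
    pcs: Sequence[int] = (1, 3),
) -> pd.DataFrame:
    """Euclidean distances between group centroids in the named PCs.

    Groups are boolean masks or index arrays over the embedding's cells;
    empty groups are an error.
    """
    coords = {}
    for name, mask in groups.items():
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        if idx.size == 0:
            raise ValueError(f"group {name!r} is empty")
        pts = np.column_stack([emb.pc(i)[idx] for i in pcs])
        coords[name] = pts.mean(axis=0)
    names = list(coords)
    out = pd.DataFrame(0.0, index=names, columns=names)
    for x, y in combinations(names, 2):
        d = float(np.linalg.norm(coords[x] - coords[y]))
        out.loc[x, y] = out.loc[y, x] = d
    return out


@dataclass
class ConditionVerdict:
    verdict: str  # "sequential" or "simultaneous"
    p: float
    d: float
    alternative: str


def compare_conditions(
    wt: OrderingResult,
    ko: OrderingResult,
    alpha: float = 0.01,
    ks_key: str = "CD4_before_CD8",
) -> dict[str, ConditionVerdict]:
    """Classify each condition as sequential or simultaneous timing.

    Sequential: the a-priori one-sided KS (CD4_state before CD8_state)
    rejects at ``alpha``; simultaneous otherwise. Both results must come
    from the same axis type.
    """
    if wt.axis_name != ko.axis_name:
        raise ValueError(
            f"ordering results computed on different axes: "
            f"{wt.axis_name!r} vs {ko.axis_name!r}"
        )
    out = {}
    for cond, res in (("WT", wt), ("MHCII_KO", ko)):
        if ks_key not in res.ks:
            raise ValueError(f"{cond}: KS result {ks_key!r} missing")
        ks = res.ks[ks_key]
        verdict = "sequential" if ks.p < alpha else "simultaneous"
        out[cond] = ConditionVerdict(verdict, ks.p, ks.d, ks.alternative)
    return out
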