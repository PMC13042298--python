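"""Desk-scale linkage-group assignment and marker ordering.

Works from phase-known transmission vectors (one entry per meiosis, 0/1
for the transmitted parental haplotype, -1 missing).  Pairwise two-point
estimates feed single-linkage grouping at a LOD threshold and a greedy +
2-opt seriation; cumulative map positions come from adjacent
recombination fractions through the Haldane or Kosambi mapping function.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .containers import MISSING

MAX_CM = 1_000.0  # ceiling for map_distance as r -> 0.5
DEFAULT_LOD_LIMIT = 19.0


@dataclass
class TwoPointEstimate:
    """Maximum-likelihood two-point linkage estimate for one marker pair."""

    pair: tuple
    r_hat: float
    lod: float
    n_informative: int


@dataclass
class LinkageGroupMap:
    lg_id: str
    marker_ids: list
    cum_cM: np.ndarray
    mapping_function: str

    @property
    def length_cM(self) -> float:
        return float(self.cum_cM[-1]) if len(self.cum_cM) else 0.0


# ---------------------------------------------------------------------------
# mapping functions
# ---------------------------------------------------------------------------

def map_distance(r, fn: str = "kosambi"):
    """Map recombination fraction(s) to cM; capped at ``MAX_CM`` near r=0.5."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    with np.errstate(divide="ignore"):
        if fn == "kosambi":
            d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
        elif fn == "haldane":
            d = -50.0 * np.log(1.0 - 2.0 * r)
        else:
            raise ValueError(f"unknown mapping function: {fn}")
    if np.any(d > MAX_CM):
        warnings.warn(f"map distance capped at {MAX_CM} cM (r near 0.5)")
        d = np.minimum(d, MAX_CM)
    return float(d) if d.ndim == 0 else d


def inverse_map_distance(d, fn: str = "kosambi"):
    """Inverse mapping: cM back to recombination fraction."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    if fn == "kosambi":
        r = 0.5 * np.tanh(d / 50.0)
    elif fn == "haldane":
        r = 0.5 * (1.0 - np.exp(-d / 50.0))
    else:
        raise ValueError(f"unknown mapping function: {fn}")
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# two-point estimation
# ---------------------------------------------------------------------------

def pairwise_lod(ta, tb, pair=("A", "B")) -> TwoPointEstimate:
    """Two-point estimate for one pair of transmission vectors.

    Phase (which relabelling of one vector counts as parental) is chosen
    to maximize the LOD, i.e. k = min(#discordant, #concordant).
    """
    ta = np.asarray(ta)
    tb = np.asarray(tb)
    ok = (ta != MISSING) & (tb != MISSING)
    n = int(ok.sum())
    if n == 0:
        return TwoPointEstimate(pair, np.nan, np.nan, 0)
    d = int((ta[ok] != tb[ok]).sum())
    k = min(d, n - d)
    r, lod = _r_lod(k, n)
    return TwoPointEstimate(pair, r, lod, n)


def _r_lod(k, n):
    r = k / n
    # 0*log(0) == 0 convention at the boundary
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(k > 0, k * np.log10(np.maximum(r, 1e-300) / 0.5), 0.0)
        t2 = np.where(n - k > 0, (n - k) * np.log10(np.maximum(1 - r, 1e-300) / 0.5), 0.0)
    return r, t1 + t2


def pairwise_lod_matrix(haps: np.ndarray):
    """All-pairs r-hat and LOD for a (markers x meioses) transmission matrix.

    Returns (r, lod, n) square matrices; entries with no co-scored meioses
    are NaN in ``r``/``lod`` and 0 in ``n``.  Diagonals are r=0, lod=0.
    """
    H = np.asarray(haps, dtype=np.float64)
    valid = (H != MISSING).astype(np.float64)
    X = np.where(H == 1, 1.0, 0.0) * valid
    Y = valid - X                               # indicator of hap 0 (and valid)
    n = valid @ valid.T
    same = X @ X.T + Y @ Y.T
    diff = n - same
    k = np.minimum(diff, same)
    with np.errstate(divide="ignore", invalid="ignore"):
        r, lod = _r_lod(k, np.maximum(n, 1))
    empty = n == 0
    r[empty] = np.nan
    lod[empty] = np.nan
    np.fill_diagonal(lod, 0.0)
    np.fill_diagonal(r, 0.0)
    return r, lod, n.astype(np.int64)


# ---------------------------------------------------------------------------
# grouping and ordering
# ---------------------------------------------------------------------------

def assign_linkage_groups(lod: np.ndarray, lod_limit: float = DEFAULT_LOD_LIMIT):
    """Single-linkage partition: connected components of lod > lod_limit.

    Returns a list of marker-index lists, sorted by decreasing size then
    smallest member, so the output is order-independent and deterministic.
    """
    m = lod.shape[0]
    adj = np.nan_to_num(lod, nan=-np.inf) > lod_limit
    np.fill_diagonal(adj, False)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    groups = [np.flatnonzero(labels == c).tolist() for c in range(labels.max() + 1)]
    return sorted(groups, key=lambda g: (-len(g), g[0]))


def order_markers(group, r: np.ndarray, mapping_function: str = "kosambi",
                  lg_id: str = "LG", marker_ids=None,
                  physical_pos=None) -> LinkageGroupMap:
    """Order one linkage group by greedy seriation plus 2-opt refinement.

    The objective is the sum of adjacent recombination fractions; 2-opt
    moves (segment reversals on the path, implemented as a tour through a
    zero-cost depot) are applied best-first until no move improves.
    Orientation is canonicalized: lower physical position first when
    positions are known, else the smaller endpoint marker index.
    """
    group = list(group)
    m = len(group)
    if m < 2:
        raise ValueError("a linkage group needs at least 2 markers to order")
    sub = r[np.ix_(group, group)].copy()
    disconnected = np.isnan(sub)
    if disconnected.any():
        warnings.warn("unscored pairs in group treated as r=0.5 with a gap")
        sub[disconnected] = 0.5
    order = _greedy_path(sub)
    order = _two_opt(sub, order)

    # canonical orientation
    first, last = group[order[0]], group[order[-1]]
    if physical_pos is not None:
        if physical_pos[first] > physical_pos[last]:
            order = order[::-1]
    elif first > last:
        order = order[::-1]

    adj_r = sub[order[:-1], order[1:]]
    cum = np.concatenate([[0.0], np.cumsum(map_distance(adj_r, mapping_function))])
    ids = [group[i] if marker_ids is None else marker_ids[group[i]] for i in order]
    return LinkageGroupMap(lg_id, ids, cum, mapping_function)


def _greedy_path(r: np.ndarray) -> np.ndarray:
    """Nearest-neighbour chain started from the most peripheral marker."""
    m = r.shape[0]
    start = int(np.argmax(np.nansum(r, axis=1)))   # likely an end of the LG
    order = [start]
    used = np.zeros(m, dtype=bool)
    used[start] = True
    cur = start
    for _ in range(m - 1):
        cand = np.where(used, np.inf, r[cur])
        # ties broken by lower index (argmin returns the first minimum)
        nxt = int(np.argmin(cand))
        order.append(nxt)
        used[nxt] = True
        cur = nxt
    return np.array(order)


def _two_opt(r: np.ndarray, order: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Best-improvement 2-opt on the path, via a tour with a free depot."""
    m = len(order)
    tour = np.concatenate([order, [m]])            # depot index m, cost 0
    R = np.zeros((m + 1, m + 1))
    R[:m, :m] = r
    n = m + 1
    while True:
        t = tour
        nxt = np.roll(t, -1)
        # delta[i, j] for reversing tour[i+1..j]: replace edges (t[i],t[i+1])
        # and (t[j],t[j+1]) by (t[i],t[j]) and (t[i+1],t[j+1])
        gain_new = R[np.ix_(t, t)] + R[np.ix_(nxt, nxt)]
        cost_old = R[t, nxt][:, None] + R[t, nxt][None, :]
        delta = gain_new - cost_old
        iu = np.triu_indices(n, k=1)
        flat = delta[iu]
        best = int(np.argmin(flat))
        if flat[best] >= -tol:
            break
        i, j = iu[0][best], iu[1][best]
        tour[i + 1:j + 1] = tour[i + 1:j + 1][::-1]
    pos = int(np.argmax(tour == m))
    path = np.concatenate([tour[pos + 1:], tour[:pos]])
    return path


def group_lod_sweep(lod: np.ndarray, limits) -> dict:
    """Number of non-singleton groups at each LOD limit (threshold exploration)."""
    out = {}
    for lim in limits:
        groups = assign_linkage_groups(lod, lim)
        out[float(lim)] = sum(1 for g in groups if len(g) > 1)
    return out
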