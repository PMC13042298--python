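"""Region-level recombination comparisons and feature enrichment.

Implements the collinear-vs-inversion rate comparison by label
permutation, 50-kb window feature densities, a relocation-based
enrichment test for interval tracks inside inversions, and a
coverage-ratio classifier for sex-linked contigs.

Empirical p-values always use the add-one rule
p = (1 + #{null at least as extreme}) / (n_perm + 1), so they are never
zero, and every result records its seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .marey import MareyMap

DEFAULT_N_PERM = 1_000
DEFAULT_WINDOW_BP = 50_000


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    statistic: str = ""
    direction: str = ""
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# region recombination rates
# ---------------------------------------------------------------------------

def region_rates(marey: MareyMap, regions: pd.DataFrame) -> pd.DataFrame:
    """cM/Mb for each region, with boundary cM linearly interpolated.

    Regions extending beyond the mapped extent are flagged missing
    (NaN rate) rather than extrapolated.
    """
    rows = []
    for _, reg in regions.iterrows():
        start, end = float(reg["start"]), float(reg["end"])
        if start < marey.bp[0] or end > marey.bp[-1]:
            rate = np.nan
        else:
            cm0, cm1 = np.interp([start, end], marey.bp, marey.cm)
            rate = (cm1 - cm0) / ((end - start) / 1e6)
        rows.append((reg.get("name", f"{reg['lg']}:{int(start)}"), reg["lg"],
                     reg.get("label", ""), start, end, rate))
    return pd.DataFrame(rows, columns=["region", "lg", "label", "start", "end",
                                       "rate_cM_per_Mb"])


def label_permutation_test(rates: pd.DataFrame, n_perm: int = DEFAULT_N_PERM,
                           seed: int = 0) -> PermutationResult:
    """Mean-rate difference (collinear - inversion) under label reshuffles.

    The null reassigns the collinear/inversion labels at random while
    preserving group sizes; the one-sided p asks whether the observed
    excess of collinear over inversion rates could arise by labeling.
    """
    df = rates.dropna(subset=["rate_cM_per_Mb"])
    labels = df["label"].to_numpy()
    vals = df["rate_cM_per_Mb"].to_numpy(dtype=float)
    is_inv = labels == "inversion"
    n_inv = int(is_inv.sum())
    if n_inv == 0 or n_inv == len(vals):
        raise ValueError("both region labels must be present")
    obs = vals[~is_inv].mean() - vals[is_inv].mean()
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(len(vals))
        inv_idx = perm[:n_inv]
        mask = np.zeros(len(vals), dtype=bool)
        mask[inv_idx] = True
        null[i] = vals[~mask].mean() - vals[mask].mean()
    p = (1 + int((null >= obs).sum())) / (n_perm + 1)
    return PermutationResult(float(obs), null, float(p), n_perm, seed,
                             statistic="mean(collinear) - mean(inversion)",
                             direction="suppressed" if obs > 0 else "not suppressed")


# ---------------------------------------------------------------------------
# interval utilities and window densities
# ---------------------------------------------------------------------------

def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Union of half-open intervals as a sorted, non-overlapping array."""
    if len(intervals) == 0:
        return np.empty((0, 2), dtype=np.int64)
    iv = np.asarray(intervals, dtype=np.int64)
    if np.any(iv[:, 0] > iv[:, 1]):
        raise ValueError("negative-length interval")
    iv = iv[np.argsort(iv[:, 0], kind="stable")]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


def _covered_in(merged: np.ndarray, lo: float, hi: float) -> float:
    """Covered bases of a merged interval set inside [lo, hi)."""
    if len(merged) == 0:
        return 0.0
    s = np.clip(merged[:, 0], lo, hi)
    e = np.clip(merged[:, 1], lo, hi)
    return float(np.maximum(0, e - s).sum())


def window_density(features: pd.DataFrame, lg_lengths: dict,
                   window_bp: int = DEFAULT_WINDOW_BP) -> pd.DataFrame:
    """Fraction of each tiling window covered by the feature union.

    Overlapping features are merged before counting, so a base is never
    counted twice; windows tile each LG from 0.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    rows = []
    for lg, L in lg_lengths.items():
        sub = features[features["lg"] == lg]
        iv = sub[["start", "end"]].to_numpy()
        if np.any(iv < 0):
            raise ValueError(f"negative interval coordinate on {lg}")
        merged = merge_intervals(np.clip(iv, 0, L)) if len(iv) else np.empty((0, 2))
        for lo in range(0, int(L), window_bp):
            hi = min(lo + window_bp, int(L))
            cov = _covered_in(merged, lo, hi)
            rows.append((lg, lo, hi, cov, cov / (hi - lo)))
    return pd.DataFrame(rows, columns=["lg", "start", "end", "covered_bp", "density"])


# ---------------------------------------------------------------------------
# enrichment by inversion relocation
# ---------------------------------------------------------------------------

def enrichment_permutation(features: pd.DataFrame, inversions: pd.DataFrame,
                           lg_lengths: dict, n_perm: int = DEFAULT_N_PERM,
                           seed: int = 0) -> PermutationResult:
    """Are inversions enriched or depleted in a feature track?

    Statistic: fraction of total feature bases lying inside inversions.
    Null: every inversion-sized segment is relocated to a uniform random
    start on a uniform random LG (long enough to hold it), rejecting
    overlapping placements.  Reported p is two-sided (doubled smaller
    tail, add-one rule, capped at 1) with the direction labeled.
    """
    merged = {lg: merge_intervals(
        features.loc[features["lg"] == lg, ["start", "end"]].to_numpy())
        for lg in lg_lengths}
    total_bp = sum(_covered_in(m, 0, lg_lengths[lg]) for lg, m in merged.items())
    if total_bp == 0:
        raise ValueError("feature track is empty")
    sizes = (inversions["end"] - inversions["start"]).to_numpy()
    eligible = {int(s): [lg for lg, L in lg_lengths.items() if L > s] for s in sizes}
    for s, lgs in eligible.items():
        if not lgs:
            raise ValueError(f"inversion of {s} bp longer than every LG")
    for _, iv in inversions.iterrows():
        if iv["lg"] not in lg_lengths or iv["end"] > lg_lengths[iv["lg"]]:
            raise ValueError(f"inversion outside genome bounds on {iv['lg']}")

    def inside_fraction(placements):
        tot = 0.0
        for lg, lo, hi in placements:
            tot += _covered_in(merged[lg], lo, hi)
        return tot / total_bp

    obs = inside_fraction(
        [(iv["lg"], iv["start"], iv["end"]) for _, iv in inversions.iterrows()])
    rng = np.random.default_rng(seed)
    lg_list = list(lg_lengths)
    null = np.empty(n_perm)
    for i in range(n_perm):
        placed = []
        for s in sizes:
            for _ in range(1000):
                lg = eligible[int(s)][int(rng.integers(len(eligible[int(s)])))]
                lo = int(rng.integers(0, lg_lengths[lg] - s))
                hi = lo + int(s)
                if all(not (lg == plg and lo < phi and plo < hi)
                       for plg, plo, phi in placed):
                    placed.append((lg, lo, hi))
                    break
            else:
                raise RuntimeError("could not place relocated inversion")
        null[i] = inside_fraction(placed)
    p_hi = (1 + int((null >= obs).sum())) / (n_perm + 1)
    p_lo = (1 + int((null <= obs).sum())) / (n_perm + 1)
    direction = "depleted" if obs < null.mean() else "enriched"
    p = min(1.0, 2.0 * min(p_hi, p_lo))
    return PermutationResult(float(obs), null, float(p), n_perm, seed,
                             statistic="feature bp fraction inside inversions",
                             direction=direction,
                             extra={"p_enriched": p_hi, "p_depleted": p_lo})


# ---------------------------------------------------------------------------
# coverage-based sex linkage
# ---------------------------------------------------------------------------

X_MALE_BAND = (0.4, 0.6)
AUTOSOMAL_BAND = (0.85, 1.15)


def sex_linkage_scan(coverage: pd.DataFrame, sexes: dict,
                     male_band=X_MALE_BAND,
                     autosomal_band=AUTOSOMAL_BAND) -> pd.DataFrame:
    """Classify contigs as autosomal / X-linked / ambiguous by depth ratio.

    ``coverage`` is individuals x contigs, normalized so each individual's
    autosomal median depth is 1.0.  A contig at half depth in males and
    full depth in females behaves as X-linked; half depth in both sexes is
    the unresolved (putative-Y-like) pattern and stays ambiguous.
    """
    males = [i for i, s in sexes.items() if s == "male"]
    females = [i for i, s in sexes.items() if s == "female"]
    if not males or not females:
        raise ValueError("need at least one individual of each sex")
    rows = []
    for contig in coverage.columns:
        m = float(coverage.loc[males, contig].median())
        f = float(coverage.loc[females, contig].median())
        if male_band[0] <= m <= male_band[1] and autosomal_band[0] <= f <= autosomal_band[1]:
            cls = "X-linked"
        elif (autosomal_band[0] <= m <= autosomal_band[1]
              and autosomal_band[0] <= f <= autosomal_band[1]):
            cls = "autosomal"
        else:
            cls = "ambiguous"
        rows.append((contig, m, f, cls))
    return pd.DataFrame(rows, columns=["contig", "male_median", "female_median",
                                       "classification"])
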