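"""Marey maps, sliding-window recombination rates and map summaries.

A Marey map plots cumulative genetic position (cM) against physical
position (bp); its local slope is the recombination rate in cM/Mb.
Local rates are estimated by ordinary least squares inside fixed-width
windows that tile each linkage group; large jumps in genetic distance
between adjacent markers flag candidate misassemblies.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

DEFAULT_GAP_CM = 10.0
AUTOSOMES = [str(i) for i in range(1, 16)]   # LG1..LG15; LG16 is the X


@dataclass
class MareyMap:
    lg_id: str
    bp: np.ndarray              # strictly increasing after de-duplication
    cm: np.ndarray
    n_monotonic_violations: int = 0

    @property
    def span_bp(self) -> int:
        return int(self.bp[-1] - self.bp[0])


def build_marey(physical_bp, cum_cM, lg_id: str = "LG") -> MareyMap:
    """Assemble a Marey map from per-marker physical and genetic positions.

    Markers sharing a physical position are collapsed to their mean cM.
    Monotonicity violations (cM decreasing with bp) are kept but counted,
    as a diagnostic of ordering/anchoring disagreement.
    """
    bp = np.asarray(physical_bp, dtype=np.int64)
    cm = np.asarray(cum_cM, dtype=float)
    order = np.argsort(bp, kind="stable")
    bp, cm = bp[order], cm[order]
    uniq, inverse = np.unique(bp, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 distinct physical positions")
    mean_cm = np.bincount(inverse, weights=cm) / np.bincount(inverse)
    violations = int((np.diff(mean_cm) < 0).sum())
    return MareyMap(lg_id, uniq, mean_cm, violations)


def sliding_rate(marey: MareyMap, window_bp: int | None = None) -> pd.DataFrame:
    """OLS recombination rate (cM/Mb) in windows tiling the mapped extent.

    Default window is 1/20 of the LG span, fixed per LG.  Windows with
    fewer than 2 points get a missing rate; negative slopes clamp to 0
    (raw slope kept in ``raw_slope``).  The final partial window is kept
    when it holds at least 2 points.
    """
    if window_bp is None:
        window_bp = max(1, marey.span_bp // 20)
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    start0 = int(marey.bp[0])
    edges = np.arange(start0, marey.bp[-1] + window_bp, window_bp)
    rows = []
    mb = marey.bp / 1e6
    lows = edges[:-1] if len(edges) > 1 else [start0]
    for i, lo in enumerate(lows):
        hi = lo + window_bp
        # final window closes on the right so the last marker is covered
        inside = (marey.bp >= lo) & ((marey.bp <= hi) if i == len(lows) - 1
                                     else (marey.bp < hi))
        n = int(inside.sum())
        if n >= 2 and np.ptp(marey.bp[inside]) > 0:
            slope = np.polyfit(mb[inside], marey.cm[inside], 1)[0]
            rows.append((lo, hi, max(0.0, slope), slope, n))
        else:
            rows.append((lo, hi, np.nan, np.nan, n))
    return pd.DataFrame(rows, columns=["start", "end", "rate", "raw_slope", "n_points"])


def detect_breaks(marey: MareyMap, gap_cM: float = DEFAULT_GAP_CM) -> np.ndarray:
    """Midpoints of adjacent-marker intervals with |dcM| above the threshold.

    Large jumps in genetic distance between physically adjacent markers
    are the signature of a misjoined contig; the returned positions are
    candidate cut points.
    """
    jump = np.abs(np.diff(marey.cm)) > gap_cM
    mid = (marey.bp[:-1] + marey.bp[1:]) / 2.0
    return mid[jump]


# ---------------------------------------------------------------------------
# per-LG map summary (Table-1-style)
# ---------------------------------------------------------------------------

@dataclass
class MapSummary:
    per_lg: pd.DataFrame
    totals: dict
    correlations: dict


def load_reference_map_table() -> pd.DataFrame:
    """Packaged per-LG summary of the published bark-beetle linkage map."""
    with resources.files("recland.data").joinpath("table1.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", na_values="NA",
                         dtype={"lg": str})
    return df


def map_summary(table: pd.DataFrame, autosomes=None) -> MapSummary:
    """Totals, per-LG rates, and length/size correlations from a map table.

    Expects one row per LG with columns ``lg``, ``sexavg_cM``,
    ``sexavg_markers``, ``length_Mb`` and optionally ``male_*`` /
    ``female_*``.  Rates are cM/Mb ratios; the overall mean rate is total
    cM over total Mb.  Pearson r^2 is reported for (rate vs Mb) and
    (cM vs Mb) over all LGs.
    """
    required = {"lg", "sexavg_cM", "sexavg_markers", "length_Mb"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"map table lacks columns: {sorted(missing)}")
    df = table.copy()
    if autosomes is None:
        autosomes = [lg for lg in AUTOSOMES if lg in set(df["lg"])]
    absent = [lg for lg in autosomes if lg not in set(df["lg"])]
    if absent:
        raise ValueError(f"missing LG rows: {absent}")
    df["rate_cM_per_Mb"] = df["sexavg_cM"] / df["length_Mb"]
    auto = df[df["lg"].isin(autosomes)]

    totals = {
        "autosomal_cM": float(auto["sexavg_cM"].sum()),
        "autosomal_markers": int(auto["sexavg_markers"].sum()),
        "total_cM": float(df["sexavg_cM"].sum()),
        "total_markers": int(df["sexavg_markers"].sum()),
        "total_Mb": float(df["length_Mb"].sum()),
        "mean_rate_cM_per_Mb": float(df["sexavg_cM"].sum() / df["length_Mb"].sum()),
        "rate_min": float(df["rate_cM_per_Mb"].min()),
        "rate_max": float(df["rate_cM_per_Mb"].max()),
    }
    for sex in ("male", "female"):
        if f"{sex}_cM" in df.columns:
            sub = auto.dropna(subset=[f"{sex}_cM"])
            totals[f"{sex}_autosomal_cM"] = float(sub[f"{sex}_cM"].sum())
            totals[f"{sex}_autosomal_markers"] = int(sub[f"{sex}_markers"].sum())

    def _r2(x, y):
        return float(np.corrcoef(x, y)[0, 1] ** 2)

    correlations = {
        "r2_rate_vs_Mb": _r2(df["rate_cM_per_Mb"], df["length_Mb"]),
        "r2_cM_vs_Mb": _r2(df["sexavg_cM"], df["length_Mb"]),
    }
    return MapSummary(df, totals, correlations)
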