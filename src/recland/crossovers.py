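"""Crossover counting from phased transmissions and the suppression test.

A crossover shows up as a switch between consecutive non-missing entries
of a parent's transmitted-haplotype vector; the event is localized to the
interval between the two flanking informative markers.  Event counts are
weighted by 1/(family offspring count) before comparing inversion
heterokaryotypes with homokaryotypes (pooled) by a one-sided Wilcoxon
rank-sum test.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, TransmissionTable

EVENT_COLUMNS = ["offspring_id", "family_id", "parent", "lg", "left", "right", "mid"]


def count_crossovers(hapvec, positions=None):
    """Count haplotype switches in one ordered transmission vector.

    Missing entries are skipped; the count is the number of adjacent
    non-missing pairs with different haplotypes.  When ``positions`` is
    given, each event's flanking-marker interval (left bp, right bp) is
    returned as well.
    """
    h = np.asarray(hapvec)
    ok = h != MISSING
    hh = h[ok]
    if len(hh) < 2:
        return 0, np.empty((0, 2), dtype=np.int64)
    switch = hh[:-1] != hh[1:]
    count = int(switch.sum())
    if positions is None:
        return count, np.empty((0, 2), dtype=np.int64)
    pos = np.asarray(positions)[ok]
    intervals = np.column_stack([pos[:-1][switch], pos[1:][switch]])
    return count, intervals


def collect_events(tt: TransmissionTable) -> pd.DataFrame:
    """All crossover events in a transmission table, one row per event."""
    rows = []
    for b in tt:
        for j, off in enumerate(b.offspring_ids):
            _, iv = count_crossovers(b.haps[:, j], b.positions)
            for left, right in iv:
                rows.append((off, b.family_id, b.parent, b.lg,
                             int(left), int(right), (left + right) / 2.0))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def assign_events(events: pd.DataFrame, regions: pd.DataFrame,
                  family_sizes: dict, rule: str = "midpoint") -> pd.DataFrame:
    """Per (region, family, parent) raw and offspring-weighted event counts.

    An event belongs to a region when its interval midpoint lies in the
    half-open region (``rule="midpoint"``, the default) or when the
    interval overlaps it at all (``rule="overlap"``).  Weighted counts
    divide by the family's offspring count.
    """
    if rule not in ("midpoint", "overlap"):
        raise ValueError(f"unknown assignment rule: {rule}")
    known_lgs = set(events["lg"]) if len(events) else set()
    rows = []
    for _, reg in regions.iterrows():
        if len(events) and reg["lg"] not in known_lgs:
            raise ValueError(f"region {reg.get('name', '?')} on unknown LG {reg['lg']}")
        on_lg = events[events["lg"] == reg["lg"]]
        if rule == "midpoint":
            hit = on_lg[(on_lg["mid"] >= reg["start"]) & (on_lg["mid"] < reg["end"])]
        else:
            hit = on_lg[(on_lg["left"] < reg["end"]) & (on_lg["right"] > reg["start"])]
        for (fam, parent), sub in hit.groupby(["family_id", "parent"]):
            rows.append((reg.get("name", f"{reg['lg']}:{reg['start']}"), reg["lg"],
                         fam, parent, len(sub), len(sub) / family_sizes[fam]))
        # emit explicit zero rows for families/parents with no events here
        seen = set(map(tuple, hit[["family_id", "parent"]].itertuples(index=False)))
        for fam, size in family_sizes.items():
            for parent in ("father", "mother"):
                if (fam, parent) not in seen:
                    rows.append((reg.get("name", f"{reg['lg']}:{reg['start']}"),
                                 reg["lg"], fam, parent, 0, 0.0))
    return pd.DataFrame(rows, columns=["region", "lg", "family_id", "parent",
                                       "count", "weighted_count"])


@dataclass
class SuppressionTestResult:
    statistic: float            # Mann-Whitney U of the heterokaryotype group
    p_value: float
    n_het: int
    n_hom: int
    method: str
    alternative: str


def het_suppression_test(weighted_counts: pd.DataFrame, karyotypes: dict,
                         alternative: str = "less") -> SuppressionTestResult:
    """Wilcoxon rank-sum test of heterokaryotype vs pooled homokaryotypes.

    ``weighted_counts`` is the output of :func:`assign_events` restricted
    to inversion regions; ``karyotypes[family][parent][region]`` gives the
    parent's arrangement copy number (0/1/2).  Observations are pooled
    over inversions and parents; both homozygote classes form one group.
    The default alternative is one-sided (het < hom), matching the
    directional suppression hypothesis.
    """
    het, hom = [], []
    for _, row in weighted_counts.iterrows():
        kt = karyotypes[row["family_id"]][row["parent"]].get(row["region"])
        if kt is None:
            continue
        (het if kt == 1 else hom).append(row["weighted_count"])
    if not het or not hom:
        empty = "heterokaryotype" if not het else "homokaryotype"
        raise ValueError(f"{empty} group is empty")
    return _rank_sum(np.asarray(het), np.asarray(hom), alternative)


def _rank_sum(het, hom, alternative="less") -> SuppressionTestResult:
    small = len(het) <= 10 and len(hom) <= 10
    if small:
        # full enumeration of group assignments (ties handled correctly):
        # C(20,10) = 184,756 fits comfortably under the resample cap
        method = stats.PermutationMethod(n_resamples=250_000)
        label = "exact"
    else:
        method = "asymptotic"   # normal approximation with tie correction
        label = "asymptotic"
    res = stats.mannwhitneyu(het, hom, alternative=alternative, method=method)
    return SuppressionTestResult(float(res.statistic), float(res.pvalue),
                                 len(het), len(hom), label, alternative)
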