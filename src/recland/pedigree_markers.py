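"""Parental informativeness calls and marker filtering.

A marker is informative for a parent when that parent is heterozygous
(its transmissions then reveal the parent's recombination events):
paternal when only the father is het, maternal when only the mother is,
"both" when both are, "none" otherwise.  Offspring genotypes impossible
under Mendelian transmission invalidate the marker in that family.

Filters mirror the standard multi-family mapping recipe: minor-allele
frequency, segregation-distortion (per-family chi-square against the
Mendelian ratio for the cross type), missingness, and a requirement that
the marker be informative in a minimum number of families.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, GenotypeMatrix

_ALLELES = {0: (0,), 1: (0, 1), 2: (1,)}


@dataclass
class InformativeMarker:
    marker_id: str
    family_id: str
    informativeness: str        # paternal | maternal | both | none
    maf: float                  # across offspring of all families
    missing_fraction: float     # within this family's offspring
    segregation_p: float


def _legal_offspring(father: int, mother: int) -> set:
    return {fa + ma for fa in _ALLELES[father] for ma in _ALLELES[mother]}


def _classify(father: int, mother: int) -> str:
    if father == MISSING or mother == MISSING:
        return "none"
    f_het, m_het = father == 1, mother == 1
    if f_het and m_het:
        return "both"
    if f_het:
        return "paternal"
    if m_het:
        return "maternal"
    return "none"


def _segregation_p(off: np.ndarray, father: int, mother: int, kind: str) -> float:
    """Chi-square goodness of fit against the Mendelian ratio for the cross."""
    off = off[off != MISSING]
    if len(off) == 0:
        return 1.0
    if kind == "both":
        classes, ratio = (0, 1, 2), (1, 2, 1)
    elif kind == "paternal":
        classes = (0, 1) if mother == 0 else (1, 2)
        ratio = (1, 1)
    elif kind == "maternal":
        classes = (0, 1) if father == 0 else (1, 2)
        ratio = (1, 1)
    else:
        return 1.0
    counts = np.array([(off == c).sum() for c in classes], dtype=float)
    expected = np.array(ratio, dtype=float) / sum(ratio) * counts.sum()
    stat = ((counts - expected) ** 2 / expected).sum()
    return float(stats.chi2.sf(stat, df=len(classes) - 1))


def call_informative(gm: GenotypeMatrix, pedigree: pd.DataFrame) -> list:
    """Classify every marker's informativeness in every family.

    ``pedigree`` needs columns family, id, father, mother (parents have
    empty/NaN father+mother).  Unknown individuals raise.  Markers whose
    offspring contain a Mendelian impossibility are set to "none" for
    that family.
    """
    sample_idx = {s: i for i, s in enumerate(gm.samples)}
    for ind in pedigree["id"]:
        if ind not in sample_idx:
            raise ValueError(f"pedigree individual not in genotype matrix: {ind}")
    g = gm.genotypes
    out = []
    fams = []
    for fam, sub in pedigree.groupby("family"):
        parents = sub[sub["father"].isna() | (sub["father"] == "")]
        kids = sub.drop(parents.index)
        father_id = kids["father"].iloc[0]
        mother_id = kids["mother"].iloc[0]
        for pid in (father_id, mother_id):
            if pid not in sample_idx:
                raise ValueError(f"pedigree individual not in genotype matrix: {pid}")
        fams.append((str(fam), sample_idx[father_id], sample_idx[mother_id],
                     [sample_idx[k] for k in kids["id"]]))

    all_kid_cols = sorted({k for *_, kids in fams for k in kids})
    off_all = g[:, all_kid_cols]
    called = off_all != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, off_all, 0).sum(axis=1) / np.maximum(
            2 * called.sum(axis=1), 1)
    maf_all = np.minimum(p, 1 - p)

    for fam, fi, mi, kid_cols in fams:
        off = g[:, kid_cols]
        miss = (off == MISSING).mean(axis=1)
        for i in range(gm.n_sites):
            father, mother = int(g[i, fi]), int(g[i, mi])
            kind = _classify(father, mother)
            if kind != "none":
                legal = _legal_offspring(father, mother)
                seen = set(int(x) for x in off[i][off[i] != MISSING])
                if not seen <= legal:
                    kind = "none"
            seg_p = _segregation_p(off[i], father, mother, kind)
            out.append(InformativeMarker(
                marker_id=f"{gm.chrom[i]}:{gm.pos[i]}", family_id=fam,
                informativeness=kind, maf=float(maf_all[i]),
                missing_fraction=float(miss[i]), segregation_p=seg_p))
    return out


def filter_markers(markers: list, maf_min: float = 0.1, seg_alpha: float = 0.01,
                   missing_limit: float = 0.1,
                   family_informative_limit: int = 2) -> list:
    """Retain markers passing all filters (a pure conjunction).

    A marker is kept iff MAF >= maf_min, its smallest per-family
    segregation p-value is >= seg_alpha, its largest per-family
    missingness is <= missing_limit, and it is informative (not "none")
    in at least ``family_informative_limit`` families.  Returns the
    records of retained markers.
    """
    if not markers:
        warnings.warn("no markers to filter")
        return []
    by_marker = {}
    for m in markers:
        by_marker.setdefault(m.marker_id, []).append(m)
    kept = []
    for mid, recs in by_marker.items():
        informative = [r for r in recs if r.informativeness != "none"]
        if len(informative) < family_informative_limit:
            continue
        if recs[0].maf < maf_min:
            continue
        if max(r.missing_fraction for r in recs) > missing_limit:
            continue
        if min(r.segregation_p for r in informative) < seg_alpha:
            continue
        kept.extend(recs)
    return kept


def markers_to_frame(markers: list) -> pd.DataFrame:
    return pd.DataFrame([vars(m) for m in markers])
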