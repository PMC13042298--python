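"""Shared in-memory containers for the pipeline.

Coordinates are 0-based half-open everywhere inside the package; 1-based
conventions (VCF, inclusive inversion tables) are converted at I/O
boundaries only.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

MISSING = -1  # missing genotype / haplotype code in integer matrices


@dataclass
class GenotypeMatrix:
    """Biallelic genotype matrix, sites x individuals.

    Genotypes are alternate-allele dosages in {0, 1, 2}, with -1 for
    missing.  ``dp``/``gq`` are optional per-genotype depth and quality
    matrices of the same shape.  ``n_alleles`` flags sites that were not
    biallelic in the source (kept so that site filters can drop them).
    """

    chrom: np.ndarray          # (n_sites,) str
    pos: np.ndarray            # (n_sites,) int, 0-based
    genotypes: np.ndarray      # (n_sites, n_samples) int8
    samples: list[str]
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None
    dp: np.ndarray | None = None
    gq: np.ndarray | None = None
    n_alleles: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        if self.genotypes.shape != (len(self.pos), len(self.samples)):
            raise ValueError("genotype matrix shape does not match pos/samples")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def take_sites(self, idx) -> "GenotypeMatrix":
        def _sub(a):
            return None if a is None else a[idx]
        return GenotypeMatrix(
            chrom=self.chrom[idx], pos=self.pos[idx],
            genotypes=self.genotypes[idx], samples=list(self.samples),
            ref=_sub(self.ref), alt=_sub(self.alt),
            dp=_sub(self.dp), gq=_sub(self.gq), n_alleles=_sub(self.n_alleles),
        )

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per site over non-missing genotypes."""
        g = self.genotypes
        called = g != MISSING
        n = 2 * called.sum(axis=1)
        alt = np.where(called, g, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / n, np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)


@dataclass
class TransmissionBlock:
    """Phased transmissions of one parent on one linkage group.

    ``haps[i, j]`` is the parental haplotype (0 or 1, -1 missing)
    transmitted to offspring ``j`` at the informative marker at
    ``positions[i]``; positions are sorted ascending.
    """

    family_id: str
    parent: str                 # "father" | "mother"
    lg: str
    positions: np.ndarray       # (n_markers,) int bp
    haps: np.ndarray            # (n_markers, n_offspring) int8
    offspring_ids: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haps = np.asarray(self.haps, dtype=np.int8)
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("transmission positions must be sorted")


@dataclass
class TransmissionTable:
    """Collection of per-(family, parent, LG) transmission blocks."""

    blocks: dict = field(default_factory=dict)  # (family, parent, lg) -> TransmissionBlock

    def add(self, block: TransmissionBlock) -> None:
        self.blocks[(block.family_id, block.parent, block.lg)] = block

    def __iter__(self) -> Iterator[TransmissionBlock]:
        return iter(self.blocks[k] for k in sorted(self.blocks))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in self:
            m, n = b.haps.shape
            rows.append(pd.DataFrame({
                "offspring_id": np.repeat(b.offspring_ids, m),
                "family_id": b.family_id,
                "parent": b.parent,
                "lg": b.lg,
                "pos": np.tile(b.positions, n),
                "hap": b.haps.T.reshape(-1),
            }))
        if not rows:
            return pd.DataFrame(
                columns=["offspring_id", "family_id", "parent", "lg", "pos", "hap"])
        return pd.concat(rows, ignore_index=True)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df["hap"] = df["hap"].map(lambda h: "NA" if h == MISSING else str(int(h)))
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TransmissionTable":
        tt = cls()
        hap = df["hap"].replace("NA", MISSING).astype(np.int8) \
            if df["hap"].dtype == object else df["hap"].astype(np.int8)
        df = df.assign(hap=hap)
        for (fam, parent, lg), sub in df.groupby(["family_id", "parent", "lg"], sort=True):
            piv = sub.pivot_table(index="pos", columns="offspring_id", values="hap",
                                  aggfunc="first", fill_value=MISSING)
            tt.add(TransmissionBlock(
                family_id=str(fam), parent=str(parent), lg=str(lg),
                positions=piv.index.to_numpy(),
                haps=piv.to_numpy(dtype=np.int8),
                offspring_ids=[str(c) for c in piv.columns],
            ))
        return tt

    @classmethod
    def from_tsv(cls, path) -> "TransmissionTable":
        df = pd.read_csv(path, sep="\t", dtype={"hap": object})
        df["hap"] = df["hap"].map(lambda h: MISSING if str(h) == "NA" else int(h))
        return cls.from_frame(df)


REGION_COLUMNS = ["lg", "start", "end"]


def make_regions(records, label: str | None = None) -> pd.DataFrame:
    """Build a region table (0-based half-open) from (lg, start, end[, name]) tuples."""
    df = pd.DataFrame(records, columns=REGION_COLUMNS + (["name"] if records and len(records[0]) > 3 else []))
    if "name" not in df.columns:
        df["name"] = [f"region{i}" for i in range(len(df))]
    if label is not None:
        df["label"] = label
    bad = df["start"] >= df["end"]
    if bad.any():
        raise ValueError(f"empty/negative region(s): rows {list(df.index[bad])}")
    return df
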