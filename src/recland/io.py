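"""Readers and writers for the pipeline's on-disk formats.

VCF is read through cyvcf2 and written as minimal VCF 4.2 text with
GT:DP:GQ.  Regions travel as 3+ column BED (0-based half-open);
transmissions, maps, rate tracks and reports are TSV.  VCF positions are
1-based in the file and 0-based in memory; the conversion happens here
and nowhere else.
"""
from __future__ import annotations

import hashlib
import warnings

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import MISSING, GenotypeMatrix


def read_genotypes(path) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF into a GenotypeMatrix.

    Indels and non-SNP records are skipped (counted in the returned
    matrix's skip note via a warning); multi-allelic SNPs are loaded with
    ``n_alleles`` recorded so site filters can drop them.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, poss, refs, alts, nall = [], [], [], [], []
    gts, dps, gqs = [], [], []
    skipped = 0
    for var in vcf:
        if not var.is_snp:
            skipped += 1
            continue
        chroms.append(var.CHROM)
        poss.append(var.POS - 1)               # to 0-based
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
        nall.append(1 + len(var.ALT))
        g = np.asarray(var.genotype.array())[:, :2]
        dose = np.where((g < 0).any(axis=1), MISSING, (g > 0).sum(axis=1))
        gts.append(dose.astype(np.int8))
        for field, store in (("DP", dps), ("GQ", gqs)):
            try:
                val = var.format(field)
            except KeyError:
                val = None
            store.append(val[:, 0] if val is not None
                         else np.full(len(samples), -1))
    vcf.close()
    if skipped:
        warnings.warn(f"skipped {skipped} non-SNP record(s)")
    if not poss:
        raise ValueError(f"no SNP records in {path}")
    dp = np.vstack(dps).astype(np.int32)
    gq = np.vstack(gqs).astype(np.int32)
    return GenotypeMatrix(
        chrom=np.array(chroms, dtype=object), pos=np.array(poss),
        genotypes=np.vstack(gts), samples=samples,
        ref=np.array(refs, dtype=object), alt=np.array(alts, dtype=object),
        dp=None if (dp < 0).all() else dp,
        gq=None if (gq < 0).all() else gq,
        n_alleles=np.array(nall))


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_genotypes(gm: GenotypeMatrix, path, contig_lengths: dict | None = None,
                    header_extra: list | None = None) -> None:
    """Write a GenotypeMatrix as minimal VCF 4.2 (GT:DP:GQ)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=recland\n")
        for line in header_extra or []:
            fh.write(f"##{line}\n")
        contigs = (contig_lengths or
                   {c: int(gm.pos[gm.chrom == c].max()) + 2
                    for c in dict.fromkeys(gm.chrom)})
        for c, L in contigs.items():
            fh.write(f"##contig=<ID={c},length={L}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        ref = gm.ref if gm.ref is not None else np.full(gm.n_sites, "A", dtype=object)
        alt = gm.alt if gm.alt is not None else np.full(gm.n_sites, "T", dtype=object)
        for i in range(gm.n_sites):
            fields = []
            for j in range(gm.n_samples):
                gt = _GT_STR[int(gm.genotypes[i, j])]
                dp = int(gm.dp[i, j]) if gm.dp is not None else 20
                gq = int(gm.gq[i, j]) if gm.gq is not None else 60
                fields.append(f"{gt}:{dp}:{gq}")
            fh.write(f"{gm.chrom[i]}\t{gm.pos[i] + 1}\t.\t{ref[i]}\t{alt[i]}"
                     f"\t.\tPASS\t.\tGT:DP:GQ\t" + "\t".join(fields) + "\n")


def read_regions(path, lg_lengths: dict | None = None) -> pd.DataFrame:
    """Read a 3+ column BED (0-based half-open) into a region table."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
            lg, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end")
            if lg_lengths is not None:
                if lg not in lg_lengths or end > lg_lengths[lg]:
                    raise ValueError(f"{path}:{ln}: interval outside genome bounds")
            name = parts[3] if len(parts) > 3 else f"region{len(rows)}"
            rows.append((lg, start, end, name))
    return pd.DataFrame(rows, columns=["lg", "start", "end", "name"])


def write_regions(df: pd.DataFrame, path, score_col: str | None = None) -> None:
    cols = ["lg", "start", "end"]
    out = df[cols].copy()
    if "name" in df.columns:
        out["name"] = df["name"]
    if score_col is not None:
        if "name" not in out.columns:
            out["name"] = "."
        out["score"] = df[score_col]
    out.to_csv(path, sep="\t", header=False, index=False)


def write_report(df: pd.DataFrame, path, header_lines=()) -> None:
    """TSV with provenance comment header (seed, config hash, conventions)."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def config_hash(config: dict) -> str:
    blob = repr(sorted(config.items())).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
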