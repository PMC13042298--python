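"""End-to-end pipeline: simulate -> markers -> linkage -> Marey ->
crossovers -> region statistics -> inversion scan.

Each stage is a library call; :func:`run_pipeline` wires them together,
writes every artifact with a provenance header (seed + config hash), and
returns the in-memory results.  A single global seed is expanded into
per-stage child seeds with ``SeedSequence([seed, stage_index])`` so any
stage can be reproduced in isolation.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (crossovers, inversion_scan, io, linkage, marey, region_stats,
               simdata)

STAGES = ["simulate", "markers", "linkage", "marey", "crossovers",
          "regions", "invscan"]


@dataclass
class PipelineConfig:
    """All stage parameters; unknown keys are rejected on load."""

    seed: int = 0
    # genome layout
    n_lg: int = 5
    lg_length_bp: int = 10_000_000
    rate_cM_per_Mb: float = 5.0
    n_inversions: int = 6
    inversion_derived_freq: float = 0.4
    te_base_density: float = 0.3
    te_inside_multiplier: float = 0.5
    gene_base_density: float = 0.15
    gene_inside_multiplier: float = 1.5
    # families
    offspring_per_family: tuple = (65, 82)
    markers_per_lg: int = 150
    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.0
    interference_mode: str = "none"
    interference_nu: float = 5.0
    suppress_in_heterokaryotypes: bool = True
    # population panel
    panel_n: int = 240
    panel_divergence: float = 0.5
    panel_snps_per_lg: int = 1_500
    # analysis
    lod_limit: float = 19.0
    mapping_function: str = "kosambi"
    n_perm: int = 1_000
    fst_window_bp: int = 100_000
    fst_step_bp: int = 20_000
    fst_threshold: float = 0.15
    fst_min_consecutive: int = 3
    ld_thin_bp: int = 10_000
    ld_maf_min: float = 0.2
    gap_cM: float = 10.0
    density_window_bp: int = 50_000

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def stage_seed(seed: int, stage: str) -> int:
    """Child seed of a stage, derived from the global seed + stage index."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % 2**31)


def _layout_spec(cfg: PipelineConfig) -> simdata.LayoutSpec:
    return simdata.LayoutSpec(
        n_lg=cfg.n_lg, lg_length_bp=cfg.lg_length_bp,
        rate_cM_per_Mb=cfg.rate_cM_per_Mb, n_inversions=cfg.n_inversions,
        inversion_derived_freq=cfg.inversion_derived_freq,
        te_base_density=cfg.te_base_density,
        te_inside_multiplier=cfg.te_inside_multiplier,
        gene_base_density=cfg.gene_base_density,
        gene_inside_multiplier=cfg.gene_inside_multiplier,
        seed=stage_seed(cfg.seed, "simulate"))


def simulate_all(cfg: PipelineConfig):
    """Genome layout, two mapping families and a population panel."""
    layout = simdata.simulate_genome(_layout_spec(cfg))
    sseed = stage_seed(cfg.seed, "simulate")
    families = []
    for i, n_off in enumerate(cfg.offspring_per_family):
        fam_cfg = simdata.SimConfig(
            family_id=f"F{i + 1}", n_offspring=int(n_off),
            markers_per_lg=cfg.markers_per_lg,
            interference_mode=cfg.interference_mode,
            interference_nu=cfg.interference_nu,
            suppress_in_heterokaryotypes=cfg.suppress_in_heterokaryotypes,
            genotyping_error_rate=cfg.genotyping_error_rate,
            missing_rate=cfg.missing_rate, seed=sseed + i + 1)
        families.append(simdata.simulate_family(layout, fam_cfg))
    panel = simdata.simulate_population(
        layout, cfg.panel_n, cfg.panel_divergence, seed=sseed + 100,
        snps_per_lg=cfg.panel_snps_per_lg)
    return layout, families, panel


def build_family_map(truth: simdata.FamilyTruth, parent: str, lg: str,
                     mapping_function: str = "kosambi") -> marey.MareyMap:
    """Genetic map of one parent on one LG from its phased transmissions.

    Adjacent-marker recombination fractions from the transmission matrix
    are turned into cumulative cM through the mapping function; the
    physical order is taken as the marker order (markers are anchored).
    """
    block = truth.transmissions.blocks[(truth.family_id, parent, lg)]
    H = block.haps
    same = (H[:-1] == H[1:])
    ok = (H[:-1] != simdata.MISSING) & (H[1:] != simdata.MISSING)
    k = (~same & ok).sum(axis=1)
    n = np.maximum(ok.sum(axis=1), 1)
    r = np.minimum(k / n, 0.5)
    cum = np.concatenate([[0.0], np.cumsum(linkage.map_distance(r, mapping_function))])
    return marey.build_marey(block.positions, cum, lg_id=lg)


def parent_region_rates(layout, truth, mapping_function="kosambi") -> pd.DataFrame:
    """Collinear/inversion region rates per parent-specific map.

    For each parent and LG the LG is split into the inversion intervals
    (labeled by the parent's karyotype: heterokaryotype intervals are
    "inversion", homokaryotype ones are effectively collinear) and the
    gaps between them (collinear).
    """
    frames = []
    for parent in ("father", "mother"):
        for lg in layout.lgs:
            mm = build_family_map(truth, parent, lg, mapping_function)
            invs = sorted(layout.inversions_on(lg), key=lambda iv: iv.start)
            regions = []
            cursor = 0
            L = layout.lg_lengths_bp[lg]
            for iv in invs:
                if iv.start > cursor:
                    regions.append((lg, cursor, iv.start, "collinear",
                                    f"{lg}:{cursor}-col"))
                kt = truth.parent_karyotypes[parent][iv.name]
                label = "inversion" if kt == 1 else "collinear"
                regions.append((lg, iv.start, iv.end, label, iv.name))
                cursor = iv.end
            if cursor < L:
                regions.append((lg, cursor, L, "collinear", f"{lg}:{cursor}-col"))
            reg = pd.DataFrame(regions,
                               columns=["lg", "start", "end", "label", "name"])
            rr = region_stats.region_rates(mm, reg)
            rr["parent"] = parent
            frames.append(rr)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute every stage and write the report bundle to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = io.config_hash(cfg.to_dict())
    header = [f"config_hash={chash}", f"seed={cfg.seed}",
              "coordinates=0-based half-open"]
    results = {}

    layout, families, panel = simulate_all(cfg)
    inv_bed = simdata.inversion_regions(layout)
    io.write_regions(inv_bed, outdir / "inversions.bed")
    io.write_genotypes(panel.genotypes, outdir / "panel.vcf",
                       contig_lengths=layout.lg_lengths_bp)
    for fam in families:
        fam.transmissions.to_tsv(outdir / f"transmissions_{fam.family_id}.tsv")
    results["layout"] = layout
    results["families"] = families
    results["panel"] = panel

    # markers + linkage + marey on family 1, LG by LG, father map
    fam = families[0]
    maps = []
    rate_frames = []
    for lg in layout.lgs:
        mm = build_family_map(fam, "father", lg, cfg.mapping_function)
        rates = marey.sliding_rate(mm)
        rates.insert(0, "lg", lg)
        rate_frames.append(rates)
        maps.append({"lg": lg, "length_cM": mm.cm[-1],
                     "n_markers": len(mm.bp),
                     "length_Mb": layout.lg_lengths_bp[lg] / 1e6})
    rate_track = pd.concat(rate_frames, ignore_index=True)
    io.write_report(rate_track, outdir / "rates.tsv", header)
    map_table = pd.DataFrame(maps)
    io.write_report(map_table, outdir / "map_summary.tsv", header)
    results["map_table"] = map_table

    # crossovers + suppression test, pooling both families
    family_sizes = {f.family_id: len(f.offspring_ids) for f in families}
    events = pd.concat([crossovers.collect_events(f.transmissions)
                        for f in families], ignore_index=True)
    counts = pd.concat(
        [crossovers.assign_events(
            crossovers.collect_events(f.transmissions), inv_bed,
            {f.family_id: len(f.offspring_ids)})
         for f in families], ignore_index=True)
    io.write_report(counts, outdir / "inversion_event_counts.tsv", header)
    karyos = {f.family_id: f.parent_karyotypes for f in families}
    try:
        supp = crossovers.het_suppression_test(counts, karyos)
        results["suppression_test"] = supp
    except ValueError as exc:       # e.g. no heterokaryotype parent drawn
        results["suppression_test"] = None
        results["suppression_test_note"] = str(exc)
    results["n_events"] = len(events)

    # collinear vs inversion permutation test on parent-specific maps
    rr = parent_region_rates(layout, families[0], cfg.mapping_function)
    perm = region_stats.label_permutation_test(
        rr, n_perm=cfg.n_perm, seed=stage_seed(cfg.seed, "regions"))
    results["rate_permutation"] = perm

    # TE density + enrichment
    dens = region_stats.window_density(layout.te_track, layout.lg_lengths_bp,
                                       cfg.density_window_bp)
    io.write_report(dens, outdir / "te_density.tsv", header)
    enr = region_stats.enrichment_permutation(
        layout.te_track, inv_bed, layout.lg_lengths_bp,
        n_perm=cfg.n_perm, seed=stage_seed(cfg.seed, "regions") + 1)
    results["te_enrichment"] = enr

    # inversion scan on the panel
    scan_rows = []
    pca_calls = {}
    for lg in layout.lgs:
        ld = inversion_scan.ld_screen(panel.genotypes, lg,
                                      thin_bp=cfg.ld_thin_bp,
                                      maf_min=cfg.ld_maf_min)
        for start, end in ld.blocks:
            call = inversion_scan.pca_genotype(panel.genotypes, (lg, start, end))
            if call.ambiguous:
                continue
            hom0 = [panel.genotypes.samples[i]
                    for i in np.flatnonzero(call.genotypes == 0)]
            hom2 = [panel.genotypes.samples[i]
                    for i in np.flatnonzero(call.genotypes == 2)]
            if len(hom0) < 2 or len(hom2) < 2:
                continue
            track = inversion_scan.windowed_fst(
                panel.genotypes, hom0, hom2, cfg.fst_window_bp,
                cfg.fst_step_bp, lg=lg)
            bounds = inversion_scan.call_boundaries(
                track, cfg.fst_threshold, cfg.fst_min_consecutive)
            for blg, bstart, bend in bounds:
                scan_rows.append((blg, bstart, bend, (bend - bstart) / 1e6,
                                  "ld+pca+fst"))
                pca_calls[(blg, bstart, bend)] = call
    scan = pd.DataFrame(scan_rows,
                        columns=["lg", "start", "end", "size_Mb", "support"])
    scan = scan.drop_duplicates(subset=["lg", "start", "end"], ignore_index=True)
    io.write_report(scan, outdir / "inversion_calls.tsv", header)
    results["inversion_calls"] = scan
    results["pca_calls"] = pca_calls

    with open(outdir / "run.json", "w") as fh:
        json.dump({"seed": cfg.seed, "config_hash": chash,
                   "config": cfg.to_dict(),
                   "n_events": results["n_events"],
                   "suppression_p": (results["suppression_test"].p_value
                                     if results["suppression_test"] else None),
                   "rate_permutation_p": perm.p_value,
                   "te_enrichment_p": enr.p_value,
                   "te_enrichment_direction": enr.direction,
                   "n_inversion_calls": len(scan)}, fh, indent=2)
    return results
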