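"""Seeded recovery and calibration experiments on synthetic data.

These functions re-run the full method pipeline under the study
conditions the synthetic generator emulates (two families of 65 and 82
offspring, five 10-Mb linkage groups carrying six polymorphic
inversions, a 240-individual population panel) and measure how well each
stage recovers the simulated truth: suppression-test power and null
calibration, the collinear-vs-inversion permutation test, linkage-group
and marker-order recovery, inversion genotyping and boundary precision,
and TE-depletion detection.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import crossovers, inversion_scan, linkage, marey, region_stats, simdata
from .pipeline import parent_region_rates

OFFSPRING_PER_FAMILY = (65, 82)
N_LG = 5
LG_LENGTH_BP = 10_000_000
N_INVERSIONS = 6
MARKERS_PER_LG = 120
PANEL_N = 240
PANEL_DIVERGENCE = 0.5
PANEL_INVERSION = ("LG1", 1_500_000, 3_500_000, 0.4)


def _study_families(seed: int, suppress: bool):
    spec = simdata.LayoutSpec(n_lg=N_LG, lg_length_bp=LG_LENGTH_BP,
                              n_inversions=N_INVERSIONS, seed=seed)
    layout = simdata.simulate_genome(spec)
    fams = []
    for i, n_off in enumerate(OFFSPRING_PER_FAMILY):
        cfg = simdata.SimConfig(
            family_id=f"F{i + 1}", n_offspring=n_off,
            markers_per_lg=MARKERS_PER_LG, seed=seed * 10 + i + 1,
            suppress_in_heterokaryotypes=suppress)
        fams.append(simdata.simulate_family(layout, cfg))
    return layout, fams


def suppression_experiment(seed: int, suppress: bool = True) -> dict:
    """One two-family replicate: switch counts vs truth + Wilcoxon p."""
    layout, fams = _study_families(seed, suppress)
    inv = simdata.inversion_regions(layout)
    counts = []
    counted = truth = 0
    for fam in fams:
        events = crossovers.collect_events(fam.transmissions)
        counted += len(events)
        truth += len(fam.crossovers)
        counts.append(crossovers.assign_events(
            events, inv, {fam.family_id: len(fam.offspring_ids)}))
    counts = pd.concat(counts, ignore_index=True)
    karyos = {f.family_id: f.parent_karyotypes for f in fams}
    try:
        res = crossovers.het_suppression_test(counts, karyos)
        p = res.p_value
    except ValueError:
        p = None                       # no heterokaryotype drawn this seed
    return {"p": p, "counted_events": counted, "true_events": truth}


def suppression_power(n_seeds: int, base_seed: int = 0,
                      suppress: bool = True) -> dict:
    out = [suppression_experiment(base_seed + s, suppress)
           for s in range(n_seeds)]
    ps = [o["p"] for o in out if o["p"] is not None]
    exact = all(o["counted_events"] == o["true_events"] for o in out)
    return {"p_values": ps,
            "power_05": float(np.mean([p < 0.05 for p in ps])),
            "counts_match_truth": exact}


def rate_permutation_experiment(seed: int, suppress: bool = True,
                                n_perm: int = 499,
                                exchangeable_null: bool = False) -> float | None:
    """Collinear-vs-inversion mean-rate permutation p for one replicate.

    With ``exchangeable_null`` the inversion/collinear labels are
    reassigned at random over the regions (group sizes preserved), which
    makes the null hypothesis true by construction *and* the labels
    exchangeable — the calibration target of the permutation machinery.
    Merely disabling suppression leaves labels attached to systematically
    different region geometries (inversions are larger than the typical
    collinear fragment), where the mean-difference test is conservative.
    """
    layout, fams = _study_families(seed, suppress)
    rr = pd.concat([parent_region_rates(layout, f) for f in fams],
                   ignore_index=True)
    labels = rr["label"].to_numpy()
    if (labels == "inversion").all() or (labels != "inversion").all():
        return None
    if exchangeable_null:
        rng = np.random.default_rng(seed + 1)
        rr = rr.assign(label=rng.permutation(labels))
    return region_stats.label_permutation_test(rr, n_perm=n_perm,
                                               seed=seed).p_value


def rate_permutation_power(n_seeds: int, base_seed: int = 0,
                           suppress: bool = True, n_perm: int = 499,
                           exchangeable_null: bool = False) -> dict:
    ps = [rate_permutation_experiment(base_seed + s, suppress, n_perm,
                                      exchangeable_null)
          for s in range(n_seeds)]
    ps = [p for p in ps if p is not None]
    return {"p_values": ps,
            "power_005": float(np.mean([p <= 0.005 for p in ps]))}


def linkage_recovery(seed: int = 0, n_markers_total: int = 500,
                     n_meioses: int = 147,
                     lod_limits=(12, 15, 19, 22, 25)) -> dict:
    """Grouping/ordering/map-length recovery on 2 simulated LGs.

    Simulated without interference and analyzed with the Haldane map so
    the estimated total length is unbiased for the simulated truth; the
    standard error of the length comes from binomial error propagation
    through the mapping function.
    """
    per_lg = n_markers_total // 2
    spec = simdata.LayoutSpec(n_lg=2, lg_length_bp=LG_LENGTH_BP,
                              rate_cM_per_Mb=10.0, n_inversions=0, seed=seed)
    layout = simdata.simulate_genome(spec)
    cfg = simdata.SimConfig(n_offspring=n_meioses, markers_per_lg=per_lg,
                            informative_fractions=(0.0, 0.0, 1.0, 0.0),
                            seed=seed + 1)
    fam = simdata.simulate_family(layout, cfg)
    blocks = [b for b in fam.transmissions if b.parent == "father"]
    H = np.vstack([b.haps for b in blocks])
    truth_lg = np.concatenate([[b.lg] * len(b.positions) for b in blocks])
    pos = np.concatenate([b.positions for b in blocks])
    r, lod, n = linkage.pairwise_lod_matrix(H)

    plateau = []
    for lim in lod_limits:
        groups = [g for g in linkage.assign_linkage_groups(lod, lim)
                  if len(g) > 1]
        correct = (len(groups) == 2 and all(
            len(set(truth_lg[g])) == 1 and len(g) == per_lg for g in groups))
        plateau.append(correct)

    groups = [g for g in linkage.assign_linkage_groups(lod, 19) if len(g) > 1]
    taus, lengths, ses, truth_lengths = [], [], [], []
    for g in groups:
        lm = linkage.order_markers(g, r, "haldane", physical_pos=pos)
        rank = np.arange(len(lm.marker_ids))
        true_rank = np.argsort(np.argsort(pos[lm.marker_ids]))
        taus.append(abs(stats.kendalltau(rank, true_rank).statistic))
        adj_r = np.clip(r[lm.marker_ids[:-1], lm.marker_ids[1:]], 0, 0.4999)
        adj_n = n[lm.marker_ids[:-1], lm.marker_ids[1:]]
        var = ((100.0 / (1 - 2 * adj_r)) ** 2 * adj_r * (1 - adj_r) / adj_n).sum()
        lengths.append(lm.length_cM)
        ses.append(float(np.sqrt(var)))
        truth_lengths.append(layout.map_length_cm(truth_lg[g[0]]))
    return {"plateau_all_correct": all(plateau),
            "plateau": dict(zip(map(float, lod_limits), plateau)),
            "kendall_tau_min": float(min(taus)),
            "lengths_cM": lengths, "length_se_cM": ses,
            "truth_lengths_cM": truth_lengths,
            "length_within_3se": all(
                abs(est - tru) <= 3 * se for est, se, tru in
                zip(lengths, ses, truth_lengths))}


def inversion_scan_experiment(seed: int) -> dict:
    """One panel replicate: LD screen, PCA genotyping, Fst boundaries."""
    lg, start, end, freq = PANEL_INVERSION
    spec = simdata.LayoutSpec(n_lg=1, lg_length_bp=5_000_000, n_inversions=0,
                              seed=97)
    layout = simdata.simulate_genome(spec)
    layout.inversions = [simdata.Inversion("Inv1", lg, start, end, freq)]
    panel = simdata.simulate_population(layout, PANEL_N, PANEL_DIVERGENCE,
                                        seed=seed, snps_per_lg=1_500)
    truth = panel.inversion_genotypes_truth["Inv1"].to_numpy()

    ld = inversion_scan.ld_screen(panel.genotypes, lg)
    ld_hit = any(s < end and e > start for s, e in ld.blocks)

    call = inversion_scan.pca_genotype(panel.genotypes, (lg, start, end))
    if call.ambiguous:
        acc = 0.0
    else:
        acc = max(np.mean(call.genotypes == truth),
                  np.mean((2 - call.genotypes) == truth))

    hom0 = [panel.genotypes.samples[i] for i in np.flatnonzero(truth == 0)]
    hom2 = [panel.genotypes.samples[i] for i in np.flatnonzero(truth == 2)]
    track = inversion_scan.windowed_fst(panel.genotypes, hom0, hom2, lg=lg)
    bounds = inversion_scan.call_boundaries(track)
    if bounds:
        berr = min(max(abs(s - start), abs(e - end)) for _, s, e in bounds)
    else:
        berr = np.inf
    return {"ld_hit": ld_hit, "pca_accuracy": float(acc),
            "boundary_error_bp": float(berr)}


def inversion_scan_recovery(n_seeds: int = 50, base_seed: int = 0) -> dict:
    out = [inversion_scan_experiment(base_seed + s) for s in range(n_seeds)]
    window = inversion_scan.FST_WINDOW_BP
    return {
        "frac_ld_hit": float(np.mean([o["ld_hit"] for o in out])),
        "frac_pca_99": float(np.mean([o["pca_accuracy"] >= 0.99 for o in out])),
        "frac_boundary_1win": float(np.mean(
            [o["boundary_error_bp"] <= window for o in out])),
        "mean_pca_accuracy": float(np.mean([o["pca_accuracy"] for o in out])),
    }


def enrichment_experiment(seed: int, multiplier: float = 0.5,
                          n_perm: int = 199) -> region_stats.PermutationResult:
    spec = simdata.LayoutSpec(n_lg=N_LG, lg_length_bp=LG_LENGTH_BP,
                              n_inversions=N_INVERSIONS,
                              te_inside_multiplier=multiplier, seed=seed)
    layout = simdata.simulate_genome(spec)
    inv = simdata.inversion_regions(layout)
    return region_stats.enrichment_permutation(
        layout.te_track, inv, layout.lg_lengths_bp, n_perm=n_perm, seed=seed)


def enrichment_power(n_seeds: int, base_seed: int = 0,
                     multiplier: float = 0.5, n_perm: int = 199) -> dict:
    res = [enrichment_experiment(base_seed + s, multiplier, n_perm)
           for s in range(n_seeds)]
    detected = [r.direction == "depleted" and r.p_value < 0.05 for r in res]
    return {"power_05": float(np.mean(detected)),
            "p_depleted": [r.extra["p_depleted"] for r in res]}


def reference_map_statistics() -> dict:
    """Published-map summary statistics from the packaged per-LG table."""
    s = marey.map_summary(marey.load_reference_map_table())
    return {**s.totals, **s.correlations}
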