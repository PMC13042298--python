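"""Seeded synthetic genomes, pedigrees, meioses and population panels.

The generator emulates the study design the downstream stages assume: a
small number of chromosome-scale linkage groups with a known (piecewise
linear) Marey function, polymorphic inversions whose heterokaryotype
carriers recombine at rate zero inside the inverted interval, two
mapping families of sequenced offspring, and a diploid population panel
in which the two inversion arrangements carry diverged allele
frequencies.  Every product comes with a truth channel (true
transmissions, true crossover positions, true inversion genotypes) so
recovery tests can score the pipeline exactly.

No sequence-level simulation is attempted: markers are abstract biallelic
SNPs with positions, genotypes, and optional per-genotype depth/quality.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (MISSING, GenotypeMatrix, TransmissionBlock,
                         TransmissionTable)

MARKER_CLASSES = ("paternal", "maternal", "both", "none")


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Inversion:
    name: str
    lg: str
    start: int          # bp, 0-based half-open
    end: int
    derived_freq: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeLayout:
    """Physical + genetic skeleton of a simulated genome."""

    lg_lengths_bp: dict            # lg -> int
    marey_truth: dict              # lg -> (bp_nodes, cm_nodes), monotone
    inversions: list               # list[Inversion]
    te_track: pd.DataFrame         # lg, start, end
    gene_track: pd.DataFrame

    @property
    def lgs(self) -> list:
        return list(self.lg_lengths_bp)

    def map_length_cm(self, lg: str) -> float:
        return float(self.marey_truth[lg][1][-1])

    def cm_at(self, lg: str, bp) -> np.ndarray:
        nodes_bp, nodes_cm = self.marey_truth[lg]
        return np.interp(bp, nodes_bp, nodes_cm)

    def bp_at(self, lg: str, cm) -> np.ndarray:
        """Inverse Marey function (genetic -> physical)."""
        nodes_bp, nodes_cm = self.marey_truth[lg]
        return np.interp(cm, nodes_cm, nodes_bp)

    def inversions_on(self, lg: str) -> list:
        return [iv for iv in self.inversions if iv.lg == lg]


@dataclass
class LayoutSpec:
    """Parameters for :func:`simulate_genome`.

    Densities are expected feature bases per genomic base (before
    overlap merging); multipliers rescale the density inside inversions.
    """

    n_lg: int = 5
    lg_length_bp: int | list = 10_000_000
    rate_cM_per_Mb: float | list = 5.0
    n_marey_segments: int = 1        # >1 gives a random piecewise-linear map
    inversions: list | None = None   # explicit (lg, start, end, derived_freq)
    n_inversions: int = 6            # used when inversions is None
    inversion_size_bp: tuple = (1_000_000, 3_000_000)
    inversion_derived_freq: float = 0.4
    te_base_density: float = 0.3
    te_inside_multiplier: float = 0.5
    gene_base_density: float = 0.15
    gene_inside_multiplier: float = 1.5
    feature_mean_bp: int = 2_000
    allow_overlapping_inversions: bool = False
    seed: int = 0


def _sample_positions(rng, lo: int, hi: int, size: int) -> np.ndarray:
    """Sorted unique integer positions in [lo, hi) without materializing the range."""
    if size > hi - lo:
        raise ValueError("more positions requested than available")
    pos = np.unique(rng.integers(lo, hi, size=2 * size + 16))
    while len(pos) < size:
        pos = np.unique(np.concatenate([pos, rng.integers(lo, hi, size=size)]))
    return np.sort(rng.choice(pos, size=size, replace=False))


def _as_list(x, n: int) -> list:
    if np.isscalar(x):
        return [x] * n
    if len(x) != n:
        raise ValueError(f"expected {n} values, got {len(x)}")
    return list(x)


def simulate_genome(spec: LayoutSpec) -> GenomeLayout:
    """Build a deterministic :class:`GenomeLayout` from a spec."""
    if spec.n_lg < 1:
        raise ValueError("need at least one linkage group")
    rng = np.random.default_rng(spec.seed)
    lengths = _as_list(spec.lg_length_bp, spec.n_lg)
    rates = _as_list(spec.rate_cM_per_Mb, spec.n_lg)
    if any(L <= 0 for L in lengths):
        raise ValueError("LG lengths must be positive")
    lgs = [f"LG{i + 1}" for i in range(spec.n_lg)]
    lg_lengths = dict(zip(lgs, (int(L) for L in lengths)))

    marey = {}
    for lg, L, rate in zip(lgs, lengths, rates):
        total_cm = rate * L / 1e6
        k = max(1, int(spec.n_marey_segments))
        bp_nodes = np.concatenate([[0.0], np.sort(rng.uniform(0, L, k - 1)), [float(L)]])
        if k == 1:
            cm_nodes = np.array([0.0, total_cm])
        else:
            # random segment rates, rescaled so the total map length is exact
            w = rng.uniform(0.3, 1.7, k) * np.diff(bp_nodes)
            cm_nodes = np.concatenate([[0.0], np.cumsum(w / w.sum() * total_cm)])
            cm_nodes[-1] = total_cm
        marey[lg] = (bp_nodes, cm_nodes)

    inversions = _place_inversions(spec, lgs, lg_lengths, rng)
    te = _feature_track(lgs, lg_lengths, inversions, spec.te_base_density,
                        spec.te_inside_multiplier, spec.feature_mean_bp, rng)
    genes = _feature_track(lgs, lg_lengths, inversions, spec.gene_base_density,
                           spec.gene_inside_multiplier, spec.feature_mean_bp, rng)
    return GenomeLayout(lg_lengths, marey, inversions, te, genes)


def _place_inversions(spec, lgs, lg_lengths, rng) -> list:
    out = []
    if spec.inversions is not None:
        for i, rec in enumerate(spec.inversions):
            lg, start, end, freq = rec
            out.append(Inversion(f"Inv{i + 1}", str(lg), int(start), int(end), float(freq)))
    else:
        for i in range(spec.n_inversions):
            for _ in range(1000):
                lg = lgs[int(rng.integers(len(lgs)))]
                L = lg_lengths[lg]
                size = int(rng.uniform(*spec.inversion_size_bp))
                if size >= L - 2:
                    continue
                start = int(rng.integers(1, L - size))
                cand = Inversion(f"Inv{i + 1}", lg, start, start + size,
                                 spec.inversion_derived_freq)
                if not any(_overlap(cand, o) for o in out):
                    out.append(cand)
                    break
            else:
                raise ValueError("could not place a non-overlapping inversion")
    for iv in out:
        L = lg_lengths.get(iv.lg)
        if L is None:
            raise ValueError(f"inversion {iv.name} on unknown LG {iv.lg}")
        if iv.start <= 0 or iv.end >= L:
            raise ValueError(f"inversion {iv.name} touches LG ends")
        if iv.start >= iv.end:
            raise ValueError(f"inversion {iv.name} is empty")
    if not spec.allow_overlapping_inversions:
        for a in out:
            for b in out:
                if a.name < b.name and _overlap(a, b):
                    raise ValueError(f"inversions {a.name} and {b.name} overlap")
    return out


def _overlap(a: Inversion, b: Inversion) -> bool:
    return a.lg == b.lg and a.start < b.end and b.start < a.end


def _feature_track(lgs, lg_lengths, inversions, density, multiplier, mean_bp, rng):
    """Poisson-process interval track with density rescaled inside inversions.

    Expected feature bases in a region of length S are density*S outside
    inversions and density*multiplier*S inside (midpoint rule).
    """
    records = []
    for lg in lgs:
        L = lg_lengths[lg]
        invs = [iv for iv in inversions if iv.lg == lg]
        n = rng.poisson(density * L / mean_bp)
        starts = rng.uniform(0, L, n)
        sizes = np.maximum(200, rng.exponential(mean_bp, n))
        mids = starts + sizes / 2
        inside = np.zeros(n, dtype=bool)
        for iv in invs:
            inside |= (mids >= iv.start) & (mids < iv.end)
        keep = np.ones(n, dtype=bool)
        if multiplier < 1.0:
            keep[inside] = rng.random(inside.sum()) < multiplier
        for s, z in zip(starts[keep], sizes[keep]):
            records.append((lg, int(s), int(min(L, s + z))))
        if multiplier > 1.0:
            for iv in invs:
                extra = rng.poisson(density * (multiplier - 1.0) * iv.length / mean_bp)
                es = rng.uniform(iv.start, iv.end, extra)
                ez = np.maximum(200, rng.exponential(mean_bp, extra))
                for s, z in zip(es, ez):
                    records.append((lg, int(s), int(min(L, s + z))))
    df = pd.DataFrame(records, columns=["lg", "start", "end"])
    return df.sort_values(["lg", "start"], ignore_index=True)


# ---------------------------------------------------------------------------
# family / meiosis simulation
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Parameters for :func:`simulate_family`."""

    family_id: str = "F1"
    n_offspring: int = 65
    markers_per_lg: int = 150
    # fractions of markers informative in (father only, mother only, both,
    # neither); must sum to 1.  Endpoint markers are forced to "both" so
    # every crossover is bracketed by informative markers of its parent.
    informative_fractions: tuple = (0.2, 0.2, 0.55, 0.05)
    parent_karyotypes: dict | None = None      # parent -> {inv name: 0/1/2}
    suppress_in_heterokaryotypes: bool = True
    flank_boost: float = 1.0                   # >1 relocates a fraction of
    #                                            suppressed events to flanks
    interference_mode: str = "none"            # "none" (Poisson) | "gamma"
    interference_nu: float = 5.0
    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.0
    depth_mean: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.genotyping_error_rate, self.missing_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must be probabilities")
        if abs(sum(self.informative_fractions) - 1.0) > 1e-9:
            raise ValueError("informative_fractions must sum to 1")
        if self.parent_karyotypes is not None:
            for kt in self.parent_karyotypes.values():
                if any(k not in (0, 1, 2) for k in kt.values()):
                    raise ValueError("karyotypes must be in {0,1,2}")


@dataclass
class FamilyTruth:
    """One simulated family plus its truth channel."""

    family_id: str
    marker_pos: dict               # lg -> sorted bp positions
    marker_class: dict             # lg -> array of MARKER_CLASSES
    transmissions: TransmissionTable   # error-free, parent-informative markers
    crossovers: pd.DataFrame       # parent, lg, offspring_id, pos (realized)
    genotypes: GenotypeMatrix      # with error/missingness applied
    parent_karyotypes: dict
    offspring_ids: list = field(default_factory=list)

    def crossover_count(self, parent=None, lg=None) -> int:
        df = self.crossovers
        if parent is not None:
            df = df[df.parent == parent]
        if lg is not None:
            df = df[df.lg == lg]
        return len(df)


def _draw_crossover_positions_cm(rng, total_cm, mode, nu):
    """Crossover positions (cM scale) of one transmitted gamete."""
    L = total_cm / 100.0  # Morgans
    if mode == "none":
        k = rng.poisson(L)
        return np.sort(rng.uniform(0.0, total_cm, k))
    if mode == "gamma":
        # stationary gamma-renewal chiasma process at rate 2 per Morgan,
        # thinned by 1/2 for the sampled chromatid, so the expected
        # crossover count per gamete still equals the map length in Morgans
        burn = 10.0
        t = -burn
        pts = []
        while t < L:
            t += rng.gamma(nu, 1.0 / (2.0 * nu))
            if 0.0 <= t < L:
                pts.append(t)
        pts = np.array([p for p in pts if rng.random() < 0.5])
        return np.sort(pts * 100.0)
    raise ValueError(f"unknown interference mode: {mode}")


def simulate_family(layout: GenomeLayout, cfg: SimConfig) -> FamilyTruth:
    """Simulate meioses, transmissions and genotypes for one family.

    Crossover counts per gamete follow Poisson(map length in Morgans)
    under no interference; positions are uniform on the genetic scale and
    mapped to bp through the inverse Marey function.  In a parent
    heterozygous for an inversion, events falling inside the inversion
    are removed and not redistributed (local flattening of that parent's
    map).  Within one meiosis, positions are redrawn until each event
    falls in a distinct interval of its parent's informative-marker grid,
    so phased transmissions identify every realized event.
    """
    for lg in layout.lgs:
        if layout.map_length_cm(lg) <= 0:
            raise ValueError(f"non-positive map length on {lg}")
    rng = np.random.default_rng(cfg.seed)
    karyotypes = cfg.parent_karyotypes
    if karyotypes is None:
        karyotypes = {
            p: {iv.name: int(rng.binomial(2, iv.derived_freq)) for iv in layout.inversions}
            for p in ("father", "mother")
        }
    else:
        for p in ("father", "mother"):
            missing = [iv.name for iv in layout.inversions
                       if iv.name not in karyotypes.get(p, {})]
            if missing:
                raise ValueError(f"karyotype of {p} undefined for {missing}")

    off_ids = [f"{cfg.family_id}_o{i + 1}" for i in range(cfg.n_offspring)]
    marker_pos, marker_class = {}, {}
    for lg in layout.lgs:
        L = layout.lg_lengths_bp[lg]
        inner = _sample_positions(rng, 1, L - 1, cfg.markers_per_lg - 2)
        pos = np.concatenate([[0], inner, [L - 1]])
        cls = rng.choice(MARKER_CLASSES, size=cfg.markers_per_lg,
                         p=cfg.informative_fractions)
        cls[0] = cls[-1] = "both"
        marker_pos[lg] = pos
        marker_class[lg] = cls

    tt = TransmissionTable()
    xo_records = []
    # per-offspring transmitted haplotype index at every marker, per parent
    hap_full = {p: {} for p in ("father", "mother")}
    for parent in ("father", "mother"):
        for lg in layout.lgs:
            pos = marker_pos[lg]
            cls = marker_class[lg]
            informative = (cls == "both") | (cls == ("paternal" if parent == "father"
                                                     else "maternal"))
            info_pos = pos[informative]
            total_cm = layout.map_length_cm(lg)
            het_invs = [iv for iv in layout.inversions_on(lg)
                        if karyotypes[parent][iv.name] == 1]
            haps = np.empty((len(pos), cfg.n_offspring), dtype=np.int8)
            for j in range(cfg.n_offspring):
                for _ in range(200):
                    cm = _draw_crossover_positions_cm(
                        rng, total_cm, cfg.interference_mode, cfg.interference_nu)
                    bp = layout.bp_at(lg, cm)
                    iv_ok = np.searchsorted(info_pos, bp)
                    if len(np.unique(iv_ok)) == len(bp):
                        break
                if cfg.suppress_in_heterokaryotypes and het_invs:
                    keep = np.ones(len(bp), dtype=bool)
                    extras = []
                    for iv in het_invs:
                        inside = (bp >= iv.start) & (bp < iv.end)
                        keep &= ~inside
                        if cfg.flank_boost > 1.0 and inside.any():
                            extras.extend(_boost_flanks(
                                rng, int(inside.sum()), iv, layout, lg,
                                cfg.flank_boost))
                    bp = np.sort(np.concatenate([bp[keep], np.asarray(extras)]))
                start = int(rng.integers(2))
                haps[:, j] = (start + np.searchsorted(bp, pos, side="left")) % 2
                for x in bp:
                    xo_records.append((parent, lg, off_ids[j], float(x)))
            hap_full[parent][lg] = haps
            tt.add(TransmissionBlock(
                family_id=cfg.family_id, parent=parent, lg=lg,
                positions=info_pos, haps=haps[informative],
                offspring_ids=list(off_ids)))

    xo = pd.DataFrame(xo_records, columns=["parent", "lg", "offspring_id", "pos"])
    genotypes = _family_genotypes(layout, cfg, rng, marker_pos, marker_class,
                                  hap_full, off_ids)
    return FamilyTruth(cfg.family_id, marker_pos, marker_class, tt, xo,
                       genotypes, karyotypes, list(off_ids))


def _boost_flanks(rng, n_suppressed, iv, layout, lg, boost):
    """Optionally relocate suppressed events to the inversion flanks."""
    L = layout.lg_lengths_bp[lg]
    half = iv.length // 2
    out = []
    for _ in range(n_suppressed):
        if rng.random() < min(1.0, boost - 1.0):
            if rng.random() < 0.5:
                lo, hi = max(0, iv.start - half), iv.start
            else:
                lo, hi = iv.end, min(L, iv.end + half)
            if hi > lo:
                out.append(rng.uniform(lo, hi))
    return out


def _family_genotypes(layout, cfg, rng, marker_pos, marker_class, hap_full, off_ids):
    """Genotypes of parents + offspring from the transmitted haplotypes.

    At markers informative in a parent, the parent's haplotype h carries
    allele h (so the parent is 0/1); non-informative parents are 0/0.
    """
    chroms, poss, classes = [], [], []
    gts = []
    for lg in layout.lgs:
        pos = marker_pos[lg]
        cls = marker_class[lg]
        f_inf = (cls == "both") | (cls == "paternal")
        m_inf = (cls == "both") | (cls == "maternal")
        f_allele = np.where(f_inf[:, None], hap_full["father"][lg], 0)
        m_allele = np.where(m_inf[:, None], hap_full["mother"][lg], 0)
        off = (f_allele + m_allele).astype(np.int8)
        father = f_inf.astype(np.int8)   # dosage 1 when het, else 0
        mother = m_inf.astype(np.int8)
        gts.append(np.column_stack([father, mother, off]))
        chroms.extend([lg] * len(pos))
        poss.extend(pos.tolist())
        classes.extend(cls.tolist())
    g = np.vstack(gts)
    samples = [f"{cfg.family_id}_father", f"{cfg.family_id}_mother"] + list(off_ids)
    if cfg.genotyping_error_rate > 0:
        flip = rng.random(g.shape) < cfg.genotyping_error_rate
        shift = rng.integers(1, 3, size=g.shape)
        g = np.where(flip, (g + shift) % 3, g).astype(np.int8)
    if cfg.missing_rate > 0:
        g = np.where(rng.random(g.shape) < cfg.missing_rate, MISSING, g).astype(np.int8)
    dp = rng.poisson(cfg.depth_mean, g.shape).astype(np.int32)
    gq = np.clip(rng.normal(60, 15, g.shape), 0, 99).astype(np.int32)
    return GenotypeMatrix(chrom=np.array(chroms, dtype=object),
                          pos=np.array(poss), genotypes=g, samples=samples,
                          dp=dp, gq=gq)


# ---------------------------------------------------------------------------
# population panel
# ---------------------------------------------------------------------------

@dataclass
class PopulationPanel:
    genotypes: GenotypeMatrix
    inversion_genotypes_truth: pd.DataFrame   # individuals x inversion names
    haplotype_divergence: dict                # inversion name -> divergence


def simulate_population(layout: GenomeLayout, n: int, divergence,
                        seed: int = 0, snps_per_lg: int = 1_500,
                        missing_rate: float = 0.0,
                        depth_mean: float = 20.0) -> PopulationPanel:
    """Diploid panel with arrangement-diverged allele frequencies.

    Inversion genotypes are drawn at Hardy-Weinberg proportions from each
    inversion's derived frequency.  Inside an inversion, every SNP has an
    ancestral-arrangement frequency p and a derived-arrangement frequency
    clip(p +/- divergence); outside inversions the panel is panmictic.
    """
    if n < 2:
        raise ValueError("panel needs at least 2 individuals")
    div = ({iv.name: float(divergence) for iv in layout.inversions}
           if np.isscalar(divergence) else dict(divergence))
    for d in div.values():
        if not 0.0 <= d <= 1.0:
            raise ValueError("divergence must be in [0, 1]")
    for iv in layout.inversions:
        if not 0.0 < iv.derived_freq < 1.0:
            raise ValueError(f"{iv.name}: derived_freq must be in (0, 1)")
    rng = np.random.default_rng(seed)
    inds = [f"ind{i + 1}" for i in range(n)]
    inv_truth = pd.DataFrame(
        {iv.name: rng.binomial(2, iv.derived_freq, n) for iv in layout.inversions},
        index=inds)

    chroms, poss, gts = [], [], []
    for lg in layout.lgs:
        L = layout.lg_lengths_bp[lg]
        pos = _sample_positions(rng, 1, L, min(snps_per_lg, L - 1))
        p_anc = rng.uniform(0.05, 0.95, len(pos))
        g = rng.binomial(2, p_anc[:, None], (len(pos), n)).astype(np.int8)
        for iv in layout.inversions_on(lg):
            inside = (pos >= iv.start) & (pos < iv.end)
            if not inside.any():
                continue
            sign = rng.choice([-1.0, 1.0], inside.sum())
            pa = p_anc[inside]
            pd_ = np.clip(pa + sign * div[iv.name], 0.0, 1.0)
            k = inv_truth[iv.name].to_numpy()          # derived copies per ind
            g_in = (rng.binomial((2 - k)[None, :], pa[:, None])
                    + rng.binomial(k[None, :], pd_[:, None])).astype(np.int8)
            g[inside] = g_in
        chroms.extend([lg] * len(pos))
        poss.extend(pos.tolist())
        gts.append(g)
    g = np.vstack(gts)
    if missing_rate > 0:
        g = np.where(rng.random(g.shape) < missing_rate, MISSING, g).astype(np.int8)
    dp = rng.poisson(depth_mean, g.shape).astype(np.int32)
    gq = np.clip(rng.normal(60, 15, g.shape), 0, 99).astype(np.int32)
    gm = GenotypeMatrix(chrom=np.array(chroms, dtype=object),
                        pos=np.array(poss), genotypes=g, samples=inds,
                        dp=dp, gq=gq)
    return PopulationPanel(gm, inv_truth, div)


def inversion_regions(layout: GenomeLayout) -> pd.DataFrame:
    """Inversion intervals as a region table (lg, start, end, name)."""
    return pd.DataFrame(
        [(iv.lg, iv.start, iv.end, iv.name) for iv in layout.inversions],
        columns=["lg", "start", "end", "name"])
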