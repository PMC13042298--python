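# Methods

## The meiosis model

Each transmitted gamete receives crossovers whose count is
Poisson-distributed with mean equal to the map length in Morgans
(`interference_mode="none"`, the default). Positions are uniform on the
genetic (cM) scale and mapped to physical coordinates through the inverse
of the linkage group's Marey function, so regions of high cM/Mb receive
proportionally more events. An optional gamma-renewal mode
(`interference_mode="gamma"`, shape `interference_nu`, default 5) places
chiasmata at rate 2 per Morgan with gamma interarrivals and thins them by
1/2 for the sampled chromatid; crossover interference strength has not
been measured in the bark beetle, so the shape default is a generic
modeling choice and the mode is off by default. Recovery tests pair the
interference-free simulator with the Haldane mapping function, under
which total map length is recovered without bias; Kosambi remains the
pipeline default for real data, where interference is the norm. Obligate
chiasma formation is *not* enforced — a Poisson model permits
zero-crossover meioses, which real beetle bivalents largely avoid; this
mildly widens the simulated count distribution.

In a parent heterozygous for an inversion, every crossover falling inside
the inverted interval is removed and **not** redistributed: suppression
flattens that parent's map locally without compensatory increase
elsewhere. An optional `flank_boost > 1` relocates a fraction of the
suppressed events into flanking windows for sensitivity analyses; it is
off by default because the analyses here test suppression, not
compensation.

One deliberate deviation from pure uniform placement: when a marker grid
is in play, the positions within one meiosis are redrawn (the Poisson
count is kept) until each event falls in a distinct interval of its
parent's informative-marker grid, and the first and last markers of every
LG are forced to be informative in both parents. Two crossovers inside
one marker interval are invisible to switch counting (they cancel), so
without this the simulator's truth channel and any switch-based counter
must disagree at a low but nonzero rate. The redraw leaves the count law
untouched and perturbs the position distribution only at the scale of a
single marker interval; in exchange, "events counted from error-free
transmissions equal the simulated truth exactly" is a testable invariant
rather than an approximation.

## Families, genotypes and marker informativeness

The default family design mirrors a two-family sequencing cross: 65 and
82 offspring, five 10-Mb linkage groups at 5 cM/Mb, six inversions of
1–3 Mb at derived-arrangement frequency 0.4, and ~120 markers per LG
(marker densities of 10²–10⁴ per LG are supported). Markers are assigned
an informativeness class (father-only het 20%, mother-only 20%, both 55%,
neither 5%); offspring genotypes are the sum of the two transmitted
parental alleles, with genotyping error modeled as a symmetric uniform
mis-call (a flipped genotype moves to one of the other two states with
equal probability — no allele-dropout bias) and missingness as an
independent mask. Parent karyotypes, when not supplied, are drawn at
Hardy–Weinberg proportions from each inversion's derived frequency.

The marker filters are explicit rather than delegated: the segregation
filter is a Pearson chi-square goodness-of-fit of offspring genotype
counts against the Mendelian ratio for the cross type (1:1 for
backcross-type markers, 1:2:1 for double-het intercross markers), with
df = classes − 1 and threshold p ≥ 0.01. MAF is computed across the
offspring of all families; missingness is computed per family and the
worst family is compared to the 0.1 limit. On undistorted synthetic data
the filter's type-I rate matches its nominal alpha (tested at 2,500
markers).

## Linkage reconstruction

Two-point estimation assumes phase-known, fully informative transmission
vectors — the artifact consumes the simulator's (or pre-phased)
transmissions, so the likelihood is binomial in the recombinant count,
with the phase chosen to maximize the LOD and the `0·log 0 ≡ 0`
convention at the boundary. Grouping is the transitive closure of
`lod > lod_limit` (default 19); component assignment is order-independent
and deterministic. Ordering uses greedy nearest-neighbour seriation from
the most peripheral marker followed by best-improvement 2-opt on the path
(implemented as a tour through a zero-cost depot so prefix and suffix
reversals are ordinary moves), minimizing the sum of adjacent r̂; ties
break toward the lower marker index, and orientation is canonicalized by
physical position where available. Markers with no observed recombinants
between them are genuinely exchangeable at finite sample size; recovery
is therefore judged by Kendall tau and by reaching an objective value at
least as good as the true order, not by exact identity.

`map_distance` accepts r ∈ [0, 0.5]; distances beyond 1,000 cM (r → 0.5)
are capped with a warning, and both mapping functions invert exactly
(round-trip error ≤ 1e-12). Family maps are combined by averaging
cumulative positions of shared markers; no sex-specific dosage model is
attempted for the X.

## Marey maps and rates

Markers sharing a physical position are collapsed to their mean cM;
monotonicity violations are retained but counted as a diagnostic. Local
rate is the OLS slope of cM on Mb inside fixed windows tiling the LG from
its first mapped base; the window defaults to span/20 per LG (the
"automatically calculated" window of the online tool this emulates is
unpublished, so the divisor is exposed). Negative slopes clamp to zero —
rates are physical quantities — with the raw slope kept in a diagnostic
column; a final partial window is kept if it still holds two points.
Misassembly candidates are midpoints of adjacent-marker intervals with
|ΔcM| > 10 by default. Per-LG summary rates are cM/Mb ratios (not
averages of window rates), which is also how the packaged published table
reproduces its printed 3.4–8.7 cM/Mb range.

## Crossover counting and the suppression test

An event is an adjacent pair of non-missing transmission entries with
different haplotypes, localized to the interval between its flanking
informative markers; events are assigned to regions by interval midpoint
(half-open; an any-overlap rule is available behind a flag since the
midpoint convention is an artifact choice). Counts are weighted by
1/(family offspring count) so families of different size contribute
comparably. The suppression test is a one-sided Wilcoxon rank-sum
(heterokaryotype < pooled homokaryotypes, both homozygote classes as one
group) on weighted counts pooled over inversions and parents: exact
(full enumeration of group assignments, ties handled) when both groups
have ≤ 10 observations, normal approximation with tie correction
otherwise. The one-sided default reflects the directional suppression
hypothesis; a two-sided alternative is a flag. Genotyping error creates
spurious double switches; an optional despiking rule (collapsing
single-marker haplotype islands) exists but is off by default because raw
switch counting is the reference behavior.

## Permutation tests

All empirical p-values use the add-one rule
p = (1 + #{null at least as extreme})/(n_perm + 1) and record their seed;
defaults are 1,000 permutations. The rate comparison permutes
collinear/inversion labels over regions with group sizes preserved,
one-sided in the suppression direction. Its calibration experiment
reassigns labels at random (making the null true *and* the labels
exchangeable); note that merely switching suppression off leaves labels
attached to systematically different region geometries — inversions are
1–3 Mb while collinear fragments vary and can be small — and the
mean-difference test is then conservative, which is the expected behavior
of a permutation test under variance heterogeneity, not a defect.

Feature enrichment relocates each inversion-sized segment to a uniform
random start on a uniform random LG that can hold it, rejecting
overlapping placements; relocation was chosen over circular rotation
because the inversions sit on multiple LGs. The permutation unit is the
whole inversion, and every report logs that choice. The p is two-sided
(doubled smaller tail, capped at 1) with an enriched/depleted direction
label and both one-sided tails in the result. Densities are defined as
expected feature bases per genomic base *before* overlap merging; window
densities merge overlaps, so the union density undershoots the nominal
density at high coverage (1 − e^(−d) for a Poisson process).

## Inversion scanning on a population panel

Masking: genotype-level DP < 8 and GQ < 20; site-level biallelism, MAF,
a depth cap at the across-site mean + 1 SD, and an exact one-sided
Hardy–Weinberg heterozygote-excess test (Levene's conditional
distribution, phred-scaled, threshold 54.69). The exact test is a
substitute for the variant-caller statistic of the same name, which is a
likelihood-based quantity; the phred threshold is retained and the
substitution is deliberate and documented.

Windowed Fst is the Weir & Cockerham (1984) weighted estimator
Σa/Σ(a+b+c) over the SNPs in each 100-kb window (20-kb step), between the
two arrangement-homozygote groups; monomorphic and under-called sites are
skipped, and a single-SNP window equals the per-site value by
construction (the Hudson estimator is a possible future flag; the
variance-components form matches the ANOVA oracle to 1e-12). Boundary
calling reports the earliest run of ≥ 3 consecutive windows with
Fst > 0.15, merging qualifying runs across gaps shorter than 3 windows,
from the start of the first window to the end of the last; the interval
is a *differentiation region*, not a breakpoint pair. "Multiple
consecutive windows" is quantified as 3 and configurable. When Fst never
returns below threshold the region simply runs to the end of the track.

PCA genotyping mean-imputes missing genotypes (sites > 20% missing
dropped first), takes PC1, and clusters it with deterministic 1-D 3-means
(quantile initialization + Lloyd). A call is ambiguous unless all three
clusters are occupied, the middle center lies in the middle third of the
homozygote-center interval, and the 3-means solution explains ≥ 0.9 of
the PC1 variance — an unstructured Gaussian PC1 cannot exceed the
Lloyd-Max 3-level quantization limit of ≈ 0.81, while genuine
three-cluster structure exceeds 0.95, so the rule separates real
inversion signals from noise without a significance test. Genotype 0 is
assigned to the larger homozygote cluster (the commoner arrangement);
downstream comparisons must therefore tolerate the 0↔2 relabeling.

LD screening thins to the first SNP per 10-kb bin with MAF > 0.2
(deterministic, no random choice), computes squared dosage correlations,
and reports maximal runs of ≥ 5 consecutive kept SNPs with median
pairwise r² > 0.5 as candidate regions. A known model-level limitation:
under the panel generator's frequency-offset divergence model, SNP
dosages are conditionally independent given the inversion karyotype, so
pairwise r² between inside-inversion SNPs is bounded by
(δ²·Var(k)/(δ²·Var(k)+B))² — about 0.14 at divergence 0.5 and frequency
0.4 even in the most favorable frequency configuration. The r² > 0.5
block rule therefore only fires on panels with near-diagnostic
(fixed-difference) sites, i.e. deeply diverged arrangements; at moderate
divergence the Fst scan and PCA carry the detection. This is a property
of the data model (no within-arrangement haplotype structure is
simulated), stated here so that block-based screens are not expected to
succeed in regimes where they mathematically cannot.

## The synthetic generator: what it does and does not emulate

It emulates the statistical skeleton downstream stages rely on: Mendelian
transmissions with realistic family sizes, per-parent crossover processes
shaped by a known Marey function, inversion suppression by karyotype,
genotyping error/missingness, Hardy–Weinberg panels with
arrangement-diverged frequencies, and TE/gene interval tracks with
configurable density multipliers inside inversions. It does **not**
simulate sequence (no reads, mutation, or selection), within-arrangement
haplotype structure or background LD, population structure across
sampling sites, or reference-bias/mapping artifacts. Passing recovery
tests therefore demonstrates correctness of the inference machinery under
the stated models — not robustness to the full messiness of real
resequencing data, where filtering and structure effects dominate.

## Reproducibility and problem sizes

Every stochastic routine takes an explicit seed; the pipeline expands a
single global seed into per-stage child seeds via
`SeedSequence([seed, stage_index])`, so any stage reruns in isolation,
and equal configurations produce byte-identical report files. The bundled
experiments use desk-scale problem sizes chosen to exercise the study
design while keeping a full run in minutes on one CPU: two families of
65 + 82 offspring on 5 × 10-Mb LGs with 6 inversions and ~120 markers/LG;
linkage recovery at 500 markers / 147 meioses on 2 LGs; a 240-individual
panel with ~1,500 SNPs on a 5-Mb LG; 100–200 seeded replicates for power
and calibration, with 199–999 permutations inside replicates (1,000 is
the single-analysis default).
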