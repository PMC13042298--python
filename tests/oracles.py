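"""Independent oracles used to cross-check the implementation.

Each oracle recomputes a quantity by a different route than the package
(brute force, exhaustive enumeration, exact rational arithmetic, or a
different algebraic formulation) so agreement is informative.
"""
from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np

MISSING = -1


def brute_force_switch_count(hapvec) -> int:
    """Crossover count by explicit pair scan after removing missing entries."""
    clean = [h for h in hapvec if h != MISSING]
    return sum(1 for a, b in zip(clean, clean[1:]) if a != b)


def grid_search_lod(ta, tb, grid_n: int = 200_001):
    """Two-point (r, LOD) by dense likelihood grid search over both phases."""
    ta = np.asarray(ta)
    tb = np.asarray(tb)
    ok = (ta != MISSING) & (tb != MISSING)
    n = int(ok.sum())
    d = int((ta[ok] != tb[ok]).sum())
    best = (np.nan, -np.inf)
    r = np.linspace(0.0, 0.5, grid_n)
    for k in (d, n - d):                      # the two phase labelings
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(k > 0, k * np.log10(np.maximum(r, 1e-300) / 0.5), 0.0) \
                + np.where(n - k > 0,
                           (n - k) * np.log10(np.maximum(1 - r, 1e-300) / 0.5), 0.0)
        i = int(np.nanargmax(ll))
        if ll[i] > best[1]:
            best = (float(r[i]), float(ll[i]))
    return best


def exact_wilcoxon_less_p(x, y) -> float:
    """One-sided (x < y) rank-sum p by full enumeration of group assignments.

    Enumerates every C(n1+n2, n1) split of the pooled sample, computing the
    Mann-Whitney U of the first group with 0.5 credit for ties; p is the
    fraction of splits with U at most the observed value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1 = len(x)
    idx_all = range(len(pooled))
    # U(first group) = #pairs (i in first, j in second) with x_i > y_j (+0.5 ties)
    cmp = (pooled[:, None] > pooled[None, :]).astype(float) \
        + 0.5 * (pooled[:, None] == pooled[None, :])
    u_obs = cmp[np.ix_(range(n1), range(n1, len(pooled)))].sum()
    count = total = 0
    for comb in itertools.combinations(idx_all, n1):
        rest = [i for i in idx_all if i not in comb]
        u = cmp[np.ix_(comb, rest)].sum()
        total += 1
        if u <= u_obs + 1e-9:
            count += 1
    return count / total


def exact_het_excess_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """One-sided heterozygote-excess p by exact rational arithmetic.

    Uses the conditional distribution of heterozygote counts given allele
    counts (Levene's exact Hardy-Weinberg distribution), computed with
    Fractions so there is no floating-point route shared with the
    implementation.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    na = n_het + 2 * n_hom_alt
    rare = min(na, 2 * n - na)

    def weight(h: int) -> Fraction:
        if (rare - h) % 2:
            return Fraction(0)
        return Fraction(2 ** h * math.factorial(n),
                        math.factorial((rare - h) // 2) * math.factorial(h)
                        * math.factorial(n - (rare + h) // 2))

    hs = [h for h in range(rare % 2, rare + 1, 2)]
    ws = [weight(h) for h in hs]
    tot = sum(ws)
    num = sum(w for h, w in zip(hs, ws) if h >= n_het)
    return float(Fraction(num, tot))


def anova_wc_fst(gA: np.ndarray, gB: np.ndarray):
    """Per-site Weir-Cockerham variance components via the nested ANOVA.

    Works from allele indicators (two 0/1 alleles per individual) and the
    observed mean squares of the pops / individuals-within-pops / alleles-
    within-individuals decomposition — a different algebraic route than
    the closed-form frequency formulas.
    """
    out = []
    for ga, gb in zip(np.atleast_2d(gA), np.atleast_2d(gB)):
        pops = []
        for g in (ga, gb):
            g = g[g != MISSING]
            alleles = np.stack([(g >= 1).astype(float), (g == 2).astype(float)], axis=1)
            pops.append(alleles)
        r = 2
        n_i = np.array([len(p) for p in pops], dtype=float)
        n_tot = n_i.sum()
        nc = (n_tot - (n_i ** 2).sum() / n_tot) / (r - 1)
        xbar = sum(p.sum() for p in pops) / (2 * n_tot)
        ssg = sum(((p - p.mean(axis=1, keepdims=True)) ** 2).sum() for p in pops)
        msg = ssg / n_tot
        ssi = sum(2 * ((p.mean(axis=1) - p.mean()) ** 2).sum() for p in pops)
        msi = ssi / (n_tot - r)
        ssp = sum(2 * len(p) * (p.mean() - xbar) ** 2 for p in pops)
        msp = ssp / (r - 1)
        c = msg
        b = (msi - msg) / 2.0
        a = (msp - msi) / (2.0 * nc)
        out.append((a, b, c))
    return np.array(out)


def interval_union_bp(intervals) -> int:
    """Total covered bases by sweeping over every integer-ish boundary."""
    events = []
    for s, e in intervals:
        events.append((s, 1))
        events.append((e, -1))
    events.sort()
    depth = 0
    covered = 0
    prev = None
    for x, d in events:
        if depth > 0 and prev is not None:
            covered += x - prev
        depth += d
        prev = x
    return covered


def enumerate_label_perm_p(values, labels, observed_stat=None) -> float:
    """Exact permutation p for the mean-difference label test (small inputs)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    n_inv = int((labels == "inversion").sum())
    idx = range(len(values))
    obs = (values[labels != "inversion"].mean() - values[labels == "inversion"].mean()
           if observed_stat is None else observed_stat)
    count = total = 0
    for comb in itertools.combinations(idx, n_inv):
        mask = np.zeros(len(values), dtype=bool)
        mask[list(comb)] = True
        stat = values[~mask].mean() - values[mask].mean()
        total += 1
        if stat >= obs - 1e-12:
            count += 1
    return count / total
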