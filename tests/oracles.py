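"""Independent straightforward re-implementations used as test oracles.

Everything here is written against the documented behaviour only, using
plain loops and direct formulas, so it shares no code path with the
package implementation it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy import stats


# --- island caller ---------------------------------------------------------


def oracle_call_islands(fragments, genome, params):
    """Scan-based island caller: returns (chrom, start, end, score, q) tuples."""
    lam = (
        len(fragments)
        * params.window_size
        / (genome.total_length * params.effective_genome_fraction)
    )
    candidates = []
    for chrom in genome:
        L = genome.length(chrom)
        n_win = math.ceil(L / params.window_size)
        counts = [0] * n_win
        for fr in fragments:
            if fr.chrom != chrom:
                continue
            shift = params.fragment_size // 2
            mid = fr.five_prime + shift if fr.strand == "+" else fr.five_prime - shift
            mid = min(max(mid, 0), L - 1)
            counts[mid // params.window_size] += 1
        eligible = [
            stats.poisson.sf(c - 1, lam) <= params.window_p for c in counts
        ]
        idx = [i for i, e in enumerate(eligible) if e]
        runs: list[list[int]] = []
        for i in idx:
            if runs and i - runs[-1][-1] - 1 <= params.gap_size // params.window_size:
                runs[-1].append(i)
            else:
                runs.append([i])
        for run in runs:
            first, last = run[0], run[-1]
            span = counts[first : last + 1]
            elig_counts = [c for c, e in zip(span, eligible[first : last + 1]) if e]
            score = sum(-stats.poisson.logpmf(c, lam) for c in elig_counts)
            total = sum(span)
            p = stats.poisson.sf(total - 1, lam * len(span))
            candidates.append(
                [
                    chrom,
                    first * params.window_size,
                    min((last + 1) * params.window_size, L),
                    float(score),
                    total,
                    float(p),
                ]
            )
    # textbook Benjamini-Hochberg
    m = len(candidates)
    order = sorted(range(m), key=lambda i: candidates[i][5])
    qs = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        q = min(prev, candidates[i][5] * m / rank_from_end)
        qs[i] = q
        prev = q
    out = []
    for cand, q in zip(candidates, qs):
        if q <= params.fdr_threshold:
            out.append((cand[0], cand[1], cand[2], cand[3], q))
    return sorted(out)


# --- stitching -------------------------------------------------------------


def oracle_stitch(intervals, distance):
    """O(n^2) transitive closure merge; returns sorted (chrom, start, end)."""
    items = [[iv.chrom, iv.start, iv.end] for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                if a[0] != b[0]:
                    continue
                gap = max(a[1], b[1]) - min(a[2], b[2])
                if gap <= distance:
                    items[i] = [a[0], min(a[1], b[1]), max(a[2], b[2])]
                    del items[j]
                    changed = True
                    break
            if changed:
                break
    return sorted((c, s, e) for c, s, e in items)


# --- elbow cut -------------------------------------------------------------


def oracle_rank_cut(signals):
    """Brute-force argmax(x - y) with ties to the largest index."""
    s = sorted(signals)
    n = len(s)
    smax = max(s)
    best_i, best_d = 0, -np.inf
    for i in range(n):
        d = i / (n - 1) - s[i] / smax
        if d >= best_d:  # >= keeps the largest tied index
            best_i, best_d = i, d
    cutoff = s[best_i]
    return cutoff, best_i, sum(1 for x in signals if x > cutoff)


# --- coverage --------------------------------------------------------------


def oracle_coverage(fragments, genome, extend_to):
    """Per-base accumulation by explicit loop (bin_size 1)."""
    cov = {c: np.zeros(genome.length(c)) for c in genome}
    for fr in fragments:
        L = genome.length(fr.chrom)
        if fr.strand == "+":
            lo, hi = fr.five_prime, fr.five_prime + extend_to
        else:
            lo, hi = fr.five_prime - extend_to + 1, fr.five_prime + 1
        for p in range(max(0, lo), min(L, hi)):
            cov[fr.chrom][p] += 1
    return cov


# --- GSEA ------------------------------------------------------------------


def oracle_ks_es(gene_order, member_set):
    """Classic unweighted KS enrichment score (weight 0) by direct loop."""
    n = len(gene_order)
    nh = sum(1 for g in gene_order if g in member_set)
    run = 0.0
    best = 0.0
    for g in gene_order:
        if g in member_set:
            run += 1.0 / nh
        else:
            run -= 1.0 / (n - nh)
        if abs(run) > abs(best) or (abs(run) == abs(best) and run > best):
            best = run
    return best


def oracle_exhaustive_p(ranked, set_size, observed_es, weight_p, es_fn):
    """Exact permutation p over all same-size subsets (same-sign, as extreme)."""
    null = [
        es_fn(ranked, list(c), weight_p).es
        for c in combinations(ranked.gene_ids, set_size)
    ]
    sign = 1 if observed_es >= 0 else -1
    extreme = sum(
        1 for e in null if np.sign(e) == sign and abs(e) >= abs(observed_es)
    )
    return extreme / len(null)


# --- hypergeometric --------------------------------------------------------


def oracle_hypergeom_p(universe: int, na: int, nb: int, k: int) -> float:
    """P(overlap >= k) by direct combinatorial sum."""
    total = math.comb(universe, nb)
    return sum(
        math.comb(na, j) * math.comb(universe - na, nb - j)
        for j in range(k, min(na, nb) + 1)
    ) / total


def oracle_hypergeom_enumerate(universe: int, set_a, nb: int, k: int) -> float:
    """P(overlap >= k) by literally enumerating all subsets of size nb."""
    items = list(range(universe))
    a = set(set_a)
    hits = total = 0
    for combo in combinations(items, nb):
        total += 1
        hits += len(a.intersection(combo)) >= k
    return hits / total


# --- paired t-test ---------------------------------------------------------


def oracle_paired_t(x, y):
    """Textbook paired two-tailed t-test."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = len(d)
    sd = d.std(ddof=1)
    t = d.mean() / (sd / math.sqrt(n))
    return 2 * stats.t.sf(abs(t), n - 1)
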