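"""Preranked gene-set enrichment and set-overlap statistics.

Genes are ranked by a differential-expression test statistic; a gene set's
enrichment score (ES) is the signed maximum deviation of a weighted
Kolmogorov-Smirnov running sum (hit steps proportional to |metric|^p, miss
steps uniform). Significance comes from a "gene set" permutation null:
random same-size sets drawn from the ranked universe. The normalized ES
divides by the mean |null ES| of matching sign, nominal p counts same-sign
null scores at least as extreme, and FDR q pools sign-stratified normalized
null scores across sets. Small universes can be enumerated exhaustively,
which makes the nominal p exact.

Also provides the hypergeometric overlap test between gene lists and the
compilation of a composite signature from several sets restricted to
significantly downregulated genes.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "rank_genes",
    "enrichment_score",
    "gsea_preranked",
    "compile_signature",
    "overlap_test",
]


@dataclass(frozen=True)
class RankedList:
    """Genes in descending metric order with a deterministic tie rule."""

    gene_ids: tuple[str, ...]
    metrics: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    running_sum: np.ndarray
    leading_edge: list[str]
    set_size: int
    nes: float = float("nan")
    nominal_p: float = float("nan")
    fdr_q: float = float("nan")


def rank_genes(table: pd.DataFrame) -> RankedList:
    """Rank genes by descending test statistic; ties break lexicographically."""
    if len(table) == 0:
        raise ValueError("empty expression table; nothing to rank")
    if table["gene_id"].duplicated().any():
        dup = table["gene_id"][table["gene_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate gene {dup!r} in ranking input")
    df = table.sort_values(
        ["stat", "gene_id"], ascending=[False, True], kind="stable"
    )
    return RankedList(tuple(df["gene_id"]), tuple(float(x) for x in df["stat"]))


def enrichment_score(
    ranked: RankedList, members: Sequence[str], weight_p: float = 1.0, set_name: str = ""
) -> EnrichmentResult:
    """Weighted KS enrichment score of a gene set in a ranked list.

    Hit steps are |metric|^p normalized over hits; miss steps are uniform
    1/(N - N_hits); the ES is the running sum's extremum (the more extreme
    of max and min, positive winning exact ties). The leading edge contains
    the members at or before the extremum (at or after it for negative ES).
    """
    universe = set(ranked.gene_ids)
    hits = universe.intersection(members)
    if not hits:
        raise ValueError(f"gene set {set_name!r} is disjoint from the ranked universe")
    n = len(ranked)
    hit_mask = np.array([g in hits for g in ranked.gene_ids])
    if len(hits) == n:
        warnings.warn(f"gene set {set_name!r} equals the universe; ES defined as 1")
        return EnrichmentResult(set_name, 1.0, np.ones(n), list(ranked.gene_ids), n)
    w = np.abs(np.asarray(ranked.metrics)) ** weight_p
    hit_w = np.where(hit_mask, w, 0.0)
    total_hit = hit_w.sum()
    if total_hit == 0:  # all hit metrics are exactly zero: fall back to equal steps
        hit_w = hit_mask.astype(float)
        total_hit = hit_w.sum()
    miss_step = 1.0 / (n - len(hits))
    steps = hit_w / total_hit - np.where(hit_mask, 0.0, miss_step)
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        es, i_es = float(running[i_max]), i_max
        leading = [g for g in ranked.gene_ids[: i_es + 1] if g in hits]
    else:
        es, i_es = float(running[i_min]), i_min
        leading = [g for g in ranked.gene_ids[i_es:] if g in hits]
    return EnrichmentResult(set_name, es, running, leading, len(hits))


def _null_scores(
    ranked: RankedList,
    set_size: int,
    n_perm: int,
    rng: np.random.Generator,
    weight_p: float,
    exhaustive: bool,
) -> np.ndarray:
    ids = ranked.gene_ids
    if exhaustive:
        combos = itertools.combinations(ids, set_size)
        return np.array(
            [enrichment_score(ranked, c, weight_p).es for c in combos]
        )
    n = len(ids)
    out = np.empty(n_perm)
    for j in range(n_perm):
        pick = rng.choice(n, size=set_size, replace=False)
        out[j] = enrichment_score(ranked, [ids[i] for i in pick], weight_p).es
    return out


def gsea_preranked(
    ranked: RankedList,
    gene_sets: dict[str, Sequence[str]],
    n_perm: int = 1000,
    seed: int | None = None,
    weight_p: float = 1.0,
    exhaustive: bool = False,
) -> dict[str, EnrichmentResult]:
    """Preranked GSEA with a gene-set permutation null.

    For each set the null is the ES of ``n_perm`` random same-size subsets
    of the universe (all subsets when ``exhaustive``). NES = ES / mean
    |null ES| of the same sign; nominal p = (1 + #{same-sign null >= ES}) /
    (n_perm + 1) (exact ratio when exhaustive); FDR q compares each NES to
    the pooled sign-matched normalized null across all sets, divided by the
    fraction of observed NES at least as extreme, capped at 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if seed is None and not exhaustive:
        raise ValueError("a seed is required for reproducible permutations")
    n = len(ranked)
    rng = np.random.default_rng(seed)
    results: dict[str, EnrichmentResult] = {}
    null_by_set: dict[str, np.ndarray] = {}
    for name, members in gene_sets.items():
        size = len(set(ranked.gene_ids).intersection(members))
        if size > n:
            raise ValueError(f"gene set {name!r} larger than the universe")
        res = enrichment_score(ranked, members, weight_p, set_name=name)
        if res.set_size == n:  # degenerate: set equals universe
            res.nes, res.nominal_p, res.fdr_q = 1.0, 1.0 / (n_perm + 1), 0.0
            results[name] = res
            continue
        null = _null_scores(ranked, res.set_size, n_perm, rng, weight_p, exhaustive)
        null_by_set[name] = null
        same = null[np.sign(null) == np.sign(res.es)] if res.es != 0 else null
        extreme = int((np.abs(same) >= abs(res.es)).sum())
        if exhaustive:
            res.nominal_p = extreme / len(null)
        else:
            res.nominal_p = (1 + extreme) / (n_perm + 1)
        denom = np.abs(same).mean() if len(same) else float("nan")
        res.nes = res.es / denom if denom and denom > 0 else float("nan")
        results[name] = res
    _assign_fdr(results, null_by_set)
    return results


def _assign_fdr(
    results: dict[str, EnrichmentResult], null_by_set: dict[str, np.ndarray]
) -> None:
    """Sign-stratified pooled-null FDR over normalized enrichment scores."""
    pooled: list[float] = []
    for name, null in null_by_set.items():
        for sign in (1, -1):
            same = null[np.sign(null) == sign]
            if len(same):
                pooled.extend(sign * np.abs(same) / np.abs(same).mean())
    pooled_arr = np.asarray(pooled)
    observed = np.array(
        [r.nes for r in results.values() if r.set_name in null_by_set and np.isfinite(r.nes)]
    )
    for name, res in results.items():
        if name not in null_by_set or not np.isfinite(res.nes):
            continue
        sign = 1 if res.es >= 0 else -1
        null_same = pooled_arr[np.sign(pooled_arr) == sign]
        obs_same = observed[np.sign(observed) == sign]
        if len(null_same) == 0 or len(obs_same) == 0:
            res.fdr_q = 1.0
            continue
        frac_null = (np.abs(null_same) >= abs(res.nes)).mean()
        frac_obs = (np.abs(obs_same) >= abs(res.nes)).mean()
        res.fdr_q = float(min(1.0, frac_null / frac_obs)) if frac_obs > 0 else 1.0


def compile_signature(
    gene_sets: dict[str, Sequence[str]],
    expression_tables: Sequence[pd.DataFrame],
    fdr_threshold: float = 0.05,
) -> list[str]:
    """Composite signature: union of set members that are significantly
    downregulated (log2fc < 0 and fdr < threshold) in at least one table."""
    if not gene_sets or not len(expression_tables):
        raise ValueError("need at least one gene set and one expression table")
    union: set[str] = set()
    for members in gene_sets.values():
        union.update(members)
    down: set[str] = set()
    for tbl in expression_tables:
        sig = tbl[(tbl["log2fc"] < 0) & (tbl["fdr"] < fdr_threshold)]
        down.update(sig["gene_id"])
    signature = sorted(union & down)
    if not signature:
        warnings.warn("compiled signature is empty: no set member is downregulated")
    return signature


def overlap_test(
    set_a: Sequence[str], set_b: Sequence[str], universe_size: int
) -> tuple[float, int]:
    """Hypergeometric upper-tail test of the overlap between two gene lists.

    p = P(X >= observed overlap) with X ~ Hypergeom(universe, |a|, |b|).
    """
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("set larger than the universe")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return min(1.0, p), k
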