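"""Set-overlap statistics, random-gene-set controls, and permutation GSEA.

Fisher's exact test (two-sided, probability-ordering definition) and the
hypergeometric upper tail are thin wrappers over scipy; the random-set
control reproduces the blinded in-situ scoring comparison, where a
candidate list's fraction of positively scored genes is tested against
randomly drawn gene lists of comparable size. GSEA follows the classic
weighted Kolmogorov-Smirnov running sum with a gene-shuffling null:
hit steps are |score|^p normalized by the in-set total, miss steps are
-1/(N - |S|), ES is the signed extremum, NES divides by the mean |ES| of
same-sign permutations, and the permutation p is the same-sign exceedance
fraction (with add-one smoothing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class FisherResult:
    odds_ratio: float
    p_value: float


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> FisherResult:
    """Two-sided Fisher's exact test with the ad/bc odds-ratio convention."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any():
        raise ValueError("table entries must be nonnegative")
    a, b = arr[0]
    c, d = arr[1]
    if b * c == 0:
        oddsr = np.inf if a * d > 0 else (0.0 if a * d == 0 else np.nan)
    else:
        oddsr = (a * d) / (b * c)
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return FisherResult(float(oddsr), float(p))


def hypergeom_overlap(set_a: set[str], set_b: set[str],
                      universe: set[str]) -> float:
    """Upper-tail P(X >= |A ∩ B|) for hypergeometric overlap in a universe."""
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be contained in the universe")
    k = len(set_a & set_b)
    return float(stats.hypergeom.sf(k - 1, len(universe),
                                    len(set_a), len(set_b)))


@dataclass
class RandomSetComparison:
    candidate_fraction: float
    random_fractions: list[float]
    fisher: list[FisherResult]


def random_set_control(
    scores: pd.DataFrame,
    candidate: Sequence[str],
    n_random_sets: int = 2,
    size_range: tuple[int, int] | None = None,
    positive_score_set: frozenset[int] = frozenset({3}),
    seed: int = 0,
) -> RandomSetComparison:
    """Blinded-scoring control: candidate positivity vs random gene lists.

    ``scores`` is indexed by gene with a ``score`` column (0-3 rubric).
    Random sets are drawn without replacement from scored non-candidate
    genes; each comparison is a 2x2 Fisher test of positive/negative
    counts (positivity = score in ``positive_score_set``).
    """
    candidate = list(dict.fromkeys(candidate))
    missing = [g for g in candidate if g not in scores.index]
    if missing:
        raise ValueError(f"candidate genes not scored: {missing[:5]}")
    pool = scores.index.difference(candidate)
    if size_range is None:
        size_range = (len(candidate), len(candidate))
    lo, hi = size_range
    if hi > len(pool):
        raise ValueError("size_range exceeds the scored non-candidate pool")

    def positive(genes) -> int:
        return int(scores.loc[list(genes), "score"]
                   .isin(list(positive_score_set)).sum())

    cand_pos = positive(candidate)
    cand_frac = cand_pos / len(candidate) if candidate else 0.0
    rng = np.random.default_rng(seed)
    fractions, tests = [], []
    for _ in range(n_random_sets):
        size = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(pool.to_numpy(), size=size, replace=False)
        rand_pos = positive(chosen)
        fractions.append(rand_pos / size)
        tests.append(fisher_exact_2x2(
            [[cand_pos, len(candidate) - cand_pos],
             [rand_pos, size - rand_pos]]))
    return RandomSetComparison(cand_frac, fractions, tests)


@dataclass
class GseaResult:
    set_name: str
    set_size: int
    es: float
    nes: float
    p_value: float
    fdr: float
    n_perm: int


def _enrichment_score(scores: np.ndarray, inset: np.ndarray,
                      weight_p: float) -> float:
    """Signed extremum of the weighted running sum over the ranking."""
    n = scores.size
    n_hit = int(inset.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("gene set must hit a strict subset of the ranking")
    if weight_p == 0:
        hit_w = np.ones(n)
    else:
        hit_w = np.abs(scores) ** weight_p
    denom = hit_w[inset].sum()
    if denom == 0:
        hit_w = np.ones(n)
        denom = float(n_hit)
    steps = np.where(inset, hit_w / denom, -1.0 / (n - n_hit))
    run = np.cumsum(steps)
    i = int(np.argmax(np.abs(run)))
    return float(run[i])


def gsea(
    ranked: Sequence[tuple[str, float]],
    gene_set: Sequence[str],
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> GseaResult:
    """Permutation GSEA for one gene set against a descending ranking.

    The null shuffles gene labels, i.e. places the same number of set
    members at random ranks. With a single set the reported FDR equals the
    permutation p; use :func:`gsea_collection` for the NES-ratio FDR
    across several sets.
    """
    res = gsea_collection(ranked, {"set": list(gene_set)},
                          weight_p=weight_p, n_perm=n_perm, seed=seed)
    out = res[0]
    return GseaResult(out.set_name, out.set_size, out.es, out.nes,
                      out.p_value, out.p_value, out.n_perm)


def gsea_collection(
    ranked: Sequence[tuple[str, float]],
    gene_sets: Mapping[str, Sequence[str]],
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[GseaResult]:
    """GSEA over several sets with the same-sign NES-ratio FDR convention."""
    genes = [g for g, _ in ranked]
    if len(genes) != len(set(genes)):
        raise ValueError("duplicate genes in ranking")
    scores = np.array([s for _, s in ranked], dtype=float)
    if np.any(np.diff(scores) > 1e-12):
        raise ValueError("ranking must be sorted by descending score")
    pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    obs_nes: list[float] = []
    null_nes_pool: list[np.ndarray] = []
    partial: list[tuple[str, int, float, float, float]] = []
    n = len(genes)
    for name, members in gene_sets.items():
        inset = np.zeros(n, dtype=bool)
        hits = [pos[g] for g in members if g in pos]
        if not hits:
            raise ValueError(f"gene set {name!r} does not intersect the ranking")
        inset[hits] = True
        es = _enrichment_score(scores, inset, weight_p)
        n_hit = len(set(hits))
        null_es = np.empty(n_perm)
        for k in range(n_perm):
            perm = np.zeros(n, dtype=bool)
            perm[rng.choice(n, size=n_hit, replace=False)] = True
            null_es[k] = _enrichment_score(scores, perm, weight_p)
        same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 \
            else null_es
        if same_sign.size == 0:
            nes = np.nan
            p = 1.0 / (n_perm + 1)
        else:
            nes = es / np.abs(same_sign).mean()
            p = (1 + int((np.abs(same_sign) >= abs(es)).sum())) \
                / (1 + same_sign.size)
        # normalized null for the FDR pool
        pos_null = null_es[null_es > 0]
        neg_null = null_es[null_es < 0]
        norm_null = np.concatenate([
            pos_null / pos_null.mean() if pos_null.size else pos_null,
            neg_null / np.abs(neg_null).mean() if neg_null.size else neg_null,
        ])
        null_nes_pool.append(norm_null)
        obs_nes.append(nes)
        partial.append((name, n_hit, es, float(nes), float(p)))

    pool = np.concatenate(null_nes_pool) if null_nes_pool else np.array([])
    obs_arr = np.array(obs_nes, dtype=float)
    results = []
    for name, size, es, nes, p in partial:
        if not np.isfinite(nes):
            fdr = 1.0
        else:
            if nes >= 0:
                null_frac = np.mean(pool >= nes) if pool.size else 0.0
                obs_frac = np.mean(obs_arr[np.isfinite(obs_arr)] >= nes)
            else:
                null_frac = np.mean(pool <= nes) if pool.size else 0.0
                obs_frac = np.mean(obs_arr[np.isfinite(obs_arr)] <= nes)
            fdr = float(np.clip(null_frac / max(obs_frac, 1e-12), 0.0, 1.0))
        results.append(GseaResult(name, size, es, nes, p, fdr, n_perm))
    return results


def gsea_results_to_tsv(results: Sequence[GseaResult], path, seed: int) -> None:
    pd.DataFrame([{
        "set": r.set_name, "size": r.set_size, "ES": r.es, "NES": r.nes,
        "pvalue": r.p_value, "FDR": r.fdr, "n_perm": r.n_perm, "seed": seed,
    } for r in results]).to_csv(path, sep="\t", index=False)
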