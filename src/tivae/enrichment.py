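"""Running-sum gene-set enrichment with gene-set-sampling empirical p-values.

The gene statistic S is signed: for a tissue's prioritized lists,
S_gene = (up occurrence count) - (down occurrence count), zero for every
other gene of the universe. Genes are ranked by descending S (ties broken by
gene ID); walking the ranking, a gene-set hit adds |S|^w normalized by the
summed hit weights and a miss subtracts 1/(N - set size). The enrichment
score is the running-sum extremum of largest magnitude, so positive scores
mean concentration among upregulated genes and negative among downregulated
ones. Significance comes from uniformly re-sampling gene sets of the same
size: the empirical p-value conditions on the permutation scores of the same
sign (with a pseudo-count so p is never zero), and NES divides the observed
score by the mean magnitude of same-sign permutation scores.
Benjamini-Hochberg controls the FDR across a result batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from statsmodels.stats.multitest import multipletests

from .prioritization import TissueGeneLists
from .synthetic import GeneSetCollection

__all__ = [
    "RankedGeneStatistic",
    "EnrichmentResult",
    "build_gene_statistic",
    "build_differential_statistic",
    "enrichment_score",
    "empirical_pvalue",
    "enrich_collection",
    "adjust_fdr",
]


@dataclass
class RankedGeneStatistic:
    """Signed per-gene statistic with its deterministic descending ranking."""

    scores: dict[str, float]
    ranked_genes: list[str] = field(init=False)
    ranked_values: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        values = np.array(list(self.scores.values()), dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("gene statistic contains non-finite values")
        self.ranked_genes = sorted(self.scores, key=lambda g: (-self.scores[g], g))
        self.ranked_values = np.array([self.scores[g] for g in self.ranked_genes])

    @property
    def universe(self) -> set[str]:
        return set(self.scores)


def build_gene_statistic(
    lists: TissueGeneLists, tissue: str, universe: list[str]
) -> RankedGeneStatistic:
    """S = up count - down count over a tissue's retained lists, 0 elsewhere."""
    if tissue not in lists.up_counts:
        raise ValueError(f"no lists for tissue {tissue!r}")
    up = lists.retained_up.get(tissue, [])
    down = lists.retained_down.get(tissue, [])
    if not up and not down:
        raise ValueError(
            f"tissue {tissue!r} has empty retained lists; skip it in enrichment"
        )
    scores = {g: 0.0 for g in universe}
    for g in up:
        scores[g] = scores.get(g, 0.0) + lists.up_counts[tissue][g]
    for g in down:
        scores[g] = scores.get(g, 0.0) - lists.down_counts[tissue][g]
    return RankedGeneStatistic(scores=scores)


def build_differential_statistic(
    case_lists: TissueGeneLists,
    control_lists: TissueGeneLists,
    tissue: str,
    universe: list[str],
) -> RankedGeneStatistic:
    """Case-minus-control signed occurrence counts: the disease-specific statistic.

    S = (case up count - case down count) - (control up count - control down
    count), over all counted genes (no retention threshold), 0 elsewhere.
    Structure shared by case and control embeddings — tissue signatures,
    missing-gene patterns — appears with equal counts in both and cancels,
    leaving genes differentially regulated in cases but not in controls.
    The smooth counts avoid the cliff a retention cutoff would introduce.
    """
    if tissue not in case_lists.up_counts or tissue not in control_lists.up_counts:
        raise ValueError(f"no lists for tissue {tissue!r}")
    scores = {g: 0.0 for g in universe}
    counted = (
        set(case_lists.up_counts[tissue])
        | set(case_lists.down_counts[tissue])
        | set(control_lists.up_counts[tissue])
        | set(control_lists.down_counts[tissue])
    )
    if not counted:
        raise ValueError(
            f"tissue {tissue!r} has no counted genes; skip it in enrichment"
        )
    for g in counted:
        case_s = case_lists.up_counts[tissue][g] - case_lists.down_counts[tissue][g]
        control_s = control_lists.up_counts[tissue][g] - control_lists.down_counts[tissue][g]
        scores[g] = float(case_s - control_s)
    return RankedGeneStatistic(scores=scores)


def _running_sum_es(
    abs_weights: np.ndarray, hit_mask: np.ndarray
) -> tuple[float, int]:
    """Signed extremum of the running sum and its position (internal core)."""
    n = hit_mask.size
    n_hits = int(hit_mask.sum())
    hit_weight = abs_weights * hit_mask
    total = hit_weight.sum()
    if total > 0:
        increments = hit_weight / total
    else:  # all hit statistics are zero: fall back to uniform hit increments
        increments = hit_mask / n_hits
    miss = n - n_hits
    decrement = 1.0 / miss if miss else 0.0
    steps = np.where(hit_mask, increments, -decrement)
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if abs(running[i_max]) >= abs(running[i_min]):
        return float(running[i_max]), i_max
    return float(running[i_min]), i_min


def enrichment_score(
    stat: RankedGeneStatistic,
    gene_set: set[str] | list[str],
    weight_exponent: float = 1.0,
) -> tuple[float, list[str]]:
    """Enrichment score of a gene set against the ranked statistic.

    Returns the signed score and the leading-edge genes: for a positive score
    the set members at or before the running-sum maximum, for a negative one
    the members at or after the minimum.
    """
    members = set(gene_set) & stat.universe
    if not members:
        raise ValueError("gene set is disjoint from the statistic's universe")
    hit_mask = np.array([g in members for g in stat.ranked_genes])
    abs_w = np.abs(stat.ranked_values) ** weight_exponent
    es, pos = _running_sum_es(abs_w, hit_mask)
    if es > 0:
        leading = [g for i, g in enumerate(stat.ranked_genes) if hit_mask[i] and i <= pos]
    elif es < 0:
        leading = [g for i, g in enumerate(stat.ranked_genes) if hit_mask[i] and i >= pos]
    else:
        leading = []
    return es, leading


def empirical_pvalue(
    stat: RankedGeneStatistic,
    gene_set: set[str] | list[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> tuple[float, float]:
    """Empirical p-value and NES by uniform same-size gene-set sampling.

    p = (1 + #{same-sign permutation scores at least as extreme}) /
        (1 + #{same-sign permutation scores}); NES = ES / mean |same-sign
    permutation score|. With no same-sign permutation score the p-value
    floors at 1/(1 + n_perm) and NES is reported missing (NaN). A zero
    observed score yields p = 1 and NES = 0. Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable empirical p-value")
    es, _ = enrichment_score(stat, gene_set, weight_exponent)
    if es == 0.0:
        return 1.0, 0.0
    size = len(set(gene_set) & stat.universe)
    n = len(stat.ranked_genes)
    rng = np.random.default_rng(seed)
    abs_w = np.abs(stat.ranked_values) ** weight_exponent

    perm_es = np.empty(n_perm)
    hit_mask = np.zeros(n, dtype=bool)
    for r in range(n_perm):
        idx = rng.choice(n, size=size, replace=False)
        hit_mask[:] = False
        hit_mask[idx] = True
        perm_es[r], _ = _running_sum_es(abs_w, hit_mask)

    same_sign = perm_es > 0 if es > 0 else perm_es < 0
    m = int(same_sign.sum())
    if m == 0:
        return 1.0 / (1.0 + n_perm), float("nan")
    extreme = int((np.abs(perm_es[same_sign]) >= abs(es)).sum())
    pval = (1.0 + extreme) / (1.0 + m)
    nes = es / float(np.mean(np.abs(perm_es[same_sign])))
    return pval, nes


@dataclass
class EnrichmentResult:
    """One gene set's enrichment against one ranked statistic (a table row)."""

    pathway: str
    es: float
    nes: float
    pval: float
    padj: float
    size: int
    leading_edge: list[str]


def enrich_collection(
    stat: RankedGeneStatistic,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> list[EnrichmentResult]:
    """Score every gene set of a collection and BH-adjust within the batch.

    Gene sets disjoint from the universe are skipped. Each set gets its own
    deterministic permutation stream derived from ``seed``.
    """
    results: list[EnrichmentResult] = []
    for i, (name, genes) in enumerate(sorted(collection.sets.items())):
        members = set(genes) & stat.universe
        if not members:
            continue
        es, leading = enrichment_score(stat, members, weight_exponent)
        pval, nes = empirical_pvalue(stat, members, n_perm, seed + i, weight_exponent)
        results.append(
            EnrichmentResult(
                pathway=name,
                es=es,
                nes=nes,
                pval=pval,
                padj=float("nan"),
                size=len(members),
                leading_edge=leading,
            )
        )
    return adjust_fdr(results)


def adjust_fdr(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """Benjamini-Hochberg step-up over the batch's p-values."""
    if not results:
        raise ValueError("no enrichment results to adjust")
    pvals = np.array([r.pval for r in results])
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    return [replace(r, padj=float(a)) for r, a in zip(results, padj)]
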