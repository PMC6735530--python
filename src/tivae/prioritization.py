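"""Gene prioritization from decoder weights of tissue-associated latent units.

Because the embedding has a single hidden layer, each latent unit is
connected to every reconstructed gene by one linear weight, so the relative
importance of a gene to a unit is read directly off the decoder weight
matrix: the k most positive weights give the unit's upregulated list, the k
most negative its downregulated list. Lists from every repeat's associated
units are pooled per tissue and direction; a gene is retained when it
appears strictly more than ``min_count`` times. The disease-specific
signature of a tissue is the set of genes retained from the case-model
lists but absent from the control-model lists.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matching import TissueLatentMap
from .vae import VAEModel

__all__ = [
    "UnitGeneRanking",
    "TissueGeneLists",
    "SignatureLists",
    "rank_unit_genes",
    "tissue_rankings",
    "aggregate_across_vaes",
    "disease_signature",
    "export_gene_lists",
]


@dataclass
class UnitGeneRanking:
    """Top-k positively and negatively weighted genes of one latent unit."""

    unit: int
    up_genes: list[str]
    down_genes: list[str]


@dataclass
class TissueGeneLists:
    """Per-tissue occurrence-counted up/down gene lists after the count filter."""

    up_counts: dict[str, Counter] = field(default_factory=dict)
    down_counts: dict[str, Counter] = field(default_factory=dict)
    retained_up: dict[str, list[str]] = field(default_factory=dict)
    retained_down: dict[str, list[str]] = field(default_factory=dict)
    class_tag: str = ""
    min_count: int = 3
    #: tissues that had no associated latent unit in any repeat
    unmatched_tissues: list[str] = field(default_factory=list)

    @property
    def tissues(self) -> list[str]:
        return sorted(self.up_counts)

    def combined_retained(self, tissue: str) -> list[str]:
        return sorted(set(self.retained_up.get(tissue, [])) | set(self.retained_down.get(tissue, [])))


@dataclass
class SignatureLists:
    """Genes regulated in case-model lists but not control-model lists."""

    up: dict[str, list[str]]
    down: dict[str, list[str]]
    #: case-list occurrence counts carried along for export
    up_counts: dict[str, Counter] = field(default_factory=dict)
    down_counts: dict[str, Counter] = field(default_factory=dict)

    @property
    def tissues(self) -> list[str]:
        return sorted(self.up)


def rank_unit_genes(model: VAEModel, unit: int, k: int = 100) -> UnitGeneRanking:
    """Select the k most positive and k most negative decoder weights of a unit.

    Ties are broken by gene ID (lexicographic), making the lists fully
    deterministic. Raises when the lists would overlap (k > n_genes / 2).
    """
    if not 0 <= unit < model.latent_dim:
        raise ValueError(f"unit {unit} outside latent dimension {model.latent_dim}")
    genes = model.gene_universe
    if genes is None:
        genes = [f"g{j}" for j in range(model.n_genes)]
    if 2 * k > len(genes):
        raise ValueError(f"k={k} would make up/down lists overlap over {len(genes)} genes")
    weights = model.decoder_weights[unit]
    order_up = sorted(range(len(genes)), key=lambda j: (-weights[j], genes[j]))
    order_down = sorted(range(len(genes)), key=lambda j: (weights[j], genes[j]))
    return UnitGeneRanking(
        unit=unit,
        up_genes=[genes[j] for j in order_up[:k]],
        down_genes=[genes[j] for j in order_down[:k]],
    )


def tissue_rankings(
    models: list[VAEModel],
    maps: list[TissueLatentMap],
    k: int = 100,
) -> dict[str, list[UnitGeneRanking]]:
    """Group unit rankings by tissue across repeats via each repeat's latent map.

    A unit associated with several tissues contributes its ranking to each of
    them. Tissues with no associated unit in any repeat map to empty lists.
    """
    if len(models) != len(maps):
        raise ValueError("one TissueLatentMap per model is required")
    tissues: set[str] = set()
    for m in maps:
        tissues.update(m.f1_matrix.columns)
    grouped: dict[str, list[UnitGeneRanking]] = {t: [] for t in sorted(tissues)}
    for model, lat_map in zip(models, maps):
        for tissue in lat_map.f1_matrix.columns:
            for unit in sorted(lat_map.associated_units(tissue)):
                grouped[tissue].append(rank_unit_genes(model, unit, k))
    return grouped


def aggregate_across_vaes(
    rankings: dict[str, list[UnitGeneRanking]],
    min_count: int = 3,
    class_tag: str = "",
) -> TissueGeneLists:
    """Count gene occurrences over all (repeat, unit) rankings of each tissue.

    Counting is within direction and tissue; a gene is retained iff its count
    exceeds ``min_count`` strictly. A tissue without any contributing ranking
    yields empty lists and is flagged, not an error.
    """
    lists = TissueGeneLists(class_tag=class_tag, min_count=min_count)
    for tissue, unit_rankings in rankings.items():
        up = Counter()
        down = Counter()
        for ranking in unit_rankings:
            up.update(ranking.up_genes)
            down.update(ranking.down_genes)
        lists.up_counts[tissue] = up
        lists.down_counts[tissue] = down
        lists.retained_up[tissue] = sorted(g for g, c in up.items() if c > min_count)
        lists.retained_down[tissue] = sorted(g for g, c in down.items() if c > min_count)
        if not unit_rankings:
            lists.unmatched_tissues.append(tissue)
    return lists


def disease_signature(
    case_lists: TissueGeneLists, control_lists: TissueGeneLists
) -> SignatureLists:
    """Per tissue and direction: case retained genes absent from control lists."""
    if set(case_lists.up_counts) != set(control_lists.up_counts):
        raise ValueError("case and control lists cover different tissue sets")
    up: dict[str, list[str]] = {}
    down: dict[str, list[str]] = {}
    up_counts: dict[str, Counter] = {}
    down_counts: dict[str, Counter] = {}
    for tissue in case_lists.up_counts:
        up[tissue] = sorted(
            set(case_lists.retained_up[tissue]) - set(control_lists.retained_up[tissue])
        )
        down[tissue] = sorted(
            set(case_lists.retained_down[tissue]) - set(control_lists.retained_down[tissue])
        )
        up_counts[tissue] = Counter({g: case_lists.up_counts[tissue][g] for g in up[tissue]})
        down_counts[tissue] = Counter({g: case_lists.down_counts[tissue][g] for g in down[tissue]})
    return SignatureLists(up=up, down=down, up_counts=up_counts, down_counts=down_counts)


def _rows_for_export(lists: TissueGeneLists | SignatureLists):
    if isinstance(lists, TissueGeneLists):
        for tissue in lists.tissues:
            both = set(lists.retained_up[tissue]) & set(lists.retained_down[tissue])
            for direction, retained, counts in (
                ("up", lists.retained_up[tissue], lists.up_counts[tissue]),
                ("down", lists.retained_down[tissue], lists.down_counts[tissue]),
            ):
                for gene in retained:
                    yield tissue, direction, gene, counts[gene], gene in both
    else:
        for tissue in lists.tissues:
            for direction, retained, counts in (
                ("up", lists.up[tissue], lists.up_counts.get(tissue, Counter())),
                ("down", lists.down[tissue], lists.down_counts.get(tissue, Counter())),
            ):
                both = set(lists.up[tissue]) & set(lists.down[tissue])
                for gene in retained:
                    yield tissue, direction, gene, counts.get(gene, 0), gene in both


def export_gene_lists(lists: TissueGeneLists | SignatureLists, path: str | Path) -> pd.DataFrame:
    """Write one TSV row per (tissue, direction, gene, count).

    Ordered by tissue, direction, count descending, gene ID; genes appearing
    in both directions are flagged. Returns the written frame.
    """
    frame = pd.DataFrame(
        _rows_for_export(lists),
        columns=["tissue", "direction", "gene", "count", "both_directions"],
    )
    frame = frame.sort_values(
        by=["tissue", "direction", "count", "gene"],
        ascending=[True, True, False, True],
    ).reset_index(drop=True)
    frame["count"] = frame["count"].astype(int) if len(frame) else frame["count"]
    frame.to_csv(path, sep="\t", index=False)
    return frame
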