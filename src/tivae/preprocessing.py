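"""Reading, scaling, stacking and splitting of per-tissue expression matrices.

The embedding stage consumes one design matrix whose rows are
(individual, tissue) pairs over the union gene universe: each tissue matrix
is min-max scaled to [0, 1] per gene, genes absent from a tissue are filled
with exactly 0, and rows are ordered tissue-major (tissues in declared
order, individuals in cohort order). Splits are stratified so every stratum
keeps the requested train fraction to within one row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import CASE, CONTROL, GeneSetCollection, MultiTissueDataset, PlantedTruth

__all__ = [
    "ScalingParams",
    "StackedDataset",
    "SplitIndex",
    "PhenotypeLabels",
    "scale_minmax",
    "stack_tissues",
    "split_stratified",
    "compute_decline_labels",
    "subset_by_stratum",
    "read_dataset",
]


@dataclass
class ScalingParams:
    """Per-gene min/max learned on a fitting partition."""

    minimum: pd.Series
    maximum: pd.Series

    def __post_init__(self) -> None:
        if (self.maximum < self.minimum).any():
            raise ValueError("scaling params violate max >= min")


def scale_minmax(
    matrix: pd.DataFrame, params: ScalingParams | None = None
) -> tuple[pd.DataFrame, ScalingParams]:
    """Scale each gene column to [0, 1].

    When ``params`` is None the per-gene min/max are fit on ``matrix`` itself;
    otherwise the supplied params (from another partition) are applied and the
    result is clipped into [0, 1]. A constant gene (max == min) maps to 0
    everywhere, which keeps the output in range without special-casing
    downstream.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("cannot scale an empty matrix")
    fit_here = params is None
    if params is None:
        params = ScalingParams(minimum=matrix.min(axis=0), maximum=matrix.max(axis=0))
    span = (params.maximum - params.minimum).to_numpy()
    degenerate = span <= 0
    safe_span = np.where(degenerate, 1.0, span)
    scaled = (matrix.to_numpy() - params.minimum.to_numpy()) / safe_span
    scaled[:, degenerate] = 0.0
    if not fit_here:
        scaled = np.clip(scaled, 0.0, 1.0)
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns), params


@dataclass
class StackedDataset:
    """(individual, tissue) rows over the union gene universe, values in [0, 1]."""

    matrix: np.ndarray
    row_meta: pd.DataFrame  # columns: individual, tissue, label
    gene_universe: list[str]

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != len(self.row_meta):
            raise ValueError("matrix rows and row_meta length differ")
        if self.matrix.shape[1] != len(self.gene_universe):
            raise ValueError("matrix columns and gene_universe length differ")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def rows_for(self, mask: np.ndarray) -> "StackedDataset":
        return StackedDataset(
            matrix=self.matrix[mask],
            row_meta=self.row_meta.loc[mask].reset_index(drop=True),
            gene_universe=self.gene_universe,
        )

    def class_partition(self) -> tuple["StackedDataset", "StackedDataset"]:
        """Split rows into (case rows, control rows)."""
        labels = self.row_meta["label"].to_numpy()
        return self.rows_for(labels == CASE), self.rows_for(labels == CONTROL)


def stack_tissues(dataset: MultiTissueDataset) -> StackedDataset:
    """Stack all tissues over the union universe, scaled to [0, 1], zero-filled.

    The gene universe is the sorted union of the tissue gene subsets. Each
    gene is min-max scaled over all stacked rows where it is present (any
    tissue), so cross-tissue mean differences — the signal latent units
    specialize on — survive scaling; entries for genes absent from a row's
    tissue (the NaNs of a rectangular concatenation) are then set to exactly
    0. A single-tissue dataset therefore reduces to the per-gene scaled
    input.
    """
    universe = dataset.gene_universe
    col_index = {g: j for j, g in enumerate(universe)}
    n_ind = len(dataset.labels)
    n_rows = n_ind * len(dataset.tissues)
    matrix = np.full((n_rows, len(universe)), np.nan)

    meta_records = []
    for t, tissue in enumerate(dataset.tissues):
        frame = dataset.matrices[tissue]
        if frame.columns.duplicated().any():
            dupes = frame.columns[frame.columns.duplicated()].tolist()
            raise ValueError(f"duplicate gene IDs in tissue {tissue!r}: {dupes[:5]}")
        if list(frame.index) != dataset.individuals:
            raise ValueError(f"tissue {tissue!r} does not share the cohort individual index")
        cols = [col_index[g] for g in frame.columns]
        matrix[t * n_ind : (t + 1) * n_ind, cols] = frame.to_numpy()
        for ind, label in dataset.labels.items():
            meta_records.append((ind, tissue, label))

    with np.errstate(invalid="ignore"):
        lo = np.nanmin(matrix, axis=0)
        hi = np.nanmax(matrix, axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    matrix = (matrix - lo) / span
    matrix[:, hi <= lo] = 0.0  # constant genes map to 0 by convention
    matrix = np.nan_to_num(matrix, nan=0.0)

    row_meta = pd.DataFrame(meta_records, columns=["individual", "tissue", "label"])
    return StackedDataset(matrix=matrix, row_meta=row_meta, gene_universe=universe)


@dataclass
class SplitIndex:
    """Disjoint train/test row indices, stratified on tissue or phenotype."""

    train_rows: np.ndarray
    test_rows: np.ndarray
    stratify_key: str
    seed: int

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_rows, self.test_rows).size:
            raise ValueError("train and test rows overlap")


def split_stratified(
    stacked: StackedDataset, train_fraction: float, key: str = "tissue", seed: int = 0
) -> SplitIndex:
    """Stratified train/test split of stacked rows.

    Per stratum, the train allocation is round-half-up of
    ``train_fraction * stratum_size``; the remainder goes to test. Row order
    within each partition follows the shuffled draw, deterministic in ``seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must lie in (0, 1), got {train_fraction!r}")
    if key not in stacked.row_meta.columns:
        raise ValueError(f"unknown stratify key {key!r}")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for stratum, group in stacked.row_meta.groupby(key, sort=True):
        rows = group.index.to_numpy()
        if rows.size < 2:
            raise ValueError(f"stratum {stratum!r} has fewer than 2 rows")
        rng.shuffle(rows)
        n_train = int(np.floor(train_fraction * rows.size + 0.5))
        train_parts.append(rows[:n_train])
        test_parts.append(rows[n_train:])
    return SplitIndex(
        train_rows=np.concatenate(train_parts),
        test_rows=np.concatenate(test_parts),
        stratify_key=key,
        seed=seed,
    )


@dataclass
class PhenotypeLabels:
    """Per-individual diagnosis plus optional covariates and MMSE scores.

    ``table`` is indexed by individual ID with a mandatory ``label`` column
    (case/control) and optional columns ``sex``, ``onset_age``, ``apoe4``,
    ``mmse_baseline``, ``mmse_4y``. Covariates may be missing (NaN).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "label" not in self.table.columns:
            raise ValueError("phenotype table requires a 'label' column")


#: Decliner labels derived from 4-year MMSE change.
DECLINE = "decline"
NO_DECLINE = "no-decline"


def compute_decline_labels(labels: PhenotypeLabels) -> PhenotypeLabels:
    """Relabel individuals by 4-year cognitive decline.

    The decline score is MMSE at 4 years minus MMSE at recruitment; a
    negative difference marks a decliner, a difference of zero or more a
    non-decliner. Individuals missing either score are excluded.
    """
    table = labels.table
    for col in ("mmse_baseline", "mmse_4y"):
        if col not in table.columns:
            raise ValueError(f"phenotype table lacks {col!r}")
    complete = table[["mmse_baseline", "mmse_4y"]].notna().all(axis=1)
    if not complete.any():
        raise ValueError("no individual has both MMSE scores")
    kept = table.loc[complete].copy()
    diff = kept["mmse_4y"] - kept["mmse_baseline"]
    kept["label"] = np.where(diff < 0, DECLINE, NO_DECLINE)
    return PhenotypeLabels(table=kept)


def subset_by_stratum(
    stacked: StackedDataset, labels: PhenotypeLabels, stratum
) -> StackedDataset:
    """Restrict stacked rows to individuals matching a covariate predicate.

    ``stratum`` is a callable evaluated on each phenotype-table row (e.g.
    ``lambda r: r["sex"] == "F"`` or ``lambda r: r["onset_age"] < 65``); rows
    whose predicate is NaN-valued or raises on a missing covariate are
    treated as errors. The gene universe is unchanged.
    """
    try:
        mask = labels.table.apply(stratum, axis=1)
    except KeyError as exc:
        raise ValueError(f"predicate references an absent covariate: {exc}") from exc
    selected = set(labels.table.index[mask.fillna(False).astype(bool)])
    if not selected:
        raise ValueError("stratum predicate selects no individuals")
    row_mask = stacked.row_meta["individual"].isin(selected).to_numpy()
    if not row_mask.any():
        raise ValueError("stratum predicate selects no stacked rows")
    return stacked.rows_for(row_mask)


def read_dataset(directory: str | Path) -> MultiTissueDataset:
    """Read a dataset written by :func:`tivae.synthetic.write_dataset`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    tissues = sorted(
        key.split(":", 1)[1] for key in manifest if key.startswith("matrix:")
    )
    matrices = {
        tissue: pd.read_csv(directory / f"{tissue}.expression.tsv", sep="\t", index_col=0)
        for tissue in tissues
    }
    pheno = pd.read_csv(manifest["phenotypes"], sep="\t", index_col=0)
    labels = pheno["label"]
    truth = None
    if "truth" in manifest:
        raw = json.loads(Path(manifest["truth"]).read_text())
        truth = PlantedTruth(
            signature_genes=raw["signature_genes"],
            diff_genes=raw["diff_genes"],
            enriched_sets=raw.get("enriched_sets", []),
            diff_gene_signs={
                t: {g: int(s) for g, s in d.items()}
                for t, d in raw.get("diff_gene_signs", {}).items()
            },
        )
    return MultiTissueDataset(tissues=tissues, matrices=matrices, labels=labels, truth=truth)
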