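"""Synthetic multi-tissue imputed-expression cohorts with planted ground truth.

The generator emulates the structure of PrediXcan-style genetically imputed
expression: one signed continuous matrix (individuals x genes) per tissue,
where each tissue carries its own subset of a shared gene universe, tissues
differ by strong mean signatures, and a chosen set of genes is shifted in
cases relative to controls. Because the planted structure is known exactly,
every downstream stage (embedding, latent-tissue matching, gene
prioritization, enrichment, classification) can be scored against a
recoverable truth.

Model for the value of gene g, individual i, tissue t::

    x[i, g, t] = b_g + s * 1[g is a signature gene of t]
               + d * sign_g * 1[g is a diff gene of t and i is a case]
               + eps,   eps ~ N(0, noise_sd)

with a per-gene baseline b_g ~ N(0, 1) shared across tissues, so values are
signed and roughly symmetric, as a linear combination of genotype dosages is.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "PlantedTruth",
    "MultiTissueDataset",
    "GeneSetCollection",
    "generate_cohort",
    "generate_pathways",
    "write_dataset",
    "read_gmt",
    "write_gmt",
]

CASE = "case"
CONTROL = "control"


class ConfigurationError(ValueError):
    """A cohort configuration field violates its invariant."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic multi-tissue cohort.

    Defaults describe a desk-scale cohort: 6 tissues, 300 individuals with the
    case/control imbalance of a typical dementia cohort (about 65% cases),
    400 of 500 universe genes present per tissue, tissue signatures at three
    noise standard deviations and case/control shifts at two.
    """

    n_tissues: int = 6
    n_individuals: int = 300
    n_cases: int = 196
    universe_size: int = 500
    genes_per_tissue: int | None = 400
    signature_genes_per_tissue: int = 30
    signature_effect: float = 3.0
    diff_genes_per_tissue: int = 25
    diff_effect: float = 2.0
    noise_sd: float = 1.0
    missing_fraction: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_tissues": self.n_tissues,
            "n_individuals": self.n_individuals,
            "n_cases": self.n_cases,
            "universe_size": self.universe_size,
            "signature_genes_per_tissue": self.signature_genes_per_tissue,
            "diff_genes_per_tissue": self.diff_genes_per_tissue,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        if self.genes_per_tissue is None and self.missing_fraction is None:
            raise ConfigurationError("one of genes_per_tissue / missing_fraction is required")
        if self.missing_fraction is not None and not 0.0 <= self.missing_fraction < 1.0:
            raise ConfigurationError(
                f"missing_fraction must lie in [0, 1), got {self.missing_fraction!r}"
            )
        gpt = self.resolved_genes_per_tissue()
        if gpt <= 0 or gpt > self.universe_size:
            raise ConfigurationError(
                f"genes_per_tissue must lie in (0, universe_size], got {gpt}"
            )
        if self.n_cases > self.n_individuals:
            raise ConfigurationError(
                f"n_cases ({self.n_cases}) exceeds n_individuals ({self.n_individuals})"
            )
        if self.signature_genes_per_tissue + self.diff_genes_per_tissue > gpt:
            raise ConfigurationError(
                "signature_genes_per_tissue + diff_genes_per_tissue exceeds genes_per_tissue"
            )
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd!r}")

    def resolved_genes_per_tissue(self) -> int:
        if self.genes_per_tissue is not None:
            return int(self.genes_per_tissue)
        return int(round((1.0 - float(self.missing_fraction)) * self.universe_size))

    def resolved_missing_fraction(self) -> float:
        return 1.0 - self.resolved_genes_per_tissue() / self.universe_size


@dataclass
class PlantedTruth:
    """Ground truth planted into a synthetic cohort."""

    signature_genes: dict[str, list[str]]
    diff_genes: dict[str, list[str]]
    enriched_sets: list[str] = field(default_factory=list)
    #: sign (+1 up in cases, -1 down in cases) per planted differential gene
    diff_gene_signs: dict[str, dict[str, int]] = field(default_factory=dict)


@dataclass
class MultiTissueDataset:
    """Per-tissue expression matrices sharing one cohort of individuals.

    ``matrices[t]`` is a DataFrame (individuals x tissue gene subset) of signed
    continuous values; ``labels`` holds one case/control label per individual;
    ``truth`` carries the planted structure (absent for real data).
    """

    tissues: list[str]
    matrices: dict[str, pd.DataFrame]
    labels: pd.Series
    truth: PlantedTruth | None = None

    @property
    def individuals(self) -> list[str]:
        return list(self.labels.index)

    @property
    def gene_universe(self) -> list[str]:
        universe: set[str] = set()
        for frame in self.matrices.values():
            universe.update(frame.columns)
        return sorted(universe)

    def case_mask(self) -> np.ndarray:
        return (self.labels == CASE).to_numpy()


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), e.g. pathways for enrichment."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.sets) != len(set(self.sets)):
            raise ValueError("gene set names must be unique")
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n + 1)]


def generate_cohort(config: CohortConfig) -> MultiTissueDataset:
    """Draw a deterministic synthetic cohort from ``config``.

    Tissue gene subsets are independent uniform draws from the universe; the
    first ``signature_genes_per_tissue`` of a tissue's subset receive the mean
    shift that makes tissues separable, the next ``diff_genes_per_tissue`` the
    signed case/control shift.
    """
    rng = np.random.default_rng(config.seed)
    universe = np.array(_gene_ids(config.universe_size))
    gpt = config.resolved_genes_per_tissue()

    tissues = [f"tissue{t:02d}" for t in range(1, config.n_tissues + 1)]
    individuals = [f"ind{i:04d}" for i in range(1, config.n_individuals + 1)]
    label_values = np.array([CASE] * config.n_cases + [CONTROL] * (config.n_individuals - config.n_cases))
    labels = pd.Series(label_values, index=pd.Index(individuals, name="individual"), name="label")
    case_rows = label_values == CASE

    baseline = rng.normal(0.0, 1.0, size=config.universe_size)  # shared per-gene baseline

    matrices: dict[str, pd.DataFrame] = {}
    signature_genes: dict[str, list[str]] = {}
    diff_genes: dict[str, list[str]] = {}
    diff_signs: dict[str, dict[str, int]] = {}

    for tissue in tissues:
        subset_idx = rng.choice(config.universe_size, size=gpt, replace=False)
        subset_idx.sort()
        genes = universe[subset_idx]

        special = rng.choice(
            gpt,
            size=config.signature_genes_per_tissue + config.diff_genes_per_tissue,
            replace=False,
        )
        sig_pos = special[: config.signature_genes_per_tissue]
        diff_pos = special[config.signature_genes_per_tissue:]
        signs = rng.choice([-1, 1], size=diff_pos.size)

        mean = np.tile(baseline[subset_idx], (config.n_individuals, 1))
        mean[:, sig_pos] += config.signature_effect
        mean[np.ix_(case_rows, diff_pos)] += config.diff_effect * signs

        values = mean + rng.normal(0.0, config.noise_sd, size=mean.shape)
        matrices[tissue] = pd.DataFrame(values, index=individuals, columns=genes)

        signature_genes[tissue] = sorted(genes[sig_pos])
        diff_genes[tissue] = sorted(genes[diff_pos])
        diff_signs[tissue] = {g: int(s) for g, s in zip(genes[diff_pos], signs)}

    truth = PlantedTruth(
        signature_genes=signature_genes,
        diff_genes=diff_genes,
        diff_gene_signs=diff_signs,
    )
    return MultiTissueDataset(tissues=tissues, matrices=matrices, labels=labels, truth=truth)


def generate_pathways(
    truth: PlantedTruth,
    universe: list[str],
    n_decoys: int = 12,
    set_size_range: tuple[int, int] = (15, 40),
    overlap: float = 0.8,
    seed: int = 0,
    direction: str = "up",
) -> GeneSetCollection:
    """Build one planted-enriched gene set per tissue plus random decoy sets.

    With ``direction="up"`` (default) the planted members of a tissue's set
    are its up-shifted differential genes — a directionally coherent
    co-regulated program, which is what gene-set collections model and what a
    signed running-sum enrichment statistic can actually detect (a set mixing
    up- and down-regulated members cancels its own signal). The set size is
    ``ceil(n_core / overlap)`` clipped to ``set_size_range``, padded with
    uniform filler genes. With ``direction="both"`` the planted members are
    ``ceil(overlap * size)`` uniform draws from all of the tissue's
    differential genes (size drawn from ``set_size_range``). Decoys are
    uniform draws; enriched set names are recorded in ``truth.enriched_sets``.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError(f"overlap must lie in [0, 1], got {overlap!r}")
    if direction not in ("up", "both"):
        raise ValueError(f"direction must be 'up' or 'both', got {direction!r}")
    lo, hi = set_size_range
    if lo <= 0 or hi < lo:
        raise ValueError(f"invalid set_size_range {set_size_range!r}")
    if hi > len(universe):
        raise ValueError(
            f"set_size_range upper bound {hi} exceeds universe size {len(universe)}"
        )
    rng = np.random.default_rng(seed)
    universe_arr = np.array(sorted(universe))
    sets: dict[str, list[str]] = {}
    enriched_names: list[str] = []

    for tissue, planted in truth.diff_genes.items():
        signs = truth.diff_gene_signs.get(tissue, {})
        if direction == "up" and signs:
            core = sorted(g for g in planted if signs.get(g, 1) > 0)
            size = int(np.clip(math.ceil(len(core) / max(overlap, 1e-9)), lo, hi))
            chosen = core[: min(len(core), size)]
        else:
            size = int(rng.integers(lo, hi + 1))
            n_planted = min(math.ceil(overlap * size), len(planted), size)
            chosen = list(rng.choice(np.array(planted), size=n_planted, replace=False))
        # fillers avoid all of the tissue's planted genes so the planted
        # member count is exactly the requested overlap
        pool = np.setdiff1d(universe_arr, np.array(sorted(planted)))
        fillers = list(rng.choice(pool, size=size - len(chosen), replace=False))
        name = f"planted_{tissue}"
        sets[name] = sorted(list(chosen) + fillers)
        enriched_names.append(name)

    for d in range(n_decoys):
        size = int(rng.integers(lo, hi + 1))
        sets[f"decoy{d:03d}"] = sorted(rng.choice(universe_arr, size=size, replace=False))

    truth.enriched_sets = enriched_names
    return GeneSetCollection(sets=sets, source="synthetic planted pathways")


def write_dataset(dataset: MultiTissueDataset, directory: str | Path) -> dict[str, str]:
    """Serialize a dataset as tab-delimited matrix files plus phenotype/truth files.

    One matrix file per tissue (rows = individuals, header row = gene IDs,
    first column = individual ID), a phenotype TSV, and a JSON truth file when
    planted truth is present. Returns a manifest mapping logical names to
    written paths. Round-trips through :func:`tivae.preprocessing.read_dataset`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if len(dataset.labels) == 0:
        raise ValueError("refusing to write a dataset with zero individuals")
    for tissue, frame in dataset.matrices.items():
        if frame.shape[0] == 0:
            raise ValueError(f"tissue {tissue!r} has zero individuals")

    manifest: dict[str, str] = {}
    for tissue in dataset.tissues:
        path = directory / f"{tissue}.expression.tsv"
        frame = dataset.matrices[tissue].copy()
        frame.index.name = "individual"
        frame.to_csv(path, sep="\t", float_format="%.10g")
        manifest[f"matrix:{tissue}"] = str(path)

    pheno_path = directory / "phenotypes.tsv"
    dataset.labels.to_frame().to_csv(pheno_path, sep="\t")
    manifest["phenotypes"] = str(pheno_path)

    if dataset.truth is not None:
        truth_path = directory / "truth.json"
        truth_path.write_text(json.dumps(dataclasses.asdict(dataset.truth), indent=1))
        manifest["truth"] = str(truth_path)

    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    manifest["manifest"] = str(manifest_path)
    return manifest


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name, description, genes... per tab-separated line)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, collection.source or "na", *genes])
        for name, genes in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def dataset_checksum(dataset: MultiTissueDataset) -> str:
    """Stable content hash of a dataset (used for determinism checks)."""
    h = hashlib.sha256()
    for tissue in dataset.tissues:
        frame = dataset.matrices[tissue]
        h.update(tissue.encode())
        h.update(",".join(frame.columns).encode())
        h.update(np.ascontiguousarray(frame.to_numpy()).tobytes())
    h.update(",".join(dataset.labels).encode())
    return h.hexdigest()
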