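"""End-to-end orchestration: one config drives every stage.

Stage order: simulate -> preprocess -> embed -> match -> prioritize ->
enrich -> classify -> crosstissue. Every stage's randomness derives from the
global seed plus a fixed stage offset, results are cached on disk keyed by a
hash of the semantically meaningful config fields (so partial re-runs resume
from completed stages), and all tabular artifacts are written as TSV with a
JSON manifest carrying per-file checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pickle
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classification as clf
from . import enrichment as enr
from . import matching, prioritization, synthetic, vae
from .preprocessing import scale_minmax, stack_tissues
from .synthetic import CASE, CohortConfig

__all__ = ["RunConfig", "EnrichStageConfig", "ClassifyStageConfig", "RunReport", "run_pipeline"]

logger = logging.getLogger(__name__)

MODES = ("full", "unsupervised-only", "supervised-only")
STAGES = (
    "simulate",
    "preprocess",
    "embed",
    "match",
    "prioritize",
    "enrich",
    "classify",
    "crosstissue",
)
UNSUPERVISED_STAGES = STAGES[:6]
SUPERVISED_STAGES = ("simulate", "preprocess", "classify", "crosstissue")

# fixed per-stage seed offsets added to the global seed
_SEED_OFFSETS = {name: 10 * (i + 1) for i, name in enumerate(STAGES)}


@dataclass(frozen=True)
class EnrichStageConfig:
    n_perm: int = 1000
    #: 12 decoys keep the per-tissue BH batch small enough that a permutation
    #: p-value at its 1/(1+same-sign) floor survives FDR correction at 0.05
    n_decoys: int = 12
    set_size_min: int = 15
    set_size_max: int = 40
    overlap: float = 0.8
    pathway_direction: str = "up"
    weight_exponent: float = 1.0


@dataclass(frozen=True)
class ClassifyStageConfig:
    arch_kind: str = "recurrent"
    reduced: bool = True
    chunk: int = 64
    single_timestep: bool = False
    epochs: int = 30
    batch_size: int = 100
    learning_rate: float = 0.001
    n_folds: int = 10
    #: train fraction used when the cohort size differs from the 808 of the
    #: fixed 600/208 split (600/808 ~ 0.743)
    train_fraction: float = 0.743


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig = CohortConfig()
    #: desk-scale embedding defaults: latent sized to the default tissue count,
    #: batch 64 so the optimizer takes as many Adam steps on a ~1k-row cohort
    #: as the full-scale protocol takes on its 27k rows
    vae: vae.VAEConfig = vae.VAEConfig(latent_dim=6, n_repeats=10, batch_size=64)
    match: matching.MatchConfig = matching.MatchConfig()
    enrich: EnrichStageConfig = EnrichStageConfig()
    classify: ClassifyStageConfig = ClassifyStageConfig()
    unit_list_k: int = 100
    min_count: int = 3
    mode: str = "full"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        nested = {
            "cohort": CohortConfig,
            "vae": vae.VAEConfig,
            "match": matching.MatchConfig,
            "enrich": EnrichStageConfig,
            "classify": ClassifyStageConfig,
        }
        for key, value in raw.items():
            if key in nested:
                kwargs[key] = nested[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        return (self.seed + _SEED_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class RunReport:
    config_hash: str
    seed: int
    mode: str
    stages: dict[str, dict] = field(default_factory=dict)
    summaries: dict[str, object] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "mode": self.mode,
            "stages": self.stages,
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Cache:
    def __init__(self, directory: Path, config_hash: str):
        self.directory = directory
        self.config_hash = config_hash
        directory.mkdir(parents=True, exist_ok=True)

    def path(self, stage: str) -> Path:
        return self.directory / f"{stage}-{self.config_hash}.pkl"

    def run(self, stage: str, fn):
        target = self.path(stage)
        if target.exists():
            logger.info("stage %s: cached", stage)
            with target.open("rb") as fh:
                return pickle.load(fh)
        result = fn()
        with target.open("wb") as fh:
            pickle.dump(result, fh)
        return result


def _train_test_individuals(labels: pd.Series, fraction: float, seed: int):
    """Label-stratified individual split; 600/208 when the cohort has 808."""
    rng = np.random.default_rng(seed)
    individuals = np.array(labels.index)
    n = individuals.size
    n_train = 600 if n == 808 else int(np.floor(fraction * n + 0.5))
    train: list[str] = []
    for cls in sorted(labels.unique()):
        members = individuals[labels.to_numpy() == cls]
        rng.shuffle(members)
        take = int(round(n_train * members.size / n))
        train.extend(members[:take])
    train_set = set(train)
    test = [i for i in individuals if i not in train_set]
    return sorted(train_set), test


def _tissue_xy(dataset, tissue, train_ind, test_ind, universe=None, gene_filter=None):
    """Scaled (train, test) design matrices and labels for one tissue.

    Scaling is fit per gene on the training individuals and applied with
    clipping to the test individuals. With ``universe`` the matrix is
    zero-filled to the union representation (cross-tissue mode).
    """
    matrix = dataset.matrices[tissue]
    if gene_filter is not None:
        matrix = clf.apply_gene_filter(matrix, gene_filter, None if gene_filter.per_tissue is None else tissue)
    train_m, params = scale_minmax(matrix.loc[train_ind])
    test_m, _ = scale_minmax(matrix.loc[test_ind], params)
    if universe is not None:
        train_m = train_m.reindex(columns=universe, fill_value=0.0)
        test_m = test_m.reindex(columns=universe, fill_value=0.0)
    y_train = (dataset.labels.loc[train_ind] == CASE).astype(int).to_numpy()
    y_test = (dataset.labels.loc[test_ind] == CASE).astype(int).to_numpy()
    return train_m.to_numpy(), y_train, test_m.to_numpy(), y_test, train_m.shape[1]


def run_pipeline(config: RunConfig, outdir: str | Path, until: str = "crosstissue") -> RunReport:
    """Execute the pipeline (or its prefix up to ``until``) into ``outdir``."""
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    cache = _Cache(outdir / "cache", chash)
    report = RunReport(config_hash=chash, seed=config.seed, mode=config.mode)

    if config.mode == "unsupervised-only":
        active = UNSUPERVISED_STAGES
    elif config.mode == "supervised-only":
        active = SUPERVISED_STAGES
    else:
        active = STAGES
    active = [s for s in active if STAGES.index(s) <= STAGES.index(until)]

    def record(stage: str, started: float, artifacts: dict[str, Path]) -> None:
        report.stages[stage] = {
            "wall_time_s": round(time.monotonic() - started, 3),
            "seed": config.stage_seed(stage),
            "artifacts": {name: {"path": str(p), "sha256": _sha256(p)} for name, p in artifacts.items()},
        }

    # ---- simulate ---------------------------------------------------------
    t0 = time.monotonic()
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.stage_seed("simulate"))
    dataset = cache.run("simulate", lambda: synthetic.generate_cohort(cohort_cfg))
    manifest = synthetic.write_dataset(dataset, outdir / "data")
    record("simulate", t0, {k: Path(v) for k, v in manifest.items()})

    # ---- preprocess -------------------------------------------------------
    if "preprocess" in active:
        t0 = time.monotonic()
        stacked = cache.run("preprocess", lambda: stack_tissues(dataset))
        meta_path = outdir / "stacked_rows.tsv"
        stacked.row_meta.to_csv(meta_path, sep="\t", index=False)
        record("preprocess", t0, {"row_meta": meta_path})
        report.summaries["stacked"] = stacked

    case_lists = control_lists = None
    unsupervised_filter = None

    if "embed" in active:
        # ---- embed: repeated per-class VAEs -------------------------------
        t0 = time.monotonic()
        vae_cfg = dataclasses.replace(
            config.vae,
            latent_dim=config.vae.latent_dim or len(dataset.tissues),
            seed=config.stage_seed("embed"),
        )
        case_rows, control_rows = stacked.class_partition()
        case_models, control_models = cache.run(
            "embed", lambda: vae.run_repeated_vaes(case_rows, control_rows, vae_cfg)
        )
        record("embed", t0, {})
        report.summaries["n_vae_models"] = len(case_models) + len(control_models)

        # ---- match: latent unit -> tissue ---------------------------------
        t0 = time.monotonic()
        match_cfg = dataclasses.replace(config.match, seed=config.stage_seed("match"))

        def _match_all():
            out = {}
            for tag, models, rows in (
                ("case", case_models, case_rows),
                ("control", control_models, control_rows),
            ):
                tissue_labels = rows.row_meta["tissue"].to_numpy()
                out[tag] = [
                    matching.match_tissues(vae.encode(m, rows.matrix), tissue_labels, match_cfg)
                    for m in models
                ]
            return out

        maps = cache.run("match", _match_all)
        f1_path = outdir / "latent_tissue_f1.tsv"
        mean_f1 = sum(m.f1_matrix for m in maps["case"]) / len(maps["case"])
        mean_f1.to_csv(f1_path, sep="\t")
        record("match", t0, {"mean_case_f1": f1_path})
        report.summaries["maps"] = maps

        # ---- prioritize ---------------------------------------------------
        t0 = time.monotonic()

        def _prioritize():
            case_rankings = prioritization.tissue_rankings(case_models, maps["case"], config.unit_list_k)
            control_rankings = prioritization.tissue_rankings(
                control_models, maps["control"], config.unit_list_k
            )
            case_l = prioritization.aggregate_across_vaes(case_rankings, config.min_count, "case-models")
            control_l = prioritization.aggregate_across_vaes(
                control_rankings, config.min_count, "control-models"
            )
            signature = prioritization.disease_signature(case_l, control_l)
            return case_l, control_l, signature

        case_lists, control_lists, signature = cache.run("prioritize", _prioritize)
        artifacts = {}
        for name, obj in (
            ("case_gene_lists", case_lists),
            ("control_gene_lists", control_lists),
            ("signature_gene_lists", signature),
        ):
            path = outdir / f"{name}.tsv"
            prioritization.export_gene_lists(obj, path)
            artifacts[name] = path
        record("prioritize", t0, artifacts)
        report.summaries["case_lists"] = case_lists
        report.summaries["control_lists"] = control_lists
        report.summaries["signature"] = signature
        unsupervised_filter = clf.filter_from_gene_lists(case_lists)

        # ---- enrich -------------------------------------------------------
        if "enrich" in active:
            t0 = time.monotonic()
            ecfg = config.enrich
            pathways = synthetic.generate_pathways(
                dataset.truth,
                dataset.gene_universe,
                n_decoys=ecfg.n_decoys,
                set_size_range=(ecfg.set_size_min, ecfg.set_size_max),
                overlap=ecfg.overlap,
                seed=config.stage_seed("enrich"),
                direction=ecfg.pathway_direction,
            )
            synthetic.write_gmt(pathways, outdir / "pathways.gmt")

            def _enrich():
                rows = []
                for t_idx, tissue in enumerate(case_lists.tissues):
                    try:
                        stat = enr.build_differential_statistic(
                            case_lists, control_lists, tissue, dataset.gene_universe
                        )
                    except ValueError:
                        continue
                    results = enr.enrich_collection(
                        stat,
                        pathways,
                        n_perm=ecfg.n_perm,
                        seed=config.stage_seed("enrich") + 1000 * (t_idx + 1),
                        weight_exponent=ecfg.weight_exponent,
                    )
                    for r in results:
                        rows.append(
                            (tissue, r.pathway, r.pval, r.padj, r.es, r.nes, r.size,
                             ",".join(r.leading_edge))
                        )
                return pd.DataFrame(
                    rows,
                    columns=["tissue", "pathway", "pval", "padj", "ES", "NES", "size", "genes"],
                )

            table = cache.run("enrich", _enrich)
            epath = outdir / "enrichment.tsv"
            table.to_csv(epath, sep="\t", index=False)
            record("enrich", t0, {"enrichment": epath, "pathways": outdir / "pathways.gmt"})
            report.summaries["enrichment"] = table

    # ---- classify ---------------------------------------------------------
    if "classify" in active:
        t0 = time.monotonic()
        ccfg = config.classify
        train_cfg = clf.TrainConfig(
            epochs=ccfg.epochs,
            batch_size=ccfg.batch_size,
            learning_rate=ccfg.learning_rate,
            n_folds=ccfg.n_folds,
            seed=config.stage_seed("classify"),
        )
        train_ind, test_ind = _train_test_individuals(
            dataset.labels, ccfg.train_fraction, config.stage_seed("classify")
        )

        filter_variants: list[tuple[str, clf.FilterList | None]] = [("no-filter", None)]
        if unsupervised_filter is not None:
            filter_variants.append(("List-unsupervised", unsupervised_filter))

        def _classify():
            rows = []
            for tissue in dataset.tissues:
                for filter_name, gene_filter in filter_variants:
                    if gene_filter is not None and not gene_filter.genes_for(tissue):
                        continue
                    x_tr, y_tr, x_te, y_te, width = _tissue_xy(
                        dataset, tissue, train_ind, test_ind, gene_filter=gene_filter
                    )
                    arch = clf.ArchitectureSpec(
                        kind=ccfg.arch_kind,
                        input_width=width,
                        reduced=ccfg.reduced,
                        chunk=ccfg.chunk,
                        single_timestep=ccfg.single_timestep,
                    )
                    run = clf.train_classifier(x_tr, y_tr, arch, train_cfg)
                    metrics = clf.evaluate_metrics(run.model, x_te, y_te)
                    rows.append(
                        (tissue, filter_name, width, run.train_auc, metrics.auc,
                         metrics.accuracy, metrics.precision, metrics.recall, metrics.f1)
                    )
            return pd.DataFrame(
                rows,
                columns=["tissue", "filter", "n_genes", "train_auc", "test_auc",
                         "accuracy", "precision", "recall", "f1"],
            )

        table = cache.run("classify", _classify)
        cpath = outdir / "classification.tsv"
        table.to_csv(cpath, sep="\t", index=False)
        artifacts = {"classification": cpath}

        comparison = None
        pivot = table.pivot(index="tissue", columns="filter", values="test_auc")
        if "List-unsupervised" in pivot.columns and pivot.shape[0] >= 3:
            both = pivot.dropna()
            comparison = clf.compare_filters(
                both["no-filter"].to_numpy(), both["List-unsupervised"].to_numpy()
            )
            fpath = outdir / "filter_comparison.json"
            fpath.write_text(json.dumps(dataclasses.asdict(comparison), indent=1))
            artifacts["filter_comparison"] = fpath
        record("classify", t0, artifacts)
        report.summaries["classification"] = table
        report.summaries["filter_comparison"] = comparison

    # ---- crosstissue ------------------------------------------------------
    if "crosstissue" in active:
        t0 = time.monotonic()
        universe = dataset.gene_universe

        def _crosstissue():
            runs, tests = {}, {}
            arch = None
            for tissue in dataset.tissues:
                x_tr, y_tr, x_te, y_te, _ = _tissue_xy(
                    dataset, tissue, train_ind, test_ind, universe=universe
                )
                arch = clf.ArchitectureSpec(
                    kind=ccfg.arch_kind,
                    input_width=len(universe),
                    reduced=ccfg.reduced,
                    chunk=ccfg.chunk,
                    single_timestep=ccfg.single_timestep,
                )
                runs[tissue] = clf.train_classifier(x_tr, y_tr, arch, train_cfg)
                tests[tissue] = (x_te, y_te)
            return clf.cross_tissue_eval(runs, tests)

        matrix = cache.run("crosstissue", _crosstissue)
        mpath = outdir / "cross_tissue_auc.tsv"
        matrix.auc.to_csv(mpath, sep="\t")
        record("crosstissue", t0, {"cross_tissue_auc": mpath})
        report.summaries["cross_tissue"] = matrix

    report.write(outdir / "run_report.json")
    return report
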