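"""End-to-end pipeline: configuration, input validation and orchestration.

A :class:`RunConfig` describes one analysis run (inputs, scoring and
aggregation choices, rank range, seeds, downstream toggles) and serializes
to/from YAML; :func:`run_pipeline` executes the configured stages — tensor
construction (from expression data, edge lists, or the simulator), rank
selection, the decomposition at the selected rank, loading normalization and
the requested downstream analyses — writing every artifact plus the exact
config and a log into a run directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .decompose import CPTensorModel
from .downstream import build_lr_sets, compare_groups, factor_network, prerank_gsea
from .io import (
    read_cell_annotation,
    read_context_metadata,
    read_dense_expression,
    read_edge_list,
    read_gmt,
    read_lr_catalog,
    read_mtx_dir,
    write_tensor_hdf5,
)
from .simulate import SimTruth, build_simulated_tensor
from .tensor_build import (
    aggregate_expression,
    build_tensor,
    filter_catalog,
    tensor_from_edge_lists,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable description of one pipeline run.

    ``mode`` is one of ``simulate`` (built-in generator), ``build``
    (expression matrices + LR catalog) or ``edge_lists`` (external scores).
    All randomness derives from the single ``seed``.
    """

    mode: str = "simulate"
    out_dir: str = "run"
    seed: int = 0
    # tensor construction
    expression: dict = field(default_factory=dict)  # context_id -> path
    annotation: dict = field(default_factory=dict)  # context_id -> path
    edge_lists: dict = field(default_factory=dict)  # context_id -> path
    metadata: str | None = None
    lr_catalog: str | None = None
    subunit_delimiter: str = "&"
    aggregation: str = "nonzero_fraction"
    score_method: str = "mean"
    # simulation block
    sim_contexts: int = 12
    sim_pairs: int = 300
    sim_celltypes: int = 3
    sim_noise: float = 0.0
    # decomposition
    rank: int | None = None
    rank_min: int = 1
    rank_max: int = 10
    tol: float = 1e-7
    max_iter: int = 500
    n_restarts: int = 3
    # downstream toggles
    networks: bool = True
    group_column: str | None = None
    gene_sets: str | None = None
    gsea_min_size: int = 15
    gsea_permutations: int = 999
    gsea_weight: float = 1.0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def validate_inputs(config: RunConfig) -> list:
    """Check input files for consistency; returns a machine-readable issue
    list (empty means the configuration looks runnable)."""
    issues = []

    def issue(kind: str, message: str) -> None:
        issues.append({"kind": kind, "message": message})

    if config.mode not in ("simulate", "build", "edge_lists"):
        issue("config", f"unknown mode {config.mode!r}")
        return issues
    if config.mode == "simulate":
        return issues

    for label, paths in (("expression", config.expression),
                         ("annotation", config.annotation),
                         ("edge_lists", config.edge_lists)):
        for ctx, p in paths.items():
            if not Path(p).exists():
                issue("missing_file", f"{label} path for context {ctx!r}: {p}")
    if config.metadata and not Path(config.metadata).exists():
        issue("missing_file", f"metadata: {config.metadata}")
    if config.mode == "build":
        if not config.lr_catalog:
            issue("config", "build mode requires lr_catalog")
        elif not Path(config.lr_catalog).exists():
            issue("missing_file", f"lr_catalog: {config.lr_catalog}")
        else:
            try:
                read_lr_catalog(config.lr_catalog, config.subunit_delimiter)
            except Exception as exc:  # malformed rows, empty subunits, ...
                issue("malformed_pair", f"lr_catalog: {exc}")
        if set(config.expression) != set(config.annotation):
            issue(
                "config",
                "expression and annotation must cover the same contexts",
            )
        for ctx in config.expression:
            p = Path(config.expression[ctx])
            a = Path(config.annotation.get(ctx, ""))
            if not p.exists() or not a.exists():
                continue
            counts = _read_expression(p)
            labels = read_cell_annotation(a)
            unlabeled = counts.index.difference(labels.index)
            if len(unlabeled) > 0:
                issue(
                    "unlabeled_cell",
                    f"context {ctx!r}: {len(unlabeled)} barcode(s) in the "
                    f"matrix missing from the annotation, e.g. {unlabeled[0]!r}",
                )
    if config.mode == "edge_lists":
        if len(config.edge_lists) < 2:
            issue("config", "edge_lists mode requires >= 2 contexts")
        for ctx, p in config.edge_lists.items():
            if not Path(p).exists():
                continue
            try:
                read_edge_list(p)
            except Exception as exc:
                issue("malformed_edge_list", f"context {ctx!r}: {exc}")
    return issues


def _read_expression(path: Path) -> pd.DataFrame:
    if path.is_dir():
        return read_mtx_dir(path)
    return read_dense_expression(path)


def _build_from_config(config: RunConfig):
    if config.mode == "simulate":
        truth = SimTruth(
            n_contexts=config.sim_contexts,
            n_pairs=config.sim_pairs,
            n_celltypes=config.sim_celltypes,
            noise_sd=config.sim_noise,
            seed=config.seed,
        )
        return build_simulated_tensor(truth)
    if config.mode == "edge_lists":
        frames = {
            ctx: read_edge_list(p) for ctx, p in config.edge_lists.items()
        }
        return tensor_from_edge_lists(frames), None
    catalog = read_lr_catalog(config.lr_catalog, config.subunit_delimiter)
    profiles = []
    for ctx in sorted(config.expression):
        counts = _read_expression(Path(config.expression[ctx]))
        labels = read_cell_annotation(config.annotation[ctx])
        profiles.append(
            aggregate_expression(
                counts, labels, method=config.aggregation, context_id=ctx
            )
        )
    catalog = filter_catalog(catalog, profiles)
    return build_tensor(profiles, catalog, method=config.score_method), None


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages and write all outputs to a run dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        config.to_yaml(out / "config.yaml")
        logger.info("commtensor %s; seed=%d; mode=%s",
                    __version__, config.seed, config.mode)

        stage = "validate"
        issues = validate_inputs(config)
        (out / "validation.json").write_text(json.dumps(issues, indent=2))
        if issues:
            raise PipelineError(stage, ValueError(f"{len(issues)} input issue(s)"))

        stage = "build_tensor"
        try:
            result = _build_from_config(config)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, exc) from exc
        if isinstance(result, tuple):
            tensor, truth = result
        else:
            tensor, truth = result, None
        write_tensor_hdf5(tensor, out / "tensor.h5")
        if truth is not None:
            truth.to_json(out / "sim_truth.json")
        logger.info("tensor shape %s", tensor.shape)

        model = CPTensorModel(tensor)
        stage = "select_rank"
        try:
            if config.rank is None:
                scan = model.select_rank(
                    range(config.rank_min, config.rank_max + 1),
                    seed=config.seed,
                    tol=config.tol,
                    max_iter=config.max_iter,
                    n_restarts=config.n_restarts,
                )
                scan.to_frame().to_csv(out / "rank_scan.csv", index=False)
                rank = scan.selected
                logger.info("selected rank %d", rank)
            else:
                rank = config.rank
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

        stage = "decompose"
        try:
            results = model.fit(
                rank,
                seed=config.seed,
                tol=config.tol,
                max_iter=config.max_iter,
                n_restarts=config.n_restarts,
            ).normalized()
        except Exception as exc:
            raise PipelineError(stage, exc) from exc
        results.to_dir(out)
        logger.info("normalized error %.6f", results.norm_error)

        stage = "downstream"
        try:
            if config.networks:
                nets = []
                for f in results.factor_names:
                    net = factor_network(results, f)
                    edges = net.to_edge_list()
                    edges.insert(0, "factor", f)
                    edges["gini"] = net.gini
                    nets.append(edges)
                pd.concat(nets).to_csv(out / "factor_networks.tsv",
                                       sep="\t", index=False)
            if config.metadata and config.group_column:
                meta = read_context_metadata(config.metadata)
                groups = meta.loc[results.factors["contexts"].index,
                                  config.group_column]
                compare_groups(results.factors["contexts"], groups).to_csv(
                    out / "group_stats.tsv", sep="\t", index=False
                )
            if config.gene_sets and config.lr_catalog:
                catalog = read_lr_catalog(config.lr_catalog,
                                          config.subunit_delimiter)
                sets = build_lr_sets(read_gmt(config.gene_sets), catalog,
                                     min_size=config.gsea_min_size)
                prerank_gsea(
                    results.factors["pairs"], sets,
                    n_perm=config.gsea_permutations,
                    weight=config.gsea_weight,
                    seed=config.seed,
                ).to_csv(out / "gsea.tsv", sep="\t", index=False)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

        logger.info("run complete")
        return out
    except PipelineError as exc:
        logger.error("aborted: %s", exc)
        (out / "FAILED").write_text(str(exc))
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
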