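"""Configured, logged, resumable orchestration of the full analysis.

Stage order: simulate -> load -> transform -> embed -> cluster -> project ->
stats.  A run is driven by a YAML config (validated up front, echoed into
the results bundle), writes one CSV/JSON artifact per stage into the output
directory, and finishes with a manifest listing every emitted file with its
SHA-256 checksum — re-running with identical config and inputs reproduces
identical checksums.

One global seed fans out to per-stage seeds by stable hashing of the stage
name, so disabling one stage leaves the random streams of the others
untouched.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import DownsampleSettings, cluster_cells, overlay_labels
from .ct_io import (
    CT_MAX,
    DEFAULT_LOD,
    ct_to_expression,
    load_ct_matrix,
    qc_filter,
    write_ct_matrix,
)
from .projection import (
    cocluster_heatmap_order,
    match_and_project,
    similarity_matrix,
    standardize_overlap,
)
from .simulate import (
    OVERLAP_GENES,
    default_study_design,
    generate_bulk,
    generate_cohort,
    load_bulk_panel,
    scaled_study_design,
    write_bulk_panel,
    write_ground_truth,
)
from .stats import cluster_frequencies, gene_overlay_scale, prepost_comparison, rank_markers
from .tsne import TsneParams, tsne_embed

__all__ = ["RunConfig", "ResultsBundle", "ConfigError", "StageError", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


class ConfigError(ValueError):
    """A config constraint violation, reported with its key path."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated pipeline configuration (defaults injected)."""

    outdir: str = "results"
    seed: int = 0
    # inputs (ignored when simulate is enabled)
    ct_path: str | None = None
    ct_dialect: str = "wide_csv"
    bulk_path: str | None = None
    # simulate
    simulate: bool = True
    design: str = "paper"          # "paper" or "scaled:<n_cells>"
    bulk_noise_sd: float = 0.5
    # transform
    lod: float = DEFAULT_LOD
    nondetect_code: float = 999.0
    min_detected: int = 1
    # embedding
    tsne: TsneParams = field(default_factory=TsneParams)
    # clustering
    k: int = 6
    linkage: str = "ward"
    space: str = "expression"
    downsample_fraction: float = 1.0
    downsample_radius: float = 5.0
    # projection
    overlap_genes: tuple[str, ...] = OVERLAP_GENES
    m: int = 20
    # stats
    top_n: int = 10
    include_surgical_controls: bool = False
    overlay_genes: tuple[str, ...] = OVERLAP_GENES
    # stage toggles
    run_embed: bool = True
    run_cluster: bool = True
    run_project: bool = True
    run_stats: bool = True

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 2654435761 + zlib.crc32(stage.encode())) % (2**31)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["tsne"] = asdict(self.tsne)
        d["overlap_genes"] = list(self.overlap_genes)
        d["overlay_genes"] = list(self.overlay_genes)
        return d


@dataclass(frozen=True)
class ResultsBundle:
    """Manifest plus handles to every per-stage artifact of a run."""

    outdir: Path
    manifest: dict[str, Any]

    def path(self, name: str) -> Path:
        if name not in self.manifest["files"]:
            raise KeyError(f"{name} not in manifest")
        return self.outdir / name


# ---------------------------------------------------------------------------
# Config validation
# ---------------------------------------------------------------------------

_TSNE_KEYS = {f.strip() for f in (
    "iterations perplexity theta seed learning_rate early_exaggeration "
    "exaggeration_iters momentum_start momentum_final momentum_switch init trace_every "
    "restarts"
).split()}


def _design_n_cells(design: str) -> int | None:
    if design == "paper":
        return 1107
    if design.startswith("scaled:"):
        return int(design.split(":", 1)[1])
    return None


def validate_config(source: str | Path | dict) -> RunConfig:
    """Parse and validate a YAML config (or dict); inject defaults.

    Unknown keys are rejected; every violated constraint is reported with
    its key path before any stage runs.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")

    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    tsne_raw = raw.pop("tsne", {})
    if not isinstance(tsne_raw, dict):
        raise ConfigError("tsne: must be a mapping")
    bad = set(tsne_raw) - _TSNE_KEYS
    if bad:
        raise ConfigError(f"tsne: unknown keys {sorted(bad)}")
    try:
        tsne = TsneParams(**tsne_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"tsne: {exc}") from exc

    for key in ("overlap_genes", "overlay_genes"):
        if key in raw:
            raw[key] = tuple(raw[key])
    try:
        cfg = RunConfig(tsne=tsne, **raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc

    if not (0 < cfg.lod <= CT_MAX):
        raise ConfigError(f"lod: must be in (0, {CT_MAX}], got {cfg.lod}")
    if cfg.min_detected < 0:
        raise ConfigError("min_detected: must be >= 0")
    if cfg.k < 1:
        raise ConfigError(f"k: must be >= 1, got {cfg.k}")
    if cfg.m < 1:
        raise ConfigError(f"m: must be >= 1, got {cfg.m}")
    if cfg.top_n < 1:
        raise ConfigError("top_n: must be >= 1")
    if not (0 < cfg.downsample_fraction <= 1):
        raise ConfigError("downsample_fraction: must be in (0, 1]")
    if cfg.ct_dialect not in ("wide_csv", "long_csv"):
        raise ConfigError(f"ct_dialect: unknown dialect {cfg.ct_dialect!r}")
    if cfg.space not in ("expression", "embedding"):
        raise ConfigError(f"space: must be 'expression' or 'embedding', got {cfg.space!r}")
    if cfg.simulate:
        n = _design_n_cells(cfg.design)
        if n is None:
            raise ConfigError(f"design: expected 'paper' or 'scaled:<n>', got {cfg.design!r}")
        if cfg.run_embed and cfg.tsne.perplexity >= n / 3:
            raise ConfigError(
                f"tsne.perplexity: {cfg.tsne.perplexity} must be < n_cells/3 = {n / 3:.1f}"
            )
        if cfg.k > n:
            raise ConfigError(f"k: {cfg.k} exceeds design size {n}")
    elif cfg.ct_path is None:
        raise ConfigError("ct_path: required when simulate is disabled")
    return cfg


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_df(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig) -> ResultsBundle:
    """Execute the enabled stages in dependency order.

    Any stage failure aborts with the stage name; artifacts of completed
    stages are preserved on disk.  Fully deterministic under a fixed seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("ductmap")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    started = datetime.now(timezone.utc).isoformat()

    def emit(name: str) -> None:
        files[name] = _sha256(outdir / name)

    bulk = None
    design = programs = None
    try:
        # --- simulate -----------------------------------------------------
        if config.simulate:
            stage = "simulate"
            try:
                n = _design_n_cells(config.design)
                if config.design == "paper":
                    design, programs = default_study_design()
                else:
                    design, programs = scaled_study_design(n_cells=n)
                ct, truth = generate_cohort(design, programs, seed=config.stage_seed("simulate"),
                                            lod=config.lod)
                bulk, bulk_truth = generate_bulk(
                    design, programs, noise_sd=config.bulk_noise_sd,
                    seed=config.stage_seed("simulate_bulk"),
                )
                write_ct_matrix(ct, outdir / "ct.csv", dialect="wide_csv")
                write_bulk_panel(bulk, outdir / "bulk.csv")
                write_ground_truth(truth, ct.cell_ids, outdir / "ground_truth.json")
                emit("ct.csv"); emit("bulk.csv"); emit("ground_truth.json")
                logger.info("simulated cohort: %d cells, %d bulk samples", ct.n_cells, bulk.n_samples)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(stage, exc) from exc
            ct_path, ct_dialect = outdir / "ct.csv", "wide_csv"
        else:
            ct_path, ct_dialect = Path(config.ct_path), config.ct_dialect
            if config.bulk_path is not None:
                bulk = load_bulk_panel(config.bulk_path)

        # --- load + transform --------------------------------------------
        stage = "load"
        try:
            ct = load_ct_matrix(ct_path, dialect=ct_dialect)
            ct = qc_filter(ct, config.min_detected)
            if ct.n_cells == 0:
                raise ValueError("no cells survive QC")
            et = ct_to_expression(ct, lod=config.lod)
            logger.info("loaded %d cells x %d genes", et.n_cells, et.panel.size)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, exc) from exc

        embedding = None
        if config.run_embed:
            stage = "embed"
            try:
                params = TsneParams(**{**asdict(config.tsne), "seed": config.stage_seed("embed")})
                embedding = tsne_embed(et, params)
                _write_df(
                    pd.DataFrame(
                        {"cell_id": et.cell_ids,
                         "tsne1": embedding.coords[:, 0],
                         "tsne2": embedding.coords[:, 1]}
                    ),
                    outdir / "embedding.csv",
                )
                _write_df(
                    pd.DataFrame(embedding.kl_trace, columns=["iteration", "kl"]),
                    outdir / "trace.csv",
                )
                emit("embedding.csv"); emit("trace.csv")
                logger.info("embedding done; final KL %.4f", embedding.kl_trace[-1, 1])
            except StageError:
                raise
            except Exception as exc:
                raise StageError(stage, exc) from exc

        assignment = None
        if config.run_cluster:
            stage = "cluster"
            try:
                ds = None
                if config.downsample_fraction < 1.0:
                    ds = DownsampleSettings(
                        target_fraction=config.downsample_fraction,
                        kernel_radius=config.downsample_radius,
                        seed=config.stage_seed("cluster"),
                    )
                assignment = cluster_cells(
                    et, k=config.k, downsample=ds, space=config.space,
                    embedding=embedding, linkage_method=config.linkage,
                )
                _write_df(
                    pd.DataFrame({"cell_id": et.cell_ids, "cluster": assignment.labels}),
                    outdir / "clusters.csv",
                )
                cent = pd.DataFrame(assignment.centroids, columns=list(et.panel.gene_names))
                cent.insert(0, "cluster", np.arange(1, assignment.k + 1))
                _write_df(cent, outdir / "centroids.csv")
                emit("clusters.csv"); emit("centroids.csv")
                if embedding is not None:
                    _write_df(overlay_labels(assignment, embedding), outdir / "overlay.csv")
                    emit("overlay.csv")
                logger.info("clustering done; sizes %s", assignment.sizes.tolist())
            except StageError:
                raise
            except Exception as exc:
                raise StageError(stage, exc) from exc

        if config.run_project and bulk is not None and embedding is not None and assignment is not None:
            stage = "project"
            try:
                sc_z, bk_z, genes_used = standardize_overlap(et, bulk, config.overlap_genes)
                sim = similarity_matrix(sc_z, bk_z, et.cell_ids, bulk.sample_ids, genes_used)
                proj = match_and_project(sim, embedding, assignment, bulk.cell_types, m=config.m)
                sim_df = pd.DataFrame(sim.values, columns=list(sim.cell_ids))
                sim_df.insert(0, "bulk_sample", list(sim.bulk_ids))
                _write_df(sim_df, outdir / "similarity.csv")
                _write_df(proj.matches, outdir / "projection.csv")
                row_o, col_o = cocluster_heatmap_order(sim)
                identity = {
                    "m": proj.m,
                    "cluster_distribution": {
                        t: {str(k): v for k, v in d.items()}
                        for t, d in proj.cluster_distribution.items()
                    },
                    "modal_cluster": proj.modal_cluster,
                    "heatmap_row_order": row_o.tolist(),
                    "heatmap_col_order": col_o.tolist(),
                }
                (outdir / "identity.json").write_text(json.dumps(identity, indent=1))
                emit("similarity.csv"); emit("projection.csv"); emit("identity.json")
                logger.info("projection done; modal clusters %s", proj.modal_cluster)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(stage, exc) from exc

        if config.run_stats and assignment is not None:
            stage = "stats"
            try:
                freq = cluster_frequencies(assignment, et.cells)
                _write_df(freq, outdir / "frequencies.csv")
                markers = rank_markers(et, assignment, top_n=config.top_n)
                _write_df(markers, outdir / "markers.csv")
                de = prepost_comparison(
                    et, include_surgical_controls=config.include_surgical_controls
                )
                _write_df(de, outdir / "de.csv")
                overlay = pd.DataFrame({"cell_id": et.cell_ids})
                for g in config.overlay_genes:
                    if g in et.panel.gene_names:
                        overlay[g] = gene_overlay_scale(et, g)
                _write_df(overlay, outdir / "gene_overlay.csv")
                emit("frequencies.csv"); emit("markers.csv"); emit("de.csv")
                emit("gene_overlay.csv")
                logger.info("stats done")
            except StageError:
                raise
            except Exception as exc:
                raise StageError(stage, exc) from exc

        manifest = {
            "version": __version__,
            "seed": config.seed,
            "started": started,
            "finished": datetime.now(timezone.utc).isoformat(),
            "config": config.to_dict(),
            "files": files,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return ResultsBundle(outdir=outdir, manifest=manifest)
    finally:
        root.removeHandler(handler)
        handler.close()
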