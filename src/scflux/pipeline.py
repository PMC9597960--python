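"""End-to-end pipeline: preprocess → denoise → RAS → bounds → FBA → QC → cluster.

A :class:`RunConfig` pins every parameter and seed; :func:`run_pipeline`
executes the stages in order, writes every intermediate artifact plus a
manifest with checksums, and is bit-reproducible from the config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .clustering import ClusterConfig, cluster_features, correlation_diagnostics
from .denoise import DENOISE_STAGES, DiffusionConfig, apply_denoising
from .errors import ConfigurationError, ScfluxError
from .fba_features import build_flux_matrix, find_essential, flux_qc
from .flux_constraints import DEFAULT_EPSILON, make_bounds, run_fva
from .gpr_ras import sparsity_report
from .model_core import RICH_MEDIUM_UPTAKE, apply_rich_medium, read_model
from .sc_preprocess import (
    CellCycleSignature,
    log1p,
    normalize_total,
    qc_filter,
    read_counts,
    score_cell_cycle,
)

logger = logging.getLogger("scflux.pipeline")


def setup_logging(level: str = "INFO", logfile=None) -> None:
    """Configure the package logger to stderr (and optionally a file)."""
    root = logging.getLogger("scflux")
    root.setLevel(level.upper())
    root.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(fmt)
    root.addHandler(h)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        root.addHandler(fh)


@dataclass
class RunConfig:
    """Declarative description of one pipeline run.

    Serialises round-trip through YAML; every effective value is echoed in
    the run metadata.
    """

    model_path: str = ""
    model_dialect: str = "tabular"
    counts_path: str = ""
    counts_format: str = "csv"
    outdir: str = "scflux_run"
    # preprocessing
    min_genes_per_cell: int = 2000
    min_cells_per_gene: int = 3
    target_sum: float = 1e6
    s_genes_path: str | None = None
    g2m_genes_path: str | None = None
    # denoising
    denoise_stage: str = "on_counts"  # none | on_counts | on_ras
    denoise_method: str = "diffusion"
    diffusion: dict = field(default_factory=lambda: asdict(DiffusionConfig()))
    # bounds
    uptake_magnitude: float = RICH_MEDIUM_UPTAKE
    bounds_strategy: str = "plain"  # plain | epsilon
    epsilon: float = DEFAULT_EPSILON
    # FBA
    objective_id: str | None = None
    # clustering
    cluster: dict = field(default_factory=lambda: asdict(ClusterConfig()))
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.denoise_stage not in DENOISE_STAGES:
            raise ConfigurationError(f"denoise_stage must be one of {DENOISE_STAGES}")
        if self.bounds_strategy not in ("plain", "epsilon"):
            raise ConfigurationError("bounds_strategy must be 'plain' or 'epsilon'")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def diffusion_config(self) -> DiffusionConfig:
        d = dict(self.diffusion)
        d.setdefault("seed", self.seed)
        return DiffusionConfig(**d)

    def cluster_config(self) -> ClusterConfig:
        d = dict(self.cluster)
        d.setdefault("seed", self.seed)
        return ClusterConfig(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig, model=None, counts=None) -> Path:
    """Execute every stage and write artifacts + manifest under ``cfg.outdir``.

    ``model`` and ``counts`` may be passed in-memory (bypassing the path
    fields) — the programmatic entry point used by the fixtures and tests.
    Returns the run directory.  A stage failure halts the pipeline with the
    stage name; artifacts written so far are preserved.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    setup_logging(cfg.log_level, outdir / "run.log")
    artifacts: dict[str, str] = {}
    stage = "setup"

    def write(name: str, frame) -> None:
        p = outdir / name
        frame.to_csv(p, sep="\t")
        artifacts[name] = _sha256(p)

    try:
        stage = "read_model"
        if model is None:
            model = read_model(cfg.model_path, cfg.model_dialect)
        medium_model = apply_rich_medium(model, cfg.uptake_magnitude)
        objective_id = cfg.objective_id or model.objective_id

        stage = "read_counts"
        if counts is None:
            counts = read_counts(cfg.counts_path, cfg.counts_format)

        stage = "qc_filter"
        filtered = qc_filter(counts, cfg.min_genes_per_cell, cfg.min_cells_per_gene)
        stage = "normalize"
        normed = normalize_total(filtered, cfg.target_sum)
        write("filtered_normalized_counts.tsv", normed.to_frame())

        if cfg.s_genes_path and cfg.g2m_genes_path:
            stage = "cell_cycle_scoring"
            sig = CellCycleSignature.from_files(cfg.s_genes_path, cfg.g2m_genes_path)
            scored = score_cell_cycle(log1p(normed), sig, seed=cfg.seed)
            normed.cell_meta = scored.cell_meta  # keep the normalized layer itself
            write("cell_cycle_scores.tsv", normed.cell_meta)

        stage = "denoise_and_ras"
        ras, denoise_meta = apply_denoising(
            cfg.denoise_stage,
            model,
            normed,
            cfg.diffusion_config(),
            method=cfg.denoise_method,
        )
        write("ras_matrix.tsv", ras.to_frame())
        if ras.dropped_reactions:
            (outdir / "ras_dropped_reactions.tsv").write_text(
                "\n".join(ras.dropped_reactions) + "\n"
            )
            artifacts["ras_dropped_reactions.tsv"] = _sha256(
                outdir / "ras_dropped_reactions.tsv"
            )

        stage = "essentiality"
        essential = find_essential(medium_model, objective_id)

        stage = "sparsity_report"
        ess_in_ras = set(essential.reactions) & set(ras.reaction_ids)
        sparsity = sparsity_report(ras, essential_set=ess_in_ras or None)
        write("ras_sparsity_per_cell.tsv", sparsity.to_frame())

        stage = "fva"
        fva = run_fva(medium_model)
        write("fva_envelopes.tsv", fva.to_frame())

        stage = "bounds"
        bounds = make_bounds(fva, ras, medium_model, cfg.bounds_strategy, cfg.epsilon)
        write("cell_bounds_lower.tsv", bounds.lower_frame())
        write("cell_bounds_upper.tsv", bounds.upper_frame())

        stage = "fba"
        fm = build_flux_matrix(medium_model, bounds, objective_id)
        write("flux_matrix.tsv", fm.to_frame())

        stage = "flux_qc"
        qc = flux_qc(fm, ras, essential)
        write("flux_qc_removed_cells.tsv", qc.removed.set_index("cell_id") if len(qc.removed) else qc.removed)
        fm_clean = qc.flux_matrix

        stage = "clustering"
        known = None
        if "population" in counts.cell_meta.columns:
            known = counts.cell_meta.loc[list(fm_clean.cell_ids), "population"].to_numpy()
        result = cluster_features(fm_clean, cfg.cluster_config(), known_groups=known)
        write("cluster_labels.tsv", result.labels.to_frame())
        write("cluster_grid_scores.tsv", result.grid_scores)

        stage = "diagnostics"
        diag = {}
        if "S_score" in normed.cell_meta.columns:
            s = normed.cell_meta.loc[list(fm_clean.cell_ids), "S_score"].to_numpy()
            g2m = normed.cell_meta.loc[list(fm_clean.cell_ids), "G2M_score"].to_numpy()
            obj = fm_clean.objective_values
            diag["spearman_objective_vs_S_score"] = correlation_diagnostics(obj, s)
            diag["spearman_objective_vs_G2M_score"] = correlation_diagnostics(obj, g2m)

        stage = "metadata"
        meta = {
            "scflux_version": __version__,
            "config": asdict(cfg),
            "objective_id": objective_id,
            "denoise": denoise_meta,
            "solver": {"name": "glpk", "feasibility_tol": 1e-9},
            "gene_coverage": ras.coverage,
            "n_cells_in": counts.n_cells,
            "n_cells_after_qc_filter": filtered.n_cells,
            "n_cells_after_flux_qc": len(fm_clean.cell_ids),
            "ras_zero_fraction": sparsity.overall_zero_fraction,
            "essential_reactions": sorted(essential.reactions),
            "selected_n_pcs": result.selected_n_pcs,
            "selected_resolution": result.selected_resolution,
            "silhouette": result.silhouette,
            "n_clusters": result.n_clusters,
            "ari_vs_known": result.ari,
            "nmi_vs_known": result.nmi,
            "diagnostics": {k: list(v) for k, v in diag.items()},
        }
        (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=1, default=float))
        artifacts["run_metadata.json"] = _sha256(outdir / "run_metadata.json")
        (outdir / "manifest.json").write_text(json.dumps(artifacts, indent=1, sort_keys=True))
    except ScfluxError:
        logger.error("pipeline halted at stage %r", stage)
        raise
    except Exception as e:
        logger.error("pipeline halted at stage %r: %s", stage, e)
        raise ScfluxError(f"stage {stage!r} failed: {e}") from e
    return outdir
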