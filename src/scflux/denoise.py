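"""Graph-diffusion denoising of single-cell matrices (counts or RAS).

Dropout in scRNA-seq produces false zeros that, once propagated into Reaction
Activity Scores, switch off reactions essential for the FBA objective.  The
in-repo denoiser removes them by diffusion on the cell–cell similarity graph:
each cell's profile is replaced by a weighted average of similar cells'
profiles, the weights coming from powers of a Markov transition matrix built
from an adaptive Gaussian kernel in PCA space.  The same operator applies
unchanged to the RAS matrix, with reactions playing the role of genes.

External denoisers (MAGIC, ENHANCE, SAVER) are exposed only as adapters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DenoiserUnavailableError, ValidationError

logger = logging.getLogger("scflux.denoise")


@dataclass
class DiffusionConfig:
    """Hyper-parameters of the diffusion denoiser.

    ``n_pcs`` — dimensionality of the PCA space in which cell–cell distances
    are measured (capped at the data dimensions); ``knn`` — neighbourhood
    size; ``decay`` — exponent of the adaptive Gaussian kernel
    ``exp(-(d/σ_i)^decay)`` where σ_i is the distance to the knn-th
    neighbour; ``t`` — diffusion time (number of Markov steps); t=0 is
    admitted as the identity for testing.  ``distance_scale`` sets the
    transform applied before PCA when measuring cell–cell similarity:
    ``cosine`` (default) L2-normalises each cell profile, making the graph
    invariant to residual per-cell scale that total-count normalisation
    cannot remove under zero-inflation; ``linear`` uses the values as-is;
    ``log1p`` log-transforms first (under expression-independent dropout a
    zeroed coordinate flips by its full log-magnitude, which can swamp
    fold-change signal, so this is not the default).  Diffusion itself is
    always applied to the untransformed values.
    """

    n_pcs: int = 20
    knn: int = 15
    decay: float = 1.0
    t: int = 3
    seed: int = 0
    distance_scale: str = "cosine"

    def __post_init__(self):
        if self.knn < 1:
            raise ValidationError("knn must be >= 1")
        if self.n_pcs < 1:
            raise ValidationError("n_pcs must be >= 1")
        if self.decay <= 0:
            raise ValidationError("decay must be positive")
        if self.t < 0:
            raise ValidationError("t must be >= 0")
        if self.distance_scale not in ("cosine", "log1p", "linear"):
            raise ValidationError("distance_scale must be 'cosine', 'log1p' or 'linear'")


def diffusion_operator(cells_by_features: np.ndarray, cfg: DiffusionConfig) -> np.ndarray:
    """Row-stochastic Markov matrix P over cells.

    kNN graph on the top ``n_pcs`` principal components; adaptive Gaussian
    affinities symmetrised as (K + Kᵀ)/2; rows normalised to sum to one.
    """
    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors

    n_cells, n_feat = cells_by_features.shape
    n_pcs = min(cfg.n_pcs, n_cells - 1, n_feat)
    X = cells_by_features
    if cfg.distance_scale == "log1p":
        X = np.log1p(X)
    elif cfg.distance_scale == "cosine":
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        X = X / np.where(norms > 0, norms, 1.0)
    pcs = PCA(n_components=n_pcs, random_state=cfg.seed).fit_transform(X)
    nn = NearestNeighbors(n_neighbors=cfg.knn + 1).fit(pcs)  # +1: self included
    dist, idx = nn.kneighbors(pcs)
    sigma = dist[:, -1]  # distance to the knn-th neighbour (excluding self)
    sigma = np.where(sigma > 0, sigma, np.finfo(float).tiny)
    K = np.zeros((n_cells, n_cells))
    with np.errstate(over="ignore"):
        aff = np.exp(-((dist / sigma[:, None]) ** cfg.decay))
    rows = np.repeat(np.arange(n_cells), idx.shape[1])
    K[rows, idx.ravel()] = aff.ravel()
    K = (K + K.T) / 2.0
    P = K / K.sum(axis=1, keepdims=True)
    return P


def diffusion_denoise(x, cfg: DiffusionConfig | None = None):
    """Denoise an ExpressionMatrix or RASMatrix by graph diffusion.

    Returns the same container type with ``layer_tag='denoised'``; cells are
    unchanged in number and order, the output is nonnegative, and every
    output cell profile is a convex combination of input profiles.
    """
    cfg = cfg or DiffusionConfig()
    values = np.asarray(x.values, dtype=float)  # features x cells
    n_cells = values.shape[1]
    if np.nanmin(values, initial=0.0) < 0:
        raise ValidationError("diffusion_denoise requires nonnegative input")
    if n_cells < cfg.knn + 1:
        raise ValidationError(
            f"need at least knn+1={cfg.knn + 1} cells, got {n_cells}"
        )
    out = x.copy()
    out.layer_tag = "denoised"
    if cfg.t == 0:
        return out
    Y = values.T  # cells x features
    if np.allclose(Y, Y[0], atol=0.0):
        warnings.warn("constant matrix: PCA degenerate, returned unchanged")
        return out
    P = diffusion_operator(Y, cfg)
    smoothed = Y
    for _ in range(cfg.t):
        smoothed = P @ smoothed
    out.values = np.maximum(smoothed.T, 0.0)  # clip solver-level negatives (~0)
    return out


# ---------------------------------------------------------------------------
# External denoiser adapters
# ---------------------------------------------------------------------------

_INSTALL_HINTS = {
    "magic": "pip install magic-impute",
    "enhance": "clone https://github.com/yanailab/enhance and put enhance.py on PYTHONPATH",
    "saver": "install the R package SAVER: install.packages('SAVER')",
}


def external_denoiser_adapter(x, tool_name: str, workdir=None, _runner=None):
    """Round-trip a matrix through an external denoiser with default parameters.

    ``x`` is an ExpressionMatrix or RASMatrix.  ``_runner`` is an injection
    point used in tests: a callable (cells × features array → array) standing
    in for the tool.  Raises :class:`DenoiserUnavailableError` with an
    install hint when the named tool is not importable/installed.
    """
    if tool_name not in _INSTALL_HINTS:
        raise ConfigurationError(
            f"unknown denoiser {tool_name!r}; expected one of {sorted(_INSTALL_HINTS)}"
        )
    Y = np.asarray(x.values, dtype=float).T  # cells x features
    if _runner is not None:
        run = _runner
    elif tool_name == "magic":
        try:
            import magic  # noqa: F401
        except ImportError as e:
            raise DenoiserUnavailableError(
                f"MAGIC is not installed ({_INSTALL_HINTS['magic']})"
            ) from e

        def run(mat):
            return magic.MAGIC(verbose=0).fit_transform(mat)

    elif tool_name == "enhance":
        try:
            import enhance  # noqa: F401
        except ImportError as e:
            raise DenoiserUnavailableError(
                f"ENHANCE is not installed ({_INSTALL_HINTS['enhance']})"
            ) from e

        def run(mat):
            return enhance.enhance(mat)

    else:  # saver, via Rscript
        import shutil
        import subprocess

        if shutil.which("Rscript") is None or subprocess.run(
            ["Rscript", "-e", "library(SAVER)"], capture_output=True
        ).returncode != 0:
            raise DenoiserUnavailableError(
                f"SAVER is not installed ({_INSTALL_HINTS['saver']})"
            )

        def run(mat):
            raise DenoiserUnavailableError(
                "SAVER adapter requires a workdir-based Rscript round-trip; "
                "not implemented without SAVER present"
            )

    denoised = np.asarray(run(Y), dtype=float)
    if denoised.shape != Y.shape:
        raise ValidationError(
            f"{tool_name} adapter changed the matrix shape {Y.shape} -> {denoised.shape}"
        )
    out = x.copy()
    out.values = denoised.T
    out.layer_tag = "denoised"
    return out


# ---------------------------------------------------------------------------
# Pipeline wiring
# ---------------------------------------------------------------------------

DENOISE_STAGES = ("none", "on_counts", "on_ras")


def apply_denoising(
    stage: str,
    model,
    x,
    cfg: DiffusionConfig | None = None,
    method: str = "diffusion",
    gene_map=None,
):
    """Compute the RAS matrix with denoising at the requested stage.

    ``on_counts`` denoises the expression matrix before RAS computation (the
    whole transcriptome informs the cell graph); ``on_ras`` computes RAS
    first and denoises the reactions × cells matrix (only metabolic features
    inform the graph); ``none`` is the undenoised reference path.  Returns
    ``(ras_matrix, metadata dict)``.
    """
    from .gpr_ras import compute_ras

    if stage not in DENOISE_STAGES:
        raise ConfigurationError(
            f"unknown denoising stage {stage!r}; expected one of {DENOISE_STAGES}"
        )

    def denoise(mat):
        if method == "diffusion":
            return diffusion_denoise(mat, cfg)
        return external_denoiser_adapter(mat, method)

    if stage == "on_counts":
        ras = compute_ras(model, denoise(x), gene_map=gene_map)
    elif stage == "on_ras":
        ras = denoise(compute_ras(model, x, gene_map=gene_map))
    else:
        ras = compute_ras(model, x, gene_map=gene_map)
    meta = {
        "denoise_stage": stage,
        "denoise_method": method if stage != "none" else None,
        "denoise_config": None if (stage == "none" or cfg is None) else vars(cfg).copy(),
    }
    return ras, meta
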