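"""Leiden clustering on counts or fluxes, with silhouette-driven model selection.

For each grid point (n_pcs, resolution): z-score features, project to n_pcs
principal components, build a kNN graph, partition with Leiden, and score
the partition with the silhouette index in that PCA space.  The grid point
with the highest silhouette is selected; single-cluster partitions are
excluded from selection.  Correlation diagnostics (Spearman, pairwise
distributions) and agreement metrics against known groups (ARI, NMI) live
here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger("scflux.clustering")


@dataclass
class ClusterConfig:
    """Hyper-parameter grid and graph parameters for cluster model selection."""

    n_pcs_grid: list = field(default_factory=lambda: [5, 10, 15, 20])
    resolution_grid: list = field(default_factory=lambda: [0.1, 0.25, 0.5, 1.0])
    neighbors_k: int = 15
    seed: int = 0
    feature_scaling: bool = True

    def __post_init__(self):
        if not self.n_pcs_grid or not self.resolution_grid:
            raise ValidationError("hyper-parameter grids must be nonempty")
        if self.neighbors_k < 1:
            raise ValidationError("neighbors_k must be >= 1")


@dataclass
class ClusterResult:
    """Selected Leiden partition and its provenance."""

    labels: pd.Series  # cell id -> cluster label (int)
    selected_n_pcs: int
    selected_resolution: float
    silhouette: float
    grid_scores: pd.DataFrame  # columns n_pcs, resolution, n_clusters, silhouette
    embedding: np.ndarray | None = None
    ari: float | None = None
    nmi: float | None = None

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())


def _feature_matrix(features) -> tuple[np.ndarray, list]:
    """Cells × features array from an ExpressionMatrix or FluxMatrix."""
    vals = np.asarray(features.values, dtype=float)
    if np.isnan(vals).any():
        raise ValidationError(
            "feature matrix contains NaN (run flux_qc / drop infeasible cells first)"
        )
    return vals.T, list(features.cell_ids)


def _leiden(adjacency: np.ndarray, resolution: float, seed: int) -> np.ndarray:
    import igraph as ig
    import leidenalg

    src, dst = np.nonzero(np.triu(adjacency, k=1))
    g = ig.Graph(
        n=adjacency.shape[0],
        edges=list(zip(src.tolist(), dst.tolist())),
        edge_attrs={"weight": adjacency[src, dst].tolist()},
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership)


def cluster_features(features, cfg: ClusterConfig | None = None, known_groups=None) -> ClusterResult:
    """Grid-searched Leiden clustering of cells on any feature matrix.

    ``features`` is an ExpressionMatrix (use the log-normalised layer) or a
    QC'd FluxMatrix.  When ``known_groups`` (a per-cell label vector aligned
    with the cells) is given, ARI and NMI against it are attached to the
    result.  Deterministic under a fixed seed.
    """
    from sklearn.decomposition import PCA
    from sklearn.metrics import silhouette_score
    from sklearn.neighbors import kneighbors_graph

    cfg = cfg or ClusterConfig()
    X, cell_ids = _feature_matrix(features)
    n_cells, n_feat = X.shape
    if n_cells < 5:
        raise ValidationError(f"need at least 5 cells to cluster, got {n_cells}")
    if n_cells < cfg.neighbors_k + 1:
        logger.info(
            "neighbors_k=%d >= %d cells; capping at %d",
            cfg.neighbors_k, n_cells, n_cells - 1,
        )
    if cfg.feature_scaling:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0  # constant features carry no signal; leave centred
        X = (X - mu) / sd

    best = None
    rows = []
    for n_pcs in cfg.n_pcs_grid:
        k_pcs = min(n_pcs, n_cells - 1, n_feat)
        pcs = PCA(n_components=k_pcs, random_state=cfg.seed).fit_transform(X)
        adj = kneighbors_graph(
            pcs, n_neighbors=min(cfg.neighbors_k, n_cells - 1), mode="connectivity"
        ).toarray()
        adj = np.maximum(adj, adj.T)  # mutual-or symmetrisation
        for res in cfg.resolution_grid:
            labels = _leiden(adj, float(res), cfg.seed)
            n_clusters = len(np.unique(labels))
            if n_clusters < 2 or n_clusters >= n_cells:
                sil = -np.inf  # silhouette undefined; excluded from selection
            else:
                sil = float(silhouette_score(pcs, labels))
            rows.append(
                {"n_pcs": n_pcs, "resolution": res, "n_clusters": n_clusters,
                 "silhouette": sil}
            )
            if sil > -np.inf and (best is None or sil > best[0]):
                best = (sil, n_pcs, float(res), labels)
    grid = pd.DataFrame(rows)
    if best is None:
        # every grid point collapsed to one cluster: report it honestly
        labels = np.zeros(n_cells, dtype=int)
        sil, n_pcs_sel, res_sel = float("nan"), cfg.n_pcs_grid[0], float(cfg.resolution_grid[0])
    else:
        sil, n_pcs_sel, res_sel, labels = best
    result = ClusterResult(
        labels=pd.Series(labels, index=cell_ids, name="cluster"),
        selected_n_pcs=n_pcs_sel,
        selected_resolution=res_sel,
        silhouette=sil,
        grid_scores=grid,
    )
    if known_groups is not None:
        result.ari, result.nmi = compare_to_known_groups(result, known_groups)
    logger.info(
        "selected n_pcs=%d resolution=%.3g: %d clusters, silhouette=%.3f",
        n_pcs_sel, res_sel, result.n_clusters, sil,
    )
    return result


def umap_embedding(features, cfg: ClusterConfig | None = None) -> np.ndarray:
    """Optional 2-D UMAP of the (scaled, PCA-reduced) features for plotting."""
    import umap
    from sklearn.decomposition import PCA

    cfg = cfg or ClusterConfig()
    X, _ = _feature_matrix(features)
    if cfg.feature_scaling:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    k = min(cfg.n_pcs_grid[-1], X.shape[0] - 1, X.shape[1])
    pcs = PCA(n_components=k, random_state=cfg.seed).fit_transform(X)
    return umap.UMAP(random_state=cfg.seed).fit_transform(pcs)


# ---------------------------------------------------------------------------
# Correlation diagnostics
# ---------------------------------------------------------------------------

def correlation_diagnostics(a, b) -> tuple[float, float]:
    """Spearman rank correlation (rho, p) between two equal-length vectors.

    A constant vector makes rho undefined; (nan, nan) is returned instead of
    raising.
    """
    from scipy import stats

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("inputs must be equal-length 1-D vectors")
    if len(a) < 3:
        raise ValidationError("need at least 3 observations")
    if np.all(a == a[0]) or np.all(b == b[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


def pairwise_spearman(matrix) -> np.ndarray:
    """Off-diagonal distribution of pairwise Spearman correlations of rows.

    ``matrix`` is features × cells (e.g. a RAS matrix); returns the condensed
    upper-triangle vector of row–row correlations, NaN where a row is
    constant.
    """
    from scipy import stats

    vals = np.asarray(matrix.values if hasattr(matrix, "values") else matrix, dtype=float)
    n = vals.shape[0]
    if n < 2:
        raise ValidationError("need at least two rows")
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        # constant rows are flagged as NaN below; silence scipy's warning
        _warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(vals, axis=1).statistic
    if np.isscalar(rho) or np.ndim(rho) == 0:  # scipy collapses the 2-row case
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    const = np.all(vals == vals[:, :1], axis=1)
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    iu = np.triu_indices(n, k=1)
    return rho[iu]


def compare_to_known_groups(result, known) -> tuple[float, float]:
    """ARI and NMI between a clustering and a known cell partition."""
    from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

    labels = result.labels if hasattr(result, "labels") else pd.Series(result)
    known = np.asarray(known)
    if len(known) != len(labels):
        raise ValidationError(
            f"known labels length {len(known)} != clustering length {len(labels)}"
        )
    pred = np.asarray(labels)
    return (
        float(adjusted_rand_score(known, pred)),
        float(normalized_mutual_info_score(known, pred)),
    )
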