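"""Single-cell expression matrix: reading, QC filtering, normalisation, cell-cycle scoring.

The container is genes × cells (transcripts ``T^c_g``).  The preprocessing
recipe is: filter cells with too few detected genes, then genes detected in
too few cells; total-count normalise each cell to a common target sum;
log1p-transform; score S and G2M cell-cycle signatures against expression-
matched control gene sets and call a phase per cell.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyResultError, ReadError, ValidationError

logger = logging.getLogger("scflux.sc_preprocess")


@dataclass
class ExpressionMatrix:
    """Genes × cells expression values with per-cell annotations.

    ``layer_tag`` records the processing state: raw counts, total-count
    ``normalized``, ``lognormalized``, or ``denoised``.  ``cell_meta`` is
    indexed by cell id and carries phase labels, cycle scores and known
    group labels when available.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray
    layer_tag: str = "raw"
    cell_meta: pd.DataFrame | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene identifiers (collapse on read)")
        if self.layer_tag in ("raw", "normalized") and self.values.size and self.values.min() < 0:
            raise ValidationError(f"negative values in {self.layer_tag} layer")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        else:
            self.cell_meta = self.cell_meta.loc[list(self.cell_ids)]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.gene_ids),
            list(self.cell_ids),
            self.values.copy(),
            self.layer_tag,
            self.cell_meta.copy(),
        )

    def subset(self, gene_mask=None, cell_mask=None) -> "ExpressionMatrix":
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask)
        cm = np.ones(self.n_cells, bool) if cell_mask is None else np.asarray(cell_mask)
        return ExpressionMatrix(
            [g for g, k in zip(self.gene_ids, gm) if k],
            [c for c, k in zip(self.cell_ids, cm) if k],
            self.values[np.ix_(gm, cm)],
            self.layer_tag,
            self.cell_meta.loc[cm.tolist()] if self.cell_meta is not None else None,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    def to_anndata(self):
        """Cells × genes AnnData view (the single-cell toolkit convention)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.values.T.copy(),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )
        adata.obs_names = list(self.cell_ids)
        return adata


def _collapse_duplicate_genes(gene_ids, values):
    """Sum rows sharing a gene identifier; keep first-occurrence order."""
    if len(set(gene_ids)) == len(gene_ids):
        return list(gene_ids), values
    order: list[str] = []
    index: dict[str, int] = {}
    for g in gene_ids:
        if g not in index:
            index[g] = len(order)
            order.append(g)
    out = np.zeros((len(order), values.shape[1]))
    for i, g in enumerate(gene_ids):
        out[index[g]] += values[i]
    logger.info("collapsed %d duplicate gene rows by summing", len(gene_ids) - len(order))
    return order, out


def read_counts(path, format: str) -> ExpressionMatrix:
    """Read a raw counts matrix.

    ``mtx_dir`` expects a directory with ``matrix.mtx`` (genes × cells),
    ``genes.tsv`` and ``barcodes.tsv`` (first column = identifier);
    ``csv`` expects genes as rows (index) and cells as columns (header).
    Duplicate gene identifiers are collapsed by summing their counts.
    """
    path = Path(path)
    if format == "mtx_dir":
        from scipy.io import mmread

        mtx = path / "matrix.mtx"
        genes_f = path / "genes.tsv"
        cells_f = path / "barcodes.tsv"
        for f in (mtx, genes_f, cells_f):
            if not f.exists():
                raise ReadError(f"missing file {f}")
        raw = mmread(str(mtx))
        values = np.asarray(raw.todense() if hasattr(raw, "todense") else raw, dtype=float)
        genes = pd.read_csv(genes_f, sep="\t", header=None)[0].astype(str).tolist()
        cells = pd.read_csv(cells_f, sep="\t", header=None)[0].astype(str).tolist()
        if values.shape != (len(genes), len(cells)):
            raise ReadError(
                f"matrix shape {values.shape} does not match {len(genes)} genes "
                f"/ {len(cells)} barcodes"
            )
    elif format == "csv":
        df = pd.read_csv(path, index_col=0)
        genes = df.index.astype(str).tolist()
        cells = df.columns.astype(str).tolist()
        values = df.to_numpy(dtype=float)
    else:
        raise ReadError(f"unknown counts format {format!r}")
    genes, values = _collapse_duplicate_genes(genes, values)
    return ExpressionMatrix(genes, cells, values, layer_tag="raw")


def qc_filter(
    x: ExpressionMatrix,
    min_genes_per_cell: int = 2000,
    min_cells_per_gene: int = 3,
) -> ExpressionMatrix:
    """Quality filter: drop shallow cells first, then rarely detected genes.

    A cell is kept when it detects (count > 0) at least ``min_genes_per_cell``
    genes; a gene is then kept when it is detected in at least
    ``min_cells_per_gene`` of the surviving cells.  The cells-then-genes
    order is fixed: it changes which genes survive.
    """
    detected = x.values > 0
    cell_mask = detected.sum(axis=0) >= min_genes_per_cell
    if not cell_mask.any():
        raise EmptyResultError(
            f"qc_filter removed all {x.n_cells} cells "
            f"(min_genes_per_cell={min_genes_per_cell})"
        )
    gene_mask = detected[:, cell_mask].sum(axis=1) >= min_cells_per_gene
    out = x.subset(gene_mask, cell_mask)
    logger.info(
        "qc_filter: %d/%d cells, %d/%d genes kept",
        out.n_cells, x.n_cells, out.n_genes, x.n_genes,
    )
    return out


def normalize_total(x: ExpressionMatrix, target_sum: float = 1e6) -> ExpressionMatrix:
    """Scale each cell so its total over genes equals ``target_sum`` (CPM-style)."""
    if target_sum <= 0:
        raise ValidationError("target_sum must be positive")
    totals = x.values.sum(axis=0)
    if np.any(totals <= 0):
        bad = [c for c, t in zip(x.cell_ids, totals) if t <= 0]
        raise ValidationError(
            f"cells with zero total counts {bad[:5]}; run qc_filter first"
        )
    out = x.copy()
    out.values = x.values * (target_sum / totals)
    out.layer_tag = "normalized"
    return out


def log1p(x: ExpressionMatrix) -> ExpressionMatrix:
    """Natural-log(1 + x) transform; tags the layer ``lognormalized``."""
    out = x.copy()
    out.values = np.log1p(out.values)
    out.layer_tag = "lognormalized"
    return out


@dataclass
class CellCycleSignature:
    """S-phase and G2M-phase marker gene lists.

    The two sets need not be disjoint, but neither may be empty at scoring
    time.
    """

    s_genes: set[str] = field(default_factory=set)
    g2m_genes: set[str] = field(default_factory=set)

    @classmethod
    def from_files(cls, s_path, g2m_path) -> "CellCycleSignature":
        def load(p):
            return {ln.strip() for ln in Path(p).read_text().splitlines() if ln.strip()}

        return cls(load(s_path), load(g2m_path))


def score_cell_cycle(
    x: ExpressionMatrix,
    sig: CellCycleSignature,
    n_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
) -> ExpressionMatrix:
    """Score S and G2M signatures and call a phase per cell.

    Per cell, each signature score is the mean expression of its genes minus
    the mean of a control gene set matched on expression bins (``n_bins``
    bins, ``ctrl_size`` controls per signature gene, sampled with ``seed``).
    Phase is G1 when both scores are negative, otherwise the phase of the
    larger score.  Expects the log-normalised layer.  Adds ``S_score``,
    ``G2M_score`` and ``phase`` columns to ``cell_meta``.
    """
    import scanpy as sc

    for name, genes in (("s_genes", sig.s_genes), ("g2m_genes", sig.g2m_genes)):
        if not genes:
            raise ValidationError(f"cell-cycle signature {name} is empty")
        missing = set(genes) - set(x.gene_ids)
        if missing == set(genes):
            raise ValidationError(
                f"no {name} present in the matrix; missing: {sorted(missing)}"
            )

    adata = x.to_anndata()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, genes in (
            ("S_score", sorted(sig.s_genes & set(x.gene_ids))),
            ("G2M_score", sorted(sig.g2m_genes & set(x.gene_ids))),
        ):
            sc.tl.score_genes(
                adata,
                genes,
                score_name=name,
                n_bins=n_bins,
                ctrl_size=ctrl_size,
                random_state=seed,
            )
    out = x.copy()
    s = np.asarray(adata.obs["S_score"], dtype=float)
    g2m = np.asarray(adata.obs["G2M_score"], dtype=float)
    phase = np.where(
        (s <= 0) & (g2m <= 0), "G1", np.where(s > g2m, "S", "G2M")
    )
    out.cell_meta["S_score"] = s
    out.cell_meta["G2M_score"] = g2m
    out.cell_meta["phase"] = phase
    return out


def write_counts_tsv(x: ExpressionMatrix, path) -> None:
    x.to_frame().to_csv(path, sep="\t")
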