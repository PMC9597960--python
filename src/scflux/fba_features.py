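"""Per-cell FBA, essential reactions, and the flux feature matrix.

One LP per cell: maximise the objective flux subject to S·v = 0 and the
cell's RAS-derived bounds.  Because the optimal vertex of an LP is not
unique, a parsimonious tiebreak (minimise Σ|v| at the fixed optimum, i.e.
pFBA) pins a single reproducible flux vector per cell; the resulting
reactions × cells matrix is the feature space for clustering.

A reaction is *essential* for the objective when forcing its flux to zero
forces the optimal objective to zero as well.  Essentiality is computed once
on the rich-medium model, not per cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyResultError, InfeasibleModelError, ValidationError
from .flux_constraints import CellBoundsSet
from .gpr_ras import RASMatrix
from .model_core import MetabolicModel

logger = logging.getLogger("scflux.fba_features")

ZERO_TOL = 1e-9


@dataclass
class EssentialSet:
    """Reactions whose knockout zeroes the objective optimum."""

    objective_id: str
    reactions: frozenset[str]

    def __contains__(self, rid: str) -> bool:
        return rid in self.reactions

    def __iter__(self):
        return iter(sorted(self.reactions))

    def __len__(self):
        return len(self.reactions)


def find_essential(
    model: MetabolicModel,
    objective_id: str | None = None,
    zero_tol: float = ZERO_TOL,
) -> EssentialSet:
    """Single-reaction knockout scan against the objective.

    Each candidate reaction's bounds are temporarily set to (0, 0), the
    objective re-optimised, and the reaction called essential when the
    optimum drops to ≤ ``zero_tol`` (or the LP becomes infeasible).  Original
    bounds are restored.  Requires a strictly positive baseline optimum.
    """
    objective_id = objective_id or model.objective_id
    cm = model.to_cobra()
    cm.objective = objective_id
    baseline = cm.slim_optimize(error_value=float("nan"))
    if not np.isfinite(baseline) or baseline <= zero_tol:
        raise InfeasibleModelError(
            f"baseline optimum for {objective_id!r} is {baseline}; "
            "essentiality is undefined (apply a growth medium first)"
        )
    essential = set()
    for rxn in cm.reactions:
        with cm:
            rxn.bounds = (0.0, 0.0)
            opt = cm.slim_optimize(error_value=float("nan"))
        if not np.isfinite(opt) or opt <= zero_tol:
            essential.add(rxn.id)
    return EssentialSet(objective_id, frozenset(essential))


@dataclass
class FluxMatrix:
    """Reactions × cells optimal fluxes with per-cell optimum and LP status."""

    reaction_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray
    objective_values: np.ndarray
    statuses: list[str]
    objective_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.objective_values = np.asarray(self.objective_values, dtype=float)
        shape = (len(self.reaction_ids), len(self.cell_ids))
        if self.values.shape != shape:
            raise ValidationError(f"flux values must have shape {shape}")
        if len(self.statuses) != len(self.cell_ids):
            raise ValidationError("one solver status per cell required")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.reaction_ids, columns=self.cell_ids)

    def copy(self) -> "FluxMatrix":
        return FluxMatrix(
            list(self.reaction_ids),
            list(self.cell_ids),
            self.values.copy(),
            self.objective_values.copy(),
            list(self.statuses),
            self.objective_id,
        )

    def subset_cells(self, keep_mask) -> "FluxMatrix":
        keep_mask = np.asarray(keep_mask, dtype=bool)
        return FluxMatrix(
            list(self.reaction_ids),
            [c for c, k in zip(self.cell_ids, keep_mask) if k],
            self.values[:, keep_mask],
            self.objective_values[keep_mask],
            [s for s, k in zip(self.statuses, keep_mask) if k],
            self.objective_id,
        )


def _solve_one(cm, lower, upper, reaction_ids, objective_id):
    """Maximise the objective under per-reaction bounds; pFBA tiebreak."""
    from cobra.flux_analysis import pfba

    with cm:
        for rid, lo, hi in zip(reaction_ids, lower, upper):
            cm.reactions.get_by_id(rid).bounds = (float(lo), float(hi))
        cm.objective = objective_id
        opt = cm.slim_optimize(error_value=float("nan"))
        if not np.isfinite(opt):
            return None, float("nan"), "infeasible"
        try:
            sol = pfba(cm)
            fluxes = sol.fluxes.loc[reaction_ids].to_numpy()
            return fluxes, float(opt), "optimal"
        except Exception:
            # fall back to the plain optimum vertex if the tiebreak LP fails
            sol = cm.optimize()
            return sol.fluxes.loc[reaction_ids].to_numpy(), float(opt), "optimal_no_tiebreak"


def solve_cell_fba(
    model: MetabolicModel,
    bounds: CellBoundsSet,
    cell: str,
    objective_id: str | None = None,
):
    """Optimal flux vector and optimum for one cell.

    Returns ``(fluxes, optimum, status)``; an infeasible cell yields
    ``(None, nan, 'infeasible')`` rather than raising.
    """
    objective_id = objective_id or model.objective_id
    lo, hi = bounds.for_cell(cell)
    cm = model.to_cobra()
    return _solve_one(cm, lo, hi, bounds.reaction_ids, objective_id)


def build_flux_matrix(
    model: MetabolicModel,
    bounds: CellBoundsSet,
    objective_id: str | None = None,
) -> FluxMatrix:
    """Solve FBA for every cell and assemble the reactions × cells matrix.

    Infeasible cells get NaN fluxes and a recorded status so downstream QC
    can act on them.
    """
    objective_id = objective_id or model.objective_id
    cm = model.to_cobra()
    n_rxn, n_cells = len(bounds.reaction_ids), len(bounds.cell_ids)
    values = np.full((n_rxn, n_cells), np.nan)
    optima = np.full(n_cells, np.nan)
    statuses = []
    for c, cell in enumerate(bounds.cell_ids):
        fluxes, opt, status = _solve_one(
            cm, bounds.lower[c], bounds.upper[c], bounds.reaction_ids, objective_id
        )
        statuses.append(status)
        optima[c] = opt
        if fluxes is not None:
            values[:, c] = fluxes
    n_bad = sum(s == "infeasible" for s in statuses)
    if n_bad:
        logger.warning("%d/%d cells infeasible under their RAS bounds", n_bad, n_cells)
    return FluxMatrix(
        list(bounds.reaction_ids), list(bounds.cell_ids), values, optima, statuses,
        objective_id,
    )


@dataclass
class FluxQCResult:
    """Filtered flux matrix plus the per-cell removal log."""

    flux_matrix: FluxMatrix
    removed: pd.DataFrame  # columns: cell_id, zero_essential_reactions

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def flux_qc(
    fm: FluxMatrix,
    ras: RASMatrix,
    essential: EssentialSet,
    zero_tol: float = ZERO_TOL,
) -> FluxQCResult:
    """Remove cells with zero RAS on any essential GPR-bearing reaction.

    A cell whose RAS switches off a reaction essential for the objective
    cannot achieve a positive objective flux; such cells (typically victims
    of dropout) are removed before clustering and logged.
    """
    if essential.objective_id != fm.objective_id and fm.objective_id:
        raise ValidationError(
            f"essential set is for {essential.objective_id!r}, "
            f"flux matrix for {fm.objective_id!r}"
        )
    ess_rows = [i for i, r in enumerate(ras.reaction_ids) if r in essential]
    ras_cells = {c: i for i, c in enumerate(ras.cell_ids)}
    keep = np.ones(len(fm.cell_ids), dtype=bool)
    records = []
    for c, cell in enumerate(fm.cell_ids):
        if cell not in ras_cells:
            raise ValidationError(f"cell {cell!r} missing from the RAS matrix")
        col = ras.values[ess_rows, ras_cells[cell]]
        zero = [ras.reaction_ids[ess_rows[k]] for k in np.nonzero(col <= zero_tol)[0]]
        if zero:
            keep[c] = False
            records.append({"cell_id": cell, "zero_essential_reactions": ";".join(zero)})
    if not keep.any():
        raise EmptyResultError(
            "flux_qc removed every cell: each has a zero RAS on at least one "
            "essential reaction (consider denoising)"
        )
    removed = pd.DataFrame(records, columns=["cell_id", "zero_essential_reactions"])
    logger.info("flux_qc: removed %d/%d cells", len(records), len(fm.cell_ids))
    return FluxQCResult(fm.subset_cells(keep), removed)
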