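"""FVA envelopes and RAS-derived per-cell flux bounds.

Given the flux envelope [F^l_j, F^u_j] of each reaction under the growth
medium (from flux variability analysis), a cell's Reaction Activity Score is
turned into flux bounds by scaling the envelope with the RAS normalised to
its maximum across cells:

    plain:    U^c_j = F^u_j · r,              L^c_j = F^l_j · r
    epsilon:  U^c_j = ε + (F^u_j − ε) · r,    L^c_j = −ε + (F^l_j + ε) · r

with r = RAS^c_j / max_c RAS^c_j (r = 0 when the row maximum is zero).  The
ε-strategy leaves a residual capacity ±ε at zero RAS so that false zeros do
not make the cell's LP infeasible.  Reactions without a GPR keep their FVA
envelope; exchange reactions keep the medium bounds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InfeasibleModelError, ValidationError
from .gpr_ras import RASMatrix
from .model_core import MetabolicModel

logger = logging.getLogger("scflux.flux_constraints")

DEFAULT_EPSILON = 0.01
FEASIBILITY_TOL = 1e-9


@dataclass
class FVAResult:
    """Per-reaction feasible flux envelope [minimum, maximum]."""

    reaction_ids: list[str]
    minimum: np.ndarray
    maximum: np.ndarray
    status: str = "optimal"

    def __post_init__(self):
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)
        # tiny LP round-off can invert degenerate envelopes; snap it
        bad = self.minimum > self.maximum
        if np.any(self.minimum[bad] - self.maximum[bad] > 1e-6):
            raise ValidationError("FVA minimum exceeds maximum beyond tolerance")
        self.minimum = np.minimum(self.minimum, self.maximum)

    def envelope(self, rid: str) -> tuple[float, float]:
        j = self.reaction_ids.index(rid)
        return float(self.minimum[j]), float(self.maximum[j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"minimum": self.minimum, "maximum": self.maximum},
            index=self.reaction_ids,
        )


def run_fva(model: MetabolicModel, reactions: list[str] | None = None) -> FVAResult:
    """Min/max feasible flux per reaction over {S·v=0, v_L ≤ v ≤ v_U}.

    The objective is *not* fixed at any fraction of its optimum: the
    envelopes describe the whole steady-state polytope under the medium.
    """
    from cobra.flux_analysis import flux_variability_analysis

    cm = model.to_cobra()
    try:
        base = cm.slim_optimize(error_value=float("nan"))
    except Exception as e:
        raise InfeasibleModelError(f"base LP failed: {e}") from e
    if np.isnan(base):
        raise InfeasibleModelError(
            "base LP {S·v=0, v_L<=v<=v_U} is infeasible; check exchange bounds "
            "(is the medium applied?) and v_L<=v_U"
        )
    rxn_list = reactions if reactions is not None else model.reaction_ids
    fva = flux_variability_analysis(
        cm, reaction_list=rxn_list, fraction_of_optimum=0.0, processes=1
    )
    fva = fva.loc[rxn_list]
    return FVAResult(list(rxn_list), fva["minimum"].to_numpy(), fva["maximum"].to_numpy())


@dataclass
class CellBoundsSet:
    """Per-cell flux bounds for every model reaction (cells × reactions)."""

    reaction_ids: list[str]
    cell_ids: list[str]
    lower: np.ndarray
    upper: np.ndarray
    strategy: str = "plain"
    epsilon: float = 0.0
    #: reactions where Eq. L = −ε + (F^l+ε)·r dips below an irreversible
    #: reaction's zero lower bound; implemented as printed, flagged here
    negative_lower_flags: list[str] | None = None

    def __post_init__(self):
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        shape = (len(self.cell_ids), len(self.reaction_ids))
        if self.lower.shape != shape or self.upper.shape != shape:
            raise ValidationError(f"bounds arrays must have shape {shape}")
        if np.any(self.lower > self.upper + 1e-12):
            raise ValidationError("lower bound exceeds upper bound")
        if self.epsilon < 0:
            raise ValidationError("epsilon must be nonnegative")

    def for_cell(self, cell_id: str) -> tuple[np.ndarray, np.ndarray]:
        c = self.cell_ids.index(cell_id)
        return self.lower[c], self.upper[c]

    def lower_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.lower, index=self.cell_ids, columns=self.reaction_ids)

    def upper_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.upper, index=self.cell_ids, columns=self.reaction_ids)


def _ras_ratio(ras: RASMatrix) -> np.ndarray:
    """RAS normalised by its per-reaction maximum over cells (0 where max = 0)."""
    if np.any(ras.values < 0):
        raise ValidationError("RAS values must be nonnegative")
    row_max = ras.values.max(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(row_max > 0, ras.values / np.where(row_max > 0, row_max, 1.0), 0.0)
    return ratio


def _base_bounds(fva: FVAResult, ras: RASMatrix, model: MetabolicModel):
    """Shared scaffolding: default (envelope/medium) bounds + RAS row lookup."""
    missing = set(ras.reaction_ids) - set(fva.reaction_ids)
    if missing:
        raise ValidationError(f"FVA result does not cover RAS reactions: {sorted(missing)}")
    fva_idx = {r: j for j, r in enumerate(fva.reaction_ids)}
    n_cells, n_rxn = len(ras.cell_ids), model.n_reactions
    lower = np.empty((n_cells, n_rxn))
    upper = np.empty((n_cells, n_rxn))
    for j, rid in enumerate(model.reaction_ids):
        if model.exchange_flags[j] or rid not in fva_idx:
            # exchanges keep the medium bounds; reactions outside the FVA
            # subset keep model bounds
            lower[:, j] = model.lower_bounds[j]
            upper[:, j] = model.upper_bounds[j]
        else:
            k = fva_idx[rid]
            lower[:, j] = fva.minimum[k]
            upper[:, j] = fva.maximum[k]
    # RAS rows that constrain: GPR-bearing, non-exchange reactions
    ras_targets = []
    for i, rid in enumerate(ras.reaction_ids):
        if rid in model.reaction_ids:
            j = model.reaction_index(rid)
            if not model.exchange_flags[j]:
                ras_targets.append((i, j, rid))
    return lower, upper, fva_idx, ras_targets


def ras_bounds(fva: FVAResult, ras: RASMatrix, model: MetabolicModel) -> CellBoundsSet:
    """Plain strategy: scale each reaction's FVA envelope by the RAS ratio.

    A reaction whose RAS is zero in every cell keeps bounds (0, 0) for all
    cells — its flux is switched off everywhere.
    """
    lower, upper, fva_idx, targets = _base_bounds(fva, ras, model)
    ratio = _ras_ratio(ras)
    for i, j, rid in targets:
        k = fva_idx[rid]
        lower[:, j] = fva.minimum[k] * ratio[i]
        upper[:, j] = fva.maximum[k] * ratio[i]
    lo, hi = np.minimum(lower, upper), np.maximum(lower, upper)
    return CellBoundsSet(
        list(model.reaction_ids), list(ras.cell_ids), lo, hi, strategy="plain"
    )


def epsilon_bounds(
    fva: FVAResult,
    ras: RASMatrix,
    model: MetabolicModel,
    epsilon: float = DEFAULT_EPSILON,
) -> CellBoundsSet:
    """ε-strategy: leave residual capacity ±ε at zero RAS.

    At ratio 0 the bounds are (−ε, ε); at ratio 1 they telescope back to the
    FVA envelope (F^l, F^u).  Mitigates infeasibility caused by false zero
    RAS values.  For irreversible reactions (F^l = 0) the lower-bound
    formula is slightly negative at sub-maximal RAS; this is kept as
    defined and the affected reactions are flagged.
    """
    if epsilon <= 0:
        raise ValidationError("epsilon must be positive")
    lower, upper, fva_idx, targets = _base_bounds(fva, ras, model)
    ratio = _ras_ratio(ras)
    inverted, negative_lower = [], []
    for i, j, rid in targets:
        k = fva_idx[rid]
        fu, fl = fva.maximum[k], fva.minimum[k]
        if epsilon >= fu > 0:
            inverted.append(rid)
        u = epsilon + (fu - epsilon) * ratio[i]
        l = -epsilon + (fl + epsilon) * ratio[i]
        if fl == 0 and np.any(l < 0):
            negative_lower.append(rid)
        lower[:, j] = l
        upper[:, j] = u
    if inverted:
        warnings.warn(
            f"epsilon={epsilon} >= F^u for reactions {inverted}; "
            "bound ordering may invert, clamping L <= U"
        )
    lo, hi = np.minimum(lower, upper), np.maximum(lower, upper)
    return CellBoundsSet(
        list(model.reaction_ids),
        list(ras.cell_ids),
        lo,
        hi,
        strategy="epsilon",
        epsilon=epsilon,
        negative_lower_flags=negative_lower or None,
    )


def make_bounds(
    fva: FVAResult,
    ras: RASMatrix,
    model: MetabolicModel,
    strategy: str = "plain",
    epsilon: float = DEFAULT_EPSILON,
) -> CellBoundsSet:
    """Dispatch on ``strategy`` ∈ {plain, epsilon}."""
    if strategy == "plain":
        return ras_bounds(fva, ras, model)
    if strategy == "epsilon":
        return epsilon_bounds(fva, ras, model, epsilon)
    raise ValidationError(f"unknown bounds strategy {strategy!r}")
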