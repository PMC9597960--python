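"""Constraint-based metabolic model container, readers/writers and toy presets.

A model is the tuple (S, v_L, v_U, GPRs, objective): an M x R stoichiometric
matrix over M metabolites and R reactions, per-reaction flux bounds, one
gene-protein-reaction boolean rule per reaction (possibly empty), and the
reaction whose flux FBA maximises.  Exchange reactions follow the COBRA sign
convention: negative flux = uptake, positive flux = secretion.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ModelParseError, ValidationError

logger = logging.getLogger("scflux.model_core")

#: default magnitude encoding "unlimited" nutrient availability; a finite
#: large bound keeps every LP bounded.
RICH_MEDIUM_UPTAKE = 1000.0


@dataclass
class MetabolicModel:
    """In-memory constraint-based model.

    ``S`` is stored dense (core models are small); ``exchange_flags`` marks
    reactions that exchange matter with the environment.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    gpr: list[str]
    exchange_flags: np.ndarray
    objective_id: str

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        self.exchange_flags = np.asarray(self.exchange_flags, dtype=bool)
        self.validate()

    # -- structural invariants -------------------------------------------------
    def validate(self) -> None:
        M, R = len(self.metabolite_ids), len(self.reaction_ids)
        if self.S.shape != (M, R):
            raise ValidationError(
                f"S has shape {self.S.shape}, expected ({M}, {R})"
            )
        for name, arr in (
            ("lower_bounds", self.lower_bounds),
            ("upper_bounds", self.upper_bounds),
            ("exchange_flags", self.exchange_flags),
        ):
            if arr.shape != (R,):
                raise ValidationError(f"{name} has length {arr.shape}, expected {R}")
        if len(self.gpr) != R:
            raise ValidationError(f"gpr list has length {len(self.gpr)}, expected {R}")
        if np.any(self.lower_bounds > self.upper_bounds):
            j = int(np.argmax(self.lower_bounds > self.upper_bounds))
            raise ValidationError(
                f"lower bound exceeds upper bound for reaction {self.reaction_ids[j]!r}"
            )
        if self.objective_id not in self.reaction_ids:
            raise ValidationError(f"objective {self.objective_id!r} not in reaction_ids")
        if len(set(self.reaction_ids)) != R:
            raise ValidationError("duplicate reaction identifiers")
        if len(set(self.metabolite_ids)) != M:
            raise ValidationError("duplicate metabolite identifiers")

    # -- conveniences ----------------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def reaction_index(self, rid: str) -> int:
        return self.reaction_ids.index(rid)

    def genes(self) -> set[str]:
        """All gene identifiers appearing in any GPR."""
        out: set[str] = set()
        for g in self.gpr:
            out.update(_gpr_genes(g))
        return out

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            list(self.metabolite_ids),
            list(self.reaction_ids),
            self.S.copy(),
            self.lower_bounds.copy(),
            self.upper_bounds.copy(),
            list(self.gpr),
            self.exchange_flags.copy(),
            self.objective_id,
        )

    def to_cobra(self):
        """Convert to a :class:`cobra.Model` (GLPK solver) for LP work."""
        import cobra

        m = cobra.Model("scflux")
        mets = {
            mid: cobra.Metabolite(mid, compartment="c") for mid in self.metabolite_ids
        }
        rxns = []
        for j, rid in enumerate(self.reaction_ids):
            r = cobra.Reaction(rid)
            r.lower_bound = float(self.lower_bounds[j])
            r.upper_bound = float(self.upper_bounds[j])
            rxns.append(r)
        m.add_reactions(rxns)
        for j, rid in enumerate(self.reaction_ids):
            col = self.S[:, j]
            nz = np.nonzero(col)[0]
            m.reactions.get_by_id(rid).add_metabolites(
                {mets[self.metabolite_ids[i]]: float(col[i]) for i in nz}
            )
            if self.gpr[j]:
                m.reactions.get_by_id(rid).gene_reaction_rule = self.gpr[j]
        m.objective = self.objective_id
        m.solver = "glpk"
        return m


def _gpr_genes(gpr: str) -> set[str]:
    """Gene identifiers in a GPR string (tokens other than and/or/parens)."""
    toks = re.findall(r"[^\s()]+", gpr)
    return {t for t in toks if t.lower() not in ("and", "or")}


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

#: columns of the tabular (TSV) model dialect, in order
TABULAR_COLUMNS = ("reaction_id", "equation", "lower_bound", "upper_bound", "gpr", "is_exchange")

_ARROWS = ("<=>", "-->", "<--")


def _parse_equation(eq: str, rid: str) -> dict[str, float]:
    """Parse ``2 a + b --> c`` into a metabolite→coefficient map."""
    arrow = next((a for a in _ARROWS if a in eq), None)
    if arrow is None:
        raise ModelParseError(f"reaction {rid!r}: equation {eq!r} has no arrow")
    lhs, rhs = eq.split(arrow, 1)
    if arrow == "<--":
        lhs, rhs = rhs, lhs
    coeffs: dict[str, float] = {}

    def add(side: str, sign: float):
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            parts = term.split()
            if not parts:
                raise ModelParseError(f"reaction {rid!r}: empty term in {eq!r}")
            if len(parts) == 1:
                met, coef = parts[0], 1.0
            elif len(parts) == 2:
                try:
                    coef = float(parts[0])
                except ValueError as e:
                    raise ModelParseError(
                        f"reaction {rid!r}: bad coefficient {parts[0]!r}"
                    ) from e
                met = parts[1]
            else:
                raise ModelParseError(f"reaction {rid!r}: bad term {term!r}")
            coeffs[met] = coeffs.get(met, 0.0) + sign * coef

    add(lhs, -1.0)
    add(rhs, +1.0)
    return {m: c for m, c in coeffs.items() if c != 0.0}


def _format_equation(coeffs: dict[str, float]) -> str:
    def side(items):
        terms = []
        for met, c in items:
            c = abs(c)
            terms.append(met if c == 1.0 else f"{c:.17g} {met}")
        return " + ".join(terms)

    lhs = [(m, c) for m, c in coeffs.items() if c < 0]
    rhs = [(m, c) for m, c in coeffs.items() if c > 0]
    return f"{side(lhs)} <=> {side(rhs)}".strip()


def _from_reaction_records(records, metabolite_order, objective_id) -> MetabolicModel:
    """Assemble a model from (rid, coeffs, lb, ub, gpr, is_exchange) records."""
    mets = list(metabolite_order)
    seen = set(mets)
    for _, coeffs, *_ in records:
        for m in coeffs:
            if m not in seen:
                seen.add(m)
                mets.append(m)
    S = np.zeros((len(mets), len(records)))
    midx = {m: i for i, m in enumerate(mets)}
    rids, lbs, ubs, gprs, exch = [], [], [], [], []
    for j, (rid, coeffs, lb, ub, gpr, is_ex) in enumerate(records):
        rids.append(rid)
        lbs.append(lb)
        ubs.append(ub)
        gprs.append(gpr)
        exch.append(is_ex)
        for m, c in coeffs.items():
            S[midx[m], j] = c
    return MetabolicModel(mets, rids, S, lbs, ubs, gprs, exch, objective_id)


def read_model(path, dialect: str) -> MetabolicModel:
    """Read a constraint-based model from ``path``.

    ``dialect`` is one of ``sbml`` (Level 3 + fbc, via cobrapy), ``json`` or
    ``tabular`` (both repo-defined; see :func:`write_model`).
    """
    path = str(path)
    if dialect == "sbml":
        return _read_sbml(path)
    if dialect == "json":
        return _read_json(path)
    if dialect == "tabular":
        return _read_tabular(path)
    raise ConfigurationError(f"unknown model dialect {dialect!r}")


def _read_sbml(path: str) -> MetabolicModel:
    import cobra

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cm = cobra.io.read_sbml_model(path)
    except Exception as e:  # cobra raises assorted types for malformed SBML
        raise ModelParseError(f"cannot parse SBML file {path!r}: {e}") from e
    return from_cobra(cm)


def from_cobra(cm) -> MetabolicModel:
    """Convert a :class:`cobra.Model` into a :class:`MetabolicModel`."""
    from cobra.util.array import create_stoichiometric_matrix
    from cobra.util.solver import linear_reaction_coefficients

    S = create_stoichiometric_matrix(cm, array_type="dense")
    obj = linear_reaction_coefficients(cm)
    if not obj:
        raise ModelParseError("model declares no linear objective reaction")
    objective_id = max(obj, key=lambda r: abs(obj[r])).id
    return MetabolicModel(
        [m.id for m in cm.metabolites],
        [r.id for r in cm.reactions],
        S,
        [r.lower_bound for r in cm.reactions],
        [r.upper_bound for r in cm.reactions],
        [r.gene_reaction_rule or "" for r in cm.reactions],
        [r.boundary for r in cm.reactions],
        objective_id,
    )


def _read_tabular(path: str) -> MetabolicModel:
    objective_id = None
    metabolite_order: list[str] = []
    records = []
    with open(path) as fh:
        header = None
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*objective\s*:\s*(\S+)", line)
                if m:
                    objective_id = m.group(1)
                m = re.match(r"#\s*metabolites\s*:\s*(\S+)", line)
                if m:
                    metabolite_order = m.group(1).split(",")
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if tuple(header) != TABULAR_COLUMNS:
                    raise ModelParseError(
                        f"line {ln}: header {header} != {list(TABULAR_COLUMNS)}"
                    )
                continue
            if len(fields) != len(TABULAR_COLUMNS):
                raise ModelParseError(
                    f"line {ln}: expected {len(TABULAR_COLUMNS)} fields, got {len(fields)}"
                )
            rid, eq, lb, ub, gpr, is_ex = fields
            try:
                lb, ub = float(lb), float(ub)
            except ValueError as e:
                raise ModelParseError(f"reaction {rid!r}: non-numeric bound") from e
            records.append((rid, _parse_equation(eq, rid), lb, ub, gpr, is_ex == "1"))
    if objective_id is None:
        raise ModelParseError(f"{path!r}: missing '# objective: <id>' line")
    if not records:
        raise ModelParseError(f"{path!r}: no reactions")
    return _from_reaction_records(records, metabolite_order, objective_id)


def _read_json(path: str) -> MetabolicModel:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise ModelParseError(f"{path!r}: invalid JSON: {e}") from e
    try:
        records = [
            (
                r["id"],
                {m: float(c) for m, c in r["metabolites"].items()},
                float(r["lower_bound"]),
                float(r["upper_bound"]),
                r.get("gpr", ""),
                bool(r.get("is_exchange", False)),
            )
            for r in doc["reactions"]
        ]
        return _from_reaction_records(
            records, doc.get("metabolites", []), doc["objective"]
        )
    except KeyError as e:
        raise ModelParseError(f"{path!r}: missing key {e}") from e


def write_model(model: MetabolicModel, path, dialect: str) -> None:
    """Write ``model`` in the repo-defined ``tabular`` or ``json`` dialect.

    Both dialects round-trip S, bounds and GPR strings exactly.
    """
    path = str(path)
    if dialect == "tabular":
        lines = [
            f"# objective: {model.objective_id}",
            "# metabolites: " + ",".join(model.metabolite_ids),
            "\t".join(TABULAR_COLUMNS),
        ]
        for j, rid in enumerate(model.reaction_ids):
            col = model.S[:, j]
            coeffs = {
                model.metabolite_ids[i]: col[i] for i in np.nonzero(col)[0]
            }
            lines.append(
                "\t".join(
                    [
                        rid,
                        _format_equation(coeffs),
                        f"{model.lower_bounds[j]:.17g}",
                        f"{model.upper_bounds[j]:.17g}",
                        model.gpr[j],
                        "1" if model.exchange_flags[j] else "0",
                    ]
                )
            )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    elif dialect == "json":
        doc = {
            "metabolites": model.metabolite_ids,
            "objective": model.objective_id,
            "reactions": [
                {
                    "id": rid,
                    "metabolites": {
                        model.metabolite_ids[i]: model.S[i, j]
                        for i in np.nonzero(model.S[:, j])[0]
                    },
                    "lower_bound": model.lower_bounds[j],
                    "upper_bound": model.upper_bounds[j],
                    "gpr": model.gpr[j],
                    "is_exchange": bool(model.exchange_flags[j]),
                }
                for j, rid in enumerate(model.reaction_ids)
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
    else:
        raise ConfigurationError(f"unknown model dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Toy presets
# ---------------------------------------------------------------------------

@dataclass
class ToyModelSpec:
    """Parameters selecting and sizing a deterministic toy network."""

    preset_name: str = "branched"
    internal_bound: float = 1000.0

    def __post_init__(self):
        if self.internal_bound <= 0:
            raise ValidationError("internal_bound must be positive")


TOY_PRESETS = ("chain3", "branched")

#: GPR-class census of the "branched" preset, fixed by construction
BRANCHED_GPR_CENSUS = {"single": 4, "or_only": 1, "and_only": 1, "complex": 1}


def make_toy_model(spec: ToyModelSpec | str) -> MetabolicModel:
    """Build a deterministic toy model.

    ``chain3`` — uptake → conversion → objective sink; every reaction
    essential.  ``branched`` — a mandatory trunk feeding two parallel routes
    to the objective precursor (branch B: two steps, branch C: three steps),
    with at least one GPR of each class (single / or_only / and_only /
    complex).  The objective sink is a GPR-less reaction whose upper bound
    (300) is well below the trunk and combined branch capacities, so the
    optimum is set by the model, while *which route* carries the flux is set
    by the per-cell branch bounds — the discriminative signal for flux
    clustering.  Both presets start with the growth medium closed (uptake
    bound 0); apply :func:`apply_rich_medium` to open it.
    """
    if isinstance(spec, str):
        spec = ToyModelSpec(preset_name=spec)
    ub = spec.internal_bound
    if spec.preset_name == "chain3":
        records = [
            ("EX_A", {"a_e": -1.0}, 0.0, ub, "", True),
            ("R_CONV", {"a_e": -1.0, "b": 1.0}, 0.0, ub, "gA", False),
            ("OBJ", {"b": -1.0}, 0.0, ub, "", False),
        ]
        return _from_reaction_records(records, ["a_e", "b"], "OBJ")
    if spec.preset_name == "branched":
        records = [
            # exchange: EX_A is written as a_e <=> (environment); uptake is
            # the negative direction, closed until a medium is applied.
            ("EX_A", {"a_e": -1.0}, 0.0, ub, "", True),
            ("T_A", {"a_e": -1.0, "a": 1.0}, 0.0, ub, "gT1", False),
            ("R_TRK", {"a": -1.0, "m": 1.0}, 0.0, ub, "gT2 and gT3", False),
            # branch B: two steps m -> b -> p
            ("R_B1", {"m": -1.0, "b": 1.0}, 0.0, ub, "g1a or g1b", False),
            ("R_PB", {"b": -1.0, "p": 1.0}, 0.0, ub, "gPB", False),
            # branch C: three steps m -> c -> c2 -> p (longer, so the
            # parsimonious tiebreak prefers branch B at equal capacity)
            ("R_B2", {"m": -1.0, "c": 1.0}, 0.0, ub, "g2a or (g2b and g2c)", False),
            ("R_C2", {"c": -1.0, "c2": 1.0}, 0.0, ub, "g2d", False),
            ("R_PC", {"c2": -1.0, "p": 1.0}, 0.0, ub, "gPC", False),
            # GPR-less sink capped well below trunk/branch capacity: the
            # optimum is a model constant; route choice is the cell feature
            ("BIOMASS", {"p": -1.0}, 0.0, 0.3 * ub, "", False),
        ]
        return _from_reaction_records(
            records, ["a_e", "a", "m", "b", "c", "c2", "p"], "BIOMASS"
        )
    raise ConfigurationError(
        f"unknown toy preset {spec.preset_name!r}; available: {TOY_PRESETS}"
    )


def apply_rich_medium(
    model: MetabolicModel, uptake_magnitude: float = RICH_MEDIUM_UPTAKE
) -> MetabolicModel:
    """Open every exchange reaction's uptake direction to ``uptake_magnitude``.

    Emulates a rich growth medium in which every nutrient with a transporter
    is available in effectively unlimited quantity.  Uptake is the negative
    flux direction, so exchange lower bounds are set to ``-uptake_magnitude``;
    secretion (upper) bounds and all non-exchange bounds are untouched.
    Idempotent.  Returns a new model.
    """
    if uptake_magnitude <= 0:
        raise ValidationError("uptake_magnitude must be positive")
    out = model.copy()
    if not out.exchange_flags.any():
        warnings.warn("model flags no exchange reactions; returned unchanged")
        return out
    out.lower_bounds[out.exchange_flags] = -float(uptake_magnitude)
    out.validate()
    return out
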