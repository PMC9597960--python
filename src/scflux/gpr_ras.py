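"""GPR boolean rules and Reaction Activity Scores (RAS).

A gene-protein-reaction (GPR) rule states which gene products catalyse a
reaction: AND joins subunits of one enzyme, OR joins isoenzymes.  The RAS
evaluates the rule numerically on transcript abundances — the minimum over
AND (a complex is limited by its scarcest subunit) and the sum over OR
(isoenzymes add capacity).  Genes absent from the expression matrix are
*missing* and are dropped from their operator: ``A AND missing`` evaluates to
``A``, and so does ``A OR missing``.  A measured zero is a number, not
missing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GPRParseError, ValidationError
from .model_core import MetabolicModel

logger = logging.getLogger("scflux.gpr_ras")

MISSING = float("nan")

_OPS = ("and", "or")


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    name: str


@dataclass(frozen=True)
class BoolOp:
    op: str  # "and" | "or"
    children: tuple


@dataclass
class GPRRule:
    """Parsed GPR expression tree with its verbatim source string."""

    root: Gene | BoolOp
    source_string: str

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if isinstance(node, Gene):
                out.add(node.name)
            else:
                stack.extend(node.children)
        return frozenset(out)

    @property
    def classification(self) -> str:
        """One of ``single``, ``or_only``, ``and_only``, ``complex``.

        ``complex`` = both operators occur; ``single`` = one gene, no
        operator; otherwise named after the sole operator present.
        """
        ops: set[str] = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if isinstance(node, BoolOp):
                ops.add(node.op)
                stack.extend(node.children)
        if not ops:
            return "single"
        if ops == {"and", "or"}:
            return "complex"
        return "and_only" if ops == {"and"} else "or_only"


def _tokenize(s: str):
    tokens = []  # (kind, text, position)
    i, n = 0, len(s)
    while i < n:
        ch = s[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "()":
            tokens.append((ch, ch, i))
            i += 1
            continue
        j = i
        while j < n and not s[j].isspace() and s[j] not in "()":
            j += 1
        word = s[i:j]
        kind = word.lower() if word.lower() in _OPS else "gene"
        tokens.append((kind, word, i))
        i = j
    return tokens


def parse_gpr(s: str) -> GPRRule:
    """Parse a GPR string into an expression tree.

    Grammar (AND binds tighter than OR, parentheses override)::

        expr   := term ("or" term)*
        term   := factor ("and" factor)*
        factor := "(" expr ")" | GENE
    """
    if not s or not s.strip():
        raise GPRParseError("empty GPR string")
    tokens = _tokenize(s)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else (None, None, len(s))

    def expect_factor():
        nonlocal pos
        kind, text, at = peek()
        if kind == "(":
            pos += 1
            node = expr()
            k2, _, at2 = peek()
            if k2 != ")":
                raise GPRParseError("unbalanced parentheses: missing ')'", at2)
            pos += 1
            return node
        if kind == "gene":
            pos += 1
            return Gene(text)
        raise GPRParseError(f"expected gene or '(', found {text!r}", at)

    def term():
        nonlocal pos
        children = [expect_factor()]
        while peek()[0] == "and":
            pos += 1
            children.append(expect_factor())
        return children[0] if len(children) == 1 else BoolOp("and", tuple(children))

    def expr():
        nonlocal pos
        children = [term()]
        while peek()[0] == "or":
            pos += 1
            children.append(term())
        return children[0] if len(children) == 1 else BoolOp("or", tuple(children))

    root = expr()
    kind, text, at = peek()
    if kind is not None:
        raise GPRParseError(f"unexpected token {text!r}", at)
    return GPRRule(root, s)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def eval_gpr(rule: GPRRule, expr: dict[str, float]) -> float:
    """Evaluate a rule on a gene→value map; absent genes are missing.

    AND → minimum of non-missing children; OR → sum of non-missing children;
    a node whose children are all missing is itself missing (returned as
    NaN).  Never raises on missing genes.
    """
    return _eval_node(rule.root if isinstance(rule, GPRRule) else rule, expr)


def _eval_node(node, expr) -> float:
    if isinstance(node, Gene):
        v = expr.get(node.name, MISSING)
        return MISSING if v is None else float(v)
    vals = [_eval_node(c, expr) for c in node.children]
    vals = [v for v in vals if not math.isnan(v)]
    if not vals:
        return MISSING
    return min(vals) if node.op == "and" else sum(vals)


def _eval_node_vec(node, expr_rows: dict[str, np.ndarray], n: int) -> np.ndarray:
    """Vectorised evaluation over all cells at once (NaN = missing)."""
    if isinstance(node, Gene):
        row = expr_rows.get(node.name)
        return np.full(n, np.nan) if row is None else row
    mats = np.vstack([_eval_node_vec(c, expr_rows, n) for c in node.children])
    all_nan = np.isnan(mats).all(axis=0)
    if node.op == "and":
        with np.errstate(invalid="ignore"):
            out = np.nanmin(mats, axis=0)
    else:
        out = np.nansum(mats, axis=0)
    out = np.asarray(out, dtype=float)
    out[all_nan] = np.nan
    return out


# ---------------------------------------------------------------------------
# RAS matrix
# ---------------------------------------------------------------------------

@dataclass
class RASMatrix:
    """Reactions × cells Reaction Activity Scores.

    Rows cover only reactions carrying a GPR with at least one gene present
    in the expression matrix; ``dropped_reactions`` lists GPR-bearing
    reactions whose genes were all absent, and ``coverage`` is the fraction
    of model genes found in the expression matrix.
    """

    reaction_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray
    dropped_reactions: list[str] = field(default_factory=list)
    coverage: float = float("nan")
    layer_tag: str = "ras"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.reaction_ids), len(self.cell_ids)):
            raise ValidationError(
                f"RAS values shape {self.values.shape} does not match "
                f"{len(self.reaction_ids)} reactions x {len(self.cell_ids)} cells"
            )
        if np.nanmin(self.values, initial=0.0) < 0:
            raise ValidationError("RAS values must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.reaction_ids, columns=self.cell_ids)

    def copy(self) -> "RASMatrix":
        return RASMatrix(
            list(self.reaction_ids),
            list(self.cell_ids),
            self.values.copy(),
            list(self.dropped_reactions),
            self.coverage,
            self.layer_tag,
        )


def compute_ras(
    model: MetabolicModel,
    x,
    gene_map: dict[str, str] | None = None,
) -> RASMatrix:
    """Compute the RAS matrix from a (normalised or denoised) expression matrix.

    ``gene_map`` optionally translates expression-matrix gene identifiers into
    the model's gene namespace (e.g. Ensembl → symbol); matching is otherwise
    exact-string.  Reactions whose GPR genes are all absent from ``x`` are
    dropped and reported in ``dropped_reactions``.
    """
    gene_ids = x.gene_ids
    if gene_map:
        gene_ids = [gene_map.get(g, g) for g in gene_ids]
    n_cells = len(x.cell_ids)
    values = np.asarray(x.values, dtype=float)
    # collapse duplicates arising from the mapping by summing
    rows: dict[str, np.ndarray] = {}
    for i, g in enumerate(gene_ids):
        if g in rows:
            rows[g] = rows[g] + values[i]
        else:
            rows[g] = values[i]

    gpr_reactions = [(j, rid) for j, rid in enumerate(model.reaction_ids) if model.gpr[j]]
    if not gpr_reactions:
        raise ValidationError("model has no GPR-bearing reactions")

    model_genes = model.genes()
    present = model_genes & set(rows)
    coverage = len(present) / len(model_genes) if model_genes else float("nan")

    kept_ids, kept_rows, dropped = [], [], []
    for j, rid in gpr_reactions:
        rule = parse_gpr(model.gpr[j])
        if rule.genes & set(rows):
            kept_ids.append(rid)
            kept_rows.append(_eval_node_vec(rule.root, rows, n_cells))
        else:
            dropped.append(rid)
    if not kept_ids:
        raise ValidationError("no GPR-bearing reaction has any gene in the expression matrix")
    mat = np.vstack(kept_rows)
    if np.isnan(mat).any():  # cannot happen: each kept rule has >=1 present gene
        raise ValidationError("internal error: NaN in RAS matrix")
    logger.info(
        "RAS: %d/%d GPR reactions kept, gene coverage %.2f%%",
        len(kept_ids), len(gpr_reactions), 100 * coverage,
    )
    return RASMatrix(kept_ids, list(x.cell_ids), mat, dropped, coverage)


def classify_gprs(model: MetabolicModel) -> dict[str, str]:
    """Map each GPR-bearing reaction id to its rule class."""
    return {
        rid: parse_gpr(model.gpr[j]).classification
        for j, rid in enumerate(model.reaction_ids)
        if model.gpr[j]
    }


def gpr_census(model: MetabolicModel) -> dict[str, int]:
    """Count GPR-bearing reactions per rule class."""
    census = {"single": 0, "or_only": 0, "and_only": 0, "complex": 0}
    for cls in classify_gprs(model).values():
        census[cls] += 1
    return census


# ---------------------------------------------------------------------------
# Sparsity diagnostics
# ---------------------------------------------------------------------------

@dataclass
class SparsityReport:
    """Zero-fraction summary of a matrix, optionally restricted to a row subset."""

    overall_zero_fraction: float
    per_cell_zero_fraction: pd.Series
    essential_zero_fraction: float | None = None
    essential_per_cell_zero_fraction: pd.Series | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"zero_fraction": self.per_cell_zero_fraction})
        if self.essential_per_cell_zero_fraction is not None:
            df["essential_zero_fraction"] = self.essential_per_cell_zero_fraction
        return df


def sparsity_report(
    m, essential_set=None, zero_tol: float = 1e-9
) -> SparsityReport:
    """Fraction of (near-)zero entries, overall and per cell.

    ``m`` is any object with ``values`` (features × cells), feature ids in
    ``reaction_ids`` or ``gene_ids``, and ``cell_ids``.  ``essential_set``
    restricts an additional pair of summaries to those feature rows.
    """
    vals = np.asarray(m.values, dtype=float)
    feature_ids = getattr(m, "reaction_ids", None) or getattr(m, "gene_ids")
    zero = np.abs(vals) <= zero_tol
    per_cell = pd.Series(zero.mean(axis=0), index=list(m.cell_ids))
    report = SparsityReport(float(zero.mean()), per_cell)
    if essential_set is not None:
        essential_set = set(essential_set)
        missing = essential_set - set(feature_ids)
        if missing:
            raise ValidationError(
                f"essential ids not present in matrix: {sorted(missing)}"
            )
        mask = np.array([f in essential_set for f in feature_ids])
        sub = zero[mask]
        report.essential_zero_fraction = float(sub.mean())
        report.essential_per_cell_zero_fraction = pd.Series(
            sub.mean(axis=0), index=list(m.cell_ids)
        )
    return report
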