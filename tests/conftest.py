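"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the code paths they check: linear
programs are formulated directly for scipy's HiGHS solver (never through
cobra), GPR evaluation is a plain recursive interpreter over a freshly
parsed token stream, and rank correlation is computed from explicit ranks.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.optimize import linprog

import scflux as sf


# ---------------------------------------------------------------------------
# Independent LP oracle (scipy HiGHS)
# ---------------------------------------------------------------------------

def lp_optimize(model, objective_id, sense="max", lower=None, upper=None):
    """Optimum of one flux under steady state, formulated from scratch.

    Equality constraints S·v = 0, box bounds; HiGHS solver.  Returns the
    optimal objective value, or None when infeasible.
    """
    R = model.n_reactions
    c = np.zeros(R)
    c[model.reaction_ids.index(objective_id)] = -1.0 if sense == "max" else 1.0
    lo = model.lower_bounds if lower is None else np.asarray(lower, dtype=float)
    hi = model.upper_bounds if upper is None else np.asarray(upper, dtype=float)
    res = linprog(
        c,
        A_eq=model.S,
        b_eq=np.zeros(model.n_metabolites),
        bounds=list(zip(lo, hi)),
        method="highs",
    )
    if not res.success:
        return None
    return -res.fun if sense == "max" else res.fun


def fva_oracle(model):
    """Per-reaction [min, max] envelopes via the scipy formulation."""
    out = {}
    for rid in model.reaction_ids:
        lo = lp_optimize(model, rid, "min")
        hi = lp_optimize(model, rid, "max")
        out[rid] = (lo, hi)
    return out


def essential_oracle(model, objective_id):
    """Brute-force all-knockout essentiality scan via the scipy LP."""
    essential = set()
    for j, rid in enumerate(model.reaction_ids):
        lo = model.lower_bounds.copy()
        hi = model.upper_bounds.copy()
        lo[j] = hi[j] = 0.0
        opt = lp_optimize(model, objective_id, "max", lo, hi)
        if opt is None or opt <= 1e-9:
            essential.add(rid)
    return essential


# ---------------------------------------------------------------------------
# Independent GPR oracle
# ---------------------------------------------------------------------------

def gpr_oracle_eval(tokens, expr):
    """Recursive-descent evaluator written independently of the package.

    ``tokens`` is a list like ['(', 'A', 'or', 'B', ')', 'and', 'C'].
    Missing genes evaluate to None; AND = min of non-None, OR = sum of
    non-None, all-None propagates None.
    """
    pos = [0]

    def peek():
        return tokens[pos[0]] if pos[0] < len(tokens) else None

    def factor():
        tok = peek()
        if tok == "(":
            pos[0] += 1
            v = or_level()
            assert peek() == ")"
            pos[0] += 1
            return v
        pos[0] += 1
        return expr.get(tok)

    def and_level():
        vals = [factor()]
        while peek() is not None and peek().lower() == "and":
            pos[0] += 1
            vals.append(factor())
        vals = [v for v in vals if v is not None]
        return min(vals) if vals else None

    def or_level():
        vals = [and_level()]
        while peek() is not None and peek().lower() == "or":
            pos[0] += 1
            vals.append(and_level())
        vals = [v for v in vals if v is not None]
        return sum(vals) if vals else None

    return or_level()


def random_gpr(rng, genes, max_depth=3):
    """Random well-formed GPR token list over the given gene names."""
    def node(depth):
        if depth >= max_depth or rng.random() < 0.35:
            return [rng.choice(genes)]
        op = rng.choice(["and", "or"])
        n = rng.integers(2, 4)
        parts = []
        for i in range(n):
            child = node(depth + 1)
            if len(child) > 1:
                child = ["("] + child + [")"]
            if i:
                parts.append(op)
            parts.extend(child)
        return parts

    return node(0)


def spearman_oracle(a, b):
    """Rank correlation from explicit average ranks (Pearson on ranks)."""
    def ranks(x):
        x = np.asarray(x, dtype=float)
        order = np.argsort(x, kind="mergesort")
        r = np.empty(len(x))
        i = 0
        while i < len(x):
            j = i
            while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r

    ra, rb = ranks(a), ranks(b)
    ra -= ra.mean()
    rb -= rb.mean()
    denom = math.sqrt((ra**2).sum() * (rb**2).sum())
    return float((ra * rb).sum() / denom)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def chain3():
    return sf.make_toy_model("chain3")


@pytest.fixture(scope="session")
def branched():
    return sf.make_toy_model("branched")


@pytest.fixture(scope="session")
def branched_fed():
    return sf.apply_rich_medium(sf.make_toy_model("branched"), 1000.0)


@pytest.fixture(scope="session")
def chain3_fed():
    return sf.apply_rich_medium(sf.make_toy_model("chain3"), 10.0)


@pytest.fixture(scope="session")
def bundle0():
    """Seeded end-to-end fixture shared across tests (seed 0)."""
    return sf.end_to_end_fixture("branched", seed=0)


@pytest.fixture(scope="session")
def small_bundle():
    """A fast, small fixture for pipeline smoke tests."""
    model = sf.make_toy_model("branched")
    spec = sf.default_sim_spec(
        model, n_cells_per_population=30, n_decoy_genes=60, n_marker_decoys=20, seed=7
    )
    return sf.end_to_end_fixture("branched", spec=spec, seed=7)
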