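import numpy as np
import pytest

import scflux as sf
from scflux.errors import EmptyResultError, InfeasibleModelError, ValidationError

from conftest import essential_oracle, lp_optimize


def uniform_bounds(model, scale=1.0):
    """CellBoundsSet with every reaction at (scale × model bounds) for one cell."""
    return sf.CellBoundsSet(
        list(model.reaction_ids),
        ["c1"],
        model.lower_bounds[None, :] * scale,
        model.upper_bounds[None, :] * scale,
    )


class TestFindEssential:
    def test_chain_is_entirely_essential(self, chain3_fed):
        ess = sf.find_essential(chain3_fed, "OBJ")
        assert ess.reactions == frozenset(chain3_fed.reaction_ids)

    def test_branched_trunk_only(self, branched_fed):
        ess = sf.find_essential(branched_fed, "BIOMASS")
        assert ess.reactions == frozenset({"EX_A", "T_A", "R_TRK", "BIOMASS"})

    @pytest.mark.parametrize("preset", ["chain3", "branched"])
    def test_matches_brute_force_knockout_oracle(self, preset):
        m = sf.apply_rich_medium(sf.make_toy_model(preset), 1000.0)
        ess = sf.find_essential(m)
        assert ess.reactions == frozenset(essential_oracle(m, m.objective_id))

    def test_objective_reaction_always_essential(self, branched_fed):
        ess = sf.find_essential(branched_fed, "BIOMASS")
        assert "BIOMASS" in ess

    def test_zero_baseline_is_error(self, branched):
        # medium closed: no uptake, optimum 0, essentiality undefined
        with pytest.raises(InfeasibleModelError, match="essentiality"):
            sf.find_essential(branched, "BIOMASS")


class TestSolveCellFBA:
    def test_chain_optimum_is_uptake_cap(self, chain3_fed):
        bounds = uniform_bounds(chain3_fed)
        fluxes, opt, status = sf.solve_cell_fba(chain3_fed, bounds, "c1", "OBJ")
        assert status == "optimal"
        assert opt == pytest.approx(10.0)

    def test_closed_essential_reaction_zeroes_objective(self, branched_fed):
        bounds = uniform_bounds(branched_fed)
        j = bounds.reaction_ids.index("R_TRK")
        bounds.lower[0, j] = bounds.upper[0, j] = 0.0
        _, opt, status = sf.solve_cell_fba(branched_fed, bounds, "c1", "BIOMASS")
        assert opt == pytest.approx(0.0, abs=1e-9)

    def test_optimum_matches_independent_lp(self, branched_fed):
        bounds = uniform_bounds(branched_fed)
        # throttle one branch to exercise a nontrivial vertex
        j = bounds.reaction_ids.index("R_B1")
        bounds.upper[0, j] = 120.0
        _, opt, _ = sf.solve_cell_fba(branched_fed, bounds, "c1", "BIOMASS")
        want = lp_optimize(
            branched_fed, "BIOMASS", "max", bounds.lower[0], bounds.upper[0]
        )
        assert opt == pytest.approx(want, abs=1e-6)

    def test_parsimonious_tiebreak_prefers_short_route(self, branched_fed):
        # both routes open and ample: minimal-total-flux vertex uses only the
        # two-step branch B
        fluxes, opt, status = sf.solve_cell_fba(
            branched_fed, uniform_bounds(branched_fed), "c1", "BIOMASS"
        )
        fx = dict(zip(branched_fed.reaction_ids, fluxes))
        assert opt == pytest.approx(300.0)
        assert fx["R_B1"] == pytest.approx(300.0, abs=1e-6)
        assert fx["R_B2"] == pytest.approx(0.0, abs=1e-6)

    def test_infeasible_cell_flagged_not_raised(self, branched_fed):
        bounds = uniform_bounds(branched_fed)
        j = bounds.reaction_ids.index("BIOMASS")
        bounds.lower[0, j] = bounds.upper[0, j] = 400.0  # force flux with no uptake
        bounds.upper[0, bounds.reaction_ids.index("EX_A")] = 0.0
        bounds.lower[0, bounds.reaction_ids.index("EX_A")] = 0.0
        fluxes, opt, status = sf.solve_cell_fba(branched_fed, bounds, "c1", "BIOMASS")
        assert status == "infeasible"
        assert fluxes is None and np.isnan(opt)

    def test_invariant_to_reaction_reordering(self, branched_fed):
        perm = np.random.default_rng(0).permutation(branched_fed.n_reactions)
        reordered = sf.MetabolicModel(
            branched_fed.metabolite_ids,
            [branched_fed.reaction_ids[j] for j in perm],
            branched_fed.S[:, perm],
            branched_fed.lower_bounds[perm],
            branched_fed.upper_bounds[perm],
            [branched_fed.gpr[j] for j in perm],
            branched_fed.exchange_flags[perm],
            branched_fed.objective_id,
        )
        f1, o1, _ = sf.solve_cell_fba(
            branched_fed, uniform_bounds(branched_fed), "c1", "BIOMASS"
        )
        f2, o2, _ = sf.solve_cell_fba(
            reordered, uniform_bounds(reordered), "c1", "BIOMASS"
        )
        assert o1 == pytest.approx(o2)
        by_id1 = dict(zip(branched_fed.reaction_ids, f1))
        by_id2 = dict(zip(reordered.reaction_ids, f2))
        for rid in branched_fed.reaction_ids:
            assert by_id1[rid] == pytest.approx(by_id2[rid], abs=1e-6)


@pytest.fixture(scope="module")
def two_cell_bounds(branched_fed):
    lower = np.vstack([branched_fed.lower_bounds] * 2)
    upper = np.vstack([branched_fed.upper_bounds] * 2)
    upper[1, branched_fed.reaction_index("R_B1")] = 100.0  # reroute cell 2
    return sf.CellBoundsSet(
        list(branched_fed.reaction_ids), ["c1", "c2"], lower, upper
    )


@pytest.fixture(scope="module")
def qc_parts(branched_fed):
    essential = sf.find_essential(branched_fed, "BIOMASS")
    gpr_rids = [r for j, r in enumerate(branched_fed.reaction_ids) if branched_fed.gpr[j]]
    values = np.ones((len(gpr_rids), 3))
    values[gpr_rids.index("T_A"), 1] = 0.0  # essential zero for cell c2
    values[gpr_rids.index("R_B1"), 2] = 0.0  # non-essential zero for c3
    ras = sf.RASMatrix(gpr_rids, ["c1", "c2", "c3"], values)
    fva = sf.run_fva(branched_fed)
    bounds = sf.ras_bounds(fva, ras, branched_fed)
    fm = sf.build_flux_matrix(branched_fed, bounds, "BIOMASS")
    return essential, ras, fm


class TestBuildFluxMatrix:
    def test_columns_and_statuses(self, branched_fed, two_cell_bounds):
        fm = sf.build_flux_matrix(branched_fed, two_cell_bounds, "BIOMASS")
        assert fm.values.shape == (branched_fed.n_reactions, 2)
        assert fm.statuses == ["optimal", "optimal"]
        assert fm.objective_values[0] == pytest.approx(300.0)

    def test_steady_state_residual_small(self, branched_fed, two_cell_bounds):
        fm = sf.build_flux_matrix(branched_fed, two_cell_bounds, "BIOMASS")
        residual = branched_fed.S @ fm.values
        assert np.abs(residual).max() < 1e-6

    def test_all_max_ras_recovers_unconstrained_optimum(self, branched_fed):
        fva = sf.run_fva(branched_fed)
        gpr_rids = [r for j, r in enumerate(branched_fed.reaction_ids) if branched_fed.gpr[j]]
        ras = sf.RASMatrix(gpr_rids, ["c1", "c2"], np.ones((len(gpr_rids), 2)))
        bounds = sf.ras_bounds(fva, ras, branched_fed)
        fm = sf.build_flux_matrix(branched_fed, bounds, "BIOMASS")
        unconstrained = lp_optimize(branched_fed, "BIOMASS", "max")
        assert np.allclose(fm.objective_values, unconstrained, atol=1e-6)


class TestFluxQC:
    def test_cell_with_zero_essential_ras_removed_and_logged(self, qc_parts):
        essential, ras, fm = qc_parts
        qc = sf.flux_qc(fm, ras, essential)
        assert qc.flux_matrix.cell_ids == ["c1", "c3"]
        assert qc.removed["cell_id"].tolist() == ["c2"]
        assert "T_A" in qc.removed["zero_essential_reactions"].iloc[0]

    def test_nonessential_zero_does_not_remove(self, qc_parts):
        essential, ras, fm = qc_parts
        qc = sf.flux_qc(fm, ras, essential)
        assert "c3" in qc.flux_matrix.cell_ids

    def test_all_cells_removed_is_error(self, branched_fed):
        essential = sf.find_essential(branched_fed, "BIOMASS")
        gpr_rids = [r for j, r in enumerate(branched_fed.reaction_ids) if branched_fed.gpr[j]]
        values = np.ones((len(gpr_rids), 2))
        values[gpr_rids.index("T_A")] = 0.0
        ras = sf.RASMatrix(gpr_rids, ["c1", "c2"], values)
        fva = sf.run_fva(branched_fed)
        bounds = sf.ras_bounds(fva, ras, branched_fed)
        fm = sf.build_flux_matrix(branched_fed, bounds, "BIOMASS")
        with pytest.raises(EmptyResultError, match="denoising"):
            sf.flux_qc(fm, ras, essential)

    def test_objective_mismatch_is_error(self, qc_parts, branched_fed):
        essential, ras, fm = qc_parts
        other = sf.EssentialSet("T_A", frozenset({"T_A"}))
        with pytest.raises(ValidationError, match="essential set"):
            sf.flux_qc(fm, ras, other)
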