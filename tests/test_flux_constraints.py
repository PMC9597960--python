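import numpy as np
import pytest

import scflux as sf
from scflux.errors import InfeasibleModelError, ValidationError
from scflux.flux_constraints import _ras_ratio

from conftest import fva_oracle


def simple_ras(reaction_ids, cell_ids, values):
    return sf.RASMatrix(reaction_ids, cell_ids, np.asarray(values, dtype=float))


@pytest.fixture(scope="module")
def fva(branched_fed):
    return sf.run_fva(branched_fed)


class TestRunFVA:
    def test_chain_envelopes_forced_by_mass_balance(self, chain3_fed):
        fva = sf.run_fva(chain3_fed)
        assert fva.envelope("R_CONV") == pytest.approx((0.0, 10.0))
        assert fva.envelope("OBJ") == pytest.approx((0.0, 10.0))
        assert fva.envelope("EX_A") == pytest.approx((-10.0, 0.0))

    def test_fixed_zero_reaction_has_zero_envelope(self, chain3):
        m = sf.apply_rich_medium(chain3, 10.0)
        j = m.reaction_index("OBJ")
        m.lower_bounds[j] = m.upper_bounds[j] = 0.0
        fva = sf.run_fva(m)
        assert fva.envelope("OBJ") == (0.0, 0.0)

    def test_matches_independent_lp_oracle_on_branched(self, branched_fed):
        fva = sf.run_fva(branched_fed)
        oracle = fva_oracle(branched_fed)
        for rid in branched_fed.reaction_ids:
            lo, hi = oracle[rid]
            assert fva.envelope(rid) == pytest.approx((lo, hi), abs=1e-6)

    def test_infeasible_base_lp_is_diagnosed(self, chain3):
        m = chain3.copy()
        j = m.reaction_index("OBJ")
        m.lower_bounds[j] = 5.0  # demands flux while the medium is closed
        with pytest.raises(InfeasibleModelError, match="infeasible"):
            sf.run_fva(m)

    def test_reaction_subset(self, branched_fed):
        fva = sf.run_fva(branched_fed, reactions=["R_B1", "BIOMASS"])
        assert fva.reaction_ids == ["R_B1", "BIOMASS"]


class TestPlainBounds:
    def test_max_attaining_cell_recovers_envelope(self, branched_fed, fva):
        ras = simple_ras(["R_B1"], ["c1", "c2"], [[4.0, 2.0]])
        bounds = sf.ras_bounds(fva, ras, branched_fed)
        j = bounds.reaction_ids.index("R_B1")
        assert bounds.upper[0, j] == pytest.approx(fva.envelope("R_B1")[1])
        assert bounds.lower[0, j] == pytest.approx(fva.envelope("R_B1")[0])
        assert bounds.upper[1, j] == pytest.approx(fva.envelope("R_B1")[1] / 2)

    def test_zero_ras_closes_reaction(self, branched_fed, fva):
        ras = simple_ras(["R_B1"], ["c1", "c2"], [[0.0, 3.0]])
        bounds = sf.ras_bounds(fva, ras, branched_fed)
        j = bounds.reaction_ids.index("R_B1")
        assert bounds.lower[0, j] == bounds.upper[0, j] == 0.0

    def test_all_zero_row_closes_reaction_everywhere(self, branched_fed, fva):
        ras = simple_ras(["R_B1"], ["c1", "c2"], [[0.0, 0.0]])
        bounds = sf.ras_bounds(fva, ras, branched_fed)
        j = bounds.reaction_ids.index("R_B1")
        assert np.all(bounds.upper[:, j] == 0.0)
        assert np.all(bounds.lower[:, j] == 0.0)

    def test_gprless_reactions_keep_envelope(self, branched_fed, fva):
        ras = simple_ras(["R_B1"], ["c1"], [[1.0]])
        bounds = sf.ras_bounds(fva, ras, branched_fed)
        j = bounds.reaction_ids.index("BIOMASS")
        assert (bounds.lower[0, j], bounds.upper[0, j]) == fva.envelope("BIOMASS")

    def test_exchange_keeps_medium_bounds(self, branched_fed, fva):
        ras = simple_ras(["R_B1"], ["c1"], [[1.0]])
        bounds = sf.ras_bounds(fva, ras, branched_fed)
        j = bounds.reaction_ids.index("EX_A")
        assert bounds.lower[0, j] == branched_fed.lower_bounds[j]
        assert bounds.upper[0, j] == branched_fed.upper_bounds[j]

    def test_negative_ras_rejected_at_construction(self):
        with pytest.raises(ValidationError, match="nonnegative"):
            simple_ras(["r"], ["c"], [[-1.0]])

    def test_scaling_a_ras_row_leaves_bounds_unchanged(self, branched_fed, fva):
        ras1 = simple_ras(["R_B1"], ["c1", "c2", "c3"], [[1.0, 2.0, 4.0]])
        ras2 = simple_ras(["R_B1"], ["c1", "c2", "c3"], [[10.0, 20.0, 40.0]])
        b1 = sf.ras_bounds(fva, ras1, branched_fed)
        b2 = sf.ras_bounds(fva, ras2, branched_fed)
        assert np.allclose(b1.upper, b2.upper)
        assert np.allclose(b1.lower, b2.lower)

    def test_within_reaction_monotone_in_ras(self, branched_fed, fva):
        ras = simple_ras(["R_B1"], ["c1", "c2", "c3"], [[1.0, 2.0, 3.0]])
        bounds = sf.ras_bounds(fva, ras, branched_fed)
        j = bounds.reaction_ids.index("R_B1")
        assert np.all(np.diff(bounds.upper[:, j]) >= 0)


class TestEpsilonBounds:
    def test_zero_ratio_leaves_epsilon_capacity(self, branched_fed, fva):
        ras = simple_ras(["R_B1"], ["c1", "c2"], [[0.0, 5.0]])
        bounds = sf.epsilon_bounds(fva, ras, branched_fed, epsilon=0.01)
        j = bounds.reaction_ids.index("R_B1")
        assert bounds.upper[0, j] == pytest.approx(0.01)
        assert bounds.lower[0, j] == pytest.approx(-0.01)

    def test_unit_ratio_telescopes_to_envelope(self, branched_fed, fva):
        ras = simple_ras(["R_B1"], ["c1", "c2"], [[5.0, 1.0]])
        bounds = sf.epsilon_bounds(fva, ras, branched_fed, epsilon=0.01)
        j = bounds.reaction_ids.index("R_B1")
        fl, fu = fva.envelope("R_B1")
        assert bounds.upper[0, j] == pytest.approx(fu)
        assert bounds.lower[0, j] == pytest.approx(fl)

    def test_epsilon_limit_recovers_plain_bounds(self, branched_fed, fva):
        ras = simple_ras(
            ["R_B1", "R_TRK"], ["c1", "c2", "c3"], [[0.0, 2.0, 4.0], [1.0, 1.0, 2.0]]
        )
        plain = sf.ras_bounds(fva, ras, branched_fed)
        for eps in (1e-8, 1e-10):
            near = sf.epsilon_bounds(fva, ras, branched_fed, epsilon=eps)
            assert np.allclose(near.upper, plain.upper, atol=10 * eps)
            assert np.allclose(near.lower, plain.lower, atol=10 * eps)

    def test_epsilon_exceeding_envelope_warns_and_clamps(self, branched_fed, fva):
        m = branched_fed.copy()
        j = m.reaction_index("R_B1")
        m.upper_bounds[j] = 0.005  # envelope shrinks below epsilon
        fva_small = sf.run_fva(m)
        ras = simple_ras(["R_B1"], ["c1", "c2"], [[1.0, 2.0]])
        with pytest.warns(UserWarning, match="epsilon"):
            bounds = sf.epsilon_bounds(fva_small, ras, m, epsilon=0.01)
        assert np.all(bounds.lower <= bounds.upper)

    def test_irreversible_subsaturated_lower_bound_flagged(self, branched_fed, fva):
        # Fl = 0 makes L = -eps + eps*ratio slightly negative below max RAS
        ras = simple_ras(["R_B1"], ["c1", "c2"], [[1.0, 2.0]])
        bounds = sf.epsilon_bounds(fva, ras, branched_fed, epsilon=0.01)
        j = bounds.reaction_ids.index("R_B1")
        assert bounds.lower[0, j] == pytest.approx(-0.01 + 0.01 * 0.5)
        assert "R_B1" in (bounds.negative_lower_flags or [])

    def test_nonpositive_epsilon_rejected(self, branched_fed, fva):
        ras = simple_ras(["R_B1"], ["c1"], [[1.0]])
        with pytest.raises(ValidationError):
            sf.epsilon_bounds(fva, ras, branched_fed, epsilon=0.0)


class TestDispatchAndFeasibility:
    def test_make_bounds_dispatch(self, branched_fed):
        fva = sf.run_fva(branched_fed)
        ras = simple_ras(["R_B1"], ["c1"], [[1.0]])
        assert sf.make_bounds(fva, ras, branched_fed, "plain").strategy == "plain"
        eps = sf.make_bounds(fva, ras, branched_fed, "epsilon", 0.01)
        assert eps.strategy == "epsilon" and eps.epsilon == 0.01
        with pytest.raises(ValidationError):
            sf.make_bounds(fva, ras, branched_fed, "fuzzy")

    def test_plain_bounds_subset_of_fva_feasible_set(self, branched_fed):
        fva = sf.run_fva(branched_fed)
        idx = {r: j for j, r in enumerate(fva.reaction_ids)}
        ras = simple_ras(["R_B1", "R_TRK"], ["c1", "c2"], [[1.0, 3.0], [2.0, 1.0]])
        bounds = sf.ras_bounds(fva, ras, branched_fed)
        for c in range(2):
            for j, rid in enumerate(bounds.reaction_ids):
                if branched_fed.exchange_flags[branched_fed.reaction_index(rid)]:
                    continue
                k = idx[rid]
                assert bounds.lower[c, j] >= fva.minimum[k] - 1e-9
                assert bounds.upper[c, j] <= fva.maximum[k] + 1e-9

    def test_missing_fva_coverage_is_error(self, branched_fed):
        fva = sf.run_fva(branched_fed, reactions=["BIOMASS"])
        ras = simple_ras(["R_B1"], ["c1"], [[1.0]])
        with pytest.raises(ValidationError, match="cover"):
            sf.ras_bounds(fva, ras, branched_fed)

    def test_ratio_helper_zero_max_rows(self):
        ras = simple_ras(["r1", "r2"], ["c1", "c2"], [[0.0, 0.0], [1.0, 3.0]])
        ratio = _ras_ratio(ras)
        assert np.all(ratio[0] == 0.0)
        assert ratio[1, 1] == 1.0
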