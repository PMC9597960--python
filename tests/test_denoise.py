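import numpy as np
import pytest

import scflux as sf
from scflux.denoise import DENOISE_STAGES
from scflux.errors import (
    ConfigurationError,
    DenoiserUnavailableError,
    ValidationError,
)
from scflux.sc_preprocess import ExpressionMatrix


def make_matrix(values, layer="normalized"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        [f"g{i}" for i in range(values.shape[0])],
        [f"c{i}" for i in range(values.shape[1])],
        values,
        layer,
    )


class TestDiffusion:
    def test_two_near_identical_cells_converge_to_pair_mean(self):
        # one cell has a zeroed entry; with knn=1 and long diffusion both
        # cells converge to the average profile (2x2 Markov chain limit)
        values = np.array([[5.0, 5.0], [4.0, 0.0], [2.0, 2.0]])
        x = make_matrix(values)
        cfg = sf.DiffusionConfig(n_pcs=1, knn=1, t=64, seed=0)
        out = sf.diffusion_denoise(x, cfg)
        expected = values.mean(axis=1)
        assert np.allclose(out.values[:, 0], expected, atol=1e-8)
        assert np.allclose(out.values[:, 1], expected, atol=1e-8)

    def test_t_zero_is_identity(self, bundle0):
        x = sf.normalize_total(sf.qc_filter(bundle0.counts, 50, 3))
        out = sf.diffusion_denoise(x, sf.DiffusionConfig(t=0))
        assert np.array_equal(out.values, x.values)
        assert out.layer_tag == "denoised"

    def test_zero_fraction_strictly_decreases_on_dropout_fixture(self, bundle0):
        x = sf.normalize_total(sf.qc_filter(bundle0.counts, 50, 3))
        out = sf.diffusion_denoise(x, sf.DiffusionConfig(seed=0))
        assert (out.values == 0).mean() < (x.values == 0).mean()

    def test_output_nonnegative_and_in_convex_hull(self, bundle0):
        x = sf.normalize_total(sf.qc_filter(bundle0.counts, 50, 3))
        out = sf.diffusion_denoise(x, sf.DiffusionConfig(seed=0))
        assert out.values.min() >= 0
        # rows of P^t are stochastic: per-feature output within input range
        assert np.all(out.values.max(axis=1) <= x.values.max(axis=1) + 1e-9)
        assert np.all(out.values.min(axis=1) >= x.values.min(axis=1) - 1e-9)

    def test_cells_unchanged_in_number_and_order(self, bundle0):
        x = sf.normalize_total(sf.qc_filter(bundle0.counts, 50, 3))
        out = sf.diffusion_denoise(x, sf.DiffusionConfig(seed=0))
        assert out.cell_ids == x.cell_ids
        assert out.gene_ids == x.gene_ids

    def test_too_few_cells_raises(self):
        x = make_matrix(np.ones((4, 3)) + np.arange(3))
        with pytest.raises(ValidationError, match="knn"):
            sf.diffusion_denoise(x, sf.DiffusionConfig(knn=5))

    def test_constant_matrix_warns_and_passes_through(self):
        x = make_matrix(np.full((4, 20), 2.0))
        with pytest.warns(UserWarning, match="constant"):
            out = sf.diffusion_denoise(x, sf.DiffusionConfig(knn=3))
        assert np.array_equal(out.values, x.values)

    def test_negative_input_rejected(self):
        x = make_matrix(np.ones((3, 20)), layer="denoised")
        x.values[0, 0] = -1.0
        with pytest.raises(ValidationError, match="nonnegative"):
            sf.diffusion_denoise(x, sf.DiffusionConfig(knn=3))

    def test_applies_to_ras_matrix(self, bundle0):
        x = sf.normalize_total(sf.qc_filter(bundle0.counts, 50, 3))
        ras = sf.compute_ras(bundle0.model, x)
        out = sf.diffusion_denoise(ras, sf.DiffusionConfig(seed=0))
        assert isinstance(out, sf.RASMatrix)
        assert out.values.shape == ras.values.shape
        assert (out.values == 0).mean() <= (ras.values == 0).mean()

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            sf.DiffusionConfig(knn=0)
        with pytest.raises(ValidationError):
            sf.DiffusionConfig(t=-1)
        with pytest.raises(ValidationError):
            sf.DiffusionConfig(decay=0)
        with pytest.raises(ValidationError):
            sf.DiffusionConfig(distance_scale="sqrt")


class TestCorrelationRestoration:
    def test_planted_program_correlation_recovers(self, bundle0):
        from scflux.clustering import correlation_diagnostics

        def pair_rho(x):
            a = x.values[x.gene_ids.index("PRGA")]
            b = x.values[x.gene_ids.index("PRGB")]
            return correlation_diagnostics(a, b)[0]

        truth = sf.normalize_total(bundle0.truth)
        observed = sf.normalize_total(sf.qc_filter(bundle0.counts, 50, 3))
        denoised = sf.diffusion_denoise(observed, sf.DiffusionConfig(seed=0))
        rho_pre, rho_drop, rho_den = map(pair_rho, (truth, observed, denoised))
        assert rho_drop < rho_pre - 0.2  # dropout visibly breaks the program
        assert rho_den > rho_drop  # denoising moves it back toward truth


class TestExternalAdapters:
    def test_unknown_tool_is_configuration_error(self, bundle0):
        with pytest.raises(ConfigurationError, match="unknown denoiser"):
            sf.external_denoiser_adapter(bundle0.counts, "svd")

    @pytest.mark.parametrize("tool", ["magic", "enhance", "saver"])
    def test_absent_tool_raises_with_install_hint(self, bundle0, tool):
        try:
            __import__(tool)
            pytest.skip(f"{tool} happens to be importable here")
        except ImportError:
            pass
        with pytest.raises(DenoiserUnavailableError, match="install|pip|PYTHONPATH"):
            sf.external_denoiser_adapter(bundle0.counts, tool)

    def test_injected_runner_round_trips_shapes(self, bundle0):
        out = sf.external_denoiser_adapter(
            bundle0.counts, "magic", _runner=lambda m: m * 2.0
        )
        assert out.values.shape == bundle0.counts.values.shape
        assert out.layer_tag == "denoised"
        assert np.allclose(out.values, bundle0.counts.values * 2.0)

    def test_shape_changing_runner_is_adapter_error(self, bundle0):
        with pytest.raises(ValidationError, match="shape"):
            sf.external_denoiser_adapter(
                bundle0.counts, "magic", _runner=lambda m: m[:, :3]
            )


class TestApplyDenoising:
    @pytest.fixture()
    def normed(self, bundle0):
        return sf.normalize_total(sf.qc_filter(bundle0.counts, 50, 3))

    def test_stage_none_matches_direct_computation(self, bundle0, normed):
        ras, meta = sf.apply_denoising("none", bundle0.model, normed)
        direct = sf.compute_ras(bundle0.model, normed)
        assert np.array_equal(ras.values, direct.values)
        assert meta["denoise_stage"] == "none"
        assert meta["denoise_method"] is None

    def test_on_counts_reduces_essential_ras_zero_fraction(self, bundle0, normed):
        essential = sf.find_essential(
            sf.apply_rich_medium(bundle0.model), "BIOMASS"
        )
        ras_none, _ = sf.apply_denoising("none", bundle0.model, normed)
        ras_den, _ = sf.apply_denoising(
            "on_counts", bundle0.model, normed, sf.DiffusionConfig(seed=0)
        )
        ess = set(essential.reactions) & set(ras_none.reaction_ids)
        zf_none = sf.sparsity_report(ras_none, essential_set=ess).essential_zero_fraction
        zf_den = sf.sparsity_report(ras_den, essential_set=ess).essential_zero_fraction
        assert zf_den < zf_none

    def test_both_stages_produce_identical_shapes(self, bundle0, normed):
        cfg = sf.DiffusionConfig(seed=0)
        ras_counts, _ = sf.apply_denoising("on_counts", bundle0.model, normed, cfg)
        ras_ras, _ = sf.apply_denoising("on_ras", bundle0.model, normed, cfg)
        assert ras_counts.values.shape == ras_ras.values.shape
        assert ras_counts.reaction_ids == ras_ras.reaction_ids

    def test_invalid_stage_rejected(self, bundle0, normed):
        with pytest.raises(ConfigurationError, match="stage"):
            sf.apply_denoising("before", bundle0.model, normed)

    def test_stage_names_are_stable(self):
        assert DENOISE_STAGES == ("none", "on_counts", "on_ras")
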