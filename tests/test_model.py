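"""Unit and property tests for the generative model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arraysim import (
    ModelParams,
    add_noise,
    alpha_width,
    apply_de_shift,
    assign_de,
    draw_base_levels,
    finalize_output,
    sample_gene_profile,
    sd_de_bound,
    simulate,
)

from _reference import straight_line_simulate


class TestModelParams:
    def test_defaults_match_reference_design(self):
        p = ModelParams()
        assert (p.n, p.m1, p.m2) == (10_000, 7, 7)
        assert (p.lb, p.ub) == (4.0, 14.0)
        assert (p.lambda1, p.lambda2) == (0.13, 2.0)
        assert (p.mu_de_min, p.sd_de, p.sd_n) == (1.0, 0.5, 0.4)
        assert (p.shape1, p.shape2) == (2.0, 4.0)
        assert (p.pde, p.sym) == (0.02, 0.5)
        assert p.ratio is False and p.rseed == 50

    @pytest.mark.parametrize(
        "bad",
        [
            {"n": 0},
            {"m1": 0},
            {"m2": 0},
            {"pde": -0.1},
            {"pde": 1.5},
            {"sym": 2.0},
            {"lambda1": 0.0},
            {"lambda2": -1.0},
            {"sd_de": -0.1},
            {"sd_n": -0.1},
            {"lb": 5.0, "ub": 5.0},
            {"shape2": 0.0},
        ],
    )
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelParams(**bad)


class TestAlphaWidth:
    def test_reference_anchor_levels(self):
        # the default decay gives ~10% width at level 2, ~3.54% at level 10
        assert round(100 * alpha_width(2.0, 0.13), 1) == 10.0
        assert round(100 * alpha_width(10.0, 0.13), 2) == 3.54

    def test_zero_level_returns_rate(self):
        assert alpha_width(0.0, 0.37) == pytest.approx(0.37)

    @given(
        lam=st.floats(0.01, 1.0),
        z1=st.floats(0.1, 18.0),
        dz=st.floats(0.1, 5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_strictly_decreasing_in_level(self, lam, z1, dz):
        assert alpha_width(z1 + dz, lam) < alpha_width(z1, lam)

    def test_rejects_nonpositive_rate(self):
        with pytest.raises(ValueError):
            alpha_width(2.0, 0.0)


class TestBaseLevels:
    def test_zbar_bounds_and_alpha_consistency(self, rng):
        p = ModelParams(n=5000)
        levels = draw_base_levels(p, rng)
        assert np.all(levels.zbar >= p.lb)
        assert np.all(levels.zbar <= p.lb + p.ub)
        np.testing.assert_allclose(
            levels.alpha, p.lambda1 * np.exp(-p.lambda1 * levels.zbar)
        )

    def test_mean_level_matches_beta_moment(self, rng):
        # E[zbar] = lb + ub * shape1/(shape1+shape2) = 4 + 14/3 at defaults
        p = ModelParams(n=1_000_000)
        levels = draw_base_levels(p, rng)
        assert levels.zbar.mean() == pytest.approx(4 + 14 / 3, abs=0.02)
        # right skew: more weakly than strongly expressed genes
        assert np.median(levels.zbar) < levels.zbar.mean()


class TestGeneProfile:
    def test_degenerate_width_collapses_to_mean(self, rng):
        prof = sample_gene_profile(8.0, 0.0, 3, 4, rng)
        assert prof.shape == (8,)
        np.testing.assert_array_equal(prof, np.full(8, 8.0))

    def test_values_stay_inside_interval(self, rng):
        prof = sample_gene_profile(8.0, 0.05, 7, 7, rng)
        assert np.all(prof >= 7.6) and np.all(prof <= 8.4)

    def test_uniform_moments(self, rng):
        draws = np.concatenate(
            [sample_gene_profile(10.0, 0.0354, 0, 0, rng) for _ in range(100_000)]
        )
        assert draws.mean() == pytest.approx(10.0, abs=0.01)
        # SD of U(a, b) is (b - a)/sqrt(12) = 2*0.354/sqrt(12)
        assert draws.std() == pytest.approx(2 * 0.354 / np.sqrt(12), rel=0.02)

    def test_rejects_sign_crossing_width(self, rng):
        with pytest.raises(ValueError):
            sample_gene_profile(8.0, 1.0, 3, 3, rng)


class TestAssignDE:
    def test_no_de_when_pde_zero(self, rng):
        de = assign_de(ModelParams(pde=0.0), rng)
        assert not de.status.any()
        assert np.isnan(de.mu_de).all()

    def test_de_and_direction_frequencies(self, rng):
        # pooled over 10^6 genes: DE fraction ~ pde, up fraction ~ 1 - sym
        p = ModelParams(n=1_000_000, pde=0.02, sym=0.3)
        de = assign_de(p, rng)
        n_de = np.count_nonzero(de.status)
        assert n_de / p.n == pytest.approx(0.02, rel=0.05)
        up_frac = np.count_nonzero(de.status == 1) / n_de
        assert up_frac == pytest.approx(0.7, rel=0.02)

    def test_shift_mean_distribution(self, rng):
        p = ModelParams(n=1_000_000, pde=1.0, lambda2=2.0, mu_de_min=1.0)
        de = assign_de(p, rng)
        excess = de.mu_de - p.mu_de_min
        assert np.all(de.mu_de >= p.mu_de_min)
        assert excess.mean() == pytest.approx(0.5, rel=0.01)


class TestShiftAndNoise:
    def test_exact_shift_when_sd_zero(self, rng):
        r2 = np.array([5.0, 6.0, 7.0])
        up = apply_de_shift(r2, 1, 1.5, 0.0, rng)
        np.testing.assert_allclose(up, r2 + 1.5)
        down = apply_de_shift(r2, -1, 1.5, 0.0, rng)
        np.testing.assert_allclose(down, r2 - 1.5)

    def test_rejects_non_de_status(self, rng):
        with pytest.raises(ValueError):
            apply_de_shift(np.zeros(3), 0, 1.0, 0.5, rng)

    def test_noise_free_passthrough(self, rng):
        y = rng.random((10, 5))
        assert add_noise(y, 0.0, rng) is y

    def test_noise_moments(self, rng):
        y = np.zeros((1000, 1000))
        noisy = add_noise(y, 0.4, rng)
        delta = noisy - y
        assert delta.mean() == pytest.approx(0.0, abs=0.002)
        assert delta.std() == pytest.approx(0.4, rel=0.01)


class TestFinalize:
    def test_intensity_mode_drops_reference(self, rng):
        ybar = rng.random((20, 8))
        x, ref = finalize_output(ybar, ratio=False)
        np.testing.assert_array_equal(x, ybar[:, 1:])
        np.testing.assert_array_equal(ref, ybar[:, 0])

    def test_ratio_of_identical_columns_is_zero(self):
        ybar = np.tile(np.arange(5.0)[:, None], (1, 6))
        x, _ = finalize_output(ybar, ratio=True)
        np.testing.assert_array_equal(x, np.zeros((5, 5)))


class TestSimulate:
    def test_same_seed_bit_reproducible(self, small_params):
        a = simulate(small_params)
        b = simulate(small_params)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.reference, b.reference)
        np.testing.assert_array_equal(a.de_status, b.de_status)

    def test_ratio_equals_intensity_minus_reference(self, small_params):
        intensity = simulate(small_params.replace(ratio=False))
        ratio = simulate(small_params.replace(ratio=True))
        np.testing.assert_allclose(
            ratio.x, intensity.x - intensity.reference[:, None], atol=1e-12
        )

    def test_noise_free_values_respect_uniform_bounds(self):
        p = ModelParams(n=2000, sd_n=0.0, pde=0.0, rseed=3)
        ds = simulate(p)
        rng = np.random.default_rng(p.rseed)
        levels = draw_base_levels(p, rng)
        lo = (1 - levels.alpha) * levels.zbar
        hi = (1 + levels.alpha) * levels.zbar
        assert np.all(ds.x >= lo[:, None]) and np.all(ds.x <= hi[:, None])
        np.testing.assert_array_equal(ds.x, ds.y_noise_free[:, 1:])

    def test_noise_increment_has_expected_moments(self):
        base = ModelParams(n=5000, rseed=11)
        noisy = simulate(base)
        clean = simulate(base.replace(sd_n=0.0))
        delta = noisy.x - clean.x
        assert delta.mean() == pytest.approx(0.0, abs=0.01)
        assert delta.std() == pytest.approx(0.4, rel=0.02)

    def test_de_fraction_binomially_calibrated(self):
        # pooled over 100 seeds x 10,000 genes = 10^6 Bernoulli(pde) draws
        total = de_total = up_total = 0
        for seed in range(100):
            ds = simulate(ModelParams(rseed=seed))
            total += ds.params.n
            de_total += int(np.count_nonzero(ds.de_status))
            up_total += int(np.count_nonzero(ds.de_status == 1))
        p0 = 0.02
        z99 = 2.576
        half = z99 * np.sqrt(p0 * (1 - p0) / total)
        assert abs(de_total / total - p0) < half
        half_up = z99 * np.sqrt(0.25 / de_total)
        assert abs(up_total / de_total - 0.5) < half_up

    def test_seed_levels_define_gene_count(self):
        seed = np.array([8.0, 4.2, 12.1, 6.0])
        ds = simulate(ModelParams(sd_n=0.0, pde=0.0), seed_levels=seed)
        assert ds.x.shape == (4, 14)
        alpha = alpha_width(seed, 0.13)
        assert np.all(np.abs(ds.x - seed[:, None]) <= (alpha * seed)[:, None])

    def test_seed_levels_conflict_with_explicit_n(self):
        with pytest.raises(ValueError, match="seed_levels"):
            simulate(ModelParams(n=3), seed_levels=np.array([8.0, 9.0]))

    def test_nonpositive_seed_level_clamps_alpha_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            ds = simulate(
                ModelParams(sd_n=0.0, pde=0.0), seed_levels=np.array([-20.0, 8.0])
            )
        assert np.isfinite(ds.x).all()

    @pytest.mark.parametrize("ratio", [False, True])
    @pytest.mark.parametrize("sd_n", [0.0, 0.4])
    def test_matches_straight_line_oracle(self, ratio, sd_n):
        # scalar-loop transcription and vectorized path agree bit for bit
        p = ModelParams(
            n=10, m1=3, m2=4, pde=0.5, sym=0.4, sd_n=sd_n, ratio=ratio, rseed=99
        )
        ds = simulate(p)
        x_ref, ref_ref, status_ref = straight_line_simulate(p)
        np.testing.assert_array_equal(ds.x, x_ref)
        np.testing.assert_array_equal(ds.reference, ref_ref)
        np.testing.assert_array_equal(ds.de_status, status_ref)


class TestSdDeBound:
    def test_coefficient_and_values(self):
        assert round(1 / 1.96, 2) == 0.51
        assert sd_de_bound(1, 1.96) == pytest.approx(1.0)
        assert sd_de_bound(7, 1.0) == pytest.approx(np.sqrt(7) / 1.96)

    def test_default_design_shift_is_significant(self):
        # z = sqrt(m2) * mu_de_min / sd_de = sqrt(7)/0.5 >> 1.96
        assert np.sqrt(7) * 1.0 / 0.5 > 1.96
        assert 0.5 < sd_de_bound(7, 1.0)
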