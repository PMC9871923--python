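"""RGR correction chain, dose arithmetic, fits, d', and group tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from campariq.experiments import recover_bleedthrough
from campariq.photoconversion import (
    PhotoconversionEvent,
    compare_groups,
    compute_light_dose,
    compute_rgr,
    cumulative_dose,
    estimate_bleedthrough,
    fit_dose_response,
    normalized_green_brightness,
    pool_median_rgr,
    sensitivity_index,
    wavelength_ratio,
)


def _cell_table(green_dsub, red_dsub):
    n = len(green_dsub)
    return pd.DataFrame(
        {
            "fov_id": ["fov0"] * n,
            "cell_id": np.arange(1, n + 1),
            "green_dsub": green_dsub,
            "red_dsub": red_dsub,
            "green_raw": green_dsub,
            "red_raw": red_dsub,
        }
    )


class TestBleedthrough:
    def test_single_cell_arithmetic(self):
        table = _cell_table([1000.0], [131.0])
        assert estimate_bleedthrough(table) == pytest.approx(0.131, rel=1e-12)

    def test_zero_red_gives_zero(self):
        table = _cell_table([500.0, 800.0], [0.0, 0.0])
        assert estimate_bleedthrough(table) == 0.0

    def test_mislabeled_channels_rejected(self):
        table = _cell_table([100.0], [150.0])
        with pytest.raises(ValueError, match="mislabeled"):
            estimate_bleedthrough(table)

    def test_no_valid_cells_rejected(self):
        table = _cell_table([-5.0, 0.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            estimate_bleedthrough(table)

    def test_recovery_from_noisy_synthetic_scene(self):
        rec = recover_bleedthrough(0.146, wavelength=1040, n_cells=200, seed=5)
        assert rec.estimated == pytest.approx(0.146, rel=0.05)


class TestComputeRgr:
    def test_hand_arithmetic(self):
        table = pd.DataFrame(
            {
                "green_raw": [1100.0],
                "red_raw": [300.0],
                "green_dsub": [1100.0 - 100.0],
                "red_dsub": [300.0 - 50.0],
            }
        )
        rgr = compute_rgr(table, beta=0.131)
        assert rgr.loc[0, "rgr"] == pytest.approx((250 - 131) / 1000, rel=1e-12)

    def test_red_at_dark_and_no_bleed_gives_zero(self):
        table = pd.DataFrame({"green_dsub": [400.0], "red_dsub": [0.0]})
        assert compute_rgr(table, beta=0.0).loc[0, "rgr"] == 0.0

    def test_cells_below_dark_excluded(self):
        table = pd.DataFrame(
            {"green_dsub": [500.0, -1.0, 0.0], "red_dsub": [50.0, 10.0, 10.0]}
        )
        rgr = compute_rgr(table, beta=0.1)
        assert len(rgr) == 1

    @given(
        gain=st.floats(0.01, 100.0),
        green=st.floats(10.0, 1e4),
        red=st.floats(0.0, 1e3),
        beta=st.floats(0.0, 0.5),
    )
    def test_gain_invariance(self, gain, green, red, beta):
        """Common linear gain on both channels (raws and darks) cancels."""
        t1 = pd.DataFrame({"green_dsub": [green], "red_dsub": [red]})
        t2 = pd.DataFrame({"green_dsub": [green * gain], "red_dsub": [red * gain]})
        r1 = compute_rgr(t1, beta).loc[0, "rgr"]
        r2 = compute_rgr(t2, beta).loc[0, "rgr"]
        assert r2 == pytest.approx(r1, rel=1e-9, abs=1e-12)


class TestPooling:
    def test_simple_median(self):
        df = pd.DataFrame({"rgr": [0.1, 0.2, 0.3]})
        assert pool_median_rgr(df) == pytest.approx(0.2)

    def test_pooled_cells_not_median_of_fov_medians(self):
        df = pd.DataFrame(
            {"fov_id": ["a", "b", "b"], "rgr": [0.1, 0.2, 0.3], "group": ["g"] * 3}
        )
        pooled = pool_median_rgr(df)
        assert pooled == pytest.approx(0.2)
        fov_medians = df.groupby("fov_id")["rgr"].median()
        assert fov_medians.mean() == pytest.approx(0.175)  # the rejected scheme
        assert pooled != fov_medians.mean()

    def test_duplication_leaves_median_unchanged(self):
        df = pd.DataFrame({"rgr": [0.05, 0.2, 0.4, 0.9]})
        dup = pd.concat([df, df], ignore_index=True)
        assert pool_median_rgr(dup) == pool_median_rgr(df)

    def test_grouped_medians(self):
        df = pd.DataFrame(
            {"mouse": ["m1", "m1", "m2"], "rgr": [0.1, 0.3, 0.7]}
        )
        med = pool_median_rgr(df, group_keys=["mouse"])
        assert med["m1"] == pytest.approx(0.2)
        assert med["m2"] == pytest.approx(0.7)


class TestLightDose:
    def test_full_protocol_dose(self):
        # 200 mW, 40 x 1-s pulses, 7-mm circle -> ~208 mJ/mm^2
        ev = PhotoconversionEvent(power_mW=200.0, n_pulses=40, pulse_s=1.0)
        expected = 200.0 * 40 * 1.0 / (math.pi * 3.5**2)
        assert compute_light_dose(ev) == pytest.approx(expected, rel=1e-12)
        assert compute_light_dose(ev) == pytest.approx(207.87, abs=0.01)

    def test_half_power_dose(self):
        ev = PhotoconversionEvent(power_mW=100.0, n_pulses=40, pulse_s=1.0)
        assert compute_light_dose(ev) == pytest.approx(103.94, abs=0.01)

    def test_zero_pulses(self):
        ev = PhotoconversionEvent(power_mW=100.0, n_pulses=0, pulse_s=1.0)
        assert compute_light_dose(ev) == 0.0

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            PhotoconversionEvent(power_mW=0.0, n_pulses=1, pulse_s=1.0)
        with pytest.raises(ValueError):
            PhotoconversionEvent(power_mW=10.0, n_pulses=1, pulse_s=1.0,
                                 spot_diameter_mm=-1.0)

    @given(
        st.lists(
            st.tuples(
                st.floats(1.0, 500.0), st.integers(1, 50), st.floats(0.1, 5.0)
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_dose_additivity(self, specs):
        events = [
            PhotoconversionEvent(power_mW=p, n_pulses=n, pulse_s=s)
            for p, n, s in specs
        ]
        total = cumulative_dose(events)
        assert total == pytest.approx(sum(compute_light_dose(e) for e in events),
                                      rel=1e-12)


class TestDoseResponseFit:
    def test_two_point_closed_form(self):
        fit = fit_dose_response([100.0, 200.0], [0.079, 0.158])
        assert fit.slope == pytest.approx(7.9e-4, rel=1e-12)

    def test_all_zero_response(self):
        fit = fit_dose_response([50.0, 100.0, 150.0], [0.0, 0.0, 0.0])
        assert fit.slope == 0.0
        assert fit.p_value == 1.0

    def test_matches_sum_xy_over_sum_xx_oracle(self, rng):
        """100 random small instances against the closed form and lstsq."""
        for _ in range(100):
            n = rng.integers(2, 12)
            x = rng.uniform(1, 400, n)
            y = rng.normal(1e-3 * x, 0.01)
            fit = fit_dose_response(x, y)
            oracle = float(np.sum(x * y) / np.sum(x * x))
            lstsq = float(np.linalg.lstsq(x[:, None], y, rcond=None)[0][0])
            assert fit.slope == pytest.approx(oracle, rel=1e-12)
            assert fit.slope == pytest.approx(lstsq, rel=1e-9)

    def test_ci_contains_slope_and_p_in_range(self, rng):
        x = rng.uniform(10, 300, 8)
        y = 5e-4 * x + rng.normal(0, 0.005, 8)
        fit = fit_dose_response(x, y)
        assert fit.ci95[0] < fit.slope < fit.ci95[1]
        assert 0 < fit.p_value <= 1

    def test_input_contracts(self):
        with pytest.raises(ValueError):
            fit_dose_response([100.0], [0.1])
        with pytest.raises(ValueError):
            fit_dose_response([100.0, -5.0], [0.1, 0.2])


class TestWavelengthRatio:
    def test_arithmetic(self):
        ratios, mean, _ = wavelength_ratio([0.905], [0.100])
        assert ratios[0] == pytest.approx(9.05)
        assert mean == pytest.approx(9.05)

    def test_identical_rgr_gives_one(self):
        ratios, mean, sd = wavelength_ratio([0.2, 0.3], [0.2, 0.3])
        np.testing.assert_allclose(ratios, 1.0)
        assert mean == 1.0

    def test_unpaired_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            wavelength_ratio([0.1, 0.2], [0.1])


class TestNormalizedGreenBrightness:
    def test_arithmetic(self):
        assert normalized_green_brightness(400.0, 2.0) == pytest.approx(100.0)

    def test_unit_power_identity(self):
        assert normalized_green_brightness(123.4, 1.0) == pytest.approx(123.4)

    def test_nonpositive_power_rejected(self):
        with pytest.raises(ValueError):
            normalized_green_brightness(100.0, 0.0)

    def test_power_invariance_on_noise_free_render(self, noiseless_optics):
        from campariq.roi import DarkCurrent, extract_cell_signals, label_synthetic
        from campariq.synthetic import ConversionState, generate_population, render_stack

        pop = generate_population(6, frame_shape=(100, 100), seed=4)
        state = ConversionState.pristine(pop)
        dark = DarkCurrent(noiseless_optics.dark_green, noiseless_optics.dark_red)
        vals = []
        for power in (2.0, 4.0):
            stack = render_stack(pop, state, noiseless_optics, 1000, power)
            table = extract_cell_signals(stack, label_synthetic(pop), dark)
            vals.append(
                normalized_green_brightness(float(table["green_dsub"].median()), power)
            )
        assert vals[0] == pytest.approx(vals[1], rel=1e-10)


class TestSensitivityIndex:
    def test_hand_example(self):
        si = sensitivity_index([2.0, 3.0, 4.0], [0.0, 1.0, 2.0])
        assert si.d_prime == pytest.approx(2.0, rel=1e-12)

    def test_identical_groups_zero(self):
        si = sensitivity_index([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert si.d_prime == 0.0

    def test_antisymmetry(self, rng):
        a, b = rng.normal(1, 0.3, 50), rng.normal(0, 0.4, 60)
        assert sensitivity_index(a, b).d_prime == pytest.approx(
            -sensitivity_index(b, a).d_prime, rel=1e-12
        )

    @given(shift=st.floats(-10, 10), scale=st.floats(0.01, 100))
    def test_shift_and_scale_invariance(self, shift, scale):
        a = np.array([0.1, 0.4, 0.3, 0.9])
        b = np.array([0.0, 0.2, 0.1, 0.15])
        d0 = sensitivity_index(a, b).d_prime
        d1 = sensitivity_index(scale * (a + shift), scale * (b + shift)).d_prime
        assert d1 == pytest.approx(d0, rel=1e-6)

    def test_degenerate_variances_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_index([1.0, 1.0], [2.0, 2.0])


class TestCompareGroups:
    def test_exact_enumerated_ranksum(self):
        # all C(6,3)=20 assignments; only the two extremes are as deviant
        res = compare_groups([1.0, 2.0, 3.0], [10.0, 11.0, 12.0], "ranksum")
        assert res.method == "ranksum-exact"
        assert res.p_value == pytest.approx(0.1, rel=1e-12)

    def test_identical_samples_maximal_p(self):
        res = compare_groups([5.0, 5.0, 5.0], [5.0, 5.0, 5.0], "ranksum")
        assert res.p_value == 1.0

    def test_exact_matches_scipy_enumeration(self, rng):
        """Dual route: our enumeration vs scipy's exact Mann-Whitney null."""
        for _ in range(20):
            n, m = rng.integers(2, 7), rng.integers(2, 9)
            a = rng.normal(0, 1, n)
            b = rng.normal(0.5, 1, m)
            ours = compare_groups(a, b, "ranksum")
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert ours.p_value == pytest.approx(float(ref.pvalue), abs=1e-10)

    def test_large_n_uses_normal_approximation(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.3, 1, 45)
        res = compare_groups(a, b, "ranksum")
        assert res.method == "ranksum-normal"
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_paired_t_on_equal_vectors_flagged(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "t_paired")
        assert math.isnan(res.p_value)
        assert "degenerate" in res.method

    def test_paired_t_requires_equal_lengths(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0], "t_paired")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0], "anova")


class TestUnconvertedCellsCenteredAtZero:
    def test_prepc_rgr_expectation_zero(self):
        """Corrected red of unconverted cells has mean ~0 on noisy pre-PC data."""
        from campariq.roi import estimate_dark_current, extract_cell_signals, label_synthetic
        from campariq.synthetic import (
            ChannelOptics,
            ConversionState,
            OpticsModel,
            generate_population,
            render_stack,
        )

        pop = generate_population(150, frame_shape=(380, 380), seed=21)
        state = ConversionState.pristine(pop)
        optics = OpticsModel(
            wavelengths={1000: ChannelOptics(1.0, 1.0, 0.131)}, noise_scale=1.0
        )
        stack = render_stack(pop, state, optics, 1000, 8.0, 3, seed=22)
        table = extract_cell_signals(stack, label_synthetic(pop),
                                     estimate_dark_current(stack))
        rgr = compute_rgr(table, beta=0.131)["rgr"]
        sd = rgr.std(ddof=1)
        assert abs(rgr.mean()) < 2 * sd
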