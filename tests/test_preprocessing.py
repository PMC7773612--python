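"""Scatter correction, Savitzky-Golay filtering, cropping and config enumeration."""

import itertools

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from nirmap.io_formats import SpectraSet, WavelengthAxis
from nirmap.preprocessing import (
    DEFAULT_RANGES_NM,
    PreprocessConfig,
    apply_pipeline,
    crop_ranges,
    enumerate_configs,
    msc,
    rnv,
    savitzky_golay,
    snv,
)

# values rounded to a well-scaled lattice: scatter-correction identities are
# exact in real arithmetic but float absorption of tiny magnitudes breaks them
finite_spectra = (
    st.lists(
        st.floats(min_value=-50, max_value=50, allow_nan=False),
        min_size=8,
        max_size=40,
        unique=True,
    )
    .map(lambda xs: list(np.round(xs, 4)))
    .filter(lambda xs: len(set(xs)) == len(xs) and np.std(xs) > 1e-3)
)


class TestCrop:
    def test_paper_range_matches_membership_oracle(self, small_spectra):
        for ranges in [DEFAULT_RANGES_NM, DEFAULT_RANGES_NM[:1], DEFAULT_RANGES_NM[1:]]:
            cropped = crop_ranges(small_spectra, ranges)
            wl = small_spectra.axis.wavelengths
            keep = [any(lo <= w <= hi for lo, hi in ranges) for w in wl]
            assert cropped.n_channels == sum(keep)
            np.testing.assert_array_equal(cropped.axis.wavelengths, wl[np.array(keep)])

    def test_full_cover_is_identity(self, small_spectra):
        cropped = crop_ranges(small_spectra, [(900.0, 2600.0)])
        np.testing.assert_array_equal(cropped.values, small_spectra.values)

    def test_empty_intersection_rejected(self, small_spectra):
        with pytest.raises(ValueError, match="exclude"):
            crop_ranges(small_spectra, [(4000.0, 4100.0)])

    def test_boundary_channels_included(self):
        axis = WavelengthAxis(np.array([1.0, 2.0, 3.0, 4.0]))
        s = SpectraSet(np.ones((1, 4)), axis, ["a"], ["a"])
        cropped = crop_ranges(s, [(2.0, 3.0)])
        np.testing.assert_array_equal(cropped.axis.wavelengths, [2.0, 3.0])


class TestSnv:
    def test_three_point_example(self):
        np.testing.assert_allclose(snv(np.array([1.0, 2.0, 3.0])), [-1.0, 0.0, 1.0])

    @settings(derandomize=True, max_examples=50)
    @given(finite_spectra)
    def test_output_standardised(self, xs):
        out = snv(np.array(xs))
        assert abs(out.mean()) < 1e-12
        assert abs(out.std(ddof=1) - 1.0) < 1e-12

    @settings(derandomize=True, max_examples=50)
    @given(finite_spectra, st.floats(0.1, 10), st.floats(-5, 5))
    def test_affine_invariance(self, xs, gain, offset):
        x = np.array(xs)
        np.testing.assert_allclose(snv(gain * x + offset), snv(x), atol=1e-8)

    def test_constant_spectrum_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            snv(np.full(10, 3.0))


class TestRnv:
    @settings(derandomize=True, max_examples=50)
    @given(finite_spectra, st.floats(0.1, 10), st.floats(-5, 5))
    def test_affine_invariance(self, xs, gain, offset):
        x = np.array(xs)
        below = x[x <= np.percentile(x, 25)]
        assume(below.size > 1 and below.std(ddof=1) > 1e-9)
        np.testing.assert_allclose(rnv(gain * x + offset), rnv(x), atol=1e-8)

    def test_spike_robustness_vs_snv(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 100)
        spiked = x.copy()
        spiked[50] += 100.0
        # centring shift of non-spike channels: RNV barely moves, SNV collapses
        rnv_shift = np.abs(rnv(spiked)[:50] - rnv(x)[:50]).mean()
        snv_shift = np.abs(snv(spiked)[:50] - snv(x)[:50]).mean()
        assert rnv_shift < 0.1 * snv_shift

    def test_symmetric_spectrum_affine_of_snv(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 400)
        a, b = rnv(x), snv(x)
        # same spectrum up to a fixed affine map: residual of LS fit ~ 0
        A = np.vstack([b, np.ones_like(b)]).T
        resid = a - A @ np.linalg.lstsq(A, a, rcond=None)[0]
        assert np.abs(resid).max() < 0.2 * np.abs(a).max()

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError):
            rnv(np.array([1.0, 2.0, 3.0]))


class TestMsc:
    def _set(self, values):
        axis = WavelengthAxis(np.linspace(1000, 1100, values.shape[1]))
        return SpectraSet(values, axis, [f"s{i}" for i in range(values.shape[0])],
                          [f"s{i}" for i in range(values.shape[0])])

    def test_exact_descattering(self):
        rng = np.random.default_rng(2)
        ref = np.sin(np.linspace(0, 3, 30)) + 2
        gains = rng.uniform(0.5, 2.0, 6)
        offsets = rng.uniform(-1, 1, 6)
        values = np.outer(gains, ref) + offsets[:, None]
        corrected, used_ref = msc(self._set(values))
        # every corrected row equals the common shape up to the mean-reference affine
        for row in corrected.values:
            fit = np.polyfit(ref, row, 1)
            np.testing.assert_allclose(row, fit[0] * ref + fit[1], atol=1e-10)
            np.testing.assert_allclose(np.corrcoef(row, ref)[0, 1], 1.0, atol=1e-12)

    def test_explicit_reference_row_maps_to_itself(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(1, 2, size=(4, 25))
        s = self._set(values)
        corrected, _ = msc(s, reference=values[2])
        np.testing.assert_allclose(corrected.values[2], values[2], atol=1e-10)

    def test_matches_per_row_regression_oracle(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(0.5, 2.5, size=(5, 40))
        s = self._set(values)
        corrected, ref = msc(s)
        for i in range(5):
            b, a = np.polyfit(ref, values[i], 1)  # x = a + b*ref
            np.testing.assert_allclose(corrected.values[i], (values[i] - a) / b, atol=1e-10)

    def test_flat_spectrum_rejected_with_id(self):
        values = np.vstack([np.linspace(1, 2, 20), np.full(20, 1.5)])
        with pytest.raises(ValueError, match="s1"):
            msc(self._set(values))


class TestSavitzkyGolay:
    def _set_on(self, axis_vals, values):
        axis = WavelengthAxis(np.asarray(axis_vals, dtype=float))
        return SpectraSet(np.atleast_2d(values), axis,
                          [f"s{i}" for i in range(np.atleast_2d(values).shape[0])],
                          [f"s{i}" for i in range(np.atleast_2d(values).shape[0])])

    def test_constant_unchanged_by_smoothing(self):
        s = self._set_on(np.arange(30.0), np.full(30, 5.0))
        out = savitzky_golay(s, 7, 2, 0)
        np.testing.assert_allclose(out.values, 5.0, atol=1e-12)

    def test_polynomial_reproduced_exactly(self):
        wl = np.linspace(1000, 1200, 40)
        poly = 2.0 + 0.01 * wl + 3e-5 * wl**2
        out = savitzky_golay(self._set_on(wl, poly), 5, 2, 0)
        np.testing.assert_allclose(out.values[0], poly, rtol=1e-9)

    def test_quadratic_first_derivative_analytic(self):
        wl = np.linspace(1000, 1200, 40)
        a, b, c = 2.0, 0.01, 3e-5
        poly = a + b * wl + c * wl**2
        out = savitzky_golay(self._set_on(wl, poly), 5, 2, 1)
        np.testing.assert_allclose(out.values[0], b + 2 * c * wl, rtol=1e-6)

    def test_quadratic_second_derivative_analytic(self):
        wl = np.linspace(1000, 1200, 60)
        c = 3e-5
        poly = c * wl**2
        out = savitzky_golay(self._set_on(wl, poly), 7, 2, 2)
        np.testing.assert_allclose(out.values[0], np.full(60, 2 * c), rtol=1e-6)

    def test_linearity(self, small_spectra):
        x = small_spectra.values[0]
        y = small_spectra.values[1]

        def filt(v):
            s = SpectraSet(v[None, :], small_spectra.axis, ["a"], ["a"])
            return savitzky_golay(s, 9, 3, 1).values[0]

        np.testing.assert_allclose(filt(2 * x - 3 * y), 2 * filt(x) - 3 * filt(y), atol=1e-9)

    def test_segment_isolation_across_crop_gap(self):
        # discontinuous data: filtering must not mix channels across the gap
        wl = np.concatenate([np.arange(0, 30.0), np.arange(100.0, 130.0)])
        vals = np.concatenate([np.zeros(30), np.full(30, 10.0)])
        out = savitzky_golay(self._set_on(wl, vals), 7, 2, 0).values[0]
        np.testing.assert_allclose(out[:30], 0.0, atol=1e-10)
        np.testing.assert_allclose(out[30:], 10.0, atol=1e-10)

    def test_short_segment_rejected_naming_it(self):
        wl = np.concatenate([np.arange(0, 5.0), np.arange(100.0, 130.0)])
        s = self._set_on(wl, np.ones(35))
        with pytest.raises(ValueError, match="segment"):
            savitzky_golay(s, 7, 2, 0)


class TestEnumerateConfigs:
    def test_seven_range_subsets(self):
        configs = enumerate_configs(scatter_methods=("none",), windows=(5,),
                                    polyorders=(2,), derivs=(0,))
        assert len(configs) == 7
        assert len({c.ranges for c in configs}) == 7

    def test_sg_grid_has_48_valid_triples(self):
        triples = {
            (c.window, c.polyorder, c.deriv)
            for c in enumerate_configs(ranges=DEFAULT_RANGES_NM[:1], scatter_methods=("none",))
        }
        brute = {
            (w, p, d)
            for w, p, d in itertools.product((5, 7, 9, 11, 13, 15, 17, 19), (2, 3), (0, 1, 2))
            if p < w and d <= p
        }
        assert triples == brute
        assert len(brute) == 48

    def test_full_grid_is_1344(self):
        assert len(enumerate_configs()) == 7 * 4 * 48

    def test_deterministic_ordering(self):
        a = [c.label() for c in enumerate_configs()]
        b = [c.label() for c in enumerate_configs()]
        assert a == b


class TestPreprocessConfig:
    def test_serialisation_round_trip(self):
        cfg = PreprocessConfig(DEFAULT_RANGES_NM, "snv", 17, 2, 0)
        assert PreprocessConfig.from_dict(cfg.to_dict()) == cfg

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(window=6), "window"),
            (dict(window=3), "window"),
            (dict(polyorder=4), "polyorder"),
            (dict(deriv=3), "deriv"),
            (dict(window=5, polyorder=3, deriv=0), None),  # valid boundary
            (dict(polyorder=2, deriv=2), None),  # deriv == polyorder allowed
        ],
    )
    def test_validation(self, kwargs, msg):
        base = dict(ranges=DEFAULT_RANGES_NM, scatter="snv", window=5, polyorder=2, deriv=0)
        base.update(kwargs)
        if msg is None:
            PreprocessConfig(**base)
        else:
            with pytest.raises(ValueError, match=msg):
                PreprocessConfig(**base)

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            PreprocessConfig(((1000.0, 1100.0), (1050.0, 1200.0)))


class TestApplyPipeline:
    def test_crop_scatter_sg_order(self, small_spectra):
        cfg = PreprocessConfig(DEFAULT_RANGES_NM, "snv", 5, 2, 0)
        out, _ = apply_pipeline(small_spectra, cfg)
        manual = crop_ranges(small_spectra, DEFAULT_RANGES_NM)
        manual = manual.with_values(np.apply_along_axis(snv, 1, manual.values))
        manual = savitzky_golay(manual, 5, 2, 0)
        np.testing.assert_allclose(out.values, manual.values, atol=1e-12)

    def test_table1_water_config_applies(self, small_spectra):
        cfg = PreprocessConfig(DEFAULT_RANGES_NM, "snv", 17, 2, 0)
        out, _ = apply_pipeline(small_spectra, cfg)
        assert out.n_channels > 0
        assert out.n_samples == small_spectra.n_samples

    def test_smoothing_only_close_to_crop_on_cubic(self):
        wl = np.linspace(1060, 1172, 40)
        cubic = 1e-6 * (wl - 1100) ** 3 + 0.5
        axis = WavelengthAxis(wl)
        s = SpectraSet(cubic[None, :], axis, ["a"], ["a"])
        cfg = PreprocessConfig(((1060.0, 1172.0),), "none", 5, 3, 0)
        out, _ = apply_pipeline(s, cfg)
        np.testing.assert_allclose(out.values[0], cubic, rtol=1e-9)

    def test_msc_reference_reused_for_test_set(self, small_spectra):
        cfg = PreprocessConfig(DEFAULT_RANGES_NM, "msc", 5, 2, 0)
        train_out, ref = apply_pipeline(small_spectra, cfg)
        assert ref is not None
        single = SpectraSet(small_spectra.values[:1], small_spectra.axis, ["t"], ["t"])
        test_out, _ = apply_pipeline(single, cfg, msc_reference=ref)
        assert test_out.n_channels == train_out.n_channels

    def test_empty_intersection_propagates(self, small_spectra):
        cfg = PreprocessConfig(((9000.0, 9100.0),))
        with pytest.raises(ValueError):
            apply_pipeline(small_spectra, cfg)
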