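import numpy as np
import pytest

from conftest import disc_mask, label_for
from oracles import brute_box_counts, brute_window_sum, slope_loglog
from fishscore.multifractal import (
    AlphaImage,
    MFParams,
    detect_dots_imf,
    holder_alpha,
    inverse_select,
    local_measure,
    mf_spectrum,
)
from fishscore.nuclei import NucleusLabelMap, SegmentationParams, filter_objects, segment_nuclei
from fishscore.image_io import split_channels
from fishscore.synthetic import SyntheticSpec, generate_case, render_dot


def spike_image(shape=(16, 16), background=1e-12, value=1.0):
    img = np.full(shape, background)
    img[8, 8] = value
    return img


class TestLocalMeasure:
    def test_constant_sum_is_window_area_times_level(self):
        img = np.full((8, 8), 0.3)
        np.testing.assert_allclose(local_measure(img, 1, "sum"), 9 * 0.3)

    def test_constant_max_is_level(self):
        img = np.full((8, 8), 0.3)
        np.testing.assert_allclose(local_measure(img, 2, "max"), 0.3)

    def test_sum_matches_brute_force_windowed_sums(self):
        rng = np.random.default_rng(3)
        img = rng.random((8, 8))
        np.testing.assert_allclose(
            local_measure(img, 1, "sum"), brute_window_sum(img, 1), atol=1e-12
        )

    def test_floor_prevents_zero(self):
        assert np.all(local_measure(np.zeros((4, 4)), 1, "sum") >= 1e-12)


class TestHolderAlpha:
    def test_constant_image_sum_measure_gives_alpha_two(self):
        alpha = holder_alpha(np.full((32, 32), 0.5), MFParams(measure="sum"))
        assert np.max(np.abs(alpha.values - 2.0)) < 1e-9

    def test_constant_image_max_measure_gives_alpha_zero(self):
        alpha = holder_alpha(np.full((32, 32), 0.5), MFParams(measure="max"))
        assert np.max(np.abs(alpha.values)) < 1e-9

    def test_bright_spike_has_lower_alpha_than_background(self):
        img = np.full((16, 16), 0.1)
        img[8, 8] = 1.0
        alpha = holder_alpha(img, MFParams()).values
        assert alpha[8, 8] < alpha[0, 0]
        # oracle: direct slope at the spike from brute-force windowed sums
        eps = np.array([1.0, 3.0, 5.0, 7.0])
        mu = [brute_window_sum(img, k)[8, 8] for k in (0, 1, 2, 3)]
        direct = slope_loglog(np.log(mu), np.log(eps))
        assert alpha[8, 8] == pytest.approx(direct, abs=1e-9)

    def test_fewer_than_two_scales_rejected(self):
        with pytest.raises(ValueError, match="2 window scales"):
            MFParams(window_halfwidths=(1,))

    def test_scales_recorded(self):
        alpha = holder_alpha(np.zeros((8, 8)), MFParams())
        assert alpha.scales_used == [1, 3, 5, 7]


class TestMfSpectrum:
    def test_constant_alpha_occupied_bin_has_dimension_two(self):
        alpha = AlphaImage(values=np.full((64, 64), 2.0), scales_used=[1, 3])
        spec = mf_spectrum(alpha, MFParams())
        occupied = spec.f_per_bin[spec.f_per_bin != 0]
        assert occupied.size == 1
        assert occupied[0] == pytest.approx(2.0, abs=0.1)
        np.testing.assert_allclose(spec.values, occupied[0])

    def test_four_isolated_pixels_have_dimension_zero(self):
        values = np.zeros((64, 64))
        for r, c in [(5, 5), (5, 58), (58, 5), (58, 58)]:
            values[r, c] = 1.0
        spec = mf_spectrum(AlphaImage(values=values, scales_used=[1, 3]), MFParams())
        rare_bin = spec.values[5, 5]
        assert abs(rare_bin) < 0.15

    def test_matches_brute_force_box_count_oracle(self):
        rng = np.random.default_rng(12)
        values = rng.normal(2.0, 0.3, size=(64, 64))
        params = MFParams(n_bins=20)
        spec = mf_spectrum(AlphaImage(values=values, scales_used=[1, 3]), params)
        edges = spec.bin_edges
        idx = np.clip(np.searchsorted(edges, values, side="right") - 1, 0, params.n_bins - 1)
        counts = brute_box_counts(idx, params.n_bins, list(params.box_sizes))
        x = np.log(1.0 / np.asarray(params.box_sizes))
        for b in range(params.n_bins):
            if counts[b].min() == 0:
                assert spec.f_per_bin[b] == 0.0
            else:
                expected = slope_loglog(np.log(counts[b].astype(float)), x)
                assert spec.f_per_bin[b] == pytest.approx(expected, abs=1e-12)

    def test_f_never_exceeds_embedding_dimension(self, default_channels):
        red = default_channels[0]
        params = MFParams()
        spec = mf_spectrum(holder_alpha(red, params), params)
        assert spec.f_per_bin.max() <= 2.0 + 0.1

    def test_pixelwise_values_follow_bin_table(self):
        rng = np.random.default_rng(4)
        values = rng.normal(0, 1, size=(32, 32))
        params = MFParams(n_bins=10)
        spec = mf_spectrum(AlphaImage(values=values, scales_used=[1, 3]), params)
        idx = np.clip(
            np.searchsorted(spec.bin_edges, values, side="right") - 1, 0, params.n_bins - 1
        )
        np.testing.assert_array_equal(spec.values, spec.f_per_bin[idx])


class TestInverseSelect:
    def _alpha_and_spec(self, values, **kw):
        params = MFParams(**kw)
        alpha = AlphaImage(values=values, scales_used=[1, 3])
        return alpha, mf_spectrum(alpha, params), params

    def test_zero_percentile_low_tail_selects_nothing(self):
        rng = np.random.default_rng(0)
        alpha, spec, params = self._alpha_and_spec(
            rng.random((16, 16)), alpha_percentile=0.0, alpha_tail="low"
        )
        assert not inverse_select(alpha, spec, params).any()

    def test_zero_percentile_high_tail_no_f_cut_selects_everything(self):
        rng = np.random.default_rng(1)
        alpha, spec, params = self._alpha_and_spec(
            rng.random((16, 16)),
            alpha_percentile=0.0,
            alpha_tail="high",
            f_max=np.inf,
        )
        assert inverse_select(alpha, spec, params).all()

    def test_spike_selected_background_mode_not(self):
        img = np.full((32, 32), 0.1)
        img[16, 16] = 1.0
        params = MFParams(alpha_percentile=5.0, alpha_tail="low", f_max=1.0)
        alpha = holder_alpha(img, params)
        spec = mf_spectrum(alpha, params)
        sel = inverse_select(alpha, spec, params)
        assert sel[16, 16]
        assert not sel[0, 0]

    def test_selection_monotone_in_percentile(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(32, 32))
        alpha = AlphaImage(values=values, scales_used=[1, 3])
        spec = mf_spectrum(alpha, MFParams())
        prev = None
        for pct in (1.0, 5.0, 20.0, 50.0, 100.0):
            sel = inverse_select(alpha, spec, MFParams(alpha_percentile=pct, f_max=np.inf))
            if prev is not None:
                assert np.all(prev <= sel)  # enlarging the tail never shrinks it
            prev = sel


class TestDetectDotsIMF:
    def _nucleus(self, shape=(120, 120)):
        labels = disc_mask(shape, (60, 60), 40).astype(np.int32)
        return filter_objects(labels, SegmentationParams(min_area=100, max_area=20_000))

    def test_two_dots_with_noise_recovered(self):
        rng = np.random.default_rng(21)
        nmap = self._nucleus()
        channel = np.full((120, 120), 0.1)
        for c in [(45, 45), (75, 70)]:
            render_dot(channel, c, sigma=1.5, peak=0.8)
        channel = np.clip(channel + rng.normal(0, 0.02, channel.shape), 0, 1)
        dots = detect_dots_imf(channel, nmap, channel_name="red")
        assert len(dots) == 2
        assert {d.nucleus_id for d in dots} == {1}

    def test_uniform_nucleus_yields_no_dots(self):
        nmap = self._nucleus()
        channel = np.full((120, 120), 0.1)
        assert detect_dots_imf(channel, nmap) == []

    def test_dots_outside_nuclei_excluded(self):
        nmap = self._nucleus()
        channel = np.full((120, 120), 0.1)
        render_dot(channel, (5, 5), sigma=1.5, peak=0.8)  # far from the disc
        assert detect_dots_imf(channel, nmap) == []

    def test_exact_count_recovery_on_seeded_case(self, default_case, default_channels, default_nuclei):
        _, _, truth = default_case
        red, green, _ = default_channels
        from collections import Counter

        red_counts = Counter(d.nucleus_id for d in detect_dots_imf(red, default_nuclei, channel_name="red"))
        green_counts = Counter(
            d.nucleus_id for d in detect_dots_imf(green, default_nuclei, channel_name="green")
        )
        exact = 0
        for nuc in truth.nuclei:
            lab = label_for(nuc, default_nuclei)
            exact += (
                red_counts.get(lab, 0) == nuc.true_red
                and green_counts.get(lab, 0) == nuc.true_green
            )
        assert exact / len(truth.nuclei) >= 0.95
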