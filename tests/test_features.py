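import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spiraldx.errors import DomainError, ValidationError
from spiraldx.features import (SpectralConfig, binned_spectrum,
                               count_direction_changes, direction_change_features,
                               dominant_bin_frequency, extract_feature_vector,
                               f1c_distance_fft, force_features,
                               log_transform_features, precision_features, qyes,
                               spectral_bin_std, time_velocity_features,
                               velocity_series)
from spiraldx.io import DrawingRecording, QuestionnaireResponse
from spiraldx.spiral import DistanceSeries

from conftest import make_ideal_recording, make_participant, make_perturbed_recording


class TestQYes:
    @pytest.mark.parametrize("yes, expected", [(30, 30), (0, 0), (7, 7)])
    def test_counts_positive_answers(self, yes, expected):
        items = np.zeros(30, dtype=int)
        items[:yes] = 1
        assert qyes(QuestionnaireResponse(items)) == expected


class TestVelocity:
    def test_three_four_five_triangle(self):
        rec = DrawingRecording("V", "right", 1, t=[0.0, 1.0], x=[0.0, 3.0],
                               y=[0.0, 4.0], force=[1.0, 1.0])
        vs = velocity_series(rec)
        assert vs.v[0] == 0.0  # defined start value
        assert vs.v[1] == pytest.approx(5.0)

    def test_constant_speed_template_has_flat_velocity(self, template):
        # sqrt sweep parametrizes the spiral at constant linear speed
        rec = make_perturbed_recording(template, 0.0, 1.0, n=8000, duration=20.0)
        vs = velocity_series(rec)
        interior = vs.v[800:]
        assert np.std(interior) / np.mean(interior) < 0.01

    def test_repeated_timestamp_distinct_position_rejected(self):
        rec_kwargs = dict(participant_id="V", hand="right", repetition=1,
                          force=[1.0, 1.0, 1.0])
        rec = DrawingRecording(t=[0.0, 1.0, 1.0], x=[0, 1, 2], y=[0, 0, 0],
                               **rec_kwargs)
        with pytest.raises(ValidationError, match="repeated timestamp"):
            velocity_series(rec)

    def test_repeated_timestamp_same_position_dropped(self):
        rec = DrawingRecording("V", "right", 1, t=[0.0, 1.0, 1.0, 2.0],
                               x=[0, 1, 1, 2], y=[0, 0, 0, 0],
                               force=[1.0] * 4)
        with pytest.warns(UserWarning, match="repeated"):
            vs = velocity_series(rec)
        assert len(vs) == 3

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_bruteforce_difference_quotient(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 120))
        t = np.cumsum(rng.uniform(1e-3, 0.1, n))
        x, y = rng.normal(0, 2, n), rng.normal(0, 2, n)
        rec = DrawingRecording("V", "right", 1, t=t - t[0], x=x, y=y,
                               force=np.ones(n))
        vs = velocity_series(rec)
        brute = [0.0] + [
            np.sqrt((x[i] - x[i - 1]) ** 2 + (y[i] - y[i - 1]) ** 2) / (t[i] - t[i - 1])
            for i in range(1, n)
        ]
        np.testing.assert_allclose(vs.v, brute, rtol=1e-12)


class TestSpectrum:
    def _sine_series(self, freq, n=4800, duration=20.0, amplitude=0.3):
        t = np.linspace(0, duration, n)
        return DistanceSeries(t=t, d=amplitude * np.sin(2 * np.pi * freq * t))

    def test_identical_sides_give_zero(self):
        ds = self._sine_series(5.0)
        assert f1c_distance_fft(ds, ds) == 0.0

    def test_pure_tone_dominates_its_bin(self):
        cfg = SpectralConfig()
        ds = self._sine_series(5.0)
        assert abs(dominant_bin_frequency(ds, cfg) - 5.0) <= cfg.bin_width

    def test_tone_vs_flat_equals_tone_bin_std(self):
        tone = self._sine_series(5.0)
        flat = DistanceSeries(t=tone.t, d=np.zeros(len(tone)))
        assert f1c_distance_fft(tone, flat) == pytest.approx(
            spectral_bin_std(tone), abs=1e-15)

    def test_against_bruteforce_dft_binning(self):
        """The binned magnitudes must match a direct DFT computed by hand."""
        cfg = SpectralConfig()
        rng = np.random.default_rng(3)
        n = 2400
        t = np.arange(n) / 240.0
        d = rng.normal(0, 0.1, n) + 0.2 * np.sin(2 * np.pi * 6.3 * t)
        ds = DistanceSeries(t=t, d=d)
        # oracle: explicit DFT at matching resolution (uniform grid already)
        k = np.arange(n // 2 + 1)
        freqs = k * 240.0 / n
        dft = np.array([np.sum(d * np.exp(-2j * np.pi * kk * np.arange(n) / n))
                        for kk in k])
        mag = 2.0 * np.abs(dft) / n
        edges = cfg.bin_edges
        expected = np.zeros(cfg.n_bins)
        sel_band = (freqs >= 3.0) & (freqs <= 15.0)
        idx = np.digitize(freqs[sel_band], edges[1:-1])
        for b in range(cfg.n_bins):
            m = mag[sel_band][idx == b]
            if len(m):
                expected[b] = m.mean()
        np.testing.assert_allclose(binned_spectrum(ds, cfg), expected,
                                   rtol=1e-8, atol=1e-12)

    def test_white_noise_laterality_is_small(self):
        rng = np.random.default_rng(11)
        n = 24000
        t = np.arange(n) / 240.0
        vals = [spectral_bin_std(DistanceSeries(t=t, d=rng.normal(0, 0.1, n)))
                for _ in range(8)]
        # flat spectrum: bin stds nearly equal, between-side diff tiny
        diffs = [abs(a - b) for a, b in zip(vals[::2], vals[1::2])]
        assert np.mean(diffs) < 0.2 * np.mean(vals)

    def test_short_series_rejected(self):
        ds = DistanceSeries(t=np.linspace(0, 0.2, 100), d=np.zeros(100))
        with pytest.raises(ValidationError, match="period"):
            binned_spectrum(ds)


class TestSummaryFeatures:
    def test_zero_distance_fixed_point(self):
        assert precision_features(np.zeros(50)) == (0.0, 0.0, 0.0)

    def test_two_point_case(self):
        f2, f3, f4 = precision_features(np.array([0.5, -0.5]))
        assert (f2, f3, f4) == (0.5, 0.5, 0.5)

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_direct_formulas(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(0, 1, int(rng.integers(2, 300)))
        f2, f3, f4 = precision_features(d)
        assert f2 == pytest.approx(max(abs(v) for v in d), rel=1e-12)
        assert f3 == pytest.approx(sum(abs(v) for v in d) / len(d), rel=1e-12)
        mu = sum(d) / len(d)
        assert f4 == pytest.approx(np.sqrt(sum((v - mu) ** 2 for v in d) / len(d)),
                                   rel=1e-10)

    def test_constant_force(self):
        assert force_features(np.full(30, 1.0)) == (1.0, 0.0, 1.0)

    def test_two_value_force(self):
        assert force_features(np.array([0.0, 2.0])) == (1.0, 1.0, 1.0)


class TestDirectionChanges:
    def test_strictly_increasing_radius_has_none(self):
        assert count_direction_changes(np.arange(50)) == 0

    def test_hand_enumerated_sequence(self):
        # diffs: +1, -0.5, +1, -0.5 -> sign changes at 3 junctions
        assert count_direction_changes([0, 1, 0.5, 1.5, 1.0]) == 3

    def test_zero_differences_skipped(self):
        assert count_direction_changes([0, 1, 1, 2, 1]) == 1

    @pytest.mark.parametrize("k", [3, 5, 8])
    def test_sinusoid_matches_extrema_count(self, k):
        t = np.linspace(0, 1, 5000)
        x = np.sin(2 * np.pi * k * t)

        def brute_force_extrema(v):
            count = 0
            for i in range(1, len(v) - 1):
                if (v[i] - v[i - 1]) * (v[i + 1] - v[i]) < 0:
                    count += 1
            return count

        counted = count_direction_changes(x)
        assert counted == brute_force_extrema(x)
        assert abs(counted - 2 * k) <= 1

    def test_ideal_spiral_f5_zero(self, template, ideal_recording):
        f5, _, _ = direction_change_features(ideal_recording, template)
        assert f5 == 0


class TestTimeVelocityFeatures:
    def test_total_drawing_time(self, template):
        rec = make_ideal_recording(template, duration=30.0)
        f11, _, _ = time_velocity_features(rec)
        assert f11 == pytest.approx(30.0)

    def test_constant_velocity(self):
        t = np.linspace(0, 10, 101)
        rec = DrawingRecording("C", "right", 1, t=t, x=2 * t, y=np.zeros(101),
                               force=np.ones(101))
        _, f12, f13 = time_velocity_features(rec)
        assert f12 == pytest.approx(2.0)
        assert f13 == pytest.approx(0.0, abs=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_f13_squared_matches_population_variance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        t = np.cumsum(rng.uniform(1e-3, 0.05, n))
        rec = DrawingRecording("R", "right", 1, t=t - t[0],
                               x=rng.normal(0, 1, n), y=rng.normal(0, 1, n),
                               force=np.ones(n))
        _, f12, f13 = time_velocity_features(rec, clip_fraction=0.10)
        vs = velocity_series(rec)
        k = int(np.floor(0.10 * n))
        v = vs.v[k:n - k] if k else vs.v
        mu = sum(v) / len(v)
        var = sum((vi - mu) ** 2 for vi in v) / len(v)
        assert f13 ** 2 == pytest.approx(var, rel=1e-9, abs=1e-12)
        assert f12 == pytest.approx(mu, rel=1e-12)


class TestLogTransform:
    def test_known_value(self):
        assert log_transform_features(np.e - 1e-9) == pytest.approx(1.0)

    def test_zero_maps_to_log_eps(self):
        assert log_transform_features(0.0) == pytest.approx(np.log(1e-9))

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            log_transform_features(np.array([0.1, -0.1]))

    @settings(max_examples=30, deadline=None)
    @given(values=st.lists(st.floats(0, 1e6), min_size=2, max_size=50))
    def test_preserves_order(self, values):
        values = np.sort(np.array(values))
        out = log_transform_features(values)
        assert np.all(np.diff(out) >= 0)


class TestFeatureVector:
    def test_ideal_drawer_fixed_point(self, template):
        p = make_participant("IDEAL", yes=0, template=template)
        fv = extract_feature_vector(p, template)
        assert fv["QYes"] == 0
        assert fv["F2_MaxDistance"] == pytest.approx(0.0, abs=1e-9)
        assert fv["F3_MeanDistance"] == pytest.approx(0.0, abs=1e-9)
        assert fv["F4_StdDevDistance"] == pytest.approx(0.0, abs=1e-9)
        assert fv["F5_ChangeOfRadiusDirection"] == 0
        assert fv["F13_StdDevVelocity"] < 0.2  # constant-angle sweep, mild ramp

    def test_symmetric_sides_have_zero_laterality(self, template):
        recs = [make_perturbed_recording(template, 0.2, 5.0, participant_id="S",
                                         hand=h, repetition=rep)
                for h in ("left", "right") for rep in (1, 2)]
        p = make_participant("S", recordings=recs)
        fv = extract_feature_vector(p, template)
        assert fv["F1c_DistanceFFT"] == pytest.approx(0.0, abs=1e-12)

    def test_tremor_raises_precision_features(self, template):
        """A 5 Hz, 0.3 cm unilateral tremor must beat a clean drawer on F2-F4/F1c."""
        tremor_recs = [
            make_perturbed_recording(template, 0.3 if h == "left" else 0.02, 5.0,
                                     participant_id="PD", hand=h, repetition=rep,
                                     phase=0.3 * rep)
            for h in ("left", "right") for rep in (1, 2)
        ]
        pd_like = extract_feature_vector(
            make_participant("PD", group="PD", recordings=tremor_recs), template)
        cg_like = extract_feature_vector(make_participant("CG"), template)
        for name in ("F1c_DistanceFFT", "F2_MaxDistance", "F3_MeanDistance",
                     "F4_StdDevDistance"):
            assert pd_like[name] > cg_like[name]
        assert pd_like["_affected_arm"] == "left"
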