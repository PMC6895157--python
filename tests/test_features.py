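"""Acoustic feature extraction: each measure against a known construction."""

import numpy as np
import pytest

from herdvoice.features import (IncompleteFeatures, amplitude_features,
                                extract_features, f0_features,
                                jitter_percent, nlp_features,
                                periodicity_features, spectral_entropy,
                                validate_feature_vector)
from herdvoice.pitch import PitchContour, extract_pitch
from herdvoice.synth import NLPAnnotation, _child_rng, zero_shift
from tests.test_synth import flat_signature

FS = 44100


def contour_from(f0_values, step=0.010) -> PitchContour:
    f0 = np.asarray(f0_values, float)
    return PitchContour(times=np.arange(len(f0)) * step + step / 2,
                        f0=f0, voiced=np.isfinite(f0),
                        floor=100.0, ceiling=2500.0)


class TestF0Features:
    def test_flat_contour(self):
        c = contour_from([600.0] * 50)
        f = f0_features(c, 0.5)
        assert f["f0_var_hz_per_s"] == 0.0
        assert f["fm_rate_per_s"] == 0.0
        assert f["inflex"] == 0
        for k in ("f0_mean_hz", "f0_min_hz", "f0_max_hz", "f0_start_hz",
                  "f0_end_hz"):
            assert f[k] == 600.0

    def test_two_frame_cumulative_variation(self):
        f = f0_features(contour_from([600.0, 700.0]), 0.1)
        assert f["f0_var_hz_per_s"] == pytest.approx(1000.0)

    def test_sinusoidal_fm_recovered(self):
        # 700 +/- 50 Hz at 5 Hz for 1 s: rate ~5/s, peak-to-peak ~100 Hz,
        # total variation ~4*50*5 = 1000 Hz/s
        t = np.arange(0, 1.0, 0.010)
        c = contour_from(700 + 50 * np.sin(2 * np.pi * 5 * t))
        f = f0_features(c, 1.0)
        assert abs(f["fm_rate_per_s"] - 5.0) <= 1.0
        assert f["fm_extent_hz"] == pytest.approx(100.0, rel=0.1)
        assert f["f0_var_hz_per_s"] == pytest.approx(1000.0, rel=0.15)

    def test_too_few_voiced_frames_flagged(self):
        with pytest.raises(IncompleteFeatures):
            f0_features(contour_from([600.0, np.nan, np.nan]), 0.03)


class TestAmplitudeFeatures:
    def test_constant_envelope(self):
        t = np.arange(2 * FS) / FS
        x = np.sin(2 * np.pi * 600 * t)
        f = amplitude_features(x, FS, 2.0)
        assert f["am_var_per_s"] < 0.1
        assert f["am_rate_per_s"] == 0.0

    def test_am_rate_recovered(self):
        t = np.arange(2 * FS) / FS
        x = (1 + 0.5 * np.sin(2 * np.pi * 3 * t)) * np.sin(2 * np.pi * 600 * t)
        f = amplitude_features(x, FS, 2.0)
        assert abs(f["am_rate_per_s"] - 3.0) <= 1.0

    def test_gain_invariance(self):
        t = np.arange(2 * FS) / FS
        x = (1 + 0.5 * np.sin(2 * np.pi * 3 * t)) * np.sin(2 * np.pi * 600 * t)
        a = amplitude_features(x, FS, 2.0)
        b = amplitude_features(7.3 * x, FS, 2.0)
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-9)

    def test_silence_rejected(self):
        with pytest.raises(ValueError):
            amplitude_features(np.zeros(FS), FS, 1.0)


class TestPeriodicityFeatures:
    def test_exactly_periodic_sawtooth(self):
        fs = 42000  # 200 Hz -> integer period of 210 samples
        t = np.arange(fs) / fs
        saw = 2 * ((200 * t) % 1) - 1
        c = extract_pitch(saw, fs, floor=100, ceiling=1000)
        f = periodicity_features(saw, fs, c)
        assert f["jitter_pct"] < 0.1
        assert f["shimmer_pct"] < 0.1
        assert f["harmonicity_db"] > 40.0

    def test_jitter_formula_on_alternating_periods(self):
        periods = np.array([5.0, 5.1] * 10) / 1000.0
        assert jitter_percent(periods) == pytest.approx(0.1 / 5.05 * 100,
                                                        rel=1e-3)

    def test_insufficient_cycles_flagged(self):
        x = np.sin(2 * np.pi * 600 * np.arange(FS) / FS)
        c = extract_pitch(x, FS, floor=100, ceiling=1000)
        with pytest.raises(IncompleteFeatures):
            periodicity_features(x[:200], FS, c)


class TestSpectralEntropy:
    def test_pure_tone_near_zero(self):
        x = np.sin(2 * np.pi * 600 * np.arange(FS) / FS)
        assert spectral_entropy(x, FS) < 0.05

    def test_white_noise_near_one(self):
        x = np.random.default_rng(1).standard_normal(FS)
        assert spectral_entropy(x, FS) > 0.8

    def test_monotone_in_noise_gain(self):
        t = np.arange(FS) / FS
        tone = np.sin(2 * np.pi * 600 * t)
        noise = np.random.default_rng(2).standard_normal(FS)
        vals = [spectral_entropy(tone + g * noise, FS)
                for g in (0.0, 0.1, 0.3, 1.0, 3.0)]
        assert np.all(np.diff(vals) > 0)

    def test_silence_rejected(self):
        with pytest.raises(ValueError):
            spectral_entropy(np.zeros(FS), FS)


class TestNLPFeatures:
    def test_single_chaos_interval(self):
        ann = NLPAnnotation("c", [("chaos", 0.2, 0.4)])
        f = nlp_features(ann, 1.0)
        assert f["chaos_pct"] == pytest.approx(20.0)
        assert f["freq_jumps"] == 0

    def test_empty_annotation(self):
        f = nlp_features(NLPAnnotation("c"), 1.0)
        assert all(f[k] == 0 for k in f)

    def test_union_of_two_subharmonic_intervals(self):
        ann = NLPAnnotation("c", [("subharmonics", 0.0, 0.10),
                                  ("subharmonics", 0.25, 0.40)])
        f = nlp_features(ann, 0.5)
        assert f["subharmonics_pct"] == pytest.approx(50.0)

    def test_overlapping_intervals_counted_once(self):
        ann = NLPAnnotation("c", [("chaos", 0.1, 0.3), ("chaos", 0.2, 0.4)])
        assert nlp_features(ann, 1.0)["chaos_pct"] == pytest.approx(30.0)

    def test_interval_outside_call_rejected(self):
        ann = NLPAnnotation("c", [("chaos", 0.5, 1.5)])
        with pytest.raises(ValueError):
            nlp_features(ann, 1.0)


@pytest.fixture(scope="module")
def call():
    from herdvoice.synth import synthesize_call
    sig = flat_signature(f0=600.0, duration=1.0)
    sig.param_means.update(fm_rate_per_s=4.0, fm_extent_hz=60.0,
                           am_rate_per_s=5.0, am_extent_db=5.0,
                           f0_max_hz=750.0, f0_start_hz=580.0,
                           f0_end_hz=560.0, f0_min_hz=560.0,
                           jitter_pct=0.5, shimmer_pct=2.0)
    return synthesize_call(sig, zero_shift("positive"), _child_rng(7, "x"))


class TestExtractFeatures:

    def test_deterministic(self, call):
        a = extract_features(call, 150, 2000)
        b = extract_features(call, 150, 2000)
        assert a == b

    def test_clean_call_has_no_phenomena(self, call):
        v = extract_features(call, 150, 2000)
        assert v["chaos_pct"] == v["subharmonics_pct"] == \
            v["sidebands_pct"] == 0.0
        assert v["freq_jumps"] == 0

    def test_recovers_ground_truth_f0_and_duration(self, call):
        v = extract_features(call, 150, 2000)
        gt = call.ground_truth
        for k in ("f0_mean_hz", "f0_min_hz", "f0_max_hz", "duration_s"):
            assert v[k] == pytest.approx(gt[k], rel=0.05)

    def test_invariants_hold(self, call):
        validate_feature_vector(extract_features(call, 150, 2000))

    def test_gain_invariance(self, call):
        import dataclasses
        quiet = dataclasses.replace(call, samples=call.samples * 0.25)
        a = extract_features(call, 150, 2000)
        b = extract_features(quiet, 150, 2000)
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=0.02, abs=0.05), k

    def test_padding_with_silence_only_affects_trim(self, call):
        import dataclasses
        pad = np.zeros(int(0.05 * call.sample_rate))
        padded = dataclasses.replace(
            call, samples=np.concatenate([pad, call.samples, pad]))
        a = extract_features(call, 150, 2000)
        b = extract_features(padded, 150, 2000)
        assert b["duration_s"] == pytest.approx(a["duration_s"], rel=0.01)
        for k in ("f0_mean_hz", "f0_min_hz", "f0_max_hz", "entropy"):
            assert b[k] == pytest.approx(a[k], rel=0.03)


class TestIntervalUnionProperty:
    """The phenomenon percentage equals a rasterized union measure."""

    from hypothesis import given, settings
    from hypothesis import strategies as hs

    @given(hs.lists(hs.tuples(hs.floats(0.0, 0.9), hs.floats(0.01, 0.5)),
                    min_size=0, max_size=6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_union_matches_rasterized_measure(self, spans):
        intervals = [("chaos", s, min(s + w, 1.0)) for s, w in spans]
        ann = NLPAnnotation("c", intervals)
        pct = nlp_features(ann, 1.0)["chaos_pct"]
        grid = np.zeros(200_000, bool)
        for _, s, e in intervals:
            grid[int(s * 200_000):int(e * 200_000)] = True
        assert pct == pytest.approx(100.0 * grid.mean(), abs=0.05)
        assert 0.0 <= pct <= 100.0
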