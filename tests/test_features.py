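"""Feature schema, framing arithmetic, and the per-frame descriptors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gaitguard as gg
from gaitguard.features import (
    FRAME_LEN,
    Frame,
    FrameFeaturizer,
    feature_schema,
    frame_stream,
)
from gaitguard.simulate import SAMPLE_RATE

from conftest import make_zero_stream


def frame_of(accel_x=None, fill=0.0):
    """200-sample frame, optionally with a custom accel-X series."""
    acc = np.full((FRAME_LEN, 3), fill, dtype=float)
    gyr = np.full((FRAME_LEN, 3), fill, dtype=float)
    if accel_x is not None:
        acc[:, 0] = accel_x
    return Frame(0, acc, gyr)


def feat(vec, name):
    return vec[feature_schema().names.index(name)]


class TestSchema:
    def test_group_sizes_match_the_published_table(self):
        sch = feature_schema()
        assert len(sch) == 260
        expected = {
            "basic": 9,
            "moments": 9,
            "deriv_moments": 12,
            "extremes": 12,
            "histogram": 18,
            "fourier": 57,
            "overall_mean": 1,
            "cross_corr": 6,
            "angular_cross_corr": 6,
        }
        for sensor in ("acc", "gyr"):
            assert sch.count(sensor) == 130
            for group, n in expected.items():
                assert sch.count(sensor, group) == n, (sensor, group)

    def test_names_unique_and_stable(self):
        sch = feature_schema()
        assert len(set(sch.names)) == 260
        assert sch.names == feature_schema().names
        assert feature_schema().fingerprint() == sch.fingerprint()


class TestFraming:
    def test_five_minute_stream_yields_297_frames(self):
        frames = frame_stream(make_zero_stream(15000))
        assert len(frames) == 297
        assert frames[0].start_index == 0 and frames[1].start_index == 50

    @pytest.mark.parametrize("n,expected", [(200, 1), (199, 0), (0, 0), (250, 2)])
    def test_boundary_lengths(self, n, expected):
        assert len(frame_stream(make_zero_stream(n))) == expected

    def test_neighbours_share_150_samples(self):
        frames = frame_stream(make_zero_stream(400))
        a, b = frames[0], frames[1]
        assert b.start_index - a.start_index == 50
        assert np.array_equal(a.accel[50:], b.accel[:150])

    @given(st.integers(min_value=0, max_value=2000))
    @settings(max_examples=60, deadline=None)
    def test_frame_count_matches_bruteforce_slider(self, n):
        stream = make_zero_stream(n)
        got = len(frame_stream(stream))
        # independent brute-force slide
        count, start = 0, 0
        while start + 200 <= n:
            count += 1
            start += 50
        assert got == count
        if n >= 200:
            assert got == (n - 200) // 50 + 1

    def test_non_integer_hop_rejected(self):
        with pytest.raises(ValueError):
            frame_stream(make_zero_stream(100), frame_len=10, overlap=0.55)
        with pytest.raises(ValueError):
            frame_stream(make_zero_stream(100), frame_len=10, overlap=1.0)


class TestExtraction:
    def test_constant_frame_degenerate_conventions(self):
        c = 3.0
        vec = gg.extract_features(frame_of(fill=c))
        assert np.isfinite(vec).all()
        for sensor in ("acc", "gyr"):
            for ax in ("x", "y", "z"):
                assert feat(vec, f"{sensor}_{ax}_mean") == pytest.approx(c)
                assert feat(vec, f"{sensor}_{ax}_rms") == pytest.approx(c)
                assert feat(vec, f"{sensor}_{ax}_sd") == 0.0
                assert feat(vec, f"{sensor}_{ax}_skew") == 0.0
                assert feat(vec, f"{sensor}_{ax}_kurt") == 0.0
                for k in range(2, 21):
                    assert feat(vec, f"{sensor}_{ax}_fft{k}") == pytest.approx(0.0, abs=1e-9)
                # zero variance: all mass in the central [0, 1) z-bin
                counts = [feat(vec, f"{sensor}_{ax}_zhist{b}") for b in range(6)]
                assert counts == [0, 0, 0, 200, 0, 0]
            # zero-variance convention for cross-correlations
            assert feat(vec, f"{sensor}_xy_xcorr_mean") == 0.0
            # angle of (c, c) is 45 degrees
            assert feat(vec, f"{sensor}_xy_angcorr_mean") == pytest.approx(np.pi / 4)

    def test_sine_fourier_magnitude_against_direct_dft(self):
        t = np.arange(FRAME_LEN) / SAMPLE_RATE
        x = np.sin(2 * np.pi * 2.0 * t)  # 8 full cycles in the 4-s frame
        vec = gg.extract_features(frame_of(accel_x=x))
        # independent oracle: direct DFT summation at 0-based index 8
        n = np.arange(FRAME_LEN)
        oracle = abs(np.sum(x * np.exp(-2j * np.pi * 8 * n / FRAME_LEN)))
        fourier = {k: feat(vec, f"acc_x_fft{k}") for k in range(2, 21)}
        assert max(fourier, key=fourier.get) == 9  # 1-based component 9
        assert fourier[9] == pytest.approx(oracle) == pytest.approx(100.0, rel=1e-9)

    def test_identical_axes_cross_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=FRAME_LEN)
        acc = np.zeros((FRAME_LEN, 3))
        acc[:, 0] = x
        acc[:, 1] = x
        acc[:, 2] = 1.0
        vec = gg.extract_features(Frame(0, acc, np.ones((FRAME_LEN, 3))))
        # brute-force full cross-correlation over all lags
        seq = np.correlate(x, x, mode="full") / np.dot(x, x)
        assert seq[FRAME_LEN - 1] == pytest.approx(1.0)  # zero lag
        assert feat(vec, "acc_xy_xcorr_mean") == pytest.approx(seq.mean())
        absmean = feat(vec, "acc_xy_xcorr_absmean")
        assert absmean == pytest.approx(np.abs(seq).mean())
        assert 0.0 < absmean <= 1.0

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(FRAME_LEN, 3))
        f0 = Frame(0, base, base[:, ::-1])
        shifted = base.copy()
        shifted[:, 0] += 5.0
        f1 = Frame(0, shifted, base[:, ::-1])
        v0, v1 = gg.extract_features(f0), gg.extract_features(f1)
        sch = feature_schema()
        for spec, a, b in zip(sch.specs, v0, v1):
            if spec.sensor != "acc" or spec.axis != "x":
                continue
            stat = spec.name.split("_")[-1]
            if stat == "mean":
                assert b - a == pytest.approx(5.0)
            elif spec.group in ("moments", "deriv_moments", "histogram") or (
                spec.group == "fourier"
            ):
                assert b == pytest.approx(a, abs=1e-8), spec.name

    def test_histogram_counts_conserved_with_outliers(self):
        x = np.zeros(FRAME_LEN)
        x[:5] = 100.0  # z far beyond 3: clipped into the end bin
        vec = gg.extract_features(frame_of(accel_x=x))
        counts = [feat(vec, f"acc_x_zhist{b}") for b in range(6)]
        assert sum(counts) == FRAME_LEN
        assert counts[5] == 5

    def test_deterministic_bit_for_bit(self):
        rng = np.random.default_rng(2)
        f = Frame(0, rng.normal(size=(FRAME_LEN, 3)), rng.normal(size=(FRAME_LEN, 3)))
        assert np.array_equal(gg.extract_features(f), gg.extract_features(f))

    def test_malformed_frame_rejected(self):
        with pytest.raises(ValueError):
            Frame(0, np.zeros((10, 2)), np.zeros((10, 3)))
        with pytest.raises(ValueError):
            Frame(0, np.zeros((1, 3)), np.zeros((1, 3)))


class TestDataset:
    def test_five_minute_stream_rows_and_labels(self, profile):
        s = gg.simulate_activity(profile, "walking", 300, 4)
        fs = gg.extract_dataset([s])
        assert len(fs) == 297
        assert set(fs.y) == {"walking"} and set(fs.honesty) == {"normal"}
        assert np.isfinite(fs.X).all()

    def test_empty_and_concatenation(self, profile):
        assert len(gg.extract_dataset([])) == 0
        s = gg.simulate_activity(profile, "sitting", 20, 5)
        fs = gg.extract_dataset([s, s])
        assert len(fs) == 2 * 17
        assert np.array_equal(fs.X[:17], fs.X[17:])

    def test_mixed_sampling_rate_rejected(self, profile):
        s = gg.simulate_activity(profile, "sitting", 5, 6)
        s.sample_rate = 100.0
        with pytest.raises(ValueError):
            gg.extract_dataset([s])

    def test_featurizer_matches_extract_dataset(self, profile):
        s = gg.simulate_activity(profile, "walking", 20, 7)
        tr = FrameFeaturizer()
        assert np.array_equal(tr.fit_transform([s]), gg.extract_dataset([s]).X)
        assert list(tr.get_feature_names_out()) == list(feature_schema().names)
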