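"""Bandpass, global signal regression, scaling and window arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurocast.preprocess import (GraphSignalSequence, bandpass_filter,
                                  concat_windowed, global_signal_regression,
                                  scale_session, split_samples, windowize)

TR = 0.72


def sinusoid(freq_hz: float, t: int = 1200, n: int = 3) -> GraphSignalSequence:
    times = np.arange(t) * TR
    data = np.vstack([np.sin(2 * np.pi * freq_hz * times + 0.3 * i)
                      for i in range(n)])
    return GraphSignalSequence(data, TR)


class TestBandpass:
    def test_inband_sinusoid_retained(self):
        out = bandpass_filter(sinusoid(0.055), 0.04, 0.07)
        # compare steady-state amplitude away from the edges
        core = slice(200, 1000)
        ratio = np.ptp(out.data[0, core]) / np.ptp(sinusoid(0.055).data[0, core])
        assert abs(ratio - 1.0) < 0.05

    def test_constant_signal_removed(self):
        x = GraphSignalSequence(np.full((2, 600), 3.7), TR)
        out = bandpass_filter(x, 0.04, 0.07)
        assert np.abs(out.data).max() < 1e-6

    def test_out_of_band_sinusoid_attenuated(self):
        out = bandpass_filter(sinusoid(0.25), 0.04, 0.07)
        core = slice(200, 1000)
        ratio = np.ptp(out.data[0, core]) / np.ptp(sinusoid(0.25).data[0, core])
        assert ratio < 0.05

    def test_zero_phase(self):
        # a filtered in-band sinusoid stays aligned with the original
        x = sinusoid(0.055)
        out = bandpass_filter(x, 0.04, 0.07)
        core = slice(200, 1000)
        corr = np.corrcoef(x.data[0, core], out.data[0, core])[0, 1]
        assert corr > 0.999

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(sinusoid(0.05), 0.04, 0.8)


class TestGlobalSignalRegression:
    def test_identical_rows_vanish(self, rng):
        row = rng.normal(size=400)
        x = GraphSignalSequence(np.tile(row, (4, 1)), TR)
        out = global_signal_regression(x)
        assert np.abs(out.data).max() < 1e-8

    def test_residuals_orthogonal_to_global(self, rng):
        x = GraphSignalSequence(rng.normal(size=(6, 300)), TR)
        out = global_signal_regression(x)
        g = x.data.mean(axis=0)
        inner = out.data @ g
        np.testing.assert_allclose(inner, 0.0, atol=1e-8)

    def test_orthogonal_row_kept_up_to_intercept(self, rng):
        t = 400
        s = np.sin(2 * np.pi * np.arange(t) / 50)
        c = np.cos(2 * np.pi * np.arange(t) / 50)
        # rows sum to sin, so the global mean is sin/4 and the cos row is
        # orthogonal to it over whole cycles
        data = np.vstack([s, -s, c, s - c])
        out = global_signal_regression(GraphSignalSequence(data, TR))
        kept = out.data[2] - out.data[2].mean()
        np.testing.assert_allclose(kept, c - c.mean(), atol=1e-6)

    def test_row_permutation_commutes(self, rng):
        x = rng.normal(size=(5, 200))
        perm = rng.permutation(5)
        a = global_signal_regression(
            bandpass_filter(GraphSignalSequence(x, TR), 0.04, 0.07))
        b = global_signal_regression(
            bandpass_filter(GraphSignalSequence(x[perm], TR), 0.04, 0.07))
        np.testing.assert_allclose(a.data[perm], b.data, atol=1e-10)


class TestScaling:
    def test_minmax_hits_exact_bounds(self, rng):
        x = GraphSignalSequence(rng.uniform(-2, 2, size=(3, 100)), TR)
        scaled, _ = scale_session(x, "minmax01")
        assert scaled.data.min() == 0.0
        assert scaled.data.max() == 1.0

    def test_zscore_stats(self, rng):
        x = GraphSignalSequence(rng.normal(3, 5, size=(4, 500)), TR)
        scaled, _ = scale_session(x, "zscore")
        assert abs(scaled.data.mean()) < 1e-10
        assert abs(scaled.data.std() - 1) < 1e-10

    @pytest.mark.parametrize("mode", ["minmax01", "zscore"])
    def test_round_trip(self, rng, mode):
        x = GraphSignalSequence(rng.normal(size=(3, 80)), TR)
        scaled, scaler = scale_session(x, mode)
        np.testing.assert_allclose(scaler.inverse(scaled.data), x.data,
                                   atol=1e-10)

    def test_constant_session_rejected(self):
        with pytest.raises(ValueError):
            scale_session(GraphSignalSequence(np.ones((2, 50)), TR))


class TestWindowing:
    @pytest.mark.parametrize("t,t_p,t_f,expected", [
        (1200, 30, 30, 1141),  # reference session length
        (60, 30, 30, 1),       # boundary: exactly one window
        (600, 30, 30, 541),
    ])
    def test_sample_count_formula(self, rng, t, t_p, t_f, expected):
        x = GraphSignalSequence(rng.normal(size=(2, t)), TR)
        ds = windowize(x, t_p, t_f)
        assert len(ds) == expected

    def test_windows_contiguous(self, rng):
        x = GraphSignalSequence(rng.normal(size=(2, 50)), TR)
        ds = windowize(x, 10, 5)
        for i in range(len(ds)):
            np.testing.assert_array_equal(ds.inputs[i], x.data[:, i:i + 10])
            np.testing.assert_array_equal(ds.targets[i],
                                          x.data[:, i + 10:i + 15])

    def test_too_short_session_rejected(self, rng):
        x = GraphSignalSequence(rng.normal(size=(2, 20)), TR)
        with pytest.raises(ValueError, match="too short"):
            windowize(x, 15, 10)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(t=st.integers(10, 300), t_p=st.integers(1, 40),
           t_f=st.integers(1, 40))
    def test_sample_count_property(self, t, t_p, t_f):
        x = GraphSignalSequence(np.zeros((2, t)) + np.arange(t), TR)
        if t < t_p + t_f:
            with pytest.raises(ValueError):
                windowize(x, t_p, t_f)
        else:
            ds = windowize(x, t_p, t_f)
            assert len(ds) == t - t_p - t_f + 1
            # splitting always recovers every sample exactly once
            if len(ds) >= 10:
                split = split_samples(ds)
                sizes = [len(split.partition(p))
                         for p in ("train", "val", "test")]
                assert sum(sizes) == len(ds)


class TestSplit:
    def _session(self, rng, t, sid=0):
        return windowize(GraphSignalSequence(rng.normal(size=(2, t)), TR),
                         30, 30, session_id=sid)

    def test_reference_session_test_count(self, rng):
        ds = split_samples(self._session(rng, 1200))
        assert int((ds.split_index == 2).sum()) == 114

    def test_ten_short_sessions_total_test_count(self, rng):
        parts = [split_samples(self._session(rng, 600, sid=i))
                 for i in range(10)]
        total = sum(int((p.split_index == 2).sum()) for p in parts)
        assert total == 540

    def test_ten_samples_split_8_1_1(self, rng):
        x = GraphSignalSequence(rng.normal(size=(2, 24)), TR)
        ds = split_samples(windowize(x, 10, 5))  # 10 samples
        counts = [int((ds.split_index == c).sum()) for c in (0, 1, 2)]
        assert counts == [8, 1, 1]

    def test_partitions_exhaustive_and_ordered(self, rng):
        ds = split_samples(self._session(rng, 600))
        assert len(ds.partition("train")) + len(ds.partition("val")) + \
            len(ds.partition("test")) == len(ds)
        # temporal order: all train indices < val indices < test indices
        codes = ds.split_index
        assert (np.diff(np.flatnonzero(codes == 0)) > 0).all()
        first_val = np.flatnonzero(codes == 1)[0]
        first_test = np.flatnonzero(codes == 2)[0]
        assert np.flatnonzero(codes == 0)[-1] < first_val < first_test

    def test_gap_discards_boundary_samples(self, rng):
        ds = split_samples(self._session(rng, 600), gap=20)
        n_dropped = int((ds.split_index == -1).sum())
        assert n_dropped == 40
        # dropped samples sit immediately before the val and test blocks
        codes = ds.split_index
        first_val = np.flatnonzero(codes == 1)[0]
        assert (codes[first_val - 20:first_val] == -1).all()

    def test_concat_preserves_per_session_split(self, rng):
        parts = [self._session(rng, 600, sid=i) for i in range(3)]
        ds = split_samples(concat_windowed(parts))
        for sid in range(3):
            mask = ds.session_id == sid
            assert int((ds.split_index[mask] == 2).sum()) == 54
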