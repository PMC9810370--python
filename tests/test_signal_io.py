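import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import graphbold as gb
from graphbold.signal_io import (SessionTimeSeries, bandpass_filter,
                                 inverse_scale, load_prepared, make_windows,
                                 read_adjacency, read_session_tsv,
                                 save_prepared, scale, split_windows,
                                 write_adjacency, write_session_tsv)

TR = 0.72


def sinusoid(freq_hz, T=1200, tr=TR):
    t = np.arange(T) * tr
    return np.sin(2 * np.pi * freq_hz * t)


class TestBandpass:
    def test_passband_amplitude_retained(self):
        """A 0.055 Hz sinusoid lies inside the 0.04-0.07 Hz band and must
        survive with <5% amplitude loss away from the edge transients."""
        ts = SessionTimeSeries(sinusoid(0.055)[None, :], TR)
        out = bandpass_filter(ts, 0.04, 0.07).values[0]
        core = slice(200, 1000)  # discard edge transients
        # spectral amplitude at the driven frequency, via the DFT
        t = np.arange(1200)[core] * TR
        probe = np.exp(-2j * np.pi * 0.055 * t)
        amp_out = 2 * np.abs(np.mean(out[core] * probe))
        amp_in = 2 * np.abs(np.mean(sinusoid(0.055)[core] * probe))
        assert amp_out == pytest.approx(amp_in, rel=0.05)

    def test_stopband_attenuation(self):
        """Forward-backward order-5 Butterworth attenuates 0.2 Hz by
        >= 20 dB (frequency-response oracle)."""
        from scipy import signal as sps

        sos = sps.butter(5, [0.04, 0.07], btype="bandpass", fs=1 / TR,
                         output="sos")
        _, h = sps.sosfreqz(sos, worN=[0.2], fs=1 / TR)
        # filtfilt applies the magnitude response twice
        atten_db = -20 * np.log10(np.abs(h[0]) ** 2)
        assert atten_db >= 20
        ts = SessionTimeSeries(sinusoid(0.2)[None, :], TR)
        out = bandpass_filter(ts, 0.04, 0.07).values[0]
        assert np.abs(out[200:1000]).max() <= 10 ** (-20 / 20)

    def test_zero_input_zero_output(self):
        ts = SessionTimeSeries(np.zeros((3, 100)), TR)
        assert np.all(bandpass_filter(ts, 0.04, 0.07).values == 0)

    def test_linearity(self, rng):
        x = rng.normal(size=(2, 500))
        y = rng.normal(size=(2, 500))
        f = lambda v: bandpass_filter(SessionTimeSeries(v, TR), 0.04, 0.07).values
        lhs = f(2.5 * x - 1.5 * y)
        rhs = 2.5 * f(x) - 1.5 * f(y)
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    @pytest.mark.parametrize("band", [(0.0, 0.07), (0.04, 0.8), (0.07, 0.04)])
    def test_invalid_band_rejected(self, band):
        ts = SessionTimeSeries(np.ones((1, 50)), TR)
        with pytest.raises(ValueError):
            bandpass_filter(ts, *band)


class TestScaling:
    def test_minmax_maps_known_range(self):
        ts = SessionTimeSeries(np.array([[2.0, 3.0, 4.0]]), TR)
        scaled, params = scale(ts, "minmax01")
        np.testing.assert_allclose(scaled.values, [[0.0, 0.5, 1.0]])
        assert params.mode == "minmax01"

    def test_zscore_pooled_statistics(self, rng):
        sessions = [SessionTimeSeries(rng.normal(3, 2, size=(4, 200)), TR,
                                      f"s{i}") for i in range(3)]
        scaled, _ = scale(sessions, "zscore")
        pooled = np.concatenate([ts.values for ts in scaled], axis=1)
        assert np.abs(pooled.mean(axis=1)).max() < 1e-8
        assert np.abs(pooled.var(axis=1) - 1).max() < 1e-8

    @pytest.mark.parametrize("mode", ["minmax01", "zscore"])
    def test_round_trip_identity(self, rng, mode):
        sessions = [SessionTimeSeries(rng.normal(5, 3, size=(3, 100)), TR,
                                      f"s{i}") for i in range(2)]
        scaled, params = scale(sessions, mode)
        back = inverse_scale(scaled, params)
        for orig, rec in zip(sessions, back):
            np.testing.assert_allclose(rec.values, orig.values, rtol=1e-10)

    def test_constant_session_minmax_degenerate(self):
        ts = SessionTimeSeries(np.full((2, 10), 7.0), TR)
        with pytest.raises(ValueError, match="constant"):
            scale(ts, "minmax01")


class TestWindows:
    def test_hcp_sized_session_yields_1081_pairs(self, rng):
        ts = SessionTimeSeries(rng.normal(size=(4, 1200)), TR)
        assert len(make_windows(ts, 60, 60)) == 1081

    def test_enumerated_tiny_case(self):
        ts = SessionTimeSeries(np.arange(3.0)[None, :] + 1, TR)
        wins = make_windows(ts, 1, 1)
        assert len(wins) == 2
        assert wins[0].past[0, 0, 0] == 1 and wins[0].future[0, 0, 0] == 2
        assert wins[1].past[0, 0, 0] == 2 and wins[1].future[0, 0, 0] == 3

    def test_boundary_single_pair(self, rng):
        ts = SessionTimeSeries(rng.normal(size=(2, 7)), TR)
        assert len(make_windows(ts, 4, 3)) == 1

    def test_too_short_session_rejected(self, rng):
        ts = SessionTimeSeries(rng.normal(size=(2, 7)), TR)
        with pytest.raises(ValueError, match="T_p \\+ T_f"):
            make_windows(ts, 5, 3)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(1, 12), st.integers(1, 12), st.integers(0, 40))
    def test_count_formula_matches_enumeration(self, tp, tf, extra):
        """Stride-1 pair count is T - T_p - T_f + 1 for any feasible T."""
        T = tp + tf + extra
        ts = SessionTimeSeries(np.arange(float(2 * T)).reshape(2, T), TR)
        wins = make_windows(ts, tp, tf)
        brute = sum(1 for s in range(T) if s + tp + tf <= T)
        assert len(wins) == brute == T - tp - tf + 1

    def test_contiguity_reconstructs_source(self, rng):
        vals = rng.normal(size=(3, 40))
        ts = SessionTimeSeries(vals, TR)
        for w in make_windows(ts, 6, 4):
            s = w.origin[1]
            joined = np.concatenate([w.past, w.future], axis=1)[:, :, 0]
            np.testing.assert_array_equal(joined, vals[:, s:s + 10])


class TestSplit:
    def test_hcp_counts_108_test_pairs(self, rng):
        ts = SessionTimeSeries(rng.normal(size=(2, 1200)), TR)
        pairs = make_windows(ts, 60, 60)
        train, val, test = split_windows([pairs])
        assert (len(train), len(val), len(test)) == (865, 108, 108)

    def test_floor_rule_small_session(self, rng):
        ts = SessionTimeSeries(rng.normal(size=(2, 20)), TR)
        pairs = make_windows(ts, 6, 5)  # 10 pairs
        train, val, test = split_windows([pairs])
        assert (len(train), len(val), len(test)) == (8, 1, 1)

    def test_chronological_order(self, rng):
        ts = SessionTimeSeries(rng.normal(size=(2, 60)), TR)
        pairs = make_windows(ts, 5, 5)
        train, val, test = split_windows([pairs])
        assert max(w.origin[1] for w in train) < min(w.origin[1] for w in val)
        assert max(w.origin[1] for w in val) < min(w.origin[1] for w in test)

    def test_bad_fractions_rejected(self, rng):
        ts = SessionTimeSeries(rng.normal(size=(2, 30)), TR)
        pairs = make_windows(ts, 5, 5)
        with pytest.raises(ValueError):
            split_windows([pairs], fractions=(0.5, 0.5, 0.5))


class TestRoundTripIO:
    def test_session_tsv(self, tmp_path, rng):
        ts = SessionTimeSeries(rng.normal(size=(5, 30)), TR, "sess")
        write_session_tsv(ts, tmp_path / "sess.tsv")
        back = read_session_tsv(tmp_path / "sess.tsv")
        np.testing.assert_allclose(back.values, ts.values, rtol=1e-9)

    def test_adjacency_matrix_and_edge_list(self, tmp_path, small_graph):
        write_adjacency(small_graph, tmp_path / "adj.tsv")
        back = read_adjacency(tmp_path / "adj.tsv", kind="synthetic")
        np.testing.assert_allclose(back.weights, small_graph.weights,
                                   rtol=1e-9)
        labels = [f"R{i}" for i in range(small_graph.n_nodes)]
        with open(tmp_path / "edges.tsv", "w") as fh:
            for i in range(small_graph.n_nodes):
                for j in range(i + 1, small_graph.n_nodes):
                    if small_graph.weights[i, j] > 0:
                        fh.write(f"R{i}\tR{j}\t{small_graph.weights[i, j]:.12g}\n")
        back2 = read_adjacency(tmp_path / "edges.tsv", kind="synthetic",
                               labels=labels)
        np.testing.assert_allclose(back2.weights, small_graph.weights,
                                   rtol=1e-9)

    def test_prepared_hdf5(self, tmp_path, rng):
        ts = SessionTimeSeries(rng.normal(size=(3, 40)), TR, "s0")
        pairs = make_windows(ts, 5, 5)
        train, val, test = split_windows([pairs])
        save_prepared(tmp_path / "prep.h5",
                      {"train": train, "val": val, "test": test})
        back = load_prepared(tmp_path / "prep.h5")
        assert len(back["train"]) == len(train)
        np.testing.assert_allclose(back["test"][0].past, test[0].past)
        assert back["test"][0].origin == test[0].origin
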