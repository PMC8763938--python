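"""Epoch extraction, window statistics and the multiple-comparison helper."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from dualpath import synthgen
from dualpath.perievent import (
    PeriEventTensor,
    WindowSpec,
    animal_means,
    baseline_subtract,
    extract_epochs,
    holm_sidak,
    layer_difference,
    long_epochs,
    ordinal_split,
    validate_events,
    window_stats,
)
from dualpath.photometry import ConditionedTrace

FS = 50.0


def _trace(values, t0=0.0):
    return ConditionedTrace(fs=FS, values=np.asarray(values, dtype=float), t0=t0)


def _events(times, event_type="open_entry"):
    df = pd.DataFrame({"time": times, "event_type": event_type})
    df["ordinal"] = np.arange(1, len(df) + 1)
    return df


class TestExtractEpochs:
    def test_12s_epoch_is_600_samples(self):
        tr = _trace(np.zeros(int(100 * FS)))
        tensor = extract_epochs(tr, _events([50.0]), window=(-6.0, 6.0))
        assert tensor.epochs.shape == (1, 600)

    def test_boundary_event_dropped(self):
        tr = _trace(np.zeros(int(100 * FS)))
        tensor = extract_epochs(tr, _events([3.0, 50.0]), window=(-6.0, 6.0))
        assert tensor.n_events == 1
        assert len(tensor.dropped) == 1
        assert "outside" in tensor.dropped[0]["reason"]

    def test_impulse_at_event_peaks_at_lag_zero(self):
        n = int(200 * FS)
        vals = np.zeros(n)
        times = [40.0, 90.0, 150.0]
        for t in times:
            vals[int(round(t * FS))] = 1.0
        tensor = extract_epochs(_trace(vals), _events(times), window=(-6.0, 6.0))
        mean = tensor.epochs.mean(axis=0)
        lag0 = int(round(6.0 * FS))
        assert np.argmax(mean) == lag0

    def test_row_plus_dropped_equals_events(self):
        tr = _trace(np.zeros(int(60 * FS)))
        ev = _events([1.0, 10.0, 30.0, 59.0])
        tensor = extract_epochs(tr, ev, window=(-6.0, 6.0))
        assert tensor.n_events + len(tensor.dropped) == len(ev)

    def test_no_valid_events_yields_empty_tensor(self):
        tr = _trace(np.zeros(int(10 * FS)))
        tensor = extract_epochs(tr, _events([1.0]), window=(-6.0, 6.0))
        assert tensor.n_events == 0

    def test_respects_trace_t0(self):
        vals = np.zeros(int(60 * FS))
        vals[int(20 * FS)] = 1.0  # at absolute time 30 s for t0=10
        tensor = extract_epochs(_trace(vals, t0=10.0), _events([30.0]), window=(-6.0, 6.0))
        assert tensor.epochs[0, int(6 * FS)] == 1.0


class TestBaselineSubtract:
    def test_bl_window_means_are_zero(self, rng):
        epochs = rng.standard_normal((10, 600))
        tensor = PeriEventTensor(epochs=epochs, window=(-6.0, 6.0), fs=FS,
                                 events=_events(np.arange(10) * 20.0 + 10.0))
        out = baseline_subtract(tensor, (-6.0, -4.0))
        sl = out.window_slice((-6.0, -4.0))
        assert np.max(np.abs(out.epochs[:, sl].mean(axis=1))) < 1e-12

    def test_constant_epoch_becomes_zero(self):
        tensor = PeriEventTensor(epochs=np.full((3, 600), 4.2), window=(-6.0, 6.0),
                                 fs=FS, events=_events([10.0, 30.0, 50.0]))
        out = baseline_subtract(tensor)
        np.testing.assert_allclose(out.epochs, 0.0, atol=1e-12)

    def test_step_epoch_window_means(self):
        rel = -6.0 + np.arange(600) / FS
        step = (rel >= 0).astype(float)  # unit step at lag 0
        tensor = PeriEventTensor(epochs=step[None, :], window=(-6.0, 6.0), fs=FS,
                                 events=_events([30.0]))
        out = baseline_subtract(tensor)
        spec = WindowSpec()
        pre = out.epochs[0, out.window_slice(spec.pre)].mean()
        post = out.epochs[0, out.window_slice((2.0, 4.0))].mean()
        assert pre == 0.0
        assert post == 1.0

    def test_outside_window_rejected(self):
        tensor = PeriEventTensor(epochs=np.zeros((1, 600)), window=(-6.0, 6.0),
                                 fs=FS, events=_events([10.0]))
        with pytest.raises(ValueError):
            baseline_subtract(tensor, (-8.0, -6.0))


class TestWindowStats:
    def _tensor(self, epochs, times):
        t = PeriEventTensor(epochs=epochs, window=(-6.0, 6.0), fs=FS, events=_events(times))
        return baseline_subtract(t)

    def test_post_window_depends_on_event_type(self):
        spec = WindowSpec()
        assert spec.post_for("open_entry") == (2.0, 4.0)
        assert spec.post_for("closed_entry") == (0.0, 4.0)
        assert spec.post_for("rear") == (2.0, 4.0)

    def test_unknown_event_type_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            WindowSpec().post_for("teleport")

    def test_zero_tensor_gives_zero_stats(self):
        tensor = self._tensor(np.zeros((4, 600)), [10.0, 20.0, 30.0, 40.0])
        stats = window_stats(tensor, WindowSpec(), "open_entry")
        assert (stats["value"] == 0.0).all()
        assert set(stats["window"]) == {"bl", "pre", "post"}

    def test_requires_baseline_subtraction(self):
        tensor = PeriEventTensor(epochs=np.zeros((1, 600)), window=(-6.0, 6.0),
                                 fs=FS, events=_events([10.0]))
        with pytest.raises(ValueError, match="baseline"):
            window_stats(tensor, WindowSpec(), "open_entry")

    def test_programmed_flat_then_up_recovery(self):
        cfg = synthgen.PatternSessionConfig(
            duration=1200.0, n_open=50, n_closed=0, amplitude=1.0,
            noise_sd=0.1, seed=42,
        )
        sup, _, events, _ = synthgen.gen_pattern_session(cfg)
        tensor = baseline_subtract(
            extract_epochs(sup, events, event_type="open_entry"), (-6.0, -4.0)
        )
        spec = WindowSpec()
        stats = window_stats(tensor, spec, "open_entry")
        pre = stats.loc[stats["window"] == "pre", "value"]
        post = stats.loc[stats["window"] == "post", "value"]
        # independent oracle: raised-cosine bump on the same half-open grid
        rel = 2.0 + np.arange(int(2 * FS)) / FS
        expected = np.mean(1.0 * 0.5 * (1 - np.cos(2 * np.pi * (rel - 1.0) / 4.0)))
        se = 0.1 / np.sqrt(int(2 * FS)) / np.sqrt(50)
        assert abs(pre.mean()) < 3 * (0.1 / np.sqrt(int(2 * FS) * 50))
        assert abs(post.mean() - expected) < 3 * se + 0.01

    def test_animal_aggregation(self):
        ev = _events([10.0, 20.0, 30.0, 40.0])
        ev["animal"] = ["m1", "m1", "m2", "m2"]
        epochs = np.zeros((4, 600))
        epochs[0, :] = 1.0 - 1.0  # after bl-subtract all zero anyway
        tensor = PeriEventTensor(epochs=epochs, window=(-6.0, 6.0), fs=FS, events=ev)
        tensor = baseline_subtract(tensor)
        stats = window_stats(tensor, WindowSpec(), "open_entry")
        agg = animal_means(stats)
        assert set(agg["animal"]) == {"m1", "m2"}


class TestLayerDifference:
    def _pair(self, sup_vals, deep_vals):
        times = [30.0]
        sup = baseline_subtract(extract_epochs(_trace(sup_vals), _events(times)))
        deep = baseline_subtract(extract_epochs(_trace(deep_vals), _events(times)))
        return sup, deep

    def test_identical_layers_zero_difference(self, rng):
        v = rng.standard_normal(int(60 * FS))
        sup, deep = self._pair(v, v)
        diff, _ = layer_difference(sup, deep, WindowSpec(), "open_entry")
        np.testing.assert_allclose(diff.epochs, 0.0, atol=1e-12)

    def test_post_difference_arithmetic(self):
        rel = -6.0 + np.arange(int(60 * FS)) / FS  # absolute time here
        sup_vals = np.zeros(int(60 * FS))
        deep_vals = np.zeros(int(60 * FS))
        post_idx = slice(int((30.0 + 2.0) * FS), int((30.0 + 4.0) * FS))
        sup_vals[post_idx] = 1.0
        deep_vals[post_idx] = -1.0
        sup, deep = self._pair(sup_vals, deep_vals)
        _, stats = layer_difference(sup, deep, WindowSpec(), "open_entry")
        post = stats.loc[stats["window"] == "post", "value"].iloc[0]
        assert abs(post - 2.0) < 1e-9  # positive = superficial bias

    def test_antisymmetry(self, rng):
        a = rng.standard_normal(int(60 * FS))
        b = rng.standard_normal(int(60 * FS))
        sup, deep = self._pair(a, b)
        d1, s1 = layer_difference(sup, deep, WindowSpec(), "open_entry")
        d2, s2 = layer_difference(deep, sup, WindowSpec(), "open_entry")
        np.testing.assert_allclose(d1.epochs, -d2.epochs, atol=1e-12)
        np.testing.assert_allclose(s1["value"].to_numpy(), -s2["value"].to_numpy(), atol=1e-12)

    def test_mismatched_events_rejected(self):
        sup = baseline_subtract(extract_epochs(_trace(np.zeros(3000)), _events([20.0])))
        deep = baseline_subtract(extract_epochs(_trace(np.zeros(3000)), _events([30.0])))
        with pytest.raises(ValueError, match="identical events"):
            layer_difference(sup, deep, WindowSpec(), "open_entry")


class TestOrdinalSplit:
    def test_five_entries(self):
        ev = _events([10.0, 20.0, 30.0, 40.0, 50.0])
        out = ordinal_split(ev, "open_entry")
        assert len(out["first"]) == 1 and len(out["last"]) == 1
        assert len(out["middle"]) == 3
        assert not out["excluded"]

    def test_two_entries_empty_middle(self):
        out = ordinal_split(_events([10.0, 20.0]), "open_entry")
        assert out["middle"] == []
        assert not out["excluded"]

    def test_single_entry_flagged_excluded(self):
        out = ordinal_split(_events([10.0]), "open_entry")
        assert out["first"] == out["last"]
        assert out["excluded"]

    def test_zero_events(self):
        out = ordinal_split(_events([]), "open_entry")
        assert out["first"] == [] and out["middle"] == [] and out["last"] == []


class TestLongEpochs:
    def test_20s_epoch_is_1000_samples(self):
        tr = _trace(np.zeros(int(100 * FS)))
        tensor = long_epochs(tr, _events([50.0]))
        assert tensor.epochs.shape == (1, 1000)
        assert tensor.bl_window == (-10.0, -8.0)

    def test_bl_means_zero(self, rng):
        tr = _trace(rng.standard_normal(int(100 * FS)))
        tensor = long_epochs(tr, _events([30.0, 60.0]))
        sl = tensor.window_slice((-10.0, -8.0))
        assert np.max(np.abs(tensor.epochs[:, sl].mean(axis=1))) < 1e-12

    def test_programmed_return_to_baseline(self):
        cfg = synthgen.PatternSessionConfig(
            duration=1200.0, n_open=40, n_closed=0, amplitude=1.0, noise_sd=0.05, seed=9
        )
        sup, _, events, _ = synthgen.gen_pattern_session(cfg)
        tensor = long_epochs(sup, events, event_type="open_entry")
        final = tensor.epochs[:, tensor.window_slice((8.0, 10.0))].mean(axis=1)
        se = 0.05 / np.sqrt(int(2 * FS)) / np.sqrt(tensor.n_events)
        assert abs(final.mean()) < 3 * se + 0.005


class TestHolmSidak:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_sidak([0.04]), [0.04])

    def test_closed_form_pair(self):
        adj = holm_sidak([0.01, 0.04])
        np.testing.assert_allclose(adj, [1 - 0.99**2, 0.04], atol=1e-12)
        assert abs(adj[0] - 0.0199) < 1e-10

    def test_all_ones(self):
        np.testing.assert_allclose(holm_sidak([1.0, 1.0, 1.0]), 1.0)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(12)
        _, adj, _, _ = multipletests(p, method="holm-sidak")
        np.testing.assert_allclose(holm_sidak(p), adj, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_sidak([0.1, 1.2])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
    def test_monotone_in_rank_and_dominates_raw(self, pvals):
        p = np.asarray(pvals)
        adj = holm_sidak(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestValidateEvents:
    def test_unknown_type_rejected(self):
        df = pd.DataFrame({"time": [1.0], "event_type": ["warp"]})
        with pytest.raises(ValueError, match="unknown"):
            validate_events(df)

    def test_decreasing_times_rejected(self):
        df = pd.DataFrame({"time": [5.0, 1.0], "event_type": ["rear", "rear"]})
        with pytest.raises(ValueError, match="increasing"):
            validate_events(df)
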