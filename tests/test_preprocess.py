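import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from earlyerp.containers import ContinuousRecording, EpochSet, RejectionReport
from earlyerp.preprocess import (
    bandpass_filter,
    baseline_correct,
    correct_trigger_lag,
    drop_task_trials,
    enforce_min_trials,
    epoch,
    epoch_times,
    reject_artifacts,
    remove_blinks,
    rereference,
)
from earlyerp.simulate import simulate_recording
from conftest import simple_plan

FS = 512.0


def make_rec(data, triggers=None, names=None):
    n_ch = data.shape[0]
    names = names or [f"ch{i}" for i in range(n_ch)]
    if triggers is None:
        triggers = pd.DataFrame(
            {"sample": [600], "category": ["spider"], "location": ["FIX"], "dot_change": [False]}
        )
    return ContinuousRecording(
        data=data, sampling_rate=FS, channel_names=names, triggers=triggers
    )


def make_epochs(data, meta=None):
    nt, nc, ns = data.shape
    times = epoch_times(FS)[:ns]
    meta = meta if meta is not None else pd.DataFrame(
        {
            "participant": 0,
            "category": ["spider", "wheel"] * (nt // 2) + ["spider"] * (nt % 2),
            "location": "FIX",
            "dot_change": False,
            "kept": True,
        }
    )
    return EpochSet(
        data=data, times=times, channel_names=[f"ch{i}" for i in range(nc)],
        metadata=meta, sampling_rate=FS,
    )


class TestRereference:
    def test_all_channels_equal_reference_gives_zero(self):
        x = np.tile(np.sin(np.arange(2000) / 30.0), (4, 1))
        out = rereference(make_rec(x.copy()), "ch2")
        assert np.allclose(out.data, 0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        rec = make_rec(rng.normal(size=(5, 1500)))
        once = rereference(rec, "ch0")
        twice = rereference(once, "ch0")
        assert np.allclose(once.data, twice.data)
        assert np.allclose(once.data[0], 0.0)

    def test_channel_differences_invariant(self):
        rng = np.random.default_rng(1)
        rec = make_rec(rng.normal(size=(5, 1200)))
        out = rereference(rec, "ch4")
        assert np.allclose(rec.data[1] - rec.data[2], out.data[1] - out.data[2])

    def test_unknown_channel(self):
        rec = make_rec(np.zeros((3, 800)))
        with pytest.raises(KeyError):
            rereference(rec, "nope")


class TestBandpassFilter:
    """Oracle: the two-pass magnitude response |H(f)|^2 of the designed
    second-order Butterworth band-pass, evaluated from its transfer
    function."""

    @pytest.mark.parametrize("freq", [10.0, 50.0])
    def test_sinusoid_attenuation_matches_transfer_function(self, freq):
        sos = sps.butter(2, [0.01, 30.0], btype="bandpass", fs=FS, output="sos")
        _, h = sps.sosfreqz(sos, worN=[freq], fs=FS)
        expected = np.abs(h[0]) ** 2  # forward + reverse pass
        t = np.arange(int(240 * FS)) / FS
        x = np.sin(2 * np.pi * freq * t)[None, :]
        out = bandpass_filter(make_rec(x, names=["ch0"]))
        mid = slice(len(t) // 3, -len(t) // 3)
        ratio = np.sqrt(np.mean(out.data[0, mid] ** 2)) / np.sqrt(np.mean(x[0, mid] ** 2))
        assert ratio == pytest.approx(expected, rel=0.02)
        if freq == 10.0:
            assert ratio > 0.95  # mid-band within 5%
        else:
            assert ratio < 0.12  # stop-band strongly attenuated

    def test_zero_phase_keeps_gaussian_peak_latency(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.exp(-0.5 * ((t - 10.0) / 0.0085) ** 2)[None, :]  # 20 ms FWHM
        out = bandpass_filter(make_rec(x, names=["ch0"]))
        shift_ms = abs(t[np.argmax(out.data[0])] - 10.0) * 1000
        assert shift_ms <= 2.0

    def test_invalid_band_edges(self):
        rec = make_rec(np.zeros((1, 4000)), names=["ch0"])
        for lo, hi in [(0.0, 30.0), (30.0, 10.0), (1.0, 400.0)]:
            with pytest.raises(ValueError):
                bandpass_filter(rec, low=lo, high=hi)


class TestTriggerLag:
    def trig(self, samples):
        return pd.DataFrame(
            {"sample": samples, "category": "spider", "location": "FIX", "dot_change": False}
        )

    def test_zero_lag_identity(self):
        t = self.trig([100, 500])
        out = correct_trigger_lag(t, 0.0, FS)
        assert list(out["sample"]) == [100, 500]

    def test_8ms_at_512hz_is_4_samples(self):
        out = correct_trigger_lag(self.trig([100]), 8.0, FS)
        assert out["sample"].iloc[0] == 104

    def test_one_sample_period(self):
        out = correct_trigger_lag(self.trig([100]), 1000.0 / FS, FS)
        assert out["sample"].iloc[0] == 101

    def test_negative_lag_and_overflow(self):
        with pytest.raises(ValueError):
            correct_trigger_lag(self.trig([100]), -1.0, FS)
        with pytest.raises(ValueError):
            correct_trigger_lag(self.trig([995]), 20.0, FS, n_samples=1000)


class TestEpoching:
    def test_epoch_grid_at_512hz(self):
        times = epoch_times(512.0)
        assert len(times) == 154
        assert times[0] == -100.0
        assert np.allclose(np.diff(times), 1000.0 / 512.0)
        assert times[-1] < 200.0

    def test_constant_recording_zero_after_baseline(self):
        rec = make_rec(np.full((3, 2000), 7.5))
        es = baseline_correct(epoch(rec))
        assert np.allclose(es.data, 0.0)

    def test_baseline_mean_zero_and_idempotent(self):
        rng = np.random.default_rng(2)
        rec = make_rec(rng.normal(size=(3, 3000)))
        es = baseline_correct(epoch(rec))
        base = es.times < 0
        assert np.allclose(es.data[:, :, base].mean(axis=2), 0.0, atol=1e-12)
        again = baseline_correct(es)
        assert np.allclose(es.data, again.data)

    def test_trigger_too_close_to_edge(self):
        trig = pd.DataFrame(
            {"sample": [10], "category": ["spider"], "location": ["FIX"], "dot_change": [False]}
        )
        rec = make_rec(np.zeros((2, 500)), triggers=trig)
        with pytest.raises(ValueError):
            epoch(rec)


class TestDropTaskTrials:
    def flags(self, dot_positions, n):
        meta = pd.DataFrame(
            {
                "participant": 0,
                "category": "spider",
                "location": "FIX",
                "dot_change": [i in dot_positions for i in range(n)],
            }
        )
        es = make_epochs(np.zeros((n, 2, 154)), meta=meta)
        return set(np.flatnonzero(drop_task_trials(es).flags["dot_task"]))

    def test_dot_and_successor_flagged(self):
        assert self.flags({10, 50}, 60) == {10, 11, 50, 51}

    def test_dot_on_last_trial(self):
        assert self.flags({59}, 60) == {59}

    def test_consecutive_dots(self):
        assert self.flags({10, 11}, 60) == {10, 11, 12}


class TestRemoveBlinks:
    def _blinky_epochs(self, layout, with_blinks=True):
        params_kw = dict(blink_rate=120.0 if with_blinks else 0.0, seed=9)
        from earlyerp.simulate import SimParams

        params = SimParams(
            component_templates=(),
            noise_sd=2.0, pink_sd=0.0, alpha_amplitude=0.0, prestim_alpha_uv=0.0,
            drift_amplitude=0.0, amplitude_scale_sd=0.0, participant_effect_sd=0.0,
            trigger_lag_ms=0.0, **params_kw,
        )
        rec, _ = simulate_recording(simple_plan(8), layout, params)
        return baseline_correct(epoch(rec))

    def test_no_blinks_regression_is_near_identity(self, layout):
        es = self._blinky_epochs(layout, with_blinks=False)
        out = remove_blinks(es, method="regression")
        scalp = slice(0, 64)
        rms_in = np.sqrt((es.data[:, scalp] ** 2).mean())
        assert np.sqrt(((out.data - es.data)[:, scalp] ** 2).mean()) < 0.05 * rms_in

    def test_planted_blinks_reduced_on_frontal(self, layout):
        """Blink variance on frontal channels drops by >= 75% after
        regression removal (re-baselined, as in the pipeline)."""
        es = self._blinky_epochs(layout, with_blinks=True)
        out = baseline_correct(remove_blinks(es, method="regression"))
        frontal = [es.channel_names.index(c) for c in ("Fp1", "Fp2", "Fpz", "AF3", "AF4")]
        rms_pre = np.sqrt((es.data[:, frontal] ** 2).mean())
        rms_post = np.sqrt((out.data[:, frontal] ** 2).mean())
        assert rms_post <= 0.25 * rms_pre
        # posterior channels carry no blink loading: nearly untouched
        post = [es.channel_names.index(c) for c in ("Oz", "O1", "O2", "POz")]
        rms_pre_p = np.sqrt((es.data[:, post] ** 2).mean())
        rms_post_p = np.sqrt((out.data[:, post] ** 2).mean())
        assert abs(rms_post_p - rms_pre_p) < 0.05 * rms_pre_p

    def test_ica_backend_reduces_blinks(self, layout):
        es = self._blinky_epochs(layout, with_blinks=True)
        out = baseline_correct(remove_blinks(es, method="ica", random_state=0))
        frontal = [es.channel_names.index(c) for c in ("Fp1", "Fp2", "Fpz")]
        rms_pre = np.sqrt((es.data[:, frontal] ** 2).mean())
        rms_post = np.sqrt((out.data[:, frontal] ** 2).mean())
        assert rms_post <= 0.5 * rms_pre

    def test_missing_eog(self):
        es = make_epochs(np.zeros((4, 3, 154)))
        with pytest.raises(ValueError):
            remove_blinks(es)


class TestRejectArtifacts:
    def test_absolute_threshold(self):
        data = np.random.default_rng(3).normal(0, 5, (10, 4, 154))
        data[3, 1, 10] = 150.0
        es = make_epochs(data)
        rep = reject_artifacts(es)
        assert rep.flags.loc[3, "abs_threshold"]
        assert rep.flags["abs_threshold"].sum() == 1

    def test_identical_trials_no_sd_flags(self):
        data = np.tile(np.sin(np.arange(154) / 5.0), (12, 3, 1))
        rep = reject_artifacts(make_epochs(data))
        assert not rep.flags["global_sd"].any()

    def test_inflated_range_trial_flagged(self):
        rng = np.random.default_rng(4)
        data = rng.normal(0, 5, (200, 4, 154))
        data[77] *= 10.0
        rep = reject_artifacts(make_epochs(data))
        flagged = set(np.flatnonzero(rep.flags["global_sd"]))
        assert flagged == {77}

    def test_pooled_mode_flags_inflated_trial(self):
        rng = np.random.default_rng(5)
        data = rng.normal(0, 5, (100, 4, 154))
        data[13] *= 10.0
        rep = reject_artifacts(make_epochs(data), pooled=True)
        assert rep.flags.loc[13, "global_sd"]

    def test_needs_two_trials(self):
        with pytest.raises(ValueError):
            reject_artifacts(make_epochs(np.zeros((1, 2, 154))))

    def test_flags_accumulate_as_union(self):
        """Task-trial and artifact flags combine; kept is their complement."""
        rng = np.random.default_rng(6)
        data = rng.normal(0, 5, (30, 3, 154))
        data[20, 0, 5] = 500.0
        meta = pd.DataFrame(
            {
                "participant": 0,
                "category": "spider",
                "location": "FIX",
                "dot_change": [i == 4 for i in range(30)],
            }
        )
        es = make_epochs(data, meta=meta)
        rep = drop_task_trials(es)
        rep = reject_artifacts(es, report=rep)
        bad = set(np.flatnonzero(~rep.kept))
        assert {4, 5, 20} <= bad


class TestMinTrials:
    def counts(self, mapping):
        rows = [
            {"participant": p, "category": c, "location": l, "n_kept": n}
            for (p, c, l), n in mapping.items()
        ]
        return pd.DataFrame(rows)

    def test_passing_counts_included(self):
        c = self.counts({(0, "spider", "FIX"): 180, (0, "wheel", "FIX"): 181})
        out = enforce_min_trials(c, 150)
        assert out.loc[out["participant"] == 0, "included"].item()

    def test_boundary_exclusion(self):
        c = self.counts({(0, "spider", "FIX"): 149, (0, "wheel", "FIX"): 300})
        assert not enforce_min_trials(c, 150)["included"].item()
        assert enforce_min_trials(c, 0)["included"].all()
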