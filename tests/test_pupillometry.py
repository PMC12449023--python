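"""Pupil pipeline: filtering, epoching, exclusion rules, OLS recovery."""

import numpy as np
import pandas as pd
import pytest

from nlrl.pupillometry import (EpochMatrix, PupilSession, epoch_and_baseline,
                               preprocess_session, synth_pupil_session,
                               timepoint_regression)

FS = 500


def _session(samples, gaps=None, onsets=(1000,), meta=None):
    n = len(samples)
    is_gap = np.zeros(n, dtype=bool)
    if gaps is not None:
        for lo, hi in gaps:
            is_gap[lo:hi] = True
    meta = meta if meta is not None else pd.DataFrame({"x": np.zeros(len(onsets))})
    return PupilSession(samples=np.asarray(samples, float), is_gap=is_gap,
                        event_onsets=np.asarray(onsets), trial_meta=meta)


def _design(n_trials, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "trial_number": np.arange(n_trials, dtype=float),
        "outcome": rng.random(n_trials),
        "pe_signed": rng.normal(0, 0.3, n_trials),
        "learning_rate": rng.random(n_trials),
    })


class TestPreprocess:
    def test_gap_interpolation_preserves_constant(self):
        s = _session(np.full(5000, 3.7), gaps=[(1000, 1500)])
        out = preprocess_session(s, zscore=False)
        assert np.allclose(out, 3.7)
        with pytest.raises(ValueError):
            preprocess_session(s)  # zero variance: z-transform undefined

    def test_all_gap_session_rejected(self):
        s = _session(np.zeros(2000), gaps=[(0, 2000)])
        with pytest.raises(ValueError):
            preprocess_session(s)

    def test_stopband_attenuates_10hz(self):
        t = np.arange(20000) / FS
        s = _session(np.sin(2 * np.pi * 10 * t))
        out = preprocess_session(s, zscore=False)
        assert out[2000:-2000].std() < 0.1 * np.sin(2 * np.pi * 10 * t).std()

    def test_passband_preserves_half_hz(self):
        t = np.arange(20000) / FS
        x = np.sin(2 * np.pi * 0.5 * t)
        s = _session(x)
        out = preprocess_session(s, zscore=False)
        core = slice(2000, -2000)
        assert out[core].std() == pytest.approx(x[core].std(), rel=0.05)

    def test_idempotent_on_clean_filtered_trace(self):
        rng = np.random.default_rng(0)
        t = np.arange(30000) / FS
        raw = np.sin(2 * np.pi * 0.3 * t) + 0.2 * np.sin(2 * np.pi * 1.1 * t)
        once = preprocess_session(_session(raw))
        twice = preprocess_session(_session(once))
        assert np.allclose(once[1000:-1000], twice[1000:-1000], atol=0.02)


class TestEpoching:
    def test_flat_trace_gives_zero_epochs(self):
        s = _session(np.full(8000, 1.0), onsets=[2000])
        em = epoch_and_baseline(np.full(8000, 1.0), s, window_ms=(0, 4000))
        assert np.allclose(em.epochs[0], 0.0)

    def test_exclusion_threshold_is_strictly_above_half(self):
        n = 10000
        win = (0, 6000)  # 3000 samples
        on = 2000
        exactly_half = [(on, on + 1500)]
        over_half = [(on, on + 1501)]
        for gaps, expect in [(exactly_half, False), (over_half, True)]:
            s = _session(np.random.default_rng(1).normal(size=n), gaps=gaps,
                         onsets=[on])
            em = epoch_and_baseline(s.samples, s, window_ms=win)
            assert bool(em.excluded[0]) is expect

    def test_session_exclusion_above_half_of_trials(self):
        n = 200000
        onsets = [2000 + 4000 * k for k in range(41)]
        # gap out 21 of 41 trials (51%) entirely
        gaps = [(o, o + 3000) for o in onsets[:21]]
        s = _session(np.random.default_rng(2).normal(size=n), gaps=gaps,
                     onsets=onsets)
        em = epoch_and_baseline(s.samples, s, window_ms=(0, 6000))
        assert em.session_excluded
        assert em.excluded.sum() >= 21

    def test_window_past_recording_flags_not_fatal(self):
        s = _session(np.zeros(4000), onsets=[3500])
        em = epoch_and_baseline(np.zeros(4000), s, window_ms=(0, 6000))
        assert em.excluded[0]


class TestRegression:
    def test_exact_recovery_from_noise_free_epochs(self):
        rng = np.random.default_rng(3)
        design = _design(40)
        beta = {"intercept": 0.5, "trial_number": -0.2, "outcome": 0.8,
                "pe_signed": 0.3, "learning_rate": -0.6}
        from nlrl.pupillometry import _zscore_design
        Xz, cols = _zscore_design(design)
        amp = Xz @ np.array([beta[c] for c in cols]) + beta["intercept"]
        epochs = np.tile(amp[:, None], (1, 100))
        em = EpochMatrix(epochs=epochs, time_ms=np.arange(100) * 2.0,
                         interp_frac=np.zeros(40), excluded=np.zeros(40, bool),
                         session_excluded=False)
        res = timepoint_regression(em, design)
        for name, b in beta.items():
            assert np.allclose(res["coef"][name], b, atol=1e-9), name

    def test_rank_deficient_design_names_columns(self):
        design = _design(30)
        design["dup"] = design["outcome"] * 2.0
        em = EpochMatrix(epochs=np.random.default_rng(0).normal(size=(30, 10)),
                         time_ms=np.arange(10) * 2.0, interp_frac=np.zeros(30),
                         excluded=np.zeros(30, bool), session_excluded=False)
        with pytest.raises(ValueError, match="outcome|dup"):
            timepoint_regression(em, design)

    def test_permuted_design_yields_null_coefficients(self):
        truth = {"trial_number": 0.0, "outcome": 1.0, "pe_signed": 0.5,
                 "learning_rate": -0.8}
        # time points within a session share trials, so only one independent
        # reading (the kernel plateau) is taken per regressor and permutation
        n_sig = n_tot = 0
        for perm_seed in range(12):
            design = _design(48, seed=10)
            sess = synth_pupil_session(design, {**truth}, noise_sd=0.3,
                                       blink_rate=0.0, seed=perm_seed)
            cleaned = preprocess_session(sess)
            em = epoch_and_baseline(cleaned, sess)
            rng = np.random.default_rng(100 + perm_seed)
            shuffled = design.sample(frac=1.0, random_state=rng.integers(1 << 30)
                                     ).reset_index(drop=True)
            res = timepoint_regression(em, shuffled)
            tcrit = 2.02  # two-sided alpha=0.05, dof ~ 43
            tvals = res["tstat"].loc[3000.0, list(design.columns)].to_numpy()
            n_sig += int(np.sum(np.abs(tvals) > tcrit))
            n_tot += len(tvals)
        assert n_sig / n_tot <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_tot)


class TestSynthSession:
    def test_deterministic(self):
        d = _design(10)
        a = synth_pupil_session(d, {"trial_number": 0.1, "outcome": 0.5,
                                    "pe_signed": 0.2, "learning_rate": -0.3},
                                noise_sd=0.2, blink_rate=0.1, seed=5)
        b = synth_pupil_session(d, {"trial_number": 0.1, "outcome": 0.5,
                                    "pe_signed": 0.2, "learning_rate": -0.3},
                                noise_sd=0.2, blink_rate=0.1, seed=5)
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(a.is_gap, b.is_gap)

    def test_zero_noise_recovery_at_plateau(self):
        design = _design(40, seed=4)
        truth = {"trial_number": -0.2, "outcome": 0.9, "pe_signed": 0.4,
                 "learning_rate": -0.7}
        sess = synth_pupil_session(design, truth, noise_sd=0.0, blink_rate=0.0,
                                   seed=0)
        # epoch the raw trace directly: OLS at the kernel plateau is exact
        em = epoch_and_baseline(sess.samples, sess)
        res = timepoint_regression(em, design)
        plateau = res["coef"].loc[3000.0]  # kernel = 1 from 1.5 s to 5 s
        for name, b in truth.items():
            assert plateau[name] == pytest.approx(b, abs=1e-9)

    def test_moderate_noise_recovery_within_ten_percent(self):
        design = _design(60, seed=8)
        truth = {"trial_number": -0.5, "outcome": 1.2, "pe_signed": 0.8,
                 "learning_rate": -1.0}
        sess = synth_pupil_session(design, truth, noise_sd=0.15, blink_rate=0.02,
                                   seed=3)
        cleaned = preprocess_session(sess)
        em = epoch_and_baseline(cleaned, sess)
        res = timepoint_regression(em, design)
        # the z-transform rescales coefficients by the filtered trace's SD
        scale = preprocess_session(sess, zscore=False).std()
        plateau = res["coef"].loc[3000.0] * scale
        for name, b in truth.items():
            assert plateau[name] == pytest.approx(b, rel=0.10), name

    def test_blinked_out_trials_excluded_and_rest_recovered(self):
        design = _design(40, seed=2)
        truth = {"trial_number": 0.0, "outcome": 1.0, "pe_signed": 0.5,
                 "learning_rate": -0.5}
        sess = synth_pupil_session(design, truth, noise_sd=0.0, blink_rate=0.0,
                                   seed=0)
        # gap out 4 trials beyond the 50% threshold by hand
        for k in range(4):
            on = sess.event_onsets[k]
            sess.is_gap[on:on + 1600] = True
        cleaned = preprocess_session(sess, zscore=False)
        em = epoch_and_baseline(cleaned, sess, window_ms=(0, 3000))
        assert em.excluded[:4].all() and not em.excluded[4:].any()
        res = timepoint_regression(em, design)
        plateau = res["coef"].loc[2000.0]
        for name, b in truth.items():
            assert plateau[name] == pytest.approx(b, abs=0.05), name
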