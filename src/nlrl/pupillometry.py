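"""Pupillometry preprocessing and model-based time-point regression.

Pipeline for 500 Hz pupil-diameter recordings with blink gaps:

1. linear interpolation across flagged gaps;
2. zero-phase low-pass Butterworth filter (order 3, 3.75 Hz cut-off);
3. z-transform across the whole session;
4. outcome-locked epoching (0–6000 ms) with per-trial baseline
   correction (mean of the 200 ms before onset);
5. exclusion rules: a trial is excluded when more than half of its
   outcome window was interpolated; a session is flagged when more than
   half of its trials are excluded;
6. ordinary-least-squares regression at every time point across included
   trials, with z-scored regressors (intercept, trial number, chosen
   outcome, signed PE, learning rate, black-pixel luminance covariate),
   plus 1000-ms-bin tests of dilation against baseline.

A synthetic-session generator with known ground-truth coefficients makes
the whole pipeline testable end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "PupilSession",
    "EpochMatrix",
    "preprocess_session",
    "epoch_and_baseline",
    "timepoint_regression",
    "synth_pupil_session",
]

FS = 500  # Hz


@dataclass
class PupilSession:
    """A pupil recording with gap annotations and trial events.

    ``event_onsets`` are outcome-onset sample indices; ``trial_meta`` is
    the per-trial regressor table.
    """

    samples: np.ndarray
    is_gap: np.ndarray
    event_onsets: np.ndarray
    trial_meta: pd.DataFrame
    fs: int = FS
    truth: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.is_gap = np.asarray(self.is_gap, dtype=bool)
        self.event_onsets = np.asarray(self.event_onsets, dtype=int)
        if self.samples.shape != self.is_gap.shape:
            raise ValueError("samples and is_gap must share a shape")
        n = self.samples.size
        if np.any(self.event_onsets < 0) or np.any(self.event_onsets >= n):
            raise ValueError("event onsets must lie within the recording span")
        if len(self.trial_meta) != len(self.event_onsets):
            raise ValueError("one trial_meta row per event required")


def preprocess_session(session: PupilSession, zscore: bool = True) -> np.ndarray:
    """Interpolate gaps, low-pass filter (3.75 Hz, zero phase) and z-transform."""
    x = session.samples.copy()
    gap = session.is_gap
    valid = ~gap
    if not valid.any():
        raise ValueError("session has no valid samples outside gaps")
    if gap.any():
        idx = np.arange(x.size)
        x[gap] = np.interp(idx[gap], idx[valid], x[valid])
    sos = signal.butter(3, 3.75, btype="low", fs=session.fs, output="sos")
    x = signal.sosfiltfilt(sos, x)
    if zscore:
        sd = x.std()
        if sd <= 1e-10 * (1.0 + abs(x.mean())):
            raise ValueError("zero-variance trace: z-transform undefined")
        x = (x - x.mean()) / sd
    return x


@dataclass
class EpochMatrix:
    """Outcome-locked, baseline-corrected epochs with inclusion flags.

    Excluded trials are flagged, never dropped; ``interp_frac`` is the
    fraction of each trial's window that was interpolated.
    """

    epochs: np.ndarray           # (n_trials, n_time), NaN-padded past recording end
    time_ms: np.ndarray
    interp_frac: np.ndarray
    excluded: np.ndarray
    session_excluded: bool
    fs: int = FS

    def __post_init__(self) -> None:
        if np.any((self.interp_frac < 0) | (self.interp_frac > 1)):
            raise ValueError("interp_frac must lie in [0, 1]")

    @property
    def included(self) -> np.ndarray:
        return ~self.excluded


def epoch_and_baseline(cleaned: np.ndarray, session: PupilSession,
                       window_ms: Tuple[float, float] = (0.0, 6000.0),
                       baseline_ms: float = 200.0,
                       max_interp_frac: float = 0.5,
                       max_excluded_frac: float = 0.5) -> EpochMatrix:
    """Cut outcome-locked windows and subtract the pre-onset baseline.

    Trials with strictly more than ``max_interp_frac`` of their window
    interpolated are flagged excluded, as are trials whose window (or
    baseline) exceeds the recording; the session is flagged when the
    excluded fraction strictly exceeds ``max_excluded_frac``.
    """
    fs = session.fs
    i0 = int(round(window_ms[0] * fs / 1000.0))
    i1 = int(round(window_ms[1] * fs / 1000.0))
    nb = int(round(baseline_ms * fs / 1000.0))
    n_time = i1 - i0
    n = cleaned.size
    onsets = session.event_onsets
    if np.any(np.diff(onsets) < 0):
        raise ValueError("event onsets must be sorted")
    n_trials = onsets.size
    epochs = np.full((n_trials, n_time), np.nan)
    interp_frac = np.zeros(n_trials)
    excluded = np.zeros(n_trials, dtype=bool)
    for k, on in enumerate(onsets):
        lo, hi = on + i0, on + i1
        if on - nb < 0 or lo < 0:
            excluded[k] = True
            continue
        take = min(hi, n)
        if take <= lo:
            excluded[k] = True
            continue
        base = cleaned[on - nb:on].mean() if nb > 0 else 0.0
        epochs[k, :take - lo] = cleaned[lo:take] - base
        win_gap = session.is_gap[lo:take]
        interp_frac[k] = win_gap.mean() if win_gap.size else 0.0
        if interp_frac[k] > max_interp_frac:
            excluded[k] = True
        if take < hi:        # truncated by end of recording: flag, not fatal
            excluded[k] = True
    session_excluded = excluded.mean() > max_excluded_frac
    time_ms = (np.arange(i0, i1) * 1000.0 / fs)
    return EpochMatrix(epochs=epochs, time_ms=time_ms, interp_frac=interp_frac,
                       excluded=excluded, session_excluded=session_excluded, fs=fs)


def _zscore_design(design: pd.DataFrame) -> Tuple[np.ndarray, list]:
    cols = list(design.columns)
    X = design.to_numpy(dtype=float).copy()
    for j in range(X.shape[1]):
        sd = X[:, j].std()
        if sd > 0 and not np.allclose(X[:, j], X[0, j]):
            X[:, j] = (X[:, j] - X[:, j].mean()) / sd
    return X, cols


def timepoint_regression(epochs: EpochMatrix, design: pd.DataFrame,
                         add_intercept: bool = True, bin_ms: float = 1000.0,
                         alpha: float = 0.05) -> dict:
    """OLS at every time point across included trials.

    Regressors are z-scored per session (constants left untouched) so
    coefficient magnitudes are comparable.  Returns per-time-point
    coefficients and t-statistics per regressor, and per-1000-ms-bin
    tests of mean dilation against baseline (two-sided one-sample t).
    Raises on a rank-deficient design, naming the collinear columns.
    """
    inc = epochs.included
    if len(design) != epochs.epochs.shape[0]:
        raise ValueError("one design row per trial required")
    X, cols = _zscore_design(design.loc[inc] if hasattr(design, "loc") else design[inc])
    if add_intercept and not any(np.allclose(X[:, j], 1.0) for j in range(X.shape[1])):
        X = np.column_stack([np.ones(X.shape[0]), X])
        cols = ["intercept"] + cols
    n, k = X.shape
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} included trials, have {n}")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # name columns whose removal restores full rank
        bad = [cols[j] for j in range(k)
               if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    Y = epochs.epochs[inc]
    # time points where any included trial is truncated contribute only
    # the trials that reach them
    coef = np.full((k, Y.shape[1]), np.nan)
    tstat = np.full((k, Y.shape[1]), np.nan)
    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T
    dvar = np.diag(XtX_inv)
    full_mask = ~np.isnan(Y).any(axis=0)
    if full_mask.any():
        B = H @ Y[:, full_mask]
        resid = Y[:, full_mask] - X @ B
        dof = max(n - k, 1)
        sigma2 = (resid ** 2).sum(axis=0) / dof
        coef[:, full_mask] = B
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat[:, full_mask] = B / np.sqrt(sigma2[None, :] * dvar[:, None])
    for j in np.flatnonzero(~full_mask):
        ok = ~np.isnan(Y[:, j])
        if ok.sum() < k + 2:
            continue
        Xj = X[ok]
        try:
            Bj, *_ = np.linalg.lstsq(Xj, Y[ok, j], rcond=None)
        except np.linalg.LinAlgError:
            continue
        coef[:, j] = Bj
    coef_df = pd.DataFrame(coef.T, index=epochs.time_ms, columns=cols)
    tstat_df = pd.DataFrame(tstat.T, index=epochs.time_ms, columns=cols)
    # 1000-ms-bin dilation vs baseline
    edges = np.arange(epochs.time_ms[0], epochs.time_ms[-1] + bin_ms, bin_ms)
    rows = []
    for b in range(len(edges) - 1):
        sel = (epochs.time_ms >= edges[b]) & (epochs.time_ms < edges[b + 1])
        if not sel.any():
            continue
        per_trial = np.nanmean(Y[:, sel], axis=1)
        per_trial = per_trial[~np.isnan(per_trial)]
        if per_trial.size < 3:
            continue
        t, p = stats.ttest_1samp(per_trial, 0.0)
        rows.append({"bin_lo_ms": edges[b], "bin_hi_ms": edges[b + 1],
                     "mean": float(per_trial.mean()), "t": float(t),
                     "p": float(p), "significant": bool(p < alpha)})
    return {"coef": coef_df, "tstat": tstat_df, "bins": pd.DataFrame(rows)}


def _response_kernel(n_time: int, fs: int) -> np.ndarray:
    """Slow ramp kernel: rise over 1.5 s, plateau at 1, decay 5–6.5 s."""
    t = np.arange(n_time) / fs
    k = np.clip(t / 1.5, 0.0, 1.0)
    k = np.where(t > 5.0, np.clip(1.0 - (t - 5.0) / 1.5, 0.0, 1.0), k)
    return k


def synth_pupil_session(design: pd.DataFrame, coefficients: Dict[str, float],
                        noise_sd: float = 0.1, blink_rate: float = 0.05,
                        seed: int = 0, fs: int = FS, iti_ms: float = 9000.0,
                        pre_ms: float = 2000.0) -> PupilSession:
    """Build a synthetic 500 Hz session with known regressor effects.

    Each trial's response amplitude is the z-scored design row times the
    ground-truth ``coefficients``, shaped in time by a slow ramp kernel
    that is zero before onset and decays before the next trial.  Gaussian
    sample noise and randomly placed blink gaps (``blink_rate`` blinks
    per second, 100–400 ms each) are added on top.
    """
    n_trials = len(design)
    iti = int(round(iti_ms * fs / 1000.0))
    pre = int(round(pre_ms * fs / 1000.0))
    onsets = pre + iti * np.arange(n_trials)
    n = int(onsets[-1] + iti)
    n_kernel = int(round(6.5 * fs))
    kernel = _response_kernel(n_kernel, fs)
    Xz, cols = _zscore_design(design)
    beta = np.array([coefficients[c] for c in cols])
    amps = Xz @ beta
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    for on, a in zip(onsets, amps):
        hi = min(on + n_kernel, n)
        x[on:hi] += a * kernel[:hi - on]
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, size=n)
    is_gap = np.zeros(n, dtype=bool)
    n_blinks = rng.poisson(blink_rate * n / fs) if blink_rate > 0 else 0
    for _ in range(n_blinks):
        start = int(rng.integers(0, n))
        length = int(rng.uniform(0.1, 0.4) * fs)
        is_gap[start:start + length] = True
    return PupilSession(samples=x, is_gap=is_gap, event_onsets=onsets,
                        trial_meta=design.reset_index(drop=True), fs=fs,
                        truth=dict(coefficients))
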