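"""Seeded generators for the simulated task environments.

Three families of environment are produced, all with outcomes normalised
to [0, 1]:

* Gaussian tracking environments with piecewise-constant means, where
  *volatility* (unexpected uncertainty) is the frequency of mean jumps
  and *noise* (expected uncertainty) is the generative SD;
* binary probabilistic reward schedules with stable/volatile blocks and
  anti-correlated options carrying random reward magnitudes;
* a two-option reward-magnitude task whose options share 100 points per
  trial (complementary magnitudes), in a 2x2 volatility-by-noise design.

Out-of-range Gaussian draws are clipped (not resampled); the number of
clipped trials is recorded on the schedule because clipping biases the
realized mean at extreme means/SDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "SegmentSpec",
    "OutcomeSchedule",
    "FACTORIAL_SEGMENTS",
    "gen_from_segments",
    "gen_factorial_env",
    "gen_random_env",
    "gen_binary_prob_schedule",
    "gen_magnitude_task",
]

#: Default range volatile means move over (keeps clipping rare).
DEFAULT_MEAN_RANGE = (0.2, 0.8)


@dataclass
class SegmentSpec:
    """One contiguous environment segment.

    In volatile segments the generative mean jumps to a newly drawn value
    every ``switch_every`` trials; in stable segments it stays put.
    """

    n_trials: int
    volatile: bool
    sd: float
    switch_every: Optional[int] = None
    mean_range: Tuple[float, float] = DEFAULT_MEAN_RANGE
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ValueError("n_trials must be > 0")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.volatile:
            if self.switch_every is None or not (0 < self.switch_every <= self.n_trials):
                raise ValueError("volatile segment needs 0 < switch_every <= n_trials")


@dataclass
class OutcomeSchedule:
    """Realized outcomes plus the generative process that produced them.

    ``outcomes`` is (T,) for single-stream kinds (``gaussian_track``) and
    (T, 2) for two-option kinds (``binary_prob`` rewards, or
    ``magnitude_pair`` magnitudes summing to 1 per trial).
    ``switch_points`` are 0-based trial indices at which ``gen_mean``
    jumps.
    """

    outcomes: np.ndarray
    gen_mean: np.ndarray
    gen_sd: np.ndarray
    block_id: np.ndarray
    switch_points: np.ndarray
    kind: str
    seed: Optional[int] = None
    magnitudes: Optional[np.ndarray] = None
    n_clipped: int = 0

    def __post_init__(self) -> None:
        self.outcomes = np.asarray(self.outcomes, dtype=float)
        self.gen_mean = np.asarray(self.gen_mean, dtype=float)
        self.gen_sd = np.asarray(self.gen_sd, dtype=float)
        self.block_id = np.asarray(self.block_id)
        self.switch_points = np.asarray(self.switch_points, dtype=int)
        if self.kind not in ("gaussian_track", "binary_prob", "magnitude_pair"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        T = self.n_trials
        if not (len(self.gen_mean) == len(self.gen_sd) == len(self.block_id) == T):
            raise ValueError("per-trial arrays must share one length")
        if self.outcomes.min() < 0 or self.outcomes.max() > 1:
            raise ValueError("outcomes must lie in [0, 1]")
        if np.any(np.diff(self.switch_points) <= 0):
            raise ValueError("switch_points must be strictly increasing")
        if self.kind == "magnitude_pair":
            if self.outcomes.ndim != 2 or not np.allclose(self.outcomes.sum(axis=1), 1.0):
                raise ValueError("magnitude_pair options must sum to 1.0 each trial")

    @property
    def n_trials(self) -> int:
        return self.outcomes.shape[0]

    def to_frame(self) -> pd.DataFrame:
        T = self.n_trials
        if self.outcomes.ndim == 1:
            a, b = self.outcomes, np.full(T, np.nan)
        else:
            a, b = self.outcomes[:, 0], self.outcomes[:, 1]
        is_switch = np.zeros(T, dtype=int)
        is_switch[self.switch_points] = 1
        return pd.DataFrame({
            "trial": np.arange(1, T + 1),
            "option_a": a,
            "option_b": b,
            "gen_mean": self.gen_mean,
            "gen_sd": self.gen_sd,
            "block_id": self.block_id,
            "is_switch": is_switch,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, kind: str = "gaussian_track",
                   seed: Optional[int] = None) -> "OutcomeSchedule":
        b = df["option_b"].to_numpy()
        if np.all(np.isnan(b)):
            outcomes = df["option_a"].to_numpy()
        else:
            outcomes = np.column_stack([df["option_a"].to_numpy(), b])
        return cls(outcomes=outcomes, gen_mean=df["gen_mean"].to_numpy(),
                   gen_sd=df["gen_sd"].to_numpy(), block_id=df["block_id"].to_numpy(),
                   switch_points=np.flatnonzero(df["is_switch"].to_numpy()),
                   kind=kind, seed=seed)


def gen_from_segments(segments: Sequence[SegmentSpec], seed: int,
                      jump_scheme: str = "alternate") -> OutcomeSchedule:
    """Build a single-stream Gaussian tracking environment from segment specs.

    The first segment starts from a uniformly drawn mean (not counted as
    a switch); stable segments carry the preceding mean forward; volatile
    segments jump at their start and every ``switch_every`` trials.  With
    the default ``"alternate"`` scheme the mean jumps to the far end of
    the segment's ``mean_range`` (large, clearly discriminable level
    changes, as in classic volatility manipulations); ``"uniform"`` draws
    each new mean uniformly instead.
    """
    if jump_scheme not in ("alternate", "uniform"):
        raise ValueError(f"unknown jump_scheme {jump_scheme!r}")
    rng = np.random.default_rng(seed)
    gen_mean, gen_sd, block = [], [], []
    switch_points: List[int] = []
    mean: Optional[float] = None
    t = 0
    for si, seg in enumerate(segments):
        label = seg.label if seg.label is not None else si + 1
        lo, hi = seg.mean_range
        for i in range(seg.n_trials):
            jump = (mean is None) or (seg.volatile and i % seg.switch_every == 0)
            if jump:
                if mean is None:
                    new = rng.uniform(lo, hi)
                elif jump_scheme == "alternate":
                    new = lo if mean >= (lo + hi) / 2.0 else hi
                else:
                    new = rng.uniform(lo, hi)
                if mean is not None:
                    switch_points.append(t)
                mean = new
            gen_mean.append(mean)
            gen_sd.append(seg.sd)
            block.append(label)
            t += 1
    gen_mean = np.asarray(gen_mean)
    gen_sd = np.asarray(gen_sd)
    raw = rng.normal(gen_mean, gen_sd)
    outcomes = np.clip(raw, 0.0, 1.0)
    n_clipped = int(np.sum(raw != outcomes))
    return OutcomeSchedule(outcomes=outcomes, gen_mean=gen_mean, gen_sd=gen_sd,
                           block_id=np.asarray(block), switch_points=np.asarray(switch_points),
                           kind="gaussian_track", seed=seed, n_clipped=n_clipped)


#: The 1500-trial factorial environment: volatility and noise manipulated
#: independently across five spans; the final 500-trial span is noisier
#: (SD 0.15) and itself contains a volatile and a stable stretch, which
#: obscures the regime transition.
FACTORIAL_SEGMENTS = (
    SegmentSpec(300, volatile=True, sd=0.05, switch_every=100, label=1),
    SegmentSpec(200, volatile=False, sd=0.10, label=2),
    SegmentSpec(300, volatile=True, sd=0.10, switch_every=100, label=3),
    SegmentSpec(200, volatile=False, sd=0.05, label=4),
    SegmentSpec(300, volatile=True, sd=0.15, switch_every=100, label=5),
    SegmentSpec(200, volatile=False, sd=0.15, label=5),
)


def gen_factorial_env(seed: int, segments: Sequence[SegmentSpec] = FACTORIAL_SEGMENTS
                      ) -> OutcomeSchedule:
    """The 1500-trial volatility-by-noise factorial tracking environment."""
    sched = gen_from_segments(segments, seed)
    if segments is FACTORIAL_SEGMENTS and sched.n_trials != 1500:
        raise AssertionError("factorial environment must have 1500 trials")
    return sched


def gen_random_env(n_trials: int = 60, n_switches: int = 2, sd: float = 0.1,
                   mean_range: Tuple[float, float] = DEFAULT_MEAN_RANGE,
                   seed: int = 0) -> OutcomeSchedule:
    """A short random environment with ``n_switches`` mean jumps.

    Switch trials are drawn uniformly (without replacement) from the
    interior of the sequence; segment means are drawn uniformly from
    ``mean_range`` with no minimum-jump constraint (plain uniform draws).
    """
    if not (0 <= n_switches < n_trials):
        raise ValueError("need 0 <= n_switches < n_trials")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    switch_points = np.sort(rng.choice(np.arange(1, n_trials), size=n_switches,
                                       replace=False)) if n_switches else np.empty(0, int)
    means = rng.uniform(mean_range[0], mean_range[1], size=n_switches + 1)
    gen_mean = np.empty(n_trials)
    bounds = np.concatenate([[0], switch_points, [n_trials]]).astype(int)
    for k in range(len(bounds) - 1):
        gen_mean[bounds[k]:bounds[k + 1]] = means[k]
    raw = rng.normal(gen_mean, sd)
    outcomes = np.clip(raw, 0.0, 1.0)
    return OutcomeSchedule(outcomes=outcomes, gen_mean=gen_mean,
                           gen_sd=np.full(n_trials, sd),
                           block_id=np.zeros(n_trials, dtype=int),
                           switch_points=switch_points, kind="gaussian_track",
                           seed=seed, n_clipped=int(np.sum(raw != outcomes)))


def gen_binary_prob_schedule(blocks: Sequence[tuple] = ((120, 0.75, False, None),
                                                        (170, 0.75, True, (30, 40))),
                             seed: int = 0) -> OutcomeSchedule:
    """Binary probabilistic reward schedule with anti-correlated options.

    ``blocks`` is a sequence of ``(n_trials, p_reward, volatile,
    switch_every)`` tuples; in volatile blocks the contingency flips
    between ``p_reward`` and ``1 - p_reward`` after run lengths drawn
    uniformly from the ``switch_every`` interval.  Exactly one option is
    rewarded per trial; per-option reward magnitudes are drawn uniformly
    in [0, 1] each trial.  The default mirrors a stable 120-trial block
    followed by a volatile 170-trial block at 0.75/0.25.
    """
    rng = np.random.default_rng(seed)
    p_seq, block_ids, switch_points = [], [], []
    t = 0
    for bi, (n, p_reward, volatile, switch_every) in enumerate(blocks):
        if not (0.0 <= p_reward <= 1.0):
            raise ValueError("p_reward must lie in [0, 1]")
        if not volatile:
            p_seq.extend([p_reward] * n)
        else:
            lo, hi = switch_every if switch_every else (30, 40)
            cur, filled = p_reward, 0
            while filled < n:
                run = int(rng.integers(lo, hi + 1))
                run = min(run, n - filled)
                p_seq.extend([cur] * run)
                filled += run
                if filled < n:
                    switch_points.append(t + filled)
                    cur = 1.0 - cur
        block_ids.extend([bi] * n)
        t += n
    p_seq = np.asarray(p_seq)
    T = len(p_seq)
    a_rewarded = (rng.random(T) < p_seq).astype(float)
    rewards = np.column_stack([a_rewarded, 1.0 - a_rewarded])
    magnitudes = rng.random((T, 2))
    return OutcomeSchedule(outcomes=rewards, gen_mean=p_seq,
                           gen_sd=np.sqrt(p_seq * (1 - p_seq)),
                           block_id=np.asarray(block_ids),
                           switch_points=np.asarray(switch_points, dtype=int),
                           kind="binary_prob", seed=seed, magnitudes=magnitudes)


#: 2x2 magnitude-task conditions: (volatile?, sd).
MAGNITUDE_CONDITIONS = {
    "stable_low": (False, 0.05),
    "stable_high": (False, 0.15),
    "volatile_low": (True, 0.05),
    "volatile_high": (True, 0.15),
}


def gen_magnitude_task(block_order: Sequence[str] = ("stable_low", "volatile_low",
                                                     "stable_high", "volatile_high"),
                       seed: int = 0, n_trials_per_block: int = 60,
                       switch_every: int = 20,
                       volatile_means: Tuple[float, float] = (0.2, 0.8)
                       ) -> OutcomeSchedule:
    """Two-option complementary-magnitude task (4 blocks x 60 trials, 2x2 design).

    The two options split 100 available points each trial, so their
    magnitudes sum to 1 exactly.  Stable blocks use a mean reward rate of
    0.5 for option A; volatile blocks alternate the mean between
    ``volatile_means`` every ``switch_every`` trials.
    """
    if sorted(block_order) != sorted(MAGNITUDE_CONDITIONS):
        raise ValueError(f"block_order must be a permutation of {sorted(MAGNITUDE_CONDITIONS)}")
    rng = np.random.default_rng(seed)
    gen_mean, gen_sd, block_ids, switch_points = [], [], [], []
    t = 0
    for name in block_order:
        volatile, sd = MAGNITUDE_CONDITIONS[name]
        if not volatile:
            means = [0.5] * n_trials_per_block
        else:
            start = int(rng.integers(0, 2))
            means = []
            for i in range(n_trials_per_block):
                k = i // switch_every
                if i > 0 and i % switch_every == 0:
                    switch_points.append(t + i)
                means.append(volatile_means[(start + k) % 2])
        gen_mean.extend(means)
        gen_sd.extend([sd] * n_trials_per_block)
        block_ids.extend([name] * n_trials_per_block)
        t += n_trials_per_block
    gen_mean = np.asarray(gen_mean)
    gen_sd = np.asarray(gen_sd)
    raw = rng.normal(gen_mean, gen_sd)
    a = np.clip(raw, 0.0, 1.0)
    outcomes = np.column_stack([a, 1.0 - a])
    return OutcomeSchedule(outcomes=outcomes, gen_mean=gen_mean, gen_sd=gen_sd,
                           block_id=np.asarray(block_ids),
                           switch_points=np.asarray(switch_points, dtype=int),
                           kind="magnitude_pair", seed=seed,
                           n_clipped=int(np.sum(raw != a)))
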