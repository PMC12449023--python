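"""Trial-wise belief-update rules and learning-rate transfer functions.

Four delta-rule learners over outcomes normalised to [0, 1]:

* ``RW`` — Rescorla-Wagner, constant learning rate ``eta0``:
  ``p(t+1) = p(t) + eta0 * (O(t) - p(t))``.
* ``PH`` — hybrid Pearce-Hall, whose associability ``eta`` is a
  recency-weighted average of past unsigned prediction errors,
  ``eta(t+1) = omega*eta(t) + (1-omega)*|O(t)-p(t)|``, applied to the
  belief update scaled by ``gamma``.
* ``CUBIC`` — parabolic transfer ``eta = PE^2 / (4*kappa)``; the belief
  update becomes cubic in the signed PE.
* ``EXPLOG`` — exponential-logarithmic transfer
  ``eta = exp(-delta * (-log|PE|)^lambda)``, a two-parameter family that
  reduces exactly to RW at ``lambda = 0`` (constant rate ``exp(-delta)``).

The cubic and exp-log models convert the current trial's unsigned PE to a
learning rate instantaneously; the Pearce-Hall associability is fed
forward from past trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "MODELS",
    "PE_FLOOR",
    "BeliefState",
    "ModelParams",
    "NoiseLink",
    "LearningTrace",
    "rw_step",
    "ph_step",
    "cubic_rate",
    "cubic_step",
    "explog_rate",
    "explog_step",
    "kappa_from_sigma",
    "cubic_focal_point",
    "run_model",
]

#: Model identifiers, in canonical (simplest-first) order.
MODELS = ("RW", "PH", "CUBIC", "EXPLOG")

#: Numerical floor on |PE| guarding log(0) in the exp-log transfer.
PE_FLOOR = 1e-12


def _check_unit(name: str, x: float) -> None:
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {x!r}")


@dataclass
class BeliefState:
    """Belief/learning-rate state of a learner at trial ``t`` (1-based)."""

    p: float
    eta: float
    t: int = 1

    def __post_init__(self) -> None:
        _check_unit("p", self.p)
        if self.eta < 0:
            raise ValueError(f"eta must be >= 0, got {self.eta!r}")
        if self.t < 1:
            raise ValueError(f"t must be >= 1, got {self.t!r}")


@dataclass
class ModelParams:
    """Parameters of one learning model; only the active model's fields are read.

    ``p_init`` (default 0.5, maximum uncertainty) seeds the belief and
    ``eta_init`` (default 0.5) seeds the Pearce-Hall associability.
    """

    model_id: str
    eta0: Optional[float] = None
    omega: Optional[float] = None
    gamma: Optional[float] = None
    kappa: Optional[float] = None
    delta: Optional[float] = None
    lam: Optional[float] = None
    p_init: float = 0.5
    eta_init: float = 0.5

    def __post_init__(self) -> None:
        if self.model_id not in MODELS:
            raise ValueError(f"unknown model_id {self.model_id!r}; expected one of {MODELS}")
        _check_unit("p_init", self.p_init)
        _check_unit("eta_init", self.eta_init)
        if self.model_id == "RW":
            if self.eta0 is None:
                raise ValueError("RW requires eta0")
            _check_unit("eta0", self.eta0)
        elif self.model_id == "PH":
            if self.omega is None or self.gamma is None:
                raise ValueError("PH requires omega and gamma")
            _check_unit("omega", self.omega)
            if self.gamma < 0:
                raise ValueError(f"gamma must be >= 0, got {self.gamma!r}")
        elif self.model_id == "CUBIC":
            if self.kappa is None:
                raise ValueError("CUBIC requires kappa")
            if self.kappa <= 0:
                raise ValueError(f"kappa must be > 0, got {self.kappa!r}")
        elif self.model_id == "EXPLOG":
            if self.delta is None or self.lam is None:
                raise ValueError("EXPLOG requires delta and lam")
            if self.delta < 0 or self.lam < 0:
                raise ValueError("delta and lam must be >= 0")

    def free_params(self) -> dict:
        """The active model's free parameters as a name -> value dict."""
        names = {"RW": ("eta0",), "PH": ("omega", "gamma"),
                 "CUBIC": ("kappa",), "EXPLOG": ("delta", "lam")}[self.model_id]
        return {n: getattr(self, n) for n in names}


@dataclass
class NoiseLink:
    """Exponential link from environmental noise sigma to the cubic kappa.

    ``kappa = a * exp(beta * sigma) + eps``.  ``a`` sets the baseline
    expected-uncertainty level (must be nonzero); the resulting kappa must
    be positive.  Sigma is meaningful in (0, 0.4] for outcomes normalised
    to [0, 1].
    """

    a: float
    beta: float
    eps: float
    sigma: float

    def __post_init__(self) -> None:
        if self.a == 0:
            raise ValueError("a must be nonzero")
        if not (0.0 < self.sigma <= 0.4):
            raise ValueError(f"sigma must lie in (0, 0.4], got {self.sigma!r}")


def kappa_from_sigma(link: NoiseLink) -> float:
    """Map environmental noise to the cubic focal parameter via the exponential link."""
    kappa = link.a * math.exp(link.beta * link.sigma) + link.eps
    if kappa <= 0:
        raise ValueError(f"link yields non-positive kappa ({kappa!r})")
    return kappa


def rw_step(p: float, O: float, eta: float) -> float:
    """One Rescorla-Wagner update; result clamped to [0, 1]."""
    _check_unit("p", p)
    _check_unit("O", O)
    _check_unit("eta", eta)
    return min(1.0, max(0.0, p + eta * (O - p)))


def ph_step(p: float, eta: float, O: float, omega: float, gamma: float) -> tuple:
    """One hybrid Pearce-Hall update.

    The belief is updated with the *current* associability (scaled by
    ``gamma``, effective rate clamped to [0, 1]); the associability is then
    updated for the next trial from the current unsigned PE.  Returns
    ``(new_belief, new_eta)``.
    """
    _check_unit("p", p)
    _check_unit("O", O)
    _check_unit("omega", omega)
    if eta < 0:
        raise ValueError(f"eta must be >= 0, got {eta!r}")
    if gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma!r}")
    pe = O - p
    rate = min(1.0, max(0.0, gamma * eta))
    p_new = min(1.0, max(0.0, p + rate * pe))
    eta_new = omega * eta + (1.0 - omega) * abs(pe)
    return p_new, eta_new


def cubic_rate(pe: float, kappa: float) -> float:
    """Parabolic PE -> learning-rate transfer, ``pe^2 / (4*kappa)``, clamped to [0, 1].

    Even in the sign of the PE.  For ``kappa >= 0.25`` the raw value never
    exceeds 1 (|PE| <= 1), so the clamp only engages below that.
    """
    if kappa <= 0:
        raise ValueError(f"kappa must be > 0, got {kappa!r}")
    if not (-1.0 <= pe <= 1.0):
        raise ValueError(f"pe must lie in [-1, 1], got {pe!r}")
    return min(1.0, pe * pe / (4.0 * kappa))


def cubic_step(p: float, O: float, kappa: float) -> float:
    """Cubic belief update: RW step with the parabolic transfer rate."""
    _check_unit("p", p)
    _check_unit("O", O)
    return rw_step(p, O, cubic_rate(O - p, kappa))


def cubic_focal_point(kappa: float) -> tuple:
    """Focal point of the parabola ``eta = pe^2 / (4*kappa)`` on the (PE, eta) plane.

    A parabola ``y = a x^2`` has its focus at ``(0, 1/(4a))``; here
    ``a = 1/(4*kappa)`` so the focus is ``(0, kappa)`` — computed, not
    assumed, so the identity is checkable.
    """
    if kappa <= 0:
        raise ValueError(f"kappa must be > 0, got {kappa!r}")
    a = 1.0 / (4.0 * kappa)
    return (0.0, 1.0 / (4.0 * a))


def explog_rate(pe_abs: float, delta: float, lam: float) -> float:
    """Exponential-logarithmic PE -> learning-rate transfer.

    ``eta = exp(-delta * (-log(pe_abs))**lam)`` for ``pe_abs`` in (0, 1].
    Defined by continuity as 0 at ``pe_abs = 0`` when ``lam > 0``; for
    ``lam = 0`` the transfer is the constant ``exp(-delta)`` (the RW
    reduction).  Always 1 at ``pe_abs = 1`` when ``lam > 0``.
    """
    if delta < 0 or lam < 0:
        raise ValueError("delta and lam must be >= 0")
    if pe_abs > 1.0 or pe_abs < 0.0:
        raise ValueError(f"pe_abs must lie in [0, 1], got {pe_abs!r} (normalise outcomes)")
    if lam == 0.0:
        return math.exp(-delta)
    if pe_abs <= PE_FLOOR:
        return 0.0
    return math.exp(-delta * (-math.log(pe_abs)) ** lam)


def explog_step(p: float, O: float, delta: float, lam: float) -> float:
    """Exp-log belief update: RW step with the exp-log transfer rate on |PE|."""
    _check_unit("p", p)
    _check_unit("O", O)
    return rw_step(p, O, explog_rate(abs(O - p), delta, lam))


class Learner:
    """Sequential scalar learner; shared stepping logic for simulation and fitting.

    Tracks the belief ``p`` and (for PH) the associability; ``observe``
    consumes one outcome and returns ``(signed_pe, eta)`` where ``eta`` is
    the learning-rate estimate attributed to the trial — the rate its PE
    triggers.  For PH that is the freshly updated associability
    ``omega*eta(t) + (1-omega)*|PE(t)|`` (the belief update itself applies
    ``gamma`` times the pre-update associability, exactly as the update
    equations are written); for the other models it is the rate applied.
    """

    __slots__ = ("model_id", "p", "eta_ph", "_eta0", "_omega", "_gamma",
                 "_kappa", "_delta", "_lam")

    def __init__(self, params: ModelParams):
        self.model_id = params.model_id
        self.p = params.p_init
        self.eta_ph = params.eta_init
        self._eta0 = params.eta0
        self._omega = params.omega
        self._gamma = params.gamma
        self._kappa = params.kappa
        self._delta = params.delta
        self._lam = params.lam

    def observe(self, O: float) -> tuple:
        p = self.p
        pe = O - p
        mid = self.model_id
        if mid == "RW":
            eta = self._eta0
            p += eta * pe
        elif mid == "PH":
            rate = self._gamma * self.eta_ph
            if rate > 1.0:
                rate = 1.0
            p += rate * pe
            eta = self._omega * self.eta_ph + (1.0 - self._omega) * abs(pe)
            self.eta_ph = eta
        elif mid == "CUBIC":
            eta = pe * pe / (4.0 * self._kappa)
            if eta > 1.0:
                eta = 1.0
            p += eta * pe
        else:  # EXPLOG
            a = abs(pe)
            lam = self._lam
            if lam == 0.0:
                eta = math.exp(-self._delta)
            elif a <= PE_FLOOR:
                eta = 0.0
            else:
                eta = math.exp(-self._delta * (-math.log(a)) ** lam)
            p += eta * pe
        self.p = 0.0 if p < 0.0 else (1.0 if p > 1.0 else p)
        return pe, eta


@dataclass
class LearningTrace:
    """Per-trial record of one model run: beliefs, PEs and learning rates.

    ``p`` has length T+1 (including the initial belief); the PE and eta
    sequences have length T.  ``eta[t]`` is the learning rate triggered by
    trial t's PE — for PH, the associability right after its update from
    that PE, so all four models' eta sequences are aligned on the PE that
    produced them.
    """

    p: np.ndarray
    pe_signed: np.ndarray
    pe_abs: np.ndarray
    eta: np.ndarray
    model_id: str
    params: ModelParams = None
    outcomes: np.ndarray = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.pe_signed = np.asarray(self.pe_signed, dtype=float)
        self.pe_abs = np.asarray(self.pe_abs, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        T = len(self.pe_signed)
        if len(self.p) != T + 1 or len(self.pe_abs) != T or len(self.eta) != T:
            raise ValueError("inconsistent trace lengths")
        if not np.allclose(self.pe_abs, np.abs(self.pe_signed)):
            raise ValueError("pe_abs must equal |pe_signed| elementwise")

    @property
    def n_trials(self) -> int:
        return len(self.pe_signed)

    def to_frame(self) -> pd.DataFrame:
        """Flat per-trial table (trial is 1-based)."""
        T = self.n_trials
        return pd.DataFrame({
            "trial": np.arange(1, T + 1),
            "outcome": self.outcomes if self.outcomes is not None else np.full(T, np.nan),
            "p": self.p[:-1],
            "pe_signed": self.pe_signed,
            "pe_abs": self.pe_abs,
            "eta": self.eta,
            "model_id": self.model_id,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, params: ModelParams = None) -> "LearningTrace":
        model_id = str(df["model_id"].iloc[0])
        p = df["p"].to_numpy()
        pe = df["pe_signed"].to_numpy()
        # terminal belief reconstructed from the last update
        p_full = np.append(p, np.nan)
        outcomes = df["outcome"].to_numpy()
        p_last = p[-1]
        eta = df["eta"].to_numpy()
        rate = eta[-1]
        if model_id == "PH":
            # gamma-scaled rate is not stored; terminal belief left NaN
            pass
        else:
            p_full[-1] = min(1.0, max(0.0, p_last + min(1.0, rate) * pe[-1]))
        trace = cls(p=p_full, pe_signed=pe, pe_abs=df["pe_abs"].to_numpy(),
                    eta=eta, model_id=model_id, params=params, outcomes=outcomes)
        return trace


def run_model(schedule, params: ModelParams) -> LearningTrace:
    """Run one learner over a single-stream outcome sequence.

    ``schedule`` may be an :class:`~nlrl.environments.OutcomeSchedule`
    (single-option kinds) or any 1-D sequence of outcomes in [0, 1].
    Deterministic given its inputs; the cubic and exp-log rates are
    computed from each trial's own |PE|.
    """
    outcomes = np.asarray(getattr(schedule, "outcomes", schedule), dtype=float)
    if outcomes.ndim != 1:
        raise ValueError("run_model expects a single outcome stream (1-D)")
    if outcomes.size == 0:
        raise ValueError("empty outcome sequence")
    if outcomes.min() < 0.0 or outcomes.max() > 1.0:
        raise ValueError("outcomes must lie in [0, 1] (normalise first)")
    T = outcomes.size
    learner = Learner(params)
    p = np.empty(T + 1)
    pe = np.empty(T)
    eta = np.empty(T)
    p[0] = learner.p
    for t in range(T):
        pe[t], eta[t] = learner.observe(outcomes[t])
        p[t + 1] = learner.p
    return LearningTrace(p=p, pe_signed=pe, pe_abs=np.abs(pe), eta=eta,
                         model_id=params.model_id, params=params, outcomes=outcomes)
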