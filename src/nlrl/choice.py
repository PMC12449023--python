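"""Observation model: beliefs -> choice probabilities, and choice likelihoods.

Reward magnitudes are passed through a power utility ``m**rho`` (risk
attitude) and the expected-value difference between the two options is
fed into a logistic sigmoid with slope ``inv_temp`` to yield the
probability of choosing option A.

Two task kinds are supported:

* ``binary`` — each option is rewarded or not; the learner tracks
  P(A rewarded) and ``EV_i = p_i * m_i**rho`` (probability times
  utility), with the unchosen option's probability taken as the
  complement (anti-correlated contingencies);
* ``magnitude`` — the two options split a fixed number of points; the
  learner tracks the predicted magnitude of option A and
  ``EV_i = predicted_magnitude_i ** rho``.

The learner updates the chosen option's belief from the realized outcome
of that option; the other option's belief is its complement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .models import Learner, LearningTrace, ModelParams, PE_FLOOR

__all__ = [
    "ChoiceParams",
    "ChoiceRecord",
    "power_utility",
    "choice_prob",
    "simulate_choices",
    "choice_nll",
    "records_to_frame",
    "records_from_frame",
]


@dataclass
class ChoiceParams:
    """Stochastic-choice parameters: power utility ``rho`` and sigmoid slope."""

    rho: float = 1.0
    inv_temp: float = 5.0

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError(f"rho must be > 0, got {self.rho!r}")
        if self.inv_temp < 0:
            raise ValueError(f"inv_temp must be >= 0, got {self.inv_temp!r}")


@dataclass
class ChoiceRecord:
    """One trial of a two-option choice task (the fitting unit)."""

    trial: int
    m_a: float
    m_b: float
    choice: str
    outcome: float
    p_a: Optional[float] = None

    def __post_init__(self) -> None:
        if self.choice not in ("A", "B"):
            raise ValueError(f"choice must be 'A' or 'B', got {self.choice!r}")
        for name in ("m_a", "m_b", "outcome"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")


def power_utility(m: float, rho: float) -> float:
    """Power-utility transform ``m**rho`` of a reward magnitude in [0, 1]."""
    if m < 0:
        raise ValueError(f"magnitude must be >= 0, got {m!r}")
    if rho <= 0:
        raise ValueError(f"rho must be > 0, got {rho!r}")
    return m ** rho


def choice_prob(ev_diff: float, inv_temp: float) -> float:
    """Probability of choosing option A given the EV difference A - B."""
    if inv_temp < 0:
        raise ValueError(f"inv_temp must be >= 0, got {inv_temp!r}")
    x = inv_temp * ev_diff
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    ex = math.exp(x)
    return ex / (1.0 + ex)


def _ev_diff(task: str, p_a: float, m_a: float, m_b: float, rho: float) -> float:
    if task == "binary":
        return p_a * m_a ** rho - (1.0 - p_a) * m_b ** rho
    # magnitude task: belief is the predicted magnitude of option A
    return p_a ** rho - (1.0 - p_a) ** rho


def simulate_choices(schedule, model: ModelParams, choice: ChoiceParams, seed: int,
                     task: Optional[str] = None) -> Tuple[List[ChoiceRecord], LearningTrace]:
    """Simulate an agent choosing between two options on a schedule.

    Returns the per-trial choice records together with the learning trace
    (belief about option A, chosen-frame PE, applied learning rate).
    """
    if task is None:
        task = {"binary_prob": "binary", "magnitude_pair": "magnitude"}.get(schedule.kind)
        if task is None:
            raise ValueError(f"schedule kind {schedule.kind!r} does not support two options")
    rng = np.random.default_rng(seed)
    outcomes = schedule.outcomes
    if outcomes.ndim != 2 or outcomes.shape[1] != 2:
        raise ValueError("two-option schedule required")
    if task == "binary":
        if schedule.magnitudes is None:
            raise ValueError("binary task requires per-option magnitudes")
        mags = schedule.magnitudes
    else:
        mags = outcomes
    T = outcomes.shape[0]
    learner = Learner(model)
    records: List[ChoiceRecord] = []
    p_seq = np.empty(T + 1)
    pe_seq = np.empty(T)
    eta_seq = np.empty(T)
    p_seq[0] = learner.p
    for t in range(T):
        m_a, m_b = float(mags[t, 0]), float(mags[t, 1])
        pa_choice = choice_prob(_ev_diff(task, learner.p, m_a, m_b, choice.rho),
                                choice.inv_temp)
        chose_a = bool(rng.random() < pa_choice)
        outcome = float(outcomes[t, 0] if chose_a else outcomes[t, 1])
        # update in the chosen-option frame; complement back afterwards
        if not chose_a:
            learner.p = 1.0 - learner.p
        pe, eta = learner.observe(outcome)
        if not chose_a:
            learner.p = 1.0 - learner.p
        records.append(ChoiceRecord(trial=t + 1, m_a=m_a, m_b=m_b,
                                    choice="A" if chose_a else "B",
                                    outcome=outcome, p_a=float(p_seq[t])))
        pe_seq[t] = pe
        eta_seq[t] = eta
        p_seq[t + 1] = learner.p
    trace = LearningTrace(p=p_seq, pe_signed=pe_seq, pe_abs=np.abs(pe_seq),
                          eta=eta_seq, model_id=model.model_id, params=model)
    return records, trace


def _records_arrays(records) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(records, pd.DataFrame):
        m_a = records["m_a"].to_numpy(float)
        m_b = records["m_b"].to_numpy(float)
        chose_a = (records["choice"].to_numpy() == "A")
        outcome = records["outcome"].to_numpy(float)
    else:
        m_a = np.array([r.m_a for r in records], float)
        m_b = np.array([r.m_b for r in records], float)
        chose_a = np.array([r.choice == "A" for r in records])
        outcome = np.array([r.outcome for r in records], float)
    return m_a, m_b, chose_a, outcome


def choice_nll(records, model: ModelParams, choice: ChoiceParams,
               task: str = "binary") -> float:
    """Negative log-likelihood of the observed choices under one model.

    The belief sequence is recomputed internally from the chosen
    outcomes.  Zero-probability observed choices are floored at 1e-12
    (a warning reports how many trials were floored).
    """
    m_a, m_b, chose_a, outcome = _records_arrays(records)
    n = len(m_a)
    if n == 0:
        raise ValueError("records must be non-empty")
    mid = model.model_id
    rho = choice.rho
    beta = choice.inv_temp
    p = model.p_init
    eta_ph = model.eta_init
    eta0 = model.eta0
    omega, gamma = model.omega, model.gamma
    kappa, delta, lam = model.kappa, model.delta, model.lam
    exp_, log_ = math.exp, math.log
    binary = (task == "binary")
    if not binary and task != "magnitude":
        raise ValueError(f"unknown task {task!r}")
    nll = 0.0
    floored = 0
    for i in range(n):
        if binary:
            ev = p * m_a[i] ** rho - (1.0 - p) * m_b[i] ** rho
        else:
            ev = p ** rho - (1.0 - p) ** rho
        x = beta * ev
        if x >= 0:
            pa = 1.0 / (1.0 + exp_(-x)) if x < 700 else 1.0
        else:
            ex = exp_(x) if x > -700 else 0.0
            pa = ex / (1.0 + ex)
        pr = pa if chose_a[i] else 1.0 - pa
        if pr < 1e-12:
            pr = 1e-12
            floored += 1
        nll -= log_(pr)
        # belief update in the chosen frame
        pc = p if chose_a[i] else 1.0 - p
        pe = outcome[i] - pc
        if mid == "RW":
            pc += eta0 * pe
        elif mid == "PH":
            rate = gamma * eta_ph
            if rate > 1.0:
                rate = 1.0
            pc += rate * pe
            eta_ph = omega * eta_ph + (1.0 - omega) * abs(pe)
        elif mid == "CUBIC":
            eta = pe * pe / (4.0 * kappa)
            if eta > 1.0:
                eta = 1.0
            pc += eta * pe
        else:  # EXPLOG
            a = abs(pe)
            if lam == 0.0:
                eta = exp_(-delta)
            elif a <= PE_FLOOR:
                eta = 0.0
            else:
                eta = exp_(-delta * (-log_(a)) ** lam)
            pc += eta * pe
        if pc < 0.0:
            pc = 0.0
        elif pc > 1.0:
            pc = 1.0
        p = pc if chose_a[i] else 1.0 - pc
    if floored:
        warnings.warn(f"choice_nll floored {floored} zero-probability choices at 1e-12",
                      RuntimeWarning, stacklevel=2)
    return nll


def records_to_frame(records: Sequence[ChoiceRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "trial": [r.trial for r in records],
        "m_a": [r.m_a for r in records],
        "m_b": [r.m_b for r in records],
        "choice": [r.choice for r in records],
        "outcome": [r.outcome for r in records],
    })


def records_from_frame(df: pd.DataFrame) -> List[ChoiceRecord]:
    return [ChoiceRecord(trial=int(r.trial), m_a=float(r.m_a), m_b=float(r.m_b),
                         choice=str(r.choice), outcome=float(r.outcome))
            for r in df.itertuples()]
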