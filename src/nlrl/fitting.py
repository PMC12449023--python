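"""Parameter estimation and model-comparison statistics.

Two estimation routes:

* :func:`fit_mle` — choice-likelihood maximisation with bounded local
  optimisation (L-BFGS-B) from many uniform random starts, the standard
  approach for softmax choice models;
* :func:`fit_tracking` — exhaustive grid search minimising the mean
  absolute deviation between the model's belief trajectory and a target
  sequence (realized outcomes, the generative mean, or observed
  placements), used when no stochastic choices are modelled.

Model comparison: AIC (``2k + 2*NLL``, group-aggregated by summation)
and random-effects Bayesian model selection with a variational Dirichlet
scheme, reporting expected model frequencies, exceedance probabilities
and the Bayes Omnibus Risk (the posterior probability that all model
frequencies are indistinguishable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma, gammaln

from .choice import ChoiceParams, choice_nll
from .models import MODELS, ModelParams, PE_FLOOR

__all__ = [
    "FitResult",
    "BMSResult",
    "DEFAULT_BOUNDS",
    "DEFAULT_GRIDS",
    "aic",
    "fit_mle",
    "fit_tracking",
    "tracking_error_grid",
    "bms",
]

#: Parameter names of each learning model, in fitting order.
MODEL_PARAM_NAMES = {
    "RW": ("eta0",),
    "PH": ("omega", "gamma"),
    "CUBIC": ("kappa",),
    "EXPLOG": ("delta", "lam"),
}

#: Estimation bounds.  The exp-log parameters are estimable on [0, inf);
#: finite caps keep the optimiser stable.
DEFAULT_BOUNDS = {
    "eta0": (0.0, 1.0),
    "omega": (0.0, 1.0),
    "gamma": (0.0, 5.0),
    "kappa": (1e-3, 10.0),
    "delta": (0.0, 20.0),
    "lam": (0.0, 20.0),
    "rho": (1e-2, 2.0),
    "inv_temp": (0.0, 50.0),
}


def _default_grids() -> dict:
    return {
        "RW": {"eta0": np.round(np.arange(0.01, 1.0001, 0.01), 4)},
        "CUBIC": {"kappa": np.geomspace(1e-3, 10.0, 81)},
        "PH": {"omega": np.round(np.arange(0.0, 1.0001, 0.02), 4),
               "gamma": np.round(np.arange(0.1, 3.0001, 0.1), 4)},
        # lambda starts strictly above 0: the constant-rate reduction is
        # the RW model and competes as such, not inside this family
        "EXPLOG": {"delta": np.round(np.arange(0.05, 4.0001, 0.05), 4),
                   "lam": np.round(np.arange(0.1, 3.1001, 0.1), 4)},
    }


#: Tracking-fit grids: rate-like parameters at 0.01 resolution, kappa on a
#: log grid over (1e-3, 10], two-dimensional grids for PH and exp-log.
DEFAULT_GRIDS = _default_grids()


@dataclass
class FitResult:
    """Outcome of one model fit (likelihood- or tracking-based)."""

    model_id: str
    params: Dict[str, float]
    objective: float
    n_params: int
    aic: Optional[float] = None
    n_starts: int = 1
    converged_frac: float = 1.0
    best_start_seed: Optional[int] = None
    method: str = "mle"

    def model_params(self, **overrides) -> ModelParams:
        kw = {k: v for k, v in self.params.items() if k in MODEL_PARAM_NAMES[self.model_id]}
        kw.update(overrides)
        return ModelParams(model_id=self.model_id, **kw)

    def choice_params(self) -> ChoiceParams:
        return ChoiceParams(rho=self.params.get("rho", 1.0),
                            inv_temp=self.params.get("inv_temp", 0.0))


def aic(nll: float, k: int) -> float:
    """Akaike's Information Criterion, ``2k + 2*NLL`` (= ``2k - 2*LL``)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return 2.0 * k + 2.0 * nll


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting

def fit_mle(records, model_id: str, task: str = "binary",
            bounds: Optional[dict] = None, n_starts: int = 20, seed: int = 0,
            fixed: Optional[Dict[str, float]] = None) -> FitResult:
    """Fit learning + choice parameters to observed choices by MLE.

    Bounded local optimisation from ``n_starts`` uniform random
    initialisations covering the whole parameter space; the best run
    wins.  ``fixed`` pins named parameters (e.g. ``{"rho": 1.0}``).
    Deterministic given ``seed``.
    """
    if model_id not in MODELS:
        raise ValueError(f"unknown model_id {model_id!r}")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    fixed = dict(fixed or {})
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    names = [n for n in (*MODEL_PARAM_NAMES[model_id], "rho", "inv_temp")
             if n not in fixed]
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])

    def unpack(x: np.ndarray) -> Tuple[ModelParams, ChoiceParams]:
        d = dict(zip(names, x))
        d.update(fixed)
        mp = ModelParams(model_id=model_id,
                         **{k: d[k] for k in MODEL_PARAM_NAMES[model_id]})
        cp = ChoiceParams(rho=max(d.get("rho", 1.0), 1e-2),
                          inv_temp=max(d.get("inv_temp", 0.0), 0.0))
        return mp, cp

    def objective(x: np.ndarray) -> float:
        x = np.clip(x, lo, hi)
        mp, cp = unpack(x)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            return choice_nll(records, mp, cp, task=task)

    rng = np.random.default_rng(seed)
    # scale-like parameters get log-uniform starts: uniform draws over a
    # wide range like [0, 20] pile onto flat plateaus (e.g. very large
    # lam turns the exp-log transfer into a step with zero gradient)
    log_scale = np.array([n in ("kappa", "delta", "lam", "inv_temp") for n in names])
    lo_f = np.where(log_scale, np.maximum(lo, 1e-2), lo)

    def draw_start() -> np.ndarray:
        u = rng.uniform(lo, hi)
        g = np.exp(rng.uniform(np.log(np.where(log_scale, lo_f, 1.0)),
                               np.log(np.where(log_scale, hi, 1.0))))
        return np.where(log_scale, g, u)

    best = None
    n_ok = 0
    failures = []
    for s in range(n_starts):
        x0 = draw_start()
        try:
            res = minimize(objective, x0, method="L-BFGS-B",
                           bounds=list(zip(lo, hi)),
                           options={"ftol": 1e-8, "maxiter": 500})
        except Exception as exc:  # pragma: no cover - optimizer pathologies
            failures.append(str(exc))
            continue
        n_ok += int(bool(res.success))
        if best is None or res.fun < best[0]:
            best = (float(res.fun), np.clip(res.x, lo, hi), s)
    if best is None:
        raise RuntimeError(f"all {n_starts} starts failed: {failures[:3]}")
    nll, x, start = best
    params = dict(zip(names, (float(v) for v in x)))
    params.update(fixed)
    k = len(names)
    return FitResult(model_id=model_id, params=params, objective=nll,
                     n_params=k, aic=aic(nll, k), n_starts=n_starts,
                     converged_frac=n_ok / n_starts, best_start_seed=start,
                     method="mle")


# ---------------------------------------------------------------------------
# Tracking fits (grid search on mean absolute deviation)

def _grid_matrix(model_id: str, grid: Optional[dict]) -> Tuple[list, np.ndarray]:
    """Expand a per-parameter grid dict into (names, combos) with combos
    ordered ascending lexicographically (ties break toward smaller values)."""
    g = grid if grid is not None else DEFAULT_GRIDS[model_id]
    names = list(MODEL_PARAM_NAMES[model_id])
    axes = [np.asarray(g[n], dtype=float) for n in names]
    if any(a.size == 0 for a in axes):
        raise ValueError("grid must be non-empty")
    mesh = np.meshgrid(*axes, indexing="ij")
    combos = np.column_stack([m.ravel() for m in mesh])
    return names, combos


def tracking_error_grid(outcomes: np.ndarray, target: np.ndarray, model_id: str,
                        combos: np.ndarray, p_init: float = 0.5,
                        eta_init: float = 0.5, return_eta_mean: bool = False):
    """Mean |belief - target| for every parameter combo, vectorised.

    ``outcomes``/``target`` are (T,) or (E, T) for a batch of E
    environments; ``combos`` is (P, n_params).  The belief entering trial
    t (before seeing O(t)) is compared against ``target[t]``.  Returns an
    (E, P) error matrix (optionally also the mean applied learning rate).
    """
    O = np.atleast_2d(np.asarray(outcomes, dtype=float))
    tgt = np.atleast_2d(np.asarray(target, dtype=float))
    E, T = O.shape
    P = combos.shape[0]
    p = np.full((E, P), p_init)
    err = np.zeros((E, P))
    eta_sum = np.zeros((E, P)) if return_eta_mean else None
    if model_id == "RW":
        eta = combos[:, 0][None, :]
    elif model_id == "PH":
        omega = combos[:, 0][None, :]
        gamma = combos[:, 1][None, :]
        eta_ph = np.full((E, P), eta_init)
    elif model_id == "CUBIC":
        kappa4 = 4.0 * combos[:, 0][None, :]
    elif model_id == "EXPLOG":
        delta = combos[:, 0][None, :]
        lam = combos[:, 1][None, :]
    else:
        raise ValueError(f"unknown model_id {model_id!r}")
    for t in range(T):
        err += np.abs(p - tgt[:, t:t + 1])
        pe = O[:, t:t + 1] - p
        if model_id == "RW":
            rate = eta
            p = p + rate * pe
        elif model_id == "PH":
            rate = np.minimum(gamma * eta_ph, 1.0)
            p = p + rate * pe
            eta_ph = omega * eta_ph + (1.0 - omega) * np.abs(pe)
        elif model_id == "CUBIC":
            rate = np.minimum(pe * pe / kappa4, 1.0)
            p = p + rate * pe
        else:
            a = np.maximum(np.abs(pe), PE_FLOOR)
            rate = np.exp(-delta * (-np.log(a)) ** lam)
            rate[np.broadcast_to(np.abs(pe) <= PE_FLOOR, rate.shape)] = 0.0
            p = p + rate * pe
        np.clip(p, 0.0, 1.0, out=p)
        if return_eta_mean:
            eta_sum += eta_ph if model_id == "PH" else rate
    err /= T
    if return_eta_mean:
        return err, eta_sum / T
    return err


def fit_tracking(data, model_id: str, grid: Optional[dict] = None,
                 target: Union[str, np.ndarray] = "outcomes",
                 p_init: float = 0.5, eta_init: float = 0.5) -> FitResult:
    """Grid-search fit minimising mean absolute deviation from a target.

    ``data`` is an outcome schedule or a 1-D outcome sequence the model
    learns from.  ``target`` selects what the belief is compared against:
    ``"outcomes"`` (mean |PE| minimisation), ``"gen_mean"`` (tracking the
    generative mean), or an explicit sequence such as observed bucket
    placements.  Ties break toward smaller parameter values.
    """
    outcomes = np.asarray(getattr(data, "outcomes", data), dtype=float)
    if outcomes.ndim != 1:
        raise ValueError("fit_tracking expects a single outcome stream")
    if isinstance(target, str):
        if target == "outcomes":
            tgt = outcomes
        elif target == "gen_mean":
            tgt = np.asarray(data.gen_mean, dtype=float)
        else:
            raise ValueError(f"unknown target {target!r}")
    else:
        tgt = np.asarray(target, dtype=float)
        if tgt.shape != outcomes.shape:
            raise ValueError("target sequence must match the outcome sequence length")
    names, combos = _grid_matrix(model_id, grid)
    err = tracking_error_grid(outcomes, tgt, model_id, combos,
                              p_init=p_init, eta_init=eta_init)[0]
    best = int(np.argmin(err))  # first minimum: smallest params win ties
    params = dict(zip(names, (float(v) for v in combos[best])))
    return FitResult(model_id=model_id, params=params, objective=float(err[best]),
                     n_params=len(names), aic=None, n_starts=combos.shape[0],
                     method="tracking")


# ---------------------------------------------------------------------------
# Random-effects Bayesian model selection

@dataclass
class BMSResult:
    """Random-effects model-selection summary for a subjects x models table."""

    alpha: np.ndarray
    expected_freq: np.ndarray
    xp: np.ndarray
    bor: float
    g: np.ndarray
    F1: float
    F0: float


def _dirichlet_free_energy(L: np.ndarray, g: np.ndarray, alpha: np.ndarray,
                           alpha0: np.ndarray) -> float:
    """Variational lower bound of the Dirichlet random-effects model."""
    E_ln_r = digamma(alpha) - digamma(alpha.sum())
    lnC0 = gammaln(alpha0.sum()) - gammaln(alpha0).sum()
    lnC = gammaln(alpha.sum()) - gammaln(alpha).sum()
    F = float((g * L).sum()
              + (g * E_ln_r[None, :]).sum()
              + lnC0 + ((alpha0 - 1.0) * E_ln_r).sum()
              - lnC - ((alpha - 1.0) * E_ln_r).sum()
              - (g * np.log(np.maximum(g, 1e-32))).sum())
    return F


def bms(log_evidence: np.ndarray, alpha0: float = 1.0, n_samples: int = 200_000,
        seed: int = 0, tol: float = 1e-8, max_iter: int = 500) -> BMSResult:
    """Random-effects Bayesian model selection (variational Dirichlet scheme).

    ``log_evidence`` is an (n_subjects, n_models) table (e.g. -AIC/2 per
    subject and model).  Returns expected model frequencies, exceedance
    probabilities (estimated from a seeded Dirichlet Monte-Carlo sample)
    and the Bayes Omnibus Risk — the posterior probability of the null
    that all model frequencies are equal, which approaches 1 when the
    evidences cannot discriminate the models.
    """
    L = np.asarray(log_evidence, dtype=float)
    if L.ndim != 2 or L.shape[1] < 2 or L.shape[0] < 1:
        raise ValueError("log_evidence must be (n_subjects >= 1, n_models >= 2)")
    if not np.all(np.isfinite(L)):
        raise ValueError("log_evidence must be finite")
    N, K = L.shape
    a0 = np.full(K, float(alpha0))
    alpha = a0.copy()
    for _ in range(max_iter):
        log_u = L + (digamma(alpha) - digamma(alpha.sum()))[None, :]
        log_u = log_u - log_u.max(axis=1, keepdims=True)
        g = np.exp(log_u)
        g /= g.sum(axis=1, keepdims=True)
        alpha_new = a0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    expected = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    xp = np.bincount(winners, minlength=K) / n_samples
    F1 = _dirichlet_free_energy(L, g, alpha, a0)
    # null: frequencies fixed at 1/K
    F0 = float(np.sum(np.log(np.exp(L - L.max(axis=1, keepdims=True)).mean(axis=1))
                      + L.max(axis=1)))
    bor = 1.0 / (1.0 + math.exp(min(700.0, max(-700.0, F1 - F0))))
    return BMSResult(alpha=alpha, expected_freq=expected, xp=xp, bor=bor,
                     g=g, F1=F1, F0=F0)
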