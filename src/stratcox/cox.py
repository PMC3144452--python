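"""Design-weighted Cox proportional-hazards regression.

This is the methodological core of the package: a Cox partial-likelihood
fitter that accepts sampling (design) weights in the estimating function, in
the spirit of Binder (1992) and Lin (2000), together with the design-based
sandwich variance.

Weighted score.  With covariates x_i, event indicator d_i, weight w_i and
risk-set sums S^(r)(t; b) = sum_{j: t_j >= t} w_j exp(x_j' b) x_j^{(r)}
(r = 0, 1, 2), the estimating function is

    U(b) = sum_i w_i d_i [x_i - S1(t_i; b) / S0(t_i; b)]

solved by Newton-Raphson with step-halving; ties use the Breslow convention.
Setting every weight to a common constant recovers the classical unweighted
partial-likelihood estimate, and rescaling all weights by any positive
constant changes neither the estimate nor the sandwich variance.

Sandwich variance.  V = I^{-1} M I^{-1}, with I the weighted observed
information and M = sum_i (w_i r_i)(w_i r_i)' the outer-product sum of the
per-individual score residuals

    r_i = d_i (x_i - xbar(t_i))
          - exp(eta_i) * sum_{events k: t_k <= t_i} (w_k / S0(t_k)) (x_i - xbar(t_k))

where xbar(t) = S1(t)/S0(t).

Model specifications.  Three nested covariate codings of the occupational
cohort are supported, always with professionals as the reference stratum:

* ``full``      - stratum indicators plus one smoking indicator per stratum
                  (no common smoking main effect); columns
                  ``technicians, administrative, smoking:professionals,
                  smoking:technicians, smoking:administrative``.
* ``marginal``  - stratum indicators plus a single common smoking term;
                  columns ``technicians, administrative, smoking``.
* ``smoke_only``- the smoking indicator alone (crude effect).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConvergenceError, InvalidParameterError

__all__ = [
    "ModelSpec",
    "FitResult",
    "MODEL_NAMES",
    "build_design_matrix",
    "fit_weighted_cox",
    "sandwich_variance",
    "write_fit",
]

MODEL_NAMES = ("full", "marginal", "smoke_only")

STRATA = ("professionals", "technicians", "administrative")


@dataclass(frozen=True)
class ModelSpec:
    """One of the three Cox covariate specifications (see module docstring)."""

    name: str

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise InvalidParameterError(
                f"unknown model {self.name!r}; expected one of {MODEL_NAMES}"
            )

    @property
    def columns(self) -> tuple[str, ...]:
        if self.name == "full":
            return (
                "technicians",
                "administrative",
                "smoking:professionals",
                "smoking:technicians",
                "smoking:administrative",
            )
        if self.name == "marginal":
            return ("technicians", "administrative", "smoking")
        return ("smoking",)


def _as_model(model) -> ModelSpec:
    return model if isinstance(model, ModelSpec) else ModelSpec(str(model))


def build_design_matrix(sample: pd.DataFrame, model):
    """Build covariate matrix and response vectors for one model spec.

    Returns ``(X, names, time, event, weights)``; a professionals non-smoker
    maps to an all-zero covariate row in every model.  ``sample`` must carry
    ``stratum``, ``smoker``, ``time``, ``event`` and (optionally) ``weight``
    columns; a missing weight column means unit weights.
    """
    model = _as_model(model)
    if len(sample) == 0:
        raise InvalidParameterError("sample is empty")

    stratum = np.asarray(sample["stratum"].astype(str))
    smoker = np.asarray(sample["smoker"], dtype=float)
    tech = (stratum == "technicians").astype(float)
    admin = (stratum == "administrative").astype(float)
    prof = 1.0 - tech - admin

    if model.name == "full":
        X = np.column_stack(
            [tech, admin, prof * smoker, tech * smoker, admin * smoker]
        )
    elif model.name == "marginal":
        X = np.column_stack([tech, admin, smoker])
    else:
        X = smoker.reshape(-1, 1)

    time = np.asarray(sample["time"], dtype=float)
    event = np.asarray(sample["event"], dtype=float)
    weights = (
        np.asarray(sample["weight"], dtype=float)
        if "weight" in sample.columns
        else np.ones(len(sample))
    )
    return X, model.columns, time, event, weights


@dataclass
class FitResult:
    """Estimates and variances from one weighted Cox fit.

    ``se`` is the model-based (inverse-information) standard error and
    ``robust_se`` the design-based sandwich standard error, both on the
    log-hazard-ratio scale.
    """

    names: tuple[str, ...]
    coef: np.ndarray              # log hazard ratios
    cov: np.ndarray               # model-based covariance (inverse information)
    robust_cov: np.ndarray        # sandwich covariance
    converged: bool
    n_iter: int
    n_events: int
    loglik: float

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def robust_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.robust_cov))

    def __getitem__(self, name: str) -> float:
        """Log-HR of a named coefficient."""
        return float(self.coef[self.names.index(name)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": list(self.names),
                "loghr": self.coef,
                "hr": self.hr,
                "se": self.se,
                "robust_se": self.robust_se,
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "coefficients": self.to_frame().to_dict(orient="records"),
                "converged": self.converged,
                "n_iter": self.n_iter,
                "n_events": self.n_events,
                "loglik": self.loglik,
            },
            indent=2,
        )


def _risk_index(time_sorted: np.ndarray):
    """Indices of tie groups in an ascending-sorted time vector.

    ``first[i]`` is the first position with the same time as position i (risk
    sets under Breslow start there); ``last[i]`` the last such position.
    """
    first = np.searchsorted(time_sorted, time_sorted, side="left")
    last = np.searchsorted(time_sorted, time_sorted, side="right") - 1
    return first, last


def _loglik_score_info(beta, X, time, event, weights, first):
    """Weighted log partial likelihood, score and information (Breslow ties).

    Inputs must already be sorted ascending by time; ``first`` from
    :func:`_risk_index`.
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    r = weights * np.exp(eta)                          # w_j exp(x_j'b)
    # reverse cumulative sums: position i holds the sum over j >= i
    s0_rev = np.cumsum(r[::-1])[::-1]
    s1_rev = np.cumsum((r[:, None] * X)[::-1], axis=0)[::-1]
    xo = X[:, :, None] * X[:, None, :]
    s2_rev = np.cumsum((r[:, None, None] * xo)[::-1], axis=0)[::-1]

    s0 = s0_rev[first]                                 # S0 at each subject's time
    s1 = s1_rev[first]
    s2 = s2_rev[first]

    wd = weights * event
    ll = float(np.sum(wd * (eta - np.log(s0))))
    xbar = s1 / s0[:, None]
    score = (wd[:, None] * (X - xbar)).sum(axis=0)
    v = s2 / s0[:, None, None] - xbar[:, :, None] * xbar[:, None, :]
    info = (wd[:, None, None] * v).sum(axis=0)
    return ll, score, info, xbar, s0


def fit_weighted_cox(
    X,
    time,
    event,
    weights,
    *,
    names=None,
    tol: float = 1e-9,
    max_iter: int = 50,
) -> FitResult:
    """Fit the weighted Cox model by Newton-Raphson with step-halving.

    Convergence is declared when the relative change in the weighted log
    partial likelihood falls below ``tol``.  Raises
    :class:`~stratcox.errors.ConvergenceError` (with the iteration trace) on
    non-convergence, e.g. monotone likelihood from perfect separation, and
    :class:`~stratcox.errors.InvalidParameterError` on degenerate input.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    weights = np.asarray(weights, dtype=float)
    n, p = X.shape
    if not (len(time) == len(event) == len(weights) == n):
        raise InvalidParameterError("X, time, event, weights must share length")
    if np.any(weights <= 0):
        raise InvalidParameterError("weights must be strictly positive")
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(time)):
        raise InvalidParameterError("missing or non-finite values in input")
    n_events = int(event.sum())
    if n_events == 0:
        raise InvalidParameterError("no events: the partial likelihood is empty")
    if names is None:
        names = tuple(f"x{j}" for j in range(p))
    names = tuple(names)

    order = np.argsort(time, kind="stable")
    Xs, ts, ds, ws = X[order], time[order], event[order], weights[order]
    first, last = _risk_index(ts)

    beta = np.zeros(p)
    ll, score, info, _, _ = _loglik_score_info(beta, Xs, ts, ds, ws, first)
    trace = [(0, ll, beta.copy())]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            _raise_singular(info, names, trace)
        # step-halving: never accept a decrease in the log partial likelihood
        alpha = 1.0
        for _ in range(30):
            cand = beta + alpha * step
            ll_new, score_new, info_new, _, _ = _loglik_score_info(
                cand, Xs, ts, ds, ws, first
            )
            if ll_new >= ll - 1e-14:
                break
            alpha /= 2.0
        else:
            raise ConvergenceError("step-halving failed to improve likelihood", trace)
        beta, score, info = cand, score_new, info_new
        trace.append((it, ll_new, beta.copy()))
        if abs(ll_new - ll) <= tol * (abs(ll) + tol):
            ll = ll_new
            converged = True
            break
        ll = ll_new
        if np.max(np.abs(beta)) > 50:
            raise ConvergenceError(
                "coefficients diverging (monotone likelihood / perfect separation?)",
                trace,
            )
    if not converged:
        raise ConvergenceError(f"no convergence in {max_iter} iterations", trace)
    if np.max(np.abs(beta)) > 15:
        # the likelihood plateaued at an implausibly large coefficient:
        # classic monotone-likelihood signature (R's survival warns near 23)
        raise ConvergenceError(
            "estimate ran off to an extreme value "
            f"(max |log-HR| = {np.max(np.abs(beta)):.1f}): monotone likelihood / "
            "perfect separation",
            trace,
        )

    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        _raise_singular(info, names, trace)
    robust_cov = _sandwich_sorted(beta, Xs, ts, ds, ws, first, last, info)
    return FitResult(
        names=names,
        coef=beta,
        cov=cov,
        robust_cov=robust_cov,
        converged=True,
        n_iter=it,
        n_events=n_events,
        loglik=ll,
    )


def _raise_singular(info, names, trace):
    diag = np.diag(info)
    bad = [names[j] for j in range(len(names)) if diag[j] <= 1e-12 * (1 + diag.max())]
    raise ConvergenceError(
        "singular information matrix"
        + (f"; degenerate/collinear columns: {bad}" if bad else f"; columns: {list(names)}"),
        trace,
    )


def _sandwich_sorted(beta, X, time, event, weights, first, last, info):
    """Sandwich covariance I^{-1} M I^{-1} on ascending-sorted data."""
    eta = np.clip(X @ beta, -500, 500)
    r = weights * np.exp(eta)
    s0_rev = np.cumsum(r[::-1])[::-1]
    s1_rev = np.cumsum((r[:, None] * X)[::-1], axis=0)[::-1]
    s0 = s0_rev[first]
    xbar = s1_rev[first] / s0[:, None]

    # cumulative (over event times <= t_i) of w_k d_k / S0(t_k) and its xbar-
    # weighted counterpart; ties resolved with the 'last' index so every event
    # at t_i is included in its own compensator per Breslow.
    g = weights * event / s0
    a0 = np.cumsum(g)[last]
    a1 = np.cumsum(g[:, None] * xbar, axis=0)[last]

    resid = event[:, None] * (X - xbar) - np.exp(eta)[:, None] * (
        X * a0[:, None] - a1
    )
    wr = weights[:, None] * resid
    M = wr.T @ wr
    info_inv = np.linalg.inv(info)
    V = info_inv @ M @ info_inv
    return (V + V.T) / 2.0


def sandwich_variance(X, time, event, weights, beta_hat) -> np.ndarray:
    """Design-based (Binder) robust covariance of a converged estimate.

    Symmetric positive semi-definite; invariant to rescaling all weights by a
    common positive constant.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    weights = np.asarray(weights, dtype=float)
    beta_hat = np.asarray(beta_hat, dtype=float)
    order = np.argsort(time, kind="stable")
    Xs, ts, ds, ws = X[order], time[order], event[order], weights[order]
    first, last = _risk_index(ts)
    _, _, info, _, _ = _loglik_score_info(beta_hat, Xs, ts, ds, ws, first)
    cond = np.linalg.cond(info)
    if not np.isfinite(cond) or cond > 1e12:
        _raise_singular(info, tuple(f"x{j}" for j in range(X.shape[1])), [])
    return _sandwich_sorted(beta_hat, Xs, ts, ds, ws, first, last, info)


def write_fit(fit: FitResult, csv_path=None, json_path=None) -> None:
    """Serialize a fit as a delimited table and/or structured JSON."""
    if csv_path is not None:
        fit.to_frame().to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            fh.write(fit.to_json())
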