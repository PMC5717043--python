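"""The LATER model of saccade latency and its constrained maximum-likelihood fit.

LATER (Linear Approach to Threshold with Ergodic Rate) describes a saccade
latency as the time a linearly rising decision signal needs to travel from
a baseline level ``theta0`` to a response threshold ``theta_t``.  The rate
of rise is constant within a trial but varies across trials as a Gaussian
with mean ``mu`` and standard deviation ``sigma``; the latency is therefore

    T = theta / R,   R ~ Normal(mu, sigma),   theta = theta_t - theta0,

which is the *recinormal* distribution: 1/T is normal with mean ``mu/theta``
and SD ``sigma/theta``.  On a reciprobit plot (probit of the cumulative
probability against 1/T) recinormal data fall on a straight line with slope
``-theta/sigma`` and intercept ``mu/sigma``.

Only the threshold height ``theta`` is identified from behavior, so the
threshold is fixed to an arbitrary value (default 1) and the likelihood is
invariant to jointly rescaling ``(theta, mu, sigma)``.  To ask *which*
parameter differs between experimental conditions, three constrained
variants are fitted to all conditions jointly: one lets ``theta0`` vary
across conditions, one ``mu``, one ``sigma``, with the remaining two
parameters shared.  :class:`ConstrainedLaterModel` performs that fit by
multi-start bounded quasi-Newton maximum likelihood.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

VARIANTS = ("vary_theta0", "vary_mu", "vary_sigma")

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

#: below this mu/sigma ratio the mass of non-positive rates (never reaching
#: threshold) exceeds ~3e-5 and the density is no longer properly normalized
_MU_SIGMA_WARN = 4.0


class LaterFitError(RuntimeError):
    """Raised when no optimizer start converges; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass(frozen=True)
class LaterParams:
    """Parameters of one LATER unit (one experimental condition)."""

    theta0: float
    theta_t: float
    mu: float
    sigma: float

    @property
    def theta(self) -> float:
        """Threshold height: distance from baseline to threshold."""
        return self.theta_t - self.theta0

    def validate(self) -> "LaterParams":
        if not 0.0 <= self.theta0 < self.theta_t:
            raise ValueError(f"need 0 <= theta0 < theta_t, got {self}")
        if self.mu <= 0 or self.sigma <= 0:
            raise ValueError(f"mu and sigma must be positive, got {self}")
        if self.mu / self.sigma < _MU_SIGMA_WARN:
            warnings.warn(
                f"mu/sigma = {self.mu / self.sigma:.2f} < {_MU_SIGMA_WARN}: "
                "non-negligible mass of non-rising trials; recinormal density "
                "is unnormalized", RuntimeWarning, stacklevel=2)
        return self


def _check_t(t):
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("latencies must be strictly positive")
    return t


def recinormal_pdf(t, p: LaterParams):
    """Recinormal density (per ms) at latency ``t``."""
    p.validate()
    t = _check_t(t)
    z = (p.theta / t - p.mu) / p.sigma
    out = p.theta / (t * t * p.sigma * math.sqrt(2.0 * math.pi)) * np.exp(-0.5 * z * z)
    return out if out.ndim else float(out)


def recinormal_cdf(t, p: LaterParams):
    """P(T <= t) = Phi(mu/sigma - (theta/sigma)/t)."""
    p.validate()
    t = _check_t(t)
    out = stats.norm.cdf(p.mu / p.sigma - (p.theta / p.sigma) / t)
    return out if np.ndim(out) else float(out)


def recinormal_ppf(q, p: LaterParams):
    """Latency quantile: inverse of :func:`recinormal_cdf`.

    Only defined for q below Phi(mu/sigma), the probability that the signal
    rises at all.
    """
    p.validate()
    q = np.asarray(q, dtype=float)
    zmax = p.mu / p.sigma
    if np.any((q <= 0) | (q >= stats.norm.cdf(zmax))):
        raise ValueError("q out of the attainable range (0, Phi(mu/sigma))")
    rate = p.mu - p.sigma * stats.norm.ppf(q)
    out = p.theta / rate
    return out if out.ndim else float(out)


def recinormal_sample(p: LaterParams, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` latencies: rate ~ Normal(mu, sigma) rejected at <= 0, T = theta/rate."""
    p.validate()
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = np.empty(0)
    while out.size < n:
        r = rng.normal(p.mu, p.sigma, size=max(n - out.size, 16))
        out = np.concatenate([out, r[r > 0]])
    return p.theta / out[:n]


def loglik(latencies, p: LaterParams) -> float:
    """Sum of log recinormal densities (0.0 for an empty sample)."""
    lat = np.asarray(latencies, dtype=float)
    if lat.size == 0:
        return 0.0
    lat = _check_t(lat)
    z = (p.theta / lat - p.mu) / p.sigma
    return float(np.sum(math.log(p.theta) - 2.0 * np.log(lat)
                        - math.log(p.sigma) - _LOG_SQRT_2PI - 0.5 * z * z))


def reciprobit_points(latencies) -> pd.DataFrame:
    """Reciprobit coordinates of an empirical latency distribution.

    Sorted latencies get plotting positions (i - 0.5)/n; returns columns
    ``inv_latency`` (1/ms) and ``probit`` (Phi^-1 of the cumulative
    probability).  Recinormal data fall near a line with slope -theta/sigma
    and intercept mu/sigma.
    """
    lat = _check_t(latencies)
    if lat.size < 2:
        raise ValueError("need at least 2 latencies")
    if np.ptp(lat) == 0:
        raise ValueError("degenerate sample: all latencies identical")
    lat = np.sort(lat)
    pos = (np.arange(1, lat.size + 1) - 0.5) / lat.size
    return pd.DataFrame({"inv_latency": 1.0 / lat, "probit": stats.norm.ppf(pos)})


# ---------------------------------------------------------------------------
# constrained multi-condition fit
# ---------------------------------------------------------------------------

def _neg_loglik(x, variant, theta_t, lat, cond_idx, n_cond):
    """Joint negative log-likelihood; x packs [varied per cond..., shared, shared]."""
    if variant == "vary_theta0":
        theta0 = x[:n_cond][cond_idx]
        mu, sigma = x[n_cond], x[n_cond + 1]
    elif variant == "vary_mu":
        mu = x[:n_cond][cond_idx]
        theta0, sigma = x[n_cond], x[n_cond + 1]
    else:  # vary_sigma
        sigma = x[:n_cond][cond_idx]
        theta0, mu = x[n_cond], x[n_cond + 1]
    theta = theta_t - theta0
    z = (theta / lat - mu) / sigma
    ll = np.sum(np.log(theta) - 2.0 * np.log(lat) - np.log(sigma)
                - _LOG_SQRT_2PI - 0.5 * z * z)
    return -ll


class ConstrainedLaterModel(BaseEstimator):
    """Joint recinormal ML fit with one parameter free per condition.

    Parameters
    ----------
    variant : {"vary_theta0", "vary_mu", "vary_sigma"}
        Which parameter may differ across conditions; the other two are
        shared.
    theta_t : float
        Fixed response threshold.  The likelihood is scale invariant, so
        the choice only sets the units of the fitted parameters.
    n_starts : int
        Number of moment-initialized, jittered optimizer starts.
    min_trials : int
        Minimum trials required in every condition.
    random_state : int or numpy Generator, optional
        Seeds the start jitter; fits are reproducible given it.

    Attributes
    ----------
    conditions_ : list
        Condition keys in fit order.
    condition_values_ : dict
        Fitted value of the varied parameter per condition.
    shared_values_ : dict
        The two shared parameters.
    loglik_, k_, n_, bic_ : float / int
        Maximized joint log-likelihood, free-parameter count
        (``len(conditions) + 2``), total trial count, and
        ``k * ln(n) - 2 * loglik``.
    converged_ : bool
        Whether the returned optimum came from a successful optimizer run.
    """

    def __init__(self, variant: str = "vary_theta0", theta_t: float = 1.0,
                 n_starts: int = 10, min_trials: int = 20, random_state=None):
        self.variant = variant
        self.theta_t = theta_t
        self.n_starts = n_starts
        self.min_trials = min_trials
        self.random_state = random_state

    # -- initial values ----------------------------------------------------
    def _moment_init(self, stats_by_cond):
        """Map per-condition promptness (1/T) moments to model parameters."""
        m = np.array([s[0] for s in stats_by_cond])  # mean promptness
        s = np.array([s[1] for s in stats_by_cond])  # SD of promptness
        tt = self.theta_t
        if self.variant == "vary_theta0":
            mu = tt * m.min()
            theta = mu / m
            return np.concatenate([tt - theta, [mu, float(np.mean(theta * s))]])
        theta = 0.5 * tt
        if self.variant == "vary_mu":
            return np.concatenate([theta * m, [tt - theta, float(np.mean(theta * s))]])
        return np.concatenate([theta * s, [tt - theta, float(theta * np.mean(m))]])

    def _bounds(self, n_cond):
        tt = self.theta_t
        b_theta0 = (0.0, 0.999 * tt)
        b_mu = (1e-8, None)
        b_sigma = (1e-9, None)
        varied = {"vary_theta0": b_theta0, "vary_mu": b_mu, "vary_sigma": b_sigma}
        shared = {"vary_theta0": [b_mu, b_sigma], "vary_mu": [b_theta0, b_sigma],
                  "vary_sigma": [b_theta0, b_mu]}
        return [varied[self.variant]] * n_cond + shared[self.variant]

    def fit(self, X: Mapping[object, Sequence[float]], y=None):
        """Fit to ``X``: a mapping from condition key to latency array (ms)."""
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if not X:
            raise ValueError("no conditions given")
        conds = list(X.keys())
        arrays = []
        for c in conds:
            a = np.asarray(X[c], dtype=float)
            if a.size < self.min_trials:
                raise ValueError(
                    f"condition {c!r} has {a.size} trials; need >= {self.min_trials}")
            if np.any(a <= 0):
                raise ValueError(f"condition {c!r} contains non-positive latencies")
            arrays.append(a)
        lat = np.concatenate(arrays)
        cond_idx = np.repeat(np.arange(len(conds)), [a.size for a in arrays])
        n_cond = len(conds)

        inv_stats = [(float(np.mean(1.0 / a)), float(np.std(1.0 / a) + 1e-12))
                     for a in arrays]
        x0 = self._moment_init(inv_stats)
        bounds = self._bounds(n_cond)
        lo = np.array([b[0] if b[0] is not None else -np.inf for b in bounds])
        hi = np.array([b[1] if b[1] is not None else np.inf for b in bounds])

        rng = (self.random_state if isinstance(self.random_state, np.random.Generator)
               else np.random.default_rng(self.random_state))
        args = (self.variant, self.theta_t, lat, cond_idx, n_cond)
        candidates, diags = [], []
        for k in range(max(1, self.n_starts)):
            if k == 0:
                xs = x0
            else:
                xs = x0 * np.exp(rng.normal(0.0, 0.15, size=x0.size))
                if self.variant == "vary_theta0":
                    xs[:n_cond] = x0[:n_cond] + rng.uniform(
                        -0.05, 0.05, size=n_cond) * self.theta_t
                else:
                    xs[n_cond] = x0[n_cond] + rng.uniform(-0.05, 0.05) * self.theta_t
            xs = np.clip(xs, lo + 1e-12, np.where(np.isfinite(hi), hi - 1e-12, xs))
            res = optimize.minimize(_neg_loglik, xs, args=args, method="L-BFGS-B",
                                    bounds=bounds)
            diags.append((bool(res.success), float(res.fun), res.message))
            if np.isfinite(res.fun):
                candidates.append((res.fun, tuple(res.x), bool(res.success)))
        converged = [c for c in candidates if c[2]]
        pool = converged or candidates
        if not pool:
            raise LaterFitError("no optimizer start produced a finite likelihood",
                                diags)
        # best log-likelihood first; ties broken lexicographically on params
        fun, xbest, success = sorted(pool, key=lambda c: (c[0], c[1]))[0]
        xbest = np.asarray(xbest)

        self.conditions_ = conds
        self.condition_values_ = {c: float(v) for c, v in zip(conds, xbest[:n_cond])}
        shared_names = {"vary_theta0": ("mu", "sigma"), "vary_mu": ("theta0", "sigma"),
                        "vary_sigma": ("theta0", "mu")}[self.variant]
        self.shared_values_ = {name: float(v)
                               for name, v in zip(shared_names, xbest[n_cond:])}
        self.loglik_ = -float(fun)
        self.k_ = n_cond + 2
        self.n_ = int(lat.size)
        self.bic_ = self.k_ * math.log(self.n_) - 2.0 * self.loglik_
        self.converged_ = bool(success)
        return self

    def params_for(self, condition) -> LaterParams:
        """Full LaterParams of one fitted condition."""
        v = self.condition_values_[condition]
        varied = self.variant.removeprefix("vary_")
        full = dict(self.shared_values_, **{varied: v}, theta_t=self.theta_t)
        return LaterParams(**full)

    def score(self, X, y=None) -> float:
        """Joint log-likelihood of new data under the fitted parameters."""
        return float(sum(loglik(np.asarray(X[c], dtype=float), self.params_for(c))
                         for c in X))

    def to_fit(self) -> "LaterVariantFit":
        return LaterVariantFit(
            variant=self.variant, theta_t=self.theta_t,
            condition_values={str(c): v for c, v in self.condition_values_.items()},
            shared_values=dict(self.shared_values_), loglik=self.loglik_,
            k=self.k_, n=self.n_, bic=self.bic_, converged=self.converged_,
            n_starts=self.n_starts)


@dataclass(frozen=True)
class LaterVariantFit:
    """Serializable result of one constrained variant fit."""

    variant: str
    theta_t: float
    condition_values: dict
    shared_values: dict
    loglik: float
    k: int
    n: int
    bic: float
    converged: bool
    n_starts: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thetaT"] = d.pop("theta_t")
        return d


def fit_variant(latencies_by_condition: Mapping[object, Sequence[float]],
                variant: str, theta_t_fixed: float = 1.0, n_starts: int = 10,
                seed=None, min_trials: int = 20) -> LaterVariantFit:
    """Functional wrapper over :class:`ConstrainedLaterModel`."""
    est = ConstrainedLaterModel(variant=variant, theta_t=theta_t_fixed,
                                n_starts=n_starts, min_trials=min_trials,
                                random_state=seed)
    return est.fit(latencies_by_condition).to_fit()
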