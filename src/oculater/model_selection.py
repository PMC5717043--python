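"""BIC information weights and the bootstrap comparison of LATER variants.

Which LATER parameter — baseline ``theta0``, mean rate ``mu`` or rate
variability ``sigma`` — best explains latency differences between
conditions?  Each candidate lets exactly one parameter vary across
conditions, so all three have the same number of free parameters and the
comparison reduces to the likelihood.  Evidence is expressed as BIC
information weights

    w_i = exp(-(BIC_i - min BIC) / 2) / sum_j exp(-(BIC_j - min BIC) / 2),

normalized relative evidences on [0, 1].  Their sampling variability is
assessed by a trial-level bootstrap, stratified by condition: every
iteration resamples each condition's trials with replacement (keeping the
per-condition n), fits all three variants on the identical resample, and
converts the three BICs to weights.  The summary is the mean weight per
variant with a 95% percentile interval over iterations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .later import VARIANTS, ConstrainedLaterModel, LaterFitError, LaterVariantFit


def information_weights(bics: Sequence[float]) -> np.ndarray:
    """BIC information weights (normalized exp(-delta/2))."""
    bics = np.asarray(bics, dtype=float)
    if bics.size == 0:
        raise ValueError("need at least one BIC")
    if np.any(np.isnan(bics)):
        raise ValueError("NaN BIC")
    rel = np.exp(-0.5 * (bics - bics.min()))
    return rel / rel.sum()


def baseline_reduction(fit: LaterVariantFit | Mapping, reference, comparison) -> float:
    """Percent reduction of the fitted baseline level between two conditions.

    ``100 * (theta0_ref - theta0_cmp) / theta0_ref`` from a ``vary_theta0``
    fit: positive when the comparison condition starts from a lower
    baseline (slower saccades).
    """
    if isinstance(fit, LaterVariantFit):
        variant, values = fit.variant, fit.condition_values
    else:
        variant, values = fit["variant"], fit["condition_values"]
    if variant != "vary_theta0":
        raise ValueError("baseline_reduction requires a vary_theta0 fit")
    ref = values[reference]
    cmp_ = values[comparison]
    if ref == 0:
        raise ZeroDivisionError("reference baseline level is 0")
    return 100.0 * (ref - cmp_) / ref


@dataclass(frozen=True)
class BootstrapComparison:
    """Aggregated bootstrap evidence for the three LATER variants."""

    n_boot: int
    seed: int | None
    weights_mean: dict
    weights_ci: dict
    per_iteration: np.ndarray  # (n_boot, 3) in VARIANTS order
    variant_fits_full_data: dict  # variant -> LaterVariantFit

    @property
    def best_variant(self) -> str:
        return max(self.weights_mean, key=self.weights_mean.get)

    def to_json(self, include_iterations: bool = False) -> str:
        d = {
            "n_boot": self.n_boot,
            "seed": self.seed,
            "weights_mean": self.weights_mean,
            "weights_ci": self.weights_ci,
            "best_variant": self.best_variant,
            "variant_fits_full_data": {
                v: f.to_dict() for v, f in self.variant_fits_full_data.items()},
        }
        if include_iterations:
            d["per_iteration"] = self.per_iteration.tolist()
        return json.dumps(d, indent=2)


class LaterBootstrapSelector(BaseEstimator):
    """Bootstrap BIC-weight comparison of the three constrained variants.

    Parameters mirror :class:`~oculater.later.ConstrainedLaterModel`;
    ``n_boot`` iterations resample trials within condition.  A failed fit
    inside an iteration is retried on a fresh resample up to
    ``retry_cap`` times before raising.

    Attributes (after :meth:`fit`)
    ------------------------------
    weights_mean_, weights_ci_ : dict
        Mean weight and (2.5th, 97.5th) percentile bounds per variant.
    per_iteration_ : ndarray of shape (n_boot, 3)
        Weights per iteration, columns in :data:`VARIANTS` order.
    variant_fits_ : dict
        Full-data fit of each variant (no resampling).
    """

    def __init__(self, n_boot: int = 100, theta_t: float = 1.0,
                 n_starts: int = 10, min_trials: int = 20, retry_cap: int = 5,
                 random_state=None):
        self.n_boot = n_boot
        self.theta_t = theta_t
        self.n_starts = n_starts
        self.min_trials = min_trials
        self.retry_cap = retry_cap
        self.random_state = random_state

    def _fit_all(self, data, rng) -> np.ndarray:
        bics = []
        for variant in VARIANTS:
            est = ConstrainedLaterModel(
                variant=variant, theta_t=self.theta_t, n_starts=self.n_starts,
                min_trials=self.min_trials,
                random_state=np.random.default_rng(rng.integers(2**31)))
            bics.append(est.fit(data).bic_)
        return information_weights(bics)

    def fit(self, X: Mapping[object, Sequence[float]], y=None):
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        arrays = {c: np.asarray(v, dtype=float) for c, v in X.items()}
        rng = np.random.default_rng(self.random_state)

        self.variant_fits_ = {}
        for variant in VARIANTS:
            est = ConstrainedLaterModel(
                variant=variant, theta_t=self.theta_t, n_starts=self.n_starts,
                min_trials=self.min_trials,
                random_state=np.random.default_rng(rng.integers(2**31)))
            self.variant_fits_[variant] = est.fit(arrays).to_fit()

        rows = np.empty((self.n_boot, len(VARIANTS)))
        for it in range(self.n_boot):
            last_err = None
            for _attempt in range(self.retry_cap):
                resample = {c: rng.choice(a, size=a.size, replace=True)
                            for c, a in arrays.items()}
                try:
                    rows[it] = self._fit_all(resample, rng)
                    break
                except LaterFitError as err:  # pragma: no cover - rare
                    last_err = err
            else:  # pragma: no cover - rare
                raise LaterFitError(
                    f"bootstrap iteration {it} failed {self.retry_cap} times"
                ) from last_err

        lo, hi = np.percentile(rows, [2.5, 97.5], axis=0)
        self.per_iteration_ = rows
        self.weights_mean_ = {v: float(m) for v, m in zip(VARIANTS, rows.mean(axis=0))}
        self.weights_ci_ = {v: (float(a), float(b)) for v, a, b in zip(VARIANTS, lo, hi)}
        return self

    def to_comparison(self) -> BootstrapComparison:
        seed = self.random_state if isinstance(self.random_state, (int, np.integer)) \
            else None
        return BootstrapComparison(
            n_boot=self.n_boot, seed=seed, weights_mean=dict(self.weights_mean_),
            weights_ci=dict(self.weights_ci_), per_iteration=self.per_iteration_,
            variant_fits_full_data=dict(self.variant_fits_))


def bootstrap_compare(latencies_by_condition: Mapping[object, Sequence[float]],
                      n_boot: int = 100, theta_t_fixed: float = 1.0,
                      seed=None, n_starts: int = 10,
                      min_trials: int = 20) -> BootstrapComparison:
    """Functional wrapper over :class:`LaterBootstrapSelector`."""
    sel = LaterBootstrapSelector(n_boot=n_boot, theta_t=theta_t_fixed,
                                 n_starts=n_starts, min_trials=min_trials,
                                 random_state=seed)
    return sel.fit(latencies_by_condition).to_comparison()
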