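"""Psychometric modelling of choice behavior.

The probability of a clockwise choice as a function of stimulus orientation
theta is modelled as a lapse-contaminated cumulative Gaussian,

    p(cw | theta) = lapse/2 + (1 - lapse) * Phi((theta - mu) / sigma),

fit by maximum likelihood under a Bernoulli observation model.  Orientation
sensitivity is defined as 1/sigma.  The prior-bias variant fits one curve
per prior context with a shared sigma and lapse; the decision bias is the
horizontal displacement |mu_prior_cw - mu_prior_ccw|.

Model classes follow the statsmodels convention: construct from data, call
``fit()``, get a Results object with estimates and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .containers import PRIORS

_EPS = 1e-9


class DegenerateFitError(RuntimeError):
    """The data cannot constrain the psychometric fit (e.g. one choice only)."""


def _nll_psycho(params, theta, y):
    mu, sigma, lapse = params
    p = lapse / 2.0 + (1.0 - lapse) * norm.cdf((theta - mu) / sigma)
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return -np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))


def _nll_bias(params, theta, y, prior_is_cw):
    mu1, mu2, sigma, lapse = params
    mu = np.where(prior_is_cw, mu1, mu2)
    p = lapse / 2.0 + (1.0 - lapse) * norm.cdf((theta - mu) / sigma)
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return -np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))


def _multistart(nll, args, x0s, bounds):
    best = None
    for x0 in x0s:
        res = minimize(nll, x0, args=args, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    return best


def _choice_vector(trials: pd.DataFrame) -> np.ndarray:
    return (trials["choice_category"].to_numpy() == "cw").astype(float)


@dataclass
class PsychometricResults:
    mu: float
    sigma: float
    lapse: float
    loglike: float
    n_trials: int
    group: tuple = ()

    @property
    def sensitivity(self) -> float:
        """Orientation sensitivity, 1/sigma (deg^-1)."""
        return 1.0 / self.sigma

    def predict(self, theta) -> np.ndarray:
        theta = np.asarray(theta, float)
        return self.lapse / 2.0 + (1.0 - self.lapse) * norm.cdf(
            (theta - self.mu) / self.sigma
        )

    def summary(self) -> str:
        lines = [
            "Psychometric fit (cumulative Gaussian + lapse)",
            f"  group        : {self.group or 'all trials'}",
            f"  n trials     : {self.n_trials}",
            f"  mu           : {self.mu:+.3f} deg",
            f"  sigma        : {self.sigma:.3f} deg",
            f"  sensitivity  : {self.sensitivity:.3f} 1/deg",
            f"  lapse        : {self.lapse:.4f}",
            f"  log-likelihood: {self.loglike:.2f}",
        ]
        return "\n".join(lines)


@dataclass
class BiasResults:
    mu_prior_cw: float
    mu_prior_ccw: float
    sigma: float
    lapse: float
    loglike: float
    n_trials: int
    group: tuple = ()

    @property
    def sensitivity(self) -> float:
        return 1.0 / self.sigma

    @property
    def decision_bias(self) -> float:
        """Unsigned horizontal displacement between the prior-specific curves
        (deg)."""
        return abs(self.mu_prior_cw - self.mu_prior_ccw)

    @property
    def signed_bias(self) -> float:
        """Signed displacement, positive when the cw-prior curve sits left of
        the ccw-prior curve (i.e. the prior pulls choices toward itself)."""
        return self.mu_prior_ccw - self.mu_prior_cw

    def summary(self) -> str:
        return "\n".join(
            [
                "Prior-bias psychometric fit (shared slope)",
                f"  group         : {self.group or 'all trials'}",
                f"  n trials      : {self.n_trials}",
                f"  mu (cw prior) : {self.mu_prior_cw:+.3f} deg",
                f"  mu (ccw prior): {self.mu_prior_ccw:+.3f} deg",
                f"  decision bias : {self.decision_bias:.3f} deg",
                f"  sigma         : {self.sigma:.3f} deg",
                f"  sensitivity   : {self.sensitivity:.3f} 1/deg",
                f"  lapse         : {self.lapse:.4f}",
            ]
        )


class PsychometricModel:
    """ML psychometric model for one group of trials.

    Parameters
    ----------
    theta : array
        Stimulus orientation per trial (deg).
    y : array
        1 for a clockwise choice, 0 for counterclockwise.
    """

    bounds = ((-10.0, 10.0), (0.05, 50.0), (0.0, 0.5))

    def __init__(self, theta, y):
        self.theta = np.asarray(theta, float)
        self.y = np.asarray(y, float)
        if len(np.unique(self.theta)) < 2:
            raise DegenerateFitError("need at least 2 distinct orientations")
        if self.y.min() == self.y.max():
            raise DegenerateFitError(
                "all trials share one choice; the slope is unidentifiable"
            )

    @classmethod
    def from_trials(cls, trials: pd.DataFrame) -> "PsychometricModel":
        return cls(trials["orientation"], _choice_vector(trials))

    def fit(self, n_restarts: int = 5, seed: int = 0) -> PsychometricResults:
        """Bounded quasi-Newton ML fit with random restarts (the lapse/slope
        trade-off creates local minima)."""
        rng = np.random.default_rng(seed)
        spread = self.theta.std() or 1.0
        x0s = [np.array([self.theta.mean(), spread, 0.02])]
        for _ in range(n_restarts - 1):
            x0s.append(
                np.array(
                    [
                        rng.uniform(-2, 2),
                        rng.uniform(0.3, 3) * spread,
                        rng.uniform(0, 0.2),
                    ]
                )
            )
        best = _multistart(_nll_psycho, (self.theta, self.y), x0s, self.bounds)
        mu, sigma, lapse = best.x
        return PsychometricResults(
            mu=float(mu),
            sigma=float(sigma),
            lapse=float(lapse),
            loglike=-float(best.fun),
            n_trials=len(self.y),
        )


class PriorBiasModel:
    """Joint psychometric fit across the two prior contexts.

    Both curves share sigma and lapse; each prior gets its own mean.
    """

    bounds = ((-10.0, 10.0), (-10.0, 10.0), (0.05, 50.0), (0.0, 0.5))

    def __init__(self, theta, y, prior):
        self.theta = np.asarray(theta, float)
        self.y = np.asarray(y, float)
        self.prior = np.asarray(prior)
        present = set(np.unique(self.prior))
        if not set(PRIORS) <= present:
            raise DegenerateFitError(
                f"both prior contexts required, got {sorted(present)}"
            )
        if self.y.min() == self.y.max():
            raise DegenerateFitError("all trials share one choice")

    @classmethod
    def from_trials(cls, trials: pd.DataFrame) -> "PriorBiasModel":
        return cls(trials["orientation"], _choice_vector(trials), trials["prior"])

    def fit(self, n_restarts: int = 5, seed: int = 0) -> BiasResults:
        rng = np.random.default_rng(seed)
        spread = self.theta.std() or 1.0
        x0s = [np.array([0.0, 0.0, spread, 0.02])]
        for _ in range(n_restarts - 1):
            x0s.append(
                np.array(
                    [
                        rng.uniform(-2, 2),
                        rng.uniform(-2, 2),
                        rng.uniform(0.3, 3) * spread,
                        rng.uniform(0, 0.2),
                    ]
                )
            )
        best = _multistart(
            _nll_bias, (self.theta, self.y, self.prior == "cw"), x0s, self.bounds
        )
        mu1, mu2, sigma, lapse = best.x
        return BiasResults(
            mu_prior_cw=float(mu1),
            mu_prior_ccw=float(mu2),
            sigma=float(sigma),
            lapse=float(lapse),
            loglike=-float(best.fun),
            n_trials=len(self.y),
        )


# ---------------------------------------------------------------------------
# per-group fitting + bootstrap


def fit_psychometric(trials: pd.DataFrame, by=("mapping_rule", "contrast")):
    """One psychometric fit per group of `by` columns.

    Returns a dict mapping group tuples to :class:`PsychometricResults`.
    """
    out = {}
    for key, sub in trials.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        res = PsychometricModel.from_trials(sub).fit()
        res.group = key
        out[key] = res
    return out


def fit_bias_model(trials: pd.DataFrame, by=("contrast",)):
    """One shared-slope prior-bias fit per group (default: per contrast)."""
    out = {}
    for key, sub in trials.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        res = PriorBiasModel.from_trials(sub).fit()
        res.group = key
        out[key] = res
    return out


@dataclass
class BootstrapSummary:
    statistics: dict             # name -> point estimate
    iqr: dict                    # name -> (q25, q75)
    n_boot: int
    n_rejected: int = 0
    samples: dict = field(default_factory=dict)


def bootstrap_behavior(
    trials: pd.DataFrame, n_boot: int = 100, seed: int = 0
) -> BootstrapSummary:
    """Nonparametric bootstrap of sensitivity and decision bias.

    Trials are resampled with replacement; the psychometric and prior-bias
    models are refit on each resample.  Resamples on which a fit is
    degenerate are rejected and counted.  Uncertainty is summarized as
    interquartile ranges.
    """
    rng = np.random.default_rng(seed)
    point_psy = PsychometricModel.from_trials(trials).fit()
    point_bias = PriorBiasModel.from_trials(trials).fit()
    sens, bias = [], []
    rejected = 0
    n = len(trials)
    while len(sens) < n_boot:
        idx = rng.integers(0, n, n)
        sub = trials.iloc[idx]
        try:
            sens.append(PsychometricModel.from_trials(sub).fit(n_restarts=2).sensitivity)
            bias.append(PriorBiasModel.from_trials(sub).fit(n_restarts=2).decision_bias)
        except DegenerateFitError:
            rejected += 1
            if rejected > 10 * n_boot:
                raise
    sens, bias = np.array(sens), np.array(bias)

    def iqr(x):
        lo, hi = np.percentile(x, [25, 75])
        return (float(lo), float(hi))

    return BootstrapSummary(
        statistics={
            "sensitivity": point_psy.sensitivity,
            "decision_bias": point_bias.decision_bias,
        },
        iqr={"sensitivity": iqr(sens), "decision_bias": iqr(bias)},
        n_boot=n_boot,
        n_rejected=rejected,
        samples={"sensitivity": sens, "decision_bias": bias},
    )
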