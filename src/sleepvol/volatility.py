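"""GARCH(1,1) conditional-heteroskedasticity estimation and volatility summaries.

The volatility of a feature series :math:`y_t` is modeled as

.. math::

    y_t = \\mu + \\epsilon_t, \\qquad \\epsilon_t = \\sigma_t z_t, \\qquad
    \\sigma^2_t = \\alpha_0 + \\alpha_1 \\epsilon^2_{t-1}
                + \\beta_1 \\sigma^2_{t-1},

with i.i.d. standard-normal innovations :math:`z_t`.  Parameters are
estimated by Gaussian quasi-maximum likelihood under the stationarity
constraints :math:`\\alpha_0 > 0`, :math:`\\alpha_1, \\beta_1 \\ge 0`,
:math:`\\alpha_1 + \\beta_1 \\le 1 - 10^{-6}`.  The fitted conditional
variances :math:`\\sigma^2_t` are the per-time-step volatility measures;
their group averages form the mean conditional volatility (MCV).

:class:`Garch11` follows the scikit-learn estimator protocol (constructor
parameters, ``fit``, trailing-underscore fitted attributes,
``get_params``/``set_params``); :func:`fit_garch11` is the thin functional
wrapper used by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.signal import lfilter
from sklearn.base import BaseEstimator

__all__ = [
    "GarchFit",
    "VolatilitySummary",
    "Garch11",
    "fit_garch11",
    "conditional_variances",
    "garch_loglikelihood",
    "mean_conditional_volatility",
    "volatility_table",
]

_MIN_OBS = 50
_STATIONARITY_EPS = 1e-6

# Documented multi-start initializations in (alpha1, beta1); alpha0 starts at
# the value implied by the sample variance, mu at the sample mean.
_STARTS = ((0.05, 0.90), (0.10, 0.80), (0.20, 0.60), (0.30, 0.30),
           (0.02, 0.02))


@dataclass
class GarchFit:
    """A fitted GARCH(1,1) model."""

    mu: float
    alpha0: float
    alpha1: float
    beta1: float
    log_likelihood: float
    conditional_variances: np.ndarray
    converged: bool
    n_obs: int

    def __post_init__(self) -> None:
        if self.alpha0 <= 0 or self.alpha1 < 0 or self.beta1 < 0:
            raise ValueError("inadmissible GARCH parameters")
        if self.alpha1 + self.beta1 >= 1:
            raise ValueError("alpha1 + beta1 must be < 1")
        self.conditional_variances = np.asarray(self.conditional_variances,
                                                dtype=float)
        if len(self.conditional_variances) != self.n_obs:
            raise ValueError("conditional variance length != n_obs")
        if np.any(self.conditional_variances <= 0):
            raise ValueError("conditional variances must be positive")


@dataclass
class VolatilitySummary:
    """Mean conditional volatility for one grouping cell."""

    keys: dict
    mean_volatility: float
    n_features: int

    def __post_init__(self) -> None:
        if self.mean_volatility < 0:
            raise ValueError("mean volatility must be >= 0")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")


def _sigma2_recursion(e2: np.ndarray, alpha0: float, alpha1: float,
                      beta1: float, sigma2_init: float) -> np.ndarray:
    """Forward variance recursion, vectorized as a linear IIR filter."""
    n = len(e2)
    sigma2 = np.empty(n)
    sigma2[0] = sigma2_init
    if n > 1:
        x = alpha0 + alpha1 * e2[:-1]
        sigma2[1:], _ = lfilter([1.0], [1.0, -beta1], x,
                                zi=np.array([beta1 * sigma2_init]))
    return sigma2


def garch_loglikelihood(series: np.ndarray, mu: float, alpha0: float,
                        alpha1: float, beta1: float) -> float:
    """Gaussian quasi-log-likelihood with sigma2_1 at the sample variance."""
    y = np.asarray(series, dtype=float)
    eps = y - mu
    e2 = eps * eps
    sigma2 = _sigma2_recursion(e2, alpha0, alpha1, beta1,
                               float(np.var(y)))
    if np.any(sigma2 <= 0) or not np.all(np.isfinite(sigma2)):
        return -np.inf
    return float(-0.5 * np.sum(np.log(2 * np.pi) + np.log(sigma2)
                               + e2 / sigma2))


class Garch11(BaseEstimator):
    """Scikit-learn style GARCH(1,1) maximum-likelihood estimator.

    Parameters
    ----------
    n_starts : int
        Number of multi-start initializations (taken from a documented
        list) for the constrained quasi-Newton optimizer.
    estimate_mean : bool
        Estimate the mean level jointly (default); otherwise ``mu`` is
        fixed at 0.

    Attributes
    ----------
    mu_, alpha0_, alpha1_, beta1_ : float
        Fitted parameters.
    log_likelihood_ : float
    conditional_variances_ : ndarray of shape (n_obs,)
    converged_ : bool
    n_obs_ : int

    Notes
    -----
    The series is internally rescaled by its standard deviation for
    optimizer conditioning and the parameters mapped back exactly, so the
    reported ``alpha0`` and conditional variances keep the input's scale.
    Likelihood ties between starts are broken toward the lowest ``alpha1``.
    """

    def __init__(self, n_starts: int = 5, estimate_mean: bool = True):
        self.n_starts = n_starts
        self.estimate_mean = estimate_mean

    def fit(self, y, X=None):
        y = np.asarray(y, dtype=float).ravel()
        if len(y) < _MIN_OBS:
            raise ValueError(
                f"need at least {_MIN_OBS} observations, got {len(y)}")
        if not np.all(np.isfinite(y)):
            raise ValueError("series contains non-finite values")
        scale = float(np.std(y))
        if scale < 1e-12:
            raise ValueError("constant (degenerate) series")
        z = y / scale
        var_z = float(np.var(z))
        mean_z = float(np.mean(z)) if self.estimate_mean else 0.0

        def nll(theta):
            mu, a0, a1, b1 = theta
            ll = garch_loglikelihood(z, mu, a0, a1, b1)
            return -ll if np.isfinite(ll) else 1e12

        bounds = [(None, None) if self.estimate_mean else (0.0, 0.0),
                  (1e-10, 10.0 * var_z), (0.0, 1.0 - _STATIONARITY_EPS),
                  (0.0, 1.0 - _STATIONARITY_EPS)]
        constraint = {"type": "ineq",
                      "fun": lambda th: 1.0 - _STATIONARITY_EPS - th[2] - th[3]}

        candidates = []
        converged = False
        for a1_0, b1_0 in _STARTS[:self.n_starts]:
            a0_0 = max(var_z * (1.0 - a1_0 - b1_0), 1e-8)
            x0 = np.array([mean_z, a0_0, a1_0, b1_0])
            res = optimize.minimize(nll, x0, method="SLSQP", bounds=bounds,
                                    constraints=[constraint],
                                    options={"maxiter": 300, "ftol": 1e-10})
            if np.isfinite(res.fun):
                candidates.append((-res.fun, res.x))
            converged = converged or bool(res.success)
        if not candidates:
            raise RuntimeError("GARCH likelihood evaluation failed")

        # Maximum likelihood wins; exact ties break toward lower alpha1.
        # Exception: when the likelihood maximum sits in the no-ARCH regime
        # (alpha1 ~ 0), beta1 is unidentified — the (alpha0, beta1) ridge is
        # flat and spurious near-integrated solutions can edge out the flat
        # one by a statistically meaningless margin.  There, among
        # candidates within the 5% chi-square(1) likelihood-ratio bound,
        # the least persistent one is chosen.
        ll_max = max(c[0] for c in candidates)
        top = max(candidates,
                  key=lambda c: (c[0] - 1e-8 * c[1][2]))
        if top[1][2] < 0.01:
            ridge = [c for c in candidates
                     if c[0] >= ll_max - 1.92 and c[1][2] < 0.01]
            best = min(ridge, key=lambda c: (c[1][2] + c[1][3], c[1][2]))
        else:
            best = top

        ll_z, (mu_z, a0_z, a1, b1) = best
        a0_z = max(a0_z, 1e-12)
        a1 = min(max(a1, 0.0), 1.0 - _STATIONARITY_EPS)
        b1 = min(max(b1, 0.0), 1.0 - _STATIONARITY_EPS)
        if a1 + b1 > 1.0 - _STATIONARITY_EPS:
            b1 = 1.0 - _STATIONARITY_EPS - a1
        self.mu_ = mu_z * scale
        self.alpha0_ = a0_z * scale * scale
        self.alpha1_ = a1
        self.beta1_ = b1
        # log-likelihood on the original scale: ll_z - n*log(scale)
        self.log_likelihood_ = garch_loglikelihood(y, self.mu_, self.alpha0_,
                                                   self.alpha1_, self.beta1_)
        eps2 = (y - self.mu_) ** 2
        self.conditional_variances_ = _sigma2_recursion(
            eps2, self.alpha0_, self.alpha1_, self.beta1_, float(np.var(y)))
        self.converged_ = converged
        self.n_obs_ = len(y)
        return self

    def to_result(self) -> GarchFit:
        return GarchFit(mu=self.mu_, alpha0=self.alpha0_, alpha1=self.alpha1_,
                        beta1=self.beta1_,
                        log_likelihood=self.log_likelihood_,
                        conditional_variances=self.conditional_variances_,
                        converged=self.converged_, n_obs=self.n_obs_)


def fit_garch11(series, n_starts: int = 5,
                estimate_mean: bool = True) -> GarchFit:
    """Fit GARCH(1,1) by constrained quasi-maximum likelihood."""
    return Garch11(n_starts=n_starts,
                   estimate_mean=estimate_mean).fit(series).to_result()


def conditional_variances(fit: GarchFit, series) -> np.ndarray:
    """Forward recursion of the fitted variance equation on ``series``."""
    y = np.asarray(series, dtype=float)
    eps2 = (y - fit.mu) ** 2
    return _sigma2_recursion(eps2, fit.alpha0, fit.alpha1, fit.beta1,
                             float(np.var(y)))


def mean_conditional_volatility(fits_by_group: dict) -> list[VolatilitySummary]:
    """Average conditional variances over time, then over features, per group.

    ``fits_by_group`` maps a grouping key (a dict of labels, e.g.
    ``{"age_group": ..., "condition": ...}`` — or any hashable key) to the
    list of :class:`GarchFit` belonging to that cell.  For equal-length fits
    the result equals the grand mean of all stacked variance values.  Empty
    groups are skipped.
    """
    out: list[VolatilitySummary] = []
    for key, fits in fits_by_group.items():
        if not fits:
            continue
        per_feature = [float(np.mean(f.conditional_variances)) for f in fits]
        # grouping keys are hashable: either a tuple of (name, value) pairs
        # or a bare label
        if (isinstance(key, tuple)
                and all(isinstance(kv, tuple) and len(kv) == 2 for kv in key)):
            keys = dict(key)
        else:
            keys = {"group": key}
        out.append(VolatilitySummary(keys=keys,
                                     mean_volatility=float(np.mean(per_feature)),
                                     n_features=len(fits)))
    return out


def volatility_table(summaries: list[VolatilitySummary]) -> pd.DataFrame:
    """Long-format MCV table, one row per grouping cell, stably ordered."""
    rows = []
    for s in summaries:
        row = dict(s.keys)
        row["mean_volatility"] = s.mean_volatility
        row["n_features"] = s.n_features
        rows.append(row)
    df = pd.DataFrame(rows)
    key_cols = [c for c in df.columns
                if c not in ("mean_volatility", "n_features")]
    if key_cols:
        df = df.sort_values(key_cols, kind="stable").reset_index(drop=True)
    return df
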