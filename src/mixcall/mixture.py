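"""Two-component Gaussian mixture fitting for one sample's transcriptome.

Bulk and single-cell log-expression distributions are typically bimodal: a
broad low mode of unexpressed/background genes and a narrower high mode of
expressed genes. Decomposing a sample's whole-transcriptome log-expression
vector into two normal components yields, for every gene, a posterior
probability (responsibility) of belonging to the high — expressed —
component, which downstream modules threshold into presence/absence calls.

The fit is plain expectation-maximisation on the univariate mixture

    p(x) = w_l N(x; mu_l, sigma_l^2) + w_h N(x; mu_h, sigma_h^2)

with a variance floor to prevent component collapse, multiple restarts, and
a deterministic label convention (``mean_low <= mean_high``).

Two surfaces are offered: the functional :func:`fit_two_component_mixture`
returning a :class:`MixtureFit`, and the scikit-learn style estimator
:class:`TwoComponentGaussianMixture` (``fit`` / ``predict_proba`` /
``score``) for composition with sklearn tooling.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "EMConfig",
    "MixtureFit",
    "TwoComponentGaussianMixture",
    "fit_two_component_mixture",
    "posterior_high_at",
]

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))
_INIT_METHODS = ("quantile_split", "random_responsibility")

#: Minimum number of finite observations accepted for a fit.
MIN_OBSERVATIONS = 20


@dataclasses.dataclass(frozen=True)
class EMConfig:
    """Convergence and initialisation settings for the EM fit.

    Parameters
    ----------
    tol
        Relative log-likelihood change below which iteration stops.
    max_iter
        Iteration cap per restart.
    n_restarts
        Number of independent starts; the best final log-likelihood wins.
        The first start uses ``init_method``; additional starts use random
        responsibilities.
    var_floor
        Lower bound applied to each component variance every M-step.
    init_method
        ``"quantile_split"`` (deterministic median split) or
        ``"random_responsibility"``.
    seed
        Seeds the random restarts; the quantile-split start is deterministic.
    """

    tol: float = 1e-8
    max_iter: int = 1000
    n_restarts: int = 3
    var_floor: float = 1e-6
    init_method: str = "quantile_split"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tol > 0:
            raise ValueError(f"tol must be > 0, got {self.tol}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.n_restarts < 1:
            raise ValueError(f"n_restarts must be >= 1, got {self.n_restarts}")
        if not self.var_floor > 0:
            raise ValueError(f"var_floor must be > 0, got {self.var_floor}")
        if self.init_method not in _INIT_METHODS:
            raise ValueError(
                f"init_method must be one of {_INIT_METHODS}, got {self.init_method!r}"
            )


@dataclasses.dataclass
class MixtureFit:
    """Fitted two-component Gaussian mixture for one sample.

    ``posterior_high`` is aligned with the input vector; positions holding
    non-finite input carry NaN. Components are labelled so that
    ``mean_low <= mean_high``.
    """

    weight_low: float
    weight_high: float
    mean_low: float
    mean_high: float
    sd_low: float
    sd_high: float
    posterior_high: np.ndarray
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    degenerate_flag: bool
    n_dropped: int = 0

    @property
    def loglik(self) -> float:
        """Final log-likelihood of the fit."""
        return float(self.loglik_trace[-1])

    def summary_row(self) -> dict:
        """Flat dict of scalar fit parameters, for tabular serialisation."""
        return {
            "weight_low": self.weight_low,
            "weight_high": self.weight_high,
            "mean_low": self.mean_low,
            "mean_high": self.mean_high,
            "sd_low": self.sd_low,
            "sd_high": self.sd_high,
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "degenerate_flag": self.degenerate_flag,
            "n_dropped": self.n_dropped,
        }


def _norm_logpdf(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    z = (x - mean) / sd
    return -0.5 * (z * z + _LOG_2PI) - np.log(sd)


def _m_step(x, r_high, var_floor):
    """Weighted-moment parameter update from high-component responsibilities.

    Returns None when one component's total responsibility underflows to
    (numerically) zero — the caller treats that as a degenerate run.
    """
    n = x.size
    s_high = float(r_high.sum())
    s_low = n - s_high
    if s_high <= n * 1e-12 or s_low <= n * 1e-12:
        return None
    w_high = s_high / n
    mean_high = float(r_high @ x) / s_high
    mean_low = float((1.0 - r_high) @ x) / s_low
    var_high = float(r_high @ (x - mean_high) ** 2) / s_high
    var_low = float((1.0 - r_high) @ (x - mean_low) ** 2) / s_low
    floored = var_high < var_floor or var_low < var_floor
    var_high = max(var_high, var_floor)
    var_low = max(var_low, var_floor)
    return (
        1.0 - w_high,
        w_high,
        mean_low,
        mean_high,
        np.sqrt(var_low),
        np.sqrt(var_high),
        floored,
    )


def _quantile_split_init(x: np.ndarray, var_floor: float):
    """Deterministic start: split at the median, moments from each half."""
    med = float(np.median(x))
    low = x[x <= med]
    high = x[x > med]
    if high.size == 0:  # heavy ties at the median
        low, high = x[x < med], x[x >= med]
    if low.size == 0 or high.size == 0:
        low = high = x
    sd_floor = np.sqrt(var_floor)
    return (
        0.5,
        0.5,
        float(low.mean()),
        float(high.mean()),
        max(float(low.std()), sd_floor),
        max(float(high.std()), sd_floor),
        False,
    )


def _random_responsibility_init(x: np.ndarray, var_floor: float, rng: np.random.Generator):
    r = rng.uniform(size=x.size)
    params = _m_step(x, r, var_floor)
    if params is None:  # essentially impossible, but stay safe
        params = _quantile_split_init(x, var_floor)
    return params


def _run_em(x: np.ndarray, params, config: EMConfig):
    """One EM run from a given start. Returns (params, r_high, trace, n_iter,
    converged, degenerate)."""
    w_low, w_high, mean_low, mean_high, sd_low, sd_high, floored = params
    trace: list[float] = []
    r_high = np.full(x.size, np.nan)
    prev_ll = -np.inf
    converged = False
    degenerate = bool(floored)
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        log_low = np.log(w_low) + _norm_logpdf(x, mean_low, sd_low)
        log_high = np.log(w_high) + _norm_logpdf(x, mean_high, sd_high)
        log_mix = np.logaddexp(log_low, log_high)
        ll = float(log_mix.sum())
        r_high = np.exp(log_high - log_mix)
        trace.append(ll)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= config.tol * abs(prev_ll):
            converged = True
            break
        prev_ll = ll
        updated = _m_step(x, r_high, config.var_floor)
        if updated is None:
            degenerate = True
            break
        w_low, w_high, mean_low, mean_high, sd_low, sd_high, floored = updated
        degenerate = bool(floored)
    params = (w_low, w_high, mean_low, mean_high, sd_low, sd_high)
    return params, r_high, np.asarray(trace), n_iter, converged, degenerate


def fit_two_component_mixture(
    values: Sequence[float] | np.ndarray, config: EMConfig | None = None
) -> MixtureFit:
    """Fit a two-component univariate Gaussian mixture by EM.

    Parameters
    ----------
    values
        Log-scale expression values of one sample (whole transcriptome).
        Non-finite entries are dropped with a logged count; at least
        ``MIN_OBSERVATIONS`` finite, non-identical values are required.
    config
        EM settings; defaults to ``EMConfig()``.

    Returns
    -------
    MixtureFit
        Components relabelled so ``mean_low <= mean_high``;
        ``posterior_high`` gives each observation's responsibility of the
        high component, NaN where the input was non-finite.

    Raises
    ------
    ValueError
        On fewer than ``MIN_OBSERVATIONS`` finite values or an
        all-identical input ("degenerate input").
    """
    if config is None:
        config = EMConfig()
    raw = np.asarray(values, dtype=float).ravel()
    finite = np.isfinite(raw)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.info("dropped %d non-finite values before fitting", n_dropped)
    x = raw[finite]
    if x.size < MIN_OBSERVATIONS:
        raise ValueError(
            f"need at least {MIN_OBSERVATIONS} finite values, got {x.size}"
        )
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate input: all values identical")

    rng = np.random.default_rng(config.seed)
    best = None
    for restart in range(config.n_restarts):
        if restart == 0 and config.init_method == "quantile_split":
            start = _quantile_split_init(x, config.var_floor)
        else:
            start = _random_responsibility_init(x, config.var_floor, rng)
        run = _run_em(x, start, config)
        # best final log-likelihood wins; ties broken toward non-degenerate
        key = (run[2][-1] if run[2].size else -np.inf, not run[5])
        if best is None or key > best[0]:
            best = (key, run)
    params, r_high, trace, n_iter, converged, degenerate = best[1]
    w_low, w_high, mean_low, mean_high, sd_low, sd_high = params

    if mean_low > mean_high:  # enforce label convention
        w_low, w_high = w_high, w_low
        mean_low, mean_high = mean_high, mean_low
        sd_low, sd_high = sd_high, sd_low
        r_high = 1.0 - r_high

    if not converged:
        warnings.warn(
            f"EM did not converge within {config.max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )

    posterior = np.full(raw.size, np.nan)
    posterior[finite] = r_high
    return MixtureFit(
        weight_low=w_low,
        weight_high=w_high,
        mean_low=mean_low,
        mean_high=mean_high,
        sd_low=sd_low,
        sd_high=sd_high,
        posterior_high=posterior,
        loglik_trace=trace,
        n_iter=n_iter,
        converged=converged,
        degenerate_flag=degenerate,
        n_dropped=n_dropped,
    )


def posterior_high_at(x, fit: MixtureFit):
    """Posterior probability that observation(s) ``x`` belong to the high
    component of a fitted mixture.

    Evaluates the responsibility
    ``w_h phi(x; mu_h, sd_h) / (w_l phi(x; mu_l, sd_l) + w_h phi(x; mu_h, sd_h))``
    in log space. Scalar in, scalar out; array in, array out.
    """
    arr = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        log_low = np.log(fit.weight_low) + _norm_logpdf(arr, fit.mean_low, fit.sd_low)
        log_high = np.log(fit.weight_high) + _norm_logpdf(arr, fit.mean_high, fit.sd_high)
    post = np.exp(log_high - np.logaddexp(log_low, log_high))
    if np.isscalar(x) or arr.ndim == 0:
        return float(post)
    return post


class TwoComponentGaussianMixture(BaseEstimator):
    """Scikit-learn style estimator for the two-component univariate mixture.

    ``fit`` expects a single feature — shape ``(n, 1)`` or a 1-d vector of
    one sample's log-expression values. Fitted attributes follow the sklearn
    convention (trailing underscore); component 0 is the low/unexpressed
    mode and component 1 the high/expressed mode.

    Parameters mirror :class:`EMConfig`; ``random_state`` seeds the random
    restarts.

    Attributes
    ----------
    weights_ : ndarray of shape (2,)
        Mixing proportions ``(w_low, w_high)``.
    means_ : ndarray of shape (2,)
        Component means ``(mean_low, mean_high)``.
    sds_ : ndarray of shape (2,)
        Component standard deviations.
    posterior_high_ : ndarray
        Responsibility of the high component for each training value.
    loglik_trace_ : ndarray
        Per-iteration log-likelihood of the winning restart.
    n_iter_ : int
    converged_ : bool
    degenerate_ : bool
    mixture_fit_ : MixtureFit
        The underlying functional fit object.
    """

    def __init__(
        self,
        tol: float = 1e-8,
        max_iter: int = 1000,
        n_restarts: int = 3,
        var_floor: float = 1e-6,
        init_method: str = "quantile_split",
        random_state: int = 0,
    ):
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.var_floor = var_floor
        self.init_method = init_method
        self.random_state = random_state

    def _config(self) -> EMConfig:
        return EMConfig(
            tol=self.tol,
            max_iter=self.max_iter,
            n_restarts=self.n_restarts,
            var_floor=self.var_floor,
            init_method=self.init_method,
            seed=self.random_state,
        )

    @staticmethod
    def _as_vector(X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 2:
            if arr.shape[1] != 1:
                raise ValueError(
                    f"expected a single feature, got shape {arr.shape}"
                )
            arr = arr[:, 0]
        elif arr.ndim != 1:
            raise ValueError(f"expected 1-d or (n, 1) input, got ndim={arr.ndim}")
        return arr

    def fit(self, X, y=None):
        x = self._as_vector(X)
        fit = fit_two_component_mixture(x, self._config())
        self.mixture_fit_ = fit
        self.weights_ = np.array([fit.weight_low, fit.weight_high])
        self.means_ = np.array([fit.mean_low, fit.mean_high])
        self.sds_ = np.array([fit.sd_low, fit.sd_high])
        self.posterior_high_ = fit.posterior_high
        self.loglik_trace_ = fit.loglik_trace
        self.n_iter_ = fit.n_iter
        self.converged_ = fit.converged
        self.degenerate_ = fit.degenerate_flag
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Posterior component probabilities, columns ``(low, high)``."""
        self._check_fitted()
        x = self._as_vector(X)
        high = posterior_high_at(x, self.mixture_fit_)
        high = np.atleast_1d(high)
        return np.column_stack([1.0 - high, high])

    def predict(self, X) -> np.ndarray:
        """MAP component labels: 0 = low/unexpressed, 1 = high/expressed."""
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)

    def score(self, X, y=None) -> float:
        """Mean per-observation log-likelihood under the fitted mixture."""
        self._check_fitted()
        x = self._as_vector(X)
        f = self.mixture_fit_
        log_low = np.log(f.weight_low) + _norm_logpdf(x, f.mean_low, f.sd_low)
        log_high = np.log(f.weight_high) + _norm_logpdf(x, f.mean_high, f.sd_high)
        return float(np.logaddexp(log_low, log_high).mean())

    def _check_fitted(self) -> None:
        if not hasattr(self, "mixture_fit_"):
            raise AttributeError(
                "This TwoComponentGaussianMixture instance is not fitted yet; "
                "call 'fit' first."
            )
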