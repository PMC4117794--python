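"""scikit-learn style estimator wrappers around the fitting routines.

These classes expose the package's statistical fits with the estimator
protocol (``fit``, ``get_params``/``set_params``, fitted attributes with
a trailing underscore) so they compose with sklearn model selection and
pipelines.  The module-level functions in :mod:`g4pull.inference` and
:mod:`g4pull.trace_analysis` remain thin functional equivalents.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from . import inference, trace_analysis
from .constants import DEFAULT_CONSTANTS
from .trace_synthesis import ExtensionTrace, PfoldCurve

__all__ = [
    "ExponentialDwellMLE",
    "BellRateFit",
    "RuptureForceMLE",
    "PfoldKineticsFit",
    "StepDetector",
]


class ExponentialDwellMLE(BaseEstimator):
    """Censored 1- or 2-component exponential dwell-time MLE.

    Parameters
    ----------
    n_components : 1 or 2 mixture components.
    use_censored : include right-censored dwells as survival terms.
    dead_time : left-truncation at the detector's minimum resolvable
        dwell (s).
    """

    def __init__(
        self,
        n_components: int = 1,
        use_censored: bool = True,
        dead_time: float = 0.0,
        n_restarts: int = 5,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.use_censored = use_censored
        self.dead_time = dead_time
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None, censored: Optional[np.ndarray] = None):
        """Fit dwell durations X (1-d array, seconds)."""
        X = np.asarray(X, dtype=float).ravel()
        data = (X, censored) if censored is not None else X
        res = inference.fit_exponential(
            data,
            n_components=self.n_components,
            use_censored=self.use_censored,
            dead_time=self.dead_time,
            n_restarts=self.n_restarts,
            seed=self.random_state,
        )
        self.result_ = res
        self.lifetimes_ = np.array(res.lifetimes)
        self.amplitudes_ = np.array(res.amplitudes)
        self.se_lifetimes_ = np.array(res.se_lifetimes)
        self.loglik_ = res.loglik
        return self

    def score(self, X=None, y=None) -> float:
        """Log-likelihood of the fitted model (training objective)."""
        return float(self.loglik_)


class BellRateFit(BaseEstimator):
    """Weighted log-linear fit of the Bell rate law k(f)=k0*exp(dx f/kBT)."""

    def __init__(self, temperature: float = 295.0):
        self.temperature = temperature

    def fit(self, X, y, sample_se: Optional[np.ndarray] = None):
        """X: forces (pN); y: rates (1/s); sample_se: rate SEs."""
        from .constants import PhysicalConstants

        res = inference.fit_bell(
            np.asarray(X, dtype=float).ravel(),
            np.asarray(y, dtype=float).ravel(),
            rate_se=sample_se,
            consts=PhysicalConstants(self.temperature),
        )
        self.result_ = res
        self.k0_ = res.k0
        self.dx_ = res.dx
        self.k0_ci_ = res.k0_ci
        self.dx_se_ = res.dx_se
        return self

    def predict(self, X):
        """Bell-law rates at forces X."""
        from .constants import PhysicalConstants

        kbt = PhysicalConstants(self.temperature).kbt
        return self.k0_ * np.exp(self.dx_ * np.asarray(X, float).ravel() / kbt)


class RuptureForceMLE(BaseEstimator):
    """MLE of the Bell-Evans rupture-force density at fixed loading rate."""

    def __init__(self, loading_rate: float = 2.0, temperature: float = 295.0):
        self.loading_rate = loading_rate
        self.temperature = temperature

    def fit(self, X, y=None):
        """X: rupture forces (pN)."""
        from .constants import PhysicalConstants

        res = inference.fit_rupture_distribution(
            np.asarray(X, dtype=float).ravel(),
            self.loading_rate,
            consts=PhysicalConstants(self.temperature),
        )
        self.result_ = res
        self.k0_ = res.k0
        self.dx_ = res.dx
        self.se_dx_ = res.se_dx
        return self

    def score(self, X=None, y=None) -> float:
        return float(self.result_.loglik)


class PfoldKineticsFit(BaseEstimator):
    """Binomial ML fit of (k12, k32) to a p_fold(t) curve."""

    def __init__(
        self,
        alpha: float = 10.0,
        topology: str = "sequential",
        n_grid: int = 15,
    ):
        self.alpha = alpha
        self.topology = topology
        self.n_grid = n_grid

    def fit(self, X, y=None):
        """X: a :class:`PfoldCurve`."""
        if not isinstance(X, PfoldCurve):
            raise TypeError("X must be a PfoldCurve")
        res = inference.fit_pfold(
            X, alpha=self.alpha, topology=self.topology, n_grid=self.n_grid
        )
        self.result_ = res
        self.k12_ = res.k12
        self.k32_ = res.k32
        self.nll_ = res.nll
        return self

    def predict(self, X):
        """p_fold at hold times X with the fitted rates."""
        return inference.pfold_curve_model(
            np.asarray(X, dtype=float).ravel(),
            self.k12_,
            self.k32_,
            self.alpha,
            self.topology,
        )


class StepDetector(BaseEstimator):
    """Change-point step detector over force-clamp extension traces."""

    def __init__(
        self,
        window_s: float = 0.5,
        min_step: float = 3.0,
        min_dwell_s: Optional[float] = None,
        penalty_scale: float = 3.0,
    ):
        self.window_s = window_s
        self.min_step = min_step
        self.min_dwell_s = min_dwell_s
        self.penalty_scale = penalty_scale

    def _config(self) -> trace_analysis.DetectorConfig:
        return trace_analysis.DetectorConfig(
            window_s=self.window_s,
            min_step=self.min_step,
            min_dwell_s=self.min_dwell_s,
            penalty_scale=self.penalty_scale,
        )

    def fit(self, X: ExtensionTrace, y=None):
        cfg = self._config()
        res = trace_analysis.detect_steps(X, cfg)
        self.result_ = res
        self.events_ = res.events
        self.state_path_ = res.state_path
        self.dwells_ = trace_analysis.extract_dwells(
            res.state_path,
            X.sampling_rate,
            min_dwell=cfg.dead_time,
            force=float(np.median(X.force)),
        )
        return self

    def predict(self, X: ExtensionTrace):
        """Binary folded/unfolded path for a new trace."""
        return trace_analysis.detect_steps(X, self._config()).state_path
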