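"""Statistical estimation for dwell times, Bell rates, rupture forces and p_fold.

All dwell fits are maximum likelihood on the raw durations (no binning):
right-censored dwells enter through survival terms and the detector dead
time through left truncation, both optional.  The histogram form
A*exp(-k t) used for display is provided separately.  Rate-vs-force
(Bell) fits are weighted log-linear regressions; the rupture-force fit
is an MLE of the Bell-Evans density; the p_fold(t) fit minimizes the
binomial negative log-likelihood of (M, N) outcomes over (k12, k32)
under the constraint k23 = k21 = alpha*k32.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize
from statsmodels.stats.proportion import proportion_confint
import statsmodels.api as sm

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .kinetic_model import BellEdge, RateSet
from .trace_analysis import DwellSet
from .trace_synthesis import PfoldCurve

__all__ = [
    "ExpFitResult",
    "BellFitResult",
    "RuptureFitResult",
    "PfoldFitResult",
    "fit_exponential",
    "select_model",
    "fit_bell",
    "fit_rupture_distribution",
    "peak_force",
    "estimate_pfold",
    "fit_pfold",
    "pfold_curve_model",
    "dead_time_corrected_lifetimes",
]


# --------------------------------------------------------------------------
# exponential dwell-time MLE
# --------------------------------------------------------------------------
@dataclass
class ExpFitResult:
    """Result of a 1- or 2-component exponential dwell-time MLE."""

    n_components: int
    lifetimes: Tuple[float, ...]  # (tau,) or (tau_short, tau_long)
    amplitudes: Tuple[float, ...]  # event-count fractions, sum to 1
    se_lifetimes: Tuple[float, ...]
    loglik: float
    n_used: int
    n_censored: int
    converged: bool = True
    dead_time: float = 0.0
    message: str = ""

    @property
    def bic(self) -> float:
        k = 1 if self.n_components == 1 else 3
        return k * np.log(max(self.n_used, 1)) - 2.0 * self.loglik

    def histogram_model(self, t, bin_width: float, n_events: Optional[int] = None):
        """Expected histogram counts A_i*exp(-t/tau_i) for display."""
        t = np.asarray(t, dtype=float)
        n = self.n_used if n_events is None else n_events
        out = np.zeros_like(t)
        for a, tau in zip(self.amplitudes, self.lifetimes):
            out += n * bin_width * a / tau * np.exp(-t / tau)
        return out


def _mixture_nll(
    params: np.ndarray, t: np.ndarray, cens: np.ndarray, t0: float
) -> float:
    """NLL of a 2-exp mixture, left-truncated at t0, right-censoring terms."""
    log_l1, log_l2, logit_a = params
    l1, l2 = np.exp(log_l1), np.exp(log_l2)
    a1 = 1.0 / (1.0 + np.exp(-logit_a))
    a2 = 1.0 - a1
    norm = a1 * np.exp(-l1 * t0) + a2 * np.exp(-l2 * t0)
    dens = a1 * l1 * np.exp(-l1 * t) + a2 * l2 * np.exp(-l2 * t)
    surv = a1 * np.exp(-l1 * t) + a2 * np.exp(-l2 * t)
    with np.errstate(divide="ignore"):
        ll = np.where(cens, np.log(surv), np.log(dens)) - np.log(norm)
    if not np.all(np.isfinite(ll)):
        return 1e300
    return -float(ll.sum())


def fit_exponential(
    dwells,
    n_components: int = 1,
    use_censored: bool = True,
    state_class: str = "unfolded",
    dead_time: float = 0.0,
    n_restarts: int = 5,
    seed: int = 0,
) -> ExpFitResult:
    """Maximum-likelihood exponential fit of dwell durations.

    ``dwells`` may be a :class:`DwellSet` (one ``state_class`` is
    selected) or a plain array of durations (optionally with a boolean
    censoring array as tuple ``(durations, censored)``).

    Right-censored dwells contribute survival terms when
    ``use_censored``; otherwise they are dropped.  ``dead_time`` left-
    truncates the distribution at the detector's minimum resolvable
    dwell (the memoryless property makes the 1-component MLE exact:
    tau = mean(t - t0) over uncensored dwells plus censoring mass).

    The 2-component fit maximizes the mixture likelihood directly from
    ``n_restarts`` starting points; standard errors come from the
    observed information matrix.
    """
    if isinstance(dwells, DwellSet):
        t, cens = dwells.durations(state_class)
    elif isinstance(dwells, tuple):
        t, cens = (np.asarray(v) for v in dwells)
        cens = cens.astype(bool)
    else:
        t = np.asarray(dwells, dtype=float)
        cens = np.zeros(len(t), dtype=bool)
    if not use_censored:
        t, cens = t[~cens], cens[~cens]
    keep = t >= max(dead_time, 0.0)
    if dead_time > 0 and not np.all(keep):
        t, cens = t[keep], cens[keep]
    n_unc = int((~cens).sum())
    n_cens = int(cens.sum())
    if n_unc < 10:
        raise ValueError(f"need >= 10 uncensored dwells, got {n_unc}")
    t0 = max(dead_time, 0.0)

    if n_components == 1:
        # closed form: exponential MLE with truncation and censoring
        tau = float((t - t0).sum() / n_unc)
        se = tau / np.sqrt(n_unc)
        ll = float(-n_unc * np.log(tau) - ((t - t0) / tau).sum())
        return ExpFitResult(
            n_components=1,
            lifetimes=(tau,),
            amplitudes=(1.0,),
            se_lifetimes=(se,),
            loglik=ll,
            n_used=n_unc + n_cens,
            n_censored=n_cens,
            dead_time=t0,
        )
    if n_components != 2:
        raise ValueError("n_components must be 1 or 2")

    rng = np.random.default_rng(seed)
    unc = t[~cens]
    # moment/quantile-flavoured starts plus random perturbations
    med = np.median(unc - t0) + 1e-9
    lo = np.mean(unc[unc <= np.quantile(unc, 0.5)] - t0) + 1e-9
    hi = np.mean(unc[unc >= np.quantile(unc, 0.5)] - t0) + 1e-9
    starts = [
        np.array([np.log(1 / lo), np.log(1 / (hi + 1e-9)), 0.0]),
        np.array([np.log(2 / med), np.log(0.2 / med), 0.0]),
    ]
    while len(starts) < max(n_restarts, 2):
        starts.append(starts[0] + rng.normal(0, 0.7, size=3))

    best = None
    for x0 in starts:
        res = optimize.minimize(
            _mixture_nll,
            x0,
            args=(t, cens, t0),
            method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    log_l1, log_l2, logit_a = best.x
    l = np.exp([log_l1, log_l2])
    a = np.array([1, 0]) * (1 / (1 + np.exp(-logit_a))) + np.array([0, 1]) * (
        1 - 1 / (1 + np.exp(-logit_a))
    )
    order = np.argsort(-l)  # fast component first -> tau_short first
    l, a = l[order], a[order]
    taus = 1.0 / l

    # observed-information SEs on the log-rate scale; |d tau / d log lambda|
    # = tau, so se(tau_i) = tau_i * se(log lambda_i)
    se_taus = (np.nan, np.nan)
    try:
        h = _numerical_hessian(
            lambda p: _mixture_nll(p, t, cens, t0), best.x
        )
        cov = np.linalg.inv(h)
        se_log_l = np.sqrt(np.maximum(np.diag(cov)[:2], 0.0))
        se_taus = tuple(((1.0 / np.exp([log_l1, log_l2])) * se_log_l)[order])
    except np.linalg.LinAlgError:
        pass

    converged = bool(best.success) and np.all(np.isfinite(best.x))
    return ExpFitResult(
        n_components=2,
        lifetimes=(float(taus[0]), float(taus[1])),
        amplitudes=(float(a[0]), float(a[1])),
        se_lifetimes=tuple(float(s) for s in se_taus),
        loglik=float(-best.fun),
        n_used=n_unc + n_cens,
        n_censored=n_cens,
        converged=converged,
        dead_time=t0,
        message="" if converged else "mixture optimization did not converge",
    )


def _numerical_hessian(fun, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = np.zeros((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            xi = x.copy()
            xi[i] += eps
            xi[j] += eps
            fpp = fun(xi)
            xi = x.copy()
            xi[i] += eps
            xi[j] -= eps
            fpm = fun(xi)
            xi = x.copy()
            xi[i] -= eps
            xi[j] += eps
            fmp = fun(xi)
            xi = x.copy()
            xi[i] -= eps
            xi[j] -= eps
            fmm = fun(xi)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    return h


def select_model(
    dwells,
    state_class: str = "folded",
    use_censored: bool = True,
    dead_time: float = 0.0,
    min_events: int = 20,
    delta_bic: float = 2.0,
) -> Tuple[int, ExpFitResult, Optional[ExpFitResult]]:
    """Choose 1 vs 2 exponential components by BIC.

    Returns (n_components, fit1, fit2).  Two components are selected iff
    BIC improves by more than ``delta_bic``.  Underpowered samples
    (< ``min_events`` uncensored dwells) default to one component with a
    warning.
    """
    fit1 = fit_exponential(
        dwells, 1, use_censored, state_class, dead_time
    )
    n_unc = fit1.n_used - fit1.n_censored
    if n_unc < min_events:
        warnings.warn(
            f"only {n_unc} uncensored dwells: defaulting to 1 component",
            stacklevel=2,
        )
        return 1, fit1, None
    fit2 = fit_exponential(
        dwells, 2, use_censored, state_class, dead_time
    )
    choose2 = (fit1.bic - fit2.bic) > delta_bic
    return (2 if choose2 else 1), fit1, fit2


def dead_time_corrected_lifetimes(
    fit_unfolded: ExpFitResult, fit_folded: ExpFitResult, dead_time: float
) -> Tuple[float, float]:
    """First-order missed-event correction of the two class lifetimes.

    A dwell of the opposite class shorter than the dead time goes
    undetected and fuses the two flanking dwells, inflating the apparent
    lifetime by 1/(1 - q) where q is the opposite class's sub-dead-time
    probability mass.  Returns (tau_u_corrected, tau_long_corrected).
    """
    q_folded = sum(
        a * (1.0 - np.exp(-dead_time / tau))
        for a, tau in zip(fit_folded.amplitudes, fit_folded.lifetimes)
    )
    q_unfolded = sum(
        a * (1.0 - np.exp(-dead_time / tau))
        for a, tau in zip(fit_unfolded.amplitudes, fit_unfolded.lifetimes)
    )
    tau_u = fit_unfolded.lifetimes[0] * (1.0 - q_folded)
    tau_long = fit_folded.lifetimes[-1] * (1.0 - q_unfolded)
    return float(tau_u), float(tau_long)


# --------------------------------------------------------------------------
# Bell-model rate-vs-force fit
# --------------------------------------------------------------------------
@dataclass
class BellFitResult:
    """Weighted log-linear Bell fit: k(f) = k0*exp(dx*f/kBT)."""

    k0: float
    dx: float
    k0_ci: Tuple[float, float]  # 95% CI
    dx_se: float
    cov: np.ndarray
    forces: np.ndarray


def fit_bell(
    forces: Sequence[float],
    rates: Sequence[float],
    rate_se: Optional[Sequence[float]] = None,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
) -> BellFitResult:
    """Fit ln k = ln k0 + (dx/kBT) f by (weighted) least squares.

    Weights are inverse variances of ln k (se_k/k by the delta method).
    dx keeps its sign: folding rates that decrease with force give
    dx < 0.
    """
    f = np.asarray(forces, dtype=float)
    k = np.asarray(rates, dtype=float)
    if len(f) < 2:
        raise ValueError("need rates at >= 2 forces")
    if np.ptp(f) == 0:
        raise ValueError("all forces equal: design is singular")
    if np.any(k <= 0):
        raise ValueError("rates must be positive")
    y = np.log(k)
    x = sm.add_constant(f)
    if rate_se is not None:
        se = np.asarray(rate_se, dtype=float)
        w = 1.0 / np.maximum(se / k, 1e-12) ** 2
        model = sm.WLS(y, x, weights=w)
    else:
        model = sm.OLS(y, x)
    res = model.fit()
    intercept, slope = res.params
    ci = res.conf_int(alpha=0.05)
    k0_ci = (float(np.exp(ci[0][0])), float(np.exp(ci[0][1])))
    dx = float(slope * consts.kbt)
    dx_se = float(res.bse[1] * consts.kbt)
    return BellFitResult(
        k0=float(np.exp(intercept)),
        dx=dx,
        k0_ci=k0_ci,
        dx_se=dx_se,
        cov=np.asarray(res.cov_params()),
        forces=f,
    )


# --------------------------------------------------------------------------
# rupture-force distribution fit (constant loading rate)
# --------------------------------------------------------------------------
@dataclass
class RuptureFitResult:
    """MLE of the Bell-Evans rupture-force density."""

    k0: float
    dx: float
    loading_rate: float
    se_k0: float
    se_dx: float
    loglik: float
    n: int


def _rupture_nll(
    log_params: np.ndarray, f: np.ndarray, r: float, kbt: float
) -> float:
    k0, dx = np.exp(log_params)
    z = dx * f / kbt
    if np.any(z > 500):
        return 1e300
    a = kbt * k0 / (dx * r)
    ll = np.log(k0 / r) + z + a * (1.0 - np.exp(z))
    return -float(ll.sum())


def fit_rupture_distribution(
    forces: Sequence[float],
    r: float,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
) -> RuptureFitResult:
    """Maximum-likelihood fit of (k0, dx) to rupture forces at rate r.

    Uses the analytic profile of k0 given dx (the k0 score equation has
    a closed-form root), then a 1-d optimization over dx — robust and
    free of histogram binning.
    """
    f = np.asarray(forces, dtype=float)
    if len(f) < 20:
        raise ValueError("need >= 20 rupture forces")
    if np.ptp(f) == 0:
        raise ValueError("degenerate sample: all rupture forces equal")
    if r <= 0:
        raise ValueError("loading rate must be positive")
    kbt = consts.kbt
    n = len(f)

    def k0_profile(dx: float) -> float:
        z = np.clip(dx * f / kbt, None, 500)
        return n * dx * r / (kbt * np.sum(np.expm1(z)))

    def profile_nll(log_dx: float) -> float:
        dx = float(np.exp(log_dx))
        k0 = k0_profile(dx)
        if not np.isfinite(k0) or k0 <= 0:
            return 1e300
        return _rupture_nll(np.log([k0, dx]), f, r, kbt)

    res = optimize.minimize_scalar(
        profile_nll, bounds=(np.log(1e-3), np.log(50.0)), method="bounded",
        options={"xatol": 1e-10},
    )
    dx = float(np.exp(res.x))
    k0 = float(k0_profile(dx))
    h = _numerical_hessian(lambda p: _rupture_nll(p, f, r, kbt), np.log([k0, dx]))
    try:
        cov = np.linalg.inv(h)
        se_k0 = k0 * np.sqrt(max(cov[0, 0], 0.0))
        se_dx = dx * np.sqrt(max(cov[1, 1], 0.0))
    except np.linalg.LinAlgError:
        se_k0 = se_dx = float("nan")
    return RuptureFitResult(
        k0=k0,
        dx=dx,
        loading_rate=r,
        se_k0=float(se_k0),
        se_dx=float(se_dx),
        loglik=float(-res.fun),
        n=n,
    )


def peak_force(
    edge: BellEdge, r: float, consts: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Closed-form mode of the rupture-force density.

    f* = (kBT/dx) * ln( dx*r / (kBT*k0) ); requires dx > 0 and an
    argument above 1 (otherwise the density peaks at zero force).
    """
    if edge.dx <= 0:
        raise ValueError("peak force requires dx > 0")
    arg = edge.dx * r / (consts.kbt * edge.k0)
    if arg <= 1:
        raise ValueError("no interior force peak: dx*r <= kBT*k0")
    return float(consts.kbt / edge.dx * np.log(arg))


# --------------------------------------------------------------------------
# p_fold estimation and fitting
# --------------------------------------------------------------------------
def estimate_pfold(curve: PfoldCurve) -> Dict[str, np.ndarray]:
    """Point estimates M/N with Wilson 95% confidence intervals."""
    if np.any(curve.n < 1):
        raise ValueError("every point needs N >= 1 trials")
    lo, hi = proportion_confint(curve.m, curve.n, alpha=0.05, method="wilson")
    return {
        "p": curve.p_hat,
        "ci_low": np.asarray(lo, dtype=float),
        "ci_high": np.asarray(hi, dtype=float),
    }


def _sequential_generator(k12: float, k32: float, alpha: float) -> np.ndarray:
    k21 = k23 = alpha * k32
    return np.array(
        [
            [-k12, k21, 0.0],
            [k12, -(k21 + k23), k32],
            [0.0, k23, -k32],
        ]
    )


def _parallel_generator(k12: float, k32: float, alpha: float) -> np.ndarray:
    # competing direct folds with the same reverse rates as the sequential fit
    k_us, k_ul = k12, k32
    k_su = alpha * k32
    k_lu = k32
    return np.array(
        [
            [-(k_us + k_ul), k_su, k_lu],
            [k_us, -k_su, 0.0],
            [k_ul, 0.0, -k_lu],
        ]
    )


def pfold_curve_model(
    times,
    k12: float,
    k32: float,
    alpha: float = 10.0,
    topology: str = "sequential",
) -> np.ndarray:
    """p_fold(t) of the 3-state U/S/L scheme via the exact eigen-propagator.

    Used inside the fit for speed; agrees with the RK4 Master-equation
    solver to integrator accuracy.
    """
    gen = {
        "sequential": _sequential_generator,
        "parallel": _parallel_generator,
    }[topology](k12, k32, alpha)
    times = np.asarray(times, dtype=float)
    vals, vecs = np.linalg.eig(gen)
    p0 = np.array([1.0, 0.0, 0.0])
    c = np.linalg.solve(vecs, p0)
    # p(t) = V diag(exp(vals t)) c ; p_fold = 1 - p_U
    expo = np.exp(np.outer(times, vals))
    p_u = (expo * (vecs[0] * c)).sum(axis=1).real
    return np.clip(1.0 - p_u, 0.0, 1.0)


@dataclass
class PfoldFitResult:
    """Best-fit (k12, k32) of the constrained scheme at one force."""

    force: float
    k12: float
    k32: float
    alpha: float
    topology: str
    nll: float
    se_k12: float = float("nan")
    se_k32: float = float("nan")
    flat_objective: bool = False

    def to_rate_set(self) -> RateSet:
        rs = RateSet.alpha_constrained(self.force, self.k12, self.k32, self.alpha)
        return rs


def _binomial_nll(p: np.ndarray, m: np.ndarray, n: np.ndarray) -> float:
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return -float(np.sum(m * np.log(p) + (n - m) * np.log1p(-p)))


def fit_pfold(
    curve: PfoldCurve,
    alpha: float = 10.0,
    topology: str = "sequential",
    n_grid: int = 15,
    k_bounds: Tuple[float, float] = (1e-4, 2.0),
) -> PfoldFitResult:
    """Fit (k12, k32) to one p_fold(t) curve by binomial ML.

    Coarse log-spaced grid search followed by Nelder-Mead refinement on
    the log-rates; alpha >= 5 is required (the constrained scheme
    k23 = k21 = alpha*k32 is only meaningful when the intermediate
    empties much faster than it fills).
    """
    if alpha < 5:
        raise ValueError("alpha must be >= 5")
    if len(curve.times) < 3:
        raise ValueError("need >= 3 hold times")

    def nll_of(log_k: np.ndarray) -> float:
        k12, k32 = np.exp(log_k)
        p = pfold_curve_model(curve.times, k12, k32, alpha, topology)
        return _binomial_nll(p, curve.m, curve.n)

    grid = np.log(np.geomspace(k_bounds[0], k_bounds[1], n_grid))
    best_val, best_x = np.inf, None
    for g1 in grid:
        for g2 in grid:
            v = nll_of(np.array([g1, g2]))
            if v < best_val:
                best_val, best_x = v, np.array([g1, g2])
    res = optimize.minimize(
        nll_of, best_x, method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000},
    )
    k12, k32 = np.exp(res.x)
    se_k12 = se_k32 = float("nan")
    flat = False
    try:
        h = _numerical_hessian(nll_of, res.x, eps=1e-3)
        cov = np.linalg.inv(h)
        d = np.diag(cov)
        if np.any(d <= 0) or np.any(np.sqrt(np.maximum(d, 0)) > 2.0):
            flat = True
        se_k12 = k12 * np.sqrt(abs(d[0]))
        se_k32 = k32 * np.sqrt(abs(d[1]))
    except np.linalg.LinAlgError:
        flat = True
    return PfoldFitResult(
        force=curve.force,
        k12=float(k12),
        k32=float(k32),
        alpha=alpha,
        topology=topology,
        nll=float(res.fun),
        se_k12=float(se_k12),
        se_k32=float(se_k32),
        flat_objective=flat,
    )
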