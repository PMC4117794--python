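"""Reference experimental conditions for the telomeric G4 study.

These are the measured dwell-time constants and Bell parameters that the
synthetic-data generator uses as ground truth, collected in one place so
simulations, fits and the reproduction pipeline all draw from the same
numbers.

Notes
-----
* The dwell constants are the observable exponential mixture parameters
  at each clamped force: tau_u (unfolded lifetime), tau_short/tau_long
  (the two folded-dwell decay constants).  The count ratio
  N_long/N_short is not printed per force; the default of 1 matches the
  constrained-fit relation k23 = k21 and gives a folded-dominant
  stationary state at 5 pN and an unfolded-dominant one at 7 pN, as
  observed.
* RAMP_UNFOLDING is the effective one-barrier Bell description of the
  2 pN/s stretch experiments (x_u = 0.8 nm, k_u0 = 0.009 1/s; peak
  force ~17 pN).
* FOLDING_BELL / LONG_UNFOLDING_BELL are the Bell laws of k12 and k32
  from the constrained p_fold fits; the zero-force rates are the
  geometric midpoints of the reported 95% confidence ranges
  (1.6-6.7 and 0.02-0.07 1/s).
"""
from __future__ import annotations

from .kinetic_model import BellEdge, DwellConstants, RateSet, sequential_model

__all__ = [
    "DWELL_CONSTANTS",
    "RAMP_UNFOLDING",
    "FOLDING_BELL",
    "LONG_UNFOLDING_BELL",
    "RAMP_LOADING_RATE",
    "dwell_rate_set",
    "clamp_model",
    "alpha_rate_set",
]

#: Observable dwell statistics at the three clamp forces (s).
DWELL_CONSTANTS = {
    5.0: DwellConstants(tau_u=15.8, tau_short=3.0, tau_long=45.0, n_ratio=1.0),
    6.0: DwellConstants(tau_u=53.0, tau_short=2.1, tau_long=25.0, n_ratio=1.0),
    7.0: DwellConstants(tau_u=101.0, tau_short=3.2, tau_long=16.6, n_ratio=1.0),
}

#: Effective Bell edge of ramp unfolding (folded -> unfolded).
RAMP_UNFOLDING = BellEdge("F", "U", k0=0.009, dx=0.8)

#: Standard loading rate of the stretch segments (pN/s).
RAMP_LOADING_RATE = 2.0

#: Bell law of the folding rate k12 (U -> S): strong force slow-down.
FOLDING_BELL = BellEdge("U", "S", k0=3.3, dx=-3.0)

#: Bell law of the long-state unfolding rate k32 (L -> S): nearly flat.
LONG_UNFOLDING_BELL = BellEdge("L", "S", k0=0.037, dx=0.2)


def dwell_rate_set(force: float, method: str = "spectral") -> RateSet:
    """Microscopic sequential-scheme rates at one of the clamp forces."""
    if force not in DWELL_CONSTANTS:
        raise KeyError(f"no dwell constants tabulated at {force} pN")
    return RateSet.from_dwell_constants(force, DWELL_CONSTANTS[force], method)


def clamp_model(force: float, include_ul: bool = False, method: str = "spectral"):
    """Fixed-rate sequential model calibrated at one clamp force."""
    return sequential_model(dwell_rate_set(force, method), include_ul=include_ul)


def alpha_rate_set(force: float, alpha: float = 10.0) -> RateSet:
    """Constrained rate set (k23 = k21 = alpha*k32) at a tabulated force."""
    d = DWELL_CONSTANTS[force]
    return RateSet.alpha_constrained(
        force, k12=1.0 / d.tau_u, k32=1.0 / d.tau_long, alpha=alpha
    )
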