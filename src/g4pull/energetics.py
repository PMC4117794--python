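"""Unfolding free energies of the short- and long-lived folded states.

At a clamped force the transition rates give the force-dependent free
energy of unfolding directly through detailed balance,

    dG_ssDNA,short(f) = kBT ln(k12/k21)
    dG_ssDNA,long(f)  = kBT ln[k12 k23 / (k32 k21)]

(G_ssDNA - G_folded; positive when the folded state is favoured).  The
zero-force cost follows from removing the conformational stretching
term:  dG(f) = dG0 + dphi(f), so dG0 = dG(f) - dphi(f), averaged over
the forces at which rates were measured.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .kinetic_model import RateSet
from .polymer_mechanics import (
    DEFAULT_GEOMETRY,
    DEFAULT_SSDNA,
    G4Geometry,
    SsdnaParams,
    delta_phi,
)

__all__ = [
    "FreeEnergyResult",
    "delta_g_short",
    "delta_g_long",
    "delta_g0",
    "free_energy_summary",
]


def delta_g_short(rs: RateSet) -> Tuple[float, float]:
    """(dG_ssDNA,short(f) in kBT, propagated SE).

    ln(k12/k21): zero when the rates balance; swapping k12 and k21 flips
    the sign.
    """
    val = math.log(rs.k12 / rs.k21)
    se = _ratio_log_se(rs.k12, rs.se_k12, rs.k21, rs.se_k21)
    return val, se


def delta_g_long(rs: RateSet) -> Tuple[float, float]:
    """(dG_ssDNA,long(f) in kBT, propagated SE).

    ln[k12 k23/(k32 k21)] = kBT ln of the stationary ratio P_L/P_U of
    the U<->S<->L birth-death chain; reduces to dG_short when k23 = k32.
    """
    val = math.log(rs.k12 * rs.k23 / (rs.k32 * rs.k21))
    se = math.sqrt(
        _ratio_log_se(rs.k12, rs.se_k12, rs.k21, rs.se_k21) ** 2
        + _ratio_log_se(rs.k23, rs.se_k23, rs.k32, rs.se_k32) ** 2
    )
    return val, se


def _ratio_log_se(
    ka: float, se_a: Optional[float], kb: float, se_b: Optional[float]
) -> float:
    var = 0.0
    if se_a is not None:
        var += (se_a / ka) ** 2
    if se_b is not None:
        var += (se_b / kb) ** 2
    return math.sqrt(var)


def delta_g0(
    dg_at_forces: Sequence[Tuple[float, float]],
    dg_se: Optional[Sequence[float]] = None,
    geom: G4Geometry = DEFAULT_GEOMETRY,
    ssdna: SsdnaParams = DEFAULT_SSDNA,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
    weighting: str = "unweighted",
) -> Tuple[float, float]:
    """Zero-force unfolding free energy (kBT) from dG(f) measurements.

    dG0 = mean over forces of [dG(f) - dphi(f)].  The SE combines the
    across-force spread with the propagated rate uncertainties in
    quadrature.  ``weighting="inverse-variance"`` weights force points
    by their dG SEs instead of the default unweighted mean.
    """
    if len(dg_at_forces) < 1:
        raise ValueError("need at least one force point")
    per_force = np.array(
        [dg - delta_phi(f, geom, ssdna, consts) for f, dg in dg_at_forces]
    )
    se = np.asarray(
        dg_se if dg_se is not None else np.zeros(len(per_force)), dtype=float
    )
    if weighting == "inverse-variance" and np.all(se > 0):
        w = 1.0 / se**2
        val = float(np.sum(w * per_force) / np.sum(w))
        se_prop = float(1.0 / math.sqrt(np.sum(w)))
    elif weighting in ("unweighted", "inverse-variance"):
        val = float(per_force.mean())
        se_prop = float(np.sqrt(np.sum(se**2)) / len(per_force))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    n = len(per_force)
    spread = float(per_force.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return val, float(math.sqrt(spread**2 + se_prop**2))


@dataclass
class FreeEnergyResult:
    """Force-resolved and zero-force unfolding free energies (kBT)."""

    forces: np.ndarray
    dg_short: np.ndarray
    dg_long: np.ndarray
    dphi: np.ndarray
    dg0_short: float
    dg0_long: float
    se_dg0_short: float
    se_dg0_long: float
    temperature: float

    @property
    def dg0_short_kcal_mol(self) -> float:
        return PhysicalConstants(self.temperature).to_kcal_mol(self.dg0_short)

    @property
    def dg0_long_kcal_mol(self) -> float:
        return PhysicalConstants(self.temperature).to_kcal_mol(self.dg0_long)

    def to_dict(self) -> dict:
        return {
            "forces_pN": list(map(float, self.forces)),
            "dg_short_kbt": list(map(float, self.dg_short)),
            "dg_long_kbt": list(map(float, self.dg_long)),
            "dphi_kbt": list(map(float, self.dphi)),
            "dg0_short_kbt": self.dg0_short,
            "dg0_long_kbt": self.dg0_long,
            "se_dg0_short_kbt": self.se_dg0_short,
            "se_dg0_long_kbt": self.se_dg0_long,
            "dg0_short_kcal_mol": self.dg0_short_kcal_mol,
            "dg0_long_kcal_mol": self.dg0_long_kcal_mol,
            "temperature_K": self.temperature,
        }


def free_energy_summary(
    rate_sets: List[RateSet],
    geom: G4Geometry = DEFAULT_GEOMETRY,
    ssdna: SsdnaParams = DEFAULT_SSDNA,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
    weighting: str = "unweighted",
) -> FreeEnergyResult:
    """Full energetic reconstruction from rates at several forces."""
    forces = np.array([rs.force for rs in rate_sets])
    shorts = [delta_g_short(rs) for rs in rate_sets]
    longs = [delta_g_long(rs) for rs in rate_sets]
    dphis = np.array([delta_phi(f, geom, ssdna, consts) for f in forces])
    dg0_s, se_s = delta_g0(
        list(zip(forces, [v for v, _ in shorts])),
        [s for _, s in shorts],
        geom,
        ssdna,
        consts,
        weighting,
    )
    dg0_l, se_l = delta_g0(
        list(zip(forces, [v for v, _ in longs])),
        [s for _, s in longs],
        geom,
        ssdna,
        consts,
        weighting,
    )
    return FreeEnergyResult(
        forces=forces,
        dg_short=np.array([v for v, _ in shorts]),
        dg_long=np.array([v for v, _ in longs]),
        dphi=dphis,
        dg0_short=dg0_s,
        dg0_long=dg0_l,
        se_dg0_short=se_s,
        se_dg0_long=se_l,
        temperature=consts.temperature,
    )
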