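"""Force-extension mechanics of unfolded ssDNA and the folded G-quadruplex.

The unfolded 21-nt chain is modelled by default as an extensible freely
jointed chain (eFJC) calibrated so the unfolding step size is ~6 nm at
6.5 pN and ~8 nm at 20 pN, the two hallmarks of the telomeric G4 signal.
The folded structure is a rigid rod of size ``l0`` whose projection along
the force axis follows the Langevin function.  From these two curves the
module derives the force-dependent unfolding step size and the
conformational free-energy difference

    dphi(f) = -∫_0^f [x_ssDNA(f') - x_G4(f')] df'

which is the force-dependent part of the unfolding free energy.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Tuple

import numpy as np
from scipy.interpolate import PchipInterpolator

from .constants import DEFAULT_CONSTANTS, PhysicalConstants

__all__ = [
    "SsdnaParams",
    "G4Geometry",
    "ssdna_extension",
    "g4_extension",
    "step_size",
    "delta_phi",
    "DEFAULT_SSDNA",
    "DEFAULT_GEOMETRY",
]

# Below this force (pN) the Langevin function is evaluated by its series
# expansion; the crossover is far above the round-off danger zone.
_SMALL_FORCE = 1e-3


@dataclass(frozen=True)
class SsdnaParams:
    """Parametrization of the ssDNA force-extension curve.

    ``model_id="extensible-fjc"`` (default) uses an extensible freely
    jointed chain with Kuhn length ``kuhn_length``, contour length
    ``contour_per_nt`` per nucleotide and stretch modulus
    ``stretch_modulus``:

        x(f)/nt = contour_per_nt * L(f*b/kBT) * (1 + f/S)

    with L the Langevin function.

    ``model_id="phenomenological"`` interpolates a user-supplied table of
    (force pN, extension nm per nucleotide) with a monotone cubic spline;
    this is the hook for an empirical ssDNA curve when one is available.
    """

    model_id: Literal["extensible-fjc", "phenomenological"] = "extensible-fjc"
    contour_per_nt: float = 0.56
    kuhn_length: float = 1.5
    stretch_modulus: float = 800.0
    #: (forces pN, extension nm/nt) table, only for the phenomenological model.
    table: Optional[Tuple[Tuple[float, ...], Tuple[float, ...]]] = None
    _interp: Optional[PchipInterpolator] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if not (0.3 < self.contour_per_nt < 0.8):
            raise ValueError("contour_per_nt must lie in (0.3, 0.8) nm/nt")
        if self.kuhn_length <= 0:
            raise ValueError("kuhn_length must be positive")
        if self.stretch_modulus <= 0:
            raise ValueError("stretch_modulus must be positive")
        if self.model_id == "phenomenological":
            if self.table is None:
                raise ValueError("phenomenological model requires a table")
            f, x = (np.asarray(v, dtype=float) for v in self.table)
            if f.ndim != 1 or f.shape != x.shape or f.size < 4:
                raise ValueError("table must be two equal 1-d arrays, >=4 points")
            if f[0] > 0:
                f = np.concatenate([[0.0], f])
                x = np.concatenate([[0.0], x])
            object.__setattr__(self, "_interp", PchipInterpolator(f, x))
        elif self.model_id != "extensible-fjc":
            raise ValueError(f"unknown model_id {self.model_id!r}")

    def extension_per_nt(
        self, f: np.ndarray, consts: PhysicalConstants = DEFAULT_CONSTANTS
    ) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        if self.model_id == "phenomenological":
            return np.asarray(self._interp(f))
        x = f * self.kuhn_length / consts.kbt
        return (
            self.contour_per_nt
            * _langevin(x)
            * (1.0 + f / self.stretch_modulus)
        )


@dataclass(frozen=True)
class G4Geometry:
    """Rigid-body geometry of the folded quadruplex.

    ``l0`` is the folded-structure size along the helix axis (nm) and
    ``n_nt`` the number of nucleotides released on unfolding.
    """

    l0: float = 1.7
    n_nt: int = 21

    def __post_init__(self) -> None:
        if self.l0 <= 0:
            raise ValueError("l0 must be positive")
        if self.n_nt <= 0:
            raise ValueError("n_nt must be positive")


DEFAULT_SSDNA = SsdnaParams()
DEFAULT_GEOMETRY = G4Geometry()


def _langevin(x: np.ndarray) -> np.ndarray:
    """Langevin function coth(x) - 1/x, series-protected near 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 0.05
    xs = np.where(small, 1.0, x)  # keep coth away from 0
    direct = 1.0 / np.tanh(xs) - 1.0 / xs
    series = x / 3.0 - x**3 / 45.0 + 2.0 * x**5 / 945.0
    return np.where(small, series, direct)


def _check_nonneg(f) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be non-negative (pN)")
    return f


def ssdna_extension(
    f,
    n_nt: int = 21,
    params: SsdnaParams = DEFAULT_SSDNA,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Extension (nm) of ``n_nt`` nucleotides of ssDNA at force ``f`` (pN).

    Continuous and nondecreasing in f; tends to
    ``n_nt*contour_per_nt*(1+f/S)`` at large force.
    """
    f = _check_nonneg(f)
    out = n_nt * params.extension_per_nt(f, consts)
    return out if out.ndim else float(out)


def g4_extension(
    f,
    geom: G4Geometry = DEFAULT_GEOMETRY,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Projected length (nm) of the folded rigid rod along the force axis.

    x_G4(f) = l0*coth(f*l0/kBT) - kBT/f = l0*L(f*l0/kBT); the f->0 limit
    (->0) is taken analytically via the series expansion.
    """
    f = _check_nonneg(f)
    out = geom.l0 * _langevin(f * geom.l0 / consts.kbt)
    return out if out.ndim else float(out)


def step_size(
    f,
    geom: G4Geometry = DEFAULT_GEOMETRY,
    params: SsdnaParams = DEFAULT_SSDNA,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Observable extension jump (nm) on unfolding at force ``f``.

    step(f) = x_ssDNA(f; n_nt) - x_G4(f).  ~6 nm at 6.5 pN and ~8 nm at
    20 pN with the default parametrization.
    """
    return ssdna_extension(f, geom.n_nt, params, consts) - g4_extension(
        f, geom, consts
    )


def delta_phi(
    f: float,
    geom: G4Geometry = DEFAULT_GEOMETRY,
    params: SsdnaParams = DEFAULT_SSDNA,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
    scheme: Literal["trapezoid", "gauss"] = "trapezoid",
    grid_step: float = 0.005,
) -> float:
    """Conformational free-energy difference dphi(f) in kBT units.

    dphi(f) = -∫_0^f step_size(f') df' / kBT.  Nonpositive and
    nonincreasing in force (its derivative is -step_size(f)).

    Parameters
    ----------
    scheme : "trapezoid" (fixed grid, step <= ``grid_step`` pN) or
        "gauss" (64-point Gauss-Legendre), both agree to <1e-3 kBT.
    """
    f = float(f)
    if f < 0:
        raise ValueError("force must be non-negative (pN)")
    if f == 0.0:
        return 0.0
    if scheme == "trapezoid":
        n = max(int(np.ceil(f / grid_step)), 8)
        grid = np.linspace(0.0, f, n + 1)
        integrand = step_size(grid, geom, params, consts)
        integral = float(np.trapezoid(integrand, grid))
    elif scheme == "gauss":
        nodes, weights = np.polynomial.legendre.leggauss(64)
        x = 0.5 * f * (nodes + 1.0)
        integral = float(0.5 * f * np.sum(weights * step_size(x, geom, params, consts)))
    else:
        raise ValueError(f"unknown quadrature scheme {scheme!r}")
    if not np.isfinite(integral):
        raise ArithmeticError("quadrature did not converge to a finite value")
    return -integral / consts.kbt
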