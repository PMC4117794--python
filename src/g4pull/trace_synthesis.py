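"""Synthetic magnetic-tweezers recordings of single G-quadruplex tethers.

Emulates the three experiment types used to characterize telomeric G4
folding: force-clamp extension traces (stepwise transitions between the
folded and unfolded extension levels), constant-loading-rate rupture
experiments, and the stretch-hold-stretch cycling protocol that yields
the refolding probability p_fold(t) = M/N.

The observable model: the tether baseline is an arbitrary constant (the
analysis only uses extension *changes*), the unfolded state adds the
polymer-model step size at the current force, and each sample carries
Gaussian camera noise.  A per-trace multiplicative force bias (default
CV 10%) mimics the magnet calibration error; an optional one-pole
filtered noise mode mimics the low-pass character of bead tracking.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .kinetic_model import BellEdge, StateModel, gillespie_simulate, pfold_predict
from .polymer_mechanics import (
    DEFAULT_GEOMETRY,
    DEFAULT_SSDNA,
    G4Geometry,
    SsdnaParams,
    step_size,
)

__all__ = [
    "ProtocolSegment",
    "ForceProtocol",
    "NoiseParams",
    "ExtensionTrace",
    "PfoldCurve",
    "synthesize_trace",
    "synthesize_rupture_forces",
    "rupture_force_cdf",
    "rupture_force_pdf",
    "synthesize_pfold_experiment",
    "synthesize_pfold_curve",
]


@dataclass(frozen=True)
class ProtocolSegment:
    """One piece of a force protocol: a clamp or a linear ramp."""

    kind: str  # "clamp" | "ramp"
    duration: float
    force: float = 0.0  # clamp force, or ramp start force
    loading_rate: float = 0.0  # pN/s, ramps only

    def __post_init__(self) -> None:
        if self.kind not in ("clamp", "ramp"):
            raise ValueError("segment kind must be 'clamp' or 'ramp'")
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")
        if self.force < 0:
            raise ValueError("forces must be non-negative")
        if self.kind == "ramp" and self.loading_rate <= 0:
            raise ValueError("loading_rate must be positive for ramps")

    def force_at(self, local_t) -> np.ndarray:
        local_t = np.asarray(local_t, dtype=float)
        if self.kind == "clamp":
            return np.full_like(local_t, self.force)
        return self.force + self.loading_rate * local_t


@dataclass(frozen=True)
class ForceProtocol:
    """Ordered sequence of clamp/ramp segments.

    Experimental defaults: clamps at 5-7 pN, ramps at 2 pN/s up to ~50 pN.
    """

    segments: Tuple[ProtocolSegment, ...]

    @property
    def duration(self) -> float:
        return sum(s.duration for s in self.segments)

    @classmethod
    def clamp(cls, force: float, duration: float) -> "ForceProtocol":
        return cls((ProtocolSegment("clamp", duration, force),))

    @classmethod
    def ramp(
        cls, f_start: float, loading_rate: float, f_end: float
    ) -> "ForceProtocol":
        if f_end <= f_start:
            raise ValueError("f_end must exceed f_start")
        dur = (f_end - f_start) / loading_rate
        return cls((ProtocolSegment("ramp", dur, f_start, loading_rate),))

    @classmethod
    def clamp_then_ramp(
        cls,
        clamp_force: float,
        clamp_duration: float,
        loading_rate: float = 2.0,
        f_end: float = 50.0,
    ) -> "ForceProtocol":
        """The standard cycling unit: hold, then stretch at constant rate."""
        ramp_dur = (f_end - clamp_force) / loading_rate
        return cls(
            (
                ProtocolSegment("clamp", clamp_duration, clamp_force),
                ProtocolSegment("ramp", ramp_dur, clamp_force, loading_rate),
            )
        )

    def force_at(self, t) -> np.ndarray:
        """Nominal force at absolute protocol time(s) t."""
        t = np.asarray(t, dtype=float)
        out = np.empty_like(t)
        start = 0.0
        remaining = np.ones(t.shape, dtype=bool)
        for seg in self.segments:
            end = start + seg.duration
            sel = remaining & (t < end)
            out[sel] = seg.force_at(t[sel] - start)
            remaining &= ~sel
            start = end
        last = self.segments[-1]
        out[remaining] = last.force_at(
            np.minimum(t[remaining] - (start - last.duration), last.duration)
        )
        return out


@dataclass(frozen=True)
class NoiseParams:
    """Measurement-noise model of the tweezers recording.

    Defaults follow the instrument description: ~200 frames/s sampling,
    ~2 nm spatial resolution, <10% force-calibration error.
    """

    sigma_x: float = 2.0
    sampling_rate: float = 200.0
    force_bias_cv: float = 0.10
    drift: float = 0.0
    #: correlation time (s) of the optional one-pole filtered noise; None = white.
    autocorr_tau: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sigma_x < 0 or self.sampling_rate <= 0:
            raise ValueError("sigma_x >= 0 and sampling_rate > 0 required")
        if not (0 <= self.force_bias_cv < 0.5):
            raise ValueError("force_bias_cv must lie in [0, 0.5)")

    def decimated(self, factor: int) -> "NoiseParams":
        """Equivalent block-averaged acquisition at sampling_rate/factor.

        Averaging ``factor`` white-noise samples divides the per-sample
        noise by sqrt(factor); used for fast pipeline runs.
        """
        if factor < 1:
            raise ValueError("factor must be >= 1")
        return NoiseParams(
            sigma_x=self.sigma_x / np.sqrt(factor),
            sampling_rate=self.sampling_rate / factor,
            force_bias_cv=self.force_bias_cv,
            drift=self.drift,
            autocorr_tau=self.autocorr_tau,
        )


@dataclass
class ExtensionTrace:
    """Uniformly sampled (time, extension, force) record."""

    time: np.ndarray
    extension: np.ndarray
    force: np.ndarray
    sampling_rate: float
    metadata: dict = field(default_factory=dict)
    #: per-sample folded-class indicator of the generating trajectory (synthetic only)
    true_folded: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if not (len(self.time) == len(self.extension) == len(self.force)):
            raise ValueError("time/extension/force must have equal length")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class PfoldCurve:
    """Refolding-probability data at one hold force: p_fold(t) = M/N."""

    force: float
    times: np.ndarray
    m: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.m = np.asarray(self.m, dtype=int)
        self.n = np.asarray(self.n, dtype=int)
        if not (len(self.times) == len(self.m) == len(self.n)):
            raise ValueError("times/m/n must have equal length")
        if np.any(self.m < 0) or np.any(self.m > self.n):
            raise ValueError("require 0 <= M <= N")

    @property
    def p_hat(self) -> np.ndarray:
        return self.m / np.maximum(self.n, 1)


def synthesize_trace(
    model: StateModel,
    protocol: ForceProtocol,
    noise: NoiseParams = NoiseParams(),
    geom: G4Geometry = DEFAULT_GEOMETRY,
    ssdna: SsdnaParams = DEFAULT_SSDNA,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
    seed=None,
    baseline: float = 0.0,
    initial_state: str = "U",
) -> ExtensionTrace:
    """Simulate one tether recording under the given protocol.

    extension(t) = baseline + [unfolded]*step_size(f_actual(t)) + noise,
    with the state path drawn by the exact stochastic simulation and
    f_actual = bias * nominal force (bias drawn once per trace with CV
    ``force_bias_cv``).  Bit-reproducible for a given integer seed.
    """
    rng = np.random.default_rng(seed)
    bias = 1.0 + noise.force_bias_cv * rng.standard_normal() if noise.force_bias_cv else 1.0
    bias = float(np.clip(bias, 0.5, 1.5))
    traj = gillespie_simulate(
        model,
        protocol,
        seed=rng,
        consts=consts,
        initial_state=initial_state,
        force_scale=bias,
    )
    n_samples = int(round(protocol.duration * noise.sampling_rate))
    t = np.arange(n_samples) / noise.sampling_rate
    f_nominal = protocol.force_at(t)
    f_actual = bias * f_nominal
    folded = traj.folded_at(t)
    ext = baseline + np.where(
        folded, 0.0, step_size(np.maximum(f_actual, 0.0), geom, ssdna, consts)
    )
    if noise.sigma_x > 0:
        white = rng.standard_normal(n_samples) * noise.sigma_x
        if noise.autocorr_tau:
            # one-pole low-pass with matched stationary variance
            a = np.exp(-1.0 / (noise.autocorr_tau * noise.sampling_rate))
            from scipy.signal import lfilter

            white = lfilter([np.sqrt(1 - a * a)], [1, -a], white)
        ext = ext + white
    if noise.drift:
        ext = ext + noise.drift * t
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return ExtensionTrace(
        time=t,
        extension=ext,
        force=f_nominal,
        sampling_rate=noise.sampling_rate,
        metadata={
            "seed": seed_val,
            "force_bias": bias,
            "baseline": baseline,
            "protocol": [
                (s.kind, s.duration, s.force, s.loading_rate)
                for s in protocol.segments
            ],
            "trajectory": traj,
        },
        true_folded=folded,
    )


def rupture_force_cdf(f, edge: BellEdge, r: float, consts=DEFAULT_CONSTANTS):
    """Analytic CDF of the Bell-model rupture force at loading rate r.

    F(f) = 1 - exp{ (kBT k0)/(dx r) * [1 - exp(dx f / kBT)] }.
    """
    if edge.dx <= 0:
        raise ValueError("rupture-force distribution requires dx > 0")
    a = consts.kbt * edge.k0 / (edge.dx * r)
    f = np.asarray(f, dtype=float)
    return 1.0 - np.exp(a * (1.0 - np.exp(edge.dx * f / consts.kbt)))


def rupture_force_pdf(f, edge: BellEdge, r: float, consts=DEFAULT_CONSTANTS):
    """Analytic density of the Bell-model rupture force at loading rate r."""
    if edge.dx <= 0:
        raise ValueError("rupture-force distribution requires dx > 0")
    a = consts.kbt * edge.k0 / (edge.dx * r)
    f = np.asarray(f, dtype=float)
    z = edge.dx * f / consts.kbt
    return (edge.k0 / r) * np.exp(z + a * (1.0 - np.exp(z)))


def synthesize_rupture_forces(
    edge: BellEdge,
    r: float,
    n: int,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
    seed=None,
) -> np.ndarray:
    """Draw n rupture forces by inverse-CDF sampling of the Bell density."""
    if edge.dx <= 0:
        raise ValueError("rupture sampling requires dx > 0")
    if r <= 0:
        raise ValueError("loading rate must be positive")
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    a = consts.kbt * edge.k0 / (edge.dx * r)
    return (consts.kbt / edge.dx) * np.log(1.0 - np.log1p(-u) / a)


def synthesize_pfold_experiment(
    model: StateModel,
    f_hold: float,
    t_hold: float,
    n_cycles: int,
    seed=None,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
    method: str = "ssa",
) -> Tuple[int, int]:
    """Simulate n stretch-hold-stretch cycles; return (M, N).

    Each cycle starts unfolded (the preceding ramp unfolds the tether),
    evolves at the hold force for ``t_hold``, and scores a success when
    the final state is folded.  ``method="ssa"`` runs the exact
    stochastic simulation per cycle; ``method="exact"`` draws the final
    state from the Master-equation occupancies (identical distribution,
    used for speed).
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng(seed)
    if t_hold <= 0:
        return 0, int(n_cycles)
    if method == "exact":
        p = float(pfold_predict(model, f_hold, t_hold, consts))
        return int(rng.binomial(n_cycles, p)), int(n_cycles)
    if method != "ssa":
        raise ValueError(f"unknown method {method!r}")
    protocol = ForceProtocol.clamp(f_hold, t_hold)
    m = 0
    for _ in range(n_cycles):
        traj = gillespie_simulate(
            model, protocol, seed=rng, consts=consts, initial_state="U"
        )
        if traj.states[-1] in model.folded_states:
            m += 1
    return m, int(n_cycles)


def synthesize_pfold_curve(
    model: StateModel,
    f_hold: float,
    times: Sequence[float],
    n_cycles: int,
    seed=None,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
    method: str = "ssa",
) -> PfoldCurve:
    """p_fold(t) data over a grid of hold times at one force."""
    rng = np.random.default_rng(seed)
    ms: List[int] = []
    ns: List[int] = []
    for t_hold in times:
        m, n = synthesize_pfold_experiment(
            model, f_hold, float(t_hold), n_cycles, seed=rng, consts=consts,
            method=method,
        )
        ms.append(m)
        ns.append(n)
    return PfoldCurve(force=f_hold, times=np.asarray(times, float), m=ms, n=ns)
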