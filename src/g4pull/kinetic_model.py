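"""Four-state kinetic scheme for telomeric G-quadruplex folding under force.

States
------
U   unfolded ssDNA (long extension)
S   short-lived folded intermediate (lifetime ~ seconds)
L   long-lived folded state (lifetime ~ tens of seconds)
UL  ultra-long-lived folded state (survives >1000 s at 5-7 pN, ruptures
    near 42-43 pN at 2 pN/s); entered by a slow branch off the folding
    pathway, parametrized phenomenologically.

The default (sequential) topology is U <-> S <-> L with the branch
S -> UL and the rupture edge UL -> U.  Every edge carries a Bell rate law

    k(f) = k0 * exp(dx * f / kBT)

with signed transition distance dx: dx > 0 for edges accelerated by force
(unfolding), dx < 0 for folding edges.  A parallel topology (U -> S and
U -> L as competing direct folds) is provided for model comparison.

The module offers the deterministic Master-equation solution (fixed-step
RK4), the exact stationary distribution, and an exact stochastic
simulation (Gillespie SSA) including force-ramp protocols.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy.sparse.csgraph import connected_components

from .constants import DEFAULT_CONSTANTS, PhysicalConstants

__all__ = [
    "BellEdge",
    "StateModel",
    "RateSet",
    "StateTrajectory",
    "ReducibleChainError",
    "rate_matrix",
    "master_solve",
    "pfold_predict",
    "stationary_distribution",
    "gillespie_simulate",
    "sequential_model",
    "parallel_model",
    "DwellConstants",
]

FOLDED_CLASS = "folded"
UNFOLDED_CLASS = "unfolded"


class ReducibleChainError(RuntimeError):
    """Raised when a stationary distribution of a reducible chain is requested."""


@dataclass(frozen=True)
class BellEdge:
    """One transition with a Bell (exponential) force dependence.

    ``k0`` is the zero-force rate (1/s), ``dx`` the signed transition
    distance (nm): positive distances accelerate the transition with
    force, negative distances slow it down.
    """

    source: str
    target: str
    k0: float
    dx: float = 0.0

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise ValueError(f"edge {self.source}->{self.target}: k0 must be > 0")
        if self.source == self.target:
            raise ValueError("self-edges are not allowed")
        # guard against overflow at experimentally relevant forces
        if self.dx * 60.0 / DEFAULT_CONSTANTS.kbt > 500:
            raise ValueError("dx too large: rate overflows below 60 pN")

    def rate(self, f, consts: PhysicalConstants = DEFAULT_CONSTANTS):
        """Evaluate k(f) = k0*exp(dx*f/kBT)."""
        return self.k0 * np.exp(self.dx * np.asarray(f, dtype=float) / consts.kbt)


@dataclass(frozen=True)
class StateModel:
    """A labelled continuous-time Markov chain with Bell-rate edges."""

    states: Tuple[str, ...]
    edges: Tuple[BellEdge, ...]
    folded_states: frozenset = frozenset({"S", "L", "UL"})
    topology: str = "sequential"

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise ValueError("duplicate state labels")
        if "U" not in self.states:
            raise ValueError("model must contain the unfolded state 'U'")
        unknown = {e.source for e in self.edges} | {e.target for e in self.edges}
        unknown -= set(self.states)
        if unknown:
            raise KeyError(f"edges reference unknown states: {sorted(unknown)}")
        if not self.folded_states <= set(self.states) - {"U"}:
            raise ValueError("folded_states must be non-U states of the model")

    def index(self, label: str) -> int:
        return self.states.index(label)

    @property
    def folded_mask(self) -> np.ndarray:
        return np.array([s in self.folded_states for s in self.states])

    def state_class(self, label: str) -> str:
        return FOLDED_CLASS if label in self.folded_states else UNFOLDED_CLASS

    def with_edges(self, edges: Iterable[BellEdge]) -> "StateModel":
        return replace(self, edges=tuple(edges))

    def to_dict(self) -> dict:
        """Config-block form: states, folded states and (k0, dx) edges."""
        return {
            "states": list(self.states),
            "folded_states": sorted(self.folded_states),
            "topology": self.topology,
            "edges": [
                {"from": e.source, "to": e.target, "k0": e.k0, "dx": e.dx}
                for e in self.edges
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "StateModel":
        return cls(
            states=tuple(data["states"]),
            edges=tuple(
                BellEdge(d["from"], d["to"], d["k0"], d.get("dx", 0.0))
                for d in data["edges"]
            ),
            folded_states=frozenset(data["folded_states"]),
            topology=data.get("topology", "sequential"),
        )


@dataclass(frozen=True)
class DwellConstants:
    """Observable dwell-time statistics at one clamped force.

    ``tau_u``: single-exponential lifetime of the unfolded state (s).
    ``tau_short``/``tau_long``: the two decay constants of the
    double-exponential folded-dwell distribution (s).
    ``n_ratio``: N_long/N_short, the event-count ratio of the two folded
    dwell classes (equal to the amplitude ratio A2/A1 of the mixture).
    """

    tau_u: float
    tau_short: float
    tau_long: float
    n_ratio: float = 1.0

    def __post_init__(self) -> None:
        if min(self.tau_u, self.tau_short, self.tau_long) <= 0:
            raise ValueError("lifetimes must be positive")
        if self.tau_short >= self.tau_long:
            raise ValueError("tau_short must be below tau_long")
        if self.n_ratio <= 0:
            raise ValueError("n_ratio must be positive")


@dataclass(frozen=True)
class RateSet:
    """The four sequential-scheme rates at one force (all 1/s).

    k12: U->S (folding), k21: S->U, k23: S->L, k32: L->S.  ``n_ratio``
    is the long/short dwell-count ratio the set was built from, ``alpha``
    the k21/k32 ratio when the set comes from the constrained p_fold fit.
    """

    force: float
    k12: float
    k21: float
    k23: float
    k32: float
    n_ratio: Optional[float] = None
    alpha: Optional[float] = None
    # optional 1-sigma uncertainties for propagation into energetics
    se_k12: Optional[float] = None
    se_k21: Optional[float] = None
    se_k23: Optional[float] = None
    se_k32: Optional[float] = None

    def __post_init__(self) -> None:
        if min(self.k12, self.k21, self.k23, self.k32) <= 0:
            raise ValueError("all rates must be positive")

    @classmethod
    def alpha_constrained(
        cls, force: float, k12: float, k32: float, alpha: float = 10.0
    ) -> "RateSet":
        """Reduced parametrization k23 = k21 = alpha*k32 used in p_fold fits."""
        if alpha < 5:
            raise ValueError("alpha must be >= 5 for the constrained scheme")
        return cls(
            force=force,
            k12=k12,
            k21=alpha * k32,
            k23=alpha * k32,
            k32=k32,
            alpha=alpha,
        )

    @classmethod
    def from_dwell_constants(
        cls,
        force: float,
        dwell: DwellConstants,
        method: str = "spectral",
    ) -> "RateSet":
        """Build microscopic rates from observable dwell statistics.

        ``method="naive"`` uses the direct identification
        k21 = 1/tau_short, k32 = 1/tau_long, k23 = k21*n_ratio.  It is
        exact only when k23 << k21 (few aborted excursions to L).

        ``method="spectral"`` inverts the phase-type structure of the
        folded-dwell distribution exactly: an excursion into the folded
        set {S, L} starting in S decays as a two-exponential mixture
        whose rate constants are the eigenvalues of the sub-generator
        and whose count ratio fixes the remaining degree of freedom.
        Simulating with the spectral rates reproduces the observed
        (tau_short, tau_long, n_ratio) exactly.
        """
        k12 = 1.0 / dwell.tau_u
        lam1 = 1.0 / dwell.tau_short
        lam2 = 1.0 / dwell.tau_long
        n = dwell.n_ratio
        if method == "naive":
            k21 = lam1
            k32 = lam2
            k23 = k21 * n
        elif method == "spectral":
            # c2: weight of the slow mode in the S-survival; from the
            # count-ratio relation A2/A1 = (c2/c1)*(lam1/lam2).
            c2 = n * lam2 / (lam1 + n * lam2)
            out_s = lam1 - c2 * (lam1 - lam2)  # = k21 + k23
            k32 = lam1 + lam2 - out_s
            if k32 <= 0:
                raise ValueError("dwell constants admit no valid generator")
            k21 = lam1 * lam2 / k32
            k23 = out_s - k21
            if k23 <= 0:
                raise ValueError(
                    "dwell constants admit no valid generator (k23 <= 0); "
                    "n_ratio too small for this lifetime separation"
                )
        else:
            raise ValueError(f"unknown method {method!r}")
        return cls(
            force=force, k12=k12, k21=k21, k23=k23, k32=k32, n_ratio=n
        )

    def folded_dwell_mixture(self) -> Tuple[float, float, float]:
        """Observable folded-dwell mixture (tau_short, tau_long, n_ratio)
        implied by this rate set (phase-type forward map; inverse of
        ``from_dwell_constants(method='spectral')``)."""
        tr = self.k21 + self.k23 + self.k32
        det = self.k21 * self.k32
        disc = math.sqrt(max(tr * tr - 4.0 * det, 0.0))
        lam1 = 0.5 * (tr + disc)
        lam2 = 0.5 * (tr - disc)
        c2 = (lam1 - (self.k21 + self.k23)) / (lam1 - lam2)
        c1 = 1.0 - c2
        a2_over_a1 = (c2 / c1) * (lam1 / lam2)
        return 1.0 / lam1, 1.0 / lam2, a2_over_a1


# -- default UL parametrization (phenomenological, config-exposed) ----------
#: S -> UL entry rate at zero force bias (1/s), force-independent.
UL_ENTRY_RATE = 2e-4
#: UL -> U rupture edge: calibrated so the modal 2 pN/s rupture force is
#: 42.9 pN and 1000-s survival at 5-7 pN exceeds 95%.
UL_RUPTURE_K0 = 1e-7
UL_RUPTURE_DX = 1.5


def sequential_model(
    rates: Optional[RateSet] = None,
    *,
    edges: Optional[Sequence[BellEdge]] = None,
    include_ul: bool = True,
    ul_branch: str = "S",
    ul_entry_rate: float = UL_ENTRY_RATE,
    ul_rupture_k0: float = UL_RUPTURE_K0,
    ul_rupture_dx: float = UL_RUPTURE_DX,
) -> StateModel:
    """Build the sequential scheme U <-> S <-> L (+ branch to UL).

    Either supply a fixed ``RateSet`` (force-clamp conditions: edges get
    dx = 0, i.e. the rates are those calibrated at the clamp force) or an
    explicit list of Bell edges for the U/S/L core.  The UL branch point
    defaults to S and may be moved to L.
    """
    if (rates is None) == (edges is None):
        raise ValueError("supply exactly one of rates= or edges=")
    if rates is not None:
        core = [
            BellEdge("U", "S", rates.k12),
            BellEdge("S", "U", rates.k21),
            BellEdge("S", "L", rates.k23),
            BellEdge("L", "S", rates.k32),
        ]
    else:
        core = list(edges)
        required = {("U", "S"), ("S", "U"), ("S", "L"), ("L", "S")}
        have = {(e.source, e.target) for e in core}
        if have != required:
            raise ValueError(f"sequential core must have edges {sorted(required)}")
    states = ("U", "S", "L")
    folded = {"S", "L"}
    if include_ul:
        if ul_branch not in ("S", "L"):
            raise ValueError("ul_branch must be 'S' or 'L'")
        core.append(BellEdge(ul_branch, "UL", ul_entry_rate, 0.0))
        core.append(BellEdge("UL", "U", ul_rupture_k0, ul_rupture_dx))
        states = states + ("UL",)
        folded = folded | {"UL"}
    return StateModel(
        states=states,
        edges=tuple(core),
        folded_states=frozenset(folded),
        topology="sequential",
    )


def parallel_model(
    k_us: float, k_su: float, k_ul_state: float, k_lu: float
) -> StateModel:
    """Competing direct folds U -> S and U -> L (alternative topology).

    Provided for model comparison against the sequential scheme; the
    reverse rates play the same role as k21 and k32 there.
    """
    edges = (
        BellEdge("U", "S", k_us),
        BellEdge("S", "U", k_su),
        BellEdge("U", "L", k_ul_state),
        BellEdge("L", "U", k_lu),
    )
    return StateModel(
        states=("U", "S", "L"),
        edges=edges,
        folded_states=frozenset({"S", "L"}),
        topology="parallel",
    )


def rate_matrix(
    model: StateModel, f: float, consts: PhysicalConstants = DEFAULT_CONSTANTS
) -> np.ndarray:
    """Column-convention generator Q(f): dp/dt = Q p.

    Off-diagonal Q[j, i] is the i->j rate; each column sums to zero.
    """
    n = len(model.states)
    q = np.zeros((n, n))
    for e in model.edges:
        i, j = model.index(e.source), model.index(e.target)
        q[j, i] += e.rate(f, consts)
    q[np.diag_indices(n)] -= q.sum(axis=0)
    return q


def master_solve(
    model: StateModel,
    f: float,
    p0: Sequence[float],
    t_grid: Sequence[float],
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
    dt: float = 0.01,
    conservation_tol: float = 1e-8,
) -> np.ndarray:
    """Integrate the Master equations with fixed-step 4th-order Runge-Kutta.

    Returns occupancies at the requested times, shape (len(t_grid), n).
    Each row sums to 1 within ``conservation_tol``; if a step size
    violates conservation the step is halved (up to 3 times) before
    failing.
    """
    p0 = np.asarray(p0, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    if p0.shape != (len(model.states),):
        raise ValueError("p0 has wrong length")
    if np.any(p0 < -1e-12) or abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError("p0 must be a probability vector")
    if np.any(np.diff(t_grid) < 0) or np.any(t_grid < 0):
        raise ValueError("t_grid must be sorted and non-negative")
    q = rate_matrix(model, f, consts)

    for attempt in range(4):
        step = dt / (2**attempt)
        out = np.empty((len(t_grid), len(p0)))
        p = p0.copy()
        t = 0.0
        ok = True
        for row, t_target in enumerate(t_grid):
            span = t_target - t
            if span > 0:
                n_steps = max(int(np.ceil(span / step)), 1)
                h = span / n_steps
                for _ in range(n_steps):
                    k1 = q @ p
                    k2 = q @ (p + 0.5 * h * k1)
                    k3 = q @ (p + 0.5 * h * k2)
                    k4 = q @ (p + h * k3)
                    p = p + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                t = t_target
            if abs(p.sum() - 1.0) > conservation_tol:
                ok = False
                break
            out[row] = p
        if ok:
            return out
    raise ArithmeticError(
        "RK4 step failed probability conservation even after refinement"
    )


def pfold_predict(
    model: StateModel,
    f: float,
    t,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
    dt: float = 0.01,
):
    """Probability that a molecule starting unfolded is folded at time t.

    p_fold(t) = sum of folded-state occupancies from the Master equation
    with initial condition concentrated in U.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    p0 = np.zeros(len(model.states))
    p0[model.index("U")] = 1.0
    occ = master_solve(model, f, p0, t_arr, consts, dt=dt)
    pf = occ[:, model.folded_mask].sum(axis=1)
    return pf if np.ndim(t) else float(pf[0])


def stationary_distribution(
    model: StateModel, f: float, consts: PhysicalConstants = DEFAULT_CONSTANTS
) -> np.ndarray:
    """Normalized null vector of the generator at force f.

    Raises :class:`ReducibleChainError` when the chain is not strongly
    connected (an absorbing analysis is then the right tool).
    """
    q = rate_matrix(model, f, consts)
    adj = (np.abs(q) > 0) & ~np.eye(len(q), dtype=bool)
    n_comp, _ = connected_components(adj.T, directed=True, connection="strong")
    if n_comp > 1:
        raise ReducibleChainError(
            "chain is reducible at this force; stationary distribution "
            "is not unique (consider absorbing-state analysis)"
        )
    # smallest singular vector = null space of Q
    _, _, vh = np.linalg.svd(q)
    pi = vh[-1]
    pi = np.abs(pi) / np.abs(pi).sum()
    return pi


@dataclass
class StateTrajectory:
    """Piecewise-constant state path from the stochastic simulation.

    ``times[i]`` is the entry time into ``states[i]``; the path holds
    until ``times[i+1]`` (or ``duration`` for the last state).
    """

    times: np.ndarray
    states: list
    duration: float
    seed: Optional[int] = None
    model: Optional[StateModel] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("event times must be nondecreasing")

    def state_at(self, t) -> np.ndarray:
        idx = np.clip(
            np.searchsorted(self.times, np.asarray(t, float), side="right") - 1,
            0,
            len(self.states) - 1,
        )
        return np.asarray(self.states, dtype=object)[idx]

    def folded_at(self, t) -> np.ndarray:
        """Boolean folded-class indicator sampled at times t."""
        folded = np.array(
            [s in self.model.folded_states for s in self.states], dtype=bool
        )
        idx = np.clip(
            np.searchsorted(self.times, np.asarray(t, float), side="right") - 1,
            0,
            len(self.states) - 1,
        )
        return folded[idx]

    def occupancy(self, label: str) -> float:
        """Time-averaged occupancy of one state."""
        bounds = np.append(self.times, self.duration)
        spans = np.diff(bounds)
        mask = np.array([s == label for s in self.states])
        return float(spans[mask].sum() / self.duration)

    def class_dwells(self) -> Tuple[np.ndarray, np.ndarray]:
        """(durations, is_folded) of the observable two-class dwells."""
        folded = np.array(
            [s in self.model.folded_states for s in self.states], dtype=bool
        )
        change = np.flatnonzero(np.diff(folded.astype(int)) != 0) + 1
        starts = np.concatenate([[0], change])
        bounds = np.append(self.times[starts], self.duration)
        return np.diff(bounds), folded[starts]


def gillespie_simulate(
    model: StateModel,
    protocol,
    seed=None,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
    initial_state: str = "U",
    force_scale: float = 1.0,
    max_rate_dt: float = 0.05,
) -> StateTrajectory:
    """Exact stochastic simulation of the chain under a force protocol.

    Force-clamp segments use the standard SSA.  Ramp segments advance on
    a grid fine enough that (total exit rate)*dt < ``max_rate_dt``,
    re-evaluating the Bell rates as the force changes.  ``force_scale``
    multiplies the nominal protocol force (per-tether calibration bias).
    Reproducible given ``seed`` (int or numpy Generator).
    """
    from .trace_synthesis import ForceProtocol  # local import to avoid cycle

    if not isinstance(protocol, ForceProtocol):
        protocol = ForceProtocol.clamp(float(protocol[0]), float(protocol[1]))
    rng = np.random.default_rng(seed)
    seed_val = seed if isinstance(seed, (int, np.integer)) else None

    n = len(model.states)
    idx_of = {s: i for i, s in enumerate(model.states)}
    # per-state outgoing edges as (target index, k0, dx)
    out_edges: list = [[] for _ in range(n)]
    for e in model.edges:
        out_edges[idx_of[e.source]].append(
            (idx_of[e.target], e.k0, e.dx / consts.kbt)
        )

    times = [0.0]
    states = [initial_state]
    state = idx_of[initial_state]
    t = 0.0
    for seg in protocol.segments:
        seg_end = t + seg.duration
        while t < seg_end:
            edges = out_edges[state]
            if not edges:
                break
            if seg.kind == "clamp":
                f = force_scale * seg.force
                rates = [k0 * math.exp(dxk * f) for _, k0, dxk in edges]
                total = sum(rates)
                if total <= 0:
                    break
                wait = rng.exponential(1.0 / total)
                if t + wait >= seg_end:
                    break
                t += wait
                u = rng.random() * total
                acc = 0.0
                for (j, _, _), r in zip(edges, rates):
                    acc += r
                    if u <= acc:
                        state = j
                        break
                times.append(t)
                states.append(model.states[state])
            else:  # ramp: piecewise-constant thinning grid
                f = force_scale * seg.force_at(t - (seg_end - seg.duration))
                rates = [k0 * math.exp(dxk * f) for _, k0, dxk in edges]
                total = sum(rates)
                if total <= 0:
                    dt_grid = 0.1
                else:
                    dt_grid = min(
                        max_rate_dt / total, 0.2 / abs(seg.loading_rate), 0.1
                    )
                dt_grid = max(dt_grid, 1e-5)
                step_end = min(t + dt_grid, seg_end)
                if total > 0:
                    wait = rng.exponential(1.0 / total)
                    if t + wait < step_end:
                        t += wait
                        u = rng.random() * total
                        acc = 0.0
                        for (j, _, _), r in zip(edges, rates):
                            acc += r
                            if u <= acc:
                                state = j
                                break
                        times.append(t)
                        states.append(model.states[state])
                        continue
                t = step_end
        t = seg_end
    return StateTrajectory(
        times=np.array(times),
        states=states,
        duration=protocol.duration,
        seed=seed_val,
        model=model,
    )
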