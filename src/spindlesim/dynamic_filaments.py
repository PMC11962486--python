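"""Two-state plus-end dynamics, local nucleation, and their closed-form steady states.

Microtubules here have a static minus end and a dynamic plus end that switches
stochastically between a growth state (speed ``v_g``) and a shrinkage state
(speed ``v_s``), with catastrophe rate ``k_cat`` (grow -> shrink) and rescue
rate ``k_res`` (shrink -> grow).  In the bounded-growth regime
(``v_s*k_cat - v_g*k_res > 0``) the population reaches a steady state with
mean length ``L = v_g*v_s / (v_s*k_cat - v_g*k_res)`` and mean lifetime
``tau = (v_g + v_s) / (v_s*k_cat - v_g*k_res)``.  New filaments appear at a
constant rate, with isotropic orientation, inside a small nucleation volume.

Units: speeds are nm/s, rates 1/s, lengths um, times s (speeds are the single
exception to the package-wide um/pN/s convention, because motor and growth
speeds are conventionally quoted in nm/s).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

NM = 1e-3  # nm -> um

__all__ = [
    "GrowthState",
    "DynamicInstabilityParams",
    "PlusEndState",
    "NucleationSource",
    "FilamentSeed",
    "step_plus_end",
    "mean_length_closed_form",
    "lifetime_closed_form",
    "nucleate",
    "expected_steady_state_count",
    "simulate_lifetime_ensemble",
    "simulate_population",
    "params_from_targets",
]


class GrowthState(enum.IntEnum):
    GROW = 0
    SHRINK = 1


class UnboundedGrowthError(ValueError):
    """Raised when a closed form is requested outside the bounded regime."""


@dataclass(frozen=True)
class DynamicInstabilityParams:
    """Plus-end two-state parameters.

    v_g, v_s in nm/s; k_cat, k_res in 1/s.
    """

    v_g: float
    v_s: float
    k_cat: float
    k_res: float = 0.0

    def __post_init__(self) -> None:
        for name in ("v_g", "v_s", "k_cat", "k_res"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def denominator(self) -> float:
        """``v_s*k_cat - v_g*k_res`` in nm/s^2; positive in the bounded regime."""
        return self.v_s * self.k_cat - self.v_g * self.k_res

    @property
    def bounded(self) -> bool:
        return self.denominator > 0


@dataclass
class PlusEndState:
    state: GrowthState
    length: float  # um

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("length must be >= 0")


@dataclass(frozen=True)
class FilamentSeed:
    """A freshly nucleated filament: minus-end position, unit direction, length."""

    position: np.ndarray  # (3,) um, minus end
    direction: np.ndarray  # (3,) unit vector, minus -> plus
    length: float  # um
    state: GrowthState = GrowthState.GROW


@dataclass(frozen=True)
class NucleationSource:
    """Constant-rate nucleation inside an axis-aligned box or a cylinder.

    ``volume`` is (Lx, Ly, Lz) for a box; for ``kind='cylinder'`` it is
    (length, diameter) with the cylinder axis along x.  The volume is centered
    at ``center``.
    """

    rate: float  # 1/s
    volume: tuple = (1.0, 1.0, 0.2)
    kind: str = "box"
    center: tuple = (0.0, 0.0, 0.0)
    initial_length: float = 0.01  # um

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("nucleation rate must be >= 0")
        if self.kind not in ("box", "cylinder"):
            raise ValueError(f"unknown nucleation volume kind {self.kind!r}")


def mean_length_closed_form(params: DynamicInstabilityParams) -> float:
    """Steady-state mean filament length L (um)."""
    if not params.bounded:
        raise UnboundedGrowthError(
            "unbounded growth: v_s*k_cat - v_g*k_res must be positive"
        )
    return NM * params.v_g * params.v_s / params.denominator


def lifetime_closed_form(params: DynamicInstabilityParams) -> float:
    """Steady-state mean filament lifetime tau (s)."""
    if not params.bounded:
        raise UnboundedGrowthError(
            "unbounded growth: v_s*k_cat - v_g*k_res must be positive"
        )
    return (params.v_g + params.v_s) / params.denominator


def expected_steady_state_count(rate: float, params: DynamicInstabilityParams) -> float:
    """Expected steady-state filament number nu * tau."""
    if rate == 0:
        return 0.0
    return rate * lifetime_closed_form(params)


def params_from_targets(v_g: float, mean_length: float, lifetime: float) -> DynamicInstabilityParams:
    """Invert the closed forms for (v_s, k_cat) at k_res = 0.

    Given a growth speed (nm/s), a target steady-state mean length (um) and
    lifetime (s), the zero-rescue parameters are uniquely
    ``k_cat = v_g/L`` and ``v_s = v_g / (v_g*tau/L - 1)`` (speeds in nm/s).
    """
    k_cat = v_g * NM / mean_length
    # tau = (v_g+v_s)/(v_s*k_cat) => v_s = v_g/(tau*k_cat - 1)
    denom = lifetime * k_cat - 1.0
    if denom <= 0:
        raise ValueError("lifetime too short for this (v_g, L) pair at k_res=0")
    v_s = v_g / denom
    return DynamicInstabilityParams(v_g=v_g, v_s=v_s, k_cat=k_cat, k_res=0.0)


def step_plus_end(
    end: PlusEndState,
    params: DynamicInstabilityParams,
    dt: float,
    rng: np.random.Generator,
) -> PlusEndState:
    """Advance one plus end by ``dt`` (first-reaction sampling within the step).

    At most one catastrophe/rescue per step; exact for constant rates when
    ``k*dt << 1``.  The minus end never moves, so the length change is the
    plus-end displacement.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    state, length = _step_lengths(
        np.array([int(end.state)], dtype=np.int8),
        np.array([end.length]),
        params,
        dt,
        rng,
    )
    return PlusEndState(GrowthState(int(state[0])), float(length[0]))


def _step_lengths(
    states: np.ndarray,
    lengths: np.ndarray,
    params: DynamicInstabilityParams,
    dt: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-state update; shared by the scalar op and the engine."""
    vg = params.v_g * NM
    vs = params.v_s * NM
    grow = states == int(GrowthState.GROW)
    rates = np.where(grow, params.k_cat, params.k_res)
    with np.errstate(divide="ignore"):
        waits = np.where(rates > 0, rng.exponential(1.0, size=states.shape) / np.where(rates > 0, rates, 1.0), np.inf)
    switch = waits < dt
    t1 = np.where(switch, waits, dt)
    t2 = dt - t1
    disp = np.where(grow, vg * t1 - vs * t2, -vs * t1 + vg * t2)
    new_states = np.where(switch, 1 - states, states).astype(np.int8)
    new_lengths = np.maximum(lengths + disp, 0.0)
    return new_states, new_lengths


def nucleate(
    source: NucleationSource, dt: float, rng: np.random.Generator
) -> list[FilamentSeed]:
    """Draw a Poisson number of new filaments for one step.

    Positions are uniform in the source volume, orientations isotropic in 3D,
    initial state GROW.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    n = rng.poisson(source.rate * dt)
    if n == 0:
        return []
    if source.kind == "box":
        half = 0.5 * np.asarray(source.volume[:3])
        pos = rng.uniform(-half, half, size=(n, 3))
    else:  # cylinder along x: volume = (length, diameter)
        length, diam = source.volume[0], source.volume[1]
        x = rng.uniform(-0.5 * length, 0.5 * length, size=n)
        r = 0.5 * diam * np.sqrt(rng.uniform(size=n))
        phi = rng.uniform(0, 2 * np.pi, size=n)
        pos = np.column_stack([x, r * np.cos(phi), r * np.sin(phi)])
    pos = pos + np.asarray(source.center)
    # isotropic directions
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return [
        FilamentSeed(position=pos[i].copy(), direction=u[i].copy(), length=source.initial_length)
        for i in range(n)
    ]


def simulate_lifetime_ensemble(
    params: DynamicInstabilityParams,
    n: int,
    dt: float,
    rng: np.random.Generator,
    initial_length: float = 0.01,
    removal_length: float = 0.005,
    max_time: float = 1e5,
) -> dict:
    """Simulate ``n`` filaments from nucleation to complete shrinkage.

    Returns lifetimes, the time-average of length over all (filament, time)
    samples (an unbiased estimate of the steady-state population mean length),
    and the final snapshot of lengths of any still-alive filaments.
    """
    states = np.zeros(n, dtype=np.int8)
    lengths = np.full(n, initial_length)
    alive = np.ones(n, dtype=bool)
    lifetimes = np.zeros(n)
    length_integrals = np.zeros(n)  # per-filament integral of L dt
    t = 0.0
    while alive.any() and t < max_time:
        idx = np.nonzero(alive)[0]
        s, L = _step_lengths(states[idx], lengths[idx], params, dt, rng)
        states[idx] = s
        lengths[idx] = L
        length_integrals[idx] += L * dt
        t += dt
        died = idx[L < removal_length]
        alive[died] = False
        lifetimes[died] = t
    lifetimes[alive] = t  # censored (should be empty for sane max_time)
    return {
        "lifetimes": lifetimes,
        "length_integrals": length_integrals,
        "mean_lifetime": float(lifetimes.mean()),
        "mean_length": float(length_integrals.sum() / lifetimes.sum()),
        "censored": int(alive.sum()),
    }


def simulate_population(
    params: DynamicInstabilityParams,
    rate: float,
    duration: float,
    dt: float,
    rng: np.random.Generator,
    initial_length: float = 0.01,
    removal_length: float = 0.005,
    record_every: int = 100,
) -> dict:
    """Birth-death population of plus ends only (no mechanics).

    Independent oracle for the steady-state filament count and the stationary
    length distribution; also used by property tests.
    """
    lengths = np.empty(0)
    states = np.empty(0, dtype=np.int8)
    times, counts = [], []
    nsteps = int(round(duration / dt))
    for i in range(nsteps):
        n_new = rng.poisson(rate * dt)
        if n_new:
            lengths = np.append(lengths, np.full(n_new, initial_length))
            states = np.append(states, np.zeros(n_new, dtype=np.int8))
        if lengths.size:
            states, lengths = _step_lengths(states, lengths, params, dt, rng)
            keep = lengths >= removal_length
            lengths, states = lengths[keep], states[keep]
        if i % record_every == 0:
            times.append((i + 1) * dt)
            counts.append(lengths.size)
    return {
        "times": np.array(times),
        "counts": np.array(counts),
        "final_lengths": lengths,
        "final_states": states,
    }
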