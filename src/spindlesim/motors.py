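"""Two-unit crosslink complexes: motors, diffusive binders, end binders.

A complex joins two microtubule-binding units by a Hookean spring (rest
length, spring constant) with no angular constraint.  Each unit is one of

* ``MOTOR`` — walks along the lattice with a linear force-velocity relation
  ``v = v_m (1 + f.d / f_stall)`` (clamped to [0, |v_m|]); ``v_m`` is signed,
  positive toward the plus end.  At a filament end the motor dwells and keeps
  unbinding at its (force-dependent) rate.
* ``DIFFUSIVE`` — hops on an ``a`` = 8 nm lattice at rate ``D/a^2`` per
  direction; under a tangential load ``f`` the hop rates are biased by
  ``exp(+-f a / 2 kT)``, giving a mean drift ``D f / kT`` (= ``D dU/(a kT)``
  with ``dU = f a``) in the small-force limit.
* ``END_BINDER`` — binds only within ``end_zone`` of the minus end and does
  not move.

All units unbind at the Bell rate ``k_off exp(f / f_unbind)``.

Units: speeds nm/s, rates 1/s, forces pN, D um^2/s, lattice step nm,
lengths um.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np

NM = 1e-3  # nm -> um

__all__ = [
    "UnitKind",
    "MotorUnitSpec",
    "CrosslinkComplex",
    "AttachmentRecord",
    "unbind_rate",
    "motor_speed",
    "walk_step",
    "diffusive_step",
    "attach_step",
    "crosslink_force",
    "make_archetype",
    "ARCHETYPES",
]


class UnitKind(enum.IntEnum):
    MOTOR = 0
    DIFFUSIVE = 1
    END_BINDER = 2


@dataclass(frozen=True)
class MotorUnitSpec:
    kind: UnitKind
    v_m: float = 0.0  # nm/s, signed (+ toward plus end)
    k_off: float = 0.1  # 1/s, unloaded unbinding rate
    f_stall: float = 5.0  # pN
    f_unbind: float = 3.0  # pN, Bell characteristic force
    D: float = 0.0  # um^2/s, lattice diffusion (DIFFUSIVE)
    a: float = 8.0  # nm, lattice step (DIFFUSIVE)
    end_zone: float = 0.03  # um, minus-end binding zone (END_BINDER)

    def __post_init__(self) -> None:
        if self.k_off < 0:
            raise ValueError("k_off must be >= 0")
        if self.kind == UnitKind.MOTOR and self.f_stall <= 0:
            raise ValueError("f_stall must be > 0")


@dataclass(frozen=True)
class CrosslinkComplex:
    """Specification of a two-unit crosslinker species."""

    unit_a: MotorUnitSpec
    unit_b: MotorUnitSpec
    rest_length: float = 0.05  # um
    stiffness: float = 100.0  # pN/um
    k_on: float = 10.0  # 1/s per unit, within binding_range
    binding_range: float = 0.05  # um
    parallel_only: bool = False
    name: str = "custom"

    @property
    def units(self) -> tuple[MotorUnitSpec, MotorUnitSpec]:
        return (self.unit_a, self.unit_b)


@dataclass
class AttachmentRecord:
    """One unit bound to one fiber at arc-length ``abscissa`` from the minus end."""

    complex_id: int
    fiber_id: int
    abscissa: float
    bound: bool = True


# ---------------------------------------------------------------------------
# kinetic laws (scalar or ufunc-style; the engine reuses these directly)


def unbind_rate(k_off, f_load, f_unbind):
    """Bell force-dependent unbinding rate ``k_off * exp(f_load / f_unbind)``."""
    if np.any(np.asarray(f_unbind) <= 0):
        raise ValueError("f_unbind must be > 0")
    if np.any(np.asarray(f_load) < 0):
        raise ValueError("f_load is a force magnitude and must be >= 0")
    return k_off * np.exp(np.asarray(f_load) / f_unbind)


def motor_speed(v_m, load_vector, direction_vector, f_stall):
    """Linear force-velocity: ``v = v_m (1 + f.d / f_stall)``, clamped to [0, v_m].

    ``direction_vector`` is the unit tangent in the walking direction;
    assisting loads saturate at ``v_m``, super-stall opposing loads at 0.
    Returns the (unsigned) speed in the units of ``v_m``.
    """
    fdotd = float(np.dot(np.asarray(load_vector, dtype=float), np.asarray(direction_vector, dtype=float)))
    return _motor_speed_scalar(abs(v_m), fdotd, f_stall)


def _motor_speed_scalar(v_abs, f_tangential, f_stall):
    v = v_abs * (1.0 + np.asarray(f_tangential) / f_stall)
    return np.clip(v, 0.0, v_abs)


def walk_step(attachment: AttachmentRecord, speed: float, dt: float, fiber_length: float, toward_plus: bool) -> AttachmentRecord:
    """Advance a motor attachment by ``speed*dt`` toward its end, pinning there.

    ``speed`` is the unsigned nm/s speed from :func:`motor_speed`; the end
    dwell is implicit: the abscissa saturates at the end and the unit keeps
    unbinding at its force-dependent rate.
    """
    step = speed * NM * dt
    absc = attachment.abscissa + (step if toward_plus else -step)
    absc = min(max(absc, 0.0), fiber_length)
    return replace(attachment, abscissa=absc)


def hop_rates(spec: MotorUnitSpec, f_tangential, kT_um: float):
    """Biased lattice hop rates (toward_plus_rate, toward_minus_rate) in 1/s.

    ``f_tangential`` is the tangential load component, positive toward the
    plus end; the bias factor per hop is ``exp(+-f a / 2 kT)`` so the drift
    is ``D f / kT`` for small forces.
    """
    a_um = spec.a * NM
    k0 = spec.D / a_um**2
    x = np.asarray(f_tangential) * a_um / (2.0 * kT_um)
    return k0 * np.exp(x), k0 * np.exp(-x)


def diffusive_step(
    attachment: AttachmentRecord,
    f_tangential: float,
    spec: MotorUnitSpec,
    dt: float,
    rng: np.random.Generator,
    fiber_length: float,
    kT_um: float = 4.2e-3,
) -> AttachmentRecord:
    """One interval of biased lattice diffusion (Poisson hop counts)."""
    kp, km = hop_rates(spec, f_tangential, kT_um)
    n_plus = rng.poisson(kp * dt)
    n_minus = rng.poisson(km * dt)
    absc = attachment.abscissa + spec.a * NM * (n_plus - n_minus)
    absc = min(max(absc, 0.0), fiber_length)
    return replace(attachment, abscissa=absc)


def binding_probability(k_on: float, dt: float) -> float:
    return 1.0 - np.exp(-k_on * dt)


def attach_step(
    unit: MotorUnitSpec,
    complex_spec: CrosslinkComplex,
    position: np.ndarray,
    fibers,
    dt: float,
    rng: np.random.Generator,
    other_tangent: np.ndarray | None = None,
) -> AttachmentRecord | None:
    """Attempt to bind one free unit near a set of fibers.

    ``fibers`` is a sequence of objects with ``point_at``/``tangent_at``/
    ``length`` (e.g. :class:`spindlesim.mechanics.SegmentedFiber`).  The unit
    binds with probability ``1 - exp(-k_on dt)`` to the nearest fiber point
    within ``binding_range``; an ``END_BINDER`` only if that point lies within
    ``end_zone`` of the minus end; a ``parallel_only`` complex refuses a
    configuration whose local tangents oppose ``other_tangent``.
    """
    position = np.asarray(position, dtype=float)
    best = (None, np.inf, 0.0)
    for i, fib in enumerate(fibers):
        absc, dist = _nearest_abscissa(fib, position)
        if dist < best[1]:
            best = (i, dist, absc)
    i, dist, absc = best
    if i is None or dist > complex_spec.binding_range:
        return None
    fib = fibers[i]
    if unit.kind == UnitKind.END_BINDER and absc > unit.end_zone:
        return None
    if complex_spec.parallel_only and other_tangent is not None:
        if float(np.dot(fib.tangent_at(absc), other_tangent)) < 0.0:
            return None
    if rng.uniform() >= binding_probability(complex_spec.k_on, dt):
        return None
    return AttachmentRecord(complex_id=-1, fiber_id=i, abscissa=absc)


def _nearest_abscissa(fiber, position):
    V = fiber.vertices
    d = np.diff(V, axis=0)
    L2 = np.einsum("ij,ij->i", d, d)
    w = np.einsum("ij,ij->i", position[None, :] - V[:-1], d) / np.where(L2 > 0, L2, 1.0)
    w = np.clip(w, 0.0, 1.0)
    proj = V[:-1] + w[:, None] * d
    dist = np.linalg.norm(proj - position[None, :], axis=1)
    j = int(np.argmin(dist))
    absc = (j + w[j]) * fiber.segmentation
    return absc, float(dist[j])


def crosslink_force(
    complex_spec: CrosslinkComplex,
    point_a: np.ndarray,
    point_b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Signed Hookean spring forces (on unit a, on unit b).

    Tensile when stretched beyond the rest length, compressive when shorter;
    the two forces are equal and opposite.
    """
    point_a = np.asarray(point_a, dtype=float)
    point_b = np.asarray(point_b, dtype=float)
    dvec = point_b - point_a
    d = float(np.linalg.norm(dvec))
    if d < 1e-12:
        return np.zeros(3), np.zeros(3)
    f = complex_spec.stiffness * (d - complex_spec.rest_length) * (dvec / d)
    return f, -f


# ---------------------------------------------------------------------------
# archetypes (figure-legend parameterizations)


def _motor(v_m, k_off, **kw):
    return MotorUnitSpec(kind=UnitKind.MOTOR, v_m=v_m, k_off=k_off, **kw)


def _diffusive(D=0.1, k_off=0.01, **kw):
    return MotorUnitSpec(kind=UnitKind.DIFFUSIVE, D=D, k_off=k_off, **kw)


def _end_binder(k_off=0.01, **kw):
    return MotorUnitSpec(kind=UnitKind.END_BINDER, k_off=k_off, **kw)


def make_archetype(name: str, minus_speed: float = 30.0, **overrides) -> CrosslinkComplex:
    """Preset crosslinker species.

    * ``kinesin5`` — two processive plus-motor units, +30 nm/s, k_off 0.1/s.
    * ``hset`` — nonprocessive minus motor (-80 nm/s, k_off 5/s) + diffusive
      unit (D 0.1 um^2/s, k_off 0.01/s).
    * ``symmetric_minus`` — two minus-motor units at ``minus_speed`` nm/s
      (30-1200), k_off 0.1/s.
    * ``dynein_end_numa`` — fast minus motor (-1200 nm/s, k_off 0.1/s) +
      minus-end binder (k_off 0.01/s); ``dynein_end_numa_parallel_only``
      additionally refuses antiparallel crosslinks.
    * ``dynein_diffusive_numa`` — minus motor (-120 nm/s, k_off 0.1/s) +
      diffusive unit (D 0.1 um^2/s, k_off 0.01/s).

    ``overrides`` replace any :class:`CrosslinkComplex` field.
    """
    if name == "kinesin5":
        c = CrosslinkComplex(_motor(30.0, 0.1), _motor(30.0, 0.1), name=name)
    elif name == "hset":
        c = CrosslinkComplex(_motor(-80.0, 5.0), _diffusive(), name=name)
    elif name == "symmetric_minus":
        c = CrosslinkComplex(
            _motor(-abs(minus_speed), 0.1), _motor(-abs(minus_speed), 0.1), name=name
        )
    elif name == "dynein_end_numa":
        c = CrosslinkComplex(_motor(-1200.0, 0.1), _end_binder(), name=name)
    elif name == "dynein_end_numa_parallel_only":
        c = CrosslinkComplex(
            _motor(-1200.0, 0.1), _end_binder(), parallel_only=True, name=name
        )
    elif name == "dynein_diffusive_numa":
        c = CrosslinkComplex(_motor(-120.0, 0.1), _diffusive(), name=name)
    else:
        raise ValueError(f"unknown archetype {name!r}")
    return replace(c, **overrides) if overrides else c


ARCHETYPES = (
    "kinesin5",
    "hset",
    "symmetric_minus",
    "dynein_end_numa",
    "dynein_end_numa_parallel_only",
    "dynein_diffusive_numa",
)
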