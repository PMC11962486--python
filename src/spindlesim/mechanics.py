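"""Overdamped Langevin mechanics of incompressible semiflexible fibers.

Fibers are polylines of vertices with (near-)equal spacing; they carry
bending elasticity (flexural rigidity ``kappa``), short-range steric
repulsion between distinct fibers, harmonic confinement to a box or
cylinder, crosslink spring forces (see :mod:`spindlesim.motors`) and thermal
forces.  Each vertex moves by ``dx = dt/gamma * F + sqrt(2 kT dt / gamma) xi``
with isotropic per-vertex drag ``gamma = 3 pi eta s * drag_factor``, after
which inextensibility is restored by arc-length reparametrization anchored
at the minus end.

Units: um, pN, s.  ``kT`` is accepted in pN nm (the conventional unit) and
converted internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels

__all__ = [
    "SimulationConstants",
    "ConfinementGeometry",
    "StericParams",
    "SegmentedFiber",
    "SegmentHash",
    "bending_forces",
    "steric_forces",
    "confinement_forces",
    "enforce_inextensibility",
    "langevin_step",
    "TimestepInstabilityError",
]


class TimestepInstabilityError(RuntimeError):
    """A vertex moved more than half a segment in one step."""


@dataclass(frozen=True)
class SimulationConstants:
    kT: float = 4.2  # pN nm
    viscosity: float = 0.05  # Pa s = pN s / um^2
    dt: float = 0.01  # s

    def __post_init__(self) -> None:
        if self.kT <= 0 or self.viscosity <= 0 or self.dt <= 0:
            raise ValueError("kT, viscosity and dt must be positive")

    @property
    def kT_um(self) -> float:
        """Thermal energy in pN um."""
        return self.kT * 1e-3


@dataclass(frozen=True)
class ConfinementGeometry:
    """Reflecting boundaries, realized as stiff harmonic confinement.

    ``kind='box'``: dims = (Lx, Ly, Lz), centered at the origin.
    ``kind='cylinder'``: dims = (length, diameter), axis along x.
    """

    kind: str = "box"
    dims: tuple = (30.0, 30.0, 0.2)
    stiffness: float = 100.0  # pN/um

    def __post_init__(self) -> None:
        if self.kind not in ("box", "cylinder"):
            raise ValueError(f"unknown confinement kind {self.kind!r}")

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        if self.kind == "box":
            half = 0.5 * np.asarray(self.dims[:3])
            return -half, half
        length, diam = self.dims[0], self.dims[1]
        half = np.array([0.5 * length, 0.5 * diam, 0.5 * diam])
        return -half, half

    def contains(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        if self.kind == "box":
            lo, hi = self.bounds
            return np.all((points >= lo) & (points <= hi), axis=1)
        half_len, radius = 0.5 * self.dims[0], 0.5 * self.dims[1]
        r = np.hypot(points[:, 1], points[:, 2])
        return (np.abs(points[:, 0]) <= half_len) & (r <= radius)


@dataclass(frozen=True)
class StericParams:
    range: float = 0.05  # um, center-line repulsion distance d0
    stiffness: float = 100.0  # pN/um

    def __post_init__(self) -> None:
        if self.range <= 0:
            raise ValueError("steric range must be > 0")


@dataclass
class SegmentedFiber:
    """A single fiber as vertex chain; vertex 0 is the (static) minus end."""

    vertices: np.ndarray  # (n, 3) um
    segmentation: float = 0.5  # um, target segment length
    rigidity: float = 20.0  # pN um^2

    @classmethod
    def straight(
        cls,
        start,
        direction,
        length: float,
        segmentation: float = 0.5,
        rigidity: float = 20.0,
    ) -> "SegmentedFiber":
        n = vertex_count(length, segmentation)
        direction = np.asarray(direction, dtype=float)
        direction = direction / np.linalg.norm(direction)
        s = np.linspace(0.0, length, n)[:, None]
        return cls(np.asarray(start, dtype=float) + s * direction, segmentation, rigidity)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def length(self) -> float:
        """Nominal length (segment count x target segmentation)."""
        return (self.n_vertices - 1) * self.segmentation

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.vertices, axis=0), axis=1).sum())

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)

    def point_at(self, abscissa: float) -> np.ndarray:
        """Position at arc-length ``abscissa`` from the minus end."""
        s = self.segmentation
        j = min(max(int(abscissa / s), 0), self.n_vertices - 2)
        w = np.clip(abscissa / s - j, 0.0, 1.0)
        return (1 - w) * self.vertices[j] + w * self.vertices[j + 1]

    def tangent_at(self, abscissa: float) -> np.ndarray:
        s = self.segmentation
        j = min(max(int(abscissa / s), 0), self.n_vertices - 2)
        t = self.vertices[j + 1] - self.vertices[j]
        return t / np.linalg.norm(t)


def vertex_count(length: float, segmentation: float) -> int:
    """Vertex count for a fiber of given length: max(2, ceil(L/seg)+1).

    The ceiling keeps every actual segment at or below the target
    segmentation, which bounds the neighbor-search radius of the steric and
    binding machinery.
    """
    return max(2, int(np.ceil(length / segmentation - 1e-9)) + 1)


# ---------------------------------------------------------------------------
# forces


def bending_forces(fiber: SegmentedFiber, rigidity: float | None = None) -> np.ndarray:
    """Discrete-curvature elastic forces (pN) on each vertex."""
    kappa = fiber.rigidity if rigidity is None else rigidity
    F = np.zeros_like(fiber.vertices)
    if fiber.n_vertices < 3:
        return F
    off = np.array([0, fiber.n_vertices], dtype=np.int64)
    _kernels.bending_forces(
        fiber.vertices, off, np.array([fiber.segmentation]), kappa, F
    )
    return F


@dataclass
class SegmentHash:
    """Uniform spatial hash over all fiber segments (midpoint binning)."""

    seg_v0: np.ndarray
    seg_fib: np.ndarray
    seg_local: np.ndarray
    cell_of_seg: np.ndarray
    order: np.ndarray
    cell_start: np.ndarray
    dims: tuple
    origin: np.ndarray
    cell_size: float
    mids: np.ndarray | None = None
    seg_len: np.ndarray | None = None


def build_segment_hash(
    X: np.ndarray,
    off: np.ndarray,
    cell_size: float,
    origin: np.ndarray | None = None,
    dims: np.ndarray | None = None,
    seg_arrays: tuple | None = None,
) -> SegmentHash:
    nf = off.shape[0] - 1
    if seg_arrays is None:
        nv = np.diff(off)
        V = X.shape[0]
        mask = np.ones(V, dtype=bool)
        mask[off[1:] - 1] = False  # last vertex of each fiber starts no segment
        seg_v0 = np.nonzero(mask)[0].astype(np.int64)
        seg_fib = np.repeat(np.arange(nf, dtype=np.int64), nv - 1)
        seg_local = seg_v0 - off[seg_fib]
    else:
        seg_v0, seg_fib, seg_local = seg_arrays
    mids = 0.5 * (X[seg_v0] + X[seg_v0 + 1])
    if origin is None:
        origin = X.min(axis=0) - cell_size
        extent = X.max(axis=0) - origin + cell_size
        dims = np.maximum((extent / cell_size).astype(np.int64) + 1, 1)
    cc = np.clip(((mids - origin) / cell_size).astype(np.int64), 0, dims - 1)
    lin = (cc[:, 0] * dims[1] + cc[:, 1]) * dims[2] + cc[:, 2]
    ncells = int(dims[0] * dims[1] * dims[2])
    order, cell_start = _kernels.counting_sort(lin, ncells)
    seg_len = np.linalg.norm(X[seg_v0 + 1] - X[seg_v0], axis=1)
    return SegmentHash(
        seg_v0=seg_v0,
        seg_fib=seg_fib,
        seg_local=seg_local,
        cell_of_seg=lin,
        order=order,
        cell_start=cell_start,
        dims=(int(dims[0]), int(dims[1]), int(dims[2])),
        origin=origin,
        cell_size=cell_size,
        mids=mids,
        seg_len=seg_len,
    )


def steric_forces(
    fibers: list[SegmentedFiber],
    params: StericParams,
    rng: np.random.Generator | None = None,
) -> list[np.ndarray]:
    """Pairwise short-range repulsion between distinct fibers.

    Returns one per-vertex force array per fiber.  Exactly coincident segment
    pairs get a force along a random unit normal (drawn once per call).
    """
    X = np.concatenate([f.vertices for f in fibers], axis=0)
    off = np.zeros(len(fibers) + 1, dtype=np.int64)
    np.cumsum([f.n_vertices for f in fibers], out=off[1:])
    F = np.zeros_like(X)
    cell = max(params.range, max(f.segmentation for f in fibers)) * 1.2
    h = build_segment_hash(X, off, cell)
    fallback = _random_unit(rng)
    _kernels.steric_forces(
        X,
        h.seg_v0,
        h.seg_fib,
        h.mids,
        h.seg_len,
        h.cell_of_seg,
        h.order,
        h.cell_start,
        h.dims[0],
        h.dims[1],
        h.dims[2],
        params.range,
        0.0,
        params.stiffness,
        fallback,
        F,
        np.zeros(X.shape[0]),
        np.zeros((0, 2), dtype=np.int64),
        np.zeros((0, 2)),
        np.zeros((0, 3)),
        np.zeros(0),
        np.zeros(1, dtype=np.int64),
    )
    return [F[off[i] : off[i + 1]] for i in range(len(fibers))]


def _random_unit(rng: np.random.Generator | None) -> np.ndarray:
    if rng is None:
        return np.array([0.0, 0.0, 1.0])
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def confinement_forces(points: np.ndarray, geometry: ConfinementGeometry) -> np.ndarray:
    """Inward harmonic force on every point outside the container; zero inside."""
    P = np.atleast_2d(points)
    F = np.zeros_like(P)
    k = geometry.stiffness
    if geometry.kind == "box":
        half = 0.5 * np.asarray(geometry.dims[:3])
        excess = np.abs(P) - half
        out = excess > 0
        F[out] = -np.sign(P[out]) * k * excess[out]
    else:
        half_len, radius = 0.5 * geometry.dims[0], 0.5 * geometry.dims[1]
        ex = np.abs(P[:, 0]) - half_len
        cap = ex > 0
        F[cap, 0] = -np.sign(P[cap, 0]) * k * ex[cap]
        r = np.hypot(P[:, 1], P[:, 2])
        outr = r > radius
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(r > 0, k * (r - radius) / r, 0.0)
        F[outr, 1] = -scale[outr] * P[outr, 1]
        F[outr, 2] = -scale[outr] * P[outr, 2]
    return F if points.ndim == 2 else F[0]


# ---------------------------------------------------------------------------
# constraint and integration


def enforce_inextensibility(
    fiber: SegmentedFiber,
    total_length: float | None = None,
    preserve_com: bool = False,
    tol: float = 1e-3,
    max_iter: int = 8,
) -> SegmentedFiber:
    """Restore equal segment lengths by arc-length reparametrization.

    The fiber is resampled to uniform spacing along its current shape with
    total length ``total_length`` (default: the nominal length), iterating
    until every segment matches the spacing to relative ``tol``.  By default
    vertex 0 (the minus end) is kept fixed, which is how plus-end growth is
    applied; with ``preserve_com=True`` the resampled fiber is translated
    back onto the input center of mass, the correct projection after a
    Langevin step (an anchored projection would suppress the longitudinal
    force and diffusion response).
    """
    L = fiber.length if total_length is None else total_length
    n = vertex_count(L, fiber.segmentation)
    off_new = np.array([0, n], dtype=np.int64)
    com = fiber.vertices.mean(axis=0)
    X = fiber.vertices
    s = L / (n - 1)
    for _ in range(max_iter):
        Xnew = np.empty((n, 3))
        off_old = np.array([0, X.shape[0]], dtype=np.int64)
        _kernels.resample_fibers(X, off_old, Xnew, off_new, np.array([L]))
        X = Xnew
        seg = np.linalg.norm(np.diff(X, axis=0), axis=1)
        if np.abs(seg - s).max() <= tol * s:
            break
    if preserve_com:
        X = X + (com - X.mean(axis=0))
    out = replace(fiber, vertices=X)
    out.segmentation = fiber.segmentation if n == fiber.n_vertices else s
    return out


def vertex_drag(
    segmentation: float, constants: SimulationConstants, drag_factor: float = 1.0
) -> float:
    """Isotropic per-vertex drag gamma = 3 pi eta s * drag_factor (pN s/um)."""
    return 3.0 * np.pi * constants.viscosity * segmentation * drag_factor


def langevin_step(
    fibers: list[SegmentedFiber],
    forces: list[np.ndarray],
    constants: SimulationConstants,
    rng: np.random.Generator,
    drag_factor: float = 1.0,
    check_stability: bool = True,
) -> list[SegmentedFiber]:
    """One explicit overdamped step followed by the inextensibility projection.

    Raises :class:`TimestepInstabilityError` if any vertex displacement
    exceeds half a segment (diagnostic for a too-large ``dt``).
    """
    out = []
    for fiber, F in zip(fibers, forces):
        gamma = vertex_drag(fiber.segmentation, constants, drag_factor)
        noise = np.sqrt(2.0 * constants.kT_um * constants.dt / gamma) * rng.standard_normal(
            fiber.vertices.shape
        )
        drift = (constants.dt / gamma) * F
        dx = drift + noise
        if check_stability:
            # the stability criterion applies to the force-driven part;
            # thermal displacement of a short fiber is genuine diffusion
            dmax = float(np.abs(drift).max(initial=0.0))
            if dmax > 0.5 * fiber.segmentation:
                raise TimestepInstabilityError(
                    f"force-driven vertex displacement {dmax:.3g} um exceeds half "
                    f"the segmentation {fiber.segmentation:.3g} um; reduce dt"
                )
        moved = replace(fiber, vertices=fiber.vertices + dx)
        out.append(
            enforce_inextensibility(moved, total_length=fiber.length, preserve_com=True)
        )
    return out
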