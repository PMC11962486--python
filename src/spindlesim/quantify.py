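"""Analysis pipeline: end-density maps, pole detection, link topology,
kymographs, speckle flux, spindle width.

Pole detection works on a 2D ratio map ``Ratio = I_minus / (1 + I_plus)``
built from gridded minus/plus end densities (unit-mass Gaussians of width
``sigma`` = 0.25 um on a 0.5 um grid, accumulated over a window of frames,
by default the final 51).  Minus intensities below 5% of the map maximum
are filtered out first; poles are strict local maxima with density > 8 that
are at least 3 grid cells apart (closer maxima merge into the higher one).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .engine import Trajectory, _point_on_frame_fiber, _tangent_on_frame_fiber
from .mechanics import ConfinementGeometry

__all__ = [
    "DensityMap",
    "RatioMap",
    "Pole",
    "PoleStats",
    "NetworkState",
    "LinkGeometry",
    "LinkTopologyCounts",
    "Kymograph",
    "map_extent",
    "build_density_map",
    "build_count_map",
    "ratio_map",
    "detect_poles",
    "pole_stats",
    "classify_state",
    "classify_links",
    "frame_link_geometries",
    "classify_frame_links",
    "make_speckles",
    "track_speckles",
    "kymograph",
    "spindle_axis",
    "flux_speed",
    "spindle_width",
    "fit_width_scaling",
]


# ---------------------------------------------------------------------------
# density and ratio maps


@dataclass
class DensityMap:
    values: np.ndarray  # (nx, ny)
    extent: tuple  # (xmin, xmax, ymin, ymax)
    grid_size: float = 0.5
    gaussian_width: float = 0.25
    n_frames: int = 1

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def cell_center(self, ix: int, iy: int) -> np.ndarray:
        return np.array(
            [
                self.extent[0] + (ix + 0.5) * self.grid_size,
                self.extent[2] + (iy + 0.5) * self.grid_size,
            ]
        )

    def cell_of(self, xy) -> tuple[int, int]:
        ix = int((xy[0] - self.extent[0]) / self.grid_size)
        iy = int((xy[1] - self.extent[2]) / self.grid_size)
        return ix, iy


@dataclass
class RatioMap:
    values: np.ndarray
    extent: tuple
    grid_size: float = 0.5
    filter_fraction: float = 0.05


def map_extent(geometry: ConfinementGeometry) -> tuple:
    lo, hi = geometry.bounds
    return (float(lo[0]), float(hi[0]), float(lo[1]), float(hi[1]))


def _grid_shape(extent, grid_size):
    nx = max(1, int(np.ceil((extent[1] - extent[0]) / grid_size)))
    ny = max(1, int(np.ceil((extent[3] - extent[2]) / grid_size)))
    return nx, ny


def build_density_map(
    points,
    extent,
    grid_size: float = 0.5,
    gaussian_width: float = 0.25,
    n_frames: int | None = None,
) -> DensityMap:
    """Sum of unit-mass 2D Gaussians (sigma = ``gaussian_width``) on the grid.

    ``points`` is one (k, >=2) array or a list of per-frame arrays (only x, y
    are used).  Cell values are the Gaussian mass integrated over the cell,
    so the map total equals the number of deposited points up to truncation
    (the deposit window is +-5 sigma).
    """
    if isinstance(points, (list, tuple)):
        frames = [np.atleast_2d(p) for p in points if np.size(p)]
        nfr = len(points)
        pts = np.concatenate(frames, axis=0) if frames else np.zeros((0, 2))
    else:
        pts = np.atleast_2d(points)
        nfr = 1 if n_frames is None else n_frames
    if n_frames is not None:
        nfr = n_frames
    nx, ny = _grid_shape(extent, grid_size)
    values = np.zeros((nx, ny))
    if pts.shape[0]:
        _deposit_gaussians(values, pts[:, 0], pts[:, 1], extent, grid_size, gaussian_width)
    return DensityMap(values, tuple(extent), grid_size, gaussian_width, nfr)


def _deposit_gaussians(values, x, y, extent, h, sigma):
    nx, ny = values.shape
    w = int(np.ceil(5.0 * sigma / h))
    s2 = sigma * np.sqrt(2.0)
    ix0 = np.floor((x - extent[0]) / h).astype(int)
    iy0 = np.floor((y - extent[2]) / h).astype(int)
    offs = np.arange(-w, w + 1)
    # per-point per-offset cell masses (separable erf integrals)
    def masses(coord, i0, lo):
        edges_lo = lo + (i0[:, None] + offs[None, :]) * h
        a = erf((edges_lo + h - coord[:, None]) / s2)
        b = erf((edges_lo - coord[:, None]) / s2)
        return 0.5 * (a - b)

    wx = masses(x, ix0, extent[0])
    wy = masses(y, iy0, extent[2])
    IX = ix0[:, None, None] + offs[None, :, None]
    IY = iy0[:, None, None] + offs[None, None, :]
    W = wx[:, :, None] * wy[:, None, :]
    valid = (IX >= 0) & (IX < nx) & (IY >= 0) & (IY < ny)
    lin = np.where(valid, IX * ny + IY, 0)
    np.add.at(values.ravel(), lin.ravel()[valid.ravel()], W.ravel()[valid.ravel()])


def build_count_map(points, extent, grid_size: float = 0.5) -> DensityMap:
    """Plain 2D histogram of points (used for per-pole minus-end counts)."""
    if isinstance(points, (list, tuple)):
        frames = [np.atleast_2d(p) for p in points if np.size(p)]
        nfr = len(points)
        pts = np.concatenate(frames, axis=0) if frames else np.zeros((0, 2))
    else:
        pts = np.atleast_2d(points)
        nfr = 1
    nx, ny = _grid_shape(extent, grid_size)
    if pts.shape[0]:
        H, _, _ = np.histogram2d(
            pts[:, 0],
            pts[:, 1],
            bins=(nx, ny),
            range=((extent[0], extent[0] + nx * grid_size), (extent[2], extent[2] + ny * grid_size)),
        )
    else:
        H = np.zeros((nx, ny))
    return DensityMap(H, tuple(extent), grid_size, 0.0, nfr)


def ratio_map(
    minus_map: DensityMap, plus_map: DensityMap, filter_fraction: float = 0.05
) -> RatioMap:
    """``Ratio = I_minus / (1 + I_plus)`` after zeroing weak minus signals.

    Minus intensities below ``filter_fraction`` of the minus-map maximum are
    set to zero (they come from single microtubules).  Where ``I_plus`` is
    zero the formula reduces to ``I_minus`` itself.
    """
    if minus_map.values.shape != plus_map.values.shape:
        raise ValueError("minus and plus maps are not congruent")
    Im = minus_map.values.copy()
    if Im.size and Im.max() > 0:
        Im[Im < filter_fraction * Im.max()] = 0.0
    vals = Im / (1.0 + plus_map.values)
    return RatioMap(vals, minus_map.extent, minus_map.grid_size, filter_fraction)


# ---------------------------------------------------------------------------
# pole detection


@dataclass(frozen=True)
class Pole:
    ix: int
    iy: int
    position: np.ndarray  # (2,) um, cell center
    value: float  # ratio density at the pole
    minus_count: float  # minus ends in the pole's pixel (per frame)


def detect_poles(
    rmap: RatioMap,
    minus_count_map: DensityMap | None = None,
    threshold: float = 8.0,
    min_separation: int = 3,
) -> list[Pole]:
    """Strict local maxima of the ratio map with density > ``threshold``.

    Maxima closer than ``min_separation`` grid cells merge, keeping the
    higher-density one (ties: lower grid index).  The per-pole minus-end
    count is read from the (unsmoothed) count map at the pole's pixel,
    normalized per frame.
    """
    V = rmap.values
    if V.size == 0:
        return []
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    neigh_max = ndimage.maximum_filter(V, footprint=footprint, mode="constant", cval=-np.inf)
    cand = np.nonzero((V > neigh_max) & (V > threshold))
    order = sorted(
        zip(cand[0], cand[1]), key=lambda c: (-V[c[0], c[1]], c[0], c[1])
    )
    accepted: list[tuple[int, int]] = []
    for c in order:
        if all(np.hypot(c[0] - a[0], c[1] - a[1]) >= min_separation for a in accepted):
            accepted.append(c)
    poles = []
    h = rmap.grid_size
    for ix, iy in accepted:
        pos = np.array(
            [rmap.extent[0] + (ix + 0.5) * h, rmap.extent[2] + (iy + 0.5) * h]
        )
        count = 0.0
        if minus_count_map is not None:
            count = float(minus_count_map.values[ix, iy]) / max(minus_count_map.n_frames, 1)
        poles.append(Pole(int(ix), int(iy), pos, float(V[ix, iy]), count))
    return poles


# ---------------------------------------------------------------------------
# pole statistics and network-state classification


class NetworkState(str, enum.Enum):
    MONOPOLAR = "monopolar"
    BIPOLAR = "bipolar"
    MULTIPOLAR = "multipolar"
    UNFOCUSED = "unfocused"


@dataclass
class PoleStats:
    times: np.ndarray
    counts: np.ndarray
    ends_per_pole: np.ndarray  # per-sample mean minus ends per pole (0 if none)
    mean: float
    sd: float
    mean_ends_per_pole: float
    no_poles: bool = False
    poles_last: list = field(default_factory=list)


def pole_stats(
    traj: Trajectory,
    sample_interval: float = 102.0,
    map_window: int = 51,
    stats_window: float = 780.0,
    grid_size: float = 0.5,
    gaussian_width: float = 0.25,
    filter_fraction: float = 0.05,
    threshold: float = 8.0,
    min_separation: int = 3,
    extent=None,
) -> PoleStats:
    """Pole-count time series (samples every ``sample_interval``) and its
    steady-state mean/SD over the final ``stats_window`` seconds.

    Each sample detects poles on a ratio map accumulated over the
    ``map_window`` frames ending at the sample.  Defaults mirror the
    full-scale protocol: samples every 1.7 min, 51-frame maps, statistics
    over the last 13 min.
    """
    if traj.n_frames < map_window:
        raise ValueError(
            f"trajectory has {traj.n_frames} frames; needs >= {map_window}"
        )
    if extent is None:
        if traj.config is None:
            raise ValueError("no config on trajectory; pass extent explicitly")
        extent = map_extent(traj.config.geometry)
    times = traj.times
    t_end = times[-1]
    sample_times = []
    t = times[map_window - 1]
    k = 1
    while t <= t_end + 1e-9:
        sample_times.append(t)
        t = times[map_window - 1] + k * sample_interval
        k += 1
    counts, epp, stimes = [], [], []
    poles_last: list = []
    for ts in sample_times:
        i_end = int(np.searchsorted(times, ts + 1e-9))
        i_end = min(i_end, traj.n_frames)
        window = range(i_end - map_window, i_end)
        minus_pts = [traj.frames[i].minus_ends[:, :2] for i in window]
        plus_pts = [traj.frames[i].plus_ends[:, :2] for i in window]
        mmap = build_density_map(minus_pts, extent, grid_size, gaussian_width)
        pmap = build_density_map(plus_pts, extent, grid_size, gaussian_width)
        cmap = build_count_map(minus_pts, extent, grid_size)
        rmap = ratio_map(mmap, pmap, filter_fraction)
        poles = detect_poles(rmap, cmap, threshold, min_separation)
        stimes.append(times[i_end - 1])
        counts.append(len(poles))
        epp.append(float(np.mean([p.minus_count for p in poles])) if poles else 0.0)
        poles_last = poles
    stimes = np.asarray(stimes)
    counts = np.asarray(counts, dtype=float)
    epp = np.asarray(epp)
    sel = stimes >= t_end - stats_window
    n_poles_seen = counts[sel] > 0
    return PoleStats(
        times=stimes,
        counts=counts,
        ends_per_pole=epp,
        mean=float(counts[sel].mean()),
        sd=float(counts[sel].std(ddof=0)),
        mean_ends_per_pole=float(epp[sel][n_poles_seen].mean()) if n_poles_seen.any() else 0.0,
        no_poles=not n_poles_seen.any(),
        poles_last=poles_last,
    )


def classify_state(
    stats: PoleStats,
    ends_per_pole_floor: float = 5.0,
    mono_sd: float = 0.5,
    bi_sd: float = 0.75,
) -> NetworkState:
    """Network-state call from steady-state pole statistics.

    monopolar: mean in [0.5, 1.5) and SD < 0.5; bipolar: mean in [1.5, 2.5)
    and SD < 0.75; unfocused: mean minus-ends per pole below the floor (or no
    poles at all); everything else multipolar.
    """
    if 0.5 <= stats.mean < 1.5 and stats.sd < mono_sd:
        state = NetworkState.MONOPOLAR
    elif 1.5 <= stats.mean < 2.5 and stats.sd < bi_sd:
        state = NetworkState.BIPOLAR
    else:
        state = NetworkState.MULTIPOLAR
    if stats.no_poles or stats.mean_ends_per_pole < ends_per_pole_floor:
        return NetworkState.UNFOCUSED
    return state


# ---------------------------------------------------------------------------
# crosslink topology


@dataclass(frozen=True)
class LinkGeometry:
    """Geometry of one doubly-bound crosslink, enough to classify it."""

    absc_a: float
    length_a: float
    tangent_a: np.ndarray
    absc_b: float
    length_b: float
    tangent_b: np.ndarray


class LinkClass(str, enum.Enum):
    H_PARALLEL = "H_parallel"
    H_ANTIPARALLEL = "H_antiparallel"
    X = "X"
    T = "T"
    V = "V"


@dataclass
class LinkTopologyCounts:
    counts: dict
    end_zone: float = 0.03

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict:
        tot = self.total
        return {k: (v / tot if tot else 0.0) for k, v in self.counts.items()}


def classify_links(
    links,
    end_zone: float = 0.03,
    alignment_threshold: float = 0.5,
) -> LinkTopologyCounts:
    """H/X/T/V census of doubly-bound links.

    An attachment is "at an end" if it lies within ``end_zone`` (inclusive) of
    either filament end.  V: both at ends; T: exactly one; otherwise H when
    |cos(theta)| >= ``alignment_threshold`` between the local tangents (split
    into parallel/antiparallel by sign) and X when the filaments cross at a
    steeper angle.  The five classes partition the input.
    """
    counts = {c.value: 0 for c in LinkClass}
    for lk in links:
        at_end_a = lk.absc_a <= end_zone or lk.absc_a >= lk.length_a - end_zone
        at_end_b = lk.absc_b <= end_zone or lk.absc_b >= lk.length_b - end_zone
        if at_end_a and at_end_b:
            counts[LinkClass.V.value] += 1
        elif at_end_a or at_end_b:
            counts[LinkClass.T.value] += 1
        else:
            c = float(np.dot(lk.tangent_a, lk.tangent_b))
            if abs(c) >= alignment_threshold:
                key = LinkClass.H_PARALLEL if c > 0 else LinkClass.H_ANTIPARALLEL
                counts[key.value] += 1
            else:
                counts[LinkClass.X.value] += 1
    return LinkTopologyCounts(counts=counts, end_zone=end_zone)


def frame_link_geometries(traj: Trajectory, fi: int, s: int) -> list[LinkGeometry]:
    """Extract :class:`LinkGeometry` for every doubly-bound complex of
    species ``s`` in frame ``fi``."""
    frame = traj.frames[fi]
    att = frame.attachments[s]
    idx_of = traj.fiber_index(fi)
    out = []
    for r in frame.links(s):
        ja = idx_of.get(int(att.fiber_id[r, 0]))
        jb = idx_of.get(int(att.fiber_id[r, 1]))
        if ja is None or jb is None:
            continue
        out.append(
            LinkGeometry(
                absc_a=float(att.abscissa[r, 0]),
                length_a=float(frame.length[ja]),
                tangent_a=_tangent_on_frame_fiber(frame, ja, att.abscissa[r, 0]),
                absc_b=float(att.abscissa[r, 1]),
                length_b=float(frame.length[jb]),
                tangent_b=_tangent_on_frame_fiber(frame, jb, att.abscissa[r, 1]),
            )
        )
    return out


def classify_frame_links(
    traj: Trajectory, fi: int, s: int, end_zone: float = 0.03, alignment_threshold: float = 0.5
) -> LinkTopologyCounts:
    return classify_links(frame_link_geometries(traj, fi, s), end_zone, alignment_threshold)


# ---------------------------------------------------------------------------
# speckles, kymographs, flux


def make_speckles(frame, mean_spacing: float, rng: np.random.Generator):
    """Random material points along each fiber of a frame (Poisson spacing).

    Returns (fiber_id, abscissa) arrays; speckles are fixed in fiber material
    coordinates, advect with the lattice, and die with their fiber (or when
    the plus end shrinks past them).
    """
    fids, abscs = [], []
    for j in range(frame.n_fibers):
        L = frame.length[j]
        n = rng.poisson(L / mean_spacing)
        if n:
            fids.extend([int(frame.fiber_id[j])] * n)
            abscs.extend(rng.uniform(0.0, L, size=n))
    return np.asarray(fids, dtype=np.int64), np.asarray(abscs)


def track_speckles(traj: Trajectory, fiber_id, abscissa, frame_range=None):
    """Follow speckles over frames; returns a list of tracks
    ``{"times": (k,), "positions": (k, 3)}`` (ended at fiber death or when
    the abscissa exceeds the shrinking fiber's length)."""
    if frame_range is None:
        frame_range = range(traj.n_frames)
    tracks = [{"times": [], "positions": []} for _ in fiber_id]
    alive = np.ones(len(fiber_id), dtype=bool)
    for fi in frame_range:
        frame = traj.frames[fi]
        idx_of = traj.fiber_index(fi)
        for t in np.nonzero(alive)[0]:
            j = idx_of.get(int(fiber_id[t]))
            if j is None or abscissa[t] > frame.length[j]:
                alive[t] = False
                continue
            tracks[t]["times"].append(frame.time)
            tracks[t]["positions"].append(_point_on_frame_fiber(frame, j, abscissa[t]))
    for tr in tracks:
        tr["times"] = np.asarray(tr["times"])
        tr["positions"] = (
            np.asarray(tr["positions"]) if tr["positions"] else np.zeros((0, 3))
        )
    return [tr for tr in tracks if tr["times"].size]


@dataclass
class Kymograph:
    matrix: np.ndarray  # (T, nbins): vertical time axis, horizontal position
    times: np.ndarray
    positions: np.ndarray  # bin centers along the axis (um)
    axis_origin: np.ndarray
    axis_direction: np.ndarray


def spindle_axis(poles: list, minus_ends: np.ndarray | None = None):
    """Axis through the two detected poles; PCA-of-minus-ends fallback."""
    if len(poles) >= 2:
        p0 = np.asarray(poles[0].position, dtype=float)
        p1 = np.asarray(poles[1].position, dtype=float)
        d = p1 - p0
        origin = 0.5 * (p0 + p1)
        direction = d / np.linalg.norm(d)
        return origin, direction
    if minus_ends is None or minus_ends.shape[0] < 2:
        raise ValueError("axis undefined: fewer than 2 poles and no minus ends")
    warnings.warn("fewer than 2 poles; using principal axis of minus ends")
    pts = minus_ends[:, :2]
    center = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - center, full_matrices=False)
    return center, vt[0]


def kymograph(
    points_per_frame,
    times,
    axis_origin,
    axis_direction,
    bin_size: float = 0.1,
    half_extent: float | None = None,
) -> Kymograph:
    """Stack per-frame 1D projections of points onto the axis.

    The horizontal axis is the signed position along ``axis_direction``
    through ``axis_origin``, binned at ``bin_size`` (0.1 um default).
    """
    axis_origin = np.asarray(axis_origin, dtype=float)
    d = np.asarray(axis_direction, dtype=float)
    d = d / np.linalg.norm(d)
    ndim = d.shape[0]
    projs = []
    for pts in points_per_frame:
        pts = np.atleast_2d(pts)
        if pts.size == 0:
            projs.append(np.zeros(0))
        else:
            projs.append((pts[:, :ndim] - axis_origin) @ d)
    if half_extent is None:
        allp = np.concatenate([p for p in projs if p.size]) if any(p.size for p in projs) else np.zeros(1)
        half_extent = max(float(np.abs(allp).max()), bin_size) if allp.size else bin_size
    nbins = max(1, int(np.ceil(2 * half_extent / bin_size)))
    edges = np.linspace(-half_extent, half_extent, nbins + 1)
    M = np.zeros((len(projs), nbins))
    for i, p in enumerate(projs):
        if p.size:
            M[i], _ = np.histogram(p, bins=edges)
    return Kymograph(
        matrix=M,
        times=np.asarray(times),
        positions=0.5 * (edges[:-1] + edges[1:]),
        axis_origin=axis_origin,
        axis_direction=d,
    )


def flux_speed(
    tracks,
    axis_origin,
    axis_direction,
    min_tracks: int = 10,
    min_points: int = 3,
):
    """Median |axial speed| of linear fits to speckle tracks (nm/s).

    Returns (median speed, per-side median dict) where sides split by the
    sign of the track's mean axial position (the two half-spindles).
    """
    axis_origin = np.asarray(axis_origin, dtype=float)
    d = np.asarray(axis_direction, dtype=float)
    d = d / np.linalg.norm(d)
    ndim = d.shape[0]
    slopes, sides = [], []
    for tr in tracks:
        if tr["times"].size < min_points:
            continue
        s = (tr["positions"][:, :ndim] - axis_origin) @ d
        slope = np.polyfit(tr["times"], s, 1)[0]  # um/s
        slopes.append(slope)
        sides.append(1 if s.mean() >= 0 else -1)
    if len(slopes) < min_tracks:
        raise ValueError(f"only {len(slopes)} usable tracks (< {min_tracks})")
    slopes = np.asarray(slopes) * 1e3  # nm/s
    sides = np.asarray(sides)
    per_side = {
        side: float(np.median(slopes[sides == side]))
        for side in (-1, 1)
        if (sides == side).any()
    }
    return float(np.median(np.abs(slopes))), per_side


# ---------------------------------------------------------------------------
# spindle width


def spindle_width(
    frame,
    poles: list,
    percentile: float = 90.0,
    slab: float = 0.25,
) -> float:
    """Lateral extent containing ``percentile``% of fiber crossings on the
    line perpendicular to the pole-pole axis at its midpoint.

    Fiber segments crossing the mid-plane (within a +-``slab`` um band along
    the axis) contribute their lateral (perpendicular, in the projection
    plane) coordinate; the width is the central-percentile range.
    """
    if len(poles) < 2:
        raise ValueError("spindle width requires a bipolar network (2 poles)")
    p0 = np.asarray(poles[0].position, dtype=float)
    p1 = np.asarray(poles[1].position, dtype=float)
    axis = p1 - p0
    axis = axis / np.linalg.norm(axis)
    mid = 0.5 * (p0 + p1)
    perp = np.array([-axis[1], axis[0]])
    lateral = []
    for j in range(frame.n_fibers):
        V = frame.fiber_vertices(j)[:, :2]
        s = (V - mid) @ axis
        for k in range(V.shape[0] - 1):
            if abs(s[k]) <= slab or abs(s[k + 1]) <= slab or s[k] * s[k + 1] < 0:
                # crossing or inside the band: take point nearest the plane
                if s[k + 1] != s[k]:
                    w = np.clip(-s[k] / (s[k + 1] - s[k]), 0.0, 1.0)
                else:
                    w = 0.5
                pt = (1 - w) * V[k] + w * V[k + 1]
                lateral.append(float((pt - mid) @ perp))
    if not lateral:
        return 0.0
    lateral = np.asarray(lateral)
    tail = 0.5 * (100.0 - percentile)
    lo, hi = np.percentile(lateral, [tail, 100.0 - tail])
    return float(hi - lo)


def fit_width_scaling(widths, n_mt) -> float:
    """Least-squares coefficient c of ``w = c * sqrt(N)``."""
    widths = np.asarray(widths, dtype=float)
    n_mt = np.asarray(n_mt, dtype=float)
    root = np.sqrt(n_mt)
    return float((root * widths).sum() / (root * root).sum())
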