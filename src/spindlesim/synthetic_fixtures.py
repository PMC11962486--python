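"""Generators with known ground truth for testing every analysis stage.

These produce the inputs each quantification stage consumes — end-point
clouds with planted poles, link geometries with known H/X/T/V labels,
single-motor kinetic ensembles, drifting speckle fields — plus desk-scale
("mini") versions of the full spindle scenarios.  Every generator is
seed-deterministic and returns its ground truth alongside the data.
"""

from __future__ import annotations

import numpy as np

from .config import MechanicsParams, MotorBlock, SimulationConfig
from .dynamic_filaments import NucleationSource, params_from_targets
from .mechanics import ConfinementGeometry, SimulationConstants
from .motors import MotorUnitSpec, UnitKind, make_archetype
from .quantify import LinkGeometry

__all__ = [
    "planted_pole_cloud",
    "link_geometry_suite",
    "single_motor_ensemble",
    "drifting_speckle_field",
    "mini_scenario",
    "MINI_STATS",
]


def planted_pole_cloud(
    k_poles: int,
    ends_per_pole: int = 50,
    separation: float = 5.0,
    spread: float = 0.25,
    background: int = 0,
    n_frames: int = 51,
    extent: tuple = (-7.5, 7.5, -7.5, 7.5),
    frame_jitter: float = 0.05,
    plus_cloud: int | None = None,
    layout_offset: tuple = (0.25, 0.25),
    seed: int = 0,
) -> dict:
    """Minus-end clusters at known pole positions + a diffuse plus-end cloud.

    Minus ends are fixed material points (Gaussian spread around each pole)
    jittered per frame; plus ends form a broad cloud between the poles,
    emulating their enrichment in the spindle center.  Returns per-frame
    minus/plus point lists and the planted truth.
    """
    rng = np.random.default_rng(seed)
    # the default layout offset keeps pole centers off 0.5-um-grid cell
    # edges, so a pole's ends fall dominantly into a single analysis pixel
    centers = _pole_layout(k_poles, separation) + np.asarray(layout_offset)
    minus_base = []
    for c in centers:
        minus_base.append(c + spread * rng.standard_normal((ends_per_pole, 2)))
    minus_base = np.concatenate(minus_base) if centers.shape[0] else np.zeros((0, 2))
    n_plus = (
        plus_cloud
        if plus_cloud is not None
        else ends_per_pole * max(k_poles, 1)
    )
    if k_poles >= 2:
        # plus ends enriched between the poles, away from the minus clusters
        plus_base = (separation / 4.0) * rng.standard_normal((n_plus, 2)) + np.asarray(
            layout_offset
        )
    elif k_poles == 1:
        # aster: plus ends radiate outward, on a ring around the pole
        radius = max(separation / 2.0, 1.5)
        ang = rng.uniform(0, 2 * np.pi, size=n_plus)
        r = radius + 0.3 * rng.standard_normal(n_plus)
        plus_base = np.column_stack(
            [r * np.cos(ang), r * np.sin(ang)]
        ) + np.asarray(layout_offset)
    else:
        lo0 = np.array([extent[0], extent[2]])
        hi0 = np.array([extent[1], extent[3]])
        plus_base = rng.uniform(lo0, hi0, size=(n_plus, 2))
    lo = np.array([extent[0], extent[2]])
    hi = np.array([extent[1], extent[3]])
    minus_frames, plus_frames = [], []
    for _ in range(n_frames):
        m = minus_base + frame_jitter * rng.standard_normal(minus_base.shape)
        p = plus_base + frame_jitter * rng.standard_normal(plus_base.shape)
        if background:
            m = np.concatenate([m, rng.uniform(lo, hi, size=(background, 2))])
            p = np.concatenate([p, rng.uniform(lo, hi, size=(background, 2))])
        minus_frames.append(np.clip(m, lo, hi - 1e-6))
        plus_frames.append(np.clip(p, lo, hi - 1e-6))
    return {
        "minus_frames": minus_frames,
        "plus_frames": plus_frames,
        "extent": extent,
        "truth": {
            "pole_positions": centers,
            "ends_per_pole": ends_per_pole,
            "k_poles": k_poles,
        },
    }


def _pole_layout(k: int, separation: float) -> np.ndarray:
    if k == 0:
        return np.zeros((0, 2))
    if k == 1:
        return np.zeros((1, 2))
    if k == 2:
        return np.array([[-0.5 * separation, 0.0], [0.5 * separation, 0.0]])
    ang = 2 * np.pi * np.arange(k) / k
    r = separation / (2 * np.sin(np.pi / k))  # pairwise distance = separation
    return np.column_stack([r * np.cos(ang), r * np.sin(ang)])


def link_geometry_suite(end_zone: float = 0.03) -> list:
    """Enumerated link geometries with truth labels, >= 3 per class.

    Includes the inclusive boundary case: an attachment at exactly
    ``end_zone`` from a filament end counts as an end attachment.
    """
    ex = np.array([1.0, 0.0, 0.0])
    ey = np.array([0.0, 1.0, 0.0])
    mid45 = np.array([np.sqrt(0.5), np.sqrt(0.5), 0.0])
    near60 = np.array([0.45, np.sqrt(1 - 0.45**2), 0.0])  # |cos|=0.45 -> X
    near30 = np.array([0.6, 0.8, 0.0])  # |cos|=0.6 -> H
    L = 2.5

    def lg(aa, ab, ta, tb, la=L, lb=L):
        return LinkGeometry(aa, la, np.asarray(ta, dtype=float), ab, lb, np.asarray(tb, dtype=float))

    suite = [
        # H parallel: side-side, aligned tangents
        (lg(1.0, 1.2, ex, ex), "H_parallel"),
        (lg(0.5, 2.0, ex, near30), "H_parallel"),
        (lg(1.3, 1.3, mid45, mid45), "H_parallel"),
        # H antiparallel
        (lg(1.0, 1.2, ex, -ex), "H_antiparallel"),
        (lg(0.7, 1.8, ex, -near30), "H_antiparallel"),
        (lg(2.0, 0.5, -mid45, mid45), "H_antiparallel"),
        # X: crossing at steep angle, side-side
        (lg(1.0, 1.0, ex, ey), "X"),
        (lg(0.8, 1.9, ex, near60), "X"),
        (lg(1.5, 1.5, ex, -near60), "X"),
        # T: exactly one end attachment
        (lg(0.01, 1.0, ex, ey), "T"),
        (lg(1.0, L - 0.01, ex, ex), "T"),
        (lg(end_zone, 1.0, ex, -ex), "T"),  # inclusive boundary: end
        (lg(end_zone + 1e-6, 1.0, ex, -ex), "H_antiparallel"),  # just past it
        # V: both at ends (minus-minus, minus-plus)
        (lg(0.0, 0.0, ex, -ex), "V"),
        (lg(0.02, L - 0.02, ey, ex), "V"),
        (lg(end_zone, end_zone, ex, ey), "V"),
    ]
    return suite


def single_motor_ensemble(
    unit: MotorUnitSpec,
    n: int = 100_000,
    seed: int = 0,
) -> dict:
    """Run-length / dwell-time samples of one unloaded motor unit on a long
    filament (event-driven Monte Carlo: exponential dwell at the constant
    unloaded unbinding rate, run = |v| * dwell)."""
    if unit.kind != UnitKind.MOTOR:
        raise ValueError("single_motor_ensemble expects a MOTOR unit")
    rng = np.random.default_rng(seed)
    if unit.k_off <= 0:
        raise ValueError("k_off must be > 0 for a finite run length")
    dwell = rng.exponential(1.0 / unit.k_off, size=n)
    runs = np.abs(unit.v_m) * dwell  # nm
    return {
        "dwell_times": dwell,
        "run_lengths_nm": runs,
        "mean_run_length_nm": float(runs.mean()),
        "sem_run_length_nm": float(runs.std(ddof=1) / np.sqrt(n)),
        "truth": {"expected_run_length_nm": abs(unit.v_m) / unit.k_off},
    }


def drifting_speckle_field(
    speed: float,
    duration: float = 480.0,
    n_tracks: int = 50,
    noise: float = 0.02,
    seed: int = 0,
    frame_interval: float = 1.98,
    bidirectional: bool = False,
    span: float = 10.0,
) -> dict:
    """Speckle tracks drifting at a known axial speed (nm/s) along +x.

    With ``bidirectional=True`` tracks on either side of the origin drift
    outward at +-speed (a planted poleward-flux field).  Returns tracks in
    the :func:`spindlesim.quantify.track_speckles` format plus the truth.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration + 1e-9, frame_interval)
    v_um = speed * 1e-3
    tracks = []
    for i in range(n_tracks):
        x0 = rng.uniform(-0.5 * span, 0.5 * span)
        y0 = rng.uniform(-1.0, 1.0)
        side = 1.0 if (x0 >= 0 or not bidirectional) else -1.0
        x = x0 + side * v_um * times + noise * rng.standard_normal(times.size)
        y = y0 + noise * rng.standard_normal(times.size)
        z = np.zeros_like(x)
        tracks.append({"times": times.copy(), "positions": np.column_stack([x, y, z])})
    return {
        "tracks": tracks,
        "axis_origin": np.zeros(3),
        "axis_direction": np.array([1.0, 0.0, 0.0]),
        "truth": {"speed_nm_s": abs(speed), "bidirectional": bidirectional},
    }


# ---------------------------------------------------------------------------
# desk-scale spindle scenarios

#: pole-statistics settings matched to the 12 min mini runs: same 1.7-min
#: sampling and 51-frame maps as at full scale, steady-state stats over the
#: final 5.1 min.  Density thresholds scale with the steady-state
#: microtubule count (mini nu*tau = 90 vs 360 at full scale, a factor 4):
#: ratio-map pole threshold 8 -> 2.
MINI_STATS = dict(
    sample_interval=102.0, map_window=51, stats_window=306.0, threshold=2.0
)

#: network-state classification floor for the minis, scaled by the same
#: factor 4 from the full-scale default of 5 minus ends per pole.
MINI_CLASSIFY = dict(ends_per_pole_floor=1.25)

_MINI_MINUS = {
    "fig1_mini": "hset",
    "fig2_mini": "symmetric_minus",
    "fig3_mini": "dynein_end_numa",
    "fig4b_mini": "dynein_diffusive_numa",
}


def mini_scenario(name: str, minus_count: int | None = None, minus_speed: float = 30.0) -> SimulationConfig:
    """Desk-scale analogs of the figure scenarios.

    Box area, nucleation rate and motor counts are scaled down together
    (15 x 15 x 0.2 um^3, nu = 1/s, N = 800 per species), preserving the
    motors-per-microtubule ratio of the full runs; microtubule dynamics and
    motor archetypes are unchanged.  Duration 12 min.
    """
    if name not in _MINI_MINUS:
        raise ValueError(f"unknown mini scenario {name!r}")
    cfg = SimulationConfig()
    # the implicit mechanics solver is stable and kinetically faithful at
    # 20 ms for these conditions; the desk-scale runs use it, with a
    # slightly looser solve, for speed (network observables were verified
    # to be insensitive to much stricter settings)
    cfg.constants = SimulationConstants(dt=0.02)
    cfg.mechanics = MechanicsParams(cg_rtol=5e-3, cg_maxiter=12)
    cfg.dynamics = params_from_targets(30.0, 2.5, 90.0)
    cfg.geometry = ConfinementGeometry(kind="box", dims=(15.0, 15.0, 0.2))
    cfg.nucleation = NucleationSource(rate=1.0, volume=(1.0, 1.0, 0.2))
    n_minus = 800 if minus_count is None else minus_count
    cfg.motors = [
        MotorBlock(make_archetype("kinesin5"), 800),
        MotorBlock(make_archetype(_MINI_MINUS[name], minus_speed=minus_speed), n_minus),
    ]
    cfg.duration = 720.0
    cfg.name = name
    return cfg
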