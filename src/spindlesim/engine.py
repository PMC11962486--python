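"""Run orchestration: simulation loop, figure presets, sweeps, trajectory I/O.

A run is driven by a :class:`~spindlesim.config.SimulationConfig`; the result
is a :class:`Trajectory` (a list of frames sampled every ``frame_interval``)
that the :mod:`spindlesim.quantify` pipeline consumes.  Frames are pure
observation: changing ``frame_interval`` does not alter the dynamics.
"""

from __future__ import annotations

import copy
import hashlib
import itertools
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from ._world import FrameAttachments, TrajectoryFrame, World
from .config import MotorBlock, SimulationConfig
from .dynamic_filaments import DynamicInstabilityParams, NucleationSource, params_from_targets
from .mechanics import ConfinementGeometry, TimestepInstabilityError
from .motors import make_archetype

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "RunManifest",
    "run_simulation",
    "preset",
    "PRESETS",
    "sweep",
    "write_trajectory",
    "read_trajectory",
    "export_ends_csv",
    "export_links_csv",
    "read_cytosim_report",
]

_FORMAT_VERSION = 1


@dataclass
class Trajectory:
    frames: list
    config: SimulationConfig | None = None
    species_names: list = field(default_factory=list)
    diagnostic: str | None = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i) -> TrajectoryFrame:
        return self.frames[i]

    # -- derived per-frame quantities --------------------------------------

    def fiber_index(self, fi: int) -> dict:
        """Map persistent fiber id -> index within frame ``fi``."""
        frame = self.frames[fi]
        return {int(f): i for i, f in enumerate(frame.fiber_id)}

    def attachment_positions(self, fi: int, s: int):
        """World positions of bound units of species ``s`` in frame ``fi``.

        Returns (positions (k,3), complex_index (k,), unit (k,)).
        """
        frame = self.frames[fi]
        att = frame.attachments[s]
        idx_of = self.fiber_index(fi)
        pos, ci, ui = [], [], []
        for u in (0, 1):
            rows = np.nonzero(att.fiber_id[:, u] >= 0)[0]
            for r in rows:
                j = idx_of.get(int(att.fiber_id[r, u]))
                if j is None:
                    continue
                pos.append(_point_on_frame_fiber(frame, j, att.abscissa[r, u]))
                ci.append(r)
                ui.append(u)
        if not pos:
            return np.zeros((0, 3)), np.zeros(0, dtype=int), np.zeros(0, dtype=int)
        return np.array(pos), np.array(ci), np.array(ui)


def _point_on_frame_fiber(frame: TrajectoryFrame, j: int, absc: float) -> np.ndarray:
    V = frame.fiber_vertices(j)
    n = V.shape[0]
    s = frame.length[j] / (n - 1) if n > 1 else 1.0
    k = min(max(int(absc / s), 0), n - 2)
    w = np.clip(absc / s - k, 0.0, 1.0)
    return (1 - w) * V[k] + w * V[k + 1]


def _tangent_on_frame_fiber(frame: TrajectoryFrame, j: int, absc: float) -> np.ndarray:
    V = frame.fiber_vertices(j)
    n = V.shape[0]
    s = frame.length[j] / (n - 1) if n > 1 else 1.0
    k = min(max(int(absc / s), 0), n - 2)
    t = V[k + 1] - V[k]
    norm = np.linalg.norm(t)
    return t / norm if norm > 0 else np.array([1.0, 0.0, 0.0])


# ---------------------------------------------------------------------------
# simulation loop


def run_simulation(config: SimulationConfig, seed: int | None = None) -> Trajectory:
    """Run one simulation; deterministic for a given (config, seed).

    On a mechanics instability the partial trajectory is returned with its
    ``diagnostic`` field set.
    """
    world = World(config, seed=seed)
    steps_per_frame = max(1, int(round(config.frame_interval / config.constants.dt)))
    frames: list[TrajectoryFrame] = []
    names = [b.species.name for b in config.motors]
    n_frames = config.n_frames
    diagnostic = None
    step = 0
    try:
        for fi in range(n_frames):
            for _ in range(steps_per_frame):
                world.step()
                step += 1
                if step % 1000 == 0:
                    logger.info(
                        "t=%.1fs fibers=%d", world.time, world.nf
                    )
            frames.append(world.record_frame())
    except TimestepInstabilityError as err:
        diagnostic = str(err)
        logger.warning("aborted: %s", diagnostic)
    return Trajectory(frames=frames, config=config, species_names=names, diagnostic=diagnostic)


# ---------------------------------------------------------------------------
# presets (figure-legend parameterizations)

# microtubule dynamics: (v_g nm/s, target mean length um, target lifetime s)
_SLOW_DYNAMICS = params_from_targets(30.0, 2.5, 90.0)  # v_s=375, k_cat=0.012
_FAST_DYNAMICS = params_from_targets(120.0, 5.0, 96.0)  # v_s~92, k_cat=0.024


def _base(dynamics, nu, box, motors, name, nucleation=None) -> SimulationConfig:
    cfg = SimulationConfig()
    cfg.dynamics = dynamics
    cfg.geometry = ConfinementGeometry(kind="box", dims=box)
    cfg.nucleation = nucleation or NucleationSource(rate=nu, volume=(1.0, 1.0, 0.2))
    cfg.motors = motors
    cfg.name = name
    return cfg


def preset(name: str, nu: float | None = None) -> SimulationConfig:
    """Printed figure parameterizations (and their ``*_mini`` desk versions)."""
    if name.endswith("_mini"):
        from .synthetic_fixtures import mini_scenario

        return mini_scenario(name)
    if name == "fig1d":
        return _base(
            _SLOW_DYNAMICS,
            4.0,
            (30.0, 30.0, 0.2),
            [
                MotorBlock(make_archetype("kinesin5"), 3200),
                MotorBlock(make_archetype("hset"), 3200),
            ],
            name,
        )
    if name == "fig2b":
        return _base(
            _SLOW_DYNAMICS,
            4.0,
            (30.0, 30.0, 0.2),
            [
                MotorBlock(make_archetype("kinesin5"), 3200),
                MotorBlock(make_archetype("symmetric_minus", minus_speed=30.0), 3200),
            ],
            name,
        )
    if name == "fig3b":
        return _base(
            _SLOW_DYNAMICS,
            4.0,
            (30.0, 30.0, 0.2),
            [
                MotorBlock(make_archetype("kinesin5"), 3200),
                MotorBlock(make_archetype("dynein_end_numa"), 3200),
            ],
            name,
        )
    if name == "fig4b":
        return _base(
            _SLOW_DYNAMICS,
            4.0,
            (30.0, 30.0, 0.2),
            [
                MotorBlock(make_archetype("kinesin5"), 3200),
                MotorBlock(make_archetype("dynein_diffusive_numa"), 3200),
            ],
            name,
        )
    if name == "fig5b":
        return _base(
            _FAST_DYNAMICS,
            179.0 / 96.0,
            (50.0, 50.0, 0.2),
            [
                MotorBlock(make_archetype("kinesin5"), 3200),
                MotorBlock(make_archetype("dynein_diffusive_numa"), 3200),
            ],
            name,
        )
    if name == "fig6c_n":
        counts = {2.0: 3200, 4.0: 4800, 8.0: 9600, 16.0: 19000}
        if nu is None or float(nu) not in counts:
            raise ValueError("fig6c_n requires nu in {2, 4, 8, 16}")
        nu = float(nu)
        cfg = SimulationConfig()
        cfg.dynamics = _FAST_DYNAMICS
        cfg.geometry = ConfinementGeometry(kind="cylinder", dims=(50.0, 5.0))
        cfg.nucleation = NucleationSource(rate=nu, volume=(1.0, 1.0), kind="cylinder")
        n = counts[nu]
        cfg.motors = [
            MotorBlock(make_archetype("kinesin5"), n),
            MotorBlock(make_archetype("dynein_diffusive_numa"), n),
        ]
        cfg.name = f"fig6c_n{int(nu)}"
        return cfg
    if name == "sfig6d_channel":
        cfg = SimulationConfig()
        cfg.dynamics = _SLOW_DYNAMICS
        cfg.geometry = ConfinementGeometry(kind="cylinder", dims=(20.0, 2.0))
        cfg.nucleation = NucleationSource(rate=4.0, volume=(1.0, 1.0), kind="cylinder")
        cfg.motors = [
            MotorBlock(make_archetype("kinesin5"), 3200),
            MotorBlock(make_archetype("dynein_end_numa_parallel_only"), 3200),
        ]
        cfg.name = name
        return cfg
    raise ValueError(f"unknown preset {name!r}")


PRESETS = ("fig1d", "fig2b", "fig3b", "fig4b", "fig5b", "fig6c_n", "sfig6d_channel")


# ---------------------------------------------------------------------------
# sweeps


@dataclass
class RunManifest:
    config_hash: str
    seeds: list
    grid_points: list
    paths: list
    version: str = "spindlesim-0.1.0"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config_hash": self.config_hash,
                    "seeds": self.seeds,
                    "grid_points": self.grid_points,
                    "paths": self.paths,
                    "version": self.version,
                },
                fh,
                indent=1,
            )


def _apply_override(d: dict, dotted: str, value) -> None:
    keys = dotted.split(".")
    node = d
    for k in keys[:-1]:
        node = node[int(k)] if isinstance(node, list) else node[k]
    last = keys[-1]
    if isinstance(node, list):
        node[int(last)] = value
    else:
        node[last] = value


def sweep(
    base_config: SimulationConfig,
    overrides_grid: dict,
    replicates: int,
    base_seed: int,
    out_dir=None,
    run=True,
) -> RunManifest:
    """Run (grid point x replicate) simulations with derived seeds.

    ``overrides_grid`` maps dotted config paths (e.g. ``"motors.1.count"``) to
    lists of values; the grid is their Cartesian product.  An empty grid
    yields an empty manifest.
    """
    base_dict = base_config.to_dict()
    cfg_hash = hashlib.sha256(
        yaml.safe_dump(base_dict, sort_keys=True).encode()
    ).hexdigest()[:16]
    keys = sorted(overrides_grid)
    values = [overrides_grid[k] for k in keys]
    points = list(itertools.product(*values)) if keys else []
    if not keys:
        points = []
    seeds, grid_points, paths = [], [], []
    ss = np.random.SeedSequence(base_seed)
    children = ss.spawn(max(len(points) * replicates, 1))
    i = 0
    for point in points:
        for rep in range(replicates):
            d = copy.deepcopy(base_dict)
            for k, v in zip(keys, point):
                _apply_override(d, k, v)
            seed = int(children[i].generate_state(1)[0] % (2**31))
            cfg = SimulationConfig.from_dict(d)
            cfg.seed = seed
            path = None
            if run:
                traj = run_simulation(cfg, seed=seed)
                if out_dir is not None:
                    os.makedirs(out_dir, exist_ok=True)
                    path = os.path.join(out_dir, f"{base_config.name}_{i:04d}.h5")
                    write_trajectory(traj, path)
            seeds.append(seed)
            grid_points.append(dict(zip(keys, point)))
            paths.append(path)
            i += 1
    manifest = RunManifest(
        config_hash=cfg_hash, seeds=seeds, grid_points=grid_points, paths=paths
    )
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        manifest.to_json(os.path.join(out_dir, "manifest.json"))
    return manifest


# ---------------------------------------------------------------------------
# trajectory I/O


def write_trajectory(traj: Trajectory, path) -> None:
    """Lossless chunked-HDF5 round trip of a trajectory."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["format_version"] = _FORMAT_VERSION
        h5.attrs["species"] = json.dumps(traj.species_names)
        if traj.config is not None:
            h5.attrs["config"] = yaml.safe_dump(traj.config.to_dict())
        if traj.diagnostic:
            h5.attrs["diagnostic"] = traj.diagnostic
        for i, frame in enumerate(traj.frames):
            g = h5.create_group(f"frames/{i:06d}")
            g.attrs["time"] = frame.time
            g.create_dataset("fiber_id", data=frame.fiber_id)
            g.create_dataset("length", data=frame.length)
            g.create_dataset("state", data=frame.state)
            g.create_dataset("vertices", data=frame.vertices)
            g.create_dataset("offsets", data=frame.offsets)
            for s, att in enumerate(frame.attachments):
                g.create_dataset(f"att_fiber_{s}", data=att.fiber_id)
                g.create_dataset(f"att_absc_{s}", data=att.abscissa)


def read_trajectory(path) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as h5:
        version = int(h5.attrs.get("format_version", -1))
        if version != _FORMAT_VERSION:
            raise ValueError(
                f"trajectory format version {version} != {_FORMAT_VERSION}"
            )
        names = json.loads(h5.attrs.get("species", "[]"))
        config = None
        if "config" in h5.attrs:
            config = SimulationConfig.from_dict(yaml.safe_load(h5.attrs["config"]))
        frames = []
        if "frames" in h5:
            for key in sorted(h5["frames"]):
                g = h5["frames"][key]
                atts = []
                s = 0
                while f"att_fiber_{s}" in g:
                    atts.append(
                        FrameAttachments(
                            fiber_id=g[f"att_fiber_{s}"][...],
                            abscissa=g[f"att_absc_{s}"][...],
                        )
                    )
                    s += 1
                frames.append(
                    TrajectoryFrame(
                        time=float(g.attrs["time"]),
                        fiber_id=g["fiber_id"][...],
                        length=g["length"][...],
                        state=g["state"][...],
                        vertices=g["vertices"][...],
                        offsets=g["offsets"][...],
                        attachments=atts,
                    )
                )
        return Trajectory(
            frames=frames,
            config=config,
            species_names=names,
            diagnostic=h5.attrs.get("diagnostic"),
        )


def export_ends_csv(traj: Trajectory, path) -> int:
    """Per-frame end coordinates as CSV; returns the row count."""
    import csv

    n = 0
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "time", "fiber_id", "end", "x", "y", "z"])
        for i, frame in enumerate(traj.frames):
            minus, plus = frame.minus_ends, frame.plus_ends
            for j in range(frame.n_fibers):
                w.writerow([i, frame.time, int(frame.fiber_id[j]), "minus", *minus[j]])
                w.writerow([i, frame.time, int(frame.fiber_id[j]), "plus", *plus[j]])
                n += 2
    return n


def export_links_csv(traj: Trajectory, path) -> int:
    """Per-frame doubly-bound link records as CSV; returns the row count."""
    import csv

    n = 0
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["frame", "time", "species", "complex", "fiber_a", "fiber_b", "absc_a", "absc_b"]
        )
        for i, frame in enumerate(traj.frames):
            for s, att in enumerate(frame.attachments):
                name = traj.species_names[s] if s < len(traj.species_names) else str(s)
                for r in frame.links(s):
                    w.writerow(
                        [
                            i,
                            frame.time,
                            name,
                            int(r),
                            int(att.fiber_id[r, 0]),
                            int(att.fiber_id[r, 1]),
                            att.abscissa[r, 0],
                            att.abscissa[r, 1],
                        ]
                    )
                    n += 1
    return n


# ---------------------------------------------------------------------------
# Cytosim report importer (best effort, text reports only)


def read_cytosim_report(fiber_points_path, couples_path=None) -> Trajectory:
    """Import Cytosim ``report fiber:points`` text output (and optionally a
    couple report with columns ``id fiber1 abscissa1 fiber2 abscissa2``).

    Best-effort: only positions, fiber identities and link records are
    recovered; plus-end states default to GROW.
    """
    frames_pts = _parse_report_frames(fiber_points_path)
    frames_links = _parse_report_frames(couples_path) if couples_path else None
    frames = []
    for fi, (time, rows) in enumerate(frames_pts):
        by_fiber: dict[int, list] = {}
        for row in rows:
            by_fiber.setdefault(int(row[0]), []).append(row[1:4])
        fiber_ids = sorted(by_fiber)
        verts = [np.asarray(by_fiber[f], dtype=float) for f in fiber_ids]
        off = np.zeros(len(verts) + 1, dtype=np.int64)
        np.cumsum([v.shape[0] for v in verts], out=off[1:])
        lengths = np.array(
            [np.linalg.norm(np.diff(v, axis=0), axis=1).sum() for v in verts]
        )
        atts = []
        if frames_links is not None and fi < len(frames_links):
            _, lrows = frames_links[fi]
            k = len(lrows)
            fib = np.full((k, 2), -1, dtype=np.int64)
            absc = np.zeros((k, 2))
            for i, row in enumerate(lrows):
                fib[i] = (int(row[1]), int(row[3]))
                absc[i] = (row[2], row[4])
            atts.append(FrameAttachments(fiber_id=fib, abscissa=absc))
        frames.append(
            TrajectoryFrame(
                time=time,
                fiber_id=np.asarray(fiber_ids, dtype=np.int64),
                length=lengths,
                state=np.zeros(len(fiber_ids), dtype=np.int8),
                vertices=np.concatenate(verts) if verts else np.zeros((0, 3)),
                offsets=off,
                attachments=atts,
            )
        )
    return Trajectory(frames=frames, species_names=["imported"])


def _parse_report_frames(path):
    frames = []
    time = 0.0
    rows: list = []
    started = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("%"):
                tokens = line[1:].split()
                if tokens and tokens[0] == "frame":
                    if started:
                        frames.append((time, rows))
                        rows = []
                    started = True
                elif tokens and tokens[0] == "time":
                    time = float(tokens[1])
                continue
            fields = line.split()
            vals = []
            for tok in fields:
                try:
                    vals.append(float(tok))
                except ValueError:
                    continue
            if len(vals) >= 4:
                rows.append(vals[-5:] if len(vals) >= 5 else [vals[0], *vals[1:4]])
    if started or rows:
        frames.append((time, rows))
    return frames
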