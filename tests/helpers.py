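"""Shared test utilities: synthetic trajectories and hand-built worlds."""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from spindlesim._world import FrameAttachments, TrajectoryFrame, World
from spindlesim.config import MechanicsParams, SimulationConfig
from spindlesim.dynamic_filaments import DynamicInstabilityParams, NucleationSource
from spindlesim.engine import Trajectory
from spindlesim.mechanics import ConfinementGeometry


def world_with_fibers(
    starts,
    directions,
    length: float,
    seed: int = 0,
    kT: float = 4.2,
    dt: float = 0.01,
    rigidity: float = 20.0,
    segmentation: float = 0.5,
    box=(60.0, 60.0, 60.0),
    motors=(),
) -> World:
    """A world with frozen plus-end dynamics and hand-placed straight fibers."""
    cfg = SimulationConfig()
    cfg.dynamics = DynamicInstabilityParams(0.0, 0.0, 0.0, 0.0)
    cfg.nucleation = NucleationSource(rate=0.0)
    cfg.geometry = ConfinementGeometry("box", tuple(box), 100.0)
    cfg.constants = replace(cfg.constants, kT=kT, dt=dt)
    cfg.mechanics = MechanicsParams(rigidity=rigidity, segmentation=segmentation)
    cfg.motors = list(motors)
    w = World(cfg, seed=seed)
    starts = np.atleast_2d(np.asarray(starts, dtype=float))
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    nf = starts.shape[0]
    n = max(2, int(np.ceil(length / segmentation - 1e-9)) + 1)
    chunks = []
    for i in range(nf):
        d = directions[i] / np.linalg.norm(directions[i])
        s = np.linspace(0.0, length, n)[:, None]
        chunks.append(starts[i] + s * d)
    w.X = np.concatenate(chunks, axis=0)
    w.off = np.arange(0, nf * n + 1, n, dtype=np.int64)
    w.flen = np.full(nf, float(length))
    w.fstate = np.zeros(nf, dtype=np.int8)
    w.fid = np.arange(nf, dtype=np.int64)
    w.next_fid = nf
    w.seglen = w.flen / (n - 1)
    return w


def frames_from_end_points(minus_per_frame, plus_per_frame, frame_interval=1.98):
    """Build a Trajectory whose fibers are 2-vertex stubs connecting planted
    minus/plus end positions (2D points get z = 0)."""
    frames = []
    for i, (m, p) in enumerate(zip(minus_per_frame, plus_per_frame)):
        m = np.atleast_2d(np.asarray(m, dtype=float))
        p = np.atleast_2d(np.asarray(p, dtype=float))
        k = min(m.shape[0], p.shape[0])
        n = max(m.shape[0], p.shape[0])
        # pad the shorter list with far-away parking points that fall
        # outside any analysis grid
        m3 = np.full((n, 3), 1e6)
        p3 = np.full((n, 3), 1e6)
        m3[:, 2] = 0.0
        p3[:, 2] = 0.0
        m3[: m.shape[0], : m.shape[1]] = m
        p3[: p.shape[0], : p.shape[1]] = p
        verts = np.empty((2 * n, 3))
        verts[0::2] = m3
        verts[1::2] = p3
        offsets = np.arange(0, 2 * n + 1, 2, dtype=np.int64)
        frames.append(
            TrajectoryFrame(
                time=(i + 1) * frame_interval,
                fiber_id=np.arange(n, dtype=np.int64),
                length=np.linalg.norm(p3 - m3, axis=1),
                state=np.zeros(n, dtype=np.int8),
                vertices=verts,
                offsets=offsets,
                attachments=[
                    FrameAttachments(
                        fiber_id=np.zeros((0, 2), dtype=np.int64),
                        abscissa=np.zeros((0, 2)),
                    )
                ],
            )
        )
    return Trajectory(frames=frames, species_names=["planted"])
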