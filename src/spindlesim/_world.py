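"""Internal simulation state and the per-step schedule.

Struct-of-arrays state: all fiber vertices live in one (V, 3) array with
per-fiber offsets; each crosslinker species keeps fixed-size arrays for its
N complexes (fiber index / abscissa per unit, -1 = unbound, plus a free
position used while not bound).

Per-step schedule (operator splitting, documented order):
  1. plus-end dynamics (lengths/states), 2. nucleation, 3. topology rebuild
  (remove fully shrunk fibers, resample every fiber to its new length and
  vertex count, append new fibers), 4. release of attachments the plus end
  shrank past, 5. force-dependent unbinding together with motor stepping and
  lattice diffusion of the surviving bound units (one kernel pass per
  species), 6. binding (free complexes first, then second units of singly
  bound ones), 7. force assembly + semi-implicit overdamped step (with
  automatic dt-halving on the stability check) + inextensibility
  reprojection.  Bound diffusive units move in the damped diffusion limit of
  biased lattice hopping (drift D f / kT), which is the stable integration of
  the hopping picture at this dt.

Randomness: three independent generators (dynamics, motors, mechanics)
spawned from the run seed; kernels consume no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .config import SimulationConfig
from .dynamic_filaments import GrowthState, _step_lengths, nucleate
from .mechanics import (
    ConfinementGeometry,
    TimestepInstabilityError,
    build_segment_hash,
    confinement_forces,
)
from .motors import UnitKind

NM = 1e-3
_EXP_CLIP = 30.0  # cap on f/f_unbind in the Bell factor
_ZERO2 = np.zeros((32768, 2))  # shared scratch for species without diffusion
# zero-capacity elastic-element buffers (kernels skip recording into them)
_NO_ELEMENTS = (
    np.zeros((0, 2), dtype=np.int64),
    np.zeros((0, 2)),
    np.zeros((0, 3)),
    np.zeros(0),
    np.zeros(1, dtype=np.int64),
)


@dataclass
class FrameAttachments:
    """Per-species attachment snapshot: fiber ids (-1 = unbound) and abscissae."""

    fiber_id: np.ndarray  # (N, 2) int64, persistent fiber ids
    abscissa: np.ndarray  # (N, 2) float


@dataclass
class TrajectoryFrame:
    time: float
    fiber_id: np.ndarray  # (F,)
    length: np.ndarray  # (F,)
    state: np.ndarray  # (F,) int8, 0 grow / 1 shrink
    vertices: np.ndarray  # (V, 3)
    offsets: np.ndarray  # (F+1,)

    attachments: list  # list[FrameAttachments], one per species

    @property
    def n_fibers(self) -> int:
        return self.fiber_id.shape[0]

    @property
    def minus_ends(self) -> np.ndarray:
        return self.vertices[self.offsets[:-1]] if self.n_fibers else np.zeros((0, 3))

    @property
    def plus_ends(self) -> np.ndarray:
        return self.vertices[self.offsets[1:] - 1] if self.n_fibers else np.zeros((0, 3))

    def fiber_vertices(self, i: int) -> np.ndarray:
        return self.vertices[self.offsets[i] : self.offsets[i + 1]]

    def links(self, s: int) -> np.ndarray:
        """Doubly-bound complex indices of species ``s`` in this frame."""
        att = self.attachments[s]
        return np.nonzero((att.fiber_id >= 0).all(axis=1))[0]


class _SpeciesState:
    def __init__(self, block, geometry: ConfinementGeometry, rng: np.random.Generator):
        self.spec = block.species
        self.n = block.count
        self.fib = np.full((self.n, 2), -1, dtype=np.int64)
        self.absc = np.zeros((self.n, 2))
        self.pos = _uniform_in_geometry(self.n, geometry, rng)
        # time of the last free-position update (free diffusion is applied
        # lazily, only when a binding attempt samples the position)
        self.free_t = np.zeros(self.n)
        units = self.spec.units
        self.kind = np.array([int(u.kind) for u in units])
        self.vm = np.array([u.v_m * NM for u in units])  # um/s signed
        self.koff = np.array([u.k_off for u in units])
        self.fstall = np.array([u.f_stall for u in units])
        self.funbind = np.array([u.f_unbind for u in units])
        self.D = np.array([u.D for u in units])
        self.a_um = np.array([u.a * NM for u in units])
        self.end_zone = np.array([u.end_zone for u in units])

    @property
    def bound(self) -> np.ndarray:
        return self.fib >= 0

    @property
    def doubly(self) -> np.ndarray:
        return self.bound.all(axis=1)


def _uniform_in_geometry(n: int, geometry: ConfinementGeometry, rng) -> np.ndarray:
    if geometry.kind == "box":
        half = 0.5 * np.asarray(geometry.dims[:3])
        return rng.uniform(-half, half, size=(n, 3))
    length, diam = geometry.dims[0], geometry.dims[1]
    x = rng.uniform(-0.5 * length, 0.5 * length, size=n)
    r = 0.5 * diam * np.sqrt(rng.uniform(size=n))
    phi = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack([x, r * np.cos(phi), r * np.sin(phi)])


def _clamp_into_geometry(P: np.ndarray, geometry: ConfinementGeometry) -> np.ndarray:
    if geometry.kind == "box":
        half = 0.5 * np.asarray(geometry.dims[:3])
        return np.clip(P, -half, half)
    half_len, radius = 0.5 * geometry.dims[0], 0.5 * geometry.dims[1]
    P = P.copy()
    P[:, 0] = np.clip(P[:, 0], -half_len, half_len)
    r = np.hypot(P[:, 1], P[:, 2])
    over = r > radius
    if over.any():
        scale = radius / r[over]
        P[over, 1] *= scale
        P[over, 2] *= scale
    return P


class World:
    def __init__(self, config: SimulationConfig, seed: int | None = None):
        self.config = config
        seed = config.seed if seed is None else seed
        ss = np.random.SeedSequence(seed)
        self.rng_dyn, self.rng_mot, self.rng_mech = (
            np.random.default_rng(s) for s in ss.spawn(3)
        )
        self.time = 0.0
        self.seg0 = config.mechanics.segmentation
        self.dt = config.constants.dt
        # fibers (empty start)
        self.X = np.zeros((0, 3))
        self.off = np.zeros(1, dtype=np.int64)
        self.flen = np.zeros(0)
        self.fstate = np.zeros(0, dtype=np.int8)
        self.fid = np.zeros(0, dtype=np.int64)
        self.next_fid = 0
        self.seglen = np.zeros(0)
        self.gamma_v = np.zeros(0)
        self._hash = None
        self._seg_arrays = None
        # fixed hash grid covering the container (+2 um pad)
        lo, hi = config.geometry.bounds
        # the segment hash is cached across steps and rebuilt when fibers
        # have moved more than half the coverage slack; a small slack keeps
        # the scan volume (and with it the dominant steric cost in dense
        # networks) low, at the price of near-per-step rebuilds; segment
        # lengths never exceed seg0 (ceil-based vertex count), so a 1-ring
        # scan of cells this size covers every interacting pair
        self._slack = 0.05
        rmax = max(
            config.mechanics.steric.range,
            max((b.species.binding_range for b in config.motors), default=0.0),
        )
        self._cell = self.seg0 + rmax + self._slack + 0.05
        self._grid_origin = lo - 2.0

        def _dims(cell):
            return np.maximum(
                ((hi + 2.0 - self._grid_origin) / cell).astype(np.int64) + 1, 1
            )

        # bound the total cell count (the counting sort sweeps it each
        # rebuild); coarser cells only add scan candidates, never miss pairs
        self._grid_dims = _dims(self._cell)
        while int(np.prod(self._grid_dims)) > 200_000:
            self._cell *= 1.3
            self._grid_dims = _dims(self._cell)
        self._X_ref = None  # vertex snapshot at the last hash rebuild
        self._t_ref = 0.0
        cap = 8192
        self._el_v = np.zeros((cap, 2), dtype=np.int64)
        self._el_w = np.zeros((cap, 2))
        self._el_u = np.zeros((cap, 3))
        self._el_k = np.zeros(cap)
        self._el_n = np.zeros(1, dtype=np.int64)
        self.n_degenerate_steric = 0
        self.species = [
            _SpeciesState(b, config.geometry, self.rng_mot) for b in config.motors
        ]

    # -- fiber helpers ------------------------------------------------------

    @property
    def nf(self) -> int:
        return self.flen.shape[0]

    @property
    def nv(self) -> np.ndarray:
        return np.diff(self.off)

    def _attach_positions(self, fib: np.ndarray, absc: np.ndarray) -> np.ndarray:
        s = self.seglen[fib]
        nseg = self.nv[fib] - 1
        j = np.clip((absc / s).astype(np.int64), 0, nseg - 1)
        w = np.clip(absc / s - j, 0.0, 1.0)
        v0 = self.off[fib] + j
        return (1 - w)[:, None] * self.X[v0] + w[:, None] * self.X[v0 + 1]

    def _attach_tangents(self, fib: np.ndarray, absc: np.ndarray) -> np.ndarray:
        s = self.seglen[fib]
        nseg = self.nv[fib] - 1
        j = np.clip((absc / s).astype(np.int64), 0, nseg - 1)
        v0 = self.off[fib] + j
        t = self.X[v0 + 1] - self.X[v0]
        norm = np.linalg.norm(t, axis=1, keepdims=True)
        return t / np.where(norm > 0, norm, 1.0)

    # -- per-step stages ----------------------------------------------------

    def step(self) -> None:
        dt = self.dt
        cfg = self.config
        if self.nf:
            self.fstate, self.flen = _step_lengths(
                self.fstate, self.flen, cfg.dynamics, dt, self.rng_dyn
            )
        seeds = nucleate(cfg.nucleation, dt, self.rng_dyn)
        self._rebuild(seeds)
        self._release_past_end()
        # one crosslink-force evaluation serves both Bell unbinding and the
        # motor/diffusive loads of this step (springs move < nm per step)
        self._kinetics(dt)
        self._bind(dt)
        if self.nf:
            self._mechanics(dt, depth=0)
            self._constrain()
        self.time += dt

    def _rebuild(self, seeds) -> None:
        removal = self.config.mechanics.removal_length
        alive = self.flen >= removal
        # fast path: unchanged topology (no nucleation, no removal, same
        # vertex counts); growth is applied by the end-of-step reprojection
        if not seeds and alive.all() and self.nf:
            nv_new = np.maximum(2, np.ceil(self.flen / self.seg0 - 1e-9).astype(np.int64) + 1)
            nv = np.diff(self.off)
            if np.array_equal(nv_new, nv):
                self.seglen = self.flen / (nv - 1)
                mech = self.config.mechanics
                gamma_per_um = 3.0 * np.pi * self.config.constants.viscosity * mech.drag_factor
                self.gamma_v = np.repeat(gamma_per_um * self.seglen, nv)
                d = self.config.dynamics
                if self._X_ref is None or self._X_ref.shape != self.X.shape:
                    self._build_hash()
                    return
                # sub-segment nuclei diffuse fast and are excluded from the
                # rebuild trigger; their few interactions tolerate a slightly
                # stale pair list
                if self._est_mask.any():
                    moved = 1.8 * float(
                        np.abs(
                            self.X[self._est_mask] - self._X_ref[self._est_mask]
                        ).max(initial=0.0)
                    )
                else:
                    moved = 0.0
                moved += max(d.v_g, d.v_s) * NM * (self.time - self._t_ref)
                if moved > 0.5 * self._slack:
                    self._build_hash(seg_arrays=self._seg_arrays)
                return
        if not alive.all():
            remap = np.full(self.nf, -1, dtype=np.int64)
            remap[alive] = np.arange(int(alive.sum()))
            dead = ~alive
            for sp in self.species:
                hit = sp.bound & dead[np.clip(sp.fib, 0, max(self.nf - 1, 0))]
                if hit.any():
                    self._release_units(sp, hit)
            vmask = np.repeat(alive, self.nv)
            Xold = self.X[vmask]
            nv_old = self.nv[alive]
            off_old = np.zeros(nv_old.shape[0] + 1, dtype=np.int64)
            np.cumsum(nv_old, out=off_old[1:])
            self.flen = self.flen[alive]
            self.fstate = self.fstate[alive]
            self.fid = self.fid[alive]
            for sp in self.species:
                b = sp.fib >= 0
                sp.fib[b] = remap[sp.fib[b]]
        else:
            Xold = self.X
            off_old = self.off
        # new vertex counts from new lengths
        nv_new = np.maximum(2, np.ceil(self.flen / self.seg0 - 1e-9).astype(np.int64) + 1)
        n_seeds = len(seeds)
        nf_new = self.flen.shape[0] + n_seeds
        off_new = np.zeros(nf_new + 1, dtype=np.int64)
        np.cumsum(np.concatenate([nv_new, np.full(n_seeds, 2, dtype=np.int64)]), out=off_new[1:])
        Xnew = np.empty((off_new[-1], 3))
        if self.flen.shape[0]:
            _kernels.resample_fibers(
                Xold, off_old, Xnew, off_new[: self.flen.shape[0] + 1], self.flen
            )
        if n_seeds:
            for i, seed in enumerate(seeds):
                b = off_new[self.flen.shape[0] + i]
                Xnew[b] = seed.position
                Xnew[b + 1] = seed.position + seed.length * seed.direction
            self.flen = np.append(self.flen, [s.length for s in seeds])
            self.fstate = np.append(
                self.fstate, np.full(n_seeds, int(GrowthState.GROW), dtype=np.int8)
            )
            self.fid = np.append(
                self.fid, np.arange(self.next_fid, self.next_fid + n_seeds)
            )
            self.next_fid += n_seeds
        self.X = Xnew
        self.off = off_new
        self.seglen = self.flen / (np.diff(self.off) - 1)
        mech = self.config.mechanics
        gamma_per_um = 3.0 * np.pi * self.config.constants.viscosity * mech.drag_factor
        self.gamma_v = np.repeat(gamma_per_um * self.seglen, np.diff(self.off))
        if self.nf:
            self._build_hash()
        else:
            self._hash = None
            self._seg_arrays = None

    def _build_hash(self, seg_arrays=None) -> None:
        self._hash = build_segment_hash(
            self.X,
            self.off,
            self._cell,
            origin=self._grid_origin,
            dims=self._grid_dims,
            seg_arrays=seg_arrays,
        )
        self._seg_arrays = (
            self._hash.seg_v0,
            self._hash.seg_fib,
            self._hash.seg_local,
        )
        self._X_ref = self.X.copy()
        self._t_ref = self.time
        self._est_mask = np.repeat(self.flen >= self.seg0, np.diff(self.off))

    def _release_units(self, sp: _SpeciesState, mask2d: np.ndarray) -> None:
        """Release the flagged units; fully unbound complexes keep their last
        attachment point as free position."""
        other_bound = sp.bound[:, ::-1] & ~mask2d[:, ::-1]
        for u in (0, 1):
            rows = np.nonzero(mask2d[:, u])[0]
            if rows.size == 0:
                continue
            becomes_free = rows[~other_bound[rows, u]]
            if becomes_free.size:
                sp.pos[becomes_free] = self._attach_positions(
                    sp.fib[becomes_free, u], sp.absc[becomes_free, u]
                )
                sp.free_t[becomes_free] = self.time
            sp.fib[rows, u] = -1

    def _release_past_end(self) -> None:
        if self.nf == 0:
            return
        for sp in self.species:
            b = sp.bound
            past = b & (sp.absc > self.flen[np.clip(sp.fib, 0, max(self.nf - 1, 0))])
            if past.any():
                # position: the (new) plus end of the fiber
                sp.absc[past] = self.flen[sp.fib[past]]
                self._release_units(sp, past)

    def _couple_forces(
        self,
        sp: _SpeciesState,
        F: np.ndarray | None = None,
        Kv: np.ndarray | None = None,
        elements=None,
    ):
        n = sp.n
        tension = np.zeros(n)
        ftan_a = np.zeros(n)
        ftan_b = np.zeros(n)
        if F is None:
            F = np.zeros_like(self.X)
        if Kv is None:
            Kv = np.zeros(self.X.shape[0])
        if elements is None:
            elements = _NO_ELEMENTS
        el_v, el_w, el_u, el_k, el_n = elements
        if n and self.nf:
            _kernels.crosslink_forces(
                self.X,
                self.off,
                self.seglen,
                sp.fib[:, 0],
                sp.absc[:, 0],
                sp.fib[:, 1],
                sp.absc[:, 1],
                sp.spec.stiffness,
                sp.spec.rest_length,
                F,
                Kv,
                tension,
                ftan_a,
                ftan_b,
                el_v,
                el_w,
                el_u,
                el_k,
                el_n,
            )
        return tension, ftan_a, ftan_b

    def _kinetics(self, dt: float) -> None:
        """Force-dependent unbinding plus motor stepping / lattice diffusion
        of every bound unit (one kernel pass per species)."""
        kT = self.config.constants.kT_um
        for sp in self.species:
            b = sp.fib >= 0
            if not b.any():
                continue
            tension, ftan_a, ftan_b = self._couple_forces(sp)
            u_unbind = self.rng_mot.uniform(size=(sp.n, 2))
            if (sp.kind == int(UnitKind.DIFFUSIVE)).any():
                z_move = self.rng_mot.standard_normal((sp.n, 2))
            else:
                z_move = _ZERO2 if sp.n <= _ZERO2.shape[0] else np.zeros((sp.n, 2))
            release = np.empty((sp.n, 2), dtype=np.uint8)
            _kernels.unbind_and_move(
                sp.fib,
                sp.absc,
                sp.kind,
                sp.vm,
                sp.koff,
                sp.fstall,
                sp.funbind,
                np.maximum(sp.D, 1e-30),
                kT,
                sp.spec.stiffness,
                self.flen,
                tension,
                ftan_a,
                ftan_b,
                dt,
                u_unbind,
                z_move[: sp.n],
                release,
            )
            rel = release.astype(bool) & b
            if rel.any():
                self._release_units(sp, rel)

    def _bind(self, dt: float) -> None:
        if self.nf == 0 or self._hash is None:
            return
        for sp in self.species:
            bound = sp.bound
            n_bound = bound.sum(axis=1)
            free = n_bound == 0
            single = n_bound == 1
            p_on = 1.0 - np.exp(-sp.spec.k_on * dt)
            # --- first binding of free complexes (binding coin drawn first;
            # the geometric search and the lazily accumulated free diffusion
            # run only for units whose coin fired)
            rows = np.nonzero(free)[0]
            if rows.size:
                rows = rows[self.rng_mot.uniform(size=rows.size) < p_on]
            if rows.size:
                self._advance_free(sp, rows)
                cand_fib, cand_absc, _ = self._nearest(sp.pos[rows], np.full(rows.size, -1, dtype=np.int64), sp.spec.binding_range)
                ok = cand_fib >= 0
                idx = rows[ok]
                if idx.size:
                    cf, ca = cand_fib[ok], cand_absc[ok]
                    slot = self._choose_slot(sp, ca, idx.size)
                    valid = slot >= 0
                    idx, cf, ca, slot = idx[valid], cf[valid], ca[valid], slot[valid]
                    sp.fib[idx, slot] = cf
                    sp.absc[idx, slot] = ca
            # --- second binding of singly bound complexes
            rows = np.nonzero(single)[0]
            if rows.size:
                rows = rows[self.rng_mot.uniform(size=rows.size) < p_on]
            if rows.size:
                bslot = np.argmax(bound[rows], axis=1)
                ufree = 1 - bslot
                anchor_fib = sp.fib[rows, bslot]
                anchor_absc = sp.absc[rows, bslot]
                anchor = self._attach_positions(anchor_fib, anchor_absc)
                cand_fib, cand_absc, _ = self._nearest(anchor, anchor_fib, sp.spec.binding_range)
                ok = cand_fib >= 0
                # unit-kind eligibility
                kinds = sp.kind[ufree]
                ez = sp.end_zone[ufree]
                ok &= ~((kinds == int(UnitKind.END_BINDER)) & (cand_absc > ez))
                if sp.spec.parallel_only and ok.any():
                    ta = self._attach_tangents(anchor_fib[ok], anchor_absc[ok])
                    tb = self._attach_tangents(cand_fib[ok], cand_absc[ok])
                    par = np.einsum("ij,ij->i", ta, tb) >= 0.0
                    sub = np.nonzero(ok)[0]
                    ok[sub[~par]] = False
                idx = rows[ok]
                if idx.size:
                    sp.fib[idx, ufree[ok]] = cand_fib[ok]
                    sp.absc[idx, ufree[ok]] = cand_absc[ok]

    def _choose_slot(self, sp: _SpeciesState, cand_absc: np.ndarray, m: int) -> np.ndarray:
        """Pick which unit of a free complex binds; -1 if neither is eligible."""
        elig = np.empty((m, 2), dtype=bool)
        for u in (0, 1):
            if sp.kind[u] == int(UnitKind.END_BINDER):
                elig[:, u] = cand_absc <= sp.end_zone[u]
            else:
                elig[:, u] = True
        r = self.rng_mot.uniform(size=m) < 0.5
        slot = np.where(r, 0, 1)
        # if chosen slot ineligible, fall back to the other; -1 if both bad
        other = 1 - slot
        chosen_ok = elig[np.arange(m), slot]
        other_ok = elig[np.arange(m), other]
        slot = np.where(chosen_ok, slot, np.where(other_ok, other, -1))
        return slot

    def _advance_free(self, sp: _SpeciesState, rows: np.ndarray) -> None:
        """Apply the free diffusion accumulated since each complex was last
        sampled (statistically equivalent to per-step diffusion for the
        binding search; wall reflection is approximated by clamping at the
        sample times)."""
        D = self.config.mechanics.free_diffusion
        dtf = self.time - sp.free_t[rows]
        live = dtf > 0
        P = sp.pos[rows]
        P += np.sqrt(2.0 * D * np.maximum(dtf, 0.0))[:, None] * self.rng_mot.standard_normal(
            (rows.size, 3)
        )
        geometry = self.config.geometry
        if geometry.kind == "box":
            half = 0.5 * np.asarray(geometry.dims[:3])
            np.clip(P, -half, half, out=P)
        else:
            P = _clamp_into_geometry(P, geometry)
        sp.pos[rows] = P
        sp.free_t[rows] = self.time
        if not live.all():
            pass  # dtf == 0 rows get a zero-variance (no-op) kick

    def _nearest(self, P: np.ndarray, exclude: np.ndarray, max_range: float):
        h = self._hash
        m = P.shape[0]
        out_fib = np.empty(m, dtype=np.int64)
        out_absc = np.empty(m)
        out_dist = np.empty(m)
        _kernels.nearest_segment(
            P,
            self.X,
            h.seg_v0,
            h.seg_fib,
            h.seg_local.astype(np.float64),
            h.cell_of_seg,
            h.order,
            h.cell_start,
            h.dims[0],
            h.dims[1],
            h.dims[2],
            h.origin,
            h.cell_size,
            max_range,
            exclude,
            out_fib,
            out_absc,
            out_dist,
        )
        return out_fib, out_absc, out_dist

    def _mechanics(self, dt: float, depth: int) -> None:
        """Linearized backward-Euler step of the full coupled elastic system
        (bending + crosslink springs + steric contacts + confinement), solved
        matrix-free by preconditioned conjugate gradients.  Unconditionally
        stable and preserves the collective mobility of crosslinked fiber
        clusters."""
        mech = self.config.mechanics
        V = self.X.shape[0]
        F = np.zeros_like(self.X)
        Kv = np.zeros(V)
        el = self._elements()
        _kernels.bending_forces(self.X, self.off, self.seglen, mech.rigidity, F)
        if self._hash is not None:
            fallback = self.rng_mech.standard_normal(3)
            fallback /= np.linalg.norm(fallback)
            self.n_degenerate_steric += _kernels.steric_forces(
                self.X,
                self._hash.seg_v0,
                self._hash.seg_fib,
                self._hash.mids,
                self._hash.seg_len,
                self._hash.cell_of_seg,
                self._hash.order,
                self._hash.cell_start,
                self._hash.dims[0],
                self._hash.dims[1],
                self._hash.dims[2],
                mech.steric.range,
                self._slack,
                mech.steric.stiffness,
                fallback,
                F,
                Kv,
                *el,
            )
        for sp in self.species:
            self._couple_forces(sp, F=F, Kv=Kv, elements=el)
        Fc = confinement_forces(self.X, self.config.geometry)
        outside = np.abs(Fc).sum(axis=1) > 0
        diagK = np.zeros(V)
        diagK[outside] = self.config.geometry.stiffness
        F += Fc
        kT = self.config.constants.kT_um
        g = self.gamma_v
        noise = np.sqrt(2.0 * kT * dt / g)[:, None] * self.rng_mech.standard_normal(
            self.X.shape
        )
        delta = np.empty_like(self.X)
        n_el = int(el[4][0])
        _kernels.implicit_cg_step(
            self.off,
            self.seglen,
            mech.rigidity,
            g,
            diagK,
            Kv,
            F,
            noise,
            dt,
            el[0],
            el[1],
            el[2],
            el[3],
            n_el,
            mech.cg_rtol,
            mech.cg_maxiter,
            delta,
        )
        if n_el >= el[0].shape[0]:
            self._grow_elements()
        limit = np.repeat(np.maximum(self.seglen, self.seg0), np.diff(self.off))
        if np.any(np.abs(delta).max(axis=1) > limit):
            if depth < 3:
                self._mechanics(0.5 * dt, depth + 1)
                self._mechanics(0.5 * dt, depth + 1)
                return
            raise TimestepInstabilityError(
                f"t={self.time:.3f}s: vertex displacement exceeds a segment "
                f"even at dt/{2**depth}; reduce dt"
            )
        self.X = self.X + delta

    def _elements(self):
        self._el_n[0] = 0
        return (self._el_v, self._el_w, self._el_u, self._el_k, self._el_n)

    def _grow_elements(self) -> None:
        cap = 2 * self._el_v.shape[0]
        self._el_v = np.zeros((cap, 2), dtype=np.int64)
        self._el_w = np.zeros((cap, 2))
        self._el_u = np.zeros((cap, 3))
        self._el_k = np.zeros(cap)

    def _constrain(self) -> None:
        """Inextensibility reprojection after the mechanics step.

        SHAKE-style minimal-displacement projection: preserves the fiber
        shape (no corner-cutting, which would numerically smooth away
        thermal bending) and the center of mass.  Growth/shrinkage is
        applied separately by the arc-length resampling in the topology
        rebuild."""
        _kernels.shake_segments(self.X, self.off, self.seglen, 1e-3, 50)

    # -- observation --------------------------------------------------------

    def record_frame(self) -> TrajectoryFrame:
        atts = []
        for sp in self.species:
            if self.nf:
                fids = np.where(
                    sp.fib >= 0, self.fid[np.clip(sp.fib, 0, self.nf - 1)], -1
                )
            else:
                fids = np.full_like(sp.fib, -1)
            atts.append(FrameAttachments(fiber_id=fids.copy(), abscissa=sp.absc.copy()))
        return TrajectoryFrame(
            time=self.time,
            fiber_id=self.fid.copy(),
            length=self.flen.copy(),
            state=self.fstate.copy(),
            vertices=self.X.copy(),
            offsets=self.off.copy(),
            attachments=atts,
        )
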