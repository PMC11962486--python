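"""Fiber mechanics: bending, sterics, confinement, constraint, integration."""

import numpy as np
import pytest

from spindlesim.mechanics import (
    ConfinementGeometry,
    SegmentedFiber,
    SimulationConstants,
    StericParams,
    TimestepInstabilityError,
    bending_forces,
    confinement_forces,
    enforce_inextensibility,
    langevin_step,
    steric_forces,
    vertex_drag,
)


def arc_fiber(radius, length, segmentation):
    n = int(round(length / segmentation)) + 1
    theta = np.linspace(0.0, length / radius, n)
    pts = np.column_stack(
        [radius * np.sin(theta), radius * (1 - np.cos(theta)), np.zeros(n)]
    )
    return SegmentedFiber(pts, segmentation=segmentation, rigidity=20.0)


class TestBending:
    def test_straight_fiber_has_zero_forces(self):
        f = SegmentedFiber.straight([0, 0, 0], [1, 0, 0], 2.5)
        assert np.allclose(bending_forces(f), 0.0)

    def test_bent_fiber_conserves_force_and_torque(self, rng):
        verts = np.cumsum(rng.normal(scale=0.3, size=(8, 3)), axis=0)
        f = SegmentedFiber(verts, segmentation=0.5)
        F = bending_forces(f)
        assert np.allclose(F.sum(axis=0), 0.0, atol=1e-10)
        torque = np.cross(verts, F).sum(axis=0)
        assert np.allclose(torque, 0.0, atol=1e-10)

    def test_arc_energy_matches_continuum(self):
        # E = kappa * L / (2 R^2) for a circular arc, fine segmentation
        R, L, s = 2.0, 2.0, 0.02
        f = arc_fiber(R, L, s)
        d2 = np.diff(f.vertices, n=2, axis=0)
        E = f.rigidity / (2 * s**3) * (d2**2).sum()
        assert E == pytest.approx(f.rigidity * L / (2 * R**2), rel=0.05)

    def test_two_vertex_fiber_zero(self):
        f = SegmentedFiber.straight([0, 0, 0], [0, 1, 0], 0.5)
        assert bending_forces(f).shape == (2, 3)
        assert np.allclose(bending_forces(f), 0.0)


class TestSterics:
    def make_pair(self, distance):
        # single-segment fibers: exactly one interacting segment pair
        a = SegmentedFiber.straight([0, 0, 0], [1, 0, 0], 0.5)
        b = SegmentedFiber.straight([0, distance, 0], [1, 0, 0], 0.5)
        return a, b

    def test_far_pair_zero(self):
        params = StericParams(range=0.05, stiffness=100.0)
        Fa, Fb = steric_forces(list(self.make_pair(0.1)), params)
        assert np.allclose(Fa, 0) and np.allclose(Fb, 0)

    def test_overlapping_pair_hooke_law(self):
        params = StericParams(range=0.05, stiffness=100.0)
        Fa, Fb = steric_forces(list(self.make_pair(0.025)), params)
        # expected |F| = k * d0/2 = 2.5 pN in total along -y / +y
        assert Fa.sum(axis=0)[1] == pytest.approx(-2.5, rel=1e-6)
        assert Fb.sum(axis=0)[1] == pytest.approx(2.5, rel=1e-6)
        assert np.allclose(Fa.sum(axis=0) + Fb.sum(axis=0), 0.0, atol=1e-12)

    def test_three_overlapping_fibers_net_zero(self, rng):
        params = StericParams(range=0.05, stiffness=100.0)
        fibers = [
            SegmentedFiber.straight([0, 0, 0], [1, 0, 0], 1.0),
            SegmentedFiber.straight([0.5, 0.02, 0.01], [0, 1, 0], 1.0),
            SegmentedFiber.straight([0.5, -0.3, -0.01], [0, 1, 0.02], 1.0),
        ]
        forces = steric_forces(fibers, params, rng=rng)
        total = sum(F.sum(axis=0) for F in forces)
        assert np.allclose(total, 0.0, atol=1e-10)


class TestConfinement:
    def test_inside_zero(self):
        g = ConfinementGeometry("box", (30.0, 30.0, 0.2), 100.0)
        assert np.allclose(confinement_forces(np.zeros(3), g), 0.0)

    def test_box_penetration_hooke(self):
        g = ConfinementGeometry("box", (30.0, 30.0, 0.2), 100.0)
        F = confinement_forces(np.array([15.01, 0.0, 0.0]), g)
        assert F[0] == pytest.approx(-1.0)
        assert F[1] == F[2] == 0.0

    def test_cylinder_radial(self):
        g = ConfinementGeometry("cylinder", (50.0, 5.0), 100.0)
        F = confinement_forces(np.array([0.0, 3.0, 0.0]), g)
        assert F[1] == pytest.approx(-100.0 * 0.5)
        assert F[0] == 0.0
        F = confinement_forces(np.array([26.0, 0.0, 1.0]), g)
        assert F[0] == pytest.approx(-100.0)


class TestInextensibility:
    def test_constrained_fiber_unchanged(self):
        f = SegmentedFiber.straight([0, 0, 0], [1, 0, 0], 2.5)
        g = enforce_inextensibility(f)
        assert np.allclose(g.vertices, f.vertices, atol=1e-12)

    def test_uniform_stretch_restored(self):
        f = SegmentedFiber.straight([0, 0, 0], [1, 0, 0], 2.5)
        stretched = SegmentedFiber(f.vertices * 1.1, f.segmentation, f.rigidity)
        g = enforce_inextensibility(stretched)
        assert np.allclose(g.segment_lengths, g.segmentation, rtol=1e-3)

    def test_random_perturbation_restored(self, rng):
        f = SegmentedFiber.straight([0, 0, 0], [0, 1, 0], 3.0)
        noisy = SegmentedFiber(
            f.vertices + rng.normal(scale=0.05, size=f.vertices.shape),
            f.segmentation,
            f.rigidity,
        )
        g = enforce_inextensibility(noisy)
        assert np.allclose(g.segment_lengths, g.segmentation, rtol=1e-3)

    def test_minus_end_anchored_and_growth_extends_plus_end(self):
        f = SegmentedFiber.straight([1, 2, 0], [1, 0, 0], 2.0)
        g = enforce_inextensibility(f, total_length=2.5)
        assert np.allclose(g.vertices[0], f.vertices[0])
        assert np.allclose(g.vertices[-1], [3.5, 2, 0], atol=1e-9)


class TestLangevin:
    def test_no_force_no_temperature_no_motion(self, rng):
        consts = SimulationConstants(kT=1e-12, viscosity=0.05, dt=0.01)
        f = SegmentedFiber.straight([0, 0, 0], [1, 0, 0], 1.0)
        (g,) = langevin_step([f], [np.zeros_like(f.vertices)], consts, rng)
        assert np.allclose(g.vertices, f.vertices, atol=1e-6)

    def test_constant_force_drifts_at_mobility(self, rng):
        consts = SimulationConstants(kT=1e-12, viscosity=0.05, dt=0.01)
        f = SegmentedFiber.straight([0, 0, 0], [1, 0, 0], 0.5)
        gamma_total = 2 * vertex_drag(f.segmentation, consts)
        Ftot = 2.0  # pN along y, split over vertices
        F = np.tile([0.0, Ftot / 2, 0.0], (2, 1))
        (g,) = langevin_step([f], [F], consts, rng)
        com_shift = (g.vertices - f.vertices).mean(axis=0)
        assert com_shift[1] == pytest.approx(consts.dt * Ftot / gamma_total, rel=1e-3)

    def test_free_fiber_diffuses_at_einstein_coefficient(self, rng):
        # COM MSD = 2 d D t with D = kT / gamma_total
        consts = SimulationConstants(kT=4.2, viscosity=0.05, dt=0.01)
        nrep, nstep = 200, 100
        fibers = [
            SegmentedFiber.straight([0, 0, 0], [1, 0, 0], 0.5) for _ in range(nrep)
        ]
        start = [f.vertices.mean(axis=0) for f in fibers]
        zero = np.zeros((2, 3))
        for _ in range(nstep):
            fibers = langevin_step(fibers, [zero] * nrep, consts, rng)
        disp = np.array(
            [f.vertices.mean(axis=0) - s for f, s in zip(fibers, start)]
        )
        msd = (disp**2).sum(axis=1).mean()
        D = consts.kT_um / (2 * vertex_drag(0.5, consts))
        expected = 6 * D * consts.dt * nstep
        assert msd == pytest.approx(expected, rel=0.25)

    def test_persistence_length_from_equilibrium_sampling(self):
        # tangent correlations of thermally equilibrated free fibers decay
        # with characteristic length Lp = kappa/kT; a soft-fiber regime
        # makes the decay measurable on a 1 um fiber
        from helpers import world_with_fibers

        kappa, kT = 0.005, 4.2  # pN um^2, pN nm -> Lp = 1.19 um
        Lp = kappa / (kT * 1e-3)
        nf, L, s = 50, 1.5, 0.25  # coarse segments keep lambda*dt << 1
        starts = [(3.0 * (i % 8) - 12.0, 3.0 * (i // 8) - 12.0, 0.0) for i in range(nf)]
        w = world_with_fibers(
            starts,
            [(1.0, 0.0, 0.0)] * nf,
            L,
            seed=8,
            kT=kT,
            dt=0.001,
            rigidity=kappa,
            segmentation=s,
        )
        burn, n_samples, every = 5.0, 12, 1.0
        for _ in range(int(burn / w.dt)):
            w.step()
        max_lag = 3
        corr = np.zeros(max_lag)
        count = 0
        for _ in range(n_samples):
            for _ in range(int(every / w.dt)):
                w.step()
            for f in range(w.nf):
                V = w.X[w.off[f] : w.off[f + 1]]
                t = np.diff(V, axis=0)
                t /= np.linalg.norm(t, axis=1, keepdims=True)
                for lag in range(1, max_lag + 1):
                    corr[lag - 1] += np.einsum("ij,ij->", t[:-lag], t[lag:])
            count += 1
        nseg = int(round(L / s))
        norm = np.array([count * w.nf * (nseg - lag) for lag in range(1, max_lag + 1)])
        corr = corr / norm
        lags = s * np.arange(1, max_lag + 1)
        slope = np.polyfit(lags, np.log(corr), 1)[0]
        # discrete-chain oracle: per-joint <cos theta> = coth(b) - 1/b with
        # b = kappa/(s kT); reduces to exp(-s/Lp), Lp = kappa/kT, for s << Lp
        beta = kappa / (s * kT * 1e-3)
        expected_cos = 1.0 / np.tanh(beta) - 1.0 / beta
        Lp_disc = -s / np.log(expected_cos)
        assert Lp_disc == pytest.approx(Lp, rel=0.15)  # regime check
        assert -1.0 / slope == pytest.approx(Lp_disc, rel=0.15)

    def test_instability_detected(self, rng):
        consts = SimulationConstants(kT=1e-12, viscosity=0.05, dt=0.01)
        f = SegmentedFiber.straight([0, 0, 0], [1, 0, 0], 1.0)
        F = np.tile([0.0, 1e4, 0.0], (f.n_vertices, 1))
        with pytest.raises(TimestepInstabilityError):
            langevin_step([f], [F], consts, rng)
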