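"""Crosslinker kinetics: Bell unbinding, force-velocity, diffusion, archetypes."""

import numpy as np
import pytest
from scipy import stats

from spindlesim.mechanics import SegmentedFiber
from spindlesim.motors import (
    ARCHETYPES,
    AttachmentRecord,
    CrosslinkComplex,
    MotorUnitSpec,
    UnitKind,
    attach_step,
    crosslink_force,
    diffusive_step,
    hop_rates,
    make_archetype,
    motor_speed,
    unbind_rate,
    walk_step,
)
from spindlesim.synthetic_fixtures import single_motor_ensemble


class TestUnbindRate:
    def test_zero_load_is_bare_rate(self):
        assert unbind_rate(0.1, 0.0, 3.0) == pytest.approx(0.1)

    @pytest.mark.parametrize(
        "mult, expected", [(1.0, 0.1 * np.e), (2.0, 0.1 * np.e**2)]
    )
    def test_bell_exponential(self, mult, expected):
        assert unbind_rate(0.1, mult * 3.0, 3.0) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            unbind_rate(0.1, 1.0, 0.0)
        with pytest.raises(ValueError):
            unbind_rate(0.1, -1.0, 3.0)


class TestMotorSpeed:
    D = np.array([1.0, 0.0, 0.0])

    def test_unloaded(self):
        assert motor_speed(30.0, np.zeros(3), self.D, 5.0) == pytest.approx(30.0)

    def test_stall(self):
        assert motor_speed(30.0, -5.0 * self.D, self.D, 5.0) == 0.0

    def test_half_stall(self):
        assert motor_speed(30.0, -2.5 * self.D, self.D, 5.0) == pytest.approx(15.0)

    def test_assisting_load_clamped(self):
        assert motor_speed(30.0, 10.0 * self.D, self.D, 5.0) == pytest.approx(30.0)

    def test_super_stall_clamped_at_zero(self):
        assert motor_speed(30.0, -50.0 * self.D, self.D, 5.0) == 0.0


class TestWalkAndDwell:
    def test_walk_toward_plus_end_and_pin(self):
        att = AttachmentRecord(0, 0, 2.49)
        att = walk_step(att, 30.0, 1.0, fiber_length=2.5, toward_plus=True)
        assert att.abscissa == pytest.approx(2.5)  # pinned at the end
        att = walk_step(att, 30.0, 1.0, fiber_length=2.5, toward_plus=True)
        assert att.abscissa == pytest.approx(2.5)

    def test_walk_toward_minus_end(self):
        att = AttachmentRecord(0, 0, 1.0)
        att = walk_step(att, 80.0, 1.0, fiber_length=2.5, toward_plus=False)
        assert att.abscissa == pytest.approx(1.0 - 0.08)

    @pytest.mark.parametrize(
        "v, k_off, expected_nm",
        [(30.0, 0.1, 300.0), (80.0, 5.0, 16.0), (120.0, 0.1, 1200.0)],
        ids=["kinesin5", "hset", "dynein_diffusive"],
    )
    def test_run_length_v_over_koff(self, v, k_off, expected_nm):
        # the minus-motor control parameter L = v / k_off, within 2% at n=1e5
        unit = MotorUnitSpec(UnitKind.MOTOR, v_m=-v, k_off=k_off)
        out = single_motor_ensemble(unit, n=100_000, seed=7)
        assert out["mean_run_length_nm"] == pytest.approx(expected_nm, rel=0.02)

    def test_dwell_times_exponential(self):
        unit = MotorUnitSpec(UnitKind.MOTOR, v_m=30.0, k_off=0.5)
        out = single_motor_ensemble(unit, n=10_000, seed=3)
        res = stats.kstest(out["dwell_times"], "expon", args=(0.0, 2.0))
        assert res.pvalue > 0.01


class TestDiffusiveUnit:
    SPEC = MotorUnitSpec(UnitKind.DIFFUSIVE, D=0.1, a=8.0, k_off=0.01)

    def test_hop_rate_arithmetic(self):
        kp, km = hop_rates(self.SPEC, 0.0, kT_um=4.2e-3)
        assert kp == pytest.approx(1562.5)
        assert km == pytest.approx(1562.5)

    def test_unloaded_msd(self, rng):
        # along-fiber MSD = 2 D t from the hop statistics
        dt, nstep = 1e-3, 4000
        att = AttachmentRecord(0, 0, 50.0)
        pos = [att.abscissa]
        for _ in range(nstep):
            att = diffusive_step(att, 0.0, self.SPEC, dt, rng, fiber_length=100.0)
            pos.append(att.abscissa)
        inc = np.diff(pos)
        assert inc.var() == pytest.approx(2 * self.SPEC.D * dt, rel=0.1)

    def test_small_force_drift_einstein(self, rng):
        # drift = D f / kT toward the load in the small-force limit
        f, kT = 0.05, 4.2e-3
        expected = self.SPEC.D * f / kT  # um/s
        dt, nstep, nrep = 1e-3, 200, 150
        disp = []
        for _ in range(nrep):
            att = AttachmentRecord(0, 0, 50.0)
            for _ in range(nstep):
                att = diffusive_step(att, f, self.SPEC, dt, rng, fiber_length=100.0, kT_um=kT)
            disp.append(att.abscissa - 50.0)
        drift = np.mean(disp) / (nstep * dt)
        se = np.std(disp, ddof=1) / np.sqrt(nrep) / (nstep * dt)
        assert abs(drift - expected) < max(3 * se, 0.1 * expected)


class TestCrosslinkForce:
    C = CrosslinkComplex(
        MotorUnitSpec(UnitKind.MOTOR, v_m=30.0),
        MotorUnitSpec(UnitKind.MOTOR, v_m=30.0),
        rest_length=0.05,
        stiffness=100.0,
    )

    def test_rest_separation_zero_force(self):
        fa, fb = crosslink_force(self.C, [0, 0, 0], [0.05, 0, 0])
        assert np.allclose(fa, 0, atol=1e-9) and np.allclose(fb, 0, atol=1e-9)

    def test_stretched_tension(self):
        fa, fb = crosslink_force(self.C, [0, 0, 0], [0.15, 0, 0])
        assert fa[0] == pytest.approx(10.0)  # pulled toward b
        assert np.allclose(fa + fb, 0.0)

    def test_compressed_pushes_apart(self):
        fa, fb = crosslink_force(self.C, [0, 0, 0], [0.02, 0, 0])
        assert fa[0] < 0  # pushed away from b


class TestAttachStep:
    def test_zero_on_rate_never_binds(self, rng):
        c = make_archetype("kinesin5", k_on=0.0)
        fiber = SegmentedFiber.straight([0, 0, 0], [1, 0, 0], 2.5)
        for _ in range(200):
            assert attach_step(c.unit_a, c, [0.5, 0.01, 0], [fiber], 0.1, rng) is None

    def test_binding_waiting_time_exponential(self, rng):
        # mean waiting time = 1/k_on for a unit held within range
        c = make_archetype("kinesin5", k_on=1.0)
        fiber = SegmentedFiber.straight([0, 0, 0], [1, 0, 0], 2.5)
        dt, waits = 0.05, []
        for _ in range(800):
            t = 0.0
            while True:
                t += dt
                if attach_step(c.unit_a, c, [0.5, 0.01, 0], [fiber], dt, rng):
                    break
            waits.append(t)
        mean = np.mean(waits)
        se = np.std(waits, ddof=1) / np.sqrt(len(waits))
        assert abs(mean - (1.0 + dt / 2)) < 4 * se

    def test_out_of_range_never_binds(self, rng):
        c = make_archetype("kinesin5", k_on=100.0)
        fiber = SegmentedFiber.straight([0, 0, 0], [1, 0, 0], 2.5)
        assert attach_step(c.unit_a, c, [0.5, 0.2, 0], [fiber], 1.0, rng) is None

    def test_end_binder_only_near_minus_end(self, rng):
        c = make_archetype("dynein_end_numa", k_on=1000.0)
        fiber = SegmentedFiber.straight([0, 0, 0], [1, 0, 0], 2.5)
        # near the middle: the end binder refuses
        assert attach_step(c.unit_b, c, [1.2, 0.01, 0], [fiber], 1.0, rng) is None
        att = attach_step(c.unit_b, c, [0.01, 0.01, 0], [fiber], 1.0, rng)
        assert att is not None and att.abscissa <= c.unit_b.end_zone

    def test_parallel_only_refuses_antiparallel(self, rng):
        c = make_archetype("dynein_end_numa_parallel_only", k_on=1000.0)
        anti = SegmentedFiber.straight([1, 0.01, 0], [-1, 0, 0], 1.0)
        par = SegmentedFiber.straight([0, 0.01, 0], [1, 0, 0], 1.0)
        other_tangent = np.array([1.0, 0.0, 0.0])
        assert (
            attach_step(c.unit_a, c, [0.5, 0, 0], [anti], 1.0, rng, other_tangent)
            is None
        )
        assert (
            attach_step(c.unit_a, c, [0.5, 0, 0], [par], 1.0, rng, other_tangent)
            is not None
        )


class TestArchetypes:
    def test_kinesin5(self):
        c = make_archetype("kinesin5")
        for u in c.units:
            assert u.kind == UnitKind.MOTOR
            assert u.v_m == 30.0 and u.k_off == 0.1

    def test_hset(self):
        c = make_archetype("hset")
        assert c.unit_a.v_m == -80.0 and c.unit_a.k_off == 5.0
        assert c.unit_b.kind == UnitKind.DIFFUSIVE
        assert c.unit_b.D == 0.1 and c.unit_b.k_off == 0.01

    def test_dynein_diffusive_numa(self):
        c = make_archetype("dynein_diffusive_numa")
        assert c.unit_a.v_m == -120.0 and c.unit_a.k_off == 0.1
        assert c.unit_b.kind == UnitKind.DIFFUSIVE

    def test_dynein_end_numa_variants(self):
        c = make_archetype("dynein_end_numa")
        assert c.unit_a.v_m == -1200.0
        assert c.unit_b.kind == UnitKind.END_BINDER
        assert not c.parallel_only
        assert make_archetype("dynein_end_numa_parallel_only").parallel_only

    @pytest.mark.parametrize("v", [30.0, 80.0, 1200.0])
    def test_symmetric_minus_speed(self, v):
        c = make_archetype("symmetric_minus", minus_speed=v)
        assert c.unit_a.v_m == -v and c.unit_b.v_m == -v

    def test_all_archetypes_construct(self):
        for name in ARCHETYPES:
            make_archetype(name)

    def test_unknown_archetype(self):
        with pytest.raises(ValueError):
            make_archetype("myosin")
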