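"""Metropolis engine: moves, acceptance rule, drive bias, entropy bookkeeping."""

import math

import numpy as np
import pytest
from scipy import stats

from patchydsa import (
    BondRule,
    DriveSpec,
    InteractionModel,
    MoveParams,
    ParameterError,
    SimulationBox,
    StopMode,
    ThermoState,
    acceptance_probability,
    entropy_increment,
    mc_step,
    propose_move,
    random_configuration,
    run_mc,
    target_configuration,
)
from patchydsa.mc import attach_box
from patchydsa.model import HARD_CORE_ENERGY


class TestAcceptanceProbability:
    def test_neutral_move_always_accepted(self):
        assert acceptance_probability(0.0, 0, 4.0, 0.5404) == 1.0

    def test_equilibrium_limit_is_metropolis(self):
        kT = 0.5404
        for dE in [-2.0, 0.3, 5.0]:
            expected = min(1.0, math.exp(-dE / kT))
            assert acceptance_probability(dE, 1, 0.0, kT) == pytest.approx(expected)

    def test_driven_bond_break_is_suppressed(self):
        # breaking one bond at eps_patch=4 under eps_drive=4: barrier 8 kJ/mol
        p = acceptance_probability(4.0, -1, 4.0, 0.5404)
        assert p == pytest.approx(3.7e-7, rel=2e-2)

    def test_driven_bond_formation_is_favored(self):
        assert acceptance_probability(-4.0, 1, 4.0, 0.5404) == 1.0

    def test_overlap_never_accepted(self):
        assert acceptance_probability(HARD_CORE_ENERGY, 0, 10.0, 0.5404) == 0.0

    def test_invalid_temperature(self):
        with pytest.raises(ParameterError):
            acceptance_probability(1.0, 0, 0.0, 0.0)


class TestEntropyIncrement:
    def test_zero_without_drive(self):
        assert entropy_increment(True, 2, 0.0, 0.5404) == 0.0

    def test_driven_bond_formation_value(self):
        assert entropy_increment(True, 1, 4.0, 0.5404) == pytest.approx(7.402, rel=1e-3)

    def test_zero_when_rejected_or_no_bond_change(self):
        assert entropy_increment(False, 1, 4.0, 0.5404) == 0.0
        assert entropy_increment(True, 0, 4.0, 0.5404) == 0.0


class TestProposeMove:
    def test_degenerate_translation_returns_same_state(self, box45, rng):
        cfg = random_configuration(4, 0, BondRule.ONE_STATE, box45, seed=0)
        trial = propose_move(cfg, 0, MoveParams(max_translation=0.0,
                                                translation_probability=1.0), rng)
        np.testing.assert_array_equal(trial.position, cfg.positions[0])
        np.testing.assert_array_equal(trial.orientation, cfg.quaternions[0])

    def test_seeded_reproducibility(self, box45):
        cfg = random_configuration(4, 0, BondRule.ONE_STATE, box45, seed=0)
        t1 = propose_move(cfg, 1, MoveParams(), np.random.default_rng(7))
        t2 = propose_move(cfg, 1, MoveParams(), np.random.default_rng(7))
        np.testing.assert_array_equal(t1.position, t2.position)
        np.testing.assert_array_equal(t1.orientation, t2.orientation)

    def test_displacements_uniform_in_cube(self, box45):
        cfg = random_configuration(1, 0, BondRule.ONE_STATE, box45, seed=0)
        rng = np.random.default_rng(3)
        mp = MoveParams(max_translation=0.25, translation_probability=1.0)
        deltas = np.array(
            [propose_move(cfg, 0, mp, rng).position - cfg.positions[0]
             for _ in range(4000)]
        )
        for k in range(3):
            p = stats.kstest(deltas[:, k], stats.uniform(-0.25, 0.5).cdf).pvalue
            assert p > 1e-3

    def test_crowders_never_rotate(self, rng):
        box = SimulationBox.cubic(6.0)
        cfg = random_configuration(0, 4, BondRule.ONE_STATE, box, seed=0)
        mp = MoveParams(translation_probability=0.0)  # would always rotate
        trial = propose_move(cfg, 0, mp, rng)
        np.testing.assert_array_equal(trial.orientation, cfg.quaternions[0])


class TestMcStepReference:
    """Pure-python step path used as the bookkeeping oracle."""

    def _dense_system(self, eps=6.0, rule=BondRule.ONE_STATE):
        box = SimulationBox.cubic(3.0)
        model = InteractionModel(eps_patch=eps, bond_rule=rule)
        cfg = attach_box(random_configuration(6, 0, rule, box, seed=8), box)
        return cfg, model, box

    def test_crowder_moves_never_change_bonds(self, thermo65):
        box = SimulationBox.cubic(4.0)
        cfg = attach_box(random_configuration(0, 6, BondRule.ONE_STATE, box, seed=1), box)
        rng = np.random.default_rng(0)
        model = InteractionModel(eps_patch=5.0)
        for k in range(100):
            cfg, rec = mc_step(cfg, model, thermo65, DriveSpec(eps_drive=3.0),
                               MoveParams(), rng, step_index=k)
            attach_box(cfg, box)
            assert rec.delta_n_target_bonds == 0
            assert rec.entropy_increment == 0.0

    def test_bond_change_bounded_by_two(self, thermo65):
        cfg, model, box = self._dense_system()
        rng = np.random.default_rng(5)
        for k in range(800):
            cfg, rec = mc_step(cfg, model, thermo65, DriveSpec(eps_drive=4.0),
                               MoveParams(), rng, step_index=k)
            attach_box(cfg, box)
            assert abs(rec.delta_n_target_bonds) <= 2

    def test_incremental_energy_matches_full_recompute(self, thermo65):
        from patchydsa import total_energy

        cfg, model, box = self._dense_system()
        e = total_energy(cfg, model, box)
        rng = np.random.default_rng(5)
        for k in range(2000):
            cfg, rec = mc_step(cfg, model, thermo65, DriveSpec(), MoveParams(), rng, k)
            attach_box(cfg, box)
            if rec.accepted:
                e += rec.delta_E
        assert e == pytest.approx(total_energy(cfg, model, box), abs=1e-8)

    def test_entropy_ledger_matches_identity(self, thermo65):
        cfg, model, box = self._dense_system()
        rng = np.random.default_rng(6)
        drive = DriveSpec(eps_drive=4.0)
        S = 0.0
        sum_abs_dn = 0
        for k in range(1500):
            cfg, rec = mc_step(cfg, model, thermo65, drive, MoveParams(), rng, k)
            attach_box(cfg, box)
            S += rec.entropy_increment
            if rec.accepted and rec.delta_n_target_bonds != 0:
                sum_abs_dn += abs(rec.delta_n_target_bonds)
        assert S == pytest.approx(4.0 / thermo65.kT * sum_abs_dn, rel=1e-12)


class TestRunMc:
    def test_same_seed_identical_result(self, thermo65, box45, model4):
        cfg = random_configuration(8, 0, BondRule.ONE_STATE, box45, seed=2)
        kw = dict(budget_steps=200_000, record_every=20_000,
                  stop_mode=StopMode.FIRST_ASSEMBLY, seed=17, n_target_bonds=8)
        a = run_mc(cfg, model4, thermo65, DriveSpec(), MoveParams(), box45, **kw)
        b = run_mc(cfg, model4, thermo65, DriveSpec(), MoveParams(), box45, **kw)
        np.testing.assert_array_equal(a.n_bonds, b.n_bonds)
        np.testing.assert_array_equal(a.final_configuration.positions,
                                      b.final_configuration.positions)
        assert a.assembly.t_fas == b.assembly.t_fas

    def test_weak_interaction_run_is_censored(self, thermo65, box45):
        model = InteractionModel(eps_patch=0.0)
        cfg = random_configuration(8, 0, BondRule.ONE_STATE, box45, seed=3)
        res = run_mc(cfg, model, thermo65, DriveSpec(), MoveParams(), box45,
                     100_000, stop_mode=StopMode.FIRST_ASSEMBLY, seed=3,
                     n_target_bonds=8)
        assert res.assembly.t_fas_censored and res.assembly.t_fas == 100_000

    def test_strong_ring_never_breaks_in_short_run(self, thermo65, box45):
        # per-attempt break probability <= exp(-60/kT) ~ 1e-49
        model = InteractionModel(eps_patch=60.0)
        cfg = target_configuration(8, model, box45)
        res = run_mc(cfg, model, thermo65, DriveSpec(), MoveParams(), box45,
                     200_000, stop_mode=StopMode.FIRST_DISASSEMBLY, seed=5,
                     n_target_bonds=8)
        assert res.assembly.t_stable_censored
        assert res.n_bonds[-1] == 8

    def test_disassembly_requires_target_start(self, thermo65, box45, model4):
        from patchydsa import InvalidStateError

        cfg = random_configuration(8, 0, BondRule.ONE_STATE, box45, seed=1)
        with pytest.raises(InvalidStateError):
            run_mc(cfg, model4, thermo65, DriveSpec(), MoveParams(), box45,
                   1000, stop_mode=StopMode.FIRST_DISASSEMBLY, seed=1,
                   n_target_bonds=8)

    def test_entropy_zero_without_drive(self, thermo65, box45, model4):
        cfg = random_configuration(8, 0, BondRule.ONE_STATE, box45, seed=4)
        res = run_mc(cfg, model4, thermo65, DriveSpec(), MoveParams(), box45,
                     300_000, seed=4)
        assert res.entropy_final == 0.0
        assert np.all(res.entropy == 0.0)

    def test_entropy_nondecreasing_and_identity(self, thermo65, box45):
        model = InteractionModel(eps_patch=4.0)
        cfg = random_configuration(8, 0, BondRule.ONE_STATE, box45, seed=6)
        drive = DriveSpec(eps_drive=4.0)
        res = run_mc(cfg, model, thermo65, drive, MoveParams(), box45,
                     400_000, record_every=10_000, seed=6)
        assert np.all(np.diff(res.entropy) >= 0)
        assert res.entropy_final == pytest.approx(
            drive.eps_drive / thermo65.kT * res.sum_abs_dn, rel=1e-12)

    def test_no_overlap_after_dense_crowded_run(self, thermo65):
        box = SimulationBox.cubic(6.0)
        model = InteractionModel(eps_patch=5.0)
        cfg = random_configuration(8, 48, BondRule.ONE_STATE, box, seed=7)
        res = run_mc(cfg, model, thermo65, DriveSpec(eps_drive=2.0), MoveParams(),
                     box, 200_000, seed=7, n_target_bonds=8)
        pos = res.final_configuration.positions
        iu, ju = np.triu_indices(56, k=1)
        d = box.minimum_image(pos[ju] - pos[iu])
        assert np.min(np.linalg.norm(d, axis=1)) >= 1.0

    def test_order_parameter_series_quantized(self, thermo65, box45):
        model = InteractionModel(eps_patch=9.0)
        cfg = random_configuration(8, 0, BondRule.ONE_STATE, box45, seed=8)
        res = run_mc(cfg, model, thermo65, DriveSpec(), MoveParams(), box45,
                     500_000, record_every=5_000, seed=8, n_target_bonds=8)
        np.testing.assert_array_equal(res.order_parameter * 8,
                                      np.round(res.order_parameter * 8))
        assert np.all((res.order_parameter >= 0) & (res.order_parameter <= 1))


class TestAcceptanceRuleProperties:
    """Algebraic properties of the driven Metropolis rule (hypothesis)."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        dE=st.floats(-50, 50),
        dn=st.integers(-2, 2),
        drive=st.floats(0, 20),
        kT=st.floats(0.05, 5.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_probability_bounds_and_drive_direction(self, dE, dn, drive, kT):
        p = acceptance_probability(dE, dn, drive, kT)
        assert 0.0 <= p <= 1.0
        p0 = acceptance_probability(dE, dn, 0.0, kT)
        if dn > 0:  # drive rewards bond formation
            assert p >= p0
        elif dn < 0:  # drive penalizes bond breaking
            assert p <= p0

    @given(dn=st.integers(-2, 2), drive=st.floats(0, 20), kT=st.floats(0.05, 5.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_entropy_increment_nonnegative_and_zero_cases(self, dn, drive, kT):
        s = entropy_increment(True, dn, drive, kT)
        assert s >= 0.0
        assert entropy_increment(False, dn, drive, kT) == 0.0
        if dn == 0 or drive == 0.0:
            assert s == 0.0
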