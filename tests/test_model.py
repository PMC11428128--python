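"""Kern-Frenkel pair potential, configurations and their invariants."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from patchydsa import (
    BondRule,
    InteractionModel,
    InvalidStateError,
    OverlapError,
    PackingError,
    ParameterError,
    PatchGeometry,
    PatchyConfiguration,
    PatchyParticle,
    SimulationBox,
    Species,
    ThermoState,
    pair_interaction,
    random_configuration,
    target_configuration,
    total_energy,
)
from patchydsa.model import quat_rotate, random_quaternions, rotation_to_quat


def _oriented_particle(position, patch0_toward, species=Species.ALPHA):
    """Particle whose first patch points exactly along ``patch0_toward``."""
    geom = PatchGeometry()
    v = np.asarray(patch0_toward, dtype=float)
    v = v / np.linalg.norm(v)
    rot, _ = Rotation.align_vectors(v[None, :], geom.patch_directions[:1])
    q = rotation_to_quat(rot)
    return PatchyParticle(np.asarray(position, float), q, species)


class TestPairInteraction:
    def test_outside_well_no_energy(self, model4, box45):
        pi = _oriented_particle([1.0, 1.0, 1.0], [1, 0, 0])
        pj = _oriented_particle([3.0, 1.0, 1.0], [-1, 0, 0])
        res = pair_interaction(pi, pj, model4, box45)
        assert res.energy == 0.0 and not res.overlap and res.bonded_patch_pair is None

    def test_aligned_pair_in_well_bonds(self, model4, box45):
        pi = _oriented_particle([1.0, 1.0, 1.0], [1, 0, 0])
        pj = _oriented_particle([2.05, 1.0, 1.0], [-1, 0, 0])
        res = pair_interaction(pi, pj, model4, box45)
        assert res.energy == -4.0
        assert res.bonded_patch_pair == (0, 0)

    def test_two_state_alpha_alpha_is_inert(self, model4_two_state, box45):
        pi = _oriented_particle([1.0, 1.0, 1.0], [1, 0, 0])
        pj = _oriented_particle([2.05, 1.0, 1.0], [-1, 0, 0])
        res = pair_interaction(pi, pj, model4_two_state, box45)
        assert res.energy == 0.0 and res.bonded_patch_pair is None

    def test_two_state_alpha_beta_bonds(self, model4_two_state, box45):
        pi = _oriented_particle([1.0, 1.0, 1.0], [1, 0, 0])
        pj = _oriented_particle([2.05, 1.0, 1.0], [-1, 0, 0], Species.BETA)
        res = pair_interaction(pi, pj, model4_two_state, box45)
        assert res.energy == -4.0

    def test_hard_core_overlap(self, model4, box45):
        pi = _oriented_particle([1.0, 1.0, 1.0], [1, 0, 0])
        pj = _oriented_particle([1.9, 1.0, 1.0], [-1, 0, 0])
        res = pair_interaction(pi, pj, model4, box45)
        assert res.overlap and np.isinf(res.energy)

    def test_crowder_pairs_are_hard_core_only(self, model4, box45):
        pi = _oriented_particle([1.0, 1.0, 1.0], [1, 0, 0])
        pj = _oriented_particle([2.05, 1.0, 1.0], [-1, 0, 0], Species.CROWDER)
        res = pair_interaction(pi, pj, model4, box45)
        assert res.energy == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_symmetry_under_particle_swap(self, seed, model4, box45):
        rng = np.random.default_rng(seed)
        q = random_quaternions(2, rng)
        pi = PatchyParticle(rng.random(3) * 4.0, q[0])
        pj = PatchyParticle(pi.position + rng.normal(scale=0.6, size=3), q[1])
        a = pair_interaction(pi, pj, model4, box45)
        b = pair_interaction(pj, pi, model4, box45)
        assert a.energy == b.energy and a.overlap == b.overlap

    def test_non_unit_quaternion_rejected(self):
        with pytest.raises(InvalidStateError):
            PatchyParticle(np.zeros(3), np.array([1.0, 0.1, 0.0, 0.0]))

    def test_non_finite_position_rejected(self):
        with pytest.raises(InvalidStateError):
            PatchyParticle(np.array([np.nan, 0, 0]), np.array([1.0, 0, 0, 0]))


class TestTotalEnergy:
    def test_target_ring_energy_is_minus_eight_eps(self, model4, box45):
        cfg = target_configuration(8, model4, box45)
        assert total_energy(cfg, model4, box45) == pytest.approx(-32.0, abs=1e-12)

    def test_zero_eps_zero_energy(self, box45):
        model = InteractionModel(eps_patch=0.0)
        cfg = target_configuration(8, model, box45)
        assert total_energy(cfg, model, box45) == 0.0

    def test_distant_particles_zero_energy(self, model4):
        box = SimulationBox.cubic(12.0)
        pos = np.array([[2.0, 2, 2], [6.0, 2, 2], [2.0, 7, 2]])
        rng = np.random.default_rng(0)
        cfg = PatchyConfiguration(pos, random_quaternions(3, rng), np.zeros(3, dtype=int))
        assert total_energy(cfg, model4, box) == 0.0

    def test_overlap_raises_with_pair(self, model4, box45):
        pos = np.array([[1.0, 1, 1], [1.5, 1, 1]])
        rng = np.random.default_rng(0)
        cfg = PatchyConfiguration(pos, random_quaternions(2, rng), np.zeros(2, dtype=int))
        with pytest.raises(OverlapError) as exc:
            total_energy(cfg, model4, box45)
        assert exc.value.pair == (0, 1)

    def test_translation_by_lattice_vector_is_exact_symmetry(self, model4, box45, target8):
        e0 = total_energy(target8, model4, box45)
        shifted = target8.copy()
        shifted.positions += box45.edge * np.array([1.0, -2.0, 3.0])
        assert total_energy(shifted, model4, box45) == e0

    def test_rigid_rotation_invariance(self, model4, box45, target8):
        e0 = total_energy(target8, model4, box45)
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7])
        center = box45.edge / 2
        cfg = target8.copy()
        cfg.positions = rot.apply(cfg.positions - center) + center
        dq = rotation_to_quat(rot)
        from patchydsa.mc import _quat_multiply

        cfg.quaternions = np.array([_quat_multiply(dq, q) for q in cfg.quaternions])
        cfg.quaternions /= np.linalg.norm(cfg.quaternions, axis=1, keepdims=True)
        assert total_energy(cfg, model4, box45) == pytest.approx(e0, abs=1e-9)


class TestRandomConfiguration:
    def test_seed_determinism(self, box45):
        a = random_configuration(8, 0, BondRule.ONE_STATE, box45, seed=42)
        b = random_configuration(8, 0, BondRule.ONE_STATE, box45, seed=42)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.quaternions, b.quaternions)

    def test_two_state_species_split(self, box45):
        cfg = random_configuration(8, 0, BondRule.TWO_STATE, box45, seed=1)
        assert int(np.sum(cfg.species == Species.ALPHA)) == 4
        assert int(np.sum(cfg.species == Species.BETA)) == 4

    def test_large_system_has_no_overlap(self):
        box = SimulationBox.cubic(22.5)
        cfg = random_configuration(1000, 0, BondRule.ONE_STATE, box, seed=3)
        iu, ju = np.triu_indices(1000, k=1)
        d = box.minimum_image(cfg.positions[ju] - cfg.positions[iu])
        assert np.min(np.linalg.norm(d, axis=1)) >= 1.0

    def test_packing_failure_raises(self):
        with pytest.raises(PackingError):
            random_configuration(100, 0, BondRule.ONE_STATE, SimulationBox.cubic(2.0),
                                 seed=0, max_attempts=200)

    def test_quaternions_are_unit(self, box45):
        cfg = random_configuration(16, 4, BondRule.TWO_STATE, box45, seed=5)
        np.testing.assert_allclose(np.linalg.norm(cfg.quaternions, axis=1), 1.0, atol=1e-10)


class TestTargetConfiguration:
    def test_bond_count_and_energy(self, model4, box45):
        from patchydsa import build_bond_graph

        cfg = target_configuration(8, model4, box45)
        g = build_bond_graph(cfg, model4, box45)
        assert g.n_bonds == 8
        assert all(d == 2 for d in g.degrees())

    def test_two_state_ring_alternates(self, model4_two_state, box45):
        from patchydsa import build_bond_graph

        cfg = target_configuration(8, model4_two_state, box45)
        g = build_bond_graph(cfg, model4_two_state, box45)
        assert g.n_bonds == 8
        for i, _, j, _ in g.edges:
            assert {int(cfg.species[i]), int(cfg.species[j])} == {0, 1}

    def test_one_bond_per_patch_in_ring(self, model4, box45):
        from patchydsa import build_bond_graph
        from patchydsa.model import geometric_bond_candidates

        cfg = target_configuration(8, model4, box45)
        # even before slot resolution, narrow patches admit a single partner
        candidates, _ = geometric_bond_candidates(cfg, model4, box45)
        slots = [(i, a) for _, i, a, _, _ in candidates] + [
            (j, b) for _, _, _, j, b in candidates
        ]
        assert len(slots) == len(set(slots))

    def test_octagon_must_fit_box(self, model4):
        from patchydsa import GeometryError

        with pytest.raises(GeometryError):
            target_configuration(8, model4, SimulationBox.cubic(2.0))


class TestThermoAndGeometry:
    def test_kT_at_65K(self):
        assert ThermoState(65.0).kT == pytest.approx(0.5404425, rel=1e-6)

    def test_patch_opening_angle(self):
        geom = PatchGeometry()
        cosang = float(np.dot(geom.patch_directions[0], geom.patch_directions[1]))
        assert np.degrees(np.arccos(cosang)) == pytest.approx(135.0, abs=1e-9)

    def test_quat_rotation_matches_scipy(self, rng):
        q = random_quaternions(1, rng)[0]
        v = rng.standard_normal(3)
        got = quat_rotate(q, v)
        xyzw = np.concatenate([q[1:], q[:1]])
        np.testing.assert_allclose(got, Rotation.from_quat(xyzw).apply(v), atol=1e-12)

    @pytest.mark.parametrize("bad", [
        dict(eps_patch=-1.0),
        dict(eps_patch=1.0, lambda_range=0.9),
        dict(eps_patch=1.0, cos_theta_max=1.5),
    ])
    def test_invalid_model_parameters(self, bad):
        with pytest.raises(ParameterError):
            InteractionModel(**bad)
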