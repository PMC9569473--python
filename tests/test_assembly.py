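import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from xlassembly import assembly as asm
from xlassembly import restraints as rst
from xlassembly import synthetic as syn
from xlassembly.structure import AtomRecord, Structure

from conftest import cage_restraints


def _pairwise(coords):
    return cdist(coords, coords)


class TestPose:
    def test_identity_leaves_coordinates(self):
        helix = syn.make_segment("helix", 10)
        moved = asm.transform(helix, asm.Pose.identity())
        assert np.allclose(moved.coords, helix.coords)

    def test_pure_translation(self):
        helix = syn.make_segment("helix", 10)
        pose = asm.Pose(np.eye(3), np.array([0.0, 0.0, 10.0]))
        moved = asm.transform(helix, pose)
        assert np.allclose(moved.coords[:, 2] - helix.coords[:, 2], 10.0)
        assert np.allclose(moved.coords[:, :2], helix.coords[:, :2])

    @pytest.mark.parametrize("seed", range(5))
    def test_rotation_preserves_pairwise_distances(self, seed):
        helix = syn.make_segment("helix", 15)
        rng = np.random.default_rng(seed)
        pose = asm.Pose(Rotation.random(rng=rng).as_matrix(), rng.uniform(-50, 50, 3))
        moved = asm.transform(helix, pose)
        assert np.abs(_pairwise(moved.coords) - _pairwise(helix.coords)).max() < 1e-6

    def test_non_orthonormal_rejected(self):
        with pytest.raises(ValueError):
            asm.Pose(np.eye(3) * 2.0, np.zeros(3))

    def test_improper_flag_tracks_determinant(self):
        M = asm.mirror_pose([0, 0, 0], [0, 0, 1])
        assert M.improper
        assert not asm.Pose.identity().improper


class TestMirror:
    def test_point_reflection(self):
        s = Structure([AtomRecord("A", 1, "ALA", "CA", 1.0, 0.0, 0.0)])
        mirrored = asm.mirror(s, [0, 0, 0], [1, 0, 0])
        assert np.allclose(mirrored.coords[0], [-1.0, 0.0, 0.0])

    def test_double_mirror_is_identity(self):
        helix = syn.make_segment("helix", 12)
        point, normal = [3.0, -1.0, 2.0], [1.0, 2.0, -0.5]
        twice = asm.mirror(asm.mirror(helix, point, normal), point, normal)
        assert np.allclose(twice.coords, helix.coords, atol=1e-9)

    def test_zero_normal_rejected(self):
        helix = syn.make_segment("helix", 4)
        with pytest.raises(ValueError):
            asm.mirror(helix, [0, 0, 0], [0, 0, 0])

    def test_mirror_preserves_distances_but_flips_handedness(self):
        helix = syn.make_segment("helix", 12)  # right-handed: positive torsions
        mirrored = asm.mirror(helix, [0, 0, 0], [0, 1, 0])
        assert np.abs(_pairwise(mirrored.coords) - _pairwise(helix.coords)).max() < 1e-9
        before = asm.ca_pseudo_dihedrals(helix)
        after = asm.ca_pseudo_dihedrals(mirrored)
        assert np.all(before > 0)
        assert np.allclose(after, -before, atol=1e-9)


class TestClashCount:
    def test_single_close_pair(self):
        a = Structure([AtomRecord("A", 1, "ALA", "CA", 0, 0, 0)])
        b = Structure([AtomRecord("B", 2, "ALA", "CA", 3.0, 0, 0)])
        assert asm.clash_count(a, b, cutoff=4.0) == 1

    def test_distant_bodies(self):
        a = syn.make_segment("helix", 10)
        b = asm.transform(a, asm.Pose(np.eye(3), np.array([100.0, 0, 0])))
        assert asm.clash_count(a, b) == 0

    def test_boundary_is_strict(self):
        a = Structure([AtomRecord("A", 1, "ALA", "CA", 0, 0, 0)])
        b = Structure([AtomRecord("B", 2, "ALA", "CA", 4.0, 0, 0)])
        assert asm.clash_count(a, b, cutoff=4.0) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_grid_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        xa = rng.uniform(0, 30, (200, 3))
        xb = rng.uniform(0, 30, (200, 3))
        brute = int((cdist(xa, xb) < 4.0).sum())
        assert asm.clash_count(xa, xb, cutoff=4.0) == brute


class TestRestraintLoss:
    def test_all_satisfied_no_clash_is_zero(self, toy):
        from xlassembly.structure import merge

        merged = merge(toy.truth.values())
        triples = [(a, b, 26.0) for (a, b) in toy.truth_distances]
        excess, clashes, loss = asm.restraint_loss(merged, triples)
        assert excess == 0.0 and loss == 0.0

    def test_single_excess_squared(self):
        s = Structure(
            [
                AtomRecord("A", 1, "ALA", "CA", 0, 0, 0),
                AtomRecord("A", 2, "ALA", "CA", 30.0, 0, 0),
            ]
        )
        excess, clashes, loss = asm.restraint_loss(s, [(1, 2, 26.0)])
        assert excess == pytest.approx(16.0)
        assert loss == pytest.approx(16.0)

    def test_planted_fixture_hand_computed(self, toy):
        from xlassembly.structure import merge

        merged = merge(toy.truth.values())
        pairs = list(toy.truth_distances.items())[:5]
        d_max = 10.0
        triples = [(a, b, d_max) for (a, b), _ in pairs]
        expected = sum(max(0.0, d - d_max) ** 2 for _, d in pairs)
        excess, _, _ = asm.restraint_loss(merged, triples)
        assert excess == pytest.approx(expected, abs=1e-9)


class TestFitPose:
    def _scrambled_case(self, icosa_cage, seed, mirror=False):
        # a coil blob has no internal symmetry, so surrounding restraints
        # pin its pose uniquely (an ideal helix's screw symmetry would leave
        # near-degenerate alternatives)
        body = syn.make_segment("coil", 20, seed=777, start_res=100)
        rng = np.random.default_rng(seed)
        truth = asm.transform(
            body, asm.Pose(Rotation.random(rng=rng).as_matrix(), rng.uniform(-3, 3, 3))
        )
        restraints = cage_restraints(truth, icosa_cage)
        mobile, _ = syn.scramble(body, seed=seed, mirror=mirror)
        return mobile, truth, restraints

    def test_recovers_scrambled_pose(self, icosa_cage):
        mobile, truth, restraints = self._scrambled_case(icosa_cage, seed=7)
        fit = asm.fit_pose(mobile, icosa_cage, restraints, seed=0, clash_weight=0.0)
        placed = asm.transform(mobile, fit.pose)
        rmsd = np.sqrt(((placed.coords - truth.coords) ** 2).sum(axis=1).mean())
        assert rmsd < 2.0
        assert not fit.improper

    def test_single_restraint_feasible(self, icosa_cage):
        helix = syn.make_segment("helix", 8, start_res=100)
        fit = asm.fit_pose(
            helix, icosa_cage, [(104, 1, 30.0)], seed=0, clash_weight=0.0
        )
        assert fit.restraint_excess == pytest.approx(0.0, abs=1e-12)

    def test_no_bridging_restraints_raises(self, icosa_cage):
        helix = syn.make_segment("helix", 8, start_res=100)
        with pytest.raises(ValueError, match="bridge"):
            asm.fit_pose(helix, icosa_cage, [(500, 600, 26.0)])

    def test_collinear_anchors_warn_in_diagnostics(self):
        fixed = Structure(
            [AtomRecord("A", i, "ALA", "CA", float(i * 10), 0, 0) for i in (1, 2, 3)]
        )
        helix = syn.make_segment("helix", 9, start_res=100)
        restraints = [(100, 1, 20.0), (104, 2, 20.0), (108, 3, 20.0)]
        fit = asm.fit_pose(helix, fixed, restraints, n_starts=2, seed=0,
                           clash_weight=0.0)
        # mobile anchors lie along one helix; fixed anchors are collinear
        assert "degenerate" not in fit.diagnostics or isinstance(
            fit.diagnostics["degenerate"], str
        )

    def test_loss_non_increasing_during_refinement(self, icosa_cage):
        mobile, _, restraints = self._scrambled_case(icosa_cage, seed=3)
        fit = asm.fit_pose(mobile, icosa_cage, restraints, seed=1, clash_weight=0.0)
        assert fit.diagnostics["loss_history_nonincreasing"]

    def test_mirror_fixture_flagged_improper(self, icosa_cage):
        """Restraints generated from the true chirality cannot be satisfied
        by any proper transform of the mirrored model; allowing the mirror
        branch recovers a near-zero loss and flags the pose improper."""
        helix = syn.make_segment("helix", 20, start_res=100)
        rng = np.random.default_rng(11)
        truth = asm.transform(
            helix,
            asm.Pose(Rotation.random(rng=rng).as_matrix(), rng.uniform(-3, 3, 3)),
        )
        restraints = cage_restraints(truth, icosa_cage)
        wrong_hand = asm.mirror(helix, helix.coords.mean(axis=0), [0, 1, 0])
        proper_only = asm.fit_pose(
            wrong_hand, icosa_cage, restraints, seed=0, clash_weight=0.0
        )
        mirrored = asm.fit_pose(
            wrong_hand, icosa_cage, restraints, allow_mirror=True, seed=0,
            clash_weight=0.0,
        )
        assert proper_only.loss > 1.0
        assert mirrored.improper
        assert mirrored.pose.improper
        assert mirrored.loss < 1e-3
        placed = asm.transform(wrong_hand, mirrored.pose)
        rmsd = np.sqrt(((placed.coords - truth.coords) ** 2).sum(axis=1).mean())
        assert rmsd < 2.0

    def test_chirality_pair_degeneracy(self, icosa_cage):
        """Distance-only restraints admit mirror-image solution pairs:
        reflecting a zero-loss configuration (body and anchors together)
        yields another zero-loss configuration."""
        helix = syn.make_segment("helix", 20, start_res=100)
        rng = np.random.default_rng(5)
        truth = asm.transform(
            helix,
            asm.Pose(Rotation.random(rng=rng).as_matrix(), rng.uniform(-3, 3, 3)),
        )
        restraints = cage_restraints(truth, icosa_cage)
        # zero loss at the truth
        excess0, _, _ = asm.restraint_loss(
            _merge_with_cage(truth, icosa_cage), restraints
        )
        assert excess0 == pytest.approx(0.0, abs=1e-12)
        # reflect everything through an arbitrary plane: still zero loss
        point, normal = [5.0, 1.0, -2.0], [1.0, 1.0, 1.0]
        truth_m = asm.mirror(truth, point, normal)
        cage_m = asm.mirror(icosa_cage, point, normal)
        excess_m, _, _ = asm.restraint_loss(
            _merge_with_cage(truth_m, cage_m), restraints
        )
        assert excess_m == pytest.approx(0.0, abs=1e-9)


def _merge_with_cage(body, cage):
    from xlassembly.structure import merge

    return merge([body, cage])


class TestSequentialAssemble:
    def test_two_segment_toy_full_satisfaction(self, icosa_cage):
        helix = syn.make_segment("helix", 20, start_res=100)
        rng = np.random.default_rng(2)
        truth = asm.transform(
            helix, asm.Pose(Rotation.random(rng=rng).as_matrix(), rng.uniform(-3, 3, 3))
        )
        restraints = cage_restraints(truth, icosa_cage)
        mobile, _ = syn.scramble(helix, seed=2)
        state = asm.sequential_assemble(
            {"cage": icosa_cage, "body": mobile}, restraints, ["cage", "body"],
            seed=0, clash_weight=0.0,
        )
        # tight restraints (d_max = true distance) converge to a residual
        # excess of well under 0.1 Å per link
        assert state.restraint_excess == pytest.approx(0.0, abs=1e-3)

    def test_segment_without_bridging_links_skipped(self):
        a = syn.make_segment("helix", 10, start_res=1)
        b = syn.make_segment("helix", 10, start_res=100)
        with pytest.warns(UserWarning, match="skipped"):
            state = asm.sequential_assemble({"a": a, "b": b}, [], ["a", "b"])
        assert state.skipped == ["b"]

    def test_order_permutation_same_satisfaction(self, toy):
        triples = [(a, b, 26.0) for (a, b) in toy.truth_distances]
        sat = []
        for order in (["I", "II", "III", "V", "IV"], ["II", "I", "III", "V", "IV"]):
            state = asm.sequential_assemble(
                toy.segments, triples, order, seed=0
            )
            evals = rst.evaluate_crosslinks(state.merged(), toy.links)
            sat.append(rst.summarize(evals).n_satisfied)
        assert sat[0] == sat[1] == len(toy.links)


class TestParticleShell:
    def test_atoms_on_sphere_surface(self):
        particle = asm.ParticleModel("sphere", 300.0, shell=(20.0, 20.0))
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(50, 3))
        pts = pts / np.linalg.norm(pts, axis=1, keepdims=True) * 150.0
        s = Structure(
            [AtomRecord("A", i + 1, "ALA", "CA", *map(float, p)) for i, p in enumerate(pts)]
        )
        assert asm.shell_containment(s, particle) == 1.0

    def test_center_atom_outside_shell(self):
        particle = asm.ParticleModel("sphere", 300.0, shell=(20.0, 20.0))
        s = Structure([AtomRecord("A", 1, "ALA", "CA", 0.0, 0.0, 0.0)])
        assert asm.shell_containment(s, particle) == 0.0

    def test_discoid_rim_ring(self):
        """Atoms on the rim equator of the 200×200×110 Å discoid lie exactly
        on the surface: signed distance ≈ 0, inside any shell."""
        particle = asm.LDL_DISCOID
        theta = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        pts = np.column_stack(
            [100.0 * np.cos(theta), 100.0 * np.sin(theta), np.zeros_like(theta)]
        )
        sd = particle.signed_distance(pts)
        assert np.abs(sd).max() < 0.05
        s = Structure(
            [AtomRecord("A", i + 1, "ALA", "CA", *map(float, p)) for i, p in enumerate(pts)]
        )
        assert asm.shell_containment(s, particle) == 1.0

    def test_discoid_flat_faces(self):
        particle = asm.LDL_DISCOID
        # directly above the center: surface at z = 55
        sd = particle.signed_distance(np.array([[0.0, 0.0, 80.0], [0.0, 0.0, 0.0]]))
        assert sd[0] == pytest.approx(25.0, abs=1e-6)
        assert sd[1] == pytest.approx(-55.0, abs=1e-6)

    def test_invalid_particles_rejected(self):
        with pytest.raises(ValueError):
            asm.ParticleModel("sphere", -5.0)
        with pytest.raises(ValueError):
            asm.ParticleModel("cube", (1.0, 1.0, 1.0))
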