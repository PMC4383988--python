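"""Symmetry-operation enumeration, point-group classification, helical
detection, stoichiometry, and the full detection pipeline."""

import numpy as np
import pytest

from quatsym.seqcluster import cluster_chains
from quatsym.structure_io import Assembly, Chain
from quatsym.superpose import RigidTransform, axis_angle_matrix, rotation_parameters
from quatsym.symmetry import (
    Config,
    classify_point_group,
    compute_stoichiometry,
    detect_helical,
    detect_symmetry,
    enumerate_operations,
    standard_orientation,
)
from quatsym.synthetic import (
    GeneratorSpec,
    generate_helical_assembly,
    generate_point_group_assembly,
    make_subunit,
)

from oracles import (
    bin_rotation_angles,
    exhaustive_operations,
    screw_fit_centroids,
)


def _clusters(assembly, threshold=95.0):
    return cluster_chains(assembly.subunits, threshold)


class TestStoichiometry:
    def test_homopentamer(self):
        asm, _ = generate_point_group_assembly(GeneratorSpec("C", 5, seed=1))
        st = compute_stoichiometry(asm, _clusters(asm))
        assert st.composition == "A5"
        assert st.category == "homomer"

    def test_monomer(self):
        asm = Assembly("e", "1", [make_subunit(30, seed=0, chain_id="A_0")])
        st = compute_stoichiometry(asm, _clusters(asm))
        assert st.composition == "A"
        assert st.category == "monomer"

    def test_three_types_of_seven_matches_sorting_oracle(self):
        subunits = []
        for t, letter in enumerate("XYZ"):
            base = make_subunit(30, seed=50 + t, chain_id=letter)
            for k in range(7):
                subunits.append(
                    Chain(f"{letter}_{k}", base.sequence,
                          base.ca_coords + np.array([40.0 * t, 15.0 * k, 0.0]))
                )
        asm = Assembly("e", "1", subunits)
        st = compute_stoichiometry(asm, _clusters(asm))
        # oracle: sort counts descending, assign letters alphabetically
        counts = sorted((len(c) for c in _clusters(asm).clusters), reverse=True)
        expected = "".join(
            f"{chr(65 + i)}{n}" if n > 1 else chr(65 + i)
            for i, n in enumerate(counts)
        )
        assert st.composition == expected == "A7B7C7"
        assert st.category == "heteromer"

    def test_empty_assembly_reports_no_subunits(self):
        short = make_subunit(5, seed=3, chain_id="A_0")
        asm = Assembly("e", "1", [short])
        st = compute_stoichiometry(asm, _clusters(asm))
        assert st.category == "none"
        assert st.composition == ""


class TestEnumerateOperations:
    def test_perfect_trimer_yields_three_operations(self):
        asm, _ = generate_point_group_assembly(GeneratorSpec("C", 3, seed=2))
        ops = enumerate_operations(asm, _clusters(asm))
        assert len(ops) == 3
        assert all(op.rmsd <= 1e-6 for op in ops)
        angles = sorted(
            round(np.rad2deg(rotation_parameters(op.transform).angle))
            for op in ops
        )
        assert angles == [0, 120, 120]

    def test_unrelated_chains_give_identity_only(self):
        a = make_subunit(30, seed=10, chain_id="A_0")
        b = make_subunit(30, seed=11, chain_id="B_0")
        asm = Assembly("e", "1", [a, b])
        ops = enumerate_operations(asm, _clusters(asm))
        assert len(ops) == 1
        assert ops[0].is_identity()

    def test_d2_tetramer_matches_exhaustive_permutation_oracle(self):
        asm, _ = generate_point_group_assembly(GeneratorSpec("D", 2, seed=3))
        clusters = _clusters(asm)
        ops = enumerate_operations(asm, clusters)
        ids, oracle = exhaustive_operations(asm, clusters.clusters, cutoff=7.0)
        found = {tuple(op.permutation[i] for i in ids): op.rmsd for op in ops}
        assert set(found) == set(oracle)
        for key in oracle:
            assert found[key] == pytest.approx(oracle[key], abs=1e-6)
        # the three non-identity rotations are 180° about perpendicular axes
        non_id = [op for op in ops if not op.is_identity()]
        assert len(non_id) == 3
        aas = [rotation_parameters(op.transform) for op in non_id]
        assert all(aa.fold == 2 for aa in aas)
        for i in range(3):
            for j in range(i + 1, 3):
                assert abs(np.dot(aas[i].axis, aas[j].axis)) < 1e-6

    def test_accepted_set_is_closed_under_composition(self):
        asm, _ = generate_point_group_assembly(GeneratorSpec("D", 3, seed=4))
        ids = [s.chain_id for s in asm.subunits]
        ops = enumerate_operations(asm, _clusters(asm))
        keys = {tuple(op.permutation[i] for i in ids) for op in ops}
        for p in ops:
            for q in ops:
                comp = tuple(p.permutation[q.permutation[i]] for i in ids)
                assert comp in keys


class TestClassifyPointGroup:
    def test_cyclic_from_five_z_rotations(self):
        ids = [f"A_{k}" for k in range(5)]
        ops = []
        asm, _ = generate_point_group_assembly(GeneratorSpec("C", 5, seed=5))
        ops = enumerate_operations(asm, _clusters(asm))
        label, axes = classify_point_group(ops)
        assert label == "C5"
        assert len(axes) == 1
        assert axes[0].fold == 5
        assert np.allclose(np.abs(axes[0].axis), [0, 0, 1], atol=1e-6)

    def test_dihedral_seven(self):
        asm, _ = generate_point_group_assembly(GeneratorSpec("D", 7, seed=6))
        ops = enumerate_operations(asm, _clusters(asm))
        label, axes = classify_point_group(ops)
        assert label == "D7"
        folds = sorted((a.fold for a in axes), reverse=True)
        assert folds == [7] + [2] * 7

    def test_octahedral_axis_folds_match_angle_binning_oracle(self):
        asm, _ = generate_point_group_assembly(GeneratorSpec("O", seed=7))
        ops = enumerate_operations(asm, _clusters(asm))
        label, axes = classify_point_group(ops)
        assert label == "O"
        assert {a.fold for a in axes} == {4, 3, 2}
        oracle_folds = bin_rotation_angles(
            [op.transform.rotation for op in ops if not op.is_identity()]
        )
        # 90° and 270° rotations bin to fold 4, etc.
        assert sorted(f for f in oracle_folds if f) == sorted(
            [4] * 6 + [2] * 3 + [3] * 8 + [2] * 6
        )

    def test_single_operation_is_c1(self):
        from quatsym.symmetry import SymmetryOperation

        ops = [SymmetryOperation(RigidTransform.identity(), {"A_0": "A_0"}, 0.0)]
        label, axes = classify_point_group(ops)
        assert label == "C1"
        assert axes == []


class TestDetectHelical:
    def test_noiseless_screw_parameters_recovered(self):
        asm, _ = generate_helical_assembly(rise=5.0, twist=36.0, n=8, seed=8)
        hel = detect_helical(asm, _clusters(asm))
        assert hel is not None
        assert hel.rise == pytest.approx(5.0, abs=1e-3)
        assert hel.twist == pytest.approx(36.0, abs=1e-3)
        assert hel.n_subunits == 8

    def test_closed_ring_is_not_helical(self):
        asm, _ = generate_point_group_assembly(GeneratorSpec("C", 5, seed=9))
        assert detect_helical(asm, _clusters(asm)) is None

    @pytest.mark.parametrize("seed", range(20))
    def test_noisy_rise_matches_screw_fit_oracle(self, seed):
        asm, truth = generate_helical_assembly(
            rise=5.0, twist=36.0, n=10, noise_sd=0.3, seed=seed
        )
        hel = detect_helical(asm, _clusters(asm))
        assert hel is not None
        assert hel.rise == pytest.approx(5.0, abs=0.1)
        # oracle: screw fitted from consecutive centroid displacements
        order = np.argsort([c.centroid[2] for c in asm.subunits])
        centroids = np.array([asm.subunits[i].centroid for i in order])
        _, rise_oracle, twist_oracle = screw_fit_centroids(centroids)
        assert hel.rise == pytest.approx(rise_oracle, abs=0.1)
        assert hel.twist == pytest.approx(twist_oracle, abs=2.0)


class TestDetectSymmetry:
    def test_noiseless_homopentamer_ring(self):
        asm, _ = generate_point_group_assembly(GeneratorSpec("C", 5, seed=10))
        res = detect_symmetry(asm)
        assert res.stoichiometry.composition == "A5"
        assert res.group_label == "C5"
        assert res.max_rmsd <= 1e-6
        assert res.mode == "symmetric"
        assert res.order == 5

    def test_pseudo_symmetry_flip_on_divergent_trimer(self):
        asm, _ = generate_point_group_assembly(
            GeneratorSpec("C", 3, seq_identity_target=50.0, seed=11)
        )
        strict = detect_symmetry(asm, mode="symmetric")
        pseudo = detect_symmetry(asm, mode="pseudo")
        assert strict.group_label == "C1"
        assert strict.mode == "asymmetric"
        assert strict.stoichiometry.category == "heteromer"
        assert pseudo.group_label == "C3"
        assert pseudo.mode == "pseudo-symmetric"
        # oracle: the C3 geometry is exact, so the best non-identity
        # permutation passes any reasonable cutoff
        clusters = cluster_chains(asm.subunits, 30.0)
        _, oracle = exhaustive_operations(asm, clusters.clusters, cutoff=7.0)
        assert len(oracle) == 3

    def test_displaced_subunit_breaks_symmetry(self):
        asm, _ = generate_point_group_assembly(GeneratorSpec("C", 4, seed=12))
        moved = list(asm.subunits)
        bad = moved[2]
        moved[2] = Chain(bad.chain_id, bad.sequence,
                         bad.ca_coords + np.array([25.0, 0.0, 0.0]))
        broken = Assembly(asm.entry_id, asm.assembly_id, moved)
        res = detect_symmetry(broken)
        assert res.group_label == "C1"
        assert res.mode == "asymmetric"
        # oracle: no non-identity permutation superposes under 7 Å
        clusters = cluster_chains(broken.subunits, 95.0)
        _, oracle = exhaustive_operations(broken, clusters.clusters, cutoff=7.0)
        assert list(oracle.values()) == [pytest.approx(0.0, abs=1e-9)]

    def test_rigid_motion_invariance(self):
        asm, _ = generate_point_group_assembly(GeneratorSpec("D", 3, seed=13))
        res0 = detect_symmetry(asm)
        g = RigidTransform(
            axis_angle_matrix([1.0, -2.0, 0.5], 1.2), np.array([30.0, -12.0, 4.0])
        )
        moved = Assembly(
            asm.entry_id, asm.assembly_id,
            [s.transformed(g) for s in asm.subunits],
        )
        res1 = detect_symmetry(moved)
        assert res1.group_label == res0.group_label == "D3"
        assert res1.stoichiometry.composition == res0.stoichiometry.composition
        assert res1.max_rmsd == pytest.approx(res0.max_rmsd, abs=1e-6)

    def test_relabeling_invariance(self):
        asm, _ = generate_point_group_assembly(GeneratorSpec("C", 4, seed=14))
        renamed = Assembly(
            asm.entry_id, asm.assembly_id,
            [Chain(f"zz_{9 - i}", s.sequence, s.ca_coords)
             for i, s in enumerate(asm.subunits)],
        )
        res0, res1 = detect_symmetry(asm), detect_symmetry(renamed)
        assert res1.group_label == res0.group_label
        assert res1.stoichiometry.composition == res0.stoichiometry.composition

    def test_max_rmsd_nondecreasing_in_noise(self):
        levels = [0.0, 0.5, 1.0, 2.0]
        rmsds = []
        for sd in levels:
            vals = []
            for seed in range(5):
                asm, _ = generate_point_group_assembly(
                    GeneratorSpec("C", 4, noise_sd=sd, seed=seed)
                )
                vals.append(detect_symmetry(asm).max_rmsd)
            rmsds.append(np.mean(vals))
        assert all(a <= b + 1e-9 for a, b in zip(rmsds, rmsds[1:]))

    def test_symmetric_implies_pseudo_with_equal_or_higher_order(self):
        for spec in (GeneratorSpec("C", 6, seed=15), GeneratorSpec("D", 2, seed=16)):
            asm, _ = generate_point_group_assembly(spec)
            strict = detect_symmetry(asm, mode="symmetric")
            pseudo = detect_symmetry(asm, mode="pseudo")
            assert strict.group_label != "C1"
            assert pseudo.order >= strict.order

    def test_monomer_is_asymmetric(self):
        asm = Assembly("e", "1", [make_subunit(30, seed=17, chain_id="A_0")])
        res = detect_symmetry(asm)
        assert res.group_label == "C1"
        assert res.mode == "asymmetric"

    def test_short_chains_excluded_but_reported(self):
        asm, _ = generate_point_group_assembly(GeneratorSpec("C", 3, seed=18))
        extra = make_subunit(10, seed=19, chain_id="tiny_0")
        padded = Assembly(asm.entry_id, asm.assembly_id, asm.subunits + [extra])
        res = detect_symmetry(padded)
        assert res.group_label == "C3"
        assert res.excluded_subunits == ["tiny_0"]

    def test_helical_assembly_labeled_h(self):
        asm, _ = generate_helical_assembly(rise=5.0, twist=36.0, n=10, seed=20)
        res = detect_symmetry(asm)
        assert res.group_label == "H"
        assert res.helical is not None
        assert res.helical.rise == pytest.approx(5.0, abs=1e-3)


class TestStandardOrientation:
    def test_c5_principal_axis_moves_to_plus_z(self):
        asm, _ = generate_point_group_assembly(GeneratorSpec("C", 5, seed=21))
        tilt = RigidTransform(
            axis_angle_matrix(np.cross([0, 0, 1], [1, 1, 1]),
                              np.arccos(1 / np.sqrt(3))),
            np.zeros(3),
        )
        tilted = Assembly(asm.entry_id, asm.assembly_id,
                          [s.transformed(tilt) for s in asm.subunits])
        res = detect_symmetry(tilted)
        axis = res.axes[0].axis
        assert np.allclose(np.abs(axis), np.abs([1, 1, 1] / np.sqrt(3)), atol=1e-6)
        T = standard_orientation(res)
        assert np.allclose(T.rotation @ axis, [0, 0, 1], atol=1e-9)

    def test_reorientation_after_applying_once_is_identity(self):
        asm, _ = generate_point_group_assembly(GeneratorSpec("D", 3, seed=22))
        res = detect_symmetry(asm)
        T = standard_orientation(res)
        oriented = Assembly(asm.entry_id, asm.assembly_id,
                            [s.transformed(T) for s in asm.subunits])
        res2 = detect_symmetry(oriented)
        T2 = standard_orientation(res2)
        assert np.allclose(T2.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(T2.translation, 0.0, atol=1e-6)

    def test_d3_two_folds_land_in_xy_plane(self):
        asm, _ = generate_point_group_assembly(GeneratorSpec("D", 3, seed=23))
        g = RigidTransform(axis_angle_matrix([1.0, 0.3, -0.2], 0.9),
                           np.array([5.0, 5.0, 5.0]))
        moved = Assembly(asm.entry_id, asm.assembly_id,
                         [s.transformed(g) for s in asm.subunits])
        res = detect_symmetry(moved)
        T = standard_orientation(res)
        two_folds = [a.axis for a in res.axes if a.fold == 2]
        assert len(two_folds) == 3
        for axis in two_folds:
            assert abs((T.rotation @ axis)[2]) < 1e-9  # direct dot with z

    def test_c1_has_no_orientation(self):
        asm = Assembly("e", "1", [make_subunit(30, seed=24, chain_id="A_0")])
        res = detect_symmetry(asm)
        with pytest.raises(ValueError):
            standard_orientation(res)


def test_config_rejects_bad_values():
    with pytest.raises(ValueError):
        Config(rmsd_cutoff=-1.0)
    with pytest.raises(ValueError):
        Config(identity_threshold_pseudo=150.0)
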