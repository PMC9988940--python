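"""Fragment tiling geometry, Kabsch superposition, PDB I/O with pLDDT, and
fragment stitching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from afmissense.simulate import fragment_and_perturb, simulate_structure
from afmissense.structure import (
    Atom,
    DegenerateGeometryError,
    Fragment,
    PlddtRangeError,
    Provenance,
    ResidueModel,
    StitchError,
    StructureModel,
    fragment_overlap,
    global_plddt,
    kabsch_superpose,
    plan_fragments,
    read_pdb_with_plddt,
    stitch_fragments,
    write_pdb,
)


class TestPlanFragments:
    def test_long_chain_tiling_geometry(self):
        plan = plan_fragments(3418, 1400, 200)
        assert len(plan) == 12
        assert plan.fragments[0] == (1, 1400)
        assert plan.fragments[1] == (201, 1600)
        last = plan.fragments[-1]
        assert last == (2201, 3418)
        assert last[1] - last[0] + 1 == 1218

    def test_medium_chain_fragment_count(self):
        assert len(plan_fragments(3056, 1400, 200)) == 10

    def test_chain_shorter_than_window_is_single_fragment(self):
        plan = plan_fragments(1000, 1400, 200)
        assert plan.fragments == ((1, 1000),)

    @pytest.mark.parametrize("args", [(0, 1400, 200), (100, 0, 0), (100, 10, 20)])
    def test_invalid_arguments(self, args):
        with pytest.raises(ValueError):
            plan_fragments(*args)

    @given(
        length=st.integers(1, 5000),
        window=st.integers(1, 2000),
        stride=st.integers(1, 2000),
    )
    @settings(deadline=None, max_examples=200)
    def test_tiling_invariants(self, length, window, stride):
        if window < stride:
            window, stride = stride, window
        plan = plan_fragments(length, window, stride)
        starts = [s for s, _ in plan.fragments]
        ends = [e for _, e in plan.fragments]
        assert starts[0] == 1 and ends[-1] == length
        assert starts == [1 + k * stride for k in range(len(plan))]
        assert all(e == min(s + window - 1, length) for s, e in plan.fragments)
        # union covers [1, length]: consecutive fragments meet or overlap
        assert all(s2 <= e1 + 1 for (_, e1), (s2, _) in zip(plan.fragments, plan.fragments[1:]))


class TestFragmentOverlap:
    def test_consecutive_overlap_equals_window_minus_stride(self):
        plan = plan_fragments(3418, 1400, 200)
        assert fragment_overlap(plan, "F1", "F2") == 1200

    def test_distant_fragments(self):
        plan = plan_fragments(3056, 1400, 200)
        assert fragment_overlap(plan, "F1", "F7") == 200
        assert fragment_overlap(plan, "F1", "F10") == 0

    def test_unknown_label_is_error(self):
        plan = plan_fragments(1000, 1400, 200)
        with pytest.raises(KeyError):
            fragment_overlap(plan, "F1", "F9")


def random_rigid(rng):
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.normal(0, 10, 3)
    return R, t


class TestKabsch:
    def test_identical_point_sets(self, rng):
        pts = rng.normal(size=(10, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_exact_rigid_motion_recovered(self, rng):
        pts = rng.normal(size=(8, 3))
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ Rz.T + np.array([1.0, 2.0, 3.0])
        res = kabsch_superpose(moved, pts)
        assert res.rmsd < 1e-9
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rmsd_matches_iterative_rotation_search_oracle(self, rng):
        mobile = rng.normal(size=(4, 3))
        reference = mobile + rng.normal(0, 0.3, size=(4, 3))
        res = kabsch_superpose(mobile, reference)

        cm, cr = mobile.mean(0), reference.mean(0)
        P0, Q0 = mobile - cm, reference - cr

        def cost(rotvec):
            R = Rotation.from_rotvec(rotvec).as_matrix()
            return np.sqrt(((P0 @ R.T - Q0) ** 2).sum() / len(P0))

        best = np.inf
        for _ in range(60):  # multi-start iterative refinement over rotations
            x0 = rng.normal(0, np.pi / 2, 3)
            out = minimize(cost, x0, method="Nelder-Mead",
                           options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
            best = min(best, out.fun)
        assert res.rmsd == pytest.approx(best, abs=1e-6)

    def test_reflection_never_chosen(self, rng):
        pts = rng.normal(size=(6, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        res = kabsch_superpose(mirrored, pts)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
        assert res.rmsd > 0.01  # a proper rotation cannot undo a reflection here

    def test_rmsd_invariant_under_joint_rigid_pretransform(self, rng):
        mobile = rng.normal(size=(7, 3))
        reference = rng.normal(size=(7, 3))
        base = kabsch_superpose(mobile, reference).rmsd
        R, t = random_rigid(rng)
        again = kabsch_superpose(mobile @ R.T + t, reference @ R.T + t).rmsd
        assert again == pytest.approx(base, abs=1e-9)

    def test_too_few_points(self, rng):
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))

    def test_collinear_points_degenerate(self):
        line = np.outer(np.arange(5, dtype=float), np.array([1.0, 0.0, 0.0]))
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)


class TestPdbIO:
    def test_plddt_read_from_ca_bfactor(self, tmp_path):
        model = simulate_structure(3, plddt_profile=[90.0, 50.0, 30.0])
        path = tmp_path / "m.pdb"
        write_pdb(model, path)
        back = read_pdb_with_plddt(path)
        assert list(back.plddt_values()) == [90.0, 50.0, 30.0]

    def test_round_trip_precision(self, tmp_path, rng):
        model = simulate_structure(40, plddt_profile=list(rng.uniform(20, 99, 40).round(2)))
        path = tmp_path / "m.pdb"
        write_pdb(model, path)
        back = read_pdb_with_plddt(path)
        assert np.allclose(back.ca_coords(), model.ca_coords(), atol=1.5e-3)
        assert np.allclose(back.plddt_values(), model.plddt_values(), atol=5e-3)
        # second round trip is exact at PDB fixed-width precision
        path2 = tmp_path / "m2.pdb"
        write_pdb(back, path2)
        again = read_pdb_with_plddt(path2)
        assert np.array_equal(again.ca_coords(), back.ca_coords())
        assert np.array_equal(again.plddt_values(), back.plddt_values())

    def test_bfactor_outside_plddt_range_rejected(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00101.20           C\n"
            "END\n"
        )
        with pytest.raises(PlddtRangeError):
            read_pdb_with_plddt(path)

    def test_hetatm_only_file_yields_empty_model(self, tmp_path):
        path = tmp_path / "het.pdb"
        path.write_text(
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00 20.00           O\n"
            "END\n"
        )
        with pytest.warns(UserWarning):
            model = read_pdb_with_plddt(path)
        assert len(model) == 0

    def test_residue_without_ca_kept_with_warning(self, tmp_path):
        path = tmp_path / "noca.pdb"
        path.write_text(
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 90.00           N\n"
            "ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00 80.00           C\n"
            "END\n"
        )
        with pytest.warns(UserWarning, match="no CA"):
            model = read_pdb_with_plddt(path)
        assert len(model) == 2
        assert model.residues[0].plddt is None
        assert model.residues[1].plddt == 80.0


class TestGlobalPlddt:
    def test_constant(self):
        m = simulate_structure(3, [80.0] * 3)
        assert global_plddt(m) == 80.0

    def test_even_count_midpoint(self):
        m = simulate_structure(4, [10.0, 20.0, 30.0, 40.0])
        assert global_plddt(m) == 25.0

    def test_half_step_median_representable(self):
        m = simulate_structure(2, [92.62, 92.63])
        assert global_plddt(m) == 92.625

    def test_no_plddt_is_error(self):
        m = StructureModel(
            "X",
            [ResidueModel(1, "A", [Atom("CA", "C", np.zeros(3))], None)],
            Provenance.SYNTHETIC,
        )
        with pytest.raises(ValueError):
            global_plddt(m)


class TestStitchFragments:
    def make_fragments(self, length=600, window=400, stride=200, seed=42, **kwargs):
        profile = list(np.linspace(30.0, 95.0, length).round(2))
        model = simulate_structure(length, plddt_profile=profile)
        plan = plan_fragments(length, window, stride)
        return model, fragment_and_perturb(model, plan, seed=seed, **kwargs)

    def test_recovers_original_chain(self):
        model, frags = self.make_fragments()
        stitched, joins = stitch_fragments(frags, min_overlap=200)
        assert [r.index for r in stitched.residues] == list(range(1, 601))
        sup = kabsch_superpose(stitched.ca_coords(), model.ca_coords())
        assert sup.rmsd < 1e-6
        assert sorted(stitched.plddt_values()) == sorted(model.plddt_values())
        assert all(j.rmsd < 1e-6 for j in joins)

    def test_single_fragment_is_identity(self):
        model, frags = self.make_fragments(length=300, window=400, zero_rotation=True)
        stitched, joins = stitch_fragments(frags)
        assert joins == []
        assert np.allclose(stitched.ca_coords(), model.ca_coords())

    def test_three_fragments_two_join_records(self):
        # F1=(1,400), F2=(101,500), F4=(301,700): pairwise overlaps 300 and 200
        model, frags = self.make_fragments(length=800, window=400, stride=100, seed=3)
        stitched, joins = stitch_fragments([frags[0], frags[1], frags[3]], min_overlap=1)
        assert len(joins) == 2
        assert len(stitched) == 700
        assert [(j.earlier, j.later) for j in joins] == [("F1", "F2"), ("F2", "F4")]
        assert [j.overlap for j in joins] == [300, 200]

    def test_selection_by_label(self):
        model, frags = self.make_fragments(length=800, window=400, stride=100)
        stitched, joins = stitch_fragments(frags, selection=["F1", "F3", "F5"])
        assert len(stitched) == 800
        assert [j.overlap for j in joins] == [200, 200]

    def test_overlap_below_minimum_is_error(self):
        _, frags = self.make_fragments(length=800, window=400, stride=100)
        with pytest.raises(StitchError):
            stitch_fragments(frags, selection=["F1", "F3"], min_overlap=300)

    def test_bad_join_warns_but_proceeds(self, rng):
        model, frags = self.make_fragments()
        # corrupt the second fragment's overlap geometry non-rigidly
        noisy = frags[1].model
        for res in noisy.residues[:200]:
            for atom in res.atoms:
                atom.coord = atom.coord + rng.normal(0, 5, 3)
        with pytest.warns(UserWarning, match="exceeds QC threshold"):
            stitched, joins = stitch_fragments(frags, qc_rmsd_threshold=1.0)
        assert joins[0].warned
        assert len(stitched) == 600
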