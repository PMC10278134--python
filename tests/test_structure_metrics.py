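"""Trajectory geometry metrics against constructions and oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blufspec import (
    DihedralSpec,
    FixtureConfig,
    HBondSpec,
    HelixVectorSpec,
    TrajectoryView,
    backbone_rmsd,
    gen_hb_trajectory,
    gen_helix_pair,
    gen_sheet_quad,
    hbond_occupancy,
    interhelical_angle,
    metric_distributions,
    sheet_dihedral,
)
from blufspec.errors import (
    DegenerateGeometryError,
    SelectionError,
    ValidationError,
)
from conftest import random_rigid_motion

HB_SPEC = HBondSpec(
    donor={"atom_name": "ND2"},
    hydrogen={"atom_name": "HD21"},
    acceptor={"atom_name": "O4"},
)

HELIX_SPEC = HelixVectorSpec(
    helix1_start=[1, 2, 3, 4],
    helix1_end=[19, 20, 21, 22],
    helix2_start=[101, 102, 103, 104],
    helix2_end=[119, 120, 121, 122],
)


def triad(d, h, a):
    return TrajectoryView(
        coords=np.array([[d, h, a]], dtype=float),
        atom_names=["ND2", "HD21", "O4"],
        res_names=["ASN", "ASN", "FMN"],
        res_ids=np.array([45, 45, 200]),
    )


def quad_view(points):
    return TrajectoryView(
        coords=np.asarray(points, dtype=float)[None],
        atom_names=["CA"] * 4,
        res_names=["SER", "LEU", "GLY", "GLU"],
        res_ids=np.array([18, 50, 59, 89]),
    )


def torsion_oracle(p0, p1, p2, p3):
    """Signed torsion via the vector-triple-product formula (brute force)."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    return np.degrees(np.arctan2(y, x))


class TestHBondOccupancy:
    def test_linear_inside_both_cutoffs_is_bonded(self):
        occ, _ = hbond_occupancy(
            triad([0, 0, 0], [1, 0, 0], [2.8, 0, 0]), HB_SPEC
        )
        assert occ == 1.0

    def test_long_distance_not_bonded(self):
        occ, _ = hbond_occupancy(
            triad([0, 0, 0], [1, 0, 0], [3.5, 0, 0]), HB_SPEC
        )
        assert occ == 0.0

    def test_bent_angle_not_bonded(self):
        # D-A distance fine, but the angle at H is ~90 degrees
        occ, _ = hbond_occupancy(
            triad([0, 0, 0], [1, 0, 0], [1.0, 2.8, 0]), HB_SPEC
        )
        assert occ == 0.0

    def test_constructed_fraction_exact(self):
        traj = gen_hb_trajectory(
            FixtureConfig(seed=17, n_frames=1000, hb_fraction=0.37)
        )
        occ, bonded = hbond_occupancy(traj, HB_SPEC)
        assert occ == 0.37
        assert bonded.sum() == 370

    def test_unresolvable_selector_names_the_selector(self):
        traj = gen_hb_trajectory(FixtureConfig(seed=1, n_frames=5))
        bad = HBondSpec(
            donor={"atom_name": "XX9"},
            hydrogen={"atom_name": "HD21"},
            acceptor={"atom_name": "O4"},
        )
        with pytest.raises(SelectionError, match="XX9"):
            hbond_occupancy(traj, bad)

    def test_acceptor_vertex_convention_differs(self):
        """The configurable angle vertex changes the verdict for bent triads."""
        view = triad([0, 0, 0], [1, 0, 0], [1.0, 2.8, 0])
        spec_acc = HBondSpec(
            donor={"atom_name": "ND2"},
            hydrogen={"atom_name": "HD21"},
            acceptor={"atom_name": "O4"},
            angle_vertex="acceptor",
        )
        occ_h, _ = hbond_occupancy(view, HB_SPEC)
        occ_a, _ = hbond_occupancy(view, spec_acc)
        assert (occ_h, occ_a) == (0.0, 0.0) or occ_h != occ_a


class TestInterhelicalAngle:
    def test_translated_copy_is_parallel(self):
        traj = gen_helix_pair(0.0)
        assert interhelical_angle(traj, HELIX_SPEC)[0] == pytest.approx(0.0, abs=1e-9)

    def test_antiparallel_is_180(self):
        traj = gen_helix_pair(180.0)
        assert interhelical_angle(traj, HELIX_SPEC)[0] == pytest.approx(180.0, abs=1e-9)

    @pytest.mark.parametrize("angle", [10.0, 25.0, 47.5, 90.0, 135.0])
    def test_constructed_angles_recovered(self, angle):
        traj = gen_helix_pair(angle)
        assert interhelical_angle(traj, HELIX_SPEC)[0] == pytest.approx(angle, abs=2.0)

    def test_zero_length_vector_degenerate(self):
        traj = gen_helix_pair(25.0)
        collapsed = TrajectoryView(
            coords=np.tile(traj.coords[:, :1], (1, traj.n_atoms, 1)),
            atom_names=traj.atom_names,
            res_names=traj.res_names,
            res_ids=traj.res_ids,
        )
        with pytest.raises(DegenerateGeometryError):
            interhelical_angle(collapsed, HELIX_SPEC)


class TestSheetDihedral:
    SPEC = DihedralSpec(residues=[18, 50, 59, 89])

    def test_planar_cis_is_zero(self):
        view = quad_view([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]])
        assert sheet_dihedral(view, self.SPEC)[0] == pytest.approx(0.0, abs=1e-10)

    def test_planar_trans_is_180(self):
        view = quad_view([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]])
        assert abs(sheet_dihedral(view, self.SPEC)[0]) == pytest.approx(180.0, abs=1e-10)

    def test_right_angle_sign_matches_oracle(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 1]], dtype=float)
        got = sheet_dihedral(quad_view(pts), self.SPEC)[0]
        assert got == pytest.approx(torsion_oracle(*pts), abs=1e-10)
        assert abs(got) == pytest.approx(90.0, abs=1e-10)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_random_quads_match_triple_product_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-5, 5, (4, 3))
        b2 = pts[2] - pts[1]
        n1 = np.cross(pts[1] - pts[0], b2)
        n2 = np.cross(b2, pts[3] - pts[2])
        if min(np.linalg.norm(n1), np.linalg.norm(n2)) < 1e-3:
            return  # near-degenerate draw
        got = sheet_dihedral(quad_view(pts), self.SPEC)[0]
        assert got == pytest.approx(torsion_oracle(*pts), abs=1e-8)

    def test_matches_mdanalysis_cross_check(self):
        """Independent route: MDAnalysis' torsion on the same quadruple."""
        from MDAnalysis.lib.distances import calc_dihedrals

        rng = np.random.default_rng(23)
        pts = rng.uniform(-5, 5, (4, 3))
        ours = sheet_dihedral(quad_view(pts), self.SPEC)[0]
        theirs = np.degrees(
            calc_dihedrals(
                pts[0][None].astype(np.float64),
                pts[1][None],
                pts[2][None],
                pts[3][None],
            )[0]
        )
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_collinear_triple_degenerate(self):
        view = quad_view([[0, 0, 0], [1, 0, 0], [2, 0, 0], [2, 1, 0]])
        with pytest.raises(DegenerateGeometryError):
            sheet_dihedral(view, self.SPEC)

    def test_mirror_reflection_flips_sign(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 1]], dtype=float)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        a = sheet_dihedral(quad_view(pts), self.SPEC)[0]
        b = sheet_dihedral(quad_view(mirrored), self.SPEC)[0]
        assert b == pytest.approx(-a, abs=1e-10)


class TestBackboneRMSD:
    def test_self_is_zero(self):
        traj = gen_helix_pair(25.0, n_frames=1)
        assert backbone_rmsd(traj, backbone_names=("CA",))[0] == pytest.approx(
            0.0, abs=1e-12
        )

    def test_rigid_copy_is_zero_within_1e8(self):
        traj = gen_helix_pair(25.0, n_frames=4, rigid_motion=True)
        assert np.all(backbone_rmsd(traj, backbone_names=("CA",)) < 1e-8)

    def test_single_displaced_atom_closed_form(self):
        """One atom moved by d among N gives ~ d/sqrt(N) after superposition."""
        rng = np.random.default_rng(6)
        base = rng.uniform(-8, 8, (100, 3))
        moved = base.copy()
        moved[0] += np.array([1.0, 0.0, 0.0])
        traj = TrajectoryView(
            coords=np.stack([base, moved]),
            atom_names=["CA"] * 100,
            res_names=["ALA"] * 100,
            res_ids=np.arange(1, 101),
        )
        rmsd = backbone_rmsd(traj, backbone_names=("CA",))
        assert rmsd[1] == pytest.approx(0.1, rel=0.01)

    def test_exclusion_ranges_drop_residues(self):
        traj = gen_helix_pair(25.0, n_frames=2)
        full = backbone_rmsd(traj, backbone_names=("CA",))
        partial = backbone_rmsd(
            traj, backbone_names=("CA",), exclude_residues=[(1, 10)]
        )
        assert np.all(full < 1e-12) and np.all(partial < 1e-12)

    def test_empty_selection_rejected(self):
        traj = gen_helix_pair(25.0)
        with pytest.raises(ValidationError):
            backbone_rmsd(traj, backbone_names=("N",))


class TestRigidMotionInvariance:
    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_all_metrics_invariant(self, seed):
        """Occupancy, angle and dihedral unchanged by rotation+translation."""
        rng = np.random.default_rng(seed)
        rot, trans = random_rigid_motion(rng)

        hb = gen_hb_trajectory(
            FixtureConfig(seed=seed, n_frames=20, hb_fraction=0.4),
            rigid_motion=False,
        )
        helix = gen_helix_pair(33.0)
        quad = gen_sheet_quad(42.0)
        for traj, metric in (
            (hb, lambda t: hbond_occupancy(t, HB_SPEC)[0]),
            (helix, lambda t: interhelical_angle(t, HELIX_SPEC)[0]),
            (quad, lambda t: sheet_dihedral(t, DihedralSpec(residues=[18, 50, 59, 89]))[0]),
        ):
            moved = TrajectoryView(
                coords=traj.coords @ rot.T + trans,
                atom_names=traj.atom_names,
                res_names=traj.res_names,
                res_ids=traj.res_ids,
            )
            assert metric(moved) == pytest.approx(metric(traj), abs=1e-8)


class TestMetricDistributions:
    def test_single_valued_series_occupies_one_bin(self):
        dists = metric_distributions({"dark": np.full(10, 25.0)}, bins=5)
        assert np.count_nonzero(dists["dark"].counts) == 1

    def test_identical_series_identical_histograms(self):
        v = np.random.default_rng(2).normal(20.0, 2.0, 500)
        dists = metric_distributions({"a": v, "b": v.copy()}, bins=30)
        assert np.array_equal(dists["a"].counts, dists["b"].counts)
        assert np.array_equal(dists["a"].edges, dists["b"].edges)

    def test_gaussian_histogram_mean(self):
        rng = np.random.default_rng(4)
        v = rng.normal(30.0, 3.0, 4000)
        dists = metric_distributions({"light": v}, bins=60)
        se = 3.0 / np.sqrt(len(v))
        assert abs(dists["light"].mean - 30.0) < 3 * se + 0.1
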