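"""Superposition, χ1 dihedrals, open/closed classifiers and macrostates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flexprobe.conformational_states import (
    CLOSED,
    OPEN,
    DihedralReference,
    MacrostateSeries,
    StateLabelSeries,
    chi1,
    circular_distance_deg,
    classify_by_chi1,
    classify_by_rmsd,
    classify_trajectory,
    dihedral,
    macrostate_series,
    rmsd_series,
    rotamer_histogram2d,
    rmsd_reference_from_frame,
    superpose,
)
from flexprobe.structure_io import AtomSelection, Frame, Trajectory
from flexprobe.synthetic_data import (
    TwoStateModel,
    build_residue,
    default_chi1_references,
    default_rmsd_references,
    generate_two_state_trajectory,
)

from conftest import make_frame, make_trajectory


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


class TestSuperpose:
    def test_identical_sets_give_identity(self, rng):
        pts = rng.normal(size=(10, 3))
        rot, trans, fit = superpose(pts, pts)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(trans, np.zeros(3), atol=1e-10)
        assert fit == pytest.approx(0.0, abs=1e-10)

    def test_pure_translation_recovered(self, rng):
        pts = rng.normal(size=(8, 3))
        shift = np.array([1.0, 2.0, 3.0])
        rot, trans, fit = superpose(pts, pts + shift)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(trans, shift, atol=1e-10)
        assert fit == pytest.approx(0.0, abs=1e-10)

    def test_random_rotation_recovered(self, rng):
        pts = rng.normal(size=(10, 3))
        rot_true = random_rotation(rng)
        rot, trans, fit = superpose(pts, pts @ rot_true.T)
        assert fit == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(rot, rot_true, atol=1e-6)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_degenerate_collinear_points_error(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="degenerate"):
            superpose(pts, pts)

    def test_too_few_points_error(self):
        pts = np.zeros((2, 3))
        with pytest.raises(ValueError, match="at least 3"):
            superpose(pts, pts)


class TestRmsdSeries:
    @pytest.fixture
    def traj_and_ref(self):
        model = TwoStateModel(p_open=0.5, seed=3, noise_sigma=0.0)
        traj, _ = generate_two_state_trajectory(model, 6)
        return traj, traj.frames[0]

    def test_reference_against_itself_is_zero(self, traj_and_ref):
        traj, ref = traj_and_ref
        sel = AtomSelection(atom_class="backbone")
        single = Trajectory((ref,), frame_interval_ns=0.1)
        series = rmsd_series(single, ref, sel, sel)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-10)

    def test_rigid_motion_removed_by_superposition(self, traj_and_ref, rng):
        traj, ref = traj_and_ref
        rot = random_rotation(rng)
        shift = rng.normal(size=3) * 5
        moved_frames = tuple(
            f.with_coordinates(f.coordinates() @ rot.T + shift)
            for f in Trajectory((ref,) * 3, frame_interval_ns=0.1).frames
        )
        moved = Trajectory(moved_frames, frame_interval_ns=0.1)
        sel = AtomSelection(atom_class="all-heavy")
        series = rmsd_series(moved, ref, sel, sel)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-8)

    def test_unit_displacement_after_core_superposition(self):
        # core stays fixed; measured atom moves 1 Å: RMSD reads exactly 1
        core = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]], float)
        ref = make_frame(
            np.vstack([core, [[1, 1, 1]]]),
            names=["C1", "C2", "C3", "C4", "CM"],
        )
        displaced = make_frame(
            np.vstack([core, [[2, 1, 1]]]),
            names=["C1", "C2", "C3", "C4", "CM"],
        )
        traj = Trajectory((displaced,), frame_interval_ns=0.1)
        sup = AtomSelection(atom_class="named", atom_names=("C1", "C2", "C3", "C4"))
        mea = AtomSelection(atom_class="named", atom_names=("CM",))
        series = rmsd_series(traj, ref, mea, sup)
        assert series.values[0] == pytest.approx(1.0, abs=1e-10)

    def test_selection_mismatch_errors(self, traj_and_ref):
        traj, ref = traj_and_ref
        other = make_frame(np.zeros((2, 3)), names=["X1", "X2"])
        sel = AtomSelection(atom_class="all-heavy")
        with pytest.raises(ValueError, match="different atoms"):
            rmsd_series(traj, other, sel, sel)


class TestChi1:
    def test_planar_cis_is_zero(self):
        p = [np.array(v, float) for v in
             [[1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0]]]
        assert dihedral(*p) == pytest.approx(0.0)

    def test_trans_is_180(self):
        p = [np.array(v, float) for v in
             [[1, 1, 0], [0, 1, 0], [0, 0, 0], [-1, -1, 0]]]
        assert abs(dihedral(*p)) == pytest.approx(180.0)

    def test_matches_independent_two_plane_oracle(self, rng):
        for _ in range(25):
            p0, p1, p2, p3 = rng.normal(size=(4, 3)) * 3
            # oracle: angle between plane normals, signed by triple product
            n1 = np.cross(p1 - p0, p2 - p1)
            n2 = np.cross(p2 - p1, p3 - p2)
            cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
            mag = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            sign = np.sign(np.dot(np.cross(n1, n2), p2 - p1)) or 1.0
            expected = sign * mag
            assert dihedral(p0, p1, p2, p3) == pytest.approx(expected, abs=1e-8)

    def test_template_chi1_round_trips(self):
        for target in (-60.0, 60.0, 180.0, 47.3):
            frame = Frame(build_residue("ILE", target))
            assert chi1(frame, "A", 66) == pytest.approx(target, abs=1e-8)

    def test_missing_atom_named_in_error(self):
        frame = Frame(build_residue("ILE", -60.0)[:2])  # N, CA only
        with pytest.raises(KeyError, match="CB"):
            chi1(frame, "A", 66)

    def test_ala_has_no_chi1(self):
        frame = make_frame(
            np.eye(3), names=["N", "CA", "CB"], resname="ALA",
            elements=["N", "C", "C"],
        )
        with pytest.raises(ValueError, match="no χ1"):
            chi1(frame, "A", 1)


class TestClassifyByChi1:
    def refs(self, open_angle=-65.0, closed_angle=170.0):
        return (
            DihedralReference("A", 66, open_angle, OPEN),
            DihedralReference("A", 66, closed_angle, CLOSED),
        )

    def frame_at(self, angle):
        return Frame(build_residue("ILE", angle))

    def test_nearest_reference_wins(self):
        assert classify_by_chi1(self.frame_at(-60.0), *self.refs()) == OPEN

    def test_circular_distance_wraps(self):
        # −175° is 15° from 170° across the branch cut, 110° from −65°
        assert classify_by_chi1(self.frame_at(-175.0), *self.refs()) == CLOSED

    def test_exact_tie_resolves_closed(self):
        # degenerate references at the same angle: distances exactly equal
        open_ref, closed_ref = self.refs(-60.0, -60.0)
        assert classify_by_chi1(self.frame_at(-60.0), open_ref, closed_ref) == CLOSED

    @given(st.integers(min_value=-2, max_value=2))
    @settings(max_examples=5, deadline=None)
    def test_invariant_under_360_shifts(self, k):
        open_ref, closed_ref = self.refs()
        base = classify_by_chi1(self.frame_at(-60.0), open_ref, closed_ref)
        d_open = circular_distance_deg(-60.0 + 360.0 * k, open_ref.chi1_deg)
        d_closed = circular_distance_deg(-60.0 + 360.0 * k, closed_ref.chi1_deg)
        shifted = OPEN if d_open < d_closed else CLOSED
        assert shifted == base


class TestClassifyByRmsd:
    @pytest.fixture
    def refs(self):
        model = TwoStateModel(p_open=0.5, seed=0)
        return default_rmsd_references(model)

    def test_frame_at_open_reference_is_open(self, refs):
        open_ref, closed_ref = refs
        frame = Frame(build_residue("ASN", -60.0))
        assert classify_by_rmsd(frame, open_ref, closed_ref) == OPEN

    def test_frame_at_closed_reference_is_closed(self, refs):
        open_ref, closed_ref = refs
        frame = Frame(build_residue("ASN", 180.0))
        assert classify_by_rmsd(frame, open_ref, closed_ref) == CLOSED

    def test_exact_midpoint_resolves_closed(self, refs):
        open_ref, closed_ref = refs
        mid_coords = 0.5 * (open_ref.coords + closed_ref.coords)
        frame = make_frame(
            mid_coords,
            names=list(open_ref.atom_names),
            resnums=[66] * len(open_ref.atom_names),
            resname="ASN",
        )
        assert classify_by_rmsd(frame, open_ref, closed_ref) == CLOSED

    def test_invariant_under_rigid_motion_with_core(self, rng):
        # references carrying core coordinates let classification undo a
        # global rigid motion of the frame
        model = TwoStateModel(p_open=0.5, seed=4)
        core_sel = AtomSelection(atom_class="backbone")
        frame = Frame(build_residue("ASN", -60.0))
        open_ref = rmsd_reference_from_frame(frame, "A", 66, OPEN,
                                             core_selection=core_sel)
        closed_frame = Frame(build_residue("ASN", 180.0))
        closed_ref = rmsd_reference_from_frame(closed_frame, "A", 66, CLOSED,
                                               core_selection=core_sel)
        rot = random_rotation(rng)
        shift = rng.normal(size=3) * 10
        moved = frame.with_coordinates(frame.coordinates() @ rot.T + shift)
        assert classify_by_rmsd(moved, open_ref, closed_ref) == OPEN

    def test_mismatched_reference_atom_sets_error(self, refs):
        open_ref, closed_ref = refs
        import dataclasses

        bad_closed = dataclasses.replace(
            closed_ref,
            atom_names=tuple(reversed(closed_ref.atom_names)),
        )
        frame = Frame(build_residue("ASN", 180.0))
        with pytest.raises(ValueError, match="identical atom-name set"):
            classify_by_rmsd(frame, open_ref, bad_closed)


class TestClassifyTrajectory:
    def test_all_frames_at_open_reference_label_open(self):
        model = TwoStateModel(p_open=0.999999, seed=5, noise_sigma=0.0)
        traj, _ = generate_two_state_trajectory(model, 20)
        series = classify_trajectory(traj, default_chi1_references(model))
        assert set(series.labels) == {OPEN}

    @pytest.mark.parametrize("kind", ["chi1", "rmsd"])
    def test_markov_hidden_states_recovered(self, kind):
        model = TwoStateModel(p_open=0.5, seed=6, noise_sigma=0.1)
        traj, manifest = generate_two_state_trajectory(model, 2000)
        refs = (
            default_chi1_references(model)
            if kind == "chi1"
            else default_rmsd_references(model)
        )
        series = classify_trajectory(traj, refs)
        agreement = np.mean(
            [l == h for l, h in zip(series.labels, manifest.hidden_states)]
        )
        assert agreement >= 0.99

    def test_alternating_fixture_alternates(self):
        frames = []
        for i in range(6):
            angle = -60.0 if i % 2 == 0 else 180.0
            atoms = build_residue("ILE", angle)
            frames.append(Frame(atoms, frame_index=i, time_ns=i * 0.1))
        traj = Trajectory(tuple(frames), frame_interval_ns=0.1)
        model = TwoStateModel(p_open=0.5, residue_name="ILE")
        series = classify_trajectory(traj, default_chi1_references(model))
        assert series.labels == (OPEN, CLOSED) * 3

    def test_recovered_fraction_within_binomial_error(self):
        p = 0.3
        model = TwoStateModel(p_open=p, seed=8)
        traj, _ = generate_two_state_trajectory(model, 5000)
        series = classify_trajectory(traj, default_chi1_references(model))
        # Markov-chain samples: binomial SE inflated by (2−k)/k inefficiency
        n_eff = 5000 * model.k_switch / (2 - model.k_switch)
        se = np.sqrt(p * (1 - p) / n_eff)
        assert abs(series.fraction(OPEN) - p) <= 2 * se


class TestMacrostates:
    def test_order_parameter_mapping(self):
        asn = StateLabelSeries((CLOSED, OPEN, OPEN, CLOSED), "A", 66, "rmsd")
        ile = StateLabelSeries((OPEN, CLOSED, OPEN, CLOSED), "A", 126, "chi1")
        macro = macrostate_series(asn, ile)
        assert macro.labels == ("NBL", "BL_PDL1", "BL_PDL2", "unassigned")

    def test_mapping_is_total(self):
        # all four label pairs produce a macrostate
        for a in (OPEN, CLOSED):
            for b in (OPEN, CLOSED):
                asn = StateLabelSeries((a,), "A", 66, "rmsd")
                ile = StateLabelSeries((b,), "A", 126, "chi1")
                assert len(macrostate_series(asn, ile)) == 1

    def test_length_mismatch_errors(self):
        asn = StateLabelSeries((OPEN,), "A", 66, "rmsd")
        ile = StateLabelSeries((OPEN, CLOSED), "A", 126, "chi1")
        with pytest.raises(ValueError, match="length"):
            macrostate_series(asn, ile)


class TestRotamerHistogram2d:
    def test_constant_series_fills_single_bin(self):
        a = np.full(50, -60.0)
        b = np.full(50, 170.0)
        counts, edges = rotamer_histogram2d(a, b, bin_width=10.0)
        assert counts.sum() == 50
        assert counts.max() == 50
        assert (counts > 0).sum() == 1

    def test_counts_conserved(self, rng):
        a = rng.uniform(-180, 180, 1000)
        b = rng.uniform(-180, 180, 1000)
        counts, _ = rotamer_histogram2d(a, b, bin_width=30.0)
        assert counts.sum() == 1000

    def test_uniform_angles_flatten_with_n(self, rng):
        n = 40000
        a = rng.uniform(-180, 180, n)
        b = rng.uniform(-180, 180, n)
        counts, _ = rotamer_histogram2d(a, b, bin_width=90.0)
        assert counts.min() > 0
        assert counts.max() / counts.min() < 1.5

    def test_non_positive_bin_width_errors(self):
        with pytest.raises(ValueError, match="positive"):
            rotamer_histogram2d(np.zeros(3), np.zeros(3), 0.0)
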