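"""Descriptor engine: superposition, angles, distances, SASA against oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from domainmotion.errors import (
    DimensionError,
    EmptyInputError,
    GeometryError,
    MissingAtomsError,
    RadiusTableError,
)
from domainmotion.geometry import (
    BONDI_RADII,
    DescriptorConfig,
    ca_pair_distance,
    csh2_rotation_angle,
    dihedral_from_points,
    ionpair_occupancy,
    joint_contact_fraction,
    kabsch_superpose,
    min_sidechain_contact_distance,
    nsh2_rotation_angle,
    residue_sasa,
    sphere_points,
    summarize,
    tandem_sh2_dihedral,
)
from domainmotion.structure_io import AtomRecord, StructureFrame

finite = st.floats(-50.0, 50.0, allow_nan=False)
point = st.tuples(finite, finite, finite).map(np.array)


def random_rigid_transform(rng):
    rotation = Rotation.random(rng=rng)
    shift = rng.uniform(-30, 30, 3)
    return rotation, shift


class TestKabsch:
    def test_identity(self, rng):
        pts = rng.normal(size=(10, 3))
        t = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-12)
        assert t.rmsd < 1e-12

    def test_recovers_constructed_rotation_and_shift(self, rng):
        reference = rng.normal(size=(8, 3))
        rot = Rotation.from_euler("z", 90, degrees=True)
        mobile = rot.inv().apply(reference - np.array([1.0, 2.0, 3.0]))
        t = kabsch_superpose(mobile, reference)
        assert t.rmsd < 1e-9
        np.testing.assert_allclose(t.apply(mobile), reference, atol=1e-9)

    def test_rmsd_matches_brute_force_minimizer(self, rng):
        """The SVD solution must equal an independent numerical minimization
        over rotation parameters (rotation-vector parameterization)."""
        reference = rng.normal(size=(10, 3)) * 5
        rot, shift = random_rigid_transform(rng)
        mobile = rot.apply(reference) + shift + rng.normal(0, 0.3, (10, 3))
        t = kabsch_superpose(mobile, reference)

        P = mobile - mobile.mean(axis=0)
        Q = reference - reference.mean(axis=0)

        def cost(rotvec):
            moved = Rotation.from_rotvec(rotvec).apply(P)
            return np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1)))

        best = min(
            minimize(cost, x0, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-14}).fun
            for x0 in (np.zeros(3), np.array([1.0, 0.5, -0.5]), np.array([-2.0, 1.0, 2.0]))
        )
        assert abs(t.rmsd - best) < 1e-6

    def test_agrees_with_scipy_align_vectors(self, rng):
        reference = rng.normal(size=(12, 3)) * 4
        mobile = Rotation.random(rng=rng).apply(reference) + 7.0
        t = kabsch_superpose(mobile, reference)
        rot_scipy, _ = Rotation.align_vectors(
            reference - reference.mean(axis=0), mobile - mobile.mean(axis=0)
        )
        np.testing.assert_allclose(t.rotation, rot_scipy.as_matrix(), atol=1e-8)

    def test_point_count_mismatch(self):
        with pytest.raises(DimensionError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(GeometryError):
            kabsch_superpose(line, line)


class TestRotationAngles:
    def test_reference_frame_measures_zero(self, toy_system):
        model, partition = toy_system
        assert nsh2_rotation_angle(model, model, partition) < 1e-6

    @pytest.mark.parametrize("angle", [15.0, 90.0, 150.0])
    def test_constructed_rotation_about_pivot_recovered(self, toy_system, angle):
        from domainmotion.synthetic import default_rotation_schedule

        model, partition = toy_system
        schedule = default_rotation_schedule(model, partition, [angle])
        moving = np.array([a.residue_number in partition["N-SH2"] for a in model.atoms])
        coords = model.coordinates
        rot = Rotation.from_rotvec(np.radians(angle) * schedule.axis)
        coords[moving] = rot.apply(coords[moving] - schedule.pivot) + schedule.pivot
        frame = model.with_positions(coords)
        assert nsh2_rotation_angle(frame, model, partition) == pytest.approx(angle, abs=1e-6)

    def test_invariant_under_global_rigid_motion(self, toy_system, rng):
        from domainmotion.synthetic import default_rotation_schedule

        model, partition = toy_system
        schedule = default_rotation_schedule(model, partition, [70.0])
        moving = np.array([a.residue_number in partition["N-SH2"] for a in model.atoms])
        coords = model.coordinates
        rot = Rotation.from_rotvec(np.radians(70.0) * schedule.axis)
        coords[moving] = rot.apply(coords[moving] - schedule.pivot) + schedule.pivot
        frame = model.with_positions(coords)
        baseline = nsh2_rotation_angle(frame, model, partition)
        global_rot, shift = random_rigid_transform(rng)
        jolted = model.with_positions(global_rot.apply(coords) + shift)
        assert nsh2_rotation_angle(jolted, model, partition) == pytest.approx(baseline, abs=1e-6)

    def test_csh2_angle_of_reference_against_itself(self, toy_system):
        """frame == reference: angle equals the fixed angle between the two
        configured vectors inside the closed structure."""
        model, partition = toy_system
        config = DescriptorConfig()
        a = csh2_rotation_angle(model, model, config, partition)
        from domainmotion.geometry import _vector_between_cas

        v1 = _vector_between_cas(model, config.csh2_vector)
        v2 = _vector_between_cas(model, config.ptp_vector)
        expected = math.degrees(
            math.acos(np.dot(v1, v2) / np.linalg.norm(v1) / np.linalg.norm(v2))
        )
        assert a == pytest.approx(expected, abs=1e-9)

    def test_csh2_angle_tracks_constructed_domain_rotation(self, toy_system):
        """Rotating the C-SH2 domain by 45 degrees about the axis normal to its
        vector plane changes the measured angle by 45 degrees."""
        model, partition = toy_system
        config = DescriptorConfig()
        from domainmotion.geometry import _vector_between_cas

        v_c = _vector_between_cas(model, config.csh2_vector)
        v_p = _vector_between_cas(model, config.ptp_vector)
        axis = np.cross(v_c, v_p)
        axis /= np.linalg.norm(axis)
        baseline = csh2_rotation_angle(model, model, config, partition)
        moving = np.array([a.residue_number in partition["C-SH2"] for a in model.atoms])
        coords = model.coordinates
        pivot = coords[moving].mean(axis=0)
        rot = Rotation.from_rotvec(np.radians(-45.0) * axis)
        coords[moving] = rot.apply(coords[moving] - pivot) + pivot
        frame = model.with_positions(coords)
        measured = csh2_rotation_angle(frame, model, config, partition)
        assert measured == pytest.approx(baseline + 45.0, abs=1e-6) or measured == pytest.approx(
            abs(baseline - 45.0), abs=1e-6
        )

    def test_angles_bounded(self, toy_system, rng):
        model, partition = toy_system
        for _ in range(5):
            rot, shift = random_rigid_transform(rng)
            moving = np.array([a.residue_number in partition["N-SH2"] for a in model.atoms])
            coords = model.coordinates
            coords[moving] = rot.apply(coords[moving]) + shift
            frame = model.with_positions(coords)
            assert 0.0 <= nsh2_rotation_angle(frame, model, partition) <= 180.0
            assert 0.0 <= csh2_rotation_angle(frame, model, partition=partition) <= 180.0


def independent_dihedral(p1, p2, p3, p4):
    """Textbook dihedral via plane normals; sign from the scalar triple product."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    angle = math.degrees(math.acos(np.clip(cosang, -1, 1)))
    if np.dot(np.cross(n1, n2), b2) < 0:
        angle = -angle
    return angle


class TestDihedral:
    def test_cis_planar_is_zero(self):
        pts = [np.array(p, float) for p in [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)]]
        assert dihedral_from_points(*pts) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("twist", [-120.0, -60.0, 60.0, 179.0, 180.0])
    def test_constructed_twist_about_central_bond(self, twist):
        p1 = np.array([1.0, 0.0, 0.0])
        p2 = np.array([0.0, 0.0, 0.0])
        p3 = np.array([0.0, 0.0, 1.0])
        rot = Rotation.from_euler("z", twist, degrees=True)
        p4 = p3 + rot.apply([1.0, 0.0, 0.0])
        expected = 180.0 if twist == 180.0 else twist
        assert dihedral_from_points(p1, p2, p3, p4) == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(p1=point, p2=point, p3=point, p4=point)
    def test_matches_independent_formula(self, p1, p2, p3, p4):
        try:
            ours = dihedral_from_points(p1, p2, p3, p4)
        except GeometryError:
            return
        assert ours == pytest.approx(independent_dihedral(p1, p2, p3, p4), abs=1e-6)

    def test_sign_flips_under_mirror_inversion(self, toy_system):
        model, _ = toy_system
        original = tandem_sh2_dihedral(model)
        mirrored = model.with_positions(-model.coordinates)
        assert tandem_sh2_dihedral(mirrored) == pytest.approx(-original, abs=1e-9)

    def test_coincident_points_rejected(self):
        p = np.zeros(3)
        with pytest.raises(GeometryError):
            dihedral_from_points(p, p, np.array([1.0, 0, 0]), np.array([1.0, 1, 0]))

    def test_missing_dihedral_atom_raises(self, toy_system):
        model, _ = toy_system
        stripped = StructureFrame([a for a in model.atoms if a.residue_number != 111])
        with pytest.raises(MissingAtomsError):
            tandem_sh2_dihedral(stripped)


def make_pair_frame(n_positions, o_positions):
    atoms = []
    n_names = ["NE", "NH1", "NH2"]
    o_names = ["OE1", "OE2"]
    atoms.append(AtomRecord("A", 4, "ARG", "CA", [0, 0, -5], "C"))
    for name, pos in zip(n_names, n_positions):
        atoms.append(AtomRecord("A", 4, "ARG", name, pos, "N"))
    atoms.append(AtomRecord("A", 139, "GLU", "CA", [10, 0, -5], "C"))
    for name, pos in zip(o_names, o_positions):
        atoms.append(AtomRecord("A", 139, "GLU", name, pos, "O"))
    return StructureFrame(atoms)


class TestMinContactDistance:
    def test_single_pair(self):
        frame = make_pair_frame([[0, 0, 0]], [[3, 0, 0]])
        assert min_sidechain_contact_distance(frame, 4, 139) == pytest.approx(3.0)

    def test_equals_exhaustive_minimum(self, rng):
        for _ in range(20):
            n_pos = rng.uniform(-10, 10, (3, 3))
            o_pos = rng.uniform(-10, 10, (2, 3))
            frame = make_pair_frame(n_pos, o_pos)
            brute = min(
                np.linalg.norm(n - o) for n in n_pos for o in o_pos
            )
            assert min_sidechain_contact_distance(frame, 4, 139) == pytest.approx(brute, abs=1e-12)

    def test_alanine_substitution_raises_with_residue_identity(self):
        atoms = [
            AtomRecord("A", 4, "ARG", "CA", [0, 0, 0], "C"),
            AtomRecord("A", 4, "ARG", "NE", [1, 0, 0], "N"),
            AtomRecord("A", 139, "ALA", "CA", [5, 0, 0], "C"),
            AtomRecord("A", 139, "ALA", "CB", [6, 0, 0], "C"),
        ]
        frame = StructureFrame(atoms)
        with pytest.raises(MissingAtomsError) as err:
            min_sidechain_contact_distance(frame, 4, 139)
        assert err.value.residues == (139,)


class TestOccupancy:
    @pytest.mark.parametrize(
        "distances,cutoff,expected",
        [
            ([2.8] * 5, 4.0, 1.0),
            ([8.0] * 5, 4.0, 0.0),
            ([2.0, 3.0, 4.0, 5.0], 4.0, 0.75),  # cutoff is inclusive
        ],
    )
    def test_fraction_below_cutoff(self, distances, cutoff, expected):
        assert ionpair_occupancy(distances, cutoff) == pytest.approx(expected)

    def test_counting_oracle_on_scripted_schedule(self, rng):
        flags = rng.random(200) < 0.3
        distances = np.where(flags, 2.8, 8.0)
        assert ionpair_occupancy(distances, 4.0) == pytest.approx(flags.mean(), abs=0)

    def test_empty_series_rejected(self):
        with pytest.raises(EmptyInputError):
            ionpair_occupancy([], 4.0)

    def test_joint_fraction_matches_framewise_and(self, rng):
        a = np.where(rng.random(500) < 0.6, 3.0, 9.0)
        b = np.where(rng.random(500) < 0.5, 3.0, 9.0)
        expected = np.mean((a <= 4.0) & (b <= 4.0))
        assert joint_contact_fraction(a, b, 4.0) == pytest.approx(expected, abs=0)

    def test_joint_degenerate_cases(self):
        always = np.full(10, 2.0)
        never = np.full(10, 9.0)
        assert joint_contact_fraction(always, never, 4.0) == 0.0
        assert joint_contact_fraction(always, always, 4.0) == ionpair_occupancy(always, 4.0)
        with pytest.raises(DimensionError):
            joint_contact_fraction(always, never[:5], 4.0)


class TestCaPairDistance:
    def test_arithmetic(self):
        atoms = [
            AtomRecord("A", 32, "ARG", "CA", [0, 0, 0], "C"),
            AtomRecord("A", 138, "ARG", "CA", [0, 4, 3], "C"),
        ]
        frame = StructureFrame(atoms)
        assert ca_pair_distance(frame, 32, 138) == pytest.approx(5.0)
        assert ca_pair_distance(frame, 32, 32) == 0.0

    def test_missing_ca_raises(self, toy_system):
        model, _ = toy_system
        with pytest.raises(MissingAtomsError):
            ca_pair_distance(model, 32, 9999)


def spherical_cap_accessible_area(r_a, r_b, d):
    """Closed-form accessible area of expanded sphere A overlapped by B."""
    cos_theta = (r_a**2 + d**2 - r_b**2) / (2 * r_a * d)
    return 2 * math.pi * r_a**2 * (1 + cos_theta)


class TestSasa:
    def test_isolated_atom_matches_sphere_area(self):
        frame = StructureFrame([AtomRecord("A", 1, "LIG", "S", [0, 0, 0], "S")])
        # S radius 1.80 -> expanded sphere radius 3.2
        expected = 4 * math.pi * (1.80 + 1.4) ** 2
        got = residue_sasa(frame, 1, "all")
        assert got == pytest.approx(expected, rel=5e-3)

    def test_fully_enclosed_atom_is_zero(self):
        shell_dirs = sphere_points(40)
        atoms = [AtomRecord("A", 1, "LIG", "C1", [0, 0, 0], "C")]
        for i, d in enumerate(shell_dirs):
            atoms.append(AtomRecord("A", 2, "SHL", f"C{i + 1}", d * 2.2, "C"))
        frame = StructureFrame(atoms)
        assert residue_sasa(frame, 1, "all") == 0.0

    @pytest.mark.parametrize("separation", [1.5, 2.5, 3.5])
    def test_two_overlapping_atoms_match_cap_closed_form(self, separation):
        frame = StructureFrame(
            [
                AtomRecord("A", 1, "LIG", "C1", [0, 0, 0], "C"),
                AtomRecord("A", 2, "LIG", "C1", [separation, 0, 0], "C"),
            ]
        )
        r = BONDI_RADII["C"] + 1.4
        expected = spherical_cap_accessible_area(r, r, separation)
        got = residue_sasa(frame, 1, "all")
        assert got == pytest.approx(expected, rel=0.02)

    def test_additive_for_well_separated_atoms(self):
        lone = StructureFrame([AtomRecord("A", 1, "LIG", "C1", [0, 0, 0], "C")])
        lone_area = residue_sasa(lone, 1, "all")
        far = StructureFrame(
            [
                AtomRecord("A", 1, "LIG", "C1", [0, 0, 0], "C"),
                AtomRecord("A", 2, "LIG", "C1", [20.0, 0, 0], "C"),
            ]
        )
        pair_area = residue_sasa(far, 1, "all") + residue_sasa(far, 2, "all")
        assert pair_area == pytest.approx(2 * lone_area, rel=5e-3)

    def test_sidechain_scope_excludes_backbone(self, toy_system):
        model, _ = toy_system
        side = residue_sasa(model, 139, "sidechain")
        full = residue_sasa(model, 139, "all")
        assert 0 < side < full

    def test_unknown_element_raises(self):
        frame = StructureFrame([AtomRecord("A", 1, "LIG", "XX", [0, 0, 0], "Xx")])
        with pytest.raises(RadiusTableError):
            residue_sasa(frame, 1, "all")


class TestSummarize:
    def test_median_conventions(self):
        assert summarize([1, 2, 3], "x", "A").median == 2
        assert summarize([1, 2, 3, 4], "x", "A").median == 2.5

    def test_median_matches_sorting_oracle(self, rng):
        values = rng.normal(size=1001)
        s = summarize(values, "x", "A")
        ordered = np.sort(values)
        assert s.median == ordered[500]
        assert s.min == ordered[0]
        assert s.max == ordered[-1]

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            summarize([], "x", "A")

    def test_nan_frames_counted_as_missing(self):
        s = summarize([1.0, np.nan, 3.0], "x", "A")
        assert s.n_missing == 1
        assert s.median == 2.0
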