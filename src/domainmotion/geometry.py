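"""Per-frame geometric descriptors of interdomain motion.

The descriptors quantify how the N-SH2 and C-SH2 domains of an SHP2-like
phosphatase reposition relative to the catalytic PTP domain:

* ``nsh2_rotation_angle`` — angle at a C-SH2 pivot between the N-SH2 position
  in an auto-inhibited (closed) reference and in a given frame, after
  superposing both on the PTP domain;
* ``csh2_rotation_angle`` — angle between a C-SH2 vector and a PTP vector that
  are nearly parallel in the closed state;
* ``tandem_sh2_dihedral`` — signed four-point dihedral over Cα L43 – Cα R111 –
  Cα R220 – Cα L149 reporting the relative orientation of the two SH2 domains;
* minimum side-chain N···O distances and cutoff-based salt-bridge occupancies
  for the Arg4/Arg5–Glu/Asp139 ion pairs;
* Cα pair distances (Arg32–Arg138 phosphotyrosine-pocket separation);
* Shrake–Rupley solvent-accessible surface area of a residue (burial of the
  residue-139 side chain).

All angles are degrees, distances Å, areas Å². Every measure is invariant
under global rigid motion of the frame, either because superposition on the
reference domain precedes it or because it is internal to the frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from domainmotion.errors import (
    ConfigurationError,
    DimensionError,
    EmptyInputError,
    GeometryError,
    MissingAtomsError,
    RadiusTableError,
)
from domainmotion.structure_io import (
    DomainPartition,
    StructureFrame,
    coordinates_of,
    select_atoms,
)

#: Bondi van der Waals radii (Å) used for SASA.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "SE": 1.90,
    "I": 1.98,
}

#: Side-chain nitrogen atoms of basic residues (salt-bridge donors).
BASIC_SIDECHAIN_N = ("NE", "NH1", "NH2", "NZ")
#: Side-chain carboxylate oxygens of acidic residues (salt-bridge acceptors).
ACIDIC_SIDECHAIN_O = ("OE1", "OE2", "OD1", "OD2")

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


@dataclass
class DescriptorConfig:
    """Anchors, pivots, vectors, and cutoffs parameterizing every measurement.

    Defaults follow the SHP2 conventions: domain Cα centroids as the N-SH2
    anchor and C-SH2 pivot, the L43/R111/R220/L149 Cα quadruple for the
    tandem-SH2 dihedral, a 4.0 Å heavy-atom salt-bridge cutoff, and a 1.4 Å
    probe with 960 sphere points for SASA. Everything is overridable because
    the descriptor definitions, not these particular choices, are the point.
    """

    nsh2_anchor_residues: frozenset[int] | None = None  # None -> whole N-SH2 domain
    nsh2_anchor_atoms: tuple[str, ...] = ("CA",)
    csh2_pivot_residues: frozenset[int] | None = None  # None -> whole C-SH2 domain
    csh2_pivot_atoms: tuple[str, ...] = ("CA",)
    ptp_vector: tuple[int, int] = (221, 524)
    csh2_vector: tuple[int, int] = (112, 216)
    dihedral_atoms: tuple[tuple[int, str], ...] = (
        (43, "CA"),
        (111, "CA"),
        (220, "CA"),
        (149, "CA"),
    )
    ionpair_cutoff: float = 4.0
    sasa_probe_radius: float = 1.4
    sasa_points: int = 960
    alignment_domain: str = "PTP"
    include_hydrogens: bool = False

    def __post_init__(self) -> None:
        if len(self.dihedral_atoms) != 4:
            raise ConfigurationError("dihedral_atoms must have exactly 4 entries")
        if self.ionpair_cutoff <= 0:
            raise ConfigurationError("ionpair_cutoff must be positive")
        if self.sasa_points < 92:
            raise ConfigurationError("sasa_points must be >= 92")
        if self.sasa_probe_radius <= 0:
            raise ConfigurationError("sasa_probe_radius must be positive")

    def to_dict(self) -> dict:
        return {
            "nsh2_anchor_residues": sorted(self.nsh2_anchor_residues)
            if self.nsh2_anchor_residues
            else None,
            "nsh2_anchor_atoms": list(self.nsh2_anchor_atoms),
            "csh2_pivot_residues": sorted(self.csh2_pivot_residues)
            if self.csh2_pivot_residues
            else None,
            "csh2_pivot_atoms": list(self.csh2_pivot_atoms),
            "ptp_vector": list(self.ptp_vector),
            "csh2_vector": list(self.csh2_vector),
            "dihedral_atoms": [[r, n] for r, n in self.dihedral_atoms],
            "ionpair_cutoff": self.ionpair_cutoff,
            "sasa_probe_radius": self.sasa_probe_radius,
            "sasa_points": self.sasa_points,
            "alignment_domain": self.alignment_domain,
            "include_hydrogens": self.include_hydrogens,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DescriptorConfig":
        kwargs = dict(d)
        for key in ("nsh2_anchor_residues", "csh2_pivot_residues"):
            if kwargs.get(key) is not None:
                kwargs[key] = frozenset(kwargs[key])
        for key in ("nsh2_anchor_atoms", "csh2_pivot_atoms"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        for key in ("ptp_vector", "csh2_vector"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "dihedral_atoms" in kwargs:
            kwargs["dihedral_atoms"] = tuple((int(r), str(n)) for r, n in kwargs["dihedral_atoms"])
        return cls(**kwargs)


@dataclass
class RigidTransform:
    """Proper rotation + translation minimizing RMSD, with the achieved RMSD."""

    rotation: np.ndarray  # (3, 3), det +1
    translation: np.ndarray  # (3,), Å
    rmsd: float  # Å

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3):
            raise DimensionError("rotation must be 3x3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise GeometryError("rotation matrix is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise GeometryError("rotation matrix is improper (det < 0)")
        if self.rmsd < 0:
            raise GeometryError("rmsd must be >= 0")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation


@dataclass
class DescriptorSeries:
    """Per-frame values of one descriptor with summary statistics.

    Missing frames (descriptor atoms absent) are NaN; summaries are computed
    over valid frames and ``n_missing`` records how many were flagged.
    """

    name: str
    unit: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise EmptyInputError(f"descriptor series {self.name!r} has no values")

    @property
    def n_missing(self) -> int:
        return int(np.count_nonzero(np.isnan(self.values)))

    @property
    def valid(self) -> np.ndarray:
        return self.values[~np.isnan(self.values)]

    @property
    def median(self) -> float:
        return float(np.median(self.valid))

    @property
    def mean(self) -> float:
        return float(np.mean(self.valid))

    @property
    def min(self) -> float:
        return float(np.min(self.valid))

    @property
    def max(self) -> float:
        return float(np.max(self.valid))

    def summary(self) -> dict:
        return {
            "name": self.name,
            "unit": self.unit,
            "n_frames": int(self.values.size),
            "n_missing": self.n_missing,
            "median": self.median,
            "mean": self.mean,
            "min": self.min,
            "max": self.max,
        }

    def __len__(self) -> int:
        return int(self.values.size)


def summarize(values: Iterable[float], name: str, unit: str) -> DescriptorSeries:
    """Wrap per-frame values in a DescriptorSeries (exact median, midpoint convention)."""
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    if arr.size == 0:
        raise EmptyInputError("summarize requires at least one value")
    return DescriptorSeries(name=name, unit=unit, values=arr)


# ---------------------------------------------------------------------------
# Superposition


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Classic SVD solution restricted to proper rotations: with centered point
    sets P (mobile) and Q (reference), the covariance H = PᵀQ is decomposed
    H = U S Vᵀ and R = V diag(1, 1, sign det(VUᵀ)) Uᵀ. The returned transform
    maps mobile points onto the reference frame; ``rmsd`` is the minimized
    root-mean-square deviation.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise DimensionError(
            f"point counts differ: mobile {mobile.shape} vs reference {reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise DimensionError("need at least 3 points of dimension 3")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    P = mobile - cm
    Q = reference - cr
    # Collinear or coincident point sets leave a rotation axis undetermined.
    for centered, label in ((P, "mobile"), (Q, "reference")):
        if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
            raise GeometryError(f"{label} points are collinear or coincident")
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    translation = cr - R @ cm
    moved = P @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return RigidTransform(rotation=R, translation=translation, rmsd=rmsd)


def _domain_ca_coords(
    frame: StructureFrame, residues: frozenset[int]
) -> tuple[np.ndarray, list[int]]:
    atoms = select_atoms(frame, residues=residues, atom_names=("CA",), strict=True)
    return coordinates_of(atoms), [a.residue_number for a in atoms]


def superpose_frame(
    frame: StructureFrame,
    reference: StructureFrame,
    partition: DomainPartition,
    domain: str = "PTP",
) -> tuple[StructureFrame, RigidTransform]:
    """Superpose ``frame`` onto ``reference`` over the Cα atoms of one domain.

    Only residues of the domain present in *both* structures are used, so
    structures with different resolved termini still align.
    """
    residues = partition[domain]
    common = residues & frame.residue_numbers() & reference.residue_numbers()
    if len(common) < 3:
        raise MissingAtomsError(
            f"fewer than 3 shared {domain} residues between frame and reference",
            residues=sorted(common),
        )
    mob, mob_res = _domain_ca_coords(frame, frozenset(common))
    ref, ref_res = _domain_ca_coords(reference, frozenset(common))
    if mob_res != ref_res:
        order = {r: i for i, r in enumerate(ref_res)}
        mob = mob[np.argsort([order[r] for r in mob_res])]
    transform = kabsch_superpose(mob, ref)
    return frame.with_positions(transform.apply(frame.coordinates)), transform


# ---------------------------------------------------------------------------
# Rotation angles and dihedral


def _selection_centroid(
    frame: StructureFrame, residues: frozenset[int], atom_names: tuple[str, ...]
) -> np.ndarray:
    atoms = select_atoms(frame, residues=residues, atom_names=atom_names, strict=True)
    return coordinates_of(atoms).mean(axis=0)


def _angle_between(v1: np.ndarray, v2: np.ndarray) -> float:
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise GeometryError("zero-length vector in angle computation")
    # atan2 form: well conditioned near 0° and 180°, unlike arccos
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(v1, v2)), np.dot(v1, v2))))


def nsh2_rotation_angle(
    frame: StructureFrame,
    closed_reference: StructureFrame,
    partition: DomainPartition | None = None,
    config: DescriptorConfig | None = None,
) -> float:
    """Rotation of the N-SH2 domain away from its auto-inhibited position.

    The frame is superposed onto the closed reference over the alignment
    domain (PTP by default); the returned value is the angle, at the C-SH2
    pivot centroid of the aligned frame, between the vector to the closed
    reference's N-SH2 anchor centroid and the vector to the frame's N-SH2
    anchor centroid. Range [0°, 180°]; 0° for the reference itself.
    """
    partition = partition or DomainPartition.default_shp2()
    config = config or DescriptorConfig()
    aligned, _ = superpose_frame(frame, closed_reference, partition, config.alignment_domain)
    anchor_res = config.nsh2_anchor_residues or partition["N-SH2"]
    pivot_res = config.csh2_pivot_residues or partition["C-SH2"]
    ref_anchor = _selection_centroid(closed_reference, anchor_res, config.nsh2_anchor_atoms)
    frame_anchor = _selection_centroid(aligned, anchor_res, config.nsh2_anchor_atoms)
    pivot = _selection_centroid(aligned, pivot_res, config.csh2_pivot_atoms)
    return _angle_between(ref_anchor - pivot, frame_anchor - pivot)


def _vector_between_cas(frame: StructureFrame, pair: tuple[int, int]) -> np.ndarray:
    start = select_atoms(frame, residues=[pair[0]], atom_names=("CA",), strict=True)
    end = select_atoms(frame, residues=[pair[1]], atom_names=("CA",), strict=True)
    return end[0].position - start[0].position


def csh2_rotation_angle(
    frame: StructureFrame,
    closed_reference: StructureFrame,
    config: DescriptorConfig | None = None,
    partition: DomainPartition | None = None,
) -> float:
    """Rotation of the C-SH2 domain on the PTP face.

    After superposition on the alignment domain, returns the angle between
    the frame's C-SH2 Cα vector and the closed reference's PTP Cα vector.
    The default vector pairs span each domain; they are chosen so the two are
    nearly parallel in the auto-inhibited state, making the closed-state
    angle small. Range [0°, 180°].
    """
    partition = partition or DomainPartition.default_shp2()
    config = config or DescriptorConfig()
    aligned, _ = superpose_frame(frame, closed_reference, partition, config.alignment_domain)
    v_csh2 = _vector_between_cas(aligned, config.csh2_vector)
    v_ptp = _vector_between_cas(closed_reference, config.ptp_vector)
    return _angle_between(v_csh2, v_ptp)


def dihedral_from_points(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed four-point dihedral (IUPAC convention), degrees in (−180°, 180°]."""
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b3 = np.asarray(p4, float) - np.asarray(p3, float)
    if min(np.linalg.norm(b1), np.linalg.norm(b2), np.linalg.norm(b3)) < 1e-9:
        raise GeometryError("consecutive coincident points in dihedral")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise GeometryError("collinear points leave the dihedral undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2)))
    angle = math.degrees(math.atan2(y, x))
    if angle <= -180.0:
        angle += 360.0
    return angle


def tandem_sh2_dihedral(frame: StructureFrame, config: DescriptorConfig | None = None) -> float:
    """Signed dihedral over the ordered atom quadruple (default Cα L43–R111–R220–L149)."""
    config = config or DescriptorConfig()
    points = []
    for residue, atom_name in config.dihedral_atoms:
        atoms = select_atoms(frame, residues=[residue], atom_names=(atom_name,))
        if not atoms:
            raise MissingAtomsError(
                f"dihedral atom {atom_name} of residue {residue} missing", residues=[residue]
            )
        points.append(atoms[0].position)
    return dihedral_from_points(*points)


# ---------------------------------------------------------------------------
# Ion pairs and distances


def min_sidechain_contact_distance(
    frame: StructureFrame, basic_residue: int, acidic_residue: int
) -> float:
    """Minimum distance (Å) between side-chain N atoms of a basic residue and
    side-chain carboxylate O atoms of an acidic residue.

    Raises :class:`MissingAtomsError` (carrying the residue identity) when
    either atom set is absent — e.g. an alanine substitution at that position
    or an unresolved side chain.
    """
    n_atoms = select_atoms(frame, residues=[basic_residue], atom_names=BASIC_SIDECHAIN_N)
    if not n_atoms:
        raise MissingAtomsError(
            f"no side-chain N atoms on residue {basic_residue}", residues=[basic_residue]
        )
    o_atoms = select_atoms(frame, residues=[acidic_residue], atom_names=ACIDIC_SIDECHAIN_O)
    if not o_atoms:
        raise MissingAtomsError(
            f"no side-chain carboxylate O atoms on residue {acidic_residue}",
            residues=[acidic_residue],
        )
    return float(cdist(coordinates_of(n_atoms), coordinates_of(o_atoms)).min())


def _series_values(series) -> np.ndarray:
    if isinstance(series, DescriptorSeries):
        return series.values
    return np.asarray(series, dtype=float)


def ionpair_occupancy(series, cutoff: float = 4.0) -> float:
    """Fraction of frames with distance ≤ cutoff (NaN frames excluded)."""
    if cutoff <= 0:
        raise ConfigurationError("cutoff must be positive")
    values = _series_values(series)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise EmptyInputError("occupancy of an empty distance series is undefined")
    return float(np.count_nonzero(values <= cutoff) / values.size)


def joint_contact_fraction(series_a, series_b, cutoff: float = 4.0) -> float:
    """Fraction of frames where both distances are ≤ cutoff simultaneously."""
    a = _series_values(series_a)
    b = _series_values(series_b)
    if a.shape != b.shape:
        raise DimensionError(f"series lengths differ: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise EmptyInputError("joint contact fraction of empty series is undefined")
    valid = ~(np.isnan(a) | np.isnan(b))
    if not np.any(valid):
        raise EmptyInputError("no frame has both distances defined")
    both = (a[valid] <= cutoff) & (b[valid] <= cutoff)
    return float(np.count_nonzero(both) / np.count_nonzero(valid))


def ca_pair_distance(frame: StructureFrame, residue_i: int, residue_j: int) -> float:
    """Euclidean distance (Å) between the Cα atoms of two residues."""
    positions = []
    for residue in (residue_i, residue_j):
        atoms = select_atoms(frame, residues=[residue], atom_names=("CA",))
        if not atoms:
            raise MissingAtomsError(f"no Cα atom for residue {residue}", residues=[residue])
        positions.append(atoms[0].position)
    return float(np.linalg.norm(positions[0] - positions[1]))


# ---------------------------------------------------------------------------
# SASA (Shrake–Rupley)


def sphere_points(n: int) -> np.ndarray:
    """Deterministic near-uniform unit-sphere point set (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _element_of(atom) -> str:
    if atom.element:
        return atom.element.upper()
    # fall back to the leading letters of the atom name (PDB convention)
    name = "".join(c for c in atom.atom_name if c.isalpha())
    return name[:1].upper()


def _vdw_radius(atom) -> float:
    element = _element_of(atom)
    try:
        return BONDI_RADII[element]
    except KeyError:
        raise RadiusTableError(
            f"no van der Waals radius for element {element!r} (atom {atom.atom_name})"
        ) from None


def shrake_rupley_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
    subset: Sequence[int] | None = None,
) -> np.ndarray:
    """Per-atom Shrake–Rupley SASA (Å²) by probe-sphere point sampling.

    Each atom's accessible surface is the fraction of ``n_points`` sites on a
    sphere of radius r_atom + r_probe not buried inside any neighbour's
    probe-expanded sphere. ``subset`` restricts the computation (the buriers
    are always the whole coordinate set).
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n_atoms = coords.shape[0]
    unit = sphere_points(n_points)
    expanded = radii + probe_radius
    targets = range(n_atoms) if subset is None else subset
    out = np.zeros(n_atoms)
    for i in targets:
        ri = expanded[i]
        # neighbours whose expanded spheres can intersect atom i's surface
        delta = coords - coords[i]
        dist = np.linalg.norm(delta, axis=1)
        neighbour_mask = (dist < ri + expanded) & (dist > 1e-12)
        neighbours = np.nonzero(neighbour_mask)[0]
        points = coords[i] + ri * unit  # (n_points, 3)
        accessible = np.ones(len(points), dtype=bool)
        for j in neighbours:
            d2 = np.sum((points - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
            if not accessible.any():
                break
        out[i] = 4.0 * np.pi * ri**2 * np.count_nonzero(accessible) / len(points)
    return out


def residue_sasa(
    frame: StructureFrame,
    residue: int,
    scope: str = "sidechain",
    config: DescriptorConfig | None = None,
) -> float:
    """SASA (Å²) of one residue, computed in the context of the whole frame.

    ``scope`` is ``"sidechain"`` (default — burial of the residue-139
    carboxylate is a side-chain question) or ``"all"``. Hydrogens are excluded
    unless the config includes them.
    """
    config = config or DescriptorConfig()
    if scope not in ("sidechain", "all"):
        raise ConfigurationError(f"scope must be 'sidechain' or 'all', got {scope!r}")
    atoms = frame.atoms
    if not config.include_hydrogens:
        atoms = [a for a in atoms if _element_of(a) != "H"]
    indices = [
        i
        for i, a in enumerate(atoms)
        if a.residue_number == residue
        and (scope == "all" or a.atom_name not in _BACKBONE_NAMES)
    ]
    if not indices:
        raise MissingAtomsError(
            f"residue {residue} has no atoms in scope {scope!r}", residues=[residue]
        )
    coords = np.array([a.position for a in atoms])
    radii = np.array([_vdw_radius(a) for a in atoms])
    per_atom = shrake_rupley_sasa(
        coords,
        radii,
        probe_radius=config.sasa_probe_radius,
        n_points=config.sasa_points,
        subset=indices,
    )
    return float(per_atom[indices].sum())
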