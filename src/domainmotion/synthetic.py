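"""Ground-truth-known synthetic inputs for every pipeline stage.

The generators emulate, at toy scale, the data the pipeline consumes:

* rigid-body rotation of a pseudo-N-SH2 domain about a pivot on a
  pseudo-C-SH2 domain, with scripted per-frame angles and optional scripted
  salt-bridge formation/breakage, plus isotropic Gaussian coordinate noise;
* Michaelis–Menten kinetics with lognormal replicate noise;
* two-state sigmoidal DSF melt curves with known midpoints;
* replicate activity tables for a panel of phosphatase variants.

Every output is a pure function of (spec, seed) — regeneration is
bit-identical — and each generated dataset carries a ground-truth sidecar;
downstream recovery tests read truth only from the sidecar. The pseudo-domain
atoms reuse the real SHP2 anchor residue numbers (4, 5, 32, 43, 111, 138,
139, 149, 220) so descriptor configs transfer unchanged between toy and real
systems. No physics is simulated: the noise model is a crude stand-in for
thermal fluctuation, sufficient to exercise descriptor robustness but not to
mimic real dynamics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from domainmotion.biochem import MeltCurve, boltzmann_sigmoid, michaelis_menten_rate
from domainmotion.errors import SpecError
from domainmotion.structure_io import (
    AtomRecord,
    DomainPartition,
    FrameStream,
    StructureFrame,
    select_atoms,
)


@dataclass
class KineticsTruth:
    """Generative parameters for one Michaelis–Menten dataset."""

    k_cat: float = 10.0  # s^-1
    k_m: float = 100.0  # µM
    enzyme_concentration: float = 0.05  # µM
    noise_fraction: float = 0.05  # sdlog of multiplicative lognormal noise
    n_points: int = 10

    @property
    def efficiency(self) -> float:
        return self.k_cat / self.k_m


@dataclass
class MeltTruth:
    """Generative parameters for one DSF melt curve."""

    tm: float = 55.0  # °C
    slope: float = 1.5  # °C transition width parameter
    baseline: float = 1000.0
    amplitude: float = 5000.0
    noise_fraction: float = 0.02  # additive Gaussian sd as fraction of amplitude
    t_min: float = 25.0
    t_max: float = 95.0
    t_step: float = 0.5


@dataclass
class GeneratorSpec:
    """Everything the generators need; identical spec + seed => identical output."""

    seed: int = 0
    n_frames: int = 100
    coordinate_noise_sd: float = 0.2  # Å
    atoms_per_domain: int = 12
    kinetics: KineticsTruth = field(default_factory=KineticsTruth)
    melt: MeltTruth = field(default_factory=MeltTruth)

    def __post_init__(self) -> None:
        if self.coordinate_noise_sd < 0:
            raise SpecError("coordinate_noise_sd must be >= 0")
        if self.n_frames < 1:
            raise SpecError("n_frames must be >= 1")
        if self.atoms_per_domain < 4:
            raise SpecError("need at least 4 atoms per pseudo-domain")


@dataclass
class RotationSchedule:
    """Scripted per-frame rotation of one domain about (axis, pivot)."""

    angles_deg: np.ndarray
    axis: np.ndarray  # unit 3-vector
    pivot: np.ndarray  # Å
    moving_domain: str = "N-SH2"

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        self.pivot = np.asarray(self.pivot, dtype=float)
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-9:
            raise SpecError("rotation axis must be a unit vector")


@dataclass
class ContactSchedule:
    """Scripted per-frame salt-bridge contact for one residue pair."""

    flags: np.ndarray  # bool per frame: True = bound
    basic_residue: int = 4
    acidic_residue: int = 139
    bound_distance: float = 2.8  # Å, < cutoff
    unbound_distance: float = 8.0  # Å, > cutoff

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.bound_distance >= self.unbound_distance:
            raise SpecError("bound_distance must be below unbound_distance")

    @property
    def occupancy(self) -> float:
        return float(self.flags.mean())


# ---------------------------------------------------------------------------
# Toy structure


def _ball(rng: np.random.Generator, center: np.ndarray, n: int, radius: float = 6.0) -> np.ndarray:
    """n points in a ball around center (rejection-free: scaled directions)."""
    directions = rng.standard_normal((n, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return center + directions * r[:, None]


def make_toy_multidomain(spec: GeneratorSpec) -> tuple[StructureFrame, DomainPartition]:
    """Three separated pseudo-domains of Cα-like atoms plus anchor side chains.

    Residues 4/5 carry Arg-like guanidinium nitrogens (NE, NH1, NH2) and
    residue 139 Glu-like carboxylate oxygens (OE1, OE2) so the salt-bridge
    descriptors are exercisable; residues 32/43/111/138/149/220 carry the Cα
    anchors of the rotation-angle, dihedral and pocket-distance descriptors.
    Pairwise pseudo-domain centroid separation exceeds 20 Å.
    """
    n = spec.atoms_per_domain
    rng = np.random.default_rng(spec.seed)

    centers = {
        "N-SH2": np.array([40.0, 0.0, 0.0]),
        "C-SH2": np.array([0.0, 0.0, 0.0]),
        "PTP": np.array([0.0, 40.0, 0.0]),
    }
    required = {
        "N-SH2": [3, 4, 5, 32, 43],
        "C-SH2": [112, 138, 139, 149, 216],
        "PTP": [221, 524],
    }
    fillers = {"N-SH2": range(6, 105), "C-SH2": range(113, 136), "PTP": range(222, 524)}
    resnames = {4: "ARG", 5: "ARG", 43: "LEU", 111: "ARG", 138: "ARG", 139: "GLU",
                149: "LEU", 220: "ARG", 32: "ARG"}

    atoms: list[AtomRecord] = []
    domain_residues: dict[str, list[int]] = {}
    for domain in ("N-SH2", "C-SH2", "PTP"):
        residues = list(required[domain])
        for r in fillers[domain]:
            if len(residues) >= n:
                break
            if r not in residues:
                residues.append(r)
        if len(residues) < n:
            raise SpecError(f"atoms_per_domain={n} exceeds residue range of {domain}")
        residues.sort()
        domain_residues[domain] = residues
        coords = _ball(rng, centers[domain], len(residues))
        if domain == "N-SH2":
            # Deterministic Arg4/Arg5 placement: side chains point away from
            # each other so scripted contacts to residue 139 stay independent.
            coords[residues.index(4)] = centers[domain] + np.array([6.0, 0.0, 0.0])
            coords[residues.index(5)] = centers[domain] + np.array([-6.0, 0.0, 0.0])
        for resnum, pos in zip(residues, coords):
            atoms.append(
                AtomRecord("A", resnum, resnames.get(resnum, "ALA"), "CA", pos, "C")
            )
        if domain == "N-SH2":
            for resnum, outward in ((4, np.array([1.0, 0.0, 0.0])), (5, np.array([-1.0, 0.0, 0.0]))):
                ca = coords[residues.index(resnum)]
                ne = ca + 4.0 * outward + np.array([0.0, 0.0, 0.5])
                perp = np.array([0.0, 1.15, 0.0])
                for name, pos in (("NE", ne), ("NH1", ne + perp), ("NH2", ne - perp)):
                    atoms.append(AtomRecord("A", resnum, "ARG", name, pos, "N"))
        if domain == "C-SH2":
            ca139 = coords[residues.index(139)]
            for name, offset in (("OE1", np.array([2.5, 0.5, 0.0])), ("OE2", np.array([2.5, -0.5, 0.0]))):
                atoms.append(AtomRecord("A", 139, "GLU", name, ca139 + offset, "O"))

    # Linker residues (outside all domains, held fixed during rotations).
    atoms.append(AtomRecord("A", 111, "ARG", "CA", np.array([15.0, 2.0, 1.0]), "C"))
    atoms.append(AtomRecord("A", 220, "ARG", "CA", np.array([2.0, 18.0, -1.0]), "C"))

    atoms.sort(key=lambda a: (a.chain_id, a.residue_number))
    frame = StructureFrame(atoms, frame_index=0)
    partition = DomainPartition(domain_residues)
    return frame, partition


def default_rotation_schedule(
    model: StructureFrame,
    partition: DomainPartition,
    angles_deg,
    moving_domain: str = "N-SH2",
    pivot_domain: str = "C-SH2",
) -> RotationSchedule:
    """Schedule rotating ``moving_domain`` about the pivot-domain Cα centroid.

    The axis is chosen perpendicular to the pivot→moving-centroid vector, so
    the scripted angle equals the angle swept by the moving domain's centroid
    as seen from the pivot — i.e. exactly what ``nsh2_rotation_angle``
    measures.
    """
    pivot_atoms = select_atoms(model, residues=partition[pivot_domain], atom_names=("CA",), strict=True)
    moving_atoms = select_atoms(model, residues=partition[moving_domain], atom_names=("CA",), strict=True)
    pivot = np.mean([a.position for a in pivot_atoms], axis=0)
    anchor = np.mean([a.position for a in moving_atoms], axis=0)
    radial = anchor - pivot
    radial /= np.linalg.norm(radial)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(radial, helper)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    axis = np.cross(radial, helper)
    axis /= np.linalg.norm(axis)
    return RotationSchedule(
        angles_deg=np.asarray(angles_deg, dtype=float),
        axis=axis,
        pivot=pivot,
        moving_domain=moving_domain,
    )


def make_rigid_trajectory(
    model: StructureFrame,
    partition: DomainPartition,
    schedule: RotationSchedule,
    contacts: ContactSchedule | list[ContactSchedule] | None = None,
    spec: GeneratorSpec | None = None,
) -> tuple[FrameStream, dict]:
    """Rigid-body trajectory with scripted rotation and contact schedules.

    Per frame: rotate the moving domain by the scheduled angle about
    (axis, pivot); place each contact pair's carboxylate oxygens at the
    bound/unbound distance from the basic residue's NE along its side-chain
    direction; then add i.i.d. Gaussian coordinate noise to every atom.
    Returns the frame stream and a ground-truth sidecar dict.
    """
    spec = spec or GeneratorSpec()
    if schedule.moving_domain not in partition:
        raise SpecError(f"moving domain {schedule.moving_domain!r} not in partition")
    if len(schedule.angles_deg) != spec.n_frames:
        raise SpecError("schedule length must equal n_frames")
    if contacts is None:
        contacts = []
    elif isinstance(contacts, ContactSchedule):
        contacts = [contacts]
    for c in contacts:
        if len(c.flags) != spec.n_frames:
            raise SpecError("contact schedule length must equal n_frames")

    rng = np.random.default_rng(spec.seed)
    moving = np.array(
        [a.residue_number in partition[schedule.moving_domain] for a in model.atoms]
    )
    base = model.coordinates
    index = {a.key: i for i, a in enumerate(model.atoms)}

    frames = []
    for t in range(spec.n_frames):
        coords = base.copy()
        rot = Rotation.from_rotvec(np.radians(schedule.angles_deg[t]) * schedule.axis)
        coords[moving] = rot.apply(coords[moving] - schedule.pivot) + schedule.pivot
        for k, contact in enumerate(contacts):
            d = contact.bound_distance if contact.flags[t] else contact.unbound_distance
            ne = coords[index[("A", contact.basic_residue, "NE")]]
            ca = coords[index[("A", contact.basic_residue, "CA")]]
            u = ne - ca
            u /= np.linalg.norm(u)
            # OE1 serves the first contact schedule, OE2 the second.
            oxy = ("OE1", "OE2")[k % 2]
            coords[index[("A", contact.acidic_residue, oxy)]] = ne + d * u
            if len(contacts) == 1:
                # park the unused oxygen just beyond its sibling
                coords[index[("A", contact.acidic_residue, "OE2")]] = ne + (d + 0.5) * u
        if spec.coordinate_noise_sd > 0:
            coords = coords + rng.normal(0.0, spec.coordinate_noise_sd, coords.shape)
        frames.append(model.with_positions(coords, frame_index=t, time_ps=100.0 * t))

    sidecar = {
        "generator": "make_rigid_trajectory",
        "rng": "numpy.random.default_rng (PCG64)",
        "seed": spec.seed,
        "n_frames": spec.n_frames,
        "coordinate_noise_sd": spec.coordinate_noise_sd,
        "moving_domain": schedule.moving_domain,
        "axis": schedule.axis.tolist(),
        "pivot": schedule.pivot.tolist(),
        "angles_deg": schedule.angles_deg.tolist(),
        "contacts": [
            {
                "basic_residue": c.basic_residue,
                "acidic_residue": c.acidic_residue,
                "bound_distance": c.bound_distance,
                "unbound_distance": c.unbound_distance,
                "flags": c.flags.astype(int).tolist(),
                "occupancy": c.occupancy,
            }
            for c in contacts
        ],
    }
    return FrameStream(frames, source=f"synthetic(seed={spec.seed})"), sidecar


def write_sidecar(sidecar: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(sidecar, indent=2))


# ---------------------------------------------------------------------------
# Kinetics and melt curves


def simulate_kinetics(spec: GeneratorSpec) -> tuple[pd.DataFrame, dict]:
    """Initial-rate table from Michaelis–Menten truth with lognormal noise.

    Concentrations span K_M/50 to 10·K_M (log-spaced) so both the linear and
    saturating regimes are represented.
    """
    truth = spec.kinetics
    rng = np.random.default_rng(spec.seed)
    s = np.geomspace(truth.k_m / 50.0, 10.0 * truth.k_m, truth.n_points)
    v = michaelis_menten_rate(s, truth.k_cat, truth.k_m, truth.enzyme_concentration)
    if truth.noise_fraction > 0:
        v = v * np.exp(rng.normal(0.0, truth.noise_fraction, v.shape))
    table = pd.DataFrame({"concentration_uM": s, "rate": v})
    sidecar = {
        "generator": "simulate_kinetics",
        "rng": "numpy.random.default_rng (PCG64)",
        "seed": spec.seed,
        "k_cat": truth.k_cat,
        "k_m": truth.k_m,
        "enzyme_concentration": truth.enzyme_concentration,
        "efficiency": truth.efficiency,
        "noise_fraction": truth.noise_fraction,
    }
    return table, sidecar


def simulate_melt_curve(spec: GeneratorSpec) -> tuple[MeltCurve, dict]:
    """Four-parameter sigmoid melt curve with additive Gaussian noise."""
    truth = spec.melt
    rng = np.random.default_rng(spec.seed)
    t = np.arange(truth.t_min, truth.t_max + truth.t_step / 2, truth.t_step)
    f = boltzmann_sigmoid(t, truth.baseline, truth.amplitude, truth.tm, truth.slope)
    if truth.noise_fraction > 0:
        f = f + rng.normal(0.0, truth.noise_fraction * truth.amplitude, f.shape)
    sidecar = {
        "generator": "simulate_melt_curve",
        "rng": "numpy.random.default_rng (PCG64)",
        "seed": spec.seed,
        "tm": truth.tm,
        "slope": truth.slope,
        "baseline": truth.baseline,
        "amplitude": truth.amplitude,
        "noise_fraction": truth.noise_fraction,
    }
    return MeltCurve(temperatures=t, signal=f), sidecar


# ---------------------------------------------------------------------------
# Variant activity panel


#: Relative catalytic efficiencies (WT = 1) for the SHP2 variant panel.
#:
#: SYNTHETIC RECONSTRUCTION: the replicate-level catalytic parameters behind
#: the study's variant panel are not part of this repository, so this table
#: reconstructs a self-consistent set of relative efficiencies from the fold
#: changes reported for the panel (E139D 7x activation; its effect reduced to
#: 2.1x in the R5A background and amplified to 18.7x in the R4A background;
#: 4.3x / 41.9x R5A reductions in E139D / R4A+E139D backgrounds; 3.2x E139A
#: reduction in the R4A background; 1.8x enhancement of the E139A effect by
#: R5A; 7.1x D139A inactivation; >100x E76K activation). The printed panel is
#: slightly over-determined, so derived ratios can differ from printed ones
#: by a few percent.
REFERENCE_RELATIVE_EFFICIENCIES: dict[str, float] = {
    "WT": 1.0,
    "R4A": 1.5,
    "R5A": 7.0 / (4.3 * 2.1),
    "E139A": 7.0 / 7.1,
    "E139D": 7.0,
    "E76K": 110.0,
    "R4A+R5A": 18.7 * 1.5 / 41.9,
    "R4A+E139D": 18.7 * 1.5,
    "R5A+E139D": 7.0 / 4.3,
    "R4A+R5A+E139D": 18.7 * 1.5 / 41.9,
    "R4A+E139A": 1.5 / 3.2,
    "R5A+E139A": (7.0 / (4.3 * 2.1)) * (7.0 / 7.1) / 1.8,
    "E76K+E139D": 110.0,
    "E76K+E139A": 110.0 / 1.5,
}

#: Absolute scale for the synthetic panel (k_cat/K_M of wild type, M^-1 s^-1).
WT_EFFICIENCY = 1.0e3


def synthetic_activity_table(
    n_replicates: int = 3,
    noise_fraction: float = 0.0,
    seed: int = 0,
    relative_efficiencies: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Replicate activity table (columns: variant, replicate, kcat_per_km).

    ``noise_fraction`` is the sdlog of multiplicative lognormal replicate
    noise; 0 gives a noise-free table whose ratios equal the generative panel
    exactly.
    """
    panel = relative_efficiencies or REFERENCE_RELATIVE_EFFICIENCIES
    rng = np.random.default_rng(seed)
    rows = []
    for variant, rel in panel.items():
        for rep in range(1, n_replicates + 1):
            value = WT_EFFICIENCY * rel
            if noise_fraction > 0:
                value *= float(np.exp(rng.normal(0.0, noise_fraction)))
            rows.append({"variant": variant, "replicate": rep, "kcat_per_km": value})
    return pd.DataFrame(rows)
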