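"""Structure and trajectory I/O with a uniform frame stream.

Readers preserve author (PDB) residue numbering exactly — Arg4, Glu139,
Arg32/Arg138 etc. keep the numbers used in the crystal structures — and expose
every input (single-model PDB, multi-MODEL PDB, mmCIF, DCD/XTC + topology) as
the same in-memory types, so the descriptor engine never needs to know where a
frame came from.

PDB and mmCIF parsing/writing is delegated to :mod:`gemmi`; binary-trajectory
coordinate streaming to :mod:`mdtraj`.
"""

from __future__ import annotations

import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from domainmotion.errors import (
    ConfigurationError,
    DimensionError,
    FormatError,
    SelectionError,
)

_TRAJECTORY_SUFFIXES = {".dcd", ".xtc", ".trr", ".nc"}

#: Conventional SHP2 domain boundaries (author numbering). The source
#: structures never print exact boundaries, so these are overridable defaults.
DEFAULT_SHP2_DOMAINS: dict[str, tuple[int, int]] = {
    "N-SH2": (3, 104),
    "C-SH2": (112, 216),
    "PTP": (221, 524),
}


@dataclass(eq=False)
class AtomRecord:
    """One atom of one frame, in author numbering and PDB atom-name convention."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    position: np.ndarray  # (3,) Å
    element: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise DimensionError(f"position must be a 3-vector, got {self.position.shape}")
        if not np.all(np.isfinite(self.position)):
            raise FormatError(f"non-finite position for atom {self.atom_name}")
        if not self.atom_name:
            raise FormatError("atom_name must be nonempty")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.atom_name)


class StructureFrame:
    """Ordered atom list for one model / one trajectory frame."""

    def __init__(
        self,
        atoms: Sequence[AtomRecord],
        frame_index: int = 0,
        time_ps: float | None = None,
    ):
        self.atoms: list[AtomRecord] = list(atoms)
        self.frame_index = int(frame_index)
        self.time_ps = time_ps
        keys = [a.key for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen: set = set()
            dup = next(k for k in keys if k in seen or seen.add(k))
            raise FormatError(f"duplicate atom {dup} within frame")
        self._index: dict[tuple[str, int, str], int] = {k: i for i, k in enumerate(keys)}

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) array of positions in Å, in frame atom order."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_positions(
        self, positions: np.ndarray, frame_index: int | None = None, time_ps: float | None = None
    ) -> "StructureFrame":
        """New frame sharing atom identities but with replaced coordinates."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(self.atoms), 3):
            raise DimensionError(
                f"expected positions of shape {(len(self.atoms), 3)}, got {positions.shape}"
            )
        atoms = [
            AtomRecord(a.chain_id, a.residue_number, a.residue_name, a.atom_name, p, a.element)
            for a, p in zip(self.atoms, positions)
        ]
        return StructureFrame(
            atoms,
            self.frame_index if frame_index is None else frame_index,
            self.time_ps if time_ps is None else time_ps,
        )

    def residue_numbers(self) -> set[int]:
        return {a.residue_number for a in self.atoms}


class DomainPartition:
    """Named, pairwise-disjoint residue-number sets (N-SH2 / C-SH2 / PTP by default)."""

    def __init__(self, domains: Mapping[str, Iterable[int]]):
        self.domains: dict[str, frozenset[int]] = {
            name: frozenset(int(r) for r in residues) for name, residues in domains.items()
        }
        labels = list(self.domains)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                overlap = self.domains[a] & self.domains[b]
                if overlap:
                    raise ConfigurationError(
                        f"domains {a!r} and {b!r} overlap on residues {sorted(overlap)[:5]}"
                    )

    @classmethod
    def from_ranges(cls, ranges: Mapping[str, tuple[int, int]]) -> "DomainPartition":
        return cls({name: range(lo, hi + 1) for name, (lo, hi) in ranges.items()})

    @classmethod
    def default_shp2(cls) -> "DomainPartition":
        return cls.from_ranges(DEFAULT_SHP2_DOMAINS)

    def __getitem__(self, label: str) -> frozenset[int]:
        try:
            return self.domains[label]
        except KeyError:
            raise ConfigurationError(
                f"unknown domain {label!r}; have {sorted(self.domains)}"
            ) from None

    def __contains__(self, label: str) -> bool:
        return label in self.domains

    def domain_of(self, residue_number: int) -> str | None:
        for name, residues in self.domains.items():
            if residue_number in residues:
                return name
        return None


class FrameStream:
    """Order-stable sequence of frames with identical atom ordering.

    Materialized in memory: the trajectories analysed here are short enough
    that lazy chunking buys nothing, and order-stable repeated iteration comes
    for free.
    """

    def __init__(self, frames: Sequence[StructureFrame], source: str = "<memory>"):
        frames = list(frames)
        if not frames:
            raise FormatError("FrameStream requires at least one frame")
        ref_keys = [a.key for a in frames[0].atoms]
        for f in frames[1:]:
            if [a.key for a in f.atoms] != ref_keys:
                raise FormatError(
                    f"frame {f.frame_index} atom ordering differs from first frame"
                )
        self._frames = frames
        self.source = source

    @property
    def topology(self) -> StructureFrame:
        return self._frames[0]

    @property
    def count(self) -> int:
        return len(self._frames)

    def __len__(self) -> int:
        return len(self._frames)

    def __iter__(self) -> Iterator[StructureFrame]:
        return iter(self._frames)

    def __getitem__(self, i: int) -> StructureFrame:
        return self._frames[i]


# ---------------------------------------------------------------------------
# Reading


def _frame_from_gemmi_model(model, frame_index: int) -> StructureFrame:
    atoms: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            # Alternate locations: keep the highest-occupancy conformer per
            # atom name; ties broken by altloc label order (deterministic).
            by_name: dict[str, list] = {}
            for atom in residue:
                by_name.setdefault(atom.name, []).append(atom)
            for name, candidates in by_name.items():
                best = max(candidates, key=lambda a: (a.occ, -ord(a.altloc or "~")))
                atoms.append(
                    AtomRecord(
                        chain_id=chain.name,
                        residue_number=residue.seqid.num,
                        residue_name=residue.name,
                        atom_name=name,
                        position=np.array([best.pos.x, best.pos.y, best.pos.z]),
                        element=best.element.name,
                    )
                )
    return StructureFrame(atoms, frame_index=frame_index)


def _read_gemmi(path: Path, model_index) -> StructureFrame | FrameStream:
    import gemmi

    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if len(structure) == 0 or all(m.count_atom_sites() == 0 for m in structure):
        raise FormatError(f"{path} contains no atoms")
    if model_index == "all":
        if len(structure) == 1:
            return _frame_from_gemmi_model(structure[0], 0)
        frames = [_frame_from_gemmi_model(m, i) for i, m in enumerate(structure)]
        return FrameStream(frames, source=str(path))
    idx = int(model_index)
    if idx >= len(structure):
        raise FormatError(f"{path} has {len(structure)} models, requested index {idx}")
    return _frame_from_gemmi_model(structure[idx], idx)


def _read_trajectory(path: Path, topology: Path) -> FrameStream:
    import mdtraj as md

    template = _read_gemmi(topology, model_index=0)
    if isinstance(template, FrameStream):  # pragma: no cover - model_index=0 above
        template = template.topology
    try:
        traj = md.load(str(path), top=str(topology))
    except Exception as exc:
        raise FormatError(f"could not load trajectory {path}: {exc}") from exc
    if traj.n_atoms != len(template):
        raise FormatError(
            f"trajectory has {traj.n_atoms} atoms but topology {topology} has {len(template)}"
        )
    frames = [
        template.with_positions(
            traj.xyz[i] * 10.0,  # nm -> Å
            frame_index=i,
            time_ps=float(traj.time[i]) if traj.time is not None else None,
        )
        for i in range(traj.n_frames)
    ]
    return FrameStream(frames, source=str(path))


def read_structure(
    path: str | Path,
    model_index: int | str = "all",
    topology: str | Path | None = None,
) -> StructureFrame | FrameStream:
    """Read a structure or trajectory into frames with author numbering preserved.

    Parameters
    ----------
    path
        PDB / mmCIF file, or a binary trajectory (``.dcd``, ``.xtc``, ...).
    model_index
        ``"all"`` (default) returns a :class:`FrameStream` for multi-model
        input and a single :class:`StructureFrame` for single-model input; an
        integer selects one MODEL.
    topology
        Required for coordinate-only trajectory formats: a PDB file providing
        atom identities in trajectory atom order.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() in _TRAJECTORY_SUFFIXES:
        if topology is None:
            raise ConfigurationError(
                f"{path.suffix} holds coordinates only; pass topology=<pdb path>"
            )
        stream = _read_trajectory(path, Path(topology))
        if model_index == "all":
            return stream
        return stream[int(model_index)]
    return _read_gemmi(path, model_index)


def fetch_pdb(pdb_id: str, dest_dir: str | Path = ".", timeout: float = 60.0) -> Path:
    """Convenience downloader for RCSB entries (network required)."""
    pdb_id = pdb_id.lower()
    dest = Path(dest_dir) / f"{pdb_id}.pdb"
    if dest.exists():
        return dest
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        dest.write_bytes(resp.read())
    return dest


# ---------------------------------------------------------------------------
# Writing


def write_pdb(frames: StructureFrame | FrameStream | Sequence[StructureFrame], path: str | Path) -> None:
    """Write one or more frames as a (multi-MODEL) PDB file via gemmi."""
    import gemmi

    if isinstance(frames, StructureFrame):
        frames = [frames]
    structure = gemmi.Structure()
    structure.name = Path(path).stem
    for i, frame in enumerate(frames):
        model = gemmi.Model(i + 1)
        # Group contiguous runs by chain, building each chain fully before
        # adding it (gemmi's add_* copy; incremental references can dangle).
        chain_records: dict[str, list[AtomRecord]] = {}
        for record in frame.atoms:
            chain_records.setdefault(record.chain_id, []).append(record)
        for chain_id, records in chain_records.items():
            chain = gemmi.Chain(chain_id)
            current_res = None
            current_num = None
            for record in records:
                if current_res is None or current_num != record.residue_number:
                    if current_res is not None:
                        chain.add_residue(current_res)
                    current_res = gemmi.Residue()
                    current_res.name = record.residue_name
                    current_res.seqid = gemmi.SeqId(record.residue_number, " ")
                    current_num = record.residue_number
                atom = gemmi.Atom()
                atom.name = record.atom_name
                atom.pos = gemmi.Position(*record.position)
                atom.element = gemmi.Element(record.element or record.atom_name[0])
                atom.occ = 1.0
                current_res.add_atom(atom)
            if current_res is not None:
                chain.add_residue(current_res)
            model.add_chain(chain)
        structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))


def write_trajectory(stream: FrameStream, path: str | Path, topology_path: str | Path) -> None:
    """Write a frame stream as a binary trajectory (DCD/XTC) plus topology PDB."""
    import mdtraj as md

    write_pdb(stream.topology, topology_path)
    mdtop = md.load_topology(str(topology_path))
    xyz = np.stack([f.coordinates for f in stream]) / 10.0  # Å -> nm
    traj = md.Trajectory(xyz, mdtop)
    traj.save(str(path))


# ---------------------------------------------------------------------------
# Selection


def select_atoms(
    frame: StructureFrame,
    residues: Iterable[int] | None = None,
    atom_names: Iterable[str] | None = None,
    strict: bool = False,
) -> list[AtomRecord]:
    """Atoms matching both filters, in frame order.

    ``None`` for either filter means "no constraint". With ``strict=True`` an
    empty selection raises :class:`SelectionError` naming the unmatched
    residues.
    """
    residue_set = None if residues is None else {int(r) for r in residues}
    name_set = None if atom_names is None else set(atom_names)
    out = [
        a
        for a in frame.atoms
        if (residue_set is None or a.residue_number in residue_set)
        and (name_set is None or a.atom_name in name_set)
    ]
    if strict and not out:
        wanted = sorted(residue_set) if residue_set is not None else "<any>"
        names = sorted(name_set) if name_set is not None else "<any>"
        raise SelectionError(
            f"selection matched no atoms (residues {wanted}, atom names {names})"
        )
    return out


def coordinates_of(atoms: Sequence[AtomRecord]) -> np.ndarray:
    """(n, 3) coordinate array for a selection, in selection order."""
    return np.array([a.position for a in atoms], dtype=float).reshape(-1, 3)


# ---------------------------------------------------------------------------
# Descriptor tables


def write_descriptor_table(series: Sequence, path: str | Path) -> None:
    """Write DescriptorSeries to a TSV: one row per frame, one column per series.

    Columns are ``name (unit)`` in the order given; values with 6 significant
    digits, UTF-8, tab delimiter, '.' decimal separator.
    """
    lengths = {len(s.values) for s in series}
    if len(lengths) > 1:
        raise DimensionError(f"series have unequal frame counts {sorted(lengths)}")
    columns = [f"{s.name} ({s.unit})" for s in series]
    n = lengths.pop() if lengths else 0
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["frame"] + columns) + "\n")
        for i in range(n):
            row = [str(i)] + [f"{s.values[i]:.6g}" for s in series]
            fh.write("\t".join(row) + "\n")


def read_descriptor_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_descriptor_table`."""
    return pd.read_csv(path, sep="\t", index_col="frame")
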