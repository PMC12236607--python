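"""Shared fixtures: toy multi-domain structures and hand-written PDB text."""

import numpy as np
import pytest

from domainmotion.structure_io import DomainPartition, StructureFrame
from domainmotion.synthetic import GeneratorSpec, make_toy_multidomain


def pdb_atom_line(
    serial: int,
    name: str,
    res_name: str,
    chain: str,
    res_seq: int,
    x: float,
    y: float,
    z: float,
    element: str,
    altloc: str = " ",
    occupancy: float = 1.0,
) -> str:
    """Format one fixed-column PDB ATOM record."""
    padded_name = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:>5d} {padded_name}{altloc}{res_name:>3s} {chain}{res_seq:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}  0.00          {element:>2s}"
    )


@pytest.fixture(scope="session")
def toy_system() -> tuple[StructureFrame, DomainPartition]:
    spec = GeneratorSpec(seed=7, n_frames=1, coordinate_noise_sd=0.0)
    return make_toy_multidomain(spec)


@pytest.fixture()
def four_atom_pdb(tmp_path):
    lines = [
        pdb_atom_line(1, "CA", "ARG", "A", 4, 1.0, 2.0, 3.0, "C"),
        pdb_atom_line(2, "NE", "ARG", "A", 4, 2.5, 2.0, 3.0, "N"),
        pdb_atom_line(3, "CA", "GLU", "A", 139, 10.0, 0.0, 0.0, "C"),
        pdb_atom_line(4, "OE1", "GLU", "A", 139, 11.5, 0.25, 0.0, "O"),
        "END",
    ]
    path = tmp_path / "four_atoms.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture()
def multi_model_pdb(tmp_path):
    lines = []
    for m in range(1, 4):
        lines.append(f"MODEL     {m:>4d}")
        lines.append(pdb_atom_line(1, "CA", "ARG", "A", 4, 1.0 + m, 2.0, 3.0, "C"))
        lines.append(pdb_atom_line(2, "CA", "GLU", "A", 139, 10.0, float(m), 0.0, "C"))
        lines.append("ENDMDL")
    lines.append("END")
    path = tmp_path / "three_models.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture()
def altloc_pdb(tmp_path):
    # Two conformers of the same CA: B has the higher occupancy and must win.
    lines = [
        pdb_atom_line(1, "CA", "ARG", "A", 4, 1.0, 1.0, 1.0, "C", altloc="A", occupancy=0.4),
        pdb_atom_line(2, "CA", "ARG", "A", 4, 2.0, 2.0, 2.0, "C", altloc="B", occupancy=0.6),
        pdb_atom_line(3, "CA", "GLU", "A", 5, 3.0, 3.0, 3.0, "C"),
        "END",
    ]
    path = tmp_path / "altloc.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250922)
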