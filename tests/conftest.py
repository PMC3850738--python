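"""Shared fixtures: fixture-PDB writing and random toy complexes."""

from __future__ import annotations

import numpy as np
import pytest

from dockscore.potentials import AMINO_ACIDS
from dockscore.structures import AtomRecord, ComplexPartition, Residue, Structure

BACKBONE = ("N", "CA", "C", "O")


def pdb_line(serial, name, resname, chain, resseq, x, y, z, altloc=" ", icode=" ",
             element=None, hetatm=False):
    """One spec-compliant ATOM/HETATM line (columns 1-78)."""
    element = element or name[0]
    aname = name if len(name) >= 4 else f" {name:<3s}"
    rec = "HETATM" if hetatm else "ATOM  "
    return (f"{rec}{serial:5d} {aname}{altloc}{resname:>3s} {chain}{resseq:4d}{icode}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}")


def write_pdb_text(path, lines):
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


def make_residue(chain, resseq, name, atom_specs, serial_start=1):
    """Residue from [(atom_name, xyz), ...]."""
    atoms = [
        AtomRecord(serial_start + i, aname, "", name, chain, resseq, "",
                   aname[0], np.asarray(xyz, dtype=float))
        for i, (aname, xyz) in enumerate(atom_specs)
    ]
    return Residue(chain, resseq, "", name, atoms)


def random_complex(rng, n_rec=5, n_lig=5, spread=8.0, gap=4.0):
    """Two-chain toy: residues with backbone atoms at random positions.

    Residue centres are scattered in adjacent boxes so intermolecular
    distances straddle typical contact cutoffs.
    """
    residues = []
    for chain, n_res, offset in (("A", n_rec, 0.0), ("B", n_lig, spread + gap)):
        for i in range(n_res):
            centre = rng.uniform(0, spread, size=3)
            centre[0] += offset
            name = str(rng.choice(AMINO_ACIDS))
            atom_specs = [(a, centre + rng.normal(scale=0.7, size=3)) for a in BACKBONE]
            residues.append(make_residue(chain, i + 1, name, atom_specs))
    structure = Structure(residues)
    partition = ComplexPartition(frozenset({"A"}), frozenset({"B"}))
    return structure, partition


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def two_chain_pdb(tmp_path):
    """A minimal two-chain fixture file with known coordinates."""
    lines = [
        pdb_line(1, "N", "ALA", "A", 1, 1.0, 2.0, 3.0),
        pdb_line(2, "CA", "ALA", "A", 1, 2.0, 2.0, 3.0),
        pdb_line(3, "C", "ALA", "A", 1, 3.0, 2.0, 3.0),
        pdb_line(4, "O", "ALA", "A", 1, 3.5, 3.0, 3.0),
        pdb_line(5, "N", "GLY", "A", 2, 4.0, 2.0, 3.0),
        pdb_line(6, "CA", "GLY", "A", 2, 5.0, 2.0, 3.0),
        pdb_line(7, "C", "GLY", "A", 2, 6.0, 2.0, 3.0),
        pdb_line(8, "O", "GLY", "A", 2, 6.5, 3.0, 3.0),
        pdb_line(9, "N", "SER", "B", 1, 1.0, 6.0, 3.0),
        pdb_line(10, "CA", "SER", "B", 1, 2.0, 6.0, 3.0),
        pdb_line(11, "C", "SER", "B", 1, 3.0, 6.0, 3.0),
        pdb_line(12, "O", "SER", "B", 1, 3.5, 7.0, 3.0),
    ]
    return write_pdb_text(tmp_path / "two_chain.pdb", lines)
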