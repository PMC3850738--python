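"""Reading, writing and partitioning of protein complex coordinates.

The unit of currency throughout the package is a :class:`Structure`: an
ordered list of atoms grouped into residues and chains, with a
receptor/ligand chain partition (:class:`ComplexPartition`) layered on
top.  Structures are read from plain PDB coordinate files (ATOM/HETATM
records, columns 1-66 plus the element field).

Alternate locations follow the convention used when preparing docking
decoys: for each (chain, residue, atom name) with multiple location
indicators, only the first-encountered location is retained.  HETATM
records and waters are excluded by default because residue-level
potentials and docking quality measures are defined over amino acids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class PDBParseError(ValueError):
    """A malformed coordinate record; the message names the line number."""


class EmptyStructureError(ValueError):
    """A coordinate file with zero usable ATOM records."""


# Residue identity: (chain_id, residue_seq, insertion_code).  PDB numbering
# is preserved verbatim; insertion codes are part of the identity.
ResidueKey = tuple[str, int, str]


@dataclass
class AtomRecord:
    """One atom as read from a coordinate file."""

    serial: int
    name: str
    alt_loc: str
    residue_name: str
    chain_id: str
    residue_seq: int
    icode: str
    element: str
    position: np.ndarray
    hetatm: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("atom position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not self.name:
            raise ValueError("atom name must be non-empty")

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_seq, self.icode)

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    residue_seq: int
    icode: str
    name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.residue_seq, self.icode)

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_heavy]

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.position for a in self.heavy_atoms()], dtype=float)


class Structure:
    """An ordered collection of residues (each with >= 1 atom).

    Atom order within a residue and residue order within the structure
    follow the input file.  After alt-loc filtering no two atoms share
    (chain, residue, atom name).
    """

    def __init__(self, residues: Sequence[Residue]):
        self.residues: list[Residue] = [r for r in residues if r.atoms]
        self._index: dict[ResidueKey, Residue] = {r.key: r for r in self.residues}

    # -- construction -------------------------------------------------

    @classmethod
    def from_atoms(cls, atoms: Iterable[AtomRecord], altloc_policy: str = "first") -> "Structure":
        """Group atoms into residues, applying the alt-loc policy.

        ``altloc_policy='first'`` keeps, for each (chain, residue, atom
        name), only the first-encountered location; ``'all'`` keeps
        everything.  Filtering is idempotent and order-stable.
        """
        if altloc_policy not in ("first", "all"):
            raise ValueError(f"unknown altloc policy: {altloc_policy!r}")
        residues: dict[ResidueKey, Residue] = {}
        order: list[ResidueKey] = []
        seen: set[tuple[ResidueKey, str]] = set()
        for atom in atoms:
            key = atom.residue_key
            if altloc_policy == "first":
                sig = (key, atom.name)
                if sig in seen:
                    continue
                seen.add(sig)
            if key not in residues:
                residues[key] = Residue(atom.chain_id, atom.residue_seq, atom.icode, atom.residue_name)
                order.append(key)
            residues[key].atoms.append(atom)
        return cls([residues[k] for k in order])

    # -- views ---------------------------------------------------------

    @property
    def atoms(self) -> list[AtomRecord]:
        return [a for r in self.residues for a in r.atoms]

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for r in self.residues:
            if r.chain_id not in out:
                out.append(r.chain_id)
        return out

    def __len__(self) -> int:
        return len(self.atoms)

    def residue(self, key: ResidueKey) -> Residue:
        return self._index[key]

    def has_residue(self, key: ResidueKey) -> bool:
        return key in self._index

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def subset(self, chains: Iterable[str]) -> "Structure":
        """New Structure containing only the given chains (atoms shared)."""
        wanted = set(chains)
        return Structure([r for r in self.residues if r.chain_id in wanted])

    def copy(self) -> "Structure":
        residues = []
        for r in self.residues:
            atoms = [
                AtomRecord(a.serial, a.name, a.alt_loc, a.residue_name, a.chain_id,
                           a.residue_seq, a.icode, a.element, a.position.copy(), a.hetatm)
                for a in r.atoms
            ]
            residues.append(Residue(r.chain_id, r.residue_seq, r.icode, r.name, atoms))
        return Structure(residues)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    chains: Iterable[str] | None = None) -> "Structure":
        """Apply ``x -> R x + t`` to all atoms (or only to some chains)."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        wanted = set(chains) if chains is not None else None
        out = self.copy()
        for r in out.residues:
            if wanted is not None and r.chain_id not in wanted:
                continue
            for a in r.atoms:
                a.position = rotation @ a.position + translation
        return out


@dataclass(frozen=True)
class ComplexPartition:
    """Receptor/ligand split of a complex's chains (disjoint, exhaustive)."""

    receptor_chains: frozenset[str]
    ligand_chains: frozenset[str]

    def __post_init__(self) -> None:
        if self.receptor_chains & self.ligand_chains:
            raise ValueError("receptor and ligand chain sets must be disjoint")
        if not self.receptor_chains or not self.ligand_chains:
            raise ValueError("both receptor and ligand must contain >= 1 chain")

    def side_of(self, chain_id: str) -> str:
        if chain_id in self.receptor_chains:
            return "receptor"
        if chain_id in self.ligand_chains:
            return "ligand"
        raise KeyError(chain_id)


@dataclass
class DecoySet:
    """A docking case: a native complex plus its decoy poses."""

    case_id: str
    native: Structure
    decoys: list[tuple[str, Structure]]
    partition: ComplexPartition

    def decoy_ids(self) -> list[str]:
        return [d for d, _ in self.decoys]

    def decoy(self, decoy_id: str) -> Structure:
        for d, s in self.decoys:
            if d == decoy_id:
                return s
        raise KeyError(decoy_id)


# ----------------------------------------------------------------------
# PDB I/O
# ----------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = 0  # serial is cosmetic; tolerate overflow markers
    name = line[12:16].strip()
    alt_loc = line[16].strip()
    residue_name = line[17:20].strip()
    chain_id = line[21].strip() or " "
    try:
        residue_seq = int(line[22:26])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed residue number {line[22:26]!r}") from exc
    icode = line[26].strip()
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed coordinate field") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # fall back on the atom-name convention: first alphabetic character
        for ch in name:
            if ch.isalpha():
                element = ch
                break
    return AtomRecord(serial, name, alt_loc, residue_name, chain_id, residue_seq,
                      icode, element, np.array([x, y, z]),
                      hetatm=line.startswith("HETATM"))


def _read_pdb_atoms(path: str | Path, include_hetatm: bool, include_waters: bool,
                    model: int | None) -> list[AtomRecord]:
    atoms: list[AtomRecord] = []
    current_model = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec.startswith("MODEL"):
                try:
                    current_model = int(line.split()[1])
                except (IndexError, ValueError):
                    current_model += 1
                continue
            if rec.startswith("ENDMDL"):
                if model is None and atoms:
                    break  # default: first model only
                continue
            if not (rec.startswith("ATOM") or rec.startswith("HETATM")):
                continue
            if model is not None and current_model not in (0, model):
                continue
            atom = _parse_atom_line(line, lineno)
            if atom.hetatm:
                if atom.residue_name in _WATER_NAMES and not include_waters:
                    continue
                if not include_hetatm:
                    continue
            atoms.append(atom)
    return atoms


def read_pdb(path: str | Path, altloc_policy: str = "first",
             include_hetatm: bool = False, include_waters: bool = False,
             model: int | None = None) -> Structure:
    """Read a PDB coordinate file into a :class:`Structure`.

    Parameters
    ----------
    altloc_policy
        ``'first'`` (default) keeps the first-encountered location for
        each atom with alternate location indicators; ``'all'`` keeps all.
    include_hetatm, include_waters
        HETATM records and waters are dropped by default.
    model
        For multi-MODEL files, which model to read (default: the first).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    atoms = _read_pdb_atoms(path, include_hetatm, include_waters, model)
    if not atoms:
        raise EmptyStructureError(f"{path}: no ATOM records")
    return Structure.from_atoms(atoms, altloc_policy=altloc_policy)


def read_models(path: str | Path, **kwargs) -> list[Structure]:
    """Read every MODEL of a multi-model PDB file as a separate Structure."""
    models: dict[int, list[str]] = {}
    current = 1
    with open(path) as fh:
        lines = fh.readlines()
    numbers: list[int] = []
    for line in lines:
        if line.startswith("MODEL"):
            try:
                current = int(line.split()[1])
            except (IndexError, ValueError):
                current += 1
        elif line.startswith(("ATOM", "HETATM")):
            models.setdefault(current, []).append(line)
            if current not in numbers:
                numbers.append(current)
    out = []
    for num in numbers:
        atoms = [_parse_atom_line(l, i + 1) for i, l in enumerate(models[num])]
        atoms = [a for a in atoms if not a.hetatm]
        if atoms:
            out.append(Structure.from_atoms(atoms, **kwargs))
    return out


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a Structure as minimal, column-compliant PDB text."""
    with open(path, "w") as fh:
        serial = 0
        last_chain = None
        for res in structure.residues:
            if last_chain is not None and res.chain_id != last_chain:
                fh.write("TER\n")
            last_chain = res.chain_id
            for a in res.atoms:
                serial += 1
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                fh.write(
                    f"{'HETATM' if a.hetatm else 'ATOM  '}{serial:5d} {name}{a.alt_loc or ' '}"
                    f"{res.name:>3s} {res.chain_id}{res.residue_seq:4d}{a.icode or ' '}   "
                    f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}\n"
                )
        fh.write("TER\nEND\n")


# ----------------------------------------------------------------------
# Partitioning and backbone selection
# ----------------------------------------------------------------------

def partition_complex(structure: Structure,
                      receptor_chains: Iterable[str] | None = None) -> ComplexPartition:
    """Split a complex's chains into receptor and ligand.

    With an explicit ``receptor_chains`` the complement becomes the
    ligand.  Without one, the larger molecule (by atom count) is the
    receptor; with more than two chains the single smallest chain is the
    ligand and the rest the receptor.
    """
    chains = structure.chains
    if len(chains) < 2:
        raise ValueError("cannot partition a single-chain structure")
    chain_set = set(chains)
    if receptor_chains is not None:
        rec = set(receptor_chains)
        missing = rec - chain_set
        if missing:
            raise ValueError(f"receptor chains not in structure: {sorted(missing)}")
        lig = chain_set - rec
        if not lig:
            raise ValueError("receptor chains cover the whole structure; no ligand left")
        return ComplexPartition(frozenset(rec), frozenset(lig))
    counts = {c: sum(len(r.atoms) for r in structure.residues if r.chain_id == c)
              for c in chains}
    smallest = min(chains, key=lambda c: (counts[c], chains.index(c)))
    lig = {smallest}
    rec = chain_set - lig
    return ComplexPartition(frozenset(rec), frozenset(lig))


@dataclass
class BackboneSelection:
    """Ordered backbone coordinates with their (residue key, atom name) index."""

    keys: list[tuple[ResidueKey, str]]
    coords: np.ndarray
    missing: list[tuple[ResidueKey, str]] = field(default_factory=list)


def select_backbone(structure: Structure,
                    residue_keys: Iterable[ResidueKey] | None = None,
                    atom_names: Sequence[str] = BACKBONE_ATOMS) -> BackboneSelection:
    """Ordered N, CA, C, O coordinates per residue, in residue order.

    Missing backbone atoms are skipped and recorded in ``missing`` so a
    paired selection on another structure can mirror the exclusions.
    """
    wanted = set(residue_keys) if residue_keys is not None else None
    keys: list[tuple[ResidueKey, str]] = []
    coords: list[np.ndarray] = []
    missing: list[tuple[ResidueKey, str]] = []
    for res in structure.residues:
        if wanted is not None and res.key not in wanted:
            continue
        found_any = False
        for name in atom_names:
            atom = res.atom(name)
            if atom is None:
                missing.append((res.key, name))
                continue
            keys.append((res.key, name))
            coords.append(atom.position)
            found_any = True
        if not found_any:
            logger.warning("residue %s has no backbone atoms; excluded from RMSD sets", res.key)
    if missing:
        logger.warning("%d backbone atoms missing; excluded pairwise", len(missing))
    arr = np.array(coords, dtype=float) if coords else np.empty((0, 3))
    return BackboneSelection(keys, arr, missing)


def paired_backbone(a: Structure, b: Structure,
                    residue_keys: Iterable[ResidueKey] | None = None,
                    atom_names: Sequence[str] = BACKBONE_ATOMS) -> tuple[np.ndarray, np.ndarray]:
    """Index-aligned backbone coordinate arrays over atoms present in both.

    Exclusions are mirrored: an atom missing on either side is dropped
    from both, so the two arrays always have equal length.
    """
    sel_a = select_backbone(a, residue_keys, atom_names)
    sel_b = select_backbone(b, residue_keys, atom_names)
    index_b = {k: i for i, k in enumerate(sel_b.keys)}
    coords_a, coords_b = [], []
    for i, k in enumerate(sel_a.keys):
        j = index_b.get(k)
        if j is None:
            continue
        coords_a.append(sel_a.coords[i])
        coords_b.append(sel_b.coords[j])
    if not coords_a:
        return np.empty((0, 3)), np.empty((0, 3))
    return np.array(coords_a), np.array(coords_b)


# ----------------------------------------------------------------------
# Decoy-set validation
# ----------------------------------------------------------------------

def validate_decoy_set(decoy_set: DecoySet) -> list[dict]:
    """Report per-decoy mismatches versus the native (report-only).

    Each entry is a dict with keys ``decoy_id``, ``kind`` (one of
    ``residue_count``, ``sequence``, ``atom_count``) and ``detail``.  A
    decoy failing sequence identity is flagged unusable downstream.
    """
    report: list[dict] = []
    native = decoy_set.native
    nat_seq = [(r.key, r.name) for r in native.residues]
    nat_atoms = len(native.atoms)
    for decoy_id, structure in decoy_set.decoys:
        seq = [(r.key, r.name) for r in structure.residues]
        if len(seq) != len(nat_seq):
            report.append({"decoy_id": decoy_id, "kind": "residue_count",
                           "detail": f"native {len(nat_seq)} vs decoy {len(seq)}"})
        mismatches = [(kn, nn, dn) for (kn, nn), (_, dn) in zip(nat_seq, seq) if nn != dn]
        if mismatches:
            k, nn, dn = mismatches[0]
            report.append({"decoy_id": decoy_id, "kind": "sequence",
                           "detail": f"residue {k}: native {nn} vs decoy {dn} "
                                     f"({len(mismatches)} total)"})
        n_atoms = len(structure.atoms)
        if n_atoms != nat_atoms:
            report.append({"decoy_id": decoy_id, "kind": "atom_count",
                           "detail": f"native {nat_atoms} vs decoy {n_atoms}"})
    return report
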