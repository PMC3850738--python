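"""CAPRI docking quality measures and the four-class quality labels.

Every decoy is compared with the native complex through three measures:

* **fnat** — the fraction of the native's intermolecular residue-residue
  contacts recovered by the decoy;
* **LRMSD** — backbone RMSD over ligand residues after superposing the
  decoy's receptor backbone onto the native receptor (the ligand is
  never re-fit);
* **IRMSD** — minimal backbone RMSD over the native-interface residues
  after superposing the decoy interface onto the native interface.

A residue contact means at least one heavy-atom pair within 5 A (the
CAPRI convention; configurable).  Interface residues are those of either
molecule with a heavy atom within 10 A of the other molecule in the
NATIVE complex.  Backbone atoms N, CA, C, O enter both RMSDs with equal
weights; hydrogens are ignored throughout.

The three measures feed boolean predicates assigning each decoy one of
four quality classes — incorrect, acceptable, medium, high — evaluated
highest-first so boundary ties resolve upward.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structures import ComplexPartition, DecoySet, ResidueKey, Structure, paired_backbone

DEFAULT_CONTACT_CUTOFF = 5.0     # A, heavy-atom residue-contact rule
DEFAULT_INTERFACE_CUTOFF = 10.0  # A, native-interface definition for IRMSD

ContactSet = frozenset  # of (receptor ResidueKey, ligand ResidueKey)


class QualityClass(enum.IntEnum):
    """Ordered docking-quality labels (ordinal rank 0-3)."""

    INCORRECT = 0
    ACCEPTABLE = 1
    MEDIUM = 2
    HIGH = 3

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "QualityClass":
        return cls[label.upper()]


@dataclass(frozen=True)
class QualityMetrics:
    fnat: float
    irmsd: float
    lrmsd: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.fnat) and np.isfinite(self.irmsd) and np.isfinite(self.lrmsd)):
            raise ValueError("quality metrics must be finite")
        if not 0.0 <= self.fnat <= 1.0:
            raise ValueError(f"fnat out of [0,1]: {self.fnat}")
        if self.irmsd < 0 or self.lrmsd < 0:
            raise ValueError("RMSD values must be non-negative")


@dataclass(frozen=True)
class SuperpositionResult:
    """Proper rotation + translation minimising RMSD, and that RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


# ----------------------------------------------------------------------
# Contacts and fnat
# ----------------------------------------------------------------------

def _side_heavy_atoms(structure: Structure, chains: frozenset[str]):
    coords, keys = [], []
    for res in structure.residues:
        if res.chain_id not in chains:
            continue
        for atom in res.heavy_atoms():
            coords.append(atom.position)
            keys.append(res.key)
    return np.array(coords, dtype=float), keys


def intermolecular_contacts(structure: Structure, partition: ComplexPartition,
                            cutoff: float = DEFAULT_CONTACT_CUTOFF) -> ContactSet:
    """All (receptor residue, ligand residue) pairs with a heavy-atom pair <= cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    rec_xyz, rec_keys = _side_heavy_atoms(structure, partition.receptor_chains)
    lig_xyz, lig_keys = _side_heavy_atoms(structure, partition.ligand_chains)
    if len(rec_xyz) == 0 or len(lig_xyz) == 0:
        raise ValueError("one side of the partition has no heavy atoms")
    tree_r = cKDTree(rec_xyz)
    tree_l = cKDTree(lig_xyz)
    pairs = set()
    for i, neighbours in enumerate(tree_r.query_ball_tree(tree_l, cutoff)):
        for j in neighbours:
            pairs.add((rec_keys[i], lig_keys[j]))
    return frozenset(pairs)


def fnat(native_contacts: ContactSet, decoy_contacts: ContactSet) -> float:
    """Fraction of native contacts retained by the decoy."""
    if not native_contacts:
        raise ValueError("fnat undefined for an empty native contact set")
    return len(native_contacts & decoy_contacts) / len(native_contacts)


# ----------------------------------------------------------------------
# Superposition and RMSDs
# ----------------------------------------------------------------------

def kabsch_superpose(ref_coords: np.ndarray, mov_coords: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mov`` onto ``ref``.

    Returns the proper rotation R and translation t minimising
    ``RMS(R mov + t - ref)`` together with that minimal RMSD.
    """
    ref = np.asarray(ref_coords, dtype=float)
    mov = np.asarray(mov_coords, dtype=float)
    if ref.shape != mov.shape:
        raise ValueError(f"coordinate shapes differ: {ref.shape} vs {mov.shape}")
    if ref.ndim != 2 or ref.shape[1] != 3 or ref.shape[0] < 3:
        raise ValueError("need >= 3 points of dimension 3")
    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref - ref_c, mov - mov_c)
    rmsd = float(rssd / np.sqrt(len(ref)))
    matrix = rot.as_matrix()
    translation = ref_c - matrix @ mov_c
    return SuperpositionResult(matrix, translation, rmsd)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (un-fit) coordinate RMSD of two equal-length arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coordinate shapes differ")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def lrmsd(native: Structure, decoy: Structure, partition: ComplexPartition) -> float:
    """Ligand backbone RMSD after receptor-to-receptor superposition.

    The decoy receptor backbone is superposed onto the native receptor
    backbone; the resulting transform is applied to the decoy ligand and
    the RMSD taken over ligand backbone atoms without a second fit.
    """
    rec_keys = {r.key for r in native.residues if r.chain_id in partition.receptor_chains}
    lig_keys = {r.key for r in native.residues if r.chain_id in partition.ligand_chains}
    nat_rec, dec_rec = paired_backbone(native, decoy, rec_keys)
    if len(nat_rec) < 3:
        raise ValueError("receptor backbone has fewer than 3 paired atoms")
    sup = kabsch_superpose(nat_rec, dec_rec)
    nat_lig, dec_lig = paired_backbone(native, decoy, lig_keys)
    if len(nat_lig) == 0:
        raise ValueError("no paired ligand backbone atoms")
    return rmsd(nat_lig, sup.apply(dec_lig))


def interface_residues(native: Structure, partition: ComplexPartition,
                       cutoff: float = DEFAULT_INTERFACE_CUTOFF) -> set[ResidueKey]:
    """Residues of either molecule with a heavy atom within ``cutoff`` of the other."""
    rec_xyz, rec_keys = _side_heavy_atoms(native, partition.receptor_chains)
    lig_xyz, lig_keys = _side_heavy_atoms(native, partition.ligand_chains)
    tree_l = cKDTree(lig_xyz)
    out: set[ResidueKey] = set()
    for i, neighbours in enumerate(cKDTree(rec_xyz).query_ball_tree(tree_l, cutoff)):
        if neighbours:
            out.add(rec_keys[i])
            for j in neighbours:
                out.add(lig_keys[j])
    return out


def irmsd(native: Structure, decoy: Structure, partition: ComplexPartition,
          interface_cutoff: float = DEFAULT_INTERFACE_CUTOFF) -> float:
    """Minimal backbone RMSD over native-interface residues."""
    iface = interface_residues(native, partition, interface_cutoff)
    if not iface:
        raise ValueError("native interface is empty at this cutoff")
    nat, dec = paired_backbone(native, decoy, iface)
    if len(nat) < 3:
        raise ValueError("interface backbone has fewer than 3 paired atoms")
    return kabsch_superpose(nat, dec).rmsd


# ----------------------------------------------------------------------
# Classification
# ----------------------------------------------------------------------

def classify_quality(metrics: QualityMetrics) -> QualityClass:
    """Assign the four-class quality label from (fnat, LRMSD, IRMSD).

    Predicates are evaluated highest class first:

    * high:        fnat >= 0.5 and (LRMSD <= 1 or IRMSD <= 1)
    * medium:      (fnat >= 0.5 and LRMSD > 1 and IRMSD > 1)
                   or (0.3 <= fnat < 0.5 and (LRMSD <= 5 or IRMSD <= 2))
    * acceptable:  (fnat >= 0.3 and LRMSD > 5 and IRMSD > 2)
                   or (0.1 <= fnat < 0.3 and (LRMSD <= 10 or IRMSD <= 4))
    * incorrect:   otherwise (fnat < 0.1, or LRMSD > 10 and IRMSD > 4)
    """
    f, l, i = metrics.fnat, metrics.lrmsd, metrics.irmsd
    if f >= 0.5 and (l <= 1.0 or i <= 1.0):
        return QualityClass.HIGH
    if (f >= 0.5 and l > 1.0 and i > 1.0) or (0.3 <= f < 0.5 and (l <= 5.0 or i <= 2.0)):
        return QualityClass.MEDIUM
    if (f >= 0.3 and l > 5.0 and i > 2.0) or (0.1 <= f < 0.3 and (l <= 10.0 or i <= 4.0)):
        return QualityClass.ACCEPTABLE
    return QualityClass.INCORRECT


# ----------------------------------------------------------------------
# Per-case driver
# ----------------------------------------------------------------------

def evaluate_decoy_set(decoy_set: DecoySet,
                       contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
                       interface_cutoff: float = DEFAULT_INTERFACE_CUTOFF) -> pd.DataFrame:
    """Quality table for every decoy of a case.

    Returns a DataFrame indexed by decoy id with columns
    ``fnat, irmsd, lrmsd, quality`` (lower-case label) plus the
    :class:`QualityClass` objects in column ``class``.
    """
    native = decoy_set.native
    partition = decoy_set.partition
    native_contacts = intermolecular_contacts(native, partition, contact_cutoff)
    rows = []
    for decoy_id, decoy in decoy_set.decoys:
        contacts = intermolecular_contacts(decoy, partition, contact_cutoff)
        m = QualityMetrics(
            fnat=fnat(native_contacts, contacts),
            irmsd=irmsd(native, decoy, partition, interface_cutoff),
            lrmsd=lrmsd(native, decoy, partition),
        )
        cls = classify_quality(m)
        rows.append({"decoy_id": decoy_id, "fnat": m.fnat, "irmsd": m.irmsd,
                     "lrmsd": m.lrmsd, "quality": str(cls), "class": cls})
    table = pd.DataFrame(rows).set_index("decoy_id")
    # keep QualityClass objects (pandas would otherwise coerce the IntEnum)
    table["class"] = pd.Series([r["class"] for r in rows], index=table.index, dtype=object)
    return table


def write_quality_table(table: pd.DataFrame, path) -> None:
    """Per-case quality table as TSV: decoy_id, fnat, irmsd, lrmsd, class."""
    out = table[["fnat", "irmsd", "lrmsd", "quality"]].rename(columns={"quality": "class"})
    out.to_csv(path, sep="\t", float_format="%.4f")
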