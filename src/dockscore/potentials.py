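"""Residue-level statistical contact and distance-bin potentials.

This module is a generic engine for the large family of coarse-grain
scoring functions built from a symmetric 20x20 (x distance-bin) energy
table and a geometric contact rule.  A potential is fully described by

* a :class:`ContactMatrix` — the energy per (residue type, residue
  type, bin), loaded from a plain-text matrix file; and
* a :class:`ContactDefinition` — which point represents a residue
  (C-beta with a CA fallback for glycine, the heavy-atom centroid, or
  the minimum heavy-atom distance) and the distance bins.

Two application modes are supported.  ``intermolecular`` sums energies
over receptor-ligand residue pairs only.  ``separable`` evaluates the
same scorer on the complex, the isolated receptor and the isolated
ligand and reports ``E_complex - (E_receptor + E_ligand)``; for a
pairwise-additive potential the intramolecular terms cancel exactly and
the two modes agree.

Score direction matters: for most potentials lower (more negative) is
better, but count-like metrics rank descending.  :class:`MetricSpec`
records the direction so ranking downstream needs no special cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structures import ComplexPartition, DecoySet, Residue, Structure

logger = logging.getLogger(__name__)

AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Non-standard residues mapped to their standard parent; anything absent
# from this table is skipped with a warning.
PARENT_RESIDUES = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO", "SEP": "SER",
    "TPO": "THR", "PTR": "TYR", "CSO": "CYS", "HSD": "HIS", "HSE": "HIS",
    "HSP": "HIS", "MLY": "LYS", "CME": "CYS",
}

REPRESENTATIVES = ("c_beta", "centroid", "min_heavy_atom")

# Default single-interval contact rules per representative mode; the
# common conventions of the respective potential families.
DEFAULT_CUTOFFS = {"c_beta": 8.0, "centroid": 8.5, "min_heavy_atom": 5.0}


@dataclass(frozen=True)
class ContactDefinition:
    """Geometric rule deciding when (and in which bin) two residues interact."""

    representative: str = "min_heavy_atom"
    bins: tuple[tuple[float, float], ...] = ((0.0, 5.0),)

    def __post_init__(self) -> None:
        if self.representative not in REPRESENTATIVES:
            raise ValueError(f"unknown representative {self.representative!r}")
        if not self.bins:
            raise ValueError("at least one distance bin is required")
        last_hi = 0.0
        for lo, hi in self.bins:
            if not (np.isfinite(hi) and lo < hi):
                raise ValueError(f"bad bin ({lo}, {hi})")
            if lo < last_hi:
                raise ValueError("bins must be non-overlapping and ascending")
            last_hi = hi

    @property
    def max_distance(self) -> float:
        return self.bins[-1][1]

    def bin_of(self, distance: float) -> int:
        """Bin index for a distance, or -1 if in no bin."""
        for b, (lo, hi) in enumerate(self.bins):
            if lo <= distance <= hi:
                return b
        return -1

    def bin_of_array(self, distances: np.ndarray) -> np.ndarray:
        out = np.full(distances.shape, -1, dtype=int)
        for b, (lo, hi) in enumerate(self.bins):
            out[(distances >= lo) & (distances <= hi)] = b
        return out


class ContactMatrix:
    """Symmetric residue-pair energy table: entries[i, j, b] in arbitrary units."""

    def __init__(self, name: str, entries: np.ndarray,
                 definition: ContactDefinition | None = None):
        entries = np.asarray(entries, dtype=float)
        if entries.ndim == 2:
            entries = entries[:, :, None]
        if entries.shape[0] != 20 or entries.shape[1] != 20:
            raise ValueError("entries must be 20 x 20 (x bins)")
        if not np.all(np.isfinite(entries)):
            raise ValueError("matrix entries must be finite")
        asym = np.max(np.abs(entries - entries.transpose(1, 0, 2)))
        if asym > 1e-9:
            logger.warning("matrix %s asymmetric by %.3g; symmetrised by averaging", name, asym)
        self.name = name
        self.entries = 0.5 * (entries + entries.transpose(1, 0, 2))
        self.definition = definition or ContactDefinition()
        if self.entries.shape[2] != len(self.definition.bins):
            raise ValueError("number of bins in entries and definition disagree")

    @property
    def n_bins(self) -> int:
        return self.entries.shape[2]

    def value(self, res_a: str, res_b: str, b: int = 0) -> float:
        return float(self.entries[AA_INDEX[res_a], AA_INDEX[res_b], b])


def standard_type(residue_name: str) -> str | None:
    """Map a residue name to one of the 20 standard types, or None."""
    if residue_name in AA_INDEX:
        return residue_name
    parent = PARENT_RESIDUES.get(residue_name)
    if parent is not None:
        return parent
    return None


# ----------------------------------------------------------------------
# Matrix file I/O
#
# Plain-text format: header lines `#name NAME`, `#representative MODE`,
# `#bins lo:hi[,lo:hi...]`, then rows `RES1 RES2 BIN_INDEX VALUE`.
# ----------------------------------------------------------------------

def load_contact_matrix(path: str | Path, strict: bool = False) -> ContactMatrix:
    """Read a contact-potential matrix file.

    Symmetry is enforced by mirroring/averaging.  Pairs absent from the
    file default to 0.0 unless ``strict`` is set, in which case an
    incomplete file raises.
    """
    path = Path(path)
    name = path.stem
    representative = "min_heavy_atom"
    bins: tuple[tuple[float, float], ...] | None = None
    values: dict[tuple[int, int, int], float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split(None, 1)
                if not parts:
                    continue
                key = parts[0].lower()
                val = parts[1].strip() if len(parts) > 1 else ""
                if key == "name":
                    name = val
                elif key == "representative":
                    representative = val
                elif key == "bins":
                    try:
                        bins = tuple(
                            (float(lo), float(hi))
                            for lo, hi in (seg.split(":") for seg in val.split(","))
                        )
                    except ValueError as exc:
                        raise ValueError(f"{path}:{lineno}: malformed bins header") from exc
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 'RES1 RES2 BIN VALUE'")
            r1, r2, b_s, v_s = fields
            if r1 not in AA_INDEX or r2 not in AA_INDEX:
                raise ValueError(f"{path}:{lineno}: unknown residue type {r1} or {r2}")
            try:
                b = int(b_s)
                v = float(v_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric entry") from exc
            values[(AA_INDEX[r1], AA_INDEX[r2], b)] = v
    if bins is None:
        cutoff = DEFAULT_CUTOFFS.get(representative, 5.0)
        bins = ((0.0, cutoff),)
    n_bins = len(bins)
    entries = np.zeros((20, 20, n_bins))
    filled = np.zeros((20, 20, n_bins), dtype=bool)
    for (i, j, b), v in values.items():
        if b >= n_bins:
            raise ValueError(f"{path}: bin index {b} outside declared bins")
        rev = (j, i, b)
        if filled[i, j, b] and abs(entries[i, j, b] - v) > 1e-9:
            logger.warning("%s: asymmetric pair %s/%s bin %d; averaging",
                           path, AMINO_ACIDS[i], AMINO_ACIDS[j], b)
            v = 0.5 * (entries[i, j, b] + v)
        entries[i, j, b] = v
        entries[j, i, b] = v
        filled[i, j, b] = True
        filled[rev] = True
    if strict and not filled.all():
        n_missing = int((~filled).sum())
        raise ValueError(f"{path}: {n_missing} matrix entries missing (strict mode)")
    definition = ContactDefinition(representative, bins)
    return ContactMatrix(name, entries, definition)


def write_contact_matrix(matrix: ContactMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#name {matrix.name}\n")
        fh.write(f"#representative {matrix.definition.representative}\n")
        fh.write("#bins " + ",".join(f"{lo:g}:{hi:g}" for lo, hi in matrix.definition.bins) + "\n")
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS[i:], start=i):
                bname = AMINO_ACIDS[j]
                for k in range(matrix.n_bins):
                    fh.write(f"{a} {bname} {k} {matrix.entries[i, j, k]:.6f}\n")


def builtin_matrix() -> ContactMatrix:
    """The packaged exemplar matrix (synthetic quasi-chemical-style values)."""
    ref = resources.files("dockscore") / "data" / "synthetic_quasichemical.cpm"
    with resources.as_file(ref) as path:
        return load_contact_matrix(path)


# ----------------------------------------------------------------------
# Scoring
# ----------------------------------------------------------------------

def residue_representative(residue: Residue, definition: ContactDefinition):
    """The residue's representative point (or heavy-atom set in min mode)."""
    heavy = residue.heavy_atoms()
    if not heavy:
        raise ValueError(f"residue {residue.key} has no heavy atoms")
    mode = definition.representative
    if mode == "c_beta":
        atom = residue.atom("CB") or residue.atom("CA")
        if atom is None:
            raise ValueError(f"residue {residue.key} has neither CB nor CA")
        return atom.position
    if mode == "centroid":
        return residue.heavy_coords().mean(axis=0)
    return residue.heavy_coords()  # min_heavy_atom: the full set


def _typed_residues(structure: Structure, chains: frozenset[str] | None = None):
    """(residue, type index) for residues with a standard type; warn otherwise."""
    out = []
    for res in structure.residues:
        if chains is not None and res.chain_id not in chains:
            continue
        t = standard_type(res.name)
        if t is None:
            logger.warning("residue %s (%s) has no standard type; skipped", res.key, res.name)
            continue
        out.append((res, AA_INDEX[t]))
    return out


def _pair_distances(res_a, res_b, definition: ContactDefinition) -> np.ndarray:
    """Representative distance matrix between two residue lists."""
    if definition.representative == "min_heavy_atom":
        dists = np.empty((len(res_a), len(res_b)))
        coords_b = [r.heavy_coords() for r, _ in res_b]
        for i, (ra, _) in enumerate(res_a):
            ca = ra.heavy_coords()
            for j, cb in enumerate(coords_b):
                dists[i, j] = cdist(ca, cb).min()
        return dists
    pa = np.array([residue_representative(r, definition) for r, _ in res_a])
    pb = np.array([residue_representative(r, definition) for r, _ in res_b])
    return cdist(pa, pb)


def score_intermolecular(structure: Structure, partition: ComplexPartition,
                         matrix: ContactMatrix,
                         definition: ContactDefinition | None = None) -> float:
    """Sum of matrix energies over receptor-ligand residue pairs in contact."""
    definition = definition or matrix.definition
    rec = _typed_residues(structure, partition.receptor_chains)
    lig = _typed_residues(structure, partition.ligand_chains)
    if not rec or not lig:
        return 0.0
    dists = _pair_distances(rec, lig, definition)
    bins = definition.bin_of_array(dists)
    total = 0.0
    ii, jj = np.nonzero(bins >= 0)
    for i, j in zip(ii, jj):
        total += matrix.entries[rec[i][1], lig[j][1], bins[i, j]]
    return float(total)


def score_all_pairs(structure: Structure, matrix: ContactMatrix,
                    definition: ContactDefinition | None = None) -> float:
    """Energy over ALL residue pairs (intra- and intermolecular).

    This is the structure-level scorer used in separable mode; every
    unordered residue pair is counted once.
    """
    definition = definition or matrix.definition
    res = _typed_residues(structure)
    if len(res) < 2:
        return 0.0
    dists = _pair_distances(res, res, definition)
    bins = definition.bin_of_array(dists)
    total = 0.0
    for i in range(len(res)):
        for j in range(i + 1, len(res)):
            b = bins[i, j]
            if b >= 0:
                total += matrix.entries[res[i][1], res[j][1], b]
    return float(total)


def score_separable(complex_s: Structure, receptor_s: Structure, ligand_s: Structure,
                    scorer: Callable[[Structure], float]) -> float:
    """``E_complex - (E_receptor + E_ligand)`` with one structure-level scorer.

    The isolated molecules must jointly account for the complex's atom
    composition; the scorer sees intramolecular terms in all three
    evaluations, so for additive potentials they cancel.
    """
    def composition(s: Structure):
        return sorted((a.chain_id, a.residue_seq, a.icode, a.name) for a in s.atoms)

    if composition(complex_s) != sorted(composition(receptor_s) + composition(ligand_s)):
        raise ValueError("receptor + ligand atom composition does not match the complex")
    return scorer(complex_s) - (scorer(receptor_s) + scorer(ligand_s))


# ----------------------------------------------------------------------
# Metric registry and decoy-set scoring
# ----------------------------------------------------------------------

@dataclass
class MetricSpec:
    """A registered scoring metric: name, direction, mode and scorer.

    ``scorer(structure, partition)`` returns a float; ``direction`` is
    ``ascending_better`` (lower score = more promising, the energy
    convention) or ``descending_better`` (count-like metrics).
    """

    name: str
    scorer: Callable[[Structure, ComplexPartition], float]
    direction: str = "ascending_better"
    mode: str = "intermolecular"

    def __post_init__(self) -> None:
        if self.direction not in ("ascending_better", "descending_better"):
            raise ValueError(f"unknown direction {self.direction!r}")


def contact_potential_metric(matrix: ContactMatrix,
                             definition: ContactDefinition | None = None,
                             mode: str = "intermolecular",
                             name: str | None = None,
                             direction: str = "ascending_better") -> MetricSpec:
    """Wrap a contact matrix as a ready-to-use MetricSpec."""
    definition = definition or matrix.definition

    if mode == "intermolecular":
        def scorer(structure: Structure, partition: ComplexPartition) -> float:
            return score_intermolecular(structure, partition, matrix, definition)
    elif mode == "separable":
        def scorer(structure: Structure, partition: ComplexPartition) -> float:
            return score_separable(
                structure,
                structure.subset(partition.receptor_chains),
                structure.subset(partition.ligand_chains),
                lambda s: score_all_pairs(s, matrix, definition),
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return MetricSpec(name or matrix.name, scorer, direction, mode)


def score_decoy_set(decoy_set: DecoySet, metrics: Sequence[MetricSpec]) -> pd.DataFrame:
    """Score every decoy with every metric.

    Returns a DataFrame indexed by decoy id, one column per metric.  A
    metric failing on a decoy yields NaN (recorded, not fatal), and that
    decoy is simply excluded from that metric's ranking downstream.
    """
    rows = {}
    for decoy_id, structure in decoy_set.decoys:
        row = {}
        for metric in metrics:
            try:
                row[metric.name] = float(metric.scorer(structure, decoy_set.partition))
            except Exception as exc:  # noqa: BLE001 - per-decoy failures are data
                logger.warning("metric %s failed on %s/%s: %s",
                               metric.name, decoy_set.case_id, decoy_id, exc)
                row[metric.name] = np.nan
        rows[decoy_id] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "decoy_id"
    return table[[m.name for m in metrics]]


def write_score_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", na_rep="NA", float_format="%.6f")


def read_score_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="decoy_id", na_values=["NA"])
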