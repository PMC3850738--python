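"""Synthetic desk-scale docking benchmarks with known ground truth.

Real decoy benchmarks (hundreds of complexes, ~500 docked poses each)
are large and not redistributable, so this module builds miniature but
structurally honest stand-ins:

* **Native complexes** — two idealized poly-alanine (or user-sequence)
  alpha-helices built from standard backbone internal coordinates
  (NeRF chain extension, phi = -57, psi = -47), placed side by side so
  the interface has at least five residue contacts at the 5 A rule.
* **Decoys** — rigid-body perturbations of the ligand helix (rotation
  about its centroid plus a translation of scheduled magnitude in a
  random direction).  Quality labels are *computed* by the real CAPRI
  classifier on the generated coordinates, never assigned; a schedule
  spanning 0 to >= 30 A reaches all four classes.
* **Scores** — per-metric synthetic scores built from a latent pose
  energy (quality ordinal plus LRMSD) mixed with seeded Gaussian noise
  so that the Spearman correlation with the latent is approximately a
  requested informativeness rho.  Metrics can share noise (planting
  cluster structure in the set-overlap analysis) or use a planted
  per-case success probability (the case is scored by the noiseless
  latent with probability p, by its inversion otherwise), which makes
  top-10 success rates Bernoulli with known p.

Everything is deterministic under fixed seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from scipy.stats import norm, rankdata

from . import quality as _quality
from .evaluation import CaseResult
from .potentials import AMINO_ACIDS
from .quality import QualityClass, evaluate_decoy_set
from .ranking import DEFAULT_CLUSTER_THRESHOLD, rank_case
from .structures import AtomRecord, ComplexPartition, DecoySet, Residue, Structure

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

# Scheduled rigid perturbations: (translation A, rotation degrees, count).
# The default spans near-native to fully dissociated so that all four
# quality classes are reachable, with the bulk incorrect as in real
# docking decoy sets.
ScheduleEntry = tuple[float, float, int]


def default_schedule(n_decoys: int = 500) -> list[ScheduleEntry]:
    """Perturbation schedule emulating a docking run's quality profile."""
    # Near-natives are sparse, as in real docking runs: the large
    # majority of poses are incorrect, and only a handful per case reach
    # acceptable or better.
    fractions = [
        (0.0, 0.0, 0.005),    # exact natives -> high
        (0.4, 3.0, 0.01),     # near-native -> high/medium
        (1.5, 8.0, 0.02),     # -> medium
        (3.0, 12.0, 0.03),    # -> medium/acceptable
        (6.0, 20.0, 0.045),   # -> acceptable
        (12.0, 45.0, 0.09),   # borderline
        (25.0, 90.0, 0.45),   # incorrect
        (40.0, 180.0, 0.35),  # incorrect, widely scattered
    ]
    return _schedule_from_fractions(fractions, n_decoys)


def _schedule_from_fractions(fractions, n_decoys):
    schedule = []
    assigned = 0
    for t, r, frac in fractions[:-1]:
        count = max(1, int(round(frac * n_decoys)))
        schedule.append((t, r, count))
        assigned += count
    t, r, _ = fractions[-1]
    schedule.append((t, r, max(1, n_decoys - assigned)))
    return schedule


def difficulty_schedule(n_decoys: int, difficulty: str) -> list[ScheduleEntry]:
    """Schedule whose near-native abundance reflects docking difficulty.

    Conformational change on binding makes near-native poses rarer, so
    medium and difficult cases carry a thinner near-native band (down to
    one or two poses per case) and correspondingly more scattered
    incorrect poses.
    """
    scale = {"rigid_body": 1.0, "medium": 0.4, "difficult": 0.2}[difficulty]
    near = [
        (0.0, 0.0, 0.005), (0.4, 3.0, 0.01), (1.5, 8.0, 0.02),
        (3.0, 12.0, 0.03), (6.0, 20.0, 0.045),
    ]
    schedule: list[ScheduleEntry] = []
    assigned = 0
    for t, r, f in near:
        count = int(round(f * scale * n_decoys))
        if count > 0:
            schedule.append((t, r, count))
            assigned += count
    if assigned == 0:
        # mirror the benchmark's retention rule: every kept case has at
        # least one near-native pose among its decoys
        schedule.append((3.0, 12.0, 1))
        assigned = 1
    for t, r, f in ((12.0, 45.0, 0.09), (25.0, 90.0, 0.45)):
        count = max(1, int(round(f * n_decoys)))
        schedule.append((t, r, count))
        assigned += count
    schedule.append((40.0, 180.0, max(1, n_decoys - assigned)))
    return schedule


@dataclass
class SyntheticCaseSpec:
    """Recipe for one synthetic docking case."""

    case_id: str = "synth"
    receptor_size: int = 14
    ligand_size: int = 10
    n_decoys: int = 500
    schedule: list[ScheduleEntry] | None = None
    difficulty: str = "rigid_body"
    seed: int = 0
    receptor_sequence: str | None = None
    ligand_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.receptor_size < 5 or self.ligand_size < 5:
            raise ValueError("need >= 5 residues per side to form an interface")
        if self.schedule is None:
            self.schedule = default_schedule(self.n_decoys)


@dataclass
class SyntheticMetricSpec:
    """Recipe for one synthetic scoring metric.

    ``rho`` is the target Spearman correlation between the score and the
    latent pose energy (1 = perfectly informative, 0 = pure noise).
    ``shared_noise_with`` reuses another metric's noise draw, planting
    correlated found-sets.  ``success_probability``, if set, overrides
    ``rho``: each case is scored by the noiseless latent with that
    probability and by the inverted latent otherwise.
    """

    name: str
    rho: float = 0.9
    direction: str = "ascending_better"
    shared_noise_with: str | None = None
    success_probability: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")


# ----------------------------------------------------------------------
# Idealized helix construction (NeRF chain extension)
# ----------------------------------------------------------------------

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom d with |cd| = bond, angle(b,c,d) and dihedral(a,b,c,d)."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_helix(n_residues: int, chain_id: str = "A",
                sequence: str | None = None,
                phi: float = -57.0, psi: float = -47.0) -> Structure:
    """Idealized alpha-helix with backbone N, CA, C, O and CB atoms."""
    if sequence is None:
        sequence = "A" * n_residues
    if len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    # seed atoms for the first residue
    n_pos = [np.array([0.0, 0.0, 0.0])]
    ca_pos = [np.array([1.458, 0.0, 0.0])]
    c0 = _place_atom(np.array([0.0, 1.0, 0.0]), n_pos[0], ca_pos[0], 1.525, 111.2, -150.0)
    c_pos = [c0]
    for i in range(n_residues - 1):
        n_next = _place_atom(n_pos[i], ca_pos[i], c_pos[i], 1.329, 116.2, psi)
        ca_next = _place_atom(ca_pos[i], c_pos[i], n_next, 1.458, 121.7, 180.0)
        c_next = _place_atom(c_pos[i], n_next, ca_next, 1.525, 111.2, phi)
        n_pos.append(n_next)
        ca_pos.append(ca_next)
        c_pos.append(c_next)
    residues = []
    serial = 0
    for i in range(n_residues):
        res_name = ONE_TO_THREE[sequence[i]]
        o = _place_atom(n_pos[i], ca_pos[i], c_pos[i], 1.231, 120.8, psi + 180.0)
        atoms = []
        for name, element, pos in (("N", "N", n_pos[i]), ("CA", "C", ca_pos[i]),
                                   ("C", "C", c_pos[i]), ("O", "O", o)):
            serial += 1
            atoms.append(AtomRecord(serial, name, "", res_name, chain_id, i + 1, "",
                                    element, pos.copy()))
        if res_name != "GLY":
            cb = _place_atom(c_pos[i], n_pos[i], ca_pos[i], 1.530, 110.5, -122.6)
            serial += 1
            atoms.append(AtomRecord(serial, "CB", "", res_name, chain_id, i + 1, "",
                                    "C", cb))
        residues.append(Residue(chain_id, i + 1, "", res_name, atoms))
    return Structure(residues)


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    centred = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    return vt[0]


def make_native(spec: SyntheticCaseSpec) -> tuple[Structure, ComplexPartition]:
    """Two helices in contact: receptor chain A, ligand chain B.

    The ligand helix is brought in perpendicular to the receptor axis
    until the interface has >= 8 residue contacts at the 5 A heavy-atom
    rule.  The closest-approach tolerance is loose (>= 1.9 A): the toys
    carry no physics, and a snug interface gives fnat enough contact
    granularity to resolve the quality classes.
    """
    receptor = build_helix(spec.receptor_size, "A", spec.receptor_sequence)
    ligand = build_helix(spec.ligand_size, "B", spec.ligand_sequence)
    rec_coords = receptor.coords()
    axis = _principal_axis(rec_coords)
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    rec_centroid = rec_coords.mean(axis=0)
    lig_centroid = ligand.coords().mean(axis=0)
    partition = ComplexPartition(frozenset({"A"}), frozenset({"B"}))
    from scipy.spatial.distance import cdist

    fallback: tuple[Structure, ComplexPartition] | None = None
    rec_xyz = np.array([a.position for r in receptor.residues for a in r.heavy_atoms()])
    for d in np.arange(14.0, 3.0, -0.25):
        shift = rec_centroid + d * perp - lig_centroid
        candidate_lig = ligand.transformed(np.eye(3), shift)
        native = Structure(receptor.residues + candidate_lig.residues)
        lig_xyz = np.array([a.position for r in candidate_lig.residues for a in r.heavy_atoms()])
        min_d = cdist(rec_xyz, lig_xyz).min()
        if min_d < 1.9:
            break  # any closer approach only worsens the overlap
        n_contacts = len(_quality.intermolecular_contacts(native, partition))
        if n_contacts >= 8:
            return native, partition
        if n_contacts >= 5:
            fallback = (native, partition)  # keep the snuggest >= 5-contact placement
    if fallback is not None:
        return fallback
    raise ValueError("could not place the helices with >= 5 native contacts")


def make_decoys(native: Structure, partition: ComplexPartition,
                schedule: Sequence[ScheduleEntry], seed: int,
                case_id: str = "synth") -> DecoySet:
    """Rigid ligand perturbations of the native per the schedule."""
    rng = np.random.default_rng(seed)
    lig_chains = partition.ligand_chains
    lig_coords = np.array([a.position for r in native.residues
                           if r.chain_id in lig_chains for a in r.atoms])
    centroid = lig_coords.mean(axis=0)
    decoys: list[tuple[str, Structure]] = []
    idx = 0
    for translation, rotation_deg, count in schedule:
        for _ in range(count):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            rot = Rotation.from_rotvec(math.radians(rotation_deg) * axis).as_matrix()
            # rotate about the ligand centroid, then translate
            shift = centroid - rot @ centroid + translation * direction
            decoy = native.transformed(rot, shift, chains=lig_chains)
            decoys.append((f"d{idx:04d}", decoy))
            idx += 1
    return DecoySet(case_id, native, decoys, partition)


def make_case(spec: SyntheticCaseSpec) -> tuple[DecoySet, pd.DataFrame]:
    """Native + decoys + honestly computed quality table for one case."""
    native, partition = make_native(spec)
    decoy_set = make_decoys(native, partition, spec.schedule, spec.seed, spec.case_id)
    quality = evaluate_decoy_set(decoy_set)
    return decoy_set, quality


# ----------------------------------------------------------------------
# Synthetic scores
# ----------------------------------------------------------------------

def _latent_energy(quality_table: pd.DataFrame) -> pd.Series:
    """Latent pose energy: lower is better.

    Uses the quality ordinal plus LRMSD (not fnat alone) so that
    medium-versus-acceptable conditional behaviour is testable.
    """
    ordinal = quality_table["class"].map(int)
    return quality_table["lrmsd"] - 15.0 * ordinal


def make_scores(quality_table: pd.DataFrame,
                metric_specs: Sequence[SyntheticMetricSpec],
                seed: int) -> pd.DataFrame:
    """Per-decoy synthetic score table for one case.

    A metric with informativeness ``rho`` decorrelates from the latent
    through three channels, mirroring how real scoring functions fail:

    * **case failure** — with probability ``q_case = 0.25 (1 - rho)``
      the metric mis-scores the whole case (all scores drawn independent
      of the latent), the dominant reason different functions find
      different complexes;
    * **pose failure** — each remaining pose is grossly mis-scored
      (independent standard-normal draw) with probability
      ``q_pose = 0.5 (1 - rho)``;
    * **diffuse noise** — surviving scores are a bivariate-normal
      mixture of the latent's normal scores and Gaussian noise with
      Pearson coefficient ``r = 2 sin(pi * s / 6)`` where
      ``s = rho / ((1 - q_case)(1 - q_pose))``.

    Spearman's rank correlation is linear in the copula, so the rank
    correlation with the latent is ``rho`` exactly in expectation; a
    single 500-decoy draw scatters around it (SD roughly 0.02-0.05,
    with rare case-failure draws near zero).

    Metrics sharing noise (``shared_noise_with``) reuse the source
    metric's case- and pose-failure draws — they fail on the same cases
    and poses — but keep their own Gaussian component, planting
    correlated found-sets without degenerating into identical scores.
    """
    latent = _latent_energy(quality_table)
    n = len(latent)
    z_latent = norm.ppf((rankdata(latent.to_numpy()) - 0.5) / n)
    noise_bank: dict[str, np.ndarray] = {}
    columns = {}
    for k, spec in enumerate(metric_specs):
        rng = np.random.default_rng([seed, k])
        if spec.success_probability is not None:
            success = rng.random() < spec.success_probability
            scores = latent.to_numpy() if success else -latent.to_numpy()
        else:
            q_case = 0.25 * (1.0 - spec.rho)
            q_pose = 0.5 * (1.0 - spec.rho)
            if spec.shared_noise_with is not None:
                case_u, contam_u, contam_scores = noise_bank[spec.shared_noise_with]
                noise = rng.standard_normal(n)
            else:
                noise = rng.standard_normal(n)
                case_u = rng.random()
                contam_u = rng.random(n)
                contam_scores = rng.standard_normal(n)
            noise_bank[spec.name] = (case_u, contam_u, contam_scores)
            if spec.rho >= 1.0:
                scores = z_latent.copy()
            elif case_u < q_case:
                scores = contam_scores.copy()  # whole-case failure
            else:
                s = spec.rho / ((1.0 - q_case) * (1.0 - q_pose))
                r = 2.0 * math.sin(math.pi * s / 6.0)
                scores = r * z_latent + math.sqrt(1.0 - r * r) * noise
                pose_mask = contam_u < q_pose
                scores[pose_mask] = contam_scores[pose_mask]
        if spec.direction == "descending_better":
            scores = -scores
        columns[spec.name] = scores
    table = pd.DataFrame(columns, index=quality_table.index)
    table.index.name = "decoy_id"
    return table


# ----------------------------------------------------------------------
# Whole-benchmark driver
# ----------------------------------------------------------------------

def benchmark_case_specs(n_cases: int, seed: int, n_decoys: int = 40,
                         receptor_size: int = 14, ligand_size: int = 10,
                         rigid_fraction: float = 0.7,
                         sequence_diversity: bool = True) -> list[SyntheticCaseSpec]:
    """Case recipes with a difficulty mix and per-case seeds."""
    rng = np.random.default_rng(seed)
    specs = []
    n_rigid = int(round(rigid_fraction * n_cases))
    for i in range(n_cases):
        difficulty = "rigid_body" if i < n_rigid else ("medium" if i % 2 else "difficult")
        if sequence_diversity:
            rseq = "".join(rng.choice(list(ONE_TO_THREE), size=receptor_size))
            lseq = "".join(rng.choice(list(ONE_TO_THREE), size=ligand_size))
        else:
            rseq = lseq = None
        specs.append(SyntheticCaseSpec(
            case_id=f"case{i:04d}", receptor_size=receptor_size,
            ligand_size=ligand_size, n_decoys=n_decoys,
            schedule=difficulty_schedule(n_decoys, difficulty), difficulty=difficulty,
            seed=int(rng.integers(0, 2**31 - 1)),
            receptor_sequence=rseq, ligand_sequence=lseq,
        ))
    return specs


def run_synthetic_benchmark(case_specs: Sequence[SyntheticCaseSpec],
                            metric_specs: Sequence[SyntheticMetricSpec],
                            seed: int,
                            threshold: float = DEFAULT_CLUSTER_THRESHOLD) -> list[CaseResult]:
    """Full honest pipeline over a synthetic benchmark.

    For every case: build the native, generate decoys, classify them
    with the real CAPRI machinery, draw synthetic scores, then rerank,
    cluster at the threshold and keep representatives — exactly as the
    real pipeline would.
    """
    results = []
    for case_spec in case_specs:
        decoy_set, quality = make_case(case_spec)
        scores = make_scores(quality, metric_specs, seed=case_spec.seed ^ seed)
        ranked = {}
        for m in metric_specs:
            ranked[m.name] = rank_case(decoy_set, scores, quality, m.name,
                                       m.direction, threshold)
        best = QualityClass(int(quality["class"].map(int).max()))
        results.append(CaseResult(case_spec.case_id, case_spec.difficulty, ranked, best))
    return results
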