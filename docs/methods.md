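# Methods

This note documents the models, conventions and design choices behind
`dockscore`, in the spirit of a methods supplement: what is computed,
under which assumptions, and what the synthetic benchmarks do and do
not demonstrate.

## Structures and input conventions

Coordinates are read from plain PDB text (ATOM/HETATM records). For
atoms with alternate location indicators, the **first-encountered
location** is kept per (chain, residue, atom name) — the convention
used when preparing docking decoys — and the filter is idempotent.
HETATM records and waters are excluded by default because both the
quality measures and residue potentials are defined over amino acids.
PDB residue numbering and insertion codes are preserved verbatim as the
residue identity, so natives and decoys never need renumbering.
Multi-MODEL files can be read as separate decoys. The reader does not
repair structures: no hydrogen addition, side-chain rebuilding or
non-standard-residue reversion (non-standard residue *types* map to
standard parents, e.g. MSE→MET, for potential lookups only).

The receptor/ligand split is explicit or automatic; automatic
assignment makes the larger molecule (by atom count) the receptor, and
with more than two chains the single smallest chain the ligand.

## Quality measures

A residue contact is ≥ 1 heavy-atom pair within **5 Å**; the native
interface for IRMSD is defined at **10 Å** (both configurable; they are
the community conventions, not values with special status here).
Hydrogens never participate in distances. Backbone atoms N, CA, C, O
enter both RMSDs with equal weights; atoms missing on either side of a
native/decoy pair are excluded from both sides, keeping the coordinate
arrays index-aligned.

LRMSD superposes the decoy receptor backbone onto the native receptor
(least-squares, proper rotation via `scipy`'s
`Rotation.align_vectors`), applies that transform to the decoy ligand
and takes the plain RMSD — deliberately no second fit, so rigid ligand
displacement is preserved (a 10 Å shift gives LRMSD 10 Å exactly).
IRMSD is the minimal backbone RMSD over native-interface residues after
fitting the interfaces. Both are invariant under global rigid
transforms of the decoy.

The four-class predicates are evaluated highest class first
(high → medium → acceptable → incorrect), so boundary ties resolve to
the better class. A randomized 10⁵-triple sweep against a literal
re-encoding of the predicates is part of the test suite; the predicates
partition the metric space.

## Contact potentials

The scoring engine is deliberately generic: a potential is a symmetric
20×20(×bins) matrix plus a contact rule. Matrix files are plain text
(`#name`, `#representative`, `#bins lo:hi,...` headers, then
`RES1 RES2 BIN VALUE` rows); symmetry is enforced by mirroring or
averaging, and pairs absent from a file default to zero energy unless
`strict=True`. Default single-interval cutoffs per representative mode:
C<sup>β</sup> 8 Å (CA for glycine), centroid 8.5 Å, minimum heavy-atom
distance 5 Å — the common conventions of the respective potential
families, overridable per matrix file.

The packaged exemplar matrix (`data/synthetic_quasichemical.cpm`) is
**synthetic**: quasi-chemical-style values generated from the
Kyte–Doolittle hydropathy scale
(e<sub>ij</sub> = −0.60 − 0.12 (h<sub>i</sub> + h<sub>j</sub>)), giving
favourable energies to hydrophobic contacts. It exercises the engine
with realistic structure; it is not a published potential, and users
supply their own matrices for scientific use.

Separable mode evaluates one structure-level scorer on the complex and
the isolated molecules and reports
E<sub>complex</sub> − (E<sub>receptor</sub> + E<sub>ligand</sub>). For
pairwise-additive distance-based potentials this equals the
intermolecular-only sum identically (intramolecular pairs appear
unchanged in both evaluations); the identity is verified numerically to
10⁻⁸ in the tests and acceptance script.

## Ranking and clustering

Per metric, decoys are sorted best-first (ascending for energy-like
scores, descending for count-like ones; missing scores drop out; ties
keep input order, making the ranking deterministic). The sorted list is
swept into **leader clusters** at a 3 Å threshold: a decoy joins the
first existing cluster whose *leader* is within the threshold,
otherwise it founds a new cluster. Membership is tested against the
leader only, and the earliest (best-ranked) qualifying leader wins.
Only leaders survive, each keeping its pre-computed quality label.

The pose distance is the ligand backbone RMSD after superposing one
decoy's receptor backbone onto the other's (full-complex RMSD is
available via configuration). When every decoy's receptor is rigidly
congruent to the native's — rigid-body decoys — each decoy is aligned
to the native frame once and pairwise distances reduce to plain RMSDs
of the aligned ligands; this is exact (the pairwise optimum is the
composition of the two exact fits) and is taken automatically, with the
general pairwise-fit path as fallback. Equality of the two routes is
covered by a test.

Agglomerative complete-linkage clustering of scoring functions and the
cophenetic distances are delegated to `scipy.cluster.hierarchy`; its
deterministic merge order replaces a hand-written tie-break rule, and
ties are measure-zero for integer cardinality data perturbed by real
benchmarks. The union matrix is similarity-like, so its clustering uses
max(union) − union as the dissimilarity (the symmetric-difference
ordering can be reused instead); this is an interpretation, exposed as
an option. The relative-complement matrix is ordered by individual
top-10 success, descending.

## Synthetic benchmarks

The generator emulates a docking-decoy benchmark at desk scale.

**Natives** are two idealized α-helices (backbone N, CA, C, O and
C<sup>β</sup>; φ = −57°, ψ = −47°, standard bond geometry via NeRF
chain extension) placed side by side, perpendicular to the receptor
axis, advanced until the interface holds ≥ 8 residue contacts at the
5 Å rule (≥ 5 as a fallback for glycine-rich sequences). The
closest-approach floor is 1.9 Å: the toys carry no physics, and a snug
interface gives *f*<sub>nat</sub> enough contact granularity to resolve
the quality classes. Sequences are configurable so contact matrices
have non-trivial lookups.

**Decoys** are rigid-body perturbations of the ligand (rotation about
its centroid plus a translation of scheduled magnitude in a random
direction). Quality labels are always computed by the real classifier
on the generated coordinates — the generator never assigns labels. The
default schedule is near-native-sparse, as real docking output is:
roughly 10 % of poses reach acceptable or better, the rest scatter
between 12 and 40 Å. Difficulty scales the near-native band down
(medium ×0.4, difficult ×0.2, with ≥ 1 near-native pose retained per
case, mirroring a benchmark that keeps only cases where a solution
exists).

**Scores.** Each metric has an informativeness ρ ∈ [0, 1], the target
Spearman correlation between its scores and a latent pose energy
(LRMSD − 15 × quality ordinal; the ordinal term lets
medium-vs-acceptable conditional behaviour be tested). Decorrelation is
delivered through three channels chosen to mirror how scoring functions
actually fail: whole-case failures with probability 0.25 (1 − ρ) (all
scores independent of the latent — the dominant reason different
functions find different complexes), per-pose gross mis-scoring with
probability 0.5 (1 − ρ), and a diffuse bivariate-normal component
calibrated so that, Spearman being linear in the copula, the overall
rank correlation is exactly ρ in expectation (a single 500-decoy draw
scatters with SD ≈ 0.02–0.05, with rare case-failure draws near zero).
Metrics can share the case- and pose-failure draws (correlated found
sets, planted cluster structure) while keeping their own diffuse noise,
and a planted mode scores each case by the noiseless latent with a
given probability p and by its inversion otherwise, making top-10
success exactly Bernoulli(p) on cases where a near-native exists.

**What passing tests show — and don't.** The synthetic cases validate
the geometry, bookkeeping and statistics of the pipeline end to end
with known ground truth. They do not emulate conformational
flexibility, side-chain packing, energy-landscape realism or the
chemical idiosyncrasies of real interfaces; success rates measured on
them characterize the generator's operating point, not any real scoring
function.

## Problem sizes and numerical choices

Test and acceptance runs use helix cases of 14 + 10 residues.
The planted-probability recovery runs 500 cases × 40 decoys (checking
the recovered rate within three binomial standard errors of p = 0.6);
the complementarity demonstration runs 50 cases × 100 decoys at
ρ = 0.75, the regime where real scoring functions operate and where
found-set differences are observable — at ρ ≳ 0.9 an informative
metric almost never misses a case with several near-natives. Oracle
agreement suites use ≥ 50 random toy instances per primitive against
brute-force enumerations, independent SVD superposition, a second
sweep implementation, and a naive O(n³) agglomeration.

Rigid-congruence detection uses a 10⁻⁶ Å fit-RMSD tolerance; matrix
asymmetry beyond 10⁻⁹ triggers symmetrisation with a warning;
percentages are reported to the nearest integer with raw fractions
retained. Degenerate inputs fail loudly: empty native contact sets
(undefined *f*<sub>nat</sub>), empty interfaces, single-chain
partitions, < 3-point superpositions, zero-denominator conditional
probabilities (NaN with a warning).

## Known limitations

- The PDB reader covers coordinate records only (no SEQRES/occupancy
  logic beyond alt-loc selection); mmCIF is out of scope.
- Only residue-level potentials are built in; atomic-resolution
  potentials, composite weighted scores and external programs are out
  of scope, though their scores can be imported as TSV metrics.
- Leader clustering is order-dependent by design (it follows the score
  ranking); it is not a partition-optimal clustering.
- The synthetic score model's ρ calibration is exact in expectation,
  not per draw; single-case Spearman estimates carry sampling noise and
  occasional case-failure outliers.
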