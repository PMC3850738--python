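"""CAPRI quality measures: contacts, fnat, superposition, RMSDs, classes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from conftest import make_residue, random_complex
from dockscore.quality import (
    QualityClass,
    QualityMetrics,
    classify_quality,
    evaluate_decoy_set,
    fnat,
    interface_residues,
    intermolecular_contacts,
    irmsd,
    kabsch_superpose,
    lrmsd,
)
from dockscore.structures import ComplexPartition, DecoySet, Structure
from dockscore.synth import SyntheticCaseSpec, make_decoys, make_native
from oracles import brute_contacts, brute_interface_residues, brute_irmsd, brute_lrmsd, svd_kabsch


def random_rigid(rng):
    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(1 << 31))).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return rot, t


class TestContacts:
    def test_boundary_inside(self):
        a = make_residue("A", 1, "ALA", [("CA", (0.0, 0.0, 0.0))])
        b = make_residue("B", 1, "GLY", [("CA", (4.9, 0.0, 0.0))])
        s = Structure([a, b])
        p = ComplexPartition(frozenset("A"), frozenset("B"))
        assert intermolecular_contacts(s, p, 5.0) == {(("A", 1, ""), ("B", 1, ""))}

    def test_all_far_is_empty(self):
        a = make_residue("A", 1, "ALA", [("CA", (0.0, 0.0, 0.0))])
        b = make_residue("B", 1, "GLY", [("CA", (50.0, 0.0, 0.0))])
        s = Structure([a, b])
        p = ComplexPartition(frozenset("A"), frozenset("B"))
        assert intermolecular_contacts(s, p, 5.0) == frozenset()

    def test_hydrogens_ignored(self):
        a = make_residue("A", 1, "ALA", [("CA", (0.0, 0.0, 0.0)),
                                         ("H", (4.0, 0.0, 0.0))])
        b = make_residue("B", 1, "GLY", [("CA", (8.0, 0.0, 0.0))])
        s = Structure([a, b])
        p = ComplexPartition(frozenset("A"), frozenset("B"))
        # H at 4 A from the B CA would be a contact if hydrogens counted
        assert intermolecular_contacts(s, p, 5.0) == frozenset()

    def test_matches_bruteforce_on_random_toys(self, rng):
        for _ in range(50):
            s, p = random_complex(rng, gap=float(rng.uniform(-4, 4)))
            cutoff = float(rng.uniform(3, 8))
            assert intermolecular_contacts(s, p, cutoff) == brute_contacts(s, p, cutoff)

    def test_interface_matches_bruteforce(self, rng):
        for _ in range(20):
            s, p = random_complex(rng, gap=float(rng.uniform(-2, 4)))
            assert interface_residues(s, p, 10.0) == brute_interface_residues(s, p, 10.0)


class TestFnat:
    def test_identical_sets(self):
        native = frozenset({(1, 2), (3, 4)})
        assert fnat(native, native) == 1.0

    def test_disjoint_sets(self):
        assert fnat(frozenset({(1, 2)}), frozenset({(3, 4)})) == 0.0

    def test_partial_overlap(self):
        native = frozenset((i, i) for i in range(10))
        decoy = frozenset((i, i) for i in range(4)) | frozenset((90 + i, i) for i in range(6))
        assert fnat(native, decoy) == pytest.approx(0.4)

    def test_empty_native_raises(self):
        with pytest.raises(ValueError):
            fnat(frozenset(), frozenset({(1, 2)}))


class TestKabsch:
    def test_identity(self, rng):
        pts = rng.uniform(size=(10, 3))
        sup = kabsch_superpose(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_recovers_rigid_transform(self, rng):
        pts = rng.uniform(size=(12, 3)) * 10
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ rot.T + np.array([5.0, -3.0, 2.0])
        sup = kabsch_superpose(pts, moved)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(sup.apply(moved), pts, atol=1e-8)

    def test_proper_rotation_always(self, rng):
        for _ in range(20):
            a = rng.normal(size=(8, 3))
            b = rng.normal(size=(8, 3))
            sup = kabsch_superpose(a, b)
            assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_matches_svd_oracle_with_noise(self, rng):
        for _ in range(50):
            pts = rng.uniform(size=(10, 3)) * 10
            rot, t = random_rigid(rng)
            noisy = (pts @ rot.T + t) + rng.normal(scale=0.5, size=pts.shape)
            sup = kabsch_superpose(pts, noisy)
            _, _, oracle_rmsd = svd_kabsch(pts, noisy)
            assert sup.rmsd == pytest.approx(oracle_rmsd, abs=1e-8)

    def test_never_beaten_by_sampled_rotations(self, rng):
        """The fitted RMSD is minimal over a random sample of rigid transforms."""
        pts = rng.uniform(size=(10, 3)) * 8
        noisy = pts + rng.normal(scale=0.8, size=pts.shape)
        best = kabsch_superpose(pts, noisy).rmsd
        centred = noisy - noisy.mean(0)
        target = pts - pts.mean(0)
        for _ in range(500):
            r = Rotation.random(random_state=np.random.RandomState(
                rng.integers(1 << 31))).as_matrix()
            trial = np.sqrt(np.mean(np.sum((centred @ r.T - target) ** 2, axis=1)))
            assert best <= trial + 1e-9

    def test_shape_errors(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


@pytest.fixture(scope="module")
def helix_case():
    spec = SyntheticCaseSpec(case_id="hx", n_decoys=1, schedule=[(0.0, 0.0, 1)], seed=7)
    native, partition = make_native(spec)
    return native, partition


class TestLRMSD:
    def test_zero_for_native(self, helix_case):
        native, p = helix_case
        assert lrmsd(native, native.copy(), p) == pytest.approx(0.0, abs=1e-9)

    def test_pure_translation_preserved(self, helix_case):
        native, p = helix_case
        decoy = native.transformed(np.eye(3), np.array([10.0, 0, 0]),
                                   chains=p.ligand_chains)
        assert lrmsd(native, decoy, p) == pytest.approx(10.0, abs=1e-8)

    def test_matches_bruteforce_on_perturbed_poses(self, helix_case, rng):
        native, p = helix_case
        for _ in range(25):
            rot, _ = random_rigid(rng)
            t = rng.uniform(-5, 5, size=3)
            decoy = native.transformed(rot, t, chains=p.ligand_chains)
            # also jiggle the receptor rigidly so the fit is non-trivial
            grot, gt = random_rigid(rng)
            decoy = decoy.transformed(grot, gt)
            assert lrmsd(native, decoy, p) == pytest.approx(
                brute_lrmsd(native, decoy, p), abs=1e-8)


class TestIRMSD:
    def test_zero_for_native(self, helix_case):
        native, p = helix_case
        assert irmsd(native, native.copy(), p) == pytest.approx(0.0, abs=1e-9)

    def test_global_rigid_transform_invariance(self, helix_case, rng):
        native, p = helix_case
        rot, t = random_rigid(rng)
        decoy = native.transformed(rot, t)
        assert irmsd(native, decoy, p) == pytest.approx(0.0, abs=1e-6)
        assert lrmsd(native, decoy, p) == pytest.approx(0.0, abs=1e-6)

    def test_matches_bruteforce_oracle(self, helix_case, rng):
        native, p = helix_case
        for _ in range(25):
            rot, _ = random_rigid(rng)
            decoy = native.transformed(rot, rng.uniform(-3, 3, size=3),
                                       chains=p.ligand_chains)
            assert irmsd(native, decoy, p) == pytest.approx(
                brute_irmsd(native, decoy, p), abs=1e-8)


def literal_class(f, l, i):
    """Verbatim re-encoding of the printed class predicates (test-local)."""
    incorrect = f < 0.1 or (l > 10 and i > 4)
    acceptable = (f >= 0.3 and l > 5 and i > 2) or ((0.1 <= f < 0.3) and (l <= 10 or i <= 4))
    medium = (f >= 0.5 and l > 1 and i > 1) or ((0.3 <= f < 0.5) and (l <= 5 or i <= 2))
    high = f >= 0.5 and (l <= 1 or i <= 1)
    if high:
        return QualityClass.HIGH
    if medium:
        return QualityClass.MEDIUM
    if acceptable:
        return QualityClass.ACCEPTABLE
    assert incorrect
    return QualityClass.INCORRECT


class TestClassify:
    @pytest.mark.parametrize("f,l,i,expected", [
        (1.0, 0.0, 0.0, QualityClass.HIGH),
        (0.05, 12.0, 5.0, QualityClass.INCORRECT),
        (0.45, 4.0, 1.5, QualityClass.MEDIUM),
        (0.2, 8.0, 3.0, QualityClass.ACCEPTABLE),
    ])
    def test_worked_boundary_examples(self, f, l, i, expected):
        assert classify_quality(QualityMetrics(f, i, l)) is expected

    def test_randomized_sweep_matches_literal_predicates(self, rng):
        n = 100_000
        fs = rng.uniform(0, 1, n)
        ls = rng.uniform(0, 20, n)
        is_ = rng.uniform(0, 8, n)
        # sprinkle exact boundary values into the sweep
        fs[:3000] = rng.choice([0.1, 0.3, 0.5], 3000)
        ls[1000:4000] = rng.choice([1.0, 5.0, 10.0], 3000)
        is_[2000:5000] = rng.choice([1.0, 2.0, 4.0], 3000)
        for f, l, i in zip(fs, ls, is_):
            assert classify_quality(QualityMetrics(f, i, l)) is literal_class(f, l, i)

    @given(st.floats(0, 1), st.floats(0, 50), st.floats(0, 20))
    @settings(max_examples=300, derandomize=True)
    def test_totality(self, f, l, i):
        assert classify_quality(QualityMetrics(f, i, l)) in QualityClass

    def test_fnat_monotone_at_fixed_rmsds(self):
        classes = [classify_quality(QualityMetrics(f, 0.5, 0.5))
                   for f in np.linspace(0, 1, 101)]
        assert all(b >= a for a, b in zip(classes, classes[1:]))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            QualityMetrics(-0.1, 1.0, 1.0)
        with pytest.raises(ValueError):
            QualityMetrics(0.5, -1.0, 1.0)


class TestEvaluateDecoySet:
    def test_native_classifies_high(self, helix_case):
        native, p = helix_case
        ds = DecoySet("c", native, [("d0", native.copy())], p)
        table = evaluate_decoy_set(ds)
        assert table.loc["d0", "class"] is QualityClass.HIGH
        assert table.loc["d0", "fnat"] == 1.0

    def test_large_displacement_is_incorrect(self, helix_case):
        native, p = helix_case
        ds = make_decoys(native, p, [(40.0, 90.0, 3)], seed=5)
        table = evaluate_decoy_set(ds)
        assert (table["class"] == QualityClass.INCORRECT).all()
        assert (table["fnat"] == 0.0).all()
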