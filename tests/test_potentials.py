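"""Contact-potential engine: matrix I/O, representatives, scoring modes."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import make_residue, random_complex
from dockscore.potentials import (
    AMINO_ACIDS,
    ContactDefinition,
    ContactMatrix,
    MetricSpec,
    builtin_matrix,
    contact_potential_metric,
    load_contact_matrix,
    residue_representative,
    score_all_pairs,
    score_decoy_set,
    score_intermolecular,
    score_separable,
    write_contact_matrix,
)
from dockscore.structures import ComplexPartition, DecoySet, Structure
from oracles import brute_potential_score


def random_matrix(rng, n_bins=1, definition=None):
    entries = rng.normal(size=(20, 20, n_bins))
    entries = 0.5 * (entries + entries.transpose(1, 0, 2))
    return ContactMatrix("rand", entries, definition)


class TestContactDefinition:
    def test_rejects_overlapping_bins(self):
        with pytest.raises(ValueError):
            ContactDefinition("centroid", ((0.0, 5.0), (4.0, 8.0)))

    def test_bin_lookup(self):
        d = ContactDefinition("centroid", ((0.0, 4.0), (4.5, 8.0)))
        assert d.bin_of(2.0) == 0
        assert d.bin_of(5.0) == 1
        assert d.bin_of(4.2) == -1
        assert d.bin_of(9.0) == -1


class TestMatrixIO:
    def test_roundtrip(self, tmp_path, rng):
        m = random_matrix(rng)
        path = tmp_path / "m.cpm"
        write_contact_matrix(m, path)
        m2 = load_contact_matrix(path)
        np.testing.assert_allclose(m2.entries, m.entries, atol=1e-6)

    def test_single_entry_mirrored(self, tmp_path):
        path = tmp_path / "partial.cpm"
        path.write_text("#name partial\nALA GLY 0 -1.5\n")
        m = load_contact_matrix(path)
        assert m.value("ALA", "GLY") == -1.5
        assert m.value("GLY", "ALA") == -1.5
        assert m.value("TRP", "TRP") == 0.0

    def test_strict_mode_requires_completeness(self, tmp_path):
        path = tmp_path / "partial.cpm"
        path.write_text("ALA GLY 0 -1.5\n")
        with pytest.raises(ValueError, match="missing"):
            load_contact_matrix(path, strict=True)

    def test_full_matrix_resolves_all_ordered_lookups(self, tmp_path, rng):
        m = random_matrix(rng)
        path = tmp_path / "full.cpm"
        write_contact_matrix(m, path)
        loaded = load_contact_matrix(path, strict=True)
        for a in AMINO_ACIDS:
            for b in AMINO_ACIDS:
                assert loaded.value(a, b) == loaded.value(b, a)

    def test_non_numeric_entry_names_location(self, tmp_path):
        path = tmp_path / "bad.cpm"
        path.write_text("ALA GLY 0 oops\n")
        with pytest.raises(ValueError, match="bad.cpm:1"):
            load_contact_matrix(path)

    def test_unknown_residue_rejected(self, tmp_path):
        path = tmp_path / "bad.cpm"
        path.write_text("XXX GLY 0 1.0\n")
        with pytest.raises(ValueError, match="unknown residue"):
            load_contact_matrix(path)

    def test_builtin_matrix_loads_and_is_symmetric(self):
        m = builtin_matrix()
        np.testing.assert_allclose(m.entries, m.entries.transpose(1, 0, 2))
        # hydrophobic pairs are favourable, charged pairs unfavourable
        assert m.value("ILE", "ILE") < m.value("LYS", "LYS")


class TestRepresentative:
    def test_glycine_cbeta_falls_back_to_ca(self):
        res = make_residue("A", 1, "GLY", [("N", (0, 0, 0)), ("CA", (1, 0, 0))])
        pos = residue_representative(res, ContactDefinition("c_beta", ((0, 8),)))
        np.testing.assert_allclose(pos, [1, 0, 0])

    def test_single_atom_centroid(self):
        res = make_residue("A", 1, "ALA", [("CA", (2, 3, 4))])
        pos = residue_representative(res, ContactDefinition("centroid", ((0, 8),)))
        np.testing.assert_allclose(pos, [2, 3, 4])

    def test_min_mode_returns_heavy_atom_set(self):
        res = make_residue("A", 1, "ALA",
                           [("N", (0, 0, 0)), ("CA", (1, 0, 0)), ("C", (2, 0, 0)),
                            ("O", (3, 0, 0)), ("CB", (1, 1, 0))])
        pts = residue_representative(res, ContactDefinition("min_heavy_atom", ((0, 5),)))
        assert pts.shape == (5, 3)


class TestScoring:
    def test_zero_matrix_scores_zero(self, rng):
        s, p = random_complex(rng)
        m = ContactMatrix("zero", np.zeros((20, 20, 1)))
        assert score_intermolecular(s, p, m) == 0.0

    def test_single_contact_single_term(self):
        a = make_residue("A", 1, "ALA", [("CA", (0.0, 0.0, 0.0))])
        b = make_residue("B", 1, "GLY", [("CA", (3.0, 0.0, 0.0))])
        s = Structure([a, b])
        p = ComplexPartition(frozenset("A"), frozenset("B"))
        entries = np.zeros((20, 20, 1))
        i, j = AMINO_ACIDS.index("ALA"), AMINO_ACIDS.index("GLY")
        entries[i, j, 0] = entries[j, i, 0] = -1.2
        m = ContactMatrix("one", entries)
        assert score_intermolecular(s, p, m) == pytest.approx(-1.2)

    @pytest.mark.parametrize("representative,n_bins", [
        ("min_heavy_atom", 1), ("c_beta", 1), ("centroid", 2),
    ])
    def test_matches_bruteforce_all_modes(self, rng, representative, n_bins):
        bins = ((0.0, 6.0),) if n_bins == 1 else ((0.0, 4.0), (4.0, 9.0))
        definition = ContactDefinition(representative, bins)
        for _ in range(50):
            s, p = random_complex(rng, gap=float(rng.uniform(-6, 2)))
            m = random_matrix(rng, n_bins, definition)
            got = score_intermolecular(s, p, m, definition)
            want = brute_potential_score(s, p, m, definition)
            assert got == pytest.approx(want, abs=1e-9)

    def test_rigid_transform_invariance(self, rng):
        s, p = random_complex(rng, gap=-2.0)
        m = random_matrix(rng)
        base = score_intermolecular(s, p, m)
        rot = Rotation.random(random_state=np.random.RandomState(3)).as_matrix()
        moved = s.transformed(rot, np.array([5.0, -2.0, 11.0]))
        assert score_intermolecular(moved, p, m) == pytest.approx(base, abs=1e-8)

    def test_receptor_ligand_swap_symmetry(self, rng):
        s, p = random_complex(rng, gap=-2.0)
        m = random_matrix(rng)
        swapped = ComplexPartition(p.ligand_chains, p.receptor_chains)
        assert score_intermolecular(s, swapped, m) == pytest.approx(
            score_intermolecular(s, p, m), abs=1e-9)

    def test_contact_energy_steps_down_monotonically_on_separation(self, rng):
        """All-negative single-interval potential: energy is a non-increasing
        step function of ligand separation along an exit path."""
        s, p = random_complex(rng, gap=-4.0)
        entries = -np.abs(np.random.default_rng(0).normal(size=(20, 20, 1))) - 0.1
        entries = 0.5 * (entries + entries.transpose(1, 0, 2))
        m = ContactMatrix("neg", entries)
        prev = -np.inf
        for d in np.linspace(0, 40, 30):
            moved = s.transformed(np.eye(3), np.array([d, 0.0, 0.0]),
                                  chains=p.ligand_chains)
            e = score_intermolecular(moved, p, m)
            assert e >= prev - 1e-9
            prev = e
        assert prev == 0.0  # fully separated


class TestSeparable:
    def _split(self, s, p):
        return s.subset(p.receptor_chains), s.subset(p.ligand_chains)

    def test_additive_scorer_cancels(self, rng):
        s, p = random_complex(rng)
        rec, lig = self._split(s, p)
        assert score_separable(s, rec, lig, lambda x: float(len(x.atoms))) == 0.0

    def test_equals_intermolecular_for_pairwise_potential(self, rng):
        definition = ContactDefinition("min_heavy_atom", ((0.0, 6.0),))
        for _ in range(20):
            s, p = random_complex(rng, gap=float(rng.uniform(-6, 2)))
            m = random_matrix(rng, definition=definition)
            rec, lig = self._split(s, p)
            sep = score_separable(s, rec, lig, lambda x: score_all_pairs(x, m, definition))
            inter = score_intermolecular(s, p, m, definition)
            assert sep == pytest.approx(inter, abs=1e-8)

    def test_separated_ligand_scores_zero(self, rng):
        s, p = random_complex(rng)
        far = s.transformed(np.eye(3), np.array([500.0, 0, 0]), chains=p.ligand_chains)
        m = random_matrix(rng)
        rec, lig = self._split(far, p)
        assert score_separable(far, rec, lig, lambda x: score_all_pairs(x, m)) == 0.0

    def test_composition_mismatch_rejected(self, rng):
        s, p = random_complex(rng)
        rec, lig = self._split(s, p)
        truncated = Structure(lig.residues[:-1])
        with pytest.raises(ValueError, match="composition"):
            score_separable(s, rec, truncated, lambda x: 0.0)


class TestScoreDecoySet:
    def _decoy_set(self, rng, n=3):
        s, p = random_complex(rng)
        decoys = [(f"d{i}", s.transformed(np.eye(3), rng.uniform(-1, 1, 3),
                                          chains=p.ligand_chains)) for i in range(n)]
        return DecoySet("case", s, decoys, p)

    def test_shape(self, rng):
        ds = self._decoy_set(rng, 3)
        m = random_matrix(rng)
        metrics = [contact_potential_metric(m, name="a"),
                   contact_potential_metric(m, name="b")]
        table = score_decoy_set(ds, metrics)
        assert table.shape == (3, 2)
        assert table.notna().all().all()

    def test_failing_metric_records_missing(self, rng):
        ds = self._decoy_set(rng, 3)

        calls = {"n": 0}

        def flaky(structure, partition):
            calls["n"] += 1
            if calls["n"] == 2:
                raise RuntimeError("boom")
            return 1.0

        table = score_decoy_set(ds, [MetricSpec("flaky", flaky),
                                     contact_potential_metric(random_matrix(rng))])
        assert table["flaky"].isna().sum() == 1
        assert table.notna().sum().sum() == 5

    def test_deterministic(self, rng):
        ds = self._decoy_set(rng, 4)
        m = random_matrix(rng)
        metrics = [contact_potential_metric(m)]
        t1 = score_decoy_set(ds, metrics)
        t2 = score_decoy_set(ds, metrics)
        assert t1.equals(t2)
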