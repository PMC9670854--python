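"""Fingerprint computation, feature selection, binarization, similarity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

import spectox.fingerprints as fp


def _registry(defs):
    entries = [
        fp.RegistryEntry(registry_index=i, family="custom_smarts",
                         definition=smarts, absolute_index=1000 + i, label=label)
        for i, (label, smarts) in enumerate(defs)
    ]
    return fp.FingerprintRegistry(entries=entries)


TEN_BIT_DEFS = [
    ("aromatic_ring", "c1ccccc1"),
    ("amide", "[NX3][CX3](=[OX1])"),
    ("hydroxyl", "[OX2H]"),
    ("carbon_chain", "CC"),
    ("ether", "[OD2]([#6])[#6]"),
    ("nitro", "[$([NX3](=O)=O),$([NX3+](=O)[O-])]"),
    ("halogen", "[F,Cl,Br,I]"),
    ("ketone", "[#6][CX3](=O)[#6]"),
    ("amine", "[NX3;H2]"),
    ("methyl", "[CH3]"),
]

# Hand-derived truth for ethanol (CCO): has C-C, hydroxyl, methyl; nothing else.
ETHANOL_EXPECTED = [0, 0, 1, 1, 0, 0, 0, 0, 0, 1]


class TestStructureFingerprints:
    def test_benzene_bits_forced_by_chemistry(self):
        reg = _registry(TEN_BIT_DEFS)
        fv = fp.compute_structure_fingerprints("c1ccccc1", reg)
        assert fv.values[0] == 1.0   # aromatic ring
        assert fv.values[1] == 0.0   # amide
        assert fv.source == "structure"

    def test_empty_registry_still_reports_mass(self):
        fv = fp.compute_structure_fingerprints("CCO", _registry([]))
        assert fv.values.shape == (0,)
        assert fv.exact_mass == pytest.approx(46.0419, abs=1e-3)

    def test_ethanol_matches_hand_derived_bits(self):
        fv = fp.compute_structure_fingerprints("CCO", _registry(TEN_BIT_DEFS))
        assert fv.values.tolist() == ETHANOL_EXPECTED

    def test_invariant_to_smiles_spelling(self, default_reg):
        from rdkit import Chem
        mol = Chem.MolFromSmiles("CC(=O)Oc1ccccc1C(=O)O")
        base = fp.compute_structure_fingerprints("CC(=O)Oc1ccccc1C(=O)O", default_reg)
        for i in range(3):
            alt = Chem.MolToSmiles(mol, doRandom=True)
            fv = fp.compute_structure_fingerprints(alt, default_reg)
            assert np.array_equal(fv.values, base.values)
            assert fv.exact_mass == pytest.approx(base.exact_mass, abs=1e-9)

    def test_kekulized_and_aromatic_spellings_agree(self, default_reg):
        a = fp.compute_structure_fingerprints("c1ccccc1O", default_reg)
        b = fp.compute_structure_fingerprints("C1=CC=CC=C1O", default_reg)
        assert np.array_equal(a.values, b.values)

    def test_unparseable_smiles_rejected(self):
        with pytest.raises(fp.FingerprintError):
            fp.compute_structure_fingerprints("xyz(((", _registry(TEN_BIT_DEFS))

    def test_bad_smarts_fails_at_compile(self):
        reg = _registry([("broken", "[[[")])
        with pytest.raises(fp.FingerprintError, match="does not compile"):
            fp.compute_structure_fingerprints("CCO", reg)

    def test_default_registry_round_trips_through_tsv(self, default_reg, tmp_path):
        p = tmp_path / "reg.tsv"
        default_reg.to_tsv(p)
        loaded = fp.FingerprintRegistry.from_tsv(p)
        assert loaded.content_hash() == default_reg.content_hash()
        assert len(loaded) == len(default_reg)


def _nzv_oracle(X, freq_cut=19.0, uniq_cut=10.0):
    out = []
    for j in range(X.shape[1]):
        vals, counts = np.unique(X[:, j], return_counts=True)
        if len(vals) == 1:
            out.append(j)
            continue
        c = np.sort(counts)[::-1]
        if c[0] / c[1] > freq_cut and 100.0 * len(vals) / X.shape[0] < uniq_cut:
            out.append(j)
    return out


class TestFeatureSelection:
    def test_constant_column_dropped(self):
        X = np.column_stack([np.zeros(20), np.arange(20) % 2])
        sel = fp.select_model_features(X)
        assert 0 in sel.dropped_nzv and 1 in sel.kept_indices

    def test_duplicate_pair_keeps_lower_index(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 2, 30).astype(float)
        X = np.column_stack([col, rng.integers(0, 2, 30), col])
        sel = fp.select_model_features(X)
        assert 0 in sel.kept_indices and 2 not in sel.kept_indices
        assert any(d == 2 and k == 0 for d, k, _ in sel.dropped_correlated)

    def test_planted_structure_recovered_and_verified_by_pair_scan(self):
        rng = np.random.default_rng(5)
        X = (rng.random((50, 25)) < 0.4).astype(float)
        # 3 duplicate pairs and 2 constant columns appended -> 30 columns
        X = np.column_stack([X, X[:, 0], X[:, 1], X[:, 2],
                             np.zeros(50), np.ones(50)])
        sel = fp.select_model_features(X, corr_threshold=0.9)
        assert X.shape[1] == 30
        assert len(sel.kept_indices) == 25
        # exhaustive brute-force pair scan on the kept columns
        kept = X[:, sel.kept_indices]
        corr = np.corrcoef(kept, rowvar=False)
        mask = ~np.eye(len(sel.kept_indices), dtype=bool)
        assert np.nanmax(np.abs(corr[mask])) <= 0.9 + 1e-12
        # dropped NZV columns verified against an independent oracle
        assert sorted(sel.dropped_nzv) == _nzv_oracle(X)

    def test_selection_is_idempotent(self):
        rng = np.random.default_rng(8)
        X = (rng.random((60, 20)) < 0.3).astype(float)
        X = np.column_stack([X, X[:, 3]])
        sel = fp.select_model_features(X)
        again = fp.select_model_features(X[:, sel.kept_indices])
        assert again.kept_indices == list(range(len(sel.kept_indices)))
        assert again.dropped_nzv == [] and again.dropped_correlated == []

    def test_empty_matrix_rejected(self):
        with pytest.raises(fp.FingerprintError):
            fp.select_model_features(np.empty((0, 5)))

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        X = (rng.random((40, 12)) < 0.4).astype(float)
        sel = fp.select_model_features(X)
        sel.to_json(tmp_path / "sel.json")
        loaded = fp.FeatureSelection.from_json(tmp_path / "sel.json")
        assert loaded.kept_indices == sel.kept_indices
        assert loaded.dropped_correlated == sel.dropped_correlated


class TestBinarize:
    @pytest.mark.parametrize("value,expected", [(0.49, 0.0), (0.51, 1.0), (0.5, 1.0)])
    def test_threshold_rules(self, value, expected):
        assert fp.binarize(np.array([value]))[0] == expected

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hst.lists(hst.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_idempotent(self, vals):
        v = np.array(vals)
        once = fp.binarize(v)
        assert np.array_equal(fp.binarize(once), once)

    def test_threshold_domain_enforced(self):
        with pytest.raises(fp.FingerprintError):
            fp.binarize(np.array([0.3]), threshold=1.0)

    def test_vector_wrapper_preserved(self):
        fv = fp.FingerprintVector("x", np.array([0.2, 0.8]), 100.0, source="spectrum")
        out = fp.binarize(fv)
        assert isinstance(out, fp.FingerprintVector)
        assert out.values.tolist() == [0.0, 1.0]
        assert out.exact_mass == 100.0


class TestCosineSimilarity:
    def test_identity(self):
        v = np.array([1.0, 0.5, 0.0])
        assert fp.cosine_similarity(v, v) == pytest.approx(1.0)

    def test_disjoint_support(self):
        assert fp.cosine_similarity(np.array([1.0, 0, 0]), np.array([0, 1.0, 1.0])) == 0.0

    def test_closed_form(self):
        got = fp.cosine_similarity(np.array([1.0, 1, 0]), np.array([1.0, 0, 0]))
        assert got == pytest.approx(1 / math.sqrt(2), abs=1e-12)

    def test_zero_vector_is_undefined_marker(self):
        assert math.isnan(fp.cosine_similarity(np.zeros(3), np.ones(3)))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hst.lists(hst.floats(0, 1), min_size=2, max_size=10),
           hst.lists(hst.floats(0, 1), min_size=2, max_size=10),
           hst.floats(0.1, 10))
    def test_symmetric_and_scale_invariant(self, a, b, lam):
        n = min(len(a), len(b))
        va, vb = np.array(a[:n]) + 0.01, np.array(b[:n]) + 0.01  # keep nonzero
        assert fp.cosine_similarity(va, vb) == pytest.approx(
            fp.cosine_similarity(vb, va), abs=1e-12)
        assert fp.cosine_similarity(va, vb) == pytest.approx(
            fp.cosine_similarity(va, lam * vb), abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(fp.FingerprintError):
            fp.cosine_similarity(np.ones(3), np.ones(4))


class TestSimilarityProfile:
    def test_query_in_training_set_scores_one(self):
        rng = np.random.default_rng(2)
        T = (rng.random((10, 8)) < 0.5).astype(float)
        T[T.sum(axis=1) == 0, 0] = 1.0
        sims, _ = fp.similarity_profile(T[4], T)
        assert sims[4] == pytest.approx(1.0)

    def test_orthogonal_query_counts_zero(self):
        T = np.eye(4)[:3]
        sims, n = fp.similarity_profile(np.array([0.0, 0, 0, 1]), T)
        assert n == 0 and np.allclose(sims, 0.0)

    def test_matches_exhaustive_loop_oracle(self):
        rng = np.random.default_rng(3)
        T = (rng.random((10, 8)) < 0.5).astype(float)
        T[T.sum(axis=1) == 0, 0] = 1.0
        q = (rng.random(8) < 0.5).astype(float)
        q[0] = 1.0
        sims, n = fp.similarity_profile(q, T)
        expected = [fp.cosine_similarity(q, row) for row in T]
        assert np.allclose(sims, expected, atol=1e-12)
        assert n == sum(1 for s in expected if s > 0.5)

    def test_empty_training_matrix_rejected(self):
        with pytest.raises(fp.FingerprintError):
            fp.similarity_profile(np.ones(3), np.empty((0, 3)))
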