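import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from fragscreen.chem import parse_smiles, SmilesParseError
from fragscreen.fingerprints import (ABLATIONS, BitFingerprint, Scheme,
                                     combine_fingerprints,
                                     combined_fingerprint_for,
                                     fold_identifier, fp2_fingerprint,
                                     linear_path_encodings,
                                     morgan_fingerprint, pubchem_fingerprint,
                                     tanimoto)

from conftest import SMALL_MOLECULES
from oracles import fp2_bits_bruteforce, morgan_identifiers_recursive


class TestParseSmiles:
    def test_single_atom(self):
        g = parse_smiles("C")
        assert g.n_atoms == 1 and not g.bonds

    def test_ethanamine(self):
        g = parse_smiles("CCN")
        assert [a.element for a in g.atoms] == ["C", "C", "N"]
        assert len(g.bonds) == 2
        assert all(b.order == 1 for b in g.bonds)

    def test_cyclopropane_all_in_ring(self):
        g = parse_smiles("C1CC1")
        assert g.n_atoms == 3 and len(g.bonds) == 3
        assert all(a.in_ring for a in g.atoms)

    @pytest.mark.parametrize("bad", ["", "  ", "C1CC", "not-a-smiles(("])
    def test_unparsable_reports_record(self, bad):
        with pytest.raises(SmilesParseError):
            parse_smiles(bad)


class TestFold:
    @pytest.mark.parametrize("value,length,expected", [
        (0, 2048, 0),
        (2049, 2048, 1),
        (3000, 1024, 952),
        (1023, 1024, 1023),
    ])
    def test_examples(self, value, length, expected):
        assert fold_identifier(value, length) == expected

    def test_never_exceeds_length(self, rng):
        for _ in range(500):
            value = int(rng.integers(0, 2**32))
            length = int(rng.integers(1, 5000))
            assert 0 <= fold_identifier(value, length) < length


class TestMorgan:
    def test_methane_single_bit_any_radius(self):
        mol = parse_smiles("C")
        for radius in (0, 1, 2, 5):
            assert morgan_fingerprint(mol, radius=radius).n_bits_set == 1

    @pytest.mark.parametrize("smiles", SMALL_MOLECULES)
    def test_matches_recursive_rederivation(self, smiles):
        mol = parse_smiles(smiles)
        expected = {fold_identifier(h, 2048)
                    for h in morgan_identifiers_recursive(mol, radius=2)}
        assert morgan_fingerprint(mol).set_bits == expected

    def test_atom_order_invariance(self, rng):
        base = Chem.MolFromSmiles("CC(=O)Nc1ccc(O)cc1")
        reference = None
        for _ in range(25):
            order = list(rng.permutation(base.GetNumAtoms()))
            shuffled = Chem.MolToSmiles(
                Chem.RenumberAtoms(base, [int(i) for i in order]),
                canonical=False)
            bits = morgan_fingerprint(parse_smiles(shuffled)).set_bits
            reference = bits if reference is None else reference
            assert bits == reference

    def test_structural_agreement_with_rdkit(self):
        """Same-molecule fingerprints collide, different molecules do not,
        mirroring RDKit's Morgan behaviour on the same inputs (bit values
        are hash-specific; the structure of collisions is not)."""
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        for a, b in [("CCO", "OCC"), ("CCO", "CCN"), ("c1ccccc1O", "CCCCC")]:
            ours_same = (morgan_fingerprint(parse_smiles(a)).set_bits
                         == morgan_fingerprint(parse_smiles(b)).set_bits)
            rd_same = (
                set(gen.GetFingerprint(Chem.MolFromSmiles(a)).GetOnBits())
                == set(gen.GetFingerprint(Chem.MolFromSmiles(b)).GetOnBits())
            )
            assert ours_same == rd_same

    def test_empty_radius_rejected(self):
        with pytest.raises(ValueError):
            morgan_fingerprint(parse_smiles("C"), radius=-1)


class TestFP2:
    def test_ethanamine_three_paths(self):
        fp = fp2_fingerprint(parse_smiles("CCN"))
        assert fp.n_bits_set == 3

    def test_methane_no_bits(self):
        assert fp2_fingerprint(parse_smiles("C")).n_bits_set == 0

    @pytest.mark.parametrize("smiles", SMALL_MOLECULES)
    def test_matches_bruteforce_path_enumeration(self, smiles):
        mol = parse_smiles(smiles)
        assert fp2_fingerprint(mol).set_bits == fp2_bits_bruteforce(mol)

    @pytest.mark.parametrize("smiles", SMALL_MOLECULES)
    def test_bit_count_bounded_by_path_count(self, smiles):
        mol = parse_smiles(smiles)
        fp = fp2_fingerprint(mol)
        assert fp.n_bits_set <= len(linear_path_encodings(mol))

    def test_direction_canonicalization(self):
        # N-C-C and C-C-N are the same linear fragment
        assert (fp2_fingerprint(parse_smiles("CCN")).set_bits
                == fp2_fingerprint(parse_smiles("NCC")).set_bits)


class TestPubChem:
    def test_length_is_881(self, key_table):
        fp = pubchem_fingerprint(parse_smiles("CCO"), key_table)
        assert fp.length == 881 == len(key_table)

    def test_methane_carbon_count_key(self, key_table):
        fp = pubchem_fingerprint(parse_smiles("C"), key_table)
        carbon_key = [k for k in key_table
                      if k.kind == "element" and k.pattern == "C"
                      and k.min_count == 1][0]
        assert carbon_key.index in fp.set_bits
        ring_keys = {k.index for k in key_table if k.kind == "ring"}
        assert not (ring_keys & fp.set_bits)

    def test_benzene_aromatic_ring_key(self, key_table):
        fp = pubchem_fingerprint(parse_smiles("c1ccccc1"), key_table)
        key = [k for k in key_table
               if k.kind == "ring" and k.pattern == "6:aromatic"
               and k.min_count == 1][0]
        assert key.index in fp.set_bits
        hetero_key = [k for k in key_table
                      if k.kind == "ring" and k.pattern == "6:heteroaromatic"][0]
        assert hetero_key.index not in fp.set_bits


class TestTanimoto:
    def _fp(self, bits, length=2048):
        return BitFingerprint(Scheme.MORGAN, length, frozenset(bits))

    def test_identity(self):
        fp = self._fp({1, 5, 9})
        assert tanimoto(fp, fp) == 1.0

    def test_disjoint(self):
        assert tanimoto(self._fp({1, 2}), self._fp({3, 4})) == 0.0

    def test_half_overlap(self):
        assert tanimoto(self._fp({1, 2, 3}), self._fp({2, 3, 4})) == 0.5

    def test_both_empty_convention(self):
        assert tanimoto(self._fp(set()), self._fp(set())) == 0.0

    def test_symmetric_and_bounded(self, rng):
        for _ in range(100):
            a = self._fp(set(rng.integers(0, 2048, rng.integers(0, 40))))
            b = self._fp(set(rng.integers(0, 2048, rng.integers(0, 40))))
            assert tanimoto(a, b) == tanimoto(b, a) <= 1.0

    def test_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tanimoto(self._fp({1}), BitFingerprint(Scheme.FP2, 1024,
                                                   frozenset({1})))


class TestCombined:
    @pytest.mark.parametrize("ablation,length", [
        ("full", 3953), ("onlyMF", 2048), ("noFP2", 2929),
        ("noPubChem", 3072), ("noMF", 1905),
    ])
    def test_lengths(self, ablation, length):
        comb = combined_fingerprint_for(parse_smiles("CCN"), ablation)
        assert comb.length == length

    def test_block_roundtrip(self, key_table):
        mol = parse_smiles("CC(=O)Nc1ccc(O)cc1")
        pub = pubchem_fingerprint(mol, key_table)
        fp2 = fp2_fingerprint(mol)
        mf = morgan_fingerprint(mol)
        comb = combine_fingerprints(pub, fp2, mf)
        assert comb.block(Scheme.PUBCHEM).set_bits == pub.set_bits
        assert comb.block(Scheme.FP2).set_bits == fp2.set_bits
        assert comb.block(Scheme.MORGAN).set_bits == mf.set_bits
        # offsets partition the vector
        total = sum(comb.lengths.values())
        assert total == comb.length == 3953

    def test_missing_block_rejected(self):
        mol = parse_smiles("CCN")
        mf = morgan_fingerprint(mol)
        with pytest.raises(ValueError):
            combine_fingerprints(None, None, mf, ablation="full")

    def test_nonstandard_length_rejected(self):
        mol = parse_smiles("CCN")
        with pytest.raises(ValueError):
            combine_fingerprints(None, None,
                                 morgan_fingerprint(mol, length=1024),
                                 ablation="onlyMF")

    def test_unknown_ablation_rejected(self):
        with pytest.raises(ValueError):
            combined_fingerprint_for(parse_smiles("C"), "dropEverything")

    def test_all_ablations_enumerated(self):
        assert set(ABLATIONS) == {"full", "noFP2", "noPubChem", "noMF",
                                  "onlyMF"}


class TestSklearnTransformers:
    def test_transformers_match_functions(self):
        from fragscreen.fingerprints import (CombinedFingerprinter,
                                             FP2Fingerprinter,
                                             MorganFingerprinter)
        smiles = ["CCO", "c1ccccc1"]
        mat = MorganFingerprinter().fit_transform(smiles)
        assert mat.shape == (2, 2048)
        assert set(np.nonzero(mat[0])[0]) == set(
            morgan_fingerprint(parse_smiles("CCO")).set_bits)
        assert FP2Fingerprinter().fit_transform(smiles).shape == (2, 1024)
        assert CombinedFingerprinter(ablation="noPubChem") \
            .fit_transform(smiles).shape == (2, 3072)

    def test_composes_in_sklearn_pipeline(self):
        from sklearn.pipeline import make_pipeline
        from sklearn.linear_model import LogisticRegression
        from fragscreen.fingerprints import MorganFingerprinter
        smiles = ["CCO", "CCCO", "CCCCO", "c1ccccc1", "c1ccccc1C",
                  "c1ccccc1CC"]
        labels = [0, 0, 0, 1, 1, 1]
        pipe = make_pipeline(MorganFingerprinter(),
                             LogisticRegression(max_iter=1000))
        pipe.fit(smiles, labels)
        assert list(pipe.predict(smiles)) == labels

    def test_get_set_params_roundtrip(self):
        from fragscreen.fingerprints import MorganFingerprinter
        fper = MorganFingerprinter(radius=3, n_bits=512)
        params = fper.get_params()
        assert params == {"radius": 3, "n_bits": 512}
        fper.set_params(radius=1)
        assert fper.radius == 1
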