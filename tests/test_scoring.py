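import numpy as np
import pandas as pd
import pytest

from fragscreen.chem import SmilesRecord
from fragscreen.fingerprints import (BitFingerprint, CombinedFingerprint,
                                     Scheme, combined_fingerprint_for)
from fragscreen.pockets import TargetProfile
from fragscreen.scoring import (PRESETS, BinderScorer, LabeledPair,
                                ScoreModelSpec, assemble_features,
                                build_training_set, feature_layout,
                                load_model, loocv_exclusion, save_model,
                                train_scoring_model)
from fragscreen.chem import parse_smiles


def make_profile(target_id="tgt", seed=0):
    rng = np.random.default_rng(seed)
    comp = rng.dirichlet(np.ones(20))
    from fragscreen.pockets import TemplatePocketRecord
    pocket = TemplatePocketRecord(
        template_id=f"{target_id}_T0", pocket_residues="ACDEFG",
        tm_score=0.9, aligned_fraction=0.95, seq_identity=0.2,
        rank_score=0.5,
        template_ligands=[SmilesRecord("c1ccccc1CCN", f"{target_id}_L0")])
    return TargetProfile(target_id=target_id, sequence="ACDEFGHIKL",
                         accepted_pockets=[pocket], composition=comp)


class TestPresets:
    def test_published_hyperparameters(self):
        assert (PRESETS["deep"].n_estimators,
                PRESETS["deep"].max_depth,
                PRESETS["deep"].learning_rate) == (3000, 6, 0.05)
        assert (PRESETS["shallow"].n_estimators,
                PRESETS["shallow"].max_depth,
                PRESETS["shallow"].learning_rate) == (300, 6, 0.05)


class TestAssembleFeatures:
    def test_full_configuration_is_3973(self):
        profile = make_profile()
        fp = combined_fingerprint_for(parse_smiles("CCN"), "full")
        vec = assemble_features(profile, fp)
        assert vec.shape == (3973,)
        assert vec[:20].sum() == pytest.approx(1.0)

    def test_substructure_key_only_configuration_is_901(self):
        # the ancestor feature set: 20 composition + 881 keys
        profile = make_profile()
        pub = combined_fingerprint_for(parse_smiles("CCN"), "full") \
            .block(Scheme.PUBCHEM)
        single = CombinedFingerprint(
            blocks=(Scheme.PUBCHEM,), offsets={Scheme.PUBCHEM: 0},
            lengths={Scheme.PUBCHEM: 881}, length=881,
            set_bits=pub.set_bits)
        assert assemble_features(profile, single).shape == (901,)

    def test_only_morgan_configuration_is_2068(self):
        profile = make_profile()
        fp = combined_fingerprint_for(parse_smiles("CCN"), "onlyMF")
        assert assemble_features(profile, fp).shape == (2068,)

    def test_blocks_recoverable_from_vector(self):
        profile = make_profile()
        fp = combined_fingerprint_for(parse_smiles("c1ccccc1O"), "full")
        vec = assemble_features(profile, fp)
        layout = feature_layout("full")
        assert np.allclose(vec[:20], profile.composition)
        for name, start, stop in layout["blocks"][1:]:
            block_bits = {int(i) for i in
                          np.nonzero(vec[start:stop])[0]}
            assert block_bits == set(
                fp.block(Scheme(name)).set_bits)


class TestBuildTrainingSet:
    def test_decoy_subsample_fraction(self, bench_small):
        pairs = build_training_set(bench_small, decoy_fraction=0.1, seed=0)
        for target in bench_small.targets:
            mine = [p for p in pairs if p.target_id == target.target_id]
            n_pos = sum(p.label for p in mine)
            n_neg = len(mine) - n_pos
            assert n_pos == len(target.actives)
            assert n_neg == round(0.1 * len(target.decoys))

    def test_full_inclusion(self, bench_small):
        pairs = build_training_set(bench_small, decoy_fraction=1.0, seed=0)
        total = sum(len(t.actives) + len(t.decoys)
                    for t in bench_small.targets)
        assert len(pairs) == total

    def test_seed_reproducibility(self, bench_small):
        a = build_training_set(bench_small, seed=42)
        b = build_training_set(bench_small, seed=42)
        assert [(p.target_id, p.ligand_id, p.label) for p in a] == \
            [(p.target_id, p.ligand_id, p.label) for p in b]

    def test_invalid_fraction_rejected(self, bench_small):
        with pytest.raises(ValueError):
            build_training_set(bench_small, decoy_fraction=0.0)

    def test_pooled_variant_same_total(self, bench_small):
        per_target = build_training_set(bench_small, seed=1)
        pooled = build_training_set(bench_small, seed=1, pooled_decoys=True)
        n_neg = lambda pairs: sum(1 - p.label for p in pairs)
        assert n_neg(per_target) == n_neg(pooled)


class TestLoocvExclusion:
    def _matrix(self, values):
        ids = list(values)
        mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
        for a, row in values.items():
            for b, v in row.items():
                mat.loc[a, b] = mat.loc[b, a] = v
        return mat

    def test_identity_only_keeps_everyone(self):
        mat = self._matrix({"a": {}, "b": {}, "c": {}})
        assert set(loocv_exclusion("a", ["a", "b", "c"], mat)) == {"b", "c"}

    def test_high_identity_excluded(self):
        mat = self._matrix({"a": {"b": 0.95}, "b": {}, "c": {"a": 0.5}})
        assert set(loocv_exclusion("a", ["a", "b", "c"], mat)) == {"c"}

    def test_cutoff_zero_empties_training(self):
        mat = self._matrix({"a": {"b": 0.1}, "b": {}})
        assert loocv_exclusion("a", ["a", "b"], mat, cutoff=0.0) == []

    def test_missing_target_rejected(self):
        mat = self._matrix({"a": {}, "b": {}})
        with pytest.raises(KeyError):
            loocv_exclusion("zz", ["a", "b"], mat)


def planted_pairs(n_pos=25, n_neg=25, n_features=2068, seed=0):
    """Linearly separable fixture: positives carry a dense bit stripe."""
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n_pos + n_neg):
        label = int(i < n_pos)
        vec = np.zeros(n_features, dtype=np.float32)
        vec[:20] = 1 / 20
        base = rng.choice(np.arange(1000, 2000), size=30, replace=False)
        vec[base] = 1.0
        if label:
            vec[20:40] = 1.0  # planted stripe
        pairs.append(LabeledPair("t", f"L{i:03d}", vec, label))
    return pairs


class TestTrainScoringModel:
    def test_separable_fixture_orders_labels(self):
        pairs = planted_pairs()
        model = train_scoring_model(pairs, PRESETS["shallow"],
                                    ablation="onlyMF")
        X = np.stack([p.features for p in pairs])
        scores = model.predict(X)
        pos = scores[[p.label == 1 for p in pairs]]
        neg = scores[[p.label == 0 for p in pairs]]
        assert pos.min() > neg.max()

    def test_same_seed_identical_predictions(self):
        pairs = planted_pairs()
        X = np.stack([p.features for p in pairs])
        m1 = train_scoring_model(pairs, PRESETS["shallow"], seed=7,
                                 ablation="onlyMF")
        m2 = train_scoring_model(pairs, PRESETS["shallow"], seed=7,
                                 ablation="onlyMF")
        assert np.array_equal(m1.predict(X), m2.predict(X))

    def test_pair_order_invariance(self, rng):
        pairs = planted_pairs()
        shuffled = [pairs[i] for i in rng.permutation(len(pairs))]
        X = np.stack([p.features for p in pairs])
        m1 = train_scoring_model(pairs, PRESETS["shallow"],
                                 ablation="onlyMF")
        m2 = train_scoring_model(shuffled, PRESETS["shallow"],
                                 ablation="onlyMF")
        assert np.allclose(m1.predict(X), m2.predict(X), atol=1e-5)

    def test_single_class_rejected(self):
        pairs = [p for p in planted_pairs() if p.label == 1]
        with pytest.raises(ValueError):
            train_scoring_model(pairs, PRESETS["shallow"],
                                ablation="onlyMF")

    def test_inconsistent_feature_lengths_rejected(self):
        pairs = planted_pairs(n_pos=2, n_neg=2)
        pairs[0] = LabeledPair("t", "odd", np.zeros(100, dtype=np.float32), 1)
        scorer = BinderScorer.from_preset("shallow", ablation="onlyMF")
        with pytest.raises(ValueError):
            scorer.fit_pairs(pairs)

    def test_wrong_width_for_ablation_rejected(self):
        pairs = planted_pairs(n_features=3973)
        scorer = BinderScorer.from_preset("shallow", ablation="onlyMF")
        with pytest.raises(ValueError):
            scorer.fit_pairs(pairs)


@pytest.fixture(scope="module")
def trained(bench_small):
    pairs = build_training_set(bench_small, seed=0, ablation="onlyMF")
    return train_scoring_model(pairs, PRESETS["shallow"],
                               ablation="onlyMF")


class TestScoreLibrary:

    def test_singleton_library(self, trained, bench_small):
        target = bench_small.targets[0]
        screen = trained.score_library(
            target.profile, [SmilesRecord("CCO", "solo")])
        assert len(screen) == 1 and screen.entries[0].ligand_id == "solo"

    def test_duplicate_smiles_identical_scores(self, trained, bench_small):
        target = bench_small.targets[0]
        screen = trained.score_library(target.profile, [
            SmilesRecord("c1ccccc1CCN", "dup1"),
            SmilesRecord("c1ccccc1CCN", "dup2"),
        ])
        assert screen.entries[0].score == screen.entries[1].score
        assert [e.ligand_id for e in screen.entries] == ["dup1", "dup2"]

    def test_unparsable_skipped(self, trained, bench_small, caplog):
        target = bench_small.targets[0]
        screen = trained.score_library(target.profile, [
            SmilesRecord("CCO", "good"), SmilesRecord("xx((", "bad")])
        assert len(screen) == 1


class TestModelArchive:
    def test_roundtrip_predictions(self, tmp_path):
        pairs = planted_pairs()
        model = train_scoring_model(pairs, PRESETS["shallow"],
                                    ablation="onlyMF")
        save_model(model, tmp_path / "model")
        loaded = load_model(tmp_path / "model")
        X = np.stack([p.features for p in pairs])
        assert np.array_equal(model.predict(X), loaded.predict(X))
        assert loaded.ablation == "onlyMF"

    def test_layout_mismatch_refused(self, tmp_path):
        import json
        pairs = planted_pairs()
        model = train_scoring_model(pairs, PRESETS["shallow"],
                                    ablation="onlyMF")
        save_model(model, tmp_path / "model")
        manifest_path = tmp_path / "model" / "manifest.json"
        manifest = json.loads(manifest_path.read_text())
        manifest["ablation"] = "full"  # tampered: layout no longer matches
        manifest_path.write_text(json.dumps(manifest))
        with pytest.raises(ValueError):
            load_model(tmp_path / "model")
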