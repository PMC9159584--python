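"""Feature encoding, sampling protocol and forest training."""

import numpy as np
import pytest

from tisscan.forest import (
    ATG_SCHEMA,
    NEAR_COGNATE_SCHEMA,
    LabeledExample,
    SchemaError,
    decode_flanks,
    encode,
    evaluate_balanced,
    frame_to_examples,
    examples_to_frame,
    load_model,
    predict_proba,
    prepare_training_sets,
    read_training_table,
    sample_near_cognate_test,
    save_model,
    train_forest,
    write_training_table,
)
from tisscan.scoring import FlankedCodon
from tisscan.simulate import SyntheticSpec, generate_labeled_dataset


def make_example(codon="ATG", left="A" * 10, right="C" * 10, label=1):
    return LabeledExample(FlankedCodon(codon, left, right), label, "ATG")


class TestEncode:
    def test_schema_feature_counts(self):
        assert ATG_SCHEMA.n_features == 100
        assert NEAR_COGNATE_SCHEMA.n_features == 105

    def test_missing_left_flank_sets_missing_indicators(self):
        vec = encode(FlankedCodon("ATG", "-" * 10, "A" * 10), ATG_SCHEMA)
        # fifth state of each of the first ten position blocks
        assert all(vec[5 * p + 4] == 1 for p in range(10))

    def test_exactly_one_indicator_per_position(self, rng):
        flanks = "".join(rng.choice(list("ACGT-"), size=20))
        vec = encode(FlankedCodon("ATG", flanks[:10], flanks[10:]), ATG_SCHEMA)
        assert vec.sum() == 20
        blocks = vec.reshape(20, 5)
        assert np.all(blocks.sum(axis=1) == 1)

    def test_near_cognate_adds_first_base_indicator(self):
        vec = encode(FlankedCodon("GTG", "A" * 10, "A" * 10), NEAR_COGNATE_SCHEMA)
        assert vec.sum() == 21
        assert vec[100:105].tolist() == [0, 0, 1, 0, 0]  # G

    def test_round_trip_recovers_flanks(self, rng):
        flanks = "".join(rng.choice(list("ACGT-"), size=20))
        vec = encode(FlankedCodon("CTG", flanks[:10], flanks[10:]), NEAR_COGNATE_SCHEMA)
        assert decode_flanks(vec) == flanks

    def test_schema_codon_mismatch_rejected(self):
        with pytest.raises(SchemaError):
            encode(FlankedCodon("CTG", "A" * 10, "A" * 10), ATG_SCHEMA)
        with pytest.raises(SchemaError):
            encode(FlankedCodon("ATG", "A" * 10, "A" * 10), NEAR_COGNATE_SCHEMA)


class TestPrepareTrainingSets:
    @staticmethod
    def build_classes(n_pos, n_complete, n_missing):
        pos = [make_example(label=1) for _ in range(n_pos)]
        neg = [make_example(label=0) for _ in range(n_complete)] + [
            make_example(left="-" * 10, label=0) for _ in range(n_missing)
        ]
        return pos, neg

    def test_published_pool_arithmetic(self):
        # 1,805 complete negatives plus 1,628 sampled missing-flank
        # negatives form a 3,433 pool; a 5% holdout of 172 negatives plus
        # 172 positives gives the balanced 344-case test set
        pos, neg = self.build_classes(4000, 1805, 2000)
        split = prepare_training_sets(pos, neg, n_missing=1628, rng_seed=0)
        assert len(split.train_neg) + 172 == 3433
        assert len(split.test) == 344
        assert sum(ex.label for ex in split.test) == 172

    def test_default_missing_ratio_rounds_down(self):
        pos, neg = self.build_classes(100, 10, 50)
        split = prepare_training_sets(pos, neg, holdout_fraction=0.0, rng_seed=0)
        # pool = 10 complete + floor(0.9 * 10) = 19
        assert len(split.train_neg) == 19
        assert len(split.test) == 0
        assert len(split.train_pos) == 100

    def test_zero_holdout_keeps_everything(self):
        pos, neg = self.build_classes(20, 10, 0)
        split = prepare_training_sets(pos, neg, holdout_fraction=0.0, rng_seed=1)
        assert split.test == []
        assert len(split.train_pos) == 20

    def test_identical_seed_identical_split(self):
        examples = generate_labeled_dataset(SyntheticSpec(n_pos=50, n_neg=80, seed=5))
        pos = [e for e in examples if e.label == 1]
        neg = [e for e in examples if e.label == 0]
        a = prepare_training_sets(pos, neg, rng_seed=9)
        b = prepare_training_sets(pos, neg, rng_seed=9)
        assert a.test == b.test and a.train_pos == b.train_pos

    def test_holdout_disjoint_from_training(self):
        examples = generate_labeled_dataset(SyntheticSpec(n_pos=60, n_neg=90, seed=2))
        pos = [e for e in examples if e.label == 1]
        neg = [e for e in examples if e.label == 0]
        split = prepare_training_sets(pos, neg, holdout_fraction=0.1, rng_seed=3)
        train_ids = {id(e) for e in split.train_pos + split.train_neg}
        assert all(id(e) not in train_ids for e in split.test)


class TestTrainForest:
    def test_determinism_of_votes(self, atg_split):
        a = train_forest(
            atg_split.train_pos, atg_split.train_neg, ATG_SCHEMA, n_trees=20, rng_seed=4
        )
        b = train_forest(
            atg_split.train_pos, atg_split.train_neg, ATG_SCHEMA, n_trees=20, rng_seed=4
        )
        fc = atg_split.test[0].context
        assert predict_proba(a, fc) == predict_proba(b, fc)

    def test_vote_probability_granularity(self, atg_model, atg_split):
        probas = [predict_proba(atg_model, ex.context) for ex in atg_split.test[:20]]
        votes = np.array(probas) * atg_model.n_trees
        assert np.allclose(votes, np.round(votes))

    def test_trees_see_equal_label_counts(self, rng):
        # scarce positives: each tree must subsample negatives down to match
        pos = [make_example(label=1) for _ in range(10)]
        neg = [
            make_example(left="".join(rng.choice(list("ACGT"), 10)), label=0)
            for _ in range(50)
        ]
        model = train_forest(pos, neg, ATG_SCHEMA, n_trees=5, rng_seed=0)
        assert model.config["n_tree_negatives"] == 10
        for tree in model.trees:
            assert tree.tree_.n_node_samples[0] == 20

    def test_extra_feature_column_rejected(self, atg_model):
        X = np.zeros((1, ATG_SCHEMA.n_features + 1))
        with pytest.raises(SchemaError):
            atg_model.predict_proba_matrix(X)

    def test_single_label_training_rejected(self):
        pos = [make_example(label=1) for _ in range(5)]
        with pytest.raises(ValueError):
            train_forest(pos, [], ATG_SCHEMA, n_trees=2)

    def test_planted_signal_recovered(self):
        # positives from a near-deterministic consensus, negatives uniform:
        # a single strong position separates the classes almost perfectly
        from tisscan.logo import FrequencyMatrix, default_logo
        from tisscan.simulate import composition_matrix

        logo = default_logo()
        sharp = np.full((20, 4), 0.02)
        sharp[np.arange(20), logo.heights.argmax(axis=1)] = 0.94
        spec = SyntheticSpec(
            n_pos=300,
            n_neg=450,
            missing_fraction=0.0,
            positive_matrix=FrequencyMatrix(sharp),
            negative_matrix=composition_matrix([0.25] * 4),
            seed=21,
        )
        examples = generate_labeled_dataset(spec)
        pos = [e for e in examples if e.label == 1]
        neg = [e for e in examples if e.label == 0]
        split = prepare_training_sets(pos, neg, rng_seed=21)
        model = train_forest(split.train_pos, split.train_neg, ATG_SCHEMA, n_trees=100, rng_seed=21)
        accuracy, _ = evaluate_balanced(model, split.test)
        assert accuracy >= 0.95

    def test_label_shuffle_gives_chance_accuracy(self):
        rng = np.random.default_rng(0)
        accs = []
        for seed in range(8):
            examples = generate_labeled_dataset(
                SyntheticSpec(n_pos=150, n_neg=150, seed=seed)
            )
            labels = rng.permutation([e.label for e in examples])
            shuffled = [
                LabeledExample(e.context, int(l), e.codon_class)
                for e, l in zip(examples, labels)
            ]
            pos = [e for e in shuffled if e.label == 1]
            neg = [e for e in shuffled if e.label == 0]
            split = prepare_training_sets(pos, neg, holdout_fraction=0.2, rng_seed=seed)
            model = train_forest(
                split.train_pos, split.train_neg, ATG_SCHEMA, n_trees=50, rng_seed=seed
            )
            acc, _ = evaluate_balanced(model, split.test)
            accs.append(acc)
        mean = np.mean(accs)
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(mean - 0.5) < 3 * max(se, 0.02)


class TestEvaluateBalanced:
    def test_accuracy_matches_hand_count(self, atg_model, atg_split):
        test = atg_split.test
        proba = [predict_proba(atg_model, ex.context) for ex in test]
        correct = sum(
            (p >= 0.5 and ex.label == 1) or (p < 0.5 and ex.label == 0)
            for p, ex in zip(proba, test)
        )
        accuracy, _ = evaluate_balanced(atg_model, test)
        assert accuracy == pytest.approx(correct / len(test))

    def test_unbalanced_test_refused_unless_forced(self, atg_model, atg_split):
        lopsided = [ex for ex in atg_split.test if ex.label == 1][:5] + [
            ex for ex in atg_split.test if ex.label == 0
        ][:2]
        with pytest.raises(ValueError):
            evaluate_balanced(atg_model, lopsided)
        accuracy, _ = evaluate_balanced(atg_model, lopsided, force=True)
        assert 0.0 <= accuracy <= 1.0


class TestNearCognateHoldout:
    def test_twenty_per_codon_and_label(self):
        examples = generate_labeled_dataset(
            SyntheticSpec(n_pos=200, n_neg=200, codon_class="near-cognate", seed=7)
        )
        test, remainder = sample_near_cognate_test(examples, per_codon=20, rng_seed=7)
        assert len(test) == 120
        assert len(test) + len(remainder) == len(examples)
        for codon in ("CTG", "GTG", "TTG"):
            for label in (0, 1):
                count = sum(
                    1 for ex in test if ex.context.codon == codon and ex.label == label
                )
                assert count == 20


class TestPersistence:
    def test_save_load_round_trip(self, atg_model, atg_split, tmp_path):
        path = tmp_path / "atg.joblib"
        save_model(atg_model, path)
        again = load_model(path)
        fc = atg_split.test[0].context
        assert predict_proba(again, fc) == predict_proba(atg_model, fc)
        assert again.schema.name == atg_model.schema.name


class TestTrainingTableIO:
    def test_tsv_round_trip(self, tmp_path):
        examples = generate_labeled_dataset(
            SyntheticSpec(n_pos=5, n_neg=5, missing_fraction=0.5, seed=3)
        )
        path = tmp_path / "train.tsv"
        write_training_table(examples, path)
        again = read_training_table(path)
        assert examples_to_frame(again).equals(examples_to_frame(examples))

    def test_missing_columns_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            frame_to_examples(pd.DataFrame({"codon": ["ATG"]}))
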