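"""Feature scoring oracles, leak-free cross-validation, vote aggregation."""

import numpy as np
import pandas as pd
import pytest

from chromcode.ml import (
    MLConfig,
    NEGATIVE,
    POSITIVE,
    PredictionRecord,
    aggregate_predictions,
    chi_square_score,
    evaluate,
    info_gain,
    prediction_report,
    rank_features,
    run_iteration,
    run_method,
    symmetrical_uncertainty,
)

Y6 = np.array(["r", "r", "r", "n", "n", "n"])
X6 = np.array([0, 0, 1, 1, 2, 2])
# hand entropies: H(y)=1; bins (r,r),(r,n),(n,n) -> H(y|x) = 1/3
IG6 = 2.0 / 3.0
SU6 = 2 * IG6 / (np.log2(3) + 1.0)
CHI6 = 4.0  # contingency [[2,0],[1,1],[0,2]] vs all-ones expectation


def make_table(n=40, seed=0, separable=True):
    rng = np.random.default_rng(seed)
    y = np.array([POSITIVE, NEGATIVE] * (n // 2))
    signal = (y == POSITIVE).astype(float)
    cols = {
        "f_signal": signal + (0.01 * rng.random(n) if separable else rng.random(n)),
        "f_noise1": rng.random(n),
        "f_noise2": rng.random(n),
        "f_const": np.ones(n),
    }
    table = pd.DataFrame(cols, index=[f"g{i:03d}" for i in range(n)])
    table["label"] = y
    return table


class TestScores:
    def test_hand_entropy_oracle(self):
        assert info_gain(X6, Y6) == pytest.approx(IG6, abs=1e-12)
        assert symmetrical_uncertainty(X6, Y6) == pytest.approx(SU6, abs=1e-12)
        assert chi_square_score(X6, Y6) == pytest.approx(CHI6, abs=1e-12)

    def test_perfect_binary_feature_is_one_bit(self):
        y = np.array(["a"] * 5 + ["b"] * 5)
        x = (y == "a").astype(int)
        assert info_gain(x, y) == pytest.approx(1.0)
        assert symmetrical_uncertainty(x, y) == pytest.approx(1.0)

    def test_constant_feature_scores_zero(self):
        x = np.zeros(10, dtype=int)
        y = np.array(["a", "b"] * 5)
        assert info_gain(x, y) == 0.0
        assert chi_square_score(x, y) == 0.0
        assert symmetrical_uncertainty(x, y) == 0.0

    @pytest.mark.parametrize(
        "method", ["info_gain", "symmetrical_uncertainty", "chi_square", "relief"]
    )
    def test_informative_feature_ranks_first(self, method):
        ranking = rank_features(make_table(), method)
        assert ranking.iloc[0]["feature"] == "f_signal"
        assert ranking["score"].is_monotonic_decreasing

    def test_constant_label_rejected(self):
        table = make_table()
        table["label"] = POSITIVE
        with pytest.raises(ValueError, match="constant"):
            rank_features(table, "info_gain")


class TestCrossValidation:
    @pytest.mark.parametrize("classifier", ["random_forest", "naive_bayes", "knn", "svm"])
    def test_separable_table_predicted_perfectly(self, classifier):
        table = make_table(n=60)
        pred = run_iteration(table, "info_gain", classifier, top_k=2, n_folds=10, seed=1)
        assert (pred == table["label"]).all()

    def test_fixed_seed_is_reproducible(self):
        table = make_table(n=60, separable=False)
        a = run_iteration(table, "relief", "random_forest", top_k=3, seed=5)
        b = run_iteration(table, "relief", "random_forest", top_k=3, seed=5)
        assert (a == b).all()

    def test_too_few_genes_per_class_rejected(self):
        table = make_table(n=10)
        with pytest.raises(ValueError, match="class"):
            run_iteration(table, "info_gain", "knn", n_folds=10)

    def test_training_rankings_ignore_heldout_labels(self):
        # selection sees only the training slice: scrambling labels outside
        # that slice cannot change the ranking it produces
        table = make_table(n=60, separable=False)
        train = table.iloc[:50]
        scrambled = table.copy()
        scrambled.iloc[50:, scrambled.columns.get_loc("label")] = POSITIVE
        a = rank_features(train, "info_gain")
        b = rank_features(scrambled.iloc[:50], "info_gain")
        pd.testing.assert_frame_equal(a, b)

    def test_label_permutation_collapses_to_baseline(self, benchmark_runs):
        table = benchmark_runs[0]["table"].copy()
        rng = np.random.default_rng(17)
        table["label"] = rng.permutation(table["label"].to_numpy())
        baseline = 100.0 * table["label"].value_counts().max() / len(table)
        for classifier in ("naive_bayes", "knn"):
            records = run_method(
                table, "info_gain", classifier, MLConfig(n_iterations=10, base_seed=3)
            )
            acc = evaluate(records, table["label"]).overall_accuracy
            assert 42.0 <= acc <= baseline + 8.0


class TestAggregation:
    def votes(self, n_pos, n_total=50):
        row = [POSITIVE] * n_pos + [NEGATIVE] * (n_total - n_pos)
        votes = pd.DataFrame([row], index=["g1"])
        labels = pd.Series({"g1": POSITIVE})
        return aggregate_predictions(votes, labels)[0]

    def test_unanimous(self):
        rec = self.votes(50)
        assert rec.aggregate_class == POSITIVE and rec.vote_fraction == 1.0

    def test_just_over_half_wins(self):
        assert self.votes(26).aggregate_class == POSITIVE

    def test_exact_tie_falls_to_nonrepressed(self):
        assert self.votes(25).aggregate_class == NEGATIVE

    def test_missing_iterations_rejected(self):
        votes = pd.DataFrame({0: [POSITIVE], 1: [None]}, index=["g1"])
        with pytest.raises(ValueError, match="missing"):
            aggregate_predictions(votes, pd.Series({"g1": POSITIVE}))


class TestEvaluate:
    def records(self, spec):
        recs, labels = [], {}
        for i, (label, correct) in enumerate(spec):
            gid = f"g{i}"
            labels[gid] = label
            pred = label if correct else (NEGATIVE if label == POSITIVE else POSITIVE)
            recs.append(PredictionRecord(gid, (pred,), pred, float(pred == POSITIVE), correct))
        return recs, pd.Series(labels)

    def test_hand_counts(self):
        spec = [(POSITIVE, True)] * 4 + [(POSITIVE, False)] * 2
        spec += [(NEGATIVE, True)] * 3 + [(NEGATIVE, False)]
        recs, labels = self.records(spec)
        rep = evaluate(recs, labels)
        assert rep.overall_accuracy == pytest.approx(70.0)
        assert rep.repressed_accuracy == pytest.approx(100 * 4 / 6)
        assert rep.nonrepressed_accuracy == pytest.approx(75.0)
        assert rep.baseline_overall == 60
        assert rep.baseline_repressed == pytest.approx(60.0)

    def test_all_correct_is_100(self):
        recs, labels = self.records([(POSITIVE, True)] * 5 + [(NEGATIVE, True)] * 5)
        rep = evaluate(recs, labels)
        assert rep.overall_accuracy == 100.0
        assert rep.repressed_accuracy == 100.0


class TestReport:
    def test_matrix_of_calls(self):
        labels = pd.Series({"g1": POSITIVE, "g2": NEGATIVE})
        rec = lambda gid, call: PredictionRecord(gid, (call,), call, 0.0, True)
        records_by_method = {
            ("info_gain", "random_forest"): [rec("g1", POSITIVE), rec("g2", NEGATIVE)],
            ("relief", "svm"): [rec("g1", POSITIVE), rec("g2", NEGATIVE)],
        }
        out = prediction_report(records_by_method, labels)
        assert out.shape == (2, 3)
        assert (out.loc["g1"][1:] == POSITIVE).all()
        empty = prediction_report(records_by_method, labels, gene_subset=[])
        assert empty.shape == (0, 3)

    def test_errant_genes_attract_repressed_votes(self, rf_benchmark_records):
        run = rf_benchmark_records[0]
        truth = run["cohort"].truth
        frac = {r.gene_id: r.vote_fraction for r in run["records"]}
        errant = [g for g, e in truth.errant.items() if e]
        clean = [g for g, e in truth.errant.items() if not e]
        assert np.mean([frac[g] for g in errant]) > np.mean([frac[g] for g in clean]) + 0.2

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MLConfig(selectors=("bogus",))
        with pytest.raises(ValueError):
            MLConfig(n_folds=1)
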