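import numpy as np
import pandas as pd
import pytest

from stacksdm.sdm_fit import (
    BUILTIN_ALGORITHMS,
    ConfusionCounts,
    auc_rank,
    confusion_metrics,
    crossvalidate,
    fit_species,
    get_adapter,
    metrics_at_threshold,
    permutation_importance,
    select_threshold,
)


class TestConfusionMetrics:
    def test_worked_example(self):
        m = confusion_metrics(ConfusionCounts(TP=40, FN=10, TN=35, FP=15))
        assert m.sensitivity == pytest.approx(0.8)
        assert m.specificity == pytest.approx(0.7)
        assert m.tss == pytest.approx(0.5)
        assert m.omission_rate == pytest.approx(0.2)
        assert m.prop_correct == pytest.approx(0.75)
        # p_e = 0.55*0.5 + 0.45*0.5 = 0.5 -> kappa = (0.75-0.5)/0.5
        assert m.kappa == pytest.approx(0.5)
        assert m.jaccard == pytest.approx(40 / 65)

    def test_all_predicted_positive_half_prevalence(self):
        m = confusion_metrics(ConfusionCounts(TP=5, FN=0, FP=5, TN=5))
        assert m.sensitivity == pytest.approx(1.0)
        assert m.specificity == pytest.approx(0.5)
        assert m.tss == pytest.approx(0.5)

    def test_identities_hold_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(0, 50, size=4)
            if tp + fn == 0 or tn + fp == 0:
                continue
            m = confusion_metrics(ConfusionCounts(TP=int(tp), FP=int(fp), TN=int(tn), FN=int(fn)))
            assert m.tss == pytest.approx(m.sensitivity + m.specificity - 1)
            assert m.omission_rate == pytest.approx(1 - m.sensitivity)
            assert -1 <= m.kappa <= 1

    def test_empty_observed_class_raises(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionCounts(TP=0, FP=3, TN=2, FN=0))

    def test_negative_count_raises(self):
        with pytest.raises(ValueError):
            ConfusionCounts(TP=-1, FP=0, TN=1, FN=1)


class TestAucRank:
    def test_worked_example(self):
        # pos {0.9, 0.4}, neg {0.6, 0.2}: pairs won 3 of 4
        assert auc_rank([0.9, 0.4], [0.6, 0.2]) == pytest.approx(0.75)

    def test_perfect_and_inverted(self):
        assert auc_rank([0.8, 0.9], [0.1, 0.2]) == pytest.approx(1.0)
        assert auc_rank([0.1, 0.2], [0.8, 0.9]) == pytest.approx(0.0)

    def test_ties_count_half(self):
        assert auc_rank([0.5], [0.5]) == pytest.approx(0.5)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        for _ in range(20):
            pos = rng.random(13)
            neg = rng.random(17)
            y = np.concatenate([np.ones(13), np.zeros(17)])
            scores = np.concatenate([pos, neg])
            assert auc_rank(pos, neg) == pytest.approx(roc_auc_score(y, scores))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            auc_rank([], [0.5])


class TestSelectThreshold:
    def test_worked_example(self):
        preds = np.array([0.9, 0.7, 0.6, 0.4, 0.2])
        y = np.array([1, 1, 0, 1, 0])
        # t=0.7: sens 2/3, spec 1 -> 1.667 (best); returns 0.7
        assert select_threshold(preds, y) == pytest.approx(0.7)

    def test_ties_keep_smallest_threshold(self):
        preds = np.array([0.2, 0.4, 0.6, 0.8])
        y = np.array([0, 0, 1, 1])
        # both 0.6 and any t in (0.4, 0.6] give TSS 1; smallest candidate wins
        assert select_threshold(preds, y) == pytest.approx(0.6)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            select_threshold(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_equals_exhaustive_search_on_random_fixtures(self):
        from fractions import Fraction

        def exhaustive(preds, y):
            best_t, best = None, Fraction(-1)
            n_pos = int((y == 1).sum())
            n_neg = int((y == 0).sum())
            for t in np.unique(preds):
                pp = preds >= t
                s = Fraction(int((pp & (y == 1)).sum()), n_pos) + Fraction(
                    int(((~pp) & (y == 0)).sum()), n_neg
                )
                if s > best:  # exact rational ties keep the smallest threshold
                    best, best_t = s, t
            return best_t

        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(4, 60))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            # mix of continuous and heavily tied prediction values
            if rng.random() < 0.5:
                preds = rng.random(n)
            else:
                preds = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=n)
            assert select_threshold(preds, y) == pytest.approx(exhaustive(preds, y))


class TestMetricsAtThreshold:
    def test_agrees_with_confusion_metrics(self):
        preds = np.array([0.9, 0.7, 0.6, 0.4, 0.2])
        y = np.array([1, 1, 0, 1, 0])
        m = metrics_at_threshold(preds, y, 0.5)
        # >= 0.5: TP=2, FP=1, FN=1, TN=1
        ref = confusion_metrics(ConfusionCounts(TP=2, FP=1, TN=1, FN=1))
        assert m.sensitivity == pytest.approx(ref.sensitivity)
        assert m.specificity == pytest.approx(ref.specificity)
        assert np.isfinite(m.auc)


def separable_pa(n_pos=30, n_neg=30, seed=0, n_layers=3):
    """A linearly separable presence/absence problem on layer 0."""
    from stacksdm.occurrences import PresenceAbsenceSet

    rng = np.random.default_rng(seed)
    X_pos = rng.normal(loc=[3.0] + [0.0] * (n_layers - 1), size=(n_pos, n_layers))
    X_neg = rng.normal(loc=[-3.0] + [0.0] * (n_layers - 1), size=(n_neg, n_layers))
    return PresenceAbsenceSet(
        species="Testus species",
        presence_cells=[(0, i) for i in range(n_pos)],
        absence_cells=[(1, i) for i in range(n_neg)],
        X=np.vstack([X_pos, X_neg]),
        y=np.concatenate([np.ones(n_pos), np.zeros(n_neg)]).astype(int),
        layer_names=[f"l{i}" for i in range(n_layers)],
    )


class TestAdapters:
    @pytest.mark.parametrize("name", BUILTIN_ALGORITHMS)
    def test_fit_predict_contract(self, name):
        pa = separable_pa(seed=5)
        model = get_adapter(name).fit(pa.X, pa.y, seed=0)
        preds = model.predict(pa.X)
        assert preds.shape == (len(pa.y),)
        assert (preds >= 0).all() and (preds <= 1).all()
        # trivially separable: in-sample AUC should be near perfect
        assert auc_rank(preds[pa.y == 1], preds[pa.y == 0]) > 0.95

    @pytest.mark.parametrize("name", ["CTA", "RF", "SVM"])
    def test_deterministic_under_seed(self, name):
        pa = separable_pa(seed=6)
        p1 = get_adapter(name).fit(pa.X, pa.y, seed=11).predict(pa.X)
        p2 = get_adapter(name).fit(pa.X, pa.y, seed=11).predict(pa.X)
        np.testing.assert_array_equal(p1, p2)

    def test_unknown_algorithm_raises(self):
        with pytest.raises(NotImplementedError):
            get_adapter("MAXENT").build(seed=0)


class TestCrossvalidate:
    def test_metrics_high_on_separable_data(self):
        pa = separable_pa(seed=7)
        m = crossvalidate(pa, get_adapter("CTA"), k=5, n_reps=2, seed=0)
        assert m.auc > 0.9
        assert m.tss > 0.7

    def test_k_reduced_to_class_size(self, caplog):
        import logging

        pa = separable_pa(n_pos=3, n_neg=30, seed=8)
        with caplog.at_level(logging.INFO, logger="stacksdm.sdm_fit"):
            crossvalidate(pa, get_adapter("CTA"), k=10, n_reps=1, seed=0)
        assert any("k reduced" in r.message for r in caplog.records)

    def test_pooled_predictions_cover_every_cell(self):
        pa = separable_pa(seed=9)
        _, pooled = crossvalidate(
            pa, get_adapter("CTA"), k=5, n_reps=2, seed=0, return_pooled=True
        )
        assert pooled.shape == (2, len(pa.y))
        assert np.isfinite(pooled).all()

    def test_deterministic(self):
        pa = separable_pa(seed=10)
        m1, p1 = crossvalidate(pa, get_adapter("RF"), k=4, n_reps=1, seed=3, return_pooled=True)
        m2, p2 = crossvalidate(pa, get_adapter("RF"), k=4, n_reps=1, seed=3, return_pooled=True)
        assert m1.as_dict() == m2.as_dict()
        np.testing.assert_array_equal(p1, p2)


class TestPermutationImportance:
    def test_informative_layer_dominates(self):
        pa = separable_pa(seed=11)
        model = get_adapter("RF").fit(pa.X, pa.y, seed=0)
        imp = permutation_importance(model, pa, n_reps=3, seed=0)
        assert imp.sum() == pytest.approx(100.0)
        assert imp.idxmax() == "l0"
        assert imp["l0"] > 60

    def test_constant_model_gets_zero_importance(self):
        pa = separable_pa(seed=12)

        class ConstPredictor:
            name = "const"

            def predict(self, X):
                return np.full(len(X), 0.5)

        imp = permutation_importance(ConstPredictor(), pa, n_reps=2, seed=0)
        assert (imp == 0).all()


class TestFitSpecies:
    def test_full_fit_surface_and_threshold(self, small_stack):
        from stacksdm.occurrences import PresenceAbsenceSet

        spec = small_stack.spec
        # presences where layer 'a' is highest, absences where lowest
        a = small_stack["a"].values
        order = np.argsort(a.ravel())
        pres = [divmod(int(i), spec.n_cols) for i in order[-5:]]
        abs_ = [divmod(int(i), spec.n_cols) for i in order[:5]]
        cells = pres + abs_
        rows = np.array([c[0] for c in cells])
        cols = np.array([c[1] for c in cells])
        pa = PresenceAbsenceSet(
            species="Testus species",
            presence_cells=pres,
            absence_cells=abs_,
            X=small_stack.extract(rows, cols),
            y=np.array([1] * 5 + [0] * 5),
            layer_names=small_stack.names,
        )
        fit = fit_species(pa, get_adapter("CTA"), small_stack, k=3, n_reps=2, seed=0)
        assert fit.suitability.shape == spec.shape
        assert np.isfinite(fit.suitability[spec.valid_mask]).all()
        assert 0 <= fit.threshold <= 1
        assert fit.binary.dtype == bool
        # binary map respects the threshold cellwise
        expect = fit.suitability >= fit.threshold
        np.testing.assert_array_equal(fit.binary[spec.valid_mask], expect[spec.valid_mask])
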