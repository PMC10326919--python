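"""Threshold classification, ROC/PR curves, and the residual logistic model."""

import numpy as np
import pytest

import easi
from conftest import make_record


def _scores(kp, kn, polarity="similarity"):
    values = list(kp) + list(kn)
    truth = ["known_positive"] * len(kp) + ["known_negative"] * len(kn)
    ids = tuple(f"s{i}" for i in range(len(values)))
    return easi.ScoreSet(ids=ids, truth=tuple(truth), scores=np.array(values), polarity=polarity)


def _mann_whitney_auc(kp, kn, polarity):
    """Brute-force pairwise ordering probability, ties counted 1/2."""
    sign = 1.0 if polarity == "similarity" else -1.0
    wins = 0.0
    for p in kp:
        for q in kn:
            if sign * p > sign * q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(kp) * len(kn))


class TestConfusion:
    def test_enumerated_threshold_096(self):
        s = _scores([0.99, 0.96], [0.95, 0.90])
        c = easi.confusion_at_threshold(s, 0.96)
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)

    def test_enumerated_threshold_097(self):
        s = _scores([0.99, 0.96], [0.95, 0.90])
        c = easi.confusion_at_threshold(s, 0.97)
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 2, 0, 1)

    def test_threshold_below_everything_predicts_all_positive(self):
        s = _scores([0.99, 0.96], [0.95, 0.90])
        c = easi.confusion_at_threshold(s, 0.0)
        assert c.fn == 0 and c.tn == 0
        assert c.total == 4

    def test_counts_always_sum_to_n(self):
        rng = np.random.default_rng(0)
        s = _scores(rng.uniform(0, 1, 13), rng.uniform(0, 1, 7))
        for t in np.linspace(-0.5, 1.5, 9):
            assert easi.confusion_at_threshold(s, t).total == 20

    def test_dissimilarity_polarity_calls_low_scores_positive(self):
        s = _scores([1.0, 2.0], [8.0, 9.0], polarity="dissimilarity")
        c = easi.confusion_at_threshold(s, 2.0)
        assert (c.tp, c.fp) == (2, 0)


class TestROC:
    def test_perfect_separation_has_auc_one(self):
        s = _scores([0.9, 0.95, 0.99], [0.1, 0.2, 0.3])
        assert easi.roc_curve(s).auc == 1.0

    def test_auc_equals_mann_whitney_with_ties(self):
        rng = np.random.default_rng(5)
        for trial in range(30):
            n_kp = int(rng.integers(1, 26))
            n_kn = int(rng.integers(1, 26))
            # coarse grid forces plenty of ties
            kp = rng.choice(np.linspace(0, 1, 6), n_kp)
            kn = rng.choice(np.linspace(0, 1, 6), n_kn)
            polarity = "similarity" if trial % 2 == 0 else "dissimilarity"
            s = _scores(kp, kn, polarity)
            assert easi.roc_curve(s).auc == pytest.approx(
                _mann_whitney_auc(kp, kn, polarity), abs=1e-12
            )

    def test_one_class_input_is_an_error(self):
        s = easi.ScoreSet(("a",), ("known_positive",), np.array([1.0]), "similarity")
        with pytest.raises(ValueError):
            easi.roc_curve(s)

    def test_polarity_flip_with_negated_scores_is_identical(self):
        rng = np.random.default_rng(9)
        kp, kn = rng.uniform(0, 1, 15), rng.uniform(0, 1, 10)
        r1 = easi.roc_curve(_scores(kp, kn, "similarity"))
        r2 = easi.roc_curve(_scores(-kp, -kn, "dissimilarity"))
        assert r1.auc == pytest.approx(r2.auc, abs=1e-12)
        assert [(p[1], p[2]) for p in r1.points] == [(p[1], p[2]) for p in r2.points]

    def test_monotone_fpr_and_unit_endpoints(self):
        rng = np.random.default_rng(3)
        s = _scores(rng.uniform(0, 1, 20), rng.uniform(0, 1, 20))
        roc = easi.roc_curve(s)
        fpr = [p[2] for p in roc.points]
        tpr = [p[1] for p in roc.points]
        assert fpr == sorted(fpr)
        assert (tpr[0], fpr[0]) == (0.0, 0.0)
        assert (tpr[-1], fpr[-1]) == (1.0, 1.0)


class TestPR:
    def test_perfect_separation_reaches_1_1(self):
        s = _scores([0.9, 0.95], [0.1, 0.2])
        points = easi.pr_curve(s).points
        assert any(r == 1.0 and p == 1.0 for _, r, p in points)

    def test_all_equal_scores_single_point_at_prevalence(self):
        s = _scores([0.5, 0.5, 0.5], [0.5])
        points = easi.pr_curve(s).points
        assert len(points) == 1
        _, recall, precision = points[0]
        assert recall == 1.0
        assert precision == pytest.approx(0.75)

    def test_matches_exhaustive_enumeration(self):
        kp, kn = [0.9, 0.7, 0.4], [0.8, 0.3]
        s = _scores(kp, kn)
        got = {t: (r, p) for t, r, p in easi.pr_curve(s).points}
        scores = sorted(set(kp + kn), reverse=True)
        for t in scores:
            tp = sum(v >= t for v in kp)
            fp = sum(v >= t for v in kn)
            assert got[t] == (pytest.approx(tp / 3), pytest.approx(tp / (tp + fp)))


class TestZeroFP:
    def test_similarity_midpoint_placement(self):
        s = _scores([0.96, 0.99], [0.90, 0.95])
        t, c = easi.zero_fp_threshold(s)
        assert 0.95 < t <= 0.96
        assert (c.tp, c.fp) == (2, 0)

    def test_overlap_extreme_gives_zero_tp(self):
        s = _scores([0.80, 0.85], [0.90, 0.95])  # max KN above max KP
        t, c = easi.zero_fp_threshold(s)
        assert c.fp == 0 and c.tp == 0

    def test_dissimilarity_mirrors(self):
        # MAR-style: positives small, negatives down to 5.75
        s = _scores([0.8, 1.9, 2.0], [5.75, 8.5, 11.2], polarity="dissimilarity")
        t, c = easi.zero_fp_threshold(s)
        assert 2.0 <= t < 5.75
        assert (c.tp, c.fp) == (3, 0)

    def test_permissive_maximal_over_observed_scores(self):
        rng = np.random.default_rng(21)
        s = _scores(rng.uniform(0.5, 1.0, 12), rng.uniform(0.0, 0.8, 12))
        t, c = easi.zero_fp_threshold(s)
        assert c.fp == 0
        # any observed score more permissive than t admits at least one FP
        for v in s.scores:
            if v < t:
                assert easi.confusion_at_threshold(s, v).fp >= 1


class TestResidualLogit:
    @staticmethod
    def _records(pos_resid, neg_resid, channels):
        recs = []
        for i, r in enumerate(pos_resid):
            recs.append(make_record(r, np.zeros(len(r)), spectrum_id=f"p{i}",
                                    truth="known_positive", channels=channels))
        for i, r in enumerate(neg_resid):
            recs.append(make_record(r, np.zeros(len(r)), spectrum_id=f"n{i}",
                                    truth="known_negative", channels=channels))
        return recs

    def test_single_shifted_channel_is_selected_and_separates(self):
        rng = np.random.default_rng(14)
        channels = (94, 96, 152, 155)
        pos = rng.normal(0, 0.5, (40, 4))
        neg = rng.normal(0, 0.5, (12, 4))
        neg[:, 0] += 8.0  # negatives shifted on channel 94 only
        recs = self._records(pos, neg, channels)
        model = easi.fit_residual_logit_stepwise(recs)
        assert model.selected == (94,)
        assert model.method == "ridge"  # complete separation forces the fallback
        assert all(easi.classify_logit(model, r)[1] == r.truth for r in recs)

    def test_identical_distributions_give_intercept_only(self):
        rng = np.random.default_rng(15)
        pos = rng.normal(0, 1, (40, 3))
        neg = rng.normal(0, 1, (40, 3))
        model = easi.fit_residual_logit_stepwise(self._records(pos, neg, (1, 2, 3)))
        assert model.selected == ()

    def test_boundary_probability_classifies_negative(self):
        model = easi.ResidualLogit(selected=(), intercept=0.0, coefficients={})
        rec = make_record(np.zeros(3), np.zeros(3), channels=(1, 2, 3))
        prob, label = easi.classify_logit(model, rec)
        assert prob == 0.5
        assert label == "known_negative"

    def test_monotonicity_in_a_positive_coefficient(self):
        model = easi.ResidualLogit(selected=(94,), intercept=-1.0, coefficients={94: 2.0})
        probs = []
        for v in (0.0, 1.0, 2.0):
            rec = make_record([v], [0.0], channels=(94,))
            probs.append(easi.classify_logit(model, rec)[0])
        assert probs == sorted(probs)

    def test_irls_matches_statsmodels_without_separation(self):
        """Dual-route check of the in-package logistic fitter."""
        sm = pytest.importorskip("statsmodels.api")
        from easi.classify import _logit_fit

        rng = np.random.default_rng(16)
        X = rng.normal(0, 1, (200, 2))
        eta = 0.5 + 1.2 * X[:, 0] - 0.8 * X[:, 1]
        y = (rng.uniform(0, 1, 200) < 1 / (1 + np.exp(-eta))).astype(float)
        beta, ll, converged = _logit_fit(X, y)
        assert converged
        oracle = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(beta, oracle.params, rtol=1e-6)
        assert ll == pytest.approx(oracle.llf, abs=1e-6)

    def test_missing_channel_is_an_error(self):
        model = easi.ResidualLogit(selected=(94,), intercept=0.0, coefficients={94: 1.0})
        rec = make_record([1.0], [0.0], channels=(55,))
        with pytest.raises(ValueError):
            easi.classify_logit(model, rec)

    def test_single_class_input_is_an_error(self):
        rng = np.random.default_rng(17)
        pos = rng.normal(0, 1, (10, 2))
        recs = self._records(pos, np.empty((0, 2)), (1, 2))
        with pytest.raises(ValueError):
            easi.fit_residual_logit_stepwise(recs)

    def test_held_out_generator_data_classified_correctly(self, spec, easi_model, panel):
        """Fit on one batch, verify >= 99% accuracy on a held-out batch."""
        def batch(seed):
            pos = easi.nominalize(easi.simulate_lab_shift(spec, 1.0, 40, seed=seed))
            neg = easi.nominalize(easi.simulate_negatives(spec, "diastereomer", 12, seed=seed + 1))
            m = easi.assemble_matrix(pos + neg, panel)
            return easi.predict_matrix(easi_model, m, "easi")

        model = easi.fit_residual_logit_stepwise(batch(201))
        held_out = batch(301)
        correct = sum(easi.classify_logit(model, r)[1] == r.truth for r in held_out)
        assert correct / len(held_out) >= 0.99
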