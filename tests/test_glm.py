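"""Stepwise fitting, EASI prediction, and model persistence."""

import numpy as np
import pandas as pd
import pytest

import easi
from easi.peakmodel import AbundanceMatrix, PeakPanel


def _matrix_from_array(arr, channels):
    df = pd.DataFrame(
        np.asarray(arr, dtype=float),
        index=pd.Index([f"r{i}" for i in range(len(arr))], name="spectrum_id"),
        columns=list(channels),
    )
    truth = pd.Series(["known_positive"] * len(df), index=df.index, name="truth")
    return AbundanceMatrix(df, truth, PeakPanel(tuple(channels)))


class TestStepwise:
    def test_exact_dependence_recovers_identity(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(10, 90, 40)
        z = rng.uniform(10, 90, 40)
        m = _matrix_from_array(np.column_stack([x, x, z]), (101, 102, 103))
        model = easi.fit_stepwise(m, target=101)
        assert set(model.coefficients) == {102}
        assert model.coefficients[102] == pytest.approx(1.0, abs=1e-9)
        assert model.intercept == pytest.approx(0.0, abs=1e-7)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_recovers_true_support_within_3se(self):
        """Oracle: statsmodels OLS on the true support."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(42)
        n = 128
        x1 = rng.normal(50, 10, n)
        x2 = rng.normal(60, 8, n)
        noise_cols = rng.normal(40, 5, (n, 4))
        y = 50 + 0.8 * x1 - 0.3 * x2 + rng.normal(0, 0.5, n)
        m = _matrix_from_array(
            np.column_stack([y, x1, x2, noise_cols]), (100, 101, 102, 103, 104, 105, 106)
        )
        model = easi.fit_stepwise(m, target=100)
        assert {101, 102} <= set(model.coefficients)
        oracle = sm.OLS(y, sm.add_constant(np.column_stack([x1, x2]))).fit()
        se = oracle.bse
        assert abs(model.coefficients[101] - 0.8) < 3 * se[1]
        assert abs(model.coefficients[102] - (-0.3)) < 3 * se[2]
        assert model.r_squared > 0.99

    def test_final_coefficients_match_statsmodels_on_selected_support(self, train_matrix):
        sm = pytest.importorskip("statsmodels.api")
        target = train_matrix.panel.channels[1]
        model = easi.fit_stepwise(train_matrix, target)
        assert model.coefficients  # something was selected
        y = train_matrix.values[target].to_numpy()
        X = train_matrix.values[list(model.coefficients)].to_numpy()
        oracle = sm.OLS(y, sm.add_constant(X)).fit()
        assert model.intercept == pytest.approx(oracle.params[0], rel=1e-8)
        np.testing.assert_allclose(
            list(model.coefficients.values()), oracle.params[1:], rtol=1e-8
        )
        assert model.r_squared == pytest.approx(oracle.rsquared, abs=1e-10)

    def test_null_false_entry_rate_single_candidate(self):
        """Under H0 the partial-F p-value is uniform: with one candidate the
        model stays empty in ~95% of runs at p_enter = 0.05."""
        rng = np.random.default_rng(7)
        empty = 0
        runs = 400
        for _ in range(runs):
            y = rng.normal(50, 5, 30)
            x = rng.normal(50, 5, 30)
            m = _matrix_from_array(np.column_stack([y, x]), (100, 101))
            model = easi.fit_stepwise(m, target=100, candidates=[101])
            empty += not model.coefficients
        assert 0.90 < empty / runs < 0.99

    def test_zero_variance_target_gives_constant_model(self):
        rng = np.random.default_rng(1)
        m = _matrix_from_array(
            np.column_stack([np.full(20, 100.0), rng.uniform(0, 50, 20)]), (82, 94)
        )
        model = easi.fit_stepwise(m, target=82)
        assert model.coefficients == {}
        assert model.intercept == 100.0
        assert model.r_squared == 0.0

    def test_too_few_rows_is_an_error(self):
        m = _matrix_from_array([[1.0, 2.0], [3.0, 4.0]], (100, 101))
        with pytest.raises(ValueError):
            easi.fit_stepwise(m, target=100)

    def test_noise_covariates_do_not_hurt_training_r2(self):
        """Selected model explains at least as much as the true-support OLS
        fit, minus numerical tolerance (guards against under-selection)."""
        rng = np.random.default_rng(5)
        n = 128
        x1 = rng.normal(50, 10, n)
        y = 10 + 0.5 * x1 + rng.normal(0, 0.5, n)
        noise = rng.normal(50, 5, (n, 8))
        m = _matrix_from_array(
            np.column_stack([y, x1, noise]), tuple(range(100, 110))
        )
        model = easi.fit_stepwise(m, target=100)
        coef = np.polyfit(x1, y, 1)
        resid = y - np.polyval(coef, x1)
        r2_true = 1 - resid.var() / y.var()
        assert model.r_squared >= r2_true - 1e-6


class TestEASIFit:
    def test_most_models_explain_over_90pct(self, easi_model):
        r2 = [m.r_squared for m in easi_model.ion_models.values()]
        assert np.median(r2) > 0.9
        assert sum(r > 0.9 for r in r2) >= 15  # most of the 20 panel ions

    def test_one_model_per_channel(self, easi_model, panel):
        assert set(easi_model.ion_models) == set(panel.channels)

    def test_minimal_two_channel_panel(self):
        rng = np.random.default_rng(2)
        e = rng.normal(0, 1, 50)
        a = 50 + 5 * e + rng.normal(0, 0.1, 50)
        b = 30 + 3 * e + rng.normal(0, 0.1, 50)
        m = _matrix_from_array(np.column_stack([a, b]), (100, 101))
        model = easi.fit_easi(m)
        assert set(model.ion_models[100].coefficients) == {101}
        assert set(model.ion_models[101].coefficients) == {100}

    def test_identical_spectra_yield_constant_models(self):
        m = _matrix_from_array(np.tile([100.0, 40.0, 10.0], (5, 1)), (82, 94, 96))
        model = easi.fit_easi(m)
        for ion in model.ion_models.values():
            assert ion.coefficients == {}
            assert ion.r_squared == 0.0

    def test_in_sample_residual_mean_is_zero(self, easi_model, train_matrix):
        records = easi.predict_matrix(easi_model, train_matrix, "easi")
        resid = np.array([r.residuals for r in records])
        np.testing.assert_allclose(resid.mean(axis=0), 0.0, atol=1e-8)


class TestPredict:
    def test_mean_query_reproduces_consensus(self, easi_model):
        """Regression hyperplanes pass through the sample means."""
        rec = easi.predict(easi_model, easi_model.consensus.mean, "easi")
        np.testing.assert_allclose(rec.predicted, easi_model.consensus.mean, atol=1e-8)

    def test_consensus_prediction_ignores_the_query(self, easi_model, train_matrix):
        r1 = easi.predict(easi_model, train_matrix.row(train_matrix.ids[0]), "consensus")
        r2 = easi.predict(easi_model, train_matrix.row(train_matrix.ids[-1]), "consensus")
        np.testing.assert_array_equal(r1.predicted, r2.predicted)
        np.testing.assert_array_equal(r1.predicted, easi_model.consensus.mean)

    def test_predictions_are_not_clipped(self, easi_model):
        """A wildly non-matching query must be allowed to predict outside
        [0, 100] — that is how negatives reveal themselves."""
        k = len(easi_model.panel)
        query = np.zeros(k)
        query[0] = 100.0  # base peak only, everything else absent
        rec = easi.predict(easi_model, query, "easi")
        assert rec.predicted.min() < 0 or rec.predicted.max() > 100

    def test_constant_channel_predicts_the_training_constant(self, easi_model):
        base = easi_model.panel.channels[0]  # base peak, constant 100
        i = easi_model.panel.index_of(base)
        rng = np.random.default_rng(0)
        for _ in range(3):
            rec = easi.predict(easi_model, rng.uniform(0, 60, len(easi_model.panel)), "easi")
            assert rec.predicted[i] == pytest.approx(100.0)

    def test_panel_mismatch_is_an_error(self, easi_model):
        with pytest.raises(ValueError):
            easi.predict(easi_model, np.zeros(3), "easi")

    def test_easi_beats_consensus_on_shifted_queries(self, spec, easi_model, panel):
        shifted = easi.nominalize(easi.simulate_lab_shift(spec, 2.0, 20, seed=77))
        q = easi.assemble_matrix(shifted, panel)
        mar_e = np.mean([easi.mar(r) for r in easi.predict_matrix(easi_model, q, "easi")])
        mar_c = np.mean([easi.mar(r) for r in easi.predict_matrix(easi_model, q, "consensus")])
        assert mar_e < mar_c


class TestPersistence:
    def test_json_round_trip(self, tmp_path, easi_model, cov_model, train_matrix):
        full = easi.EASIModel(
            panel=easi_model.panel,
            ion_models=easi_model.ion_models,
            consensus=easi_model.consensus,
            settings=easi_model.settings,
            training_hash=easi_model.training_hash,
            covariance=cov_model,
        )
        path = tmp_path / "model.json"
        easi.save_model(full, path)
        back = easi.load_model(path)
        assert back.panel.channels == easi_model.panel.channels
        assert back.training_hash == easi_model.training_hash
        for c in easi_model.panel.channels:
            a, b = easi_model.ion_models[c], back.ion_models[c]
            assert a.intercept == b.intercept
            assert a.coefficients == b.coefficients
            assert a.r_squared == b.r_squared
        np.testing.assert_array_equal(back.consensus.mean, easi_model.consensus.mean)
        np.testing.assert_array_equal(back.covariance.covariance, cov_model.covariance)
        # identical predictions after the round trip
        row = train_matrix.row(train_matrix.ids[0])
        np.testing.assert_array_equal(
            easi.predict(full, row, "easi").predicted,
            easi.predict(back, row, "easi").predicted,
        )
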