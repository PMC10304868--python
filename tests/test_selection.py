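import numpy as np
import pandas as pd
import pytest

from gaitgrip.selection import (
    IPA_COLUMNS,
    LabelMatrix,
    NoModelError,
    PredictorTable,
    comparison_models,
    label_threshold,
    lasso_fit,
    loso_lasso,
    make_lambda_path,
    select_optimal_model,
)
from conftest import lasso_qp_oracle, make_planted_table


def _standardized_instance(rng, n=30, p=5):
    x = rng.normal(size=(n, p))
    x = (x - x.mean(0)) / x.std(0)
    beta = rng.normal(size=p)
    y = x @ beta + rng.normal(0, 0.5, size=n)
    return x, y


class TestLassoFit:
    def test_zero_penalty_is_ols(self, rng):
        x, y = _standardized_instance(rng)
        beta, b0 = lasso_fit(x, y, 0.0)
        xa = np.column_stack([np.ones(len(y)), x])
        sol, *_ = np.linalg.lstsq(xa, y, rcond=None)
        np.testing.assert_allclose(beta, sol[1:], atol=1e-8)
        assert b0 == pytest.approx(sol[0], abs=1e-8)

    def test_above_lambda_max_all_zero(self, rng):
        x, y = _standardized_instance(rng)
        lam_max = np.max(np.abs(x.T @ (y - y.mean()))) / len(y)
        beta, b0 = lasso_fit(x, y, lam_max * 1.0001)
        np.testing.assert_allclose(beta, 0.0, atol=1e-12)
        assert b0 == pytest.approx(y.mean())

    def test_matches_qp_oracle(self, rng):
        for _ in range(10):
            x, y = _standardized_instance(rng)
            lam = float(rng.uniform(0.01, 0.5))
            beta, b0 = lasso_fit(x, y, lam)
            beta_o, b0_o = lasso_qp_oracle(x, y, lam)
            np.testing.assert_allclose(beta, beta_o, atol=1e-4)
            assert b0 == pytest.approx(b0_o, abs=1e-4)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            lasso_fit(np.array([[np.inf, 0.0]]), np.array([1.0]), 0.1)


class TestLambdaPath:
    def test_length_and_geometry(self, rng):
        x, y = _standardized_instance(rng)
        lams = make_lambda_path(x, y)
        assert len(lams) == 100
        ratios = lams[1:] / lams[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-10)
        assert (np.diff(lams) < 0).all()
        assert lams[-1] == pytest.approx(lams[0] * 1e-4)

    def test_first_lambda_zeroes_everything(self, rng):
        x, y = _standardized_instance(rng)
        lams = make_lambda_path(x, y)
        beta, _ = lasso_fit(x, y, lams[0] * (1 + 1e-9))
        np.testing.assert_allclose(beta, 0.0, atol=1e-10)

    def test_selected_count_monotone(self, rng):
        x, y = _standardized_instance(rng, n=60, p=8)
        lams = make_lambda_path(x, y)
        counts = [int(np.sum(np.abs(lasso_fit(x, y, l)[0]) > 1e-12))
                  for l in lams[::10]]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_degenerate_matrix(self):
        with pytest.raises(ValueError):
            make_lambda_path(np.ones((10, 3)), np.arange(10.0))


class TestLabelThreshold:
    def test_printed_values(self):
        assert label_threshold(27) == 25
        assert label_threshold(35) == 33


class TestLosoLasso:
    def test_label_matrix_shapes_and_bounds(self):
        table, _ = make_planted_table(n_subjects=12, n_trials=2, n_noise=6,
                                      seed=1)
        label = loso_lasso(table)
        u, c = 12, 9
        assert label.b_u.shape == (u, c, 100)
        assert label.b0.min() >= 0 and label.b0.max() <= u
        assert label.threshold == label_threshold(u)
        np.testing.assert_array_equal(
            label.b, (label.b0 >= label.threshold).astype(np.int8))

    def test_perfect_predictor_always_selected(self):
        rng = np.random.default_rng(3)
        n_subj = 12
        y = rng.normal(30, 7, size=n_subj)
        rows = []
        for i in range(n_subj):
            for t in range(2):
                rows.append({"subject_id": f"S{i}", "hgs_kg": y[i],
                             "exact": y[i],
                             "n1": rng.normal(), "n2": rng.normal()})
        table = PredictorTable(frame=pd.DataFrame(rows),
                               predictors=("exact", "n1", "n2"))
        label = loso_lasso(table)
        i_exact = table.predictors.index("exact")
        assert label.b[i_exact, -1] == 1  # present at the smallest lambda

    def test_too_few_subjects(self):
        table, _ = make_planted_table(n_subjects=12, n_trials=1, seed=2)
        small = PredictorTable(
            frame=table.frame[table.frame.subject_id < "S005"],
            predictors=table.predictors)
        with pytest.raises(ValueError, match="10 subjects"):
            loso_lasso(small)


class TestModelSelection:
    def test_planted_recovery_and_icc(self):
        table, planted = make_planted_table(n_subjects=20, n_trials=4,
                                            n_noise=15, seed=4,
                                            noise_sd=0.2)
        label = loso_lasso(table)
        best = select_optimal_model(table, label)
        assert set(planted) <= set(best.support)
        assert best.icc21 > 0.95

    def test_all_noise_poor(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(25):
            y = rng.normal(30, 7)
            for t in range(4):
                rows.append({"subject_id": f"S{i:02d}", "hgs_kg": y,
                             **{f"p{j}": rng.normal() for j in range(10)}})
        table = PredictorTable(frame=pd.DataFrame(rows),
                               predictors=tuple(f"p{j}" for j in range(10)))
        label = loso_lasso(table)
        try:
            best = select_optimal_model(table, label)
        except NoModelError:
            return  # nothing survived the 95% vote: equally a null outcome
        assert best.icc21 < 0.4
        assert best.icc_band == "poor"

    def test_duplicate_supports_evaluated_once(self, monkeypatch):
        import gaitgrip.selection as sel

        table, _ = make_planted_table(n_subjects=12, n_trials=2, n_noise=5,
                                      seed=6)
        label = loso_lasso(table)
        calls = []
        original = sel._evaluate_support

        def spy(tbl, support, i):
            calls.append(support)
            return original(tbl, support, i)

        monkeypatch.setattr(sel, "_evaluate_support", spy)
        select_optimal_model(table, label)
        assert len(calls) == len(set(calls))

    def test_empty_label_matrix_raises(self):
        table, _ = make_planted_table(n_subjects=12, n_trials=1, seed=7)
        c = len(table.predictors)
        label = LabelMatrix(
            b_u=np.zeros((12, c, 100), dtype=np.int8),
            b0=np.zeros((c, 100), dtype=int),
            b=np.zeros((c, 100), dtype=np.int8),
            threshold=11, lambdas=np.geomspace(1, 1e-4, 100),
            predictors=table.predictors)
        with pytest.raises(NoModelError):
            select_optimal_model(table, label)

    def test_losocv_honesty_poisoning(self):
        from gaitgrip.selection import _losocv_predictions

        table, planted = make_planted_table(n_subjects=12, n_trials=2,
                                            n_noise=4, seed=8)
        support = tuple(planted)
        sid = table.subjects[0]
        mask = (table.frame["subject_id"] == sid).to_numpy()
        preds = _losocv_predictions(table, support)

        poisoned = table.frame.copy()
        poisoned.loc[mask, "hgs_kg"] += 100.0
        table_p = PredictorTable(frame=poisoned,
                                 predictors=table.predictors)
        preds_p = _losocv_predictions(table_p, support)
        np.testing.assert_allclose(preds[mask], preds_p[mask], atol=1e-8)
        # other subjects' predictions must of course change
        assert not np.allclose(preds[~mask], preds_p[~mask])

    def test_final_coefficients_are_full_data_refit(self):
        table, _ = make_planted_table(n_subjects=15, n_trials=2, n_noise=5,
                                      seed=9)
        label = loso_lasso(table)
        best = select_optimal_model(table, label)
        x, y = table.xy(predictors=best.support)
        xa = np.column_stack([np.ones(len(y)), x])
        sol, *_ = np.linalg.lstsq(xa, y, rcond=None)
        np.testing.assert_allclose(best.coefficients, sol[1:], atol=1e-8)
        assert best.intercept == pytest.approx(sol[0], abs=1e-8)


@pytest.fixture(scope="module")
def pool_table():
    """Table with signal living only in the waveform-style predictors."""
    rng = np.random.default_rng(10)
    n_subj = 20
    gp_cols = tuple(f"gp{i:02d}" for i in range(1, 21))
    ims_cols = ("C_1", "C_2", "C_3")
    rows = []
    for i in range(n_subj):
        ims = rng.normal(size=3)
        y = 30 + 7 * (ims.sum() / np.sqrt(3)) + rng.normal(0, 0.5)
        base = {c: rng.normal() for c in gp_cols}
        base.update({c: rng.normal() for c in IPA_COLUMNS})
        for t in range(4):
            row = {"subject_id": f"S{i:02d}", "hgs_kg": y}
            row.update({k: v + rng.normal(0, 0.05)
                        for k, v in base.items()})
            row.update({c: v + rng.normal(0, 0.05)
                        for c, v in zip(ims_cols, ims)})
            rows.append(row)
    preds = gp_cols + IPA_COLUMNS + ims_cols
    return (PredictorTable(frame=pd.DataFrame(rows), predictors=preds),
            gp_cols, ims_cols)

class TestComparisonModels:
    def test_pool_sizes_and_ordering(self, pool_table):
        table, gp_cols, ims_cols = pool_table
        models = comparison_models(table, gp_columns=gp_cols,
                                   ims_columns=ims_cols)
        assert set(models) == {"M1", "M2", "M3", "Mo"}
        assert len(models["M1"].support) <= 1
        assert models["Mo"].icc21 > models["M3"].icc21
        assert models["Mo"].icc21 > models["M1"].icc21
        assert models["Mo"].icc21 > 0.9

    def test_m3_pool_size(self):
        gp_cols = tuple(f"gp{i:02d}" for i in range(1, 21))
        assert len(gp_cols + IPA_COLUMNS) == 24


class TestPredictorTable:
    def test_unbalanced_subjects_rejected(self):
        df = pd.DataFrame({"subject_id": ["a", "a", "b"],
                           "hgs_kg": [1.0, 2.0, 3.0],
                           "p": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="same number"):
            PredictorTable(frame=df, predictors=("p",))

    def test_missing_values_rejected(self):
        df = pd.DataFrame({"subject_id": ["a", "b"],
                           "hgs_kg": [1.0, np.nan], "p": [0.1, 0.2]})
        with pytest.raises(ValueError, match="missing"):
            PredictorTable(frame=df, predictors=("p",))
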