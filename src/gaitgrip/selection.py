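"""Leave-one-subject-out LASSO feature selection and model choice.

For each left-out subject a 100-point geometric regularization path is run
and the supports are binarized into a label matrix B_u (predictors x
lambdas).  Summing over subjects gives the counter B_0; entries reaching
floor(0.95 U) survive into the final label matrix B.  Each lambda column of
B defines a candidate predictor subset; candidates are fitted by ordinary
least squares, scored by leave-one-subject-out cross-validated ICC(2,1),
and the best one is the optimal model.  Predictors are standardized inside
every LASSO fit (the objective is scale-sensitive and the pools mix units)
and coefficients are back-transformed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, lasso_path

from .agreement import icc, interpret_icc

__all__ = [
    "PredictorTable",
    "LabelMatrix",
    "CandidateModel",
    "NoModelError",
    "IPA_COLUMNS",
    "lasso_fit",
    "make_lambda_path",
    "loso_lasso",
    "select_optimal_model",
    "comparison_models",
    "label_threshold",
]

IPA_COLUMNS = ("age", "height_cm", "weight_kg", "bmi")

N_LAMBDA = 100
LAMBDA_DYNAMIC_RANGE = 1e-4


class NoModelError(ValueError):
    """All candidate predictor subsets are empty."""


@dataclass(frozen=True)
class PredictorTable:
    """Datasets x predictors with subject grouping and an HGS target."""

    frame: pd.DataFrame
    predictors: tuple
    target: str = "hgs_kg"
    subject_col: str = "subject_id"

    def __post_init__(self) -> None:
        cols = [self.subject_col, self.target, *self.predictors]
        missing = [c for c in cols if c not in self.frame.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        sub = self.frame[cols]
        if sub.isna().any().any():
            raise ValueError("predictor table contains missing values")
        counts = self.frame[self.subject_col].value_counts()
        if counts.nunique() > 1:
            raise ValueError("every subject must contribute the same number "
                             f"of rows; got counts {sorted(set(counts))}")

    @property
    def subjects(self) -> list:
        return list(dict.fromkeys(self.frame[self.subject_col]))

    def xy(self, rows: np.ndarray | None = None,
           predictors: tuple | None = None) -> tuple[np.ndarray, np.ndarray]:
        df = self.frame if rows is None else self.frame.loc[rows]
        preds = self.predictors if predictors is None else predictors
        return (df[list(preds)].to_numpy(dtype=float),
                df[self.target].to_numpy(dtype=float))


@dataclass(frozen=True)
class LabelMatrix:
    """Per-fold supports B_u, their sum B_0 and the thresholded B."""

    b_u: np.ndarray        # (U, C, 100) binary
    b0: np.ndarray         # (C, 100) integer counts
    b: np.ndarray          # (C, 100) binary
    threshold: int
    lambdas: np.ndarray    # (100,) decreasing
    predictors: tuple


@dataclass(frozen=True)
class CandidateModel:
    support: tuple                  # predictor names
    lambda_index: int
    coefficients: np.ndarray        # aligned with support, full-data refit
    intercept: float
    predictions: np.ndarray         # LOSOCV predictions, row order of table
    icc21: float
    mae: float
    adj_r2: float
    icc_band: str = field(default="")


def label_threshold(n_subjects: int, fraction: float = 0.95) -> int:
    """Count threshold floor(fraction * U) for the final label matrix."""
    return math.floor(fraction * n_subjects)


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd_safe, mu, sd_safe


def lasso_fit(x: np.ndarray, y: np.ndarray, lam: float,
              tol: float = 1e-10) -> tuple[np.ndarray, float]:
    """Solve min (1/2N) sum (y_k - b0 - x_k'b)^2 + lam * ||b||_1.

    Predictors are standardized internally and the coefficients are
    returned on the original scale.  ``lam = 0`` reduces to ordinary least
    squares.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    xs, mu, sd = _standardize(x)
    if lam == 0:
        xa = np.column_stack([np.ones(len(y)), xs])
        sol, *_ = np.linalg.lstsq(xa, y, rcond=None)
        b0_s, beta_s = sol[0], sol[1:]
    else:
        model = Lasso(alpha=lam, fit_intercept=True, tol=tol, max_iter=500000)
        model.fit(xs, y)
        beta_s, b0_s = model.coef_, model.intercept_
    beta = beta_s / sd
    return beta, float(b0_s - beta @ mu)


def make_lambda_path(x: np.ndarray, y: np.ndarray,
                     n: int = N_LAMBDA,
                     dynamic_range: float = LAMBDA_DYNAMIC_RANGE) -> np.ndarray:
    """Decreasing geometric path; lambda_1 just zeroes all coefficients.

    lambda_1 = max_j |x_j'(y - ybar)| / N on standardized predictors,
    lambda_n = lambda_1 * dynamic_range.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xs, _, sd = _standardize(x)
    if np.all(x.std(axis=0) == 0):
        raise ValueError("degenerate predictor matrix: all columns constant")
    lam_max = float(np.max(np.abs(xs.T @ (y - y.mean()))) / len(y))
    if lam_max <= 0:
        raise ValueError("target has no correlation with any predictor")
    return np.geomspace(lam_max, lam_max * dynamic_range, n)


def loso_lasso(table: PredictorTable,
               lambdas: np.ndarray | None = None) -> LabelMatrix:
    """Leave-one-subject-out LASSO supports aggregated into label matrices."""
    subjects = table.subjects
    u = len(subjects)
    if u < 10:
        raise ValueError(f"need at least 10 subjects; got {u}")
    x_full, y_full = table.xy()
    if lambdas is None:
        lambdas = make_lambda_path(x_full, y_full)
    c = len(table.predictors)
    b_u = np.zeros((u, c, len(lambdas)), dtype=np.int8)
    subj_ids = table.frame[table.subject_col].to_numpy()
    for k, sid in enumerate(subjects):
        keep = subj_ids != sid
        x, y = x_full[keep], y_full[keep]
        xs, _, _ = _standardize(x)
        # lasso_path solves the same (1/2N) objective on the centered data
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            _, coefs, _ = lasso_path(xs, y - y.mean(), alphas=lambdas,
                                     tol=1e-7, max_iter=20000)
        b_u[k] = (np.abs(coefs) > 0).astype(np.int8)
    b0 = b_u.sum(axis=0)
    thr = label_threshold(u)
    return LabelMatrix(b_u=b_u, b0=b0, b=(b0 >= thr).astype(np.int8),
                       threshold=thr, lambdas=np.asarray(lambdas),
                       predictors=table.predictors)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    xa = np.column_stack([np.ones(len(y)), x])
    sol, *_ = np.linalg.lstsq(xa, y, rcond=None)
    return sol[1:], float(sol[0])


def _losocv_predictions(table: PredictorTable, support: tuple) -> np.ndarray:
    subj_ids = table.frame[table.subject_col].to_numpy()
    preds = np.empty(len(table.frame))
    for sid in table.subjects:
        hold = subj_ids == sid
        if support:
            x, y = table.xy(predictors=support)
            beta, b0 = _ols(x[~hold], y[~hold])
            preds[hold] = x[hold] @ beta + b0
        else:
            _, y = table.xy(predictors=())
            preds[hold] = y[~hold].mean()
    return preds


def _evaluate_support(table: PredictorTable, support: tuple,
                      lambda_index: int) -> CandidateModel:
    x, y = table.xy(predictors=support)
    preds = _losocv_predictions(table, support)
    icc21 = icc(y, preds, form="(2,1)")
    mae = float(np.mean(np.abs(preds - y)))
    if support:
        beta, b0 = _ols(x, y)
        fitted = x @ beta + b0
        n, p = len(y), len(support)
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n - p - 1 > 0 else np.nan
    else:
        beta, b0 = np.zeros(0), float(y.mean())
        adj_r2 = 0.0
    return CandidateModel(support=support, lambda_index=lambda_index,
                          coefficients=beta, intercept=b0, predictions=preds,
                          icc21=icc21, mae=mae, adj_r2=float(adj_r2),
                          icc_band=interpret_icc(icc21))


def select_optimal_model(table: PredictorTable,
                         label: LabelMatrix) -> CandidateModel:
    """Best candidate by LOSOCV ICC(2,1); ties break toward parsimony.

    Every lambda column of B defines a candidate subset; duplicates are
    evaluated once and share results.  Raises :class:`NoModelError` when
    all 100 subsets are empty.
    """
    names = np.asarray(label.predictors)
    supports = []
    for i in range(label.b.shape[1]):
        supports.append(tuple(str(n) for n in names[label.b[:, i] == 1]))
    if all(len(s) == 0 for s in supports):
        raise NoModelError("LOSO-LASSO selected no predictors at any lambda")
    cache: dict[tuple, CandidateModel] = {}
    best: CandidateModel | None = None
    best_key = None
    for i, support in enumerate(supports):
        if support not in cache:
            cache[support] = _evaluate_support(table, support, i)
        cand = cache[support]
        key = (cand.icc21, -len(support), -i)
        if best_key is None or key > best_key:
            best_key = key
            best = replace(cand, lambda_index=i)
    return best


def run_selection(table: PredictorTable) -> tuple[CandidateModel, LabelMatrix]:
    label = loso_lasso(table)
    return select_optimal_model(table, label), label


def comparison_models(table: PredictorTable,
                      gp_columns: tuple,
                      ims_columns: tuple) -> dict[str, CandidateModel]:
    """The four nested predictor pools, each put through the same pipeline.

    M1: gait speed only (GP02); M2: all gait parameters; M3: M2 plus the
    individual physical attributes; Mo: M3 plus the waveform predictors.
    """
    pools = {
        "M1": ("gp02",),
        "M2": tuple(gp_columns),
        "M3": tuple(gp_columns) + tuple(IPA_COLUMNS),
        "Mo": tuple(gp_columns) + tuple(IPA_COLUMNS) + tuple(ims_columns),
    }
    out = {}
    for name, pool in pools.items():
        sub = PredictorTable(frame=table.frame, predictors=pool,
                             target=table.target,
                             subject_col=table.subject_col)
        try:
            model, _ = run_selection(sub)
        except NoModelError:
            model = _evaluate_support(sub, (), -1)
        out[name] = model
    return out
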