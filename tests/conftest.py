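"""Shared fixtures and independent test oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import minimize

from gaitgrip.selection import PredictorTable
from gaitgrip.synthetic import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def male_cohort_27():
    """Strong-signal 27-subject, 4-trial male cohort plus its ground truth."""
    spec = CohortSpec(
        n_subjects=27, sex="male", n_trials=4, seed=11,
        planted_windows=(("Gz", (12, 16)), ("Gy", (50, 55)), ("Ez", (93, 97))),
        effect_sizes=(0.4, 0.4, 0.25),
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def male_frame_27(male_cohort_27):
    from gaitgrip.strides import process_cohort

    cohort, _ = male_cohort_27
    frame, prov = process_cohort(cohort)
    return frame, prov


def smooth_null_fields(rng, n, p, q, fwhm):
    """Stationary smooth unit-variance Gaussian fields (n, p, q)."""
    x = rng.normal(size=(n, p, q))
    x = gaussian_filter1d(x, fwhm / 2.355, axis=-1, mode="wrap")
    return x / x.std()


def make_planted_table(n_subjects=35, n_trials=4, n_noise=27, seed=0,
                       effects=(1.0, 1.0, 1.0), noise_sd=0.5,
                       y_sd=7.0) -> tuple[PredictorTable, list[str]]:
    """Predictor table whose target is linear in three planted columns.

    Planted predictors have unit SD at the subject level, so an effect of
    e contributes e kg per SD; remaining columns are pure noise.  Rows
    within a subject share the subject-level predictor values plus small
    trial-level jitter.
    """
    rng = np.random.default_rng(seed)
    n_planted = len(effects)
    c = n_planted + n_noise
    subj_x = rng.normal(size=(n_subjects, c))
    y_subj = subj_x[:, :n_planted] @ np.asarray(effects) \
        + rng.normal(0, noise_sd, size=n_subjects)
    y_subj = 30.0 + y_sd * y_subj / y_subj.std()
    rows = []
    for i in range(n_subjects):
        for t in range(n_trials):
            x = subj_x[i] + rng.normal(0, 0.1, size=c)
            rows.append({"subject_id": f"S{i:03d}", "hgs_kg": y_subj[i],
                         **{f"p{j:02d}": x[j] for j in range(c)}})
    frame = pd.DataFrame(rows)
    predictors = tuple(f"p{j:02d}" for j in range(c))
    planted = [f"p{j:02d}" for j in range(n_planted)]
    return PredictorTable(frame=frame, predictors=predictors), planted


def lasso_qp_oracle(x, y, lam, tol=1e-12):
    """Brute-force solver of (1/2N)||y - b0 - Xb||^2 + lam ||b||_1.

    Independent of the package path: splits b = b+ - b- and solves the
    smooth bound-constrained program with L-BFGS-B.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = x.shape

    def fg(z):
        bp, bm, b0 = z[:p], z[p:2 * p], z[-1]
        b = bp - bm
        r = y - b0 - x @ b
        f = 0.5 * np.mean(r ** 2) + lam * (bp.sum() + bm.sum())
        gb = -(x.T @ r) / n
        g = np.concatenate([gb + lam, -gb + lam, [-r.mean()]])
        return f, g

    z0 = np.zeros(2 * p + 1)
    z0[-1] = y.mean()
    bounds = [(0, None)] * (2 * p) + [(None, None)]
    res = minimize(fg, z0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 20000, "ftol": tol, "gtol": 1e-12})
    bp, bm, b0 = res.x[:p], res.x[p:2 * p], res.x[-1]
    return bp - bm, float(b0)
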