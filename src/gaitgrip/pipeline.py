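"""End-to-end study replica on synthetic cohorts.

Three stages mirror the study design: construction (cohort -> stride
processing -> SPM predictor discovery -> LOSO-LASSO model selection with
comparison pools), Test 1 (agreement of the trained model on a fresh
cohort: Bland-Altman plus K_A bounds), and Test 2 (frailty risk scores from
estimated vs true values, against a synthetic expert rater panel).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement, frailty, selection, spm, strides, synthetic

__all__ = [
    "RunConfig",
    "ModelBundle",
    "ConstructionResult",
    "PredictorMismatchError",
    "run_construction",
    "run_test1",
    "run_test2",
    "run_all",
    "build_predictor_table",
    "save_construction",
    "load_model",
]


class PredictorMismatchError(ValueError):
    """Trained model predictors are not available on the supplied cohort."""


#: default planted dependence used by the strong-signal demo configuration
DEFAULT_PLANTED = (("Gz", (12, 16)), ("Gy", (50, 55)), ("Ez", (93, 97)))
DEFAULT_EFFECTS = (0.4, 0.4, 0.25)


@dataclass(frozen=True)
class RunConfig:
    """Run configuration; normally loaded from YAML."""

    seed: int = 0
    alpha: float = 0.05
    out_dir: str = "results/run"
    cohort: dict = field(default_factory=dict)
    test_cohort: dict = field(default_factory=dict)
    expert: dict = field(default_factory=lambda: {
        "n_raters": 6, "noise_sd": 10.0, "bias_sd": 5.0})
    qt_windows: tuple = spm.QT_WINDOWS

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "qt_windows" in d:
            d["qt_windows"] = tuple(tuple(w) for w in d["qt_windows"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps({
            "seed": self.seed, "alpha": self.alpha, "cohort": self.cohort,
            "test_cohort": self.test_cohort, "expert": self.expert,
            "qt_windows": [list(w) for w in self.qt_windows],
        }, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def cohort_spec(self, which: str = "cohort") -> synthetic.CohortSpec:
        base = {
            "n_subjects": 27, "sex": "male", "n_trials": 4,
            "strides_per_trial": 12,
            "planted_windows": DEFAULT_PLANTED,
            "effect_sizes": DEFAULT_EFFECTS,
        }
        override = dict(self.cohort if which == "cohort" else
                        {**self.cohort, "n_subjects": 12, **self.test_cohort})
        base.update(override)
        if "planted_windows" in base:
            base["planted_windows"] = tuple(
                (ch, tuple(w)) for ch, w in base["planted_windows"])
        if "effect_sizes" in base:
            base["effect_sizes"] = tuple(base["effect_sizes"])
        # seeds derive from the single master seed, offset per stage
        base.setdefault("seed", self.seed if which == "cohort"
                        else self.seed + 7919)
        return synthetic.CohortSpec(**base)


@dataclass
class ModelBundle:
    """Everything needed to apply a trained model to a new cohort."""

    sex: str
    support: tuple
    coefficients: np.ndarray
    intercept: float
    ims_defs: list
    train_residuals: np.ndarray     # LOSOCV estimate - reference, per row
    train_gs_residuals: np.ndarray  # measured - reference gait speed, per row
    icc21: float
    mae: float
    adj_r2: float


@dataclass
class ConstructionResult:
    cohort: synthetic.Cohort
    ground_truth: synthetic.GroundTruth
    table: selection.PredictorTable
    ims_defs: list
    spm_detail: dict
    models: dict                   # pool name -> CandidateModel
    label: selection.LabelMatrix
    bundle: ModelBundle
    provenance: dict


def add_ims_columns(frame: pd.DataFrame, ims_defs: list) -> tuple[pd.DataFrame, tuple]:
    """Evaluate each waveform predictor on every trial-average row."""
    frame = frame.copy()
    names = []
    grids = frame[strides.grid_columns()].to_numpy().reshape(
        len(frame), len(spm.CHANNELS), 100)
    for pdef in ims_defs:
        if pdef.name in names:
            continue
        frame[pdef.name] = [spm.ims_predictor_value(g, pdef) for g in grids]
        names.append(pdef.name)
    return frame, tuple(names)


def build_predictor_table(frame: pd.DataFrame, ims_defs: list,
                          ) -> tuple[selection.PredictorTable, tuple]:
    frame, ims_names = add_ims_columns(frame, ims_defs)
    predictors = (tuple(selection.IPA_COLUMNS) + tuple(strides.GP_NAMES)
                  + ims_names)
    return (selection.PredictorTable(frame=frame, predictors=predictors),
            ims_names)


def run_construction(config: RunConfig) -> ConstructionResult:
    """Cohort generation -> stride processing -> SPM -> LOSO-LASSO."""
    t0 = time.time()
    spec = config.cohort_spec("cohort")
    cohort, gt = synthetic.generate_cohort(spec)
    frame, prov = strides.process_cohort(cohort)

    grids = frame[strides.grid_columns()].to_numpy().reshape(
        len(frame), len(spm.CHANNELS), 100)
    y = frame["hgs_kg"].to_numpy()
    ims_defs, detail = spm.discover_predictors(grids, y, alpha=config.alpha,
                                               qt=config.qt_windows)
    table, ims_names = build_predictor_table(frame, ims_defs)
    models = selection.comparison_models(
        table, gp_columns=strides.GP_NAMES, ims_columns=ims_names)
    label = selection.loso_lasso(table)
    mo = models["Mo"]

    gs_meas = frame["gp02"].to_numpy()
    gs_ref = frame["gait_speed_mps"].to_numpy()
    bundle = ModelBundle(
        sex=spec.sex, support=mo.support,
        coefficients=np.asarray(mo.coefficients), intercept=mo.intercept,
        ims_defs=[d for d in ims_defs if d.name in mo.support],
        train_residuals=mo.predictions - y,
        train_gs_residuals=gs_meas - gs_ref,
        icc21=mo.icc21, mae=mo.mae, adj_r2=mo.adj_r2,
    )
    prov = dict(prov)
    prov.update({
        "stage": "construction", "n_rows": len(frame),
        "n_ims_predictors": len(ims_names),
        "n_predictors": len(table.predictors),
        "config_hash": config.config_hash(),
        "elapsed_s": round(time.time() - t0, 3),
    })
    return ConstructionResult(cohort=cohort, ground_truth=gt, table=table,
                              ims_defs=ims_defs, spm_detail=detail,
                              models=models, label=label, bundle=bundle,
                              provenance=prov)


def apply_model(bundle: ModelBundle, frame: pd.DataFrame) -> np.ndarray:
    """Predict HGS for each trial-average row of a processed cohort."""
    frame, _ = add_ims_columns(frame, bundle.ims_defs)
    missing = [c for c in bundle.support if c not in frame.columns]
    if missing:
        raise PredictorMismatchError(
            f"cohort lacks model predictors: {missing}")
    x = frame[list(bundle.support)].to_numpy(dtype=float)
    return x @ bundle.coefficients + bundle.intercept


def run_test1(config: RunConfig, bundle: ModelBundle,
              test_frame: pd.DataFrame | None = None) -> dict:
    """Agreement of the trained model on a held-out cohort.

    Returns Bland-Altman reports and K_A bounds for HGS estimation and
    gait-speed measurement.
    """
    if test_frame is None:
        spec = config.cohort_spec("test_cohort")
        cohort, _ = synthetic.generate_cohort(spec)
        test_frame, _ = strides.process_cohort(cohort)
    if len(test_frame) < 3:
        raise ValueError("test cohort too small for confidence intervals")
    y_ref = test_frame["hgs_kg"].to_numpy()
    y_est = apply_model(bundle, test_frame)
    gs_ref = test_frame["gait_speed_mps"].to_numpy()
    gs_est = test_frame["gp02"].to_numpy()

    out = {}
    for name, ref, est, train_res in (
            ("hgs", y_ref, y_est, bundle.train_residuals),
            ("gait_speed", gs_ref, gs_est, bundle.train_gs_residuals)):
        ba = agreement.bland_altman(ref, est)
        ka = agreement.ka_bounds(train_res, est - ref)
        rep = agreement.agreement_report(ref, est)
        out[name] = {"bland_altman": ba, "ka": ka, "agreement": rep}
    out["n_rows"] = len(test_frame)
    return out


def _expert_panel(rng: np.random.Generator, true_pfr: np.ndarray,
                  n_raters: int, noise_sd: float, bias_sd: float) -> np.ndarray:
    """Synthetic raters: risk decreasing in true performance, plus noise."""
    biases = rng.normal(0.0, bias_sd, size=n_raters)
    scores = (100.0 - true_pfr)[:, None] + biases[None, :] \
        + rng.normal(0.0, noise_sd, size=(len(true_pfr), n_raters))
    return np.clip(scores, 0.0, 100.0)


def run_test2(config: RunConfig, bundle: ModelBundle,
              test_frame: pd.DataFrame | None = None) -> dict:
    """Frailty risk scores from estimated vs true values, with raters."""
    if test_frame is None:
        spec = config.cohort_spec("test_cohort")
        cohort, _ = synthetic.generate_cohort(spec)
        test_frame, _ = strides.process_cohort(cohort)
    y_est = apply_model(bundle, test_frame)
    frame = test_frame.copy()
    frame["hgs_est"] = y_est

    per_subject = frame.groupby("subject_id").agg(
        sex=("sex", "first"), hgs_kg=("hgs_kg", "first"),
        gait_speed_mps=("gait_speed_mps", "first"),
        hgs_est=("hgs_est", "mean"), gs_est=("gp02", "mean")).reset_index()

    rows = []
    for _, r in per_subject.iterrows():
        est = frailty.score_subject(r["hgs_est"], r["gs_est"], r["sex"])
        ref = frailty.score_subject(r["hgs_kg"], r["gait_speed_mps"], r["sex"])
        rows.append({
            "subject_id": r["subject_id"], "sex": r["sex"],
            "p_hgs_est": est.p_hgs, "p_gs_est": est.p_gs, "p_fr_est": est.p_fr,
            "p_hgs_ref": ref.p_hgs, "p_gs_ref": ref.p_gs, "p_fr_ref": ref.p_fr,
        })
    scores = pd.DataFrame(rows)

    exp_cfg = config.expert
    rng = np.random.default_rng(config.seed + 104729)
    panel = _expert_panel(rng, scores["p_fr_ref"].to_numpy(),
                          int(exp_cfg.get("n_raters", 6)),
                          float(exp_cfg.get("noise_sd", 10.0)),
                          float(exp_cfg.get("bias_sd", 5.0)))
    expert_mean = panel.mean(axis=1)

    from scipy.stats import pearsonr

    def _corr(a, b):
        r, p = pearsonr(a, b)
        return {"r": float(r), "p": float(p),
                "band": agreement.interpret_r(float(r))}

    report = {
        "scores": scores,
        "expert_scores": panel,
        "corr_est_vs_expert": _corr(scores["p_fr_est"], expert_mean),
        "corr_ref_vs_expert": _corr(scores["p_fr_ref"], expert_mean),
        "corr_est_vs_ref": _corr(scores["p_fr_est"], scores["p_fr_ref"]),
        "rater_icc21": agreement.icc(panel, form="(2,1)"),
        "rater_icc2k": agreement.icc(panel, form="(2,k)"),
    }
    return report


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Construction + Test 1 + Test 2, with artifacts written to disk."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    result = run_construction(config)
    save_construction(result, out)
    test_spec = config.cohort_spec("test_cohort")
    cohort, _ = synthetic.generate_cohort(test_spec)
    test_frame, _ = strides.process_cohort(cohort)
    t1 = run_test1(config, result.bundle, test_frame)
    t2 = run_test2(config, result.bundle, test_frame)
    _write_test_reports(out, t1, t2)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "seeds": {"construction": result.cohort.spec.seed,
                  "test": test_spec.seed, "expert": config.seed + 104729},
        "rows": {"construction": result.provenance["n_rows"],
                 "test": t1["n_rows"]},
        "elapsed_s": round(time.time() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {"construction": result, "test1": t1, "test2": t2,
            "manifest": manifest}


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _model_to_dict(m: selection.CandidateModel) -> dict:
    return {
        "support": list(m.support),
        "coefficients": [float(v) for v in m.coefficients],
        "intercept": m.intercept, "lambda_index": m.lambda_index,
        "icc21": m.icc21, "mae": m.mae, "adj_r2": m.adj_r2,
        "icc_band": m.icc_band,
    }


def save_construction(result: ConstructionResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = result.bundle
    model = _model_to_dict(result.models["Mo"])
    model.update({
        "sex": bundle.sex,
        "ims_defs": [{"channel": d.channel, "t_s": d.t_s, "t_e": d.t_e}
                     for d in result.ims_defs],
        "train_residuals": bundle.train_residuals.tolist(),
        "train_gs_residuals": bundle.train_gs_residuals.tolist(),
    })
    (out / "model.json").write_text(json.dumps(model, indent=1))

    pools = {name: _model_to_dict(m) for name, m in result.models.items()}
    pd.DataFrame([
        {"pool": k, "n_predictors": len(v["support"]), "icc21": v["icc21"],
         "mae": v["mae"], "adj_r2": v["adj_r2"], "icc_band": v["icc_band"]}
        for k, v in pools.items()
    ]).to_csv(out / "pool_summary.csv", index=False)

    lm = result.label
    pd.DataFrame(lm.b, index=list(lm.predictors),
                 columns=[f"lambda_{i + 1}" for i in range(lm.b.shape[1])]
                 ).to_csv(out / "label_matrix.csv")
    gpcs = [{"channel": g.channel, "t_s": g.t_s, "t_e": g.t_e,
             "peak_stat": g.peak_stat, "threshold": g.threshold}
            for g in result.spm_detail["gpcs_qt"]]
    (out / "gpcs.json").write_text(json.dumps(gpcs, indent=1))

    curves = {"gc": list(range(1, 101)),
              "cca_chi2": result.spm_detail["cca"].z.tolist()}
    for c in result.spm_detail["pearson"]:
        curves[f"t_{c.channel}"] = c.z.tolist()
    pd.DataFrame(curves).to_csv(out / "spm_curves.csv", index=False)
    (out / "provenance.json").write_text(
        json.dumps(result.provenance, indent=1, default=str))


def load_model(run_dir: str | Path) -> ModelBundle:
    d = json.loads((Path(run_dir) / "model.json").read_text())
    return ModelBundle(
        sex=d["sex"], support=tuple(d["support"]),
        coefficients=np.asarray(d["coefficients"], dtype=float),
        intercept=float(d["intercept"]),
        ims_defs=[spm.IMSPredictorDef(e["channel"], e["t_s"], e["t_e"])
                  for e in d["ims_defs"]],
        train_residuals=np.asarray(d["train_residuals"], dtype=float),
        train_gs_residuals=np.asarray(d["train_gs_residuals"], dtype=float),
        icc21=d["icc21"], mae=d["mae"], adj_r2=d["adj_r2"],
    )


def write_test1_report(out: Path, t1: dict) -> None:
    def _ba(d):
        return {k: (v if not isinstance(v, float) or np.isfinite(v) else None)
                for k, v in d.__dict__.items()}

    rep = {}
    for name in ("hgs", "gait_speed"):
        blk = t1[name]
        rep[name] = {
            "bland_altman": _ba(blk["bland_altman"]),
            "ka": {"k_al": blk["ka"].k_al, "k_au": blk["ka"].k_au,
                   "interval": list(blk["ka"].interval)},
            "icc21": blk["agreement"].icc21, "mae": blk["agreement"].mae,
            "icc_band": blk["agreement"].icc_band,
        }
    (out / "agreement_report.json").write_text(json.dumps(rep, indent=1))


def _write_test_reports(out: Path, t1: dict, t2: dict) -> None:
    write_test1_report(out, t1)
    t2["scores"].to_csv(out / "frailty_scores.csv", index=False)
    corr = {k: t2[k] for k in
            ("corr_est_vs_expert", "corr_ref_vs_expert", "corr_est_vs_ref")}
    corr["rater_icc21"] = t2["rater_icc21"]
    corr["rater_icc2k"] = t2["rater_icc2k"]
    (out / "test2_report.json").write_text(json.dumps(corr, indent=1))
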