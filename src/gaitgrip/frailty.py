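"""Frailty questionnaire scoring and the analog frailty risk score.

The risk score maps hand grip strength (HGS) and gait speed onto percentile
performance scores through sex-specific population norms and the standard
normal CDF, then averages the two with equal weight.  The questionnaire
scorer implements the four-item J-CHS rules plus the HGS and gait-speed
criterion points, with the usual 0 / 1-2 / >2 categorisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.stats import norm

__all__ = [
    "PopulationNorms",
    "FrailtyScores",
    "JCHSRecord",
    "z_scores",
    "performance_score",
    "frailty_risk",
    "jchs_score",
    "score_subject",
    "HGS_CUTOFF_KG",
    "GAIT_SPEED_CUTOFF_MPS",
]

#: Low-HGS criterion thresholds (kg) used by the questionnaire scorer.
HGS_CUTOFF_KG = {"male": 28.0, "female": 18.0}
#: Slow-gait criterion threshold (m/s), identical for both sexes.
GAIT_SPEED_CUTOFF_MPS = 1.0


@dataclass(frozen=True)
class PopulationNorms:
    """Reference means/SDs for older-adult HGS (per sex) and gait speed.

    Defaults are large-sample Asian-population values: male HGS
    34.7 +/- 7.1 kg, female HGS 21.9 +/- 4.8 kg, and sex-pooled gait speed
    1.29 +/- 0.24 m/s.
    """

    hgs_male_mean: float = 34.7
    hgs_male_sd: float = 7.1
    hgs_female_mean: float = 21.9
    hgs_female_sd: float = 4.8
    gs_mean: float = 1.29
    gs_sd: float = 0.24

    def __post_init__(self) -> None:
        for name in ("hgs_male_sd", "hgs_female_sd", "gs_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def hgs_params(self, sex: str) -> tuple[float, float]:
        if sex == "male":
            return self.hgs_male_mean, self.hgs_male_sd
        if sex == "female":
            return self.hgs_female_mean, self.hgs_female_sd
        raise ValueError(f"unknown sex: {sex!r}")


@dataclass(frozen=True)
class FrailtyScores:
    """Z-scores and percentile performance scores for one subject.

    ``p_hgs``, ``p_gs`` and ``p_fr`` are on a 0-100 scale (``scale``
    records this explicitly; the raw CDF values live in [0, 1]).
    """

    z_hgs: float
    z_gs: float
    p_hgs: float
    p_gs: float
    p_fr: float
    scale: str = field(default="percent")


def z_scores(
    hgs: float, gs: float, sex: str, norms: PopulationNorms | None = None
) -> tuple[float, float]:
    """Standardize HGS (sex-specific norms) and gait speed (pooled norms)."""
    norms = norms or PopulationNorms()
    mean, sd = norms.hgs_params(sex)
    return (hgs - mean) / sd, (gs - norms.gs_mean) / norms.gs_sd


def performance_score(z: float, scale: str = "percent") -> float:
    """Cumulative-normal performance score: 100 * Phi(z) (or Phi(z))."""
    p = float(norm.cdf(z))
    if scale == "percent":
        return 100.0 * p
    if scale == "unit":
        return p
    raise ValueError(f"unknown scale: {scale!r}")


def frailty_risk(p_hgs: float, p_gs: float) -> float:
    """Equal-weight mean of the HGS and gait-speed performance scores."""
    for v in (p_hgs, p_gs):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"performance score out of [0, 100]: {v}")
    return (p_hgs + p_gs) / 2.0


def score_subject(
    hgs: float, gs: float, sex: str, norms: PopulationNorms | None = None
) -> FrailtyScores:
    """Full pipeline: z-scores -> performance scores -> combined risk score."""
    z_hgs, z_gs = z_scores(hgs, gs, sex, norms)
    p_hgs = performance_score(z_hgs)
    p_gs = performance_score(z_gs)
    return FrailtyScores(
        z_hgs=z_hgs, z_gs=z_gs, p_hgs=p_hgs, p_gs=p_gs,
        p_fr=frailty_risk(p_hgs, p_gs),
    )


@dataclass(frozen=True)
class JCHSRecord:
    """Scored four-item questionnaire plus HGS / gait-speed criteria."""

    q1: bool
    q2: bool
    q3: bool
    q4: bool
    hgs_kg: float
    gait_speed_mps: float
    sex: str
    score: int
    category: str


def jchs_score(
    q1: bool, q2: bool, q3: bool, q4: bool,
    hgs_kg: float, gait_speed_mps: float, sex: str,
) -> JCHSRecord:
    """Score the questionnaire.

    Q1/Q2 add one point per "yes"; Q3/Q4 add one point only if both are
    "no".  One more point each for HGS below the sex cut-off and gait speed
    below 1.0 m/s.  Category: 0 -> Robust, 1-2 -> Pre-frail, >=3 -> Frail.
    """
    if sex not in HGS_CUTOFF_KG:
        raise ValueError(f"unknown sex: {sex!r}")
    for name, v in (("q1", q1), ("q2", q2), ("q3", q3), ("q4", q4)):
        if not isinstance(v, (bool,)):
            raise TypeError(f"{name} must be a boolean yes/no answer")
    score = int(q1) + int(q2)
    if not q3 and not q4:
        score += 1
    if hgs_kg < HGS_CUTOFF_KG[sex]:
        score += 1
    if gait_speed_mps < GAIT_SPEED_CUTOFF_MPS:
        score += 1
    if score == 0:
        category = "Robust"
    elif score <= 2:
        category = "Pre-frail"
    else:
        category = "Frail"
    return JCHSRecord(
        q1=q1, q2=q2, q3=q3, q4=q4, hgs_kg=hgs_kg,
        gait_speed_mps=gait_speed_mps, sex=sex, score=score, category=category,
    )
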