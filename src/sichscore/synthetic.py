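"""Synthetic cohort generation.

Draws patient-level covariates matching the published marginal summaries
of the study population (means/SDs, medians/IQRs, category frequencies),
assigns SICH outcomes from a logistic model on the extended risk score
with the intercept solved to hit a requested marginal event rate, and
synthesizes follow-up records that adjudicate exactly to the simulated
labels under a chosen definition.

Covariates are drawn independently: only marginal summaries are
published, so no correlation structure is imposed (an optional NIHSS
shift by OCSP category is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .errors import ValidationError
from .ocsp import OCSPCategory
from .outcomes import FollowUpRecord, ICHType, ImagingFinding
from .riskscore import (
    Antiplatelet,
    GlucoseUnit,
    PatientProfile,
    compute_extended_score,
)

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "simulate_outcomes",
    "solve_intercept",
    "DEFAULT_TARGET_RATES",
]

#: Marginal SICH rates by definition used as simulation defaults.
DEFAULT_TARGET_RATES = {"ninds": 0.073, "ecass2": 0.053, "sitsmost": 0.035}

OCSP_DEFAULT_PROBS = {
    OCSPCategory.TACI: 0.378,
    OCSPCategory.PACI: 0.296,
    OCSPCategory.POCI: 0.088,
    OCSPCategory.LACI: 0.203,
    OCSPCategory.UNCERTAIN: 0.036,
}


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters, defaulted to the study population's
    marginal summaries."""

    n: int = 548
    seed: int | None = None
    age_mean: float = 67.0
    age_sd: float = 12.0
    weight_mean: float = 65.0
    weight_sd: float = 13.0
    sbp_mean: float = 161.0
    sbp_sd: float = 30.0
    glucose_mean: float = 8.49  # mmol/L
    glucose_sd: float = 3.72
    nihss_median: float = 13.0
    nihss_iqr: tuple[float, float] = (8.0, 20.0)
    ott_median: float = 125.0
    ott_iqr: tuple[float, float] = (100.0, 155.0)
    ocsp_probs: dict = field(default_factory=lambda: dict(OCSP_DEFAULT_PROBS))
    p_hypertension: float = 0.741
    p_antiplatelet: float = 0.235
    antiplatelet_combo_frac: float = 0.2  # combo share of antiplatelet users
    beta: float = 0.25  # log-odds per extended-score point
    target_rates: dict = field(default_factory=lambda: dict(DEFAULT_TARGET_RATES))
    nihss_ocsp_shift: dict | None = None  # optional additive shift per category

    def __post_init__(self):
        if self.n < 0:
            raise ValidationError(f"n must be non-negative, got {self.n}")
        for name in ("age_sd", "weight_sd", "sbp_sd", "glucose_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        # published percentages round to 100.1%; tolerate rounding slack and
        # renormalize at draw time
        total = sum(self.ocsp_probs.values())
        if abs(total - 1.0) > 5e-3:
            raise ValidationError(f"ocsp_probs must sum to 1, got {total}")
        if not 0.0 <= self.antiplatelet_combo_frac <= 1.0:
            raise ValidationError("antiplatelet_combo_frac must be in [0, 1]")


@lru_cache(maxsize=32)
def _fit_gamma_quantiles(q25: float, q50: float, q75: float):
    """Gamma(shape, scale) whose quartiles best match the targets
    (least squares on the three quantiles)."""

    def loss(log_params):
        a, scale = np.exp(log_params)
        q = stats.gamma.ppf([0.25, 0.5, 0.75], a, scale=scale)
        return np.sum((q - np.array([q25, q50, q75])) ** 2)

    res = optimize.minimize(
        loss, x0=np.log([4.0, q50 / 4.0]), method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    a, scale = np.exp(res.x)
    return float(a), float(scale)


def _truncated_normal(rng, mean, sd, size):
    """Normal truncated at zero (no negative physiological values)."""
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table in the documented CSV schema.

    Continuous covariates come from zero-truncated normals; NIHSS from a
    discretized gamma fitted to the published median/IQR, clipped to
    [0, 42]; onset-to-treatment time from a gamma fitted the same way;
    OCSP category from a multinomial; binary factors from Bernoullis.
    Fully reproducible under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    age = np.round(_truncated_normal(rng, spec.age_mean, spec.age_sd, n)).astype(int)
    weight = _truncated_normal(rng, spec.weight_mean, spec.weight_sd, n)
    sbp = _truncated_normal(rng, spec.sbp_mean, spec.sbp_sd, n)
    glucose = _truncated_normal(rng, spec.glucose_mean, spec.glucose_sd, n)

    a_n, s_n = _fit_gamma_quantiles(spec.nihss_iqr[0], spec.nihss_median,
                                    spec.nihss_iqr[1])
    nihss_raw = stats.gamma.rvs(a_n, scale=s_n, size=n, random_state=rng)

    a_t, s_t = _fit_gamma_quantiles(spec.ott_iqr[0], spec.ott_median,
                                    spec.ott_iqr[1])
    ott = stats.gamma.rvs(a_t, scale=s_t, size=n, random_state=rng)

    cats = list(spec.ocsp_probs.keys())
    probs = np.array([spec.ocsp_probs[c] for c in cats])
    probs = probs / probs.sum()
    ocsp_idx = rng.choice(len(cats), size=n, p=probs)
    ocsp = np.array([cats[i].value for i in ocsp_idx])

    if spec.nihss_ocsp_shift:
        shift = np.array(
            [spec.nihss_ocsp_shift.get(cats[i], 0.0) for i in ocsp_idx]
        )
        nihss_raw = np.clip(nihss_raw + shift, 0.0, None)
    nihss = np.clip(np.round(nihss_raw), 0, 42).astype(int)

    htn = rng.random(n) < spec.p_hypertension
    on_ap = rng.random(n) < spec.p_antiplatelet
    combo = rng.random(n) < spec.antiplatelet_combo_frac
    antiplatelet = np.where(
        on_ap,
        np.where(combo, Antiplatelet.ASPIRIN_PLUS_CLOPIDOGREL.value,
                 Antiplatelet.ASPIRIN_MONO.value),
        Antiplatelet.NONE.value,
    )

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "age": age,
            "nihss_baseline": nihss,
            "glucose": np.round(glucose, 2),
            "glucose_unit": "mmol",
            "sbp": np.round(sbp, 1),
            "weight_kg": np.round(weight, 1),
            "ott_min": np.round(ott, 0).astype(int),
            "htn_history": htn.astype(int),
            "antiplatelet": antiplatelet,
            "ocsp": ocsp,
        }
    )


def solve_intercept(scores: np.ndarray, beta: float, target_rate: float) -> float:
    """Intercept alpha such that mean(expit(alpha + beta*score)) equals
    ``target_rate`` over the given score distribution (root finding on the
    expectation)."""
    if not 0.0 < target_rate < 1.0:
        raise ValidationError(f"target rate must be in (0, 1), got {target_rate}")
    s = np.asarray(scores, dtype=float)

    def gap(alpha):
        return float(np.mean(expit(alpha + beta * s))) - target_rate

    lo, hi = -50.0, 50.0
    return float(optimize.brentq(gap, lo, hi, xtol=1e-12))


def _profile_from_row(row) -> PatientProfile:
    return PatientProfile(
        age=float(row["age"]),
        nihss_baseline=int(row["nihss_baseline"]),
        glucose=float(row["glucose"]),
        glucose_unit=GlucoseUnit.from_string(str(row["glucose_unit"])),
        sbp=float(row["sbp"]),
        weight=float(row["weight_kg"]),
        ott_minutes=float(row["ott_min"]),
        hypertension_history=bool(int(row["htn_history"])),
        antiplatelet=Antiplatelet(str(row["antiplatelet"])),
        ocsp=OCSPCategory.from_string(str(row["ocsp"])),
    )


def _positive_record(baseline: int, definition: str) -> FollowUpRecord:
    """A follow-up course that adjudicates positive under ``definition``
    (and respects the SITS-MOST => ECASS II nesting)."""
    if definition == "ninds":
        # any ICH + >=1-point worsening within 36 h; too mild for ECASS II
        return FollowUpRecord(
            nihss_baseline=baseline,
            nihss_series=((2.0, baseline), (24.0, min(42, baseline + 1))),
            death_within_7d=False,
            scans=(ImagingFinding(24.0, ICHType.HI1),),
        )
    ich = ICHType.PH2 if definition == "sitsmost" else ICHType.HI2
    if baseline <= 38:
        series = ((2.0, baseline), (30.0, baseline + 4))
        death = False
    else:  # cannot worsen by 4 points; the death clause carries the verdict
        series = ((2.0, baseline), (30.0, baseline))
        death = True
    return FollowUpRecord(
        nihss_baseline=baseline,
        nihss_series=series,
        death_within_7d=death,
        scans=(ImagingFinding(30.0 if definition == "ecass2" else 24.0, ich),),
    )


def _negative_record(baseline: int) -> FollowUpRecord:
    return FollowUpRecord(
        nihss_baseline=baseline,
        nihss_series=((2.0, baseline), (24.0, baseline)),
        death_within_7d=False,
        scans=(ImagingFinding(24.0, ICHType.NONE),),
    )


def simulate_outcomes(
    cohort: pd.DataFrame,
    spec: CohortSpec,
    definition: str = "ninds",
    seed: int | None = None,
    target_rate: float | None = None,
):
    """Simulate SICH labels and matching follow-up records.

    Labels are Bernoulli(expit(alpha + beta * extended_score)) with alpha
    solved so the expected marginal rate equals the requested target.
    Returns ``(truth, followup, records)``: a per-patient label frame, a
    long-format follow-up event frame, and a dict of
    :class:`~sichscore.outcomes.FollowUpRecord` keyed by patient id.

    A NINDS-positive label drawn for a patient at the NIHSS ceiling (42)
    is flipped to negative: a one-point worsening is impossible there.
    """
    definition = definition.lower()
    if definition not in DEFAULT_TARGET_RATES:
        raise ValidationError(f"unknown definition {definition!r}")
    if target_rate is None:
        target_rate = spec.target_rates[definition]

    scores = np.array(
        [
            compute_extended_score(_profile_from_row(row)).total
            for _, row in cohort.iterrows()
        ]
    )
    alpha = solve_intercept(scores, spec.beta, target_rate)
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    p = expit(alpha + spec.beta * scores)
    y = rng.random(len(scores)) < p

    records: dict[str, FollowUpRecord] = {}
    rows = []
    labels = []
    for (idx, row), yi in zip(cohort.iterrows(), y):
        pid = row["patient_id"]
        b = int(row["nihss_baseline"])
        if yi and definition == "ninds" and b >= 42:
            yi = False
        rec = _positive_record(b, definition) if yi else _negative_record(b)
        records[pid] = rec
        labels.append(bool(yi))
        for t, v in rec.nihss_series:
            rows.append((pid, "nihss", t, str(v)))
        for scan in rec.scans:
            rows.append((pid, "scan", scan.hours_post_tpa, scan.ich_type.value))
        if rec.death_within_7d:
            rows.append((pid, "death", 168.0, "1"))

    truth = pd.DataFrame(
        {
            "patient_id": cohort["patient_id"].to_numpy(),
            "sich": np.array(labels, dtype=int),
            "definition": definition,
            "extended_score": scores,
        }
    )
    followup = pd.DataFrame(rows, columns=["patient_id", "event_type", "hours", "value"])
    return truth, followup, records
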