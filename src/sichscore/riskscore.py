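"""Point-based risk scores for post-thrombolysis symptomatic intracerebral
hemorrhage (SICH).

Two scores are provided:

* the 12-point SITS SICH risk score, built from nine pretreatment
  variables with fixed integer weights;
* the 15-point extended score, which adds an OCSP stroke-syndrome
  component: a configurable number of points (default 3) for a total
  anterior circulation infarct (TACI), and an override that zeroes the
  whole score for posterior circulation infarcts (POCI).

Scores map to LOW / AVERAGE / ELEVATED risk strata via fixed cutpoints
that differ between the two score kinds.
"""

from __future__ import annotations

import enum
import itertools
import warnings
from dataclasses import dataclass

from .errors import MissingDataError, ValidationError
from .ocsp import OCSPCategory

__all__ = [
    "Antiplatelet",
    "GlucoseUnit",
    "PatientProfile",
    "RiskCategory",
    "RiskLabel",
    "ScoreKind",
    "ScoreResult",
    "compute_sits_score",
    "compute_extended_score",
    "stratify",
    "MGDL_PER_MMOL",
    "GLUCOSE_THRESHOLD_MGDL",
]

#: Conversion factor between glucose units (mg/dL per mmol/L).
MGDL_PER_MMOL = 18.016

#: Glucose cutoff, expressed in mg/dL; mmol/L inputs are normalized first.
GLUCOSE_THRESHOLD_MGDL = 180.0


class Antiplatelet(enum.Enum):
    """Pre-admission antiplatelet exposure; mono- and combination therapy
    are mutually exclusive states, so their points can never add."""

    NONE = "none"
    ASPIRIN_MONO = "aspirin"
    ASPIRIN_PLUS_CLOPIDOGREL = "aspirin_clopidogrel"


class GlucoseUnit(enum.Enum):
    MGDL = "mgdl"
    MMOL = "mmol"

    @classmethod
    def from_string(cls, token: str) -> "GlucoseUnit":
        token = token.strip().lower().replace("/", "").replace(".", "")
        aliases = {
            "mgdl": cls.MGDL,
            "mg": cls.MGDL,
            "mmol": cls.MMOL,
            "mmoll": cls.MMOL,
        }
        try:
            return aliases[token]
        except KeyError:
            raise ValidationError(f"unknown glucose unit {token!r}") from None


class ScoreKind(enum.Enum):
    SITS = "sits"
    EXTENDED = "extended"


class RiskLabel(enum.Enum):
    LOW = "low"
    AVERAGE = "average"
    ELEVATED = "elevated"

    @property
    def rank(self) -> int:
        return {"low": 0, "average": 1, "elevated": 2}[self.value]


@dataclass(frozen=True)
class PatientProfile:
    """Pretreatment variables feeding both risk scores.

    Any field may be ``None``; strict scoring raises
    :class:`~sichscore.errors.MissingDataError` on a missing field, while
    permissive scoring treats it as the zero-point state with a warning.
    """

    age: float | None = None
    nihss_baseline: int | None = None
    glucose: float | None = None
    glucose_unit: GlucoseUnit | None = None
    sbp: float | None = None
    weight: float | None = None
    ott_minutes: float | None = None
    hypertension_history: bool | None = None
    antiplatelet: Antiplatelet | None = None
    ocsp: OCSPCategory | None = None

    def __post_init__(self):
        if self.nihss_baseline is not None and not (0 <= self.nihss_baseline <= 42):
            raise ValidationError(
                f"nihss_baseline must be in [0, 42], got {self.nihss_baseline}"
            )
        for name in ("age", "glucose", "sbp", "weight", "ott_minutes"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be non-negative, got {v}")
        if self.glucose is not None and self.glucose_unit is None:
            raise ValidationError("glucose given without a unit tag")

    def glucose_mgdl(self) -> float | None:
        """Glucose normalized to mg/dL."""
        if self.glucose is None:
            return None
        if self.glucose_unit is GlucoseUnit.MMOL:
            return self.glucose * MGDL_PER_MMOL
        return self.glucose


@dataclass(frozen=True)
class ScoreResult:
    """Integer score plus per-component breakdown."""

    total: int
    components: tuple[tuple[str, int], ...]
    score_kind: ScoreKind
    poci_zeroed: bool = False


@dataclass(frozen=True)
class RiskCategory:
    label: RiskLabel
    score_kind: ScoreKind


# (component name, required profile fields, scoring function)
def _require(profile: PatientProfile, fields: tuple[str, ...], strict: bool) -> bool:
    """True when all fields are present; in permissive mode a missing field
    warns and the component scores zero."""
    for f in fields:
        if getattr(profile, f) is None:
            if strict:
                raise MissingDataError(f)
            warnings.warn(
                f"missing field {f!r}: component scored as absent", stacklevel=3
            )
            return False
    return True


def _sits_components(profile: PatientProfile, strict: bool) -> list[tuple[str, int]]:
    comps: list[tuple[str, int]] = []

    if _require(profile, ("antiplatelet",), strict):
        ap = profile.antiplatelet
    else:
        ap = Antiplatelet.NONE
    comps.append(
        ("aspirin_clopidogrel", 3 if ap is Antiplatelet.ASPIRIN_PLUS_CLOPIDOGREL else 0)
    )
    comps.append(("aspirin_mono", 2 if ap is Antiplatelet.ASPIRIN_MONO else 0))

    if _require(profile, ("nihss_baseline",), strict):
        n = profile.nihss_baseline
        pts = 2 if n >= 13 else (1 if n >= 7 else 0)
    else:
        pts = 0
    comps.append(("nihss", pts))

    if _require(profile, ("glucose",), strict):
        g = profile.glucose_mgdl()
        comps.append(("glucose", 2 if g >= GLUCOSE_THRESHOLD_MGDL else 0))
    else:
        comps.append(("glucose", 0))

    for name, fieldname, cutoff in (
        ("age", "age", 72),
        ("sbp", "sbp", 146),
        ("weight", "weight", 95),
        ("ott", "ott_minutes", 180),
    ):
        if _require(profile, (fieldname,), strict):
            comps.append((name, 1 if getattr(profile, fieldname) >= cutoff else 0))
        else:
            comps.append((name, 0))

    if _require(profile, ("hypertension_history",), strict):
        comps.append(("hypertension", 1 if profile.hypertension_history else 0))
    else:
        comps.append(("hypertension", 0))

    return comps


def compute_sits_score(profile: PatientProfile, *, strict: bool = True) -> ScoreResult:
    """Compute the 12-point SITS SICH risk score.

    Weights: aspirin+clopidogrel 3 (XOR aspirin monotherapy 2); NIHSS >=13
    scores 2, 7-12 scores 1; glucose >=180 mg/dL scores 2; age >=72,
    SBP >=146 mm Hg, weight >=95 kg, onset-to-treatment time >=180 min and
    a history of hypertension score 1 each.  All cutoffs are inclusive.
    """
    comps = _sits_components(profile, strict)
    total = sum(p for _, p in comps)
    return ScoreResult(total=total, components=tuple(comps), score_kind=ScoreKind.SITS)


def compute_extended_score(
    profile: PatientProfile, taci_weight: int = 3, *, strict: bool = True
) -> ScoreResult:
    """Compute the OCSP-extended risk score.

    TACI adds ``taci_weight`` points (default 3) on top of the SITS total;
    PACI, LACI and UNCERTAIN add nothing; a POCI profile scores 0 overall
    regardless of its SITS total (``poci_zeroed`` is set on the result).
    """
    if not isinstance(taci_weight, (int,)) or isinstance(taci_weight, bool):
        raise ValidationError(f"taci_weight must be an integer, got {taci_weight!r}")
    if taci_weight < 0:
        raise ValidationError(f"taci_weight must be non-negative, got {taci_weight}")

    if not _require(profile, ("ocsp",), strict):
        ocsp = OCSPCategory.UNCERTAIN
    else:
        ocsp = profile.ocsp

    comps = _sits_components(profile, strict)
    if ocsp is OCSPCategory.POCI:
        zeroed = tuple((name, 0) for name, _ in comps) + (("ocsp", 0),)
        return ScoreResult(
            total=0, components=zeroed, score_kind=ScoreKind.EXTENDED, poci_zeroed=True
        )
    comps.append(("ocsp", taci_weight if ocsp is OCSPCategory.TACI else 0))
    total = sum(p for _, p in comps)
    return ScoreResult(
        total=total, components=tuple(comps), score_kind=ScoreKind.EXTENDED
    )


_STRATA = {
    # kind: (first AVERAGE total, first ELEVATED total)
    ScoreKind.SITS: (3, 6),
    ScoreKind.EXTENDED: (4, 8),
}


def stratify(score: ScoreResult) -> RiskCategory:
    """Map a score to its risk stratum.

    SITS: 0-2 LOW, 3-5 AVERAGE, >=6 ELEVATED.
    Extended: 0-3 LOW, 4-7 AVERAGE, >=8 ELEVATED.
    """
    total = score.total
    if total < 0:
        raise ValidationError(f"score total must be non-negative, got {total}")
    avg_at, elev_at = _STRATA[score.score_kind]
    if total >= elev_at:
        label = RiskLabel.ELEVATED
    elif total >= avg_at:
        label = RiskLabel.AVERAGE
    else:
        label = RiskLabel.LOW
    return RiskCategory(label=label, score_kind=score.score_kind)


def enumerate_component_profiles() -> list[PatientProfile]:
    """All distinct component-state combinations of the nine score
    variables (antiplatelet x NIHSS band x six binary cutoffs), with
    representative field values on each side of every cutoff.

    Used for exhaustive verification of the score range.
    """
    profiles = []
    for ap, nihss, glu, age, sbp, wt, ott, htn in itertools.product(
        Antiplatelet, (5, 10, 20), (100.0, 200.0), (50, 80), (120.0, 150.0),
        (70.0, 100.0), (90.0, 185.0), (False, True),
    ):
        profiles.append(
            PatientProfile(
                age=age, nihss_baseline=nihss, glucose=glu,
                glucose_unit=GlucoseUnit.MGDL, sbp=sbp, weight=wt,
                ott_minutes=ott, hypertension_history=htn, antiplatelet=ap,
            )
        )
    return profiles
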