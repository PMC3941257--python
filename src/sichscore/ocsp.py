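"""Oxfordshire Community Stroke Project (OCSP) stroke syndromes.

Provides the five-way category enum, a rule-based classifier that maps a
structured pretreatment symptom checklist to a syndrome, a discrepancy
resolver for multiple raters, and unweighted Cohen's kappa for
inter-rater agreement.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Sequence

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "OCSPCategory",
    "DeficitExtent",
    "SymptomProfile",
    "AgreementResult",
    "classify_ocsp",
    "resolve_raters",
    "cohen_kappa",
]


class OCSPCategory(enum.Enum):
    """Clinical (imaging-free) stroke syndrome categories."""

    TACI = "TACI"  # total anterior circulation infarct
    PACI = "PACI"  # partial anterior circulation infarct
    POCI = "POCI"  # posterior circulation infarct
    LACI = "LACI"  # lacunar infarct
    UNCERTAIN = "UNCERTAIN"

    @classmethod
    def from_string(cls, token: str) -> "OCSPCategory":
        try:
            return cls(token.strip().upper())
        except ValueError:
            raise ValidationError(f"unknown OCSP category {token!r}") from None


class DeficitExtent(enum.Enum):
    """Motor/sensory deficit extent over face, arm and leg."""

    NONE = "none"
    PARTIAL = "partial"      # fewer than 2 of face/arm/leg
    EXTENSIVE = "extensive"  # at least 2 of face/arm/leg


@dataclass(frozen=True)
class SymptomProfile:
    """Structured checklist of maximal pretreatment neurological deficits."""

    higher_cortical_dysfunction: bool
    homonymous_hemianopia: bool
    motor_sensory_deficit: DeficitExtent
    brainstem_cerebellar_signs: bool
    pure_lacunar_syndrome: bool

    def __post_init__(self):
        if self.pure_lacunar_syndrome and (
            self.higher_cortical_dysfunction or self.homonymous_hemianopia
        ):
            raise ValidationError(
                "a pure lacunar syndrome excludes cortical dysfunction "
                "and hemianopia"
            )


@dataclass(frozen=True)
class AgreementResult:
    """Chance-corrected inter-rater agreement."""

    kappa: float
    observed_agreement: float
    expected_agreement: float
    n_items: int


def classify_ocsp(symptoms: SymptomProfile) -> OCSPCategory:
    """Classify a symptom checklist into an OCSP category.

    Rule order: the full anterior triad (higher cortical dysfunction +
    homonymous hemianopia + extensive deficit) gives TACI; otherwise
    brainstem/cerebellar signs or isolated hemianopia give POCI; a pure
    lacunar syndrome without cortical signs gives LACI; any partial
    anterior combination (two of the three triad elements, isolated
    cortical dysfunction, or an isolated partial deficit) gives PACI;
    anything left is UNCERTAIN.
    """
    s = symptoms
    triad = (
        s.higher_cortical_dysfunction
        and s.homonymous_hemianopia
        and s.motor_sensory_deficit is DeficitExtent.EXTENSIVE
    )
    if triad:
        return OCSPCategory.TACI
    if s.brainstem_cerebellar_signs:
        return OCSPCategory.POCI
    isolated_hemianopia = (
        s.homonymous_hemianopia
        and not s.higher_cortical_dysfunction
        and s.motor_sensory_deficit is DeficitExtent.NONE
    )
    if isolated_hemianopia:
        return OCSPCategory.POCI
    if s.pure_lacunar_syndrome:
        return OCSPCategory.LACI
    n_triad = sum(
        (
            s.higher_cortical_dysfunction,
            s.homonymous_hemianopia,
            s.motor_sensory_deficit is not DeficitExtent.NONE,
        )
    )
    if n_triad >= 2:
        return OCSPCategory.PACI
    if s.higher_cortical_dysfunction:
        return OCSPCategory.PACI
    if s.motor_sensory_deficit is DeficitExtent.PARTIAL:
        return OCSPCategory.PACI
    return OCSPCategory.UNCERTAIN


def resolve_raters(
    r1: OCSPCategory | None,
    r2: OCSPCategory | None,
    r3: OCSPCategory | None = None,
) -> OCSPCategory:
    """Resolve multi-rater discrepancies.

    Two concordant raters decide; otherwise a third rater matching either
    decides; if all three disagree the result is UNCERTAIN.
    """
    present = [r for r in (r1, r2) if r is not None]
    if len(present) < 2:
        raise ValidationError("at least two ratings are required")
    if r1 == r2:
        return r1
    if r3 is not None and r3 in (r1, r2):
        return r3
    return OCSPCategory.UNCERTAIN


def cohen_kappa(
    ratings1: Sequence[Hashable], ratings2: Sequence[Hashable]
) -> AgreementResult:
    """Unweighted Cohen's kappa between two raters.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement
    proportion and p_e the chance-expected agreement from the raters'
    marginal distributions.
    """
    if len(ratings1) != len(ratings2):
        raise ValidationError(
            f"rating vectors differ in length: {len(ratings1)} vs {len(ratings2)}"
        )
    n = len(ratings1)
    if n == 0:
        raise ValidationError("rating vectors must be non-empty")

    po = sum(a == b for a, b in zip(ratings1, ratings2)) / n
    m1 = Counter(ratings1)
    m2 = Counter(ratings2)
    labels = set(m1) | set(m2)
    pe = sum(m1[c] * m2[c] for c in labels) / (n * n)
    if pe >= 1.0:
        raise DegenerateInputError(
            "expected agreement is 1 (both raters constant); kappa undefined"
        )
    kappa = (po - pe) / (1.0 - pe)
    return AgreementResult(
        kappa=kappa, observed_agreement=po, expected_agreement=pe, n_items=n
    )
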