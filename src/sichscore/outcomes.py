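"""Adjudication of symptomatic intracerebral hemorrhage (SICH) from
structured follow-up data, under three operational definitions.

* NINDS: any ICH on post-treatment imaging together with neurological
  worsening of >=1 NIHSS point within 36 h of treatment.
* ECASS II: any ICH on any post-treatment imaging together with a
  deterioration of >=4 NIHSS points from baseline or from the lowest
  prior value within 7 days, or death within 7 days.
* SITS-MOST: a local or remote type 2 parenchymal hemorrhage on the
  22-36 h post-treatment scan together with the ECASS II deterioration
  clause or death within 7 days.

SITS-MOST positivity implies ECASS II positivity by construction.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

from .errors import MissingDataError, ValidationError

__all__ = [
    "ICHType",
    "ImagingFinding",
    "FollowUpRecord",
    "SICHVerdict",
    "adjudicate",
]

HOURS_7D = 168.0


class ICHType(enum.Enum):
    """Radiological hemorrhage type token (PHR = remote parenchymal)."""

    NONE = "none"
    HI1 = "HI1"
    HI2 = "HI2"
    PH1 = "PH1"
    PH2 = "PH2"
    PHR1 = "PHr1"
    PHR2 = "PHr2"

    @classmethod
    def from_string(cls, token: str) -> "ICHType":
        canon = {t.value.lower(): t for t in cls}
        try:
            return canon[token.strip().lower()]
        except KeyError:
            raise ValidationError(f"unknown ICH type {token!r}") from None


#: Types qualifying for the SITS-MOST definition.
PH2_TYPES = frozenset({ICHType.PH2, ICHType.PHR2})


@dataclass(frozen=True)
class ImagingFinding:
    hours_post_tpa: float
    ich_type: ICHType = ICHType.NONE

    def __post_init__(self):
        if self.hours_post_tpa < 0:
            raise ValidationError(
                f"scan time must be non-negative, got {self.hours_post_tpa}"
            )

    @property
    def ich_present(self) -> bool:
        return self.ich_type is not ICHType.NONE


@dataclass(frozen=True)
class FollowUpRecord:
    """Post-treatment course of one patient within the first 7 days."""

    nihss_baseline: int
    nihss_series: tuple[tuple[float, int], ...] = ()
    death_within_7d: bool = False
    scans: tuple[ImagingFinding, ...] = ()

    def __post_init__(self):
        if not (0 <= self.nihss_baseline <= 42):
            raise ValidationError(
                f"nihss_baseline must be in [0, 42], got {self.nihss_baseline}"
            )
        for t, v in self.nihss_series:
            if t < 0 or t > HOURS_7D:
                raise ValidationError(f"NIHSS time {t} outside [0, {HOURS_7D}] h")
            if not (0 <= v <= 42):
                raise ValidationError(f"NIHSS value {v} outside [0, 42]")


@dataclass(frozen=True)
class SICHVerdict:
    ninds: bool
    ecass2: bool
    sits_most: bool


def _deterioration_ge4(record: FollowUpRecord) -> bool:
    """True when some NIHSS measurement within 7 days exceeds by >=4 points
    the running minimum of all earlier values (baseline included).

    The reference minimum is taken strictly before the deteriorated
    measurement, so deterioration always follows its reference point.
    """
    series = sorted(record.nihss_series, key=lambda tv: tv[0])
    run_min = record.nihss_baseline
    for _, v in series:
        if v - run_min >= 4:
            return True
        run_min = min(run_min, v)
    return False


def adjudicate(record: FollowUpRecord, *, strict: bool = True) -> SICHVerdict:
    """Adjudicate one follow-up record under all three SICH definitions.

    An empty scan list yields an all-false verdict with a warning (every
    definition requires hemorrhage on imaging).  An empty NIHSS series is
    a missing-data error in strict mode; in permissive mode deterioration
    is treated as unobserved.
    """
    if not record.scans:
        warnings.warn("no post-treatment scans: all definitions adjudicated false")
        return SICHVerdict(ninds=False, ecass2=False, sits_most=False)

    if not record.nihss_series and strict:
        raise MissingDataError("nihss_series")

    any_ich = any(s.ich_present for s in record.scans)
    ph2_in_window = any(
        s.ich_type in PH2_TYPES and 22.0 <= s.hours_post_tpa <= 36.0
        for s in record.scans
    )

    worsening_1_36h = any(
        v >= record.nihss_baseline + 1
        for t, v in record.nihss_series
        if t <= 36.0
    )
    det4 = _deterioration_ge4(record)

    ninds = any_ich and worsening_1_36h
    ecass2 = any_ich and (det4 or record.death_within_7d)
    sits_most = ph2_in_window and (det4 or record.death_within_7d)
    return SICHVerdict(ninds=ninds, ecass2=ecass2, sits_most=sits_most)
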