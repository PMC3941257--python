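import numpy as np
import pytest

from sichscore import (
    Antiplatelet,
    GlucoseUnit,
    OCSPCategory,
    PatientProfile,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20140301)


@pytest.fixture
def full_profile():
    """Profile crossing every threshold: the maximal SITS scorer."""
    return PatientProfile(
        age=80,
        nihss_baseline=20,
        glucose=200.0,
        glucose_unit=GlucoseUnit.MGDL,
        sbp=150.0,
        weight=100.0,
        ott_minutes=185.0,
        hypertension_history=True,
        antiplatelet=Antiplatelet.ASPIRIN_PLUS_CLOPIDOGREL,
    )


@pytest.fixture
def zero_profile():
    """Profile crossing no threshold."""
    return PatientProfile(
        age=50,
        nihss_baseline=5,
        glucose=100.0,
        glucose_unit=GlucoseUnit.MGDL,
        sbp=120.0,
        weight=70.0,
        ott_minutes=90.0,
        hypertension_history=False,
        antiplatelet=Antiplatelet.NONE,
    )


def random_profile(rng, ocsp=None) -> PatientProfile:
    """Random valid profile (helper shared across test modules)."""
    return PatientProfile(
        age=int(rng.integers(18, 100)),
        nihss_baseline=int(rng.integers(0, 43)),
        glucose=float(rng.uniform(50, 400)),
        glucose_unit=GlucoseUnit.MGDL,
        sbp=float(rng.uniform(90, 220)),
        weight=float(rng.uniform(40, 140)),
        ott_minutes=float(rng.uniform(30, 270)),
        hypertension_history=bool(rng.integers(0, 2)),
        antiplatelet=list(Antiplatelet)[rng.integers(0, 3)],
        ocsp=ocsp if ocsp is not None else list(OCSPCategory)[rng.integers(0, 5)],
    )


@pytest.fixture
def make_random_profile():
    return random_profile
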