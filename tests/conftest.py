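import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from iolcalc.records import Cohort, EyeRecord

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# Biometry sampling windows for property tests: the observed ranges of a real
# cataract cohort, slightly tighter than the hard plausibility bounds.
SAMPLING_RANGES = {
    "axial_length": (20.8, 29.8),
    "mean_keratometry": (37.3, 49.7),
    "acd": (2.12, 4.54),
    "lens_thickness": (3.0, 5.8),
    "cct": (365.0, 634.0),
    "wtw": (10.2, 13.0),
}


def make_eye(
    patient_id="P1",
    eye_side="right",
    age=72.8,
    axial_length=23.92,
    mean_keratometry=44.35,
    acd=3.15,
    lens_thickness=4.63,
    cct=518.4,
    wtw=11.7,
    **optional,
) -> EyeRecord:
    return EyeRecord(
        patient_id=patient_id,
        eye_side=eye_side,
        age=age,
        axial_length=axial_length,
        mean_keratometry=mean_keratometry,
        acd=acd,
        lens_thickness=lens_thickness,
        cct=cct,
        wtw=wtw,
        **optional,
    )


@pytest.fixture
def mean_eye() -> EyeRecord:
    """The mean training-profile eye with a 20 D implant."""
    return make_eye(iol_power=20.0)


def random_biometry(n: int, seed: int) -> dict[str, np.ndarray]:
    """Uniform in-window biometry draws for property checks."""
    rng = np.random.default_rng(seed)
    return {
        name: rng.uniform(lo, hi, size=n) for name, (lo, hi) in SAMPLING_RANGES.items()
    }


def cohort_from_arrays(bio: dict[str, np.ndarray], iol_power=None, postop_mrse=None) -> Cohort:
    n = len(next(iter(bio.values())))
    records = []
    for i in range(n):
        records.append(
            make_eye(
                patient_id=f"P{i:04d}",
                **{k: float(v[i]) for k, v in bio.items()},
                iol_power=None if iol_power is None else float(iol_power[i]),
                postop_mrse=None if postop_mrse is None else float(postop_mrse[i]),
            )
        )
    return Cohort(records=tuple(records), label="test")
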