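"""Synthetic biometry cohorts with surgical outcomes.

The generator emulates the statistical shape of a real single-site cataract
cohort: correlated ocular biometry drawn from a truncated multivariate
normal whose marginals match the reference demographic profile, a surgeon
choosing the implanted power from the commercial half-diopter grid for a
slightly myopic target, and a postoperative refraction equal to the
truth-formula prediction plus optional biometry-dependent systematic bias, a
patient-level shared effect (fellow eyes correlate), and independent
Gaussian noise. Everything is deterministic under the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .formulas import (
    HaigisConstants,
    SRKTConstants,
    haigis_refraction_array,
    srkt_refraction_array,
)
from .records import Cohort, EyeRecord
from .reference import TRAINING_PROFILE, ParameterSummary

__all__ = [
    "BIOMETRY_PARAMS",
    "DEFAULT_CORRELATIONS",
    "CohortSpec",
    "SpecError",
    "generate_cohort",
    "inject_bias",
]

# Order of the correlated biometry block.
BIOMETRY_PARAMS = ("axial_length", "mean_keratometry", "acd", "lens_thickness", "cct", "wtw")


class SpecError(ValueError):
    """The cohort specification is internally inconsistent."""


def _default_moments() -> dict[str, ParameterSummary]:
    return {p: TRAINING_PROFILE[p] for p in BIOMETRY_PARAMS + ("age",)}


def default_correlation_matrix() -> np.ndarray:
    """Literature-typical biometry correlations: longer eyes have deeper
    chambers, flatter corneas and thinner lenses; deep chambers go with thin
    lenses. All other pairs are left uncorrelated."""
    corr = np.eye(len(BIOMETRY_PARAMS))
    pairs = {
        ("axial_length", "acd"): 0.4,
        ("axial_length", "mean_keratometry"): -0.3,
        ("axial_length", "lens_thickness"): -0.3,
        ("acd", "lens_thickness"): -0.5,
    }
    idx = {p: i for i, p in enumerate(BIOMETRY_PARAMS)}
    for (a, b), rho in pairs.items():
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
    return corr


DEFAULT_CORRELATIONS = default_correlation_matrix()


@dataclass(frozen=True)
class CohortSpec:
    """Conditions of a simulated cohort.

    ``truth_model`` ("srkt" or "haigis") with ``truth_constants`` defines the
    outcome-generating optics; ``bias_spec`` maps biometry parameter names to
    a systematic error slope in D per unit of (parameter − reference mean);
    ``noise_sd`` is the per-eye outcome noise and ``patient_effect_sd`` a
    shared per-patient effect inducing inter-eye correlation.
    """

    n_patients: int = 800
    bilateral_fraction: float = 0.38
    biometry_moments: dict = field(default_factory=_default_moments)
    correlation_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_CORRELATIONS.copy()
    )
    truth_model: str = "srkt"
    truth_constants: object = field(default_factory=lambda: SRKTConstants(119.0))
    target_refraction: float = -0.20
    bias_spec: dict | None = None
    noise_sd: float = 0.35
    patient_effect_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise SpecError("n_patients must be positive")
        if not (0.0 <= self.bilateral_fraction <= 1.0):
            raise SpecError("bilateral_fraction must be in [0, 1]")
        if self.noise_sd < 0 or self.patient_effect_sd < 0:
            raise SpecError("noise SDs must be non-negative")
        for name, m in self.biometry_moments.items():
            if m.minimum > m.maximum:
                raise SpecError(f"{name}: min {m.minimum} > max {m.maximum}")
        corr = np.asarray(self.correlation_matrix, dtype=float)
        if corr.shape != (len(BIOMETRY_PARAMS),) * 2 or not np.allclose(corr, corr.T):
            raise SpecError("correlation matrix must be symmetric over the 6 biometry parameters")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise SpecError("correlation matrix must be positive semi-definite")
        if self.truth_model not in ("srkt", "haigis"):
            raise SpecError(f"unknown truth model {self.truth_model!r}")
        if self.bias_spec:
            unknown = set(self.bias_spec) - set(BIOMETRY_PARAMS)
            if unknown:
                raise SpecError(f"bias_spec names unknown parameter(s): {sorted(unknown)}")


def _sample_biometry(spec: CohortSpec, n_eyes: int, rng: np.random.Generator) -> np.ndarray:
    """Truncated correlated normal draws, resampling out-of-range eyes."""
    moments = [spec.biometry_moments[p] for p in BIOMETRY_PARAMS]
    means = np.array([m.mean for m in moments])
    sds = np.array([m.sd for m in moments])
    lows = np.array([m.minimum for m in moments])
    highs = np.array([m.maximum for m in moments])
    chol = np.linalg.cholesky(
        np.asarray(spec.correlation_matrix, float) + 1e-12 * np.eye(len(BIOMETRY_PARAMS))
    )

    out = np.empty((n_eyes, len(BIOMETRY_PARAMS)))
    for i in range(n_eyes):
        for _ in range(100):
            z = rng.standard_normal(len(BIOMETRY_PARAMS))
            x = means + sds * (chol @ z)
            if np.all((x >= lows) & (x <= highs)):
                out[i] = x
                break
        else:
            raise SpecError(
                "could not draw in-range biometry in 100 attempts; "
                "check moments against their ranges"
            )
    return out


def _truth_refraction(spec: CohortSpec, bio: np.ndarray, powers) -> np.ndarray:
    L, K, acd = bio[:, 0], bio[:, 1], bio[:, 2]
    if spec.truth_model == "srkt":
        return srkt_refraction_array(L, K, spec.truth_constants.a_constant, powers)
    return haigis_refraction_array(L, K, acd, spec.truth_constants, powers)


def _select_powers(spec: CohortSpec, bio: np.ndarray) -> np.ndarray:
    """Closest half-diopter grid power to the refractive target per eye,
    ties toward the higher (more myopic) power."""
    grid = 6.0 + 0.5 * np.arange(49)
    L, K, acd = bio[:, 0:1], bio[:, 1:2], bio[:, 2:3]
    if spec.truth_model == "srkt":
        preds = srkt_refraction_array(L, K, spec.truth_constants.a_constant, grid[None, :])
    else:
        preds = haigis_refraction_array(L, K, acd, spec.truth_constants, grid[None, :])
    dist = np.abs(preds - spec.target_refraction)
    near = dist <= dist.min(axis=1, keepdims=True) + 1e-12
    # argmax on reversed columns returns the highest qualifying power
    rev_idx = near.shape[1] - 1 - np.argmax(near[:, ::-1], axis=1)
    return grid[rev_idx]


def generate_cohort(spec: CohortSpec, label: str = "synthetic") -> Cohort:
    """Draw a full cohort (biometry, implanted powers, outcomes) from a spec."""
    rng = np.random.default_rng(spec.seed)
    moments = spec.biometry_moments

    n_eyes_per_patient = (rng.random(spec.n_patients) < spec.bilateral_fraction) + 1
    n_eyes = int(n_eyes_per_patient.sum())
    bio = _sample_biometry(spec, n_eyes, rng)

    age_m = moments["age"]
    ages = np.clip(
        age_m.mean + age_m.sd * rng.standard_normal(spec.n_patients),
        age_m.minimum,
        age_m.maximum,
    )
    patient_effects = spec.patient_effect_sd * rng.standard_normal(spec.n_patients)

    powers = _select_powers(spec, bio)
    truth_ref = _truth_refraction(spec, bio, powers)

    bias = np.zeros(n_eyes)
    if spec.bias_spec:
        idx = {p: i for i, p in enumerate(BIOMETRY_PARAMS)}
        for name, coef in spec.bias_spec.items():
            bias += coef * (bio[:, idx[name]] - moments[name].mean)

    noise = spec.noise_sd * rng.standard_normal(n_eyes)

    records = []
    eye = 0
    for p in range(spec.n_patients):
        sides = ("right",) if n_eyes_per_patient[p] == 1 else ("right", "left")
        for side in sides:
            mrse = truth_ref[eye] + bias[eye] + patient_effects[p] + noise[eye]
            records.append(
                EyeRecord(
                    patient_id=f"P{p:05d}",
                    eye_side=side,
                    age=float(ages[p]),
                    axial_length=float(bio[eye, 0]),
                    mean_keratometry=float(bio[eye, 1]),
                    acd=float(bio[eye, 2]),
                    lens_thickness=float(bio[eye, 3]),
                    cct=float(bio[eye, 4]),
                    wtw=float(bio[eye, 5]),
                    iol_power=float(powers[eye]),
                    postop_mrse=float(np.clip(mrse, -15.0, 5.0)),
                )
            )
            eye += 1
    return Cohort(records=tuple(records), label=label)


def inject_bias(cohort: Cohort, bias_spec: dict, seed: int | None = None) -> Cohort:
    """Shift each eye's observed refraction by a linear function of biometry.

    The shift is ``sum_k coef_k * (parameter_k − reference_mean_k)`` with
    reference means from the reference demographic profile. Deterministic;
    ``seed`` is accepted for signature stability but unused.
    """
    unknown = set(bias_spec) - set(BIOMETRY_PARAMS)
    if unknown:
        raise SpecError(f"bias_spec names unknown parameter(s): {sorted(unknown)}")
    shifted = []
    for rec in cohort:
        if rec.postop_mrse is None:
            raise ValueError(f"record {rec.key} has no postop_mrse to bias")
        delta = sum(
            coef * (getattr(rec, name) - TRAINING_PROFILE[name].mean)
            for name, coef in bias_spec.items()
        )
        shifted.append(replace(rec, postop_mrse=rec.postop_mrse + delta))
    return Cohort(records=tuple(shifted), label=cohort.label)
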