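"""Cohort adaptation of SRK/T by support vector regression.

The adapted calculator refines the SRK/T predicted refraction for a
particular patient population. Its six inputs are the SRK/T prediction
itself plus the raw biometry (axial length, mean keratometry, anterior
chamber depth, lens thickness, white-to-white); the regression target is the
observed postoperative refraction, so the model output *is* the refined
predicted refraction. An epsilon-insensitive RBF-kernel SVR is trained with
a (C, gamma) grid search under patient-grouped k-fold cross-validation:
both eyes of a patient always share a fold, since fellow eyes are correlated
and splitting them across folds makes cross-validation optimistic.

Features are z-scored on training statistics (an RBF kernel mixing
millimeter and diopter scales is meaningless without it). Prediction is an
explicit kernel expansion over the stored support vectors, so a serialized
model reloads to bit-identical predictions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.svm import SVR

from .formulas import SRKTConstants, srkt_refraction_array
from .records import Cohort, EyeRecord

__all__ = [
    "FEATURE_NAMES",
    "HyperparameterGrid",
    "AdaptedCalculator",
    "ExtrapolationWarning",
    "build_features",
    "train_adapted_calculator",
    "adapted_predict_refraction",
    "save_model",
    "load_model",
]

FEATURE_NAMES = ("srkt_pred", "axial_length", "mean_k", "acd", "lens_thickness", "wtw")

MODEL_FORMAT = "iolcalc-adapted-v1"


class ExtrapolationWarning(UserWarning):
    """A feature lies far outside the training distribution (> 6 SDs)."""


@dataclass(frozen=True)
class HyperparameterGrid:
    """Grid-search space for the SVR: regularization C, kernel shape gamma,
    and the fixed epsilon tube half-width (D). The default epsilon of 0.1 D
    is below clinical refraction resolution (0.25 D steps)."""

    c_values: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gamma_values: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0)
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if not self.c_values or not self.gamma_values:
            raise ValueError("hyperparameter grid must be non-empty")
        if any(c <= 0 for c in self.c_values) or any(g <= 0 for g in self.gamma_values):
            raise ValueError("C and gamma values must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")


@dataclass(frozen=True)
class AdaptedCalculator:
    """Trained state of the adapted calculator.

    ``support_vectors`` are stored in standardized feature space;
    prediction is ``f(x) = sum_i alpha_i * exp(-gamma * ||x_i - z||^2) + b``
    where z is the standardized feature vector of the query eye.
    """

    base_a_constant: SRKTConstants
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    chosen_c: float
    chosen_gamma: float
    epsilon: float
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    cv_table: dict = field(default_factory=dict)
    n_train: int = 0
    seed: int | None = None

    def predict(self, eye: EyeRecord, iol_power: float) -> float:
        return adapted_predict_refraction(self, eye, iol_power)


def build_features(eye: EyeRecord, a_constant: SRKTConstants, iol_power: float) -> np.ndarray:
    """Six-entry feature vector ``(srkt_pred, L, K, ACD, LT, WTW)``.

    Central corneal thickness and age are deliberately not inputs of the
    adapted calculator.
    """
    srkt_pred = float(
        srkt_refraction_array(
            eye.axial_length, eye.mean_keratometry, a_constant.a_constant, iol_power
        )
    )
    return np.array(
        [
            srkt_pred,
            eye.axial_length,
            eye.mean_keratometry,
            eye.acd,
            eye.lens_thickness,
            eye.wtw,
        ]
    )


def _feature_matrix(cohort: Cohort, a_constant: SRKTConstants) -> np.ndarray:
    return np.vstack([build_features(r, a_constant, r.iol_power) for r in cohort])


def _patient_folds(patient_ids: list[str], order: list[str], n_folds: int, seed: int):
    """Deterministic patient-grouped fold assignment: shuffle distinct
    patients under ``seed``, deal them round-robin into folds, and return a
    per-record fold index array."""
    rng = np.random.default_rng(seed)
    shuffled = list(np.array(order, dtype=object)[rng.permutation(len(order))])
    fold_of_patient = {pid: i % n_folds for i, pid in enumerate(shuffled)}
    return np.array([fold_of_patient[pid] for pid in patient_ids])


def train_adapted_calculator(
    train: Cohort,
    a_constant: SRKTConstants,
    grid: HyperparameterGrid | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> AdaptedCalculator:
    """Grid-search, cross-validate and fit the adapted calculator.

    For every (C, gamma) pair the patient-grouped ``cv_folds``-fold mean
    squared error is computed; the minimizing pair (ties broken toward the
    smaller C, then the smaller gamma) is refit on the full training cohort.
    """
    grid = grid if grid is not None else HyperparameterGrid()
    if any(r.iol_power is None or r.postop_mrse is None for r in train):
        raise ValueError("all training records need iol_power and postop_mrse")
    n = len(train)
    if n < cv_folds:
        raise ValueError(f"{n} records but {cv_folds} folds requested")

    X_raw = _feature_matrix(train, a_constant)
    y = train.column("postop_mrse")

    mean = X_raw.mean(axis=0)
    scale = X_raw.std(axis=0)  # population SD, the usual z-scoring convention
    # constant columns yield a numerically-zero SD (rounding of the mean
    # subtraction), so the degeneracy test is relative
    degenerate = np.flatnonzero(scale <= 1e-10 * np.maximum(1.0, np.abs(mean)))
    if degenerate.size:
        names = ", ".join(FEATURE_NAMES[i] for i in degenerate)
        raise ValueError(f"zero-variance feature(s) cannot be standardized: {names}")
    X = (X_raw - mean) / scale

    record_pids = [r.patient_id for r in train]
    folds = _patient_folds(record_pids, train.patient_ids, cv_folds, seed)

    cv_table: dict[tuple[float, float], float] = {}
    best: tuple[float, tuple[float, float]] | None = None
    for c, g in product(sorted(grid.c_values), sorted(grid.gamma_values)):
        fold_mse = []
        for k in range(cv_folds):
            held = folds == k
            if not held.any() or held.all():
                continue
            svr = SVR(kernel="rbf", C=c, gamma=g, epsilon=grid.epsilon)
            svr.fit(X[~held], y[~held])
            resid = y[held] - svr.predict(X[held])
            fold_mse.append(float(np.mean(resid**2)))
        loss = float(np.mean(fold_mse))
        cv_table[(c, g)] = loss
        if best is None or loss < best[0]:
            best = (loss, (c, g))

    chosen_c, chosen_gamma = best[1]
    svr = SVR(kernel="rbf", C=chosen_c, gamma=chosen_gamma, epsilon=grid.epsilon)
    svr.fit(X, y)

    return AdaptedCalculator(
        base_a_constant=a_constant,
        feature_mean=mean,
        feature_scale=scale,
        chosen_c=chosen_c,
        chosen_gamma=chosen_gamma,
        epsilon=grid.epsilon,
        support_vectors=np.array(svr.support_vectors_, dtype=float),
        dual_coef=np.array(svr.dual_coef_[0], dtype=float),
        intercept=float(svr.intercept_[0]),
        cv_table=cv_table,
        n_train=n,
        seed=seed,
    )


def adapted_predict_refraction(
    model: AdaptedCalculator, eye: EyeRecord, iol_power: float
) -> float:
    """Refined predicted refraction (D) for ``eye`` at ``iol_power``.

    Deterministic kernel expansion over the stored support vectors. If any
    standardized feature is more than 6 training SDs from the training mean,
    an :class:`ExtrapolationWarning` is emitted but the value is still
    returned.
    """
    x = build_features(eye, model.base_a_constant, iol_power)
    z = (x - model.feature_mean) / model.feature_scale
    far = np.abs(z) > 6.0
    if far.any():
        names = ", ".join(FEATURE_NAMES[i] for i in np.flatnonzero(far))
        warnings.warn(
            f"feature(s) {names} are > 6 training SDs from the training mean; "
            "the adapted prediction is an extrapolation",
            ExtrapolationWarning,
            stacklevel=2,
        )
    sq = np.sum((model.support_vectors - z) ** 2, axis=1)
    return float(model.dual_coef @ np.exp(-model.chosen_gamma * sq) + model.intercept)


def save_model(model: AdaptedCalculator, path) -> None:
    """Serialize a trained calculator to a single versioned JSON file.

    Floats are written at full repr precision, so a reloaded model gives
    bit-identical predictions.
    """
    doc = {
        "format": MODEL_FORMAT,
        "base_a_constant": model.base_a_constant.a_constant,
        "feature_names": list(FEATURE_NAMES),
        "feature_mean": model.feature_mean.tolist(),
        "feature_scale": model.feature_scale.tolist(),
        "chosen_c": model.chosen_c,
        "chosen_gamma": model.chosen_gamma,
        "epsilon": model.epsilon,
        "support_vectors": model.support_vectors.tolist(),
        "dual_coef": model.dual_coef.tolist(),
        "intercept": model.intercept,
        "cv_table": [[c, g, loss] for (c, g), loss in sorted(model.cv_table.items())],
        "n_train": model.n_train,
        "seed": model.seed,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> AdaptedCalculator:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("format") != MODEL_FORMAT:
        raise ValueError(f"unrecognized model format {doc.get('format')!r}")
    return AdaptedCalculator(
        base_a_constant=SRKTConstants(a_constant=doc["base_a_constant"]),
        feature_mean=np.array(doc["feature_mean"]),
        feature_scale=np.array(doc["feature_scale"]),
        chosen_c=doc["chosen_c"],
        chosen_gamma=doc["chosen_gamma"],
        epsilon=doc["epsilon"],
        support_vectors=np.array(doc["support_vectors"]),
        dual_coef=np.array(doc["dual_coef"]),
        intercept=doc["intercept"],
        cv_table={(c, g): loss for c, g, loss in doc["cv_table"]},
        n_train=doc["n_train"],
        seed=doc["seed"],
    )
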