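"""Per-eye biometry records, cohort container, CSV I/O, eligibility filter and
the train/validation split.

A cohort is an ordered list of :class:`EyeRecord`, one per operated eye. Both
eyes of a patient may appear (distinguished by ``eye_side``); downstream code
that must avoid inter-eye leakage (cross-validation folds, the validation
split) groups on ``patient_id``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger("iolcalc")

__all__ = [
    "EyeRecord",
    "Cohort",
    "SchemaError",
    "ParseError",
    "ValidationError",
    "read_biometry_table",
    "write_biometry_table",
    "filter_eligible",
    "split_train_validation",
]


class SchemaError(ValueError):
    """A mandatory column is missing from a biometry table."""


class ParseError(ValueError):
    """A cell in a biometry table could not be parsed as a number."""


class ValidationError(ValueError):
    """A record violates the biometric plausibility window."""


# Hard plausibility bounds (a superset of what a normal cataract cohort spans).
PLAUSIBILITY_WINDOW = {
    "axial_length": (18.0, 36.0),     # mm
    "mean_keratometry": (30.0, 55.0),  # D
    "acd": (1.5, 5.5),                # mm
    "lens_thickness": (2.5, 7.0),     # mm
    "cct": (300.0, 700.0),            # um
    "wtw": (9.0, 14.0),               # mm
}

EYE_SIDES = ("right", "left")


@dataclass(frozen=True)
class EyeRecord:
    """One eye's preoperative biometry and, when available, the implanted IOL
    power and observed postoperative refraction.

    Units: ``axial_length``, ``acd``, ``lens_thickness``, ``wtw`` in mm;
    ``mean_keratometry`` in diopters; ``cct`` in micrometers; ``iol_power``
    and ``postop_mrse`` in diopters; ``cdva_decimal`` is decimal visual
    acuity (Snellen 16/20 == 0.8).
    """

    patient_id: str
    eye_side: str
    age: float
    axial_length: float
    mean_keratometry: float
    acd: float
    lens_thickness: float
    cct: float
    wtw: float
    cdva_decimal: float | None = None
    iol_power: float | None = None
    postop_mrse: float | None = None

    def __post_init__(self) -> None:
        problems = []
        if self.eye_side not in EYE_SIDES:
            problems.append(f"eye_side={self.eye_side!r} (must be one of {EYE_SIDES})")
        for name, (lo, hi) in PLAUSIBILITY_WINDOW.items():
            value = getattr(self, name)
            if not (lo <= value <= hi):
                problems.append(f"{name}={value} outside [{lo}, {hi}]")
        if self.iol_power is not None:
            p = self.iol_power
            if not (-5.0 <= p <= 40.0) or abs(p * 2 - round(p * 2)) > 1e-9:
                problems.append(f"iol_power={p} (must be a multiple of 0.5 D in [-5, 40])")
        if self.postop_mrse is not None and not (-15.0 <= self.postop_mrse <= 5.0):
            problems.append(f"postop_mrse={self.postop_mrse} outside [-15, +5]")
        if problems:
            raise ValidationError(
                f"invalid record for patient {self.patient_id!r} ({self.eye_side}): "
                + "; ".join(problems)
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.patient_id, self.eye_side)


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of eye records with unique (patient, side) keys."""

    records: tuple[EyeRecord, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            if rec.key in seen:
                raise ValidationError(f"duplicate eye {rec.key} in cohort {self.label!r}")
            seen.add(rec.key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[EyeRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> EyeRecord:
        return self.records[i]

    @property
    def patient_ids(self) -> list[str]:
        """Distinct patient ids in order of first appearance."""
        out: list[str] = []
        seen: set[str] = set()
        for rec in self.records:
            if rec.patient_id not in seen:
                seen.add(rec.patient_id)
                out.append(rec.patient_id)
        return out

    def column(self, name: str) -> np.ndarray:
        """Field values across records as a float array (None -> NaN)."""
        vals = [getattr(r, name) for r in self.records]
        return np.array([np.nan if v is None else float(v) for v in vals])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            rows.append({csv_col: getattr(rec, attr) for csv_col, attr in _COLUMN_MAP.items()})
        return pd.DataFrame(rows, columns=list(_COLUMN_MAP))


# CSV column name -> EyeRecord attribute, in file order.
_COLUMN_MAP = {
    "patient_id": "patient_id",
    "eye_side": "eye_side",
    "age": "age",
    "axial_length_mm": "axial_length",
    "mean_k_d": "mean_keratometry",
    "acd_mm": "acd",
    "lt_mm": "lens_thickness",
    "cct_um": "cct",
    "wtw_mm": "wtw",
    "iol_power_d": "iol_power",
    "postop_mrse_d": "postop_mrse",
    "cdva_decimal": "cdva_decimal",
}
_MANDATORY = [c for c in _COLUMN_MAP if c not in ("iol_power_d", "postop_mrse_d", "cdva_decimal")]
_OPTIONAL = ["iol_power_d", "postop_mrse_d", "cdva_decimal"]


def read_biometry_table(path, label: str | None = None) -> Cohort:
    """Read a comma-separated biometry table into a :class:`Cohort`.

    The file must be UTF-8 with one header row naming at least the mandatory
    columns (``patient_id, eye_side, age, axial_length_mm, mean_k_d, acd_mm,
    lt_mm, cct_um, wtw_mm``). Optional columns (``iol_power_d,
    postop_mrse_d, cdva_decimal``) may be absent or contain empty cells.
    Row order is preserved.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    records = []
    for row_idx, (_, row) in enumerate(df.iterrows(), start=1):
        kwargs = {}
        for csv_col, attr in _COLUMN_MAP.items():
            if csv_col not in df.columns:
                continue
            raw = row[csv_col]
            blank = pd.isna(raw) or str(raw).strip() == ""
            if csv_col in ("patient_id", "eye_side"):
                if blank:
                    raise ParseError(f"row {row_idx}: empty {csv_col}")
                kwargs[attr] = str(raw).strip()
                continue
            if blank:
                if csv_col in _OPTIONAL:
                    continue
                raise ParseError(f"row {row_idx}: empty mandatory cell {csv_col}")
            try:
                kwargs[attr] = float(raw)
            except ValueError:
                raise ParseError(
                    f"row {row_idx}: could not parse {csv_col}={str(raw).strip()!r} as a number"
                ) from None
        records.append(EyeRecord(**kwargs))
    return Cohort(records=tuple(records), label=label if label is not None else str(path))


def write_biometry_table(cohort: Cohort, path) -> None:
    """Write a cohort in the CSV dialect that :func:`read_biometry_table` reads."""
    cohort.to_dataframe().to_csv(path, index=False)


def filter_eligible(cohort: Cohort, min_cdva: float = 0.8) -> Cohort:
    """Drop eyes whose corrected distance visual acuity is below ``min_cdva``.

    The default 0.8 decimal acuity is Snellen 16/20. Records with no recorded
    acuity are kept (a warning is logged), so cohorts without acuity data —
    synthetic cohorts in particular — pass through unchanged.
    """
    if not min_cdva > 0:
        raise ValueError("min_cdva must be positive")
    kept = []
    n_unset = 0
    for rec in cohort:
        if rec.cdva_decimal is None:
            n_unset += 1
            kept.append(rec)
        elif rec.cdva_decimal >= min_cdva:
            kept.append(rec)
    if n_unset:
        logger.warning(
            "filter_eligible: %d/%d records have no CDVA; treated as eligible",
            n_unset,
            len(cohort),
        )
    return Cohort(records=tuple(kept), label=cohort.label)


def split_train_validation(
    cohort: Cohort,
    n_validation_patients: int,
    seed: int,
    strict: bool = False,
) -> tuple[Cohort, Cohort]:
    """Randomly assign one eye each of ``n_validation_patients`` patients to a
    validation cohort; everything else forms the training cohort.

    For a bilateral patient chosen for validation, one eye is picked uniformly
    and the fellow eye goes to the training set (so the split partitions the
    cohort). With ``strict=True`` the fellow eye is dropped from both sets,
    which removes any between-set sharing of patients at the cost of training
    data. Deterministic under ``seed``.

    Returns ``(train, validation)``.
    """
    patients = cohort.patient_ids
    if n_validation_patients > len(patients):
        raise ValueError(
            f"n_validation_patients={n_validation_patients} exceeds "
            f"{len(patients)} distinct patients"
        )
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(len(patients), size=n_validation_patients, replace=False).tolist())
    chosen_ids = {patients[i] for i in chosen}

    by_patient: dict[str, list[EyeRecord]] = {}
    for rec in cohort:
        by_patient.setdefault(rec.patient_id, []).append(rec)

    validation_keys: set[tuple[str, str]] = set()
    dropped_keys: set[tuple[str, str]] = set()
    # Draw per-patient eye choices in patient order so the stream is stable.
    for pid in patients:
        if pid not in chosen_ids:
            continue
        eyes = by_patient[pid]
        pick = eyes[0] if len(eyes) == 1 else eyes[int(rng.integers(len(eyes)))]
        validation_keys.add(pick.key)
        if strict:
            dropped_keys.update(e.key for e in eyes if e.key != pick.key)

    train = [r for r in cohort if r.key not in validation_keys and r.key not in dropped_keys]
    valid = [r for r in cohort if r.key in validation_keys]
    return (
        Cohort(records=tuple(train), label=f"{cohort.label}/train"),
        Cohort(records=tuple(valid), label=f"{cohort.label}/validation"),
    )
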