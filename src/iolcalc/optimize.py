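"""Lens-constant optimization on a training cohort.

Conventionally a surgeon "personalizes" lens constants so that the mean
signed prediction error over their own operated eyes is zero. For SRK/T this
is a one-dimensional root find over the A-constant (mean error is monotone
in A). For Haigis, each eye's zero-error effective lens position is
back-solved from the observed refraction and the (a0, a1, a2) triple is the
ordinary least-squares fit of that ELP on anterior chamber depth and axial
length — the procedure Haigis published for constant personalization.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
from scipy import optimize as sp_optimize

from .formulas import (
    HaigisConstants,
    SRKTConstants,
    haigis_backsolve_elp_array,
    haigis_refraction_array,
    srkt_refraction_array,
)
from .records import Cohort

logger = logging.getLogger("iolcalc")

__all__ = [
    "OptimizationReport",
    "OptimizationInfeasibleError",
    "DegenerateCohortError",
    "prediction_error",
    "optimize_a_constant",
    "optimize_haigis_constants",
    "report_to_json",
]


class OptimizationInfeasibleError(RuntimeError):
    """The optimization criterion has no solution in the search bracket."""


class DegenerateCohortError(ValueError):
    """The training cohort cannot identify the constants (too small/collinear)."""


@dataclass(frozen=True)
class OptimizationReport:
    """Outcome of a constant optimization run."""

    constants: SRKTConstants | HaigisConstants
    n_used: int
    n_skipped: int
    mean_pe_after: float
    iterations: int


def prediction_error(observed_mrse, predicted_refraction):
    """Signed prediction error PE = observed − predicted (D).

    Positive PE means the eye ended up more hyperopic than predicted.
    """
    return np.asarray(observed_mrse, float) - np.asarray(predicted_refraction, float)


def _training_arrays(train: Cohort):
    missing = [r.key for r in train if r.iol_power is None or r.postop_mrse is None]
    if missing:
        raise ValueError(
            f"{len(missing)} training record(s) lack iol_power or postop_mrse "
            f"(first: {missing[0]})"
        )
    return (
        train.column("axial_length"),
        train.column("mean_keratometry"),
        train.column("acd"),
        train.column("iol_power"),
        train.column("postop_mrse"),
    )


def optimize_a_constant(
    train: Cohort,
    bracket: tuple[float, float] = (110.0, 126.0),
    tol: float = 1e-4,
) -> OptimizationReport:
    """A-constant at which the cohort's mean signed SRK/T error is zero.

    Bracketed root finding over ``bracket``; the mean error is monotone in A
    (a larger A predicts a deeper lens position, hence a more hyperopic
    refraction at fixed power), so the root is unique.
    """
    L, K, _, P, mrse = _training_arrays(train)
    n = len(train)
    if n < 30:
        logger.warning("optimize_a_constant: only %d records (< 30); estimate will be noisy", n)

    def mean_pe(a: float) -> float:
        return float(np.mean(mrse - srkt_refraction_array(L, K, a, P)))

    f_lo, f_hi = mean_pe(bracket[0]), mean_pe(bracket[1])
    if np.sign(f_lo) == np.sign(f_hi):
        raise OptimizationInfeasibleError(
            f"mean prediction error does not change sign over A in {bracket}: "
            f"{f_lo:+.4f} D at A={bracket[0]}, {f_hi:+.4f} D at A={bracket[1]}"
        )
    a_star, result = sp_optimize.brentq(
        mean_pe, bracket[0], bracket[1], xtol=1e-8, full_output=True
    )
    residual = mean_pe(a_star)
    if abs(residual) > tol:
        raise OptimizationInfeasibleError(
            f"root finder converged to A={a_star:.4f} but |mean PE|={abs(residual):.2e} > {tol}"
        )
    return OptimizationReport(
        constants=SRKTConstants(a_constant=float(a_star)),
        n_used=n,
        n_skipped=0,
        mean_pe_after=residual,
        iterations=int(result.iterations),
    )


def optimize_haigis_constants(train: Cohort) -> OptimizationReport:
    """Fit the Haigis (a0, a1, a2) triple on a training cohort.

    Per eye, the effective lens position that exactly reproduces the observed
    refraction is back-solved; the triple is the OLS fit of that ELP on
    (1, ACD, L). Eyes whose observed refraction is not attainable at any ELP
    are skipped and counted. ``mean_pe_after`` is the cohort mean signed
    refraction error under the fitted triple; OLS zeroes the mean ELP
    residual, not the mean refraction residual, so it is near—but not
    exactly—zero.
    """
    L, K, acd, P, mrse = _training_arrays(train)
    d_star = haigis_backsolve_elp_array(L, K, P, mrse)
    ok = np.isfinite(d_star)
    n_skipped = int(np.sum(~ok))
    if n_skipped:
        logger.warning("optimize_haigis_constants: skipped %d infeasible record(s)", n_skipped)
    n_used = int(np.sum(ok))
    if n_used < 3:
        raise DegenerateCohortError(
            f"only {n_used} usable record(s); at least 3 are needed for (a0, a1, a2)"
        )
    X = np.column_stack([np.ones(n_used), acd[ok], L[ok]])
    if np.linalg.matrix_rank(X) < 3:
        raise DegenerateCohortError(
            "design matrix (1, ACD, L) is rank-deficient; cohort cannot identify the triple"
        )
    coefs, _, _, _ = np.linalg.lstsq(X, d_star[ok], rcond=None)
    constants = HaigisConstants(a0=float(coefs[0]), a1=float(coefs[1]), a2=float(coefs[2]))
    preds = haigis_refraction_array(L[ok], K[ok], acd[ok], constants, P[ok])
    return OptimizationReport(
        constants=constants,
        n_used=n_used,
        n_skipped=n_skipped,
        mean_pe_after=float(np.mean(mrse[ok] - preds)),
        iterations=1,
    )


def report_to_json(report: OptimizationReport, label: str = "", seed: int | None = None) -> str:
    """Serialize an optimization report (plus provenance) as a JSON document."""
    doc = {
        "format": "iolcalc-constants-v1",
        "constants": asdict(report.constants),
        "formula": "srkt" if isinstance(report.constants, SRKTConstants) else "haigis",
        "n_used": report.n_used,
        "n_skipped": report.n_skipped,
        "mean_pe_after_d": report.mean_pe_after,
        "iterations": report.iterations,
        "cohort_label": label,
        "seed": seed,
    }
    return json.dumps(doc, indent=2, sort_keys=True)
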