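"""SRK/T and Haigis vergence formulas.

Both formulas convert corneal power, axial length and an estimate of the
postoperative (effective) lens position into the spectacle-plane refraction
expected for a given IOL power. They differ in how the effective lens
position (ELP) is predicted: SRK/T derives it from corneal height and the
lens-specific A-constant; Haigis uses a linear model
``d = a0 + a1*ACD + a2*L`` with three lens-specific constants.

Scalar entry points take an :class:`~iolcalc.records.EyeRecord`; the
``*_array`` functions are the vectorized cores used by cohort-level
operations (constant optimization, synthetic cohort generation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .records import EyeRecord

__all__ = [
    "SRKTConstants",
    "HaigisConstants",
    "OpticalConstants",
    "SRKTWorkings",
    "HaigisWorkings",
    "CornealHeightClampWarning",
    "InfeasibleRecordError",
    "srkt_predict_refraction",
    "srkt_emmetropia_power",
    "haigis_predict_refraction",
    "haigis_backsolve_elp",
    "power_for_target_refraction",
    "srkt_refraction_array",
    "srkt_emmetropia_power_array",
    "haigis_refraction_array",
    "haigis_refraction_at_elp_array",
    "haigis_backsolve_elp_array",
]


class CornealHeightClampWarning(UserWarning):
    """The SRK/T corneal-height square root was clamped (H set to r)."""


class InfeasibleRecordError(ValueError):
    """No effective lens position can reproduce the observed refraction."""


@dataclass(frozen=True)
class SRKTConstants:
    """SRK/T lens constant (the manufacturer A-constant)."""

    a_constant: float

    def __post_init__(self) -> None:
        if not (110.0 <= self.a_constant <= 126.0):
            raise ValueError(f"A-constant {self.a_constant} outside [110, 126]")


@dataclass(frozen=True)
class HaigisConstants:
    """Haigis ELP model ``d = a0 + a1*ACD + a2*L`` (d, a0 in mm)."""

    a0: float
    a1: float
    a2: float

    def elp(self, acd: float, axial_length: float) -> float:
        return self.a0 + self.a1 * acd + self.a2 * axial_length


@dataclass(frozen=True)
class OpticalConstants:
    """Fixed optical constants of the published formulas.

    ``n_aqueous`` is the aqueous/vitreous refractive index used in both
    vergence chains; SRK/T uses a fictitious corneal index of 1.333
    (stored as the index minus one) while Haigis uses 1.3315 on the same
    keratometric radius r = 337.5/K. Vertex distance is the spectacle
    plane to cornea distance.
    """

    n_aqueous: float = 1.336
    n_cornea_srkt_minus1: float = 0.333
    keratometric_index_numerator: float = 337.5
    n_cornea_haigis: float = 1.3315
    vertex_distance_mm: float = 12.0


DEFAULT_OPTICS = OpticalConstants()


@dataclass(frozen=True)
class SRKTWorkings:
    """Intermediate quantities of the SRK/T chain (all lengths in mm)."""

    corneal_radius: float
    lcor: float
    corneal_width: float
    corneal_height: float
    acd_const: float
    offset: float
    elp: float
    retthick: float
    lopt: float
    clamped: bool


@dataclass(frozen=True)
class HaigisWorkings:
    """Intermediate quantities of the Haigis vergence chain."""

    corneal_power: float
    elp: float
    refraction_corneal_plane: float
    target_vergence: float


# ---------------------------------------------------------------------------
# SRK/T
# ---------------------------------------------------------------------------

def _srkt_chain(L, K, a_constant, optics: OpticalConstants = DEFAULT_OPTICS):
    """Vectorized SRK/T geometry: returns (r, elp, lopt, workings dict)."""
    L = np.asarray(L, dtype=float)
    K = np.asarray(K, dtype=float)
    r = optics.keratometric_index_numerator / K
    lcor = np.where(L <= 24.2, L, -3.446 + 1.715 * L - 0.0237 * L**2)
    cw = -5.41 + 0.58412 * lcor + 0.098 * K
    disc = r**2 - (cw / 2.0) ** 2
    clamped = disc < 0.0
    if np.any(clamped):
        warnings.warn(
            "SRK/T corneal height clamped to the corneal radius for "
            f"{int(np.sum(clamped))} eye(s)",
            CornealHeightClampWarning,
            stacklevel=3,
        )
    h = r - np.sqrt(np.clip(disc, 0.0, None))
    acd_const = 0.62467 * a_constant - 68.747
    offset = acd_const - 3.336
    elp = h + offset
    retthick = 0.65696 - 0.02029 * L
    lopt = L + retthick
    parts = {
        "corneal_radius": r,
        "lcor": lcor,
        "corneal_width": cw,
        "corneal_height": h,
        "acd_const": acd_const,
        "offset": offset,
        "elp": elp,
        "retthick": retthick,
        "lopt": lopt,
        "clamped": clamped,
    }
    return r, elp, lopt, parts


def srkt_refraction_array(L, K, a_constant, iol_power, optics: OpticalConstants = DEFAULT_OPTICS):
    """Spectacle-plane refraction under SRK/T; broadcasts over all inputs."""
    r, elp, lopt, _ = _srkt_chain(L, K, a_constant, optics)
    na = optics.n_aqueous
    nm = optics.n_cornea_srkt_minus1
    V = optics.vertex_distance_mm
    P = np.asarray(iol_power, dtype=float)
    x1 = na * r - nm * lopt
    x2 = na * r - nm * elp
    num = 1000.0 * na * x1 - P * (lopt - elp) * x2
    den = na * (V * x1 + lopt * r) - 0.001 * P * (lopt - elp) * (V * x2 + elp * r)
    return num / den


def srkt_emmetropia_power_array(L, K, a_constant, optics: OpticalConstants = DEFAULT_OPTICS):
    """IOL power giving zero SRK/T refraction (closed form)."""
    r, elp, lopt, _ = _srkt_chain(L, K, a_constant, optics)
    na = optics.n_aqueous
    nm = optics.n_cornea_srkt_minus1
    x1 = na * r - nm * lopt
    x2 = na * r - nm * elp
    return 1000.0 * na * x1 / ((lopt - elp) * x2)


def srkt_predict_refraction(
    eye: EyeRecord,
    constants: SRKTConstants,
    iol_power: float,
    optics: OpticalConstants = DEFAULT_OPTICS,
    return_workings: bool = False,
):
    """Predicted spectacle-plane refraction (D) for ``eye`` with ``iol_power``.

    Strictly decreasing in IOL power: a stronger lens leaves the eye more
    myopic. If the corneal-width chord exceeds the corneal diameter the
    published convention of clamping corneal height to the radius is applied
    and a :class:`CornealHeightClampWarning` is emitted.
    """
    if not (-5.0 <= iol_power <= 40.0):
        raise ValueError(f"iol_power {iol_power} outside [-5, 40]")
    ref = float(
        srkt_refraction_array(
            eye.axial_length, eye.mean_keratometry, constants.a_constant, iol_power, optics
        )
    )
    if not return_workings:
        return ref
    _, _, _, p = _srkt_chain(eye.axial_length, eye.mean_keratometry, constants.a_constant, optics)
    workings = SRKTWorkings(**{k: (bool(v) if k == "clamped" else float(v)) for k, v in p.items()})
    return ref, workings


def srkt_emmetropia_power(
    eye: EyeRecord, constants: SRKTConstants, optics: OpticalConstants = DEFAULT_OPTICS
) -> float:
    """IOL power (D) that makes the SRK/T predicted refraction zero."""
    return float(
        srkt_emmetropia_power_array(
            eye.axial_length, eye.mean_keratometry, constants.a_constant, optics
        )
    )


# ---------------------------------------------------------------------------
# Haigis
# ---------------------------------------------------------------------------

def haigis_refraction_at_elp_array(
    L, K, elp_mm, iol_power, optics: OpticalConstants = DEFAULT_OPTICS
):
    """Haigis vergence chain at an explicit ELP (mm); broadcasts.

    The chain runs in meters: the vergence needed at the corneal plane is
    ``z = n / (d + n / (n/(L - d) - P))`` and the corneal-plane refraction
    ``RC = z - DC`` is vertex-corrected to the spectacle plane.
    """
    L_m = np.asarray(L, dtype=float) / 1000.0
    d_m = np.asarray(elp_mm, dtype=float) / 1000.0
    K = np.asarray(K, dtype=float)
    P = np.asarray(iol_power, dtype=float)
    n = optics.n_aqueous
    r_m = (optics.keratometric_index_numerator / K) / 1000.0
    dc = (optics.n_cornea_haigis - 1.0) / r_m
    z = n / (d_m + n / (n / (L_m - d_m) - P))
    rc = z - dc
    v = optics.vertex_distance_mm / 1000.0
    return rc / (1.0 + rc * v)


def haigis_refraction_array(
    L, K, acd, constants: HaigisConstants, iol_power, optics: OpticalConstants = DEFAULT_OPTICS
):
    d = constants.a0 + constants.a1 * np.asarray(acd, float) + constants.a2 * np.asarray(L, float)
    return haigis_refraction_at_elp_array(L, K, d, iol_power, optics)


def haigis_predict_refraction(
    eye: EyeRecord,
    constants: HaigisConstants,
    iol_power: float,
    optics: OpticalConstants = DEFAULT_OPTICS,
    return_workings: bool = False,
):
    """Predicted spectacle-plane refraction (D) under the Haigis formula."""
    d = constants.elp(eye.acd, eye.axial_length)
    if not (0.0 < d < eye.axial_length):
        raise ValueError(
            f"Haigis ELP d={d:.4f} mm outside (0, L={eye.axial_length}) for constants "
            f"(a0={constants.a0}, a1={constants.a1}, a2={constants.a2})"
        )
    ref = float(
        haigis_refraction_at_elp_array(
            eye.axial_length, eye.mean_keratometry, d, iol_power, optics
        )
    )
    if not return_workings:
        return ref
    n = optics.n_aqueous
    r_m = (optics.keratometric_index_numerator / eye.mean_keratometry) / 1000.0
    dc = (optics.n_cornea_haigis - 1.0) / r_m
    L_m = eye.axial_length / 1000.0
    d_m = d / 1000.0
    z = n / (d_m + n / (n / (L_m - d_m) - iol_power))
    workings = HaigisWorkings(
        corneal_power=float(dc),
        elp=float(d),
        refraction_corneal_plane=float(z - dc),
        target_vergence=float(z),
    )
    return ref, workings


def haigis_backsolve_elp_array(
    L, K, iol_power, observed_mrse, optics: OpticalConstants = DEFAULT_OPTICS,
    lo_margin: float = 0.5, hi_margin: float = 0.5, tol: float = 1e-10, max_iter: int = 80,
):
    """Vectorized bracketed bisection for the ELP that reproduces the observed
    refraction. Entries with no root in ``[lo_margin, L - hi_margin]`` are NaN.
    """
    L = np.atleast_1d(np.asarray(L, dtype=float))
    K = np.atleast_1d(np.asarray(K, dtype=float))
    P = np.atleast_1d(np.asarray(iol_power, dtype=float))
    Rx = np.atleast_1d(np.asarray(observed_mrse, dtype=float))
    L, K, P, Rx = np.broadcast_arrays(L, K, P, Rx)

    lo = np.full(L.shape, lo_margin)
    hi = L - hi_margin

    def f(d):
        return haigis_refraction_at_elp_array(L, K, d, P, optics) - Rx

    flo = f(lo)
    fhi = f(hi)
    feasible = np.sign(flo) * np.sign(fhi) <= 0
    lo = lo.copy()
    hi = hi.copy()
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fmid = f(mid)
        go_left = np.sign(fmid) == np.sign(flo)
        lo = np.where(go_left, mid, lo)
        flo = np.where(go_left, fmid, flo)
        hi = np.where(go_left, hi, mid)
        if np.all(hi - lo < tol):
            break
    root = 0.5 * (lo + hi)
    return np.where(feasible, root, np.nan)


def haigis_backsolve_elp(
    eye: EyeRecord,
    iol_power: float,
    observed_mrse: float,
    optics: OpticalConstants = DEFAULT_OPTICS,
) -> float:
    """ELP (mm) at which the Haigis chain reproduces ``observed_mrse``.

    Solved by bracketed bisection on d in ``[0.5, L - 0.5]`` mm; the chain is
    monotone in d over that bracket for any in-window eye, so the root is
    unique when it exists.
    """
    if not (-15.0 <= observed_mrse <= 5.0):
        raise ValueError(f"observed_mrse {observed_mrse} outside [-15, +5]")
    d = haigis_backsolve_elp_array(
        eye.axial_length, eye.mean_keratometry, iol_power, observed_mrse, optics
    )
    d = float(d[0])
    if np.isnan(d):
        raise InfeasibleRecordError(
            f"no ELP in [0.5, {eye.axial_length - 0.5:.1f}] mm reproduces "
            f"MRSE {observed_mrse} D at P={iol_power} D for eye {eye.key}"
        )
    return d


# ---------------------------------------------------------------------------
# Power selection
# ---------------------------------------------------------------------------

def power_for_target_refraction(
    formula: str,
    eye: EyeRecord,
    constants_or_model,
    target: float,
    step: float = 0.5,
    power_range: tuple[float, float] = (6.0, 30.0),
) -> float:
    """The grid IOL power whose predicted refraction is closest to ``target``.

    ``formula`` is one of ``srkt``, ``haigis``, ``adapted`` with the matching
    constants object (or trained adapted calculator). Ties are broken toward
    the higher power, i.e. the more myopic outcome — the conventional
    surgeon-side choice since residual myopia is better tolerated than
    residual hyperopia.
    """
    if not step > 0:
        raise ValueError("step must be positive")
    lo, hi = power_range
    n_steps = int(np.floor((hi - lo) / step + 1e-9)) + 1
    if n_steps < 1:
        raise ValueError(f"empty power grid for range {power_range} and step {step}")
    grid = lo + step * np.arange(n_steps)

    if formula == "srkt":
        preds = srkt_refraction_array(
            eye.axial_length, eye.mean_keratometry, constants_or_model.a_constant, grid
        )
    elif formula == "haigis":
        preds = haigis_refraction_array(
            eye.axial_length, eye.mean_keratometry, eye.acd, constants_or_model, grid
        )
    elif formula == "adapted":
        preds = np.array(
            [constants_or_model.predict(eye, float(p)) for p in grid]
        )
    else:
        raise ValueError(f"unknown formula {formula!r}")

    dist = np.abs(preds - target)
    near = dist <= dist.min() + 1e-12
    return float(grid[near].max())
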