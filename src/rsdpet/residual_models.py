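"""Residual-space lp-ntPET and occupancy metrics.

With an accurate baseline prediction C_hat in hand (from
RSD-Hybrid-IMRTM), the absolute residual R_abs = C_hat - C isolates the
release-induced TAC deflection, and the lp-ntPET model difference
reduces to a two-parameter linear problem:

    R_abs(t) = gamma Integral[C h] (t) - k2a Integral[R_abs] (t)

Fitting gamma in this residual space avoids the identifiability issues
of simultaneously estimating baseline and release parameters.
Time-varying binding potential and peak occupancy follow as

    BPND(t) = k2 / (k2a + gamma h(t)) - 1
    pOcc    = 100 (BPND0 - BPND|h=1) / BPND0,   BPND0 = k2/k2a - 1

where k2 and k2a always come from an MRTM fit to the predicted baseline
TAC (the residual fit's k2a is a diagnostic only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import DynamicImage, Mask, ParametricMap, TAC, cumulative_integral_values, frame_weights
from .kinetics import BasisFunction, DegenerateFitError, batch_mrtm, make_basis_set
from .rsd import BaselinePrediction, RSDResult

__all__ = [
    "ResidualLpntpetResult",
    "OccupancyResult",
    "DomainError",
    "absolute_residuals",
    "fit_residual_lpntpet",
    "bpnd_timecourse",
    "peak_occupancy",
    "run_residual_lpntpet",
    "default_occupancy_basis",
]


class DomainError(ValueError):
    """Parameters outside the model's physical domain (e.g. BPND0 <= 0)."""


def default_occupancy_basis(tD: float = 36.0) -> list[BasisFunction]:
    """Reduced 5-member response library (tP = 37..49 min, evenly spaced)."""
    return make_basis_set(tD, np.linspace(37.0, 49.0, 5), alpha=1.0)


# ---------------------------------------------------------------------------
# Residual-space fitting
# ---------------------------------------------------------------------------


def absolute_residuals(baseline: BaselinePrediction | np.ndarray, tac: TAC) -> np.ndarray:
    """R_abs(t) = C_hat(t) - C(t); positive where the measured TAC dips."""
    chat = baseline.values if isinstance(baseline, BaselinePrediction) else np.asarray(baseline, float)
    if chat.shape != tac.values.shape:
        raise ValueError("baseline and TAC not aligned")
    return chat - tac.values


@dataclass
class ResidualLpntpetResult:
    gamma: float
    k2a: float
    best_basis: BasisFunction
    wrss: float
    per_basis: list  # (basis, gamma, k2a, wrss) diagnostics


def fit_residual_lpntpet(
    r_abs: np.ndarray,
    tac: TAC,
    basis_set: list[BasisFunction],
    clamp_gamma: bool = True,
) -> ResidualLpntpetResult:
    """Two-regressor WLS of the residual lp-ntPET model over a basis library.

    Design columns are [Integral(C h), -Integral(R_abs)] for (gamma,
    k2a); the basis minimizing weighted RSS is reported. A negative
    gamma estimate is clamped to the gamma = 0 solution when
    ``clamp_gamma`` (release can only decrease binding).
    """
    r = np.asarray(r_abs, float)
    if r.size < 3:
        raise DegenerateFitError("need >= 3 frames")
    t = tac.mid_times
    w = tac.weights
    from .kinetics import _wls

    ira = cumulative_integral_values(r, t)
    per_basis = []
    best = None
    for basis in basis_set:
        ich = cumulative_integral_values(tac.values * basis(t), t)
        X = np.column_stack([ich, -ira])
        coef, _ = _wls(X, r, w)
        if clamp_gamma and coef[0] < 0:
            # gamma = 0 leaves only the self-integral term
            denom = np.sum(w * ira**2)
            k2a0 = float(np.sum(w * (-ira) * r) / denom) if denom > 0 else 0.0
            coef = np.array([0.0, k2a0])
        resid = r - X @ coef
        wrss = float(np.sum(w * resid**2))
        per_basis.append((basis, float(coef[0]), float(coef[1]), wrss))
        if best is None or wrss < best[3]:
            best = (basis, float(coef[0]), float(coef[1]), wrss)
    basis, gamma, k2a, wrss = best
    return ResidualLpntpetResult(gamma=gamma, k2a=k2a, best_basis=basis, wrss=wrss, per_basis=per_basis)


# ---------------------------------------------------------------------------
# Occupancy metrics
# ---------------------------------------------------------------------------


@dataclass
class OccupancyResult:
    bpnd0: float
    bpnd_t: np.ndarray
    pocc: float


def bpnd_timecourse(k2: float, k2a: float, gamma: float, basis: BasisFunction,
                    t: np.ndarray) -> np.ndarray:
    """BPND(t) = k2 / (k2a + gamma h(t)) - 1."""
    if k2a <= 0:
        raise DomainError("k2a must be positive")
    denom = k2a + gamma * basis(t)
    if np.any(denom <= 0):
        raise DomainError("nonpositive k2a + gamma h(t)")
    return k2 / denom - 1.0


def peak_occupancy(k2: float, k2a: float, gamma: float) -> float:
    """Maximal percent decrease of BPND caused by release (at h = 1)."""
    if k2a <= 0 or k2 / k2a - 1.0 <= 0:
        raise DomainError("baseline BPND0 = k2/k2a - 1 must be positive")
    bpnd0 = k2 / k2a - 1.0
    denom = k2a + gamma
    if denom <= 0:
        raise DomainError("nonpositive k2a + gamma")
    bpnd_peak = k2 / denom - 1.0
    return 100.0 * (bpnd0 - bpnd_peak) / bpnd0


# ---------------------------------------------------------------------------
# Voxelwise pipeline
# ---------------------------------------------------------------------------


def run_residual_lpntpet(
    image: DynamicImage,
    striatal_mask: Mask,
    rsd_result: RSDResult,
    ref: TAC,
    basis_set: list[BasisFunction] | None = None,
    weight_mode: str = "uniform",
    clamp_gamma: bool = True,
) -> dict[str, ParametricMap]:
    """Voxelwise gamma / pOcc / BPND0 maps from RSD baselines.

    For each striatal voxel: MRTM on the predicted baseline TAC gives
    (k2, k2a); residual lp-ntPET on R_abs gives gamma; pOcc follows in
    closed form. Voxels with nonphysical baseline kinetics (BPND0 <= 0)
    or failed fits are masked out (NaN) and counted.
    """
    if basis_set is None:
        basis_set = default_occupancy_basis()
    schedule = image.schedule
    w = frame_weights(schedule, weight_mode)
    idx = rsd_result.voxel_indices
    Y = image.voxels[idx[:, 0], idx[:, 1], idx[:, 2], :].astype(float)
    baselines = rsd_result.baselines
    V, T = Y.shape
    t = schedule.mid_times

    # MRTM on predicted baselines gives the (k2, k2a) entering pOcc
    coef, _, _ = batch_mrtm(baselines, ref.values, schedule, weights=w)
    k2, k2a = coef[:, 1], coef[:, 2]

    r_abs = baselines - Y
    ira = cumulative_integral_values(r_abs, t)
    best_wrss = np.full(V, np.inf)
    gamma = np.zeros(V)
    for basis in basis_set:
        h = basis(t)
        ich = cumulative_integral_values(Y * h, t)
        # per-voxel 2x2 normal equations
        g11 = np.einsum("t,vt,vt->v", w, ich, ich)
        g22 = np.einsum("t,vt,vt->v", w, ira, ira)
        g12 = np.einsum("t,vt,vt->v", w, ich, -ira)
        b1 = np.einsum("t,vt,vt->v", w, ich, r_abs)
        b2 = np.einsum("t,vt,vt->v", w, -ira, r_abs)
        det = g11 * g22 - g12**2
        with np.errstate(divide="ignore", invalid="ignore"):
            g_est = (g22 * b1 - g12 * b2) / det
            k_est = (g11 * b2 - g12 * b1) / det
        bad = ~np.isfinite(g_est)
        g_est = np.where(bad, 0.0, g_est)
        k_est = np.where(bad, 0.0, k_est)
        if clamp_gamma:
            neg = g_est < 0
            with np.errstate(divide="ignore", invalid="ignore"):
                k0 = np.where(g22 > 0, b2 / g22, 0.0)
            g_est = np.where(neg, 0.0, g_est)
            k_est = np.where(neg, k0, k_est)
        fitted = g_est[:, None] * ich - k_est[:, None] * ira
        wrss = np.einsum("t,vt->v", w, (r_abs - fitted) ** 2)
        better = wrss < best_wrss
        best_wrss[better] = wrss[better]
        gamma[better] = g_est[better]

    with np.errstate(divide="ignore", invalid="ignore"):
        bpnd0 = k2 / k2a - 1.0
        bpnd_peak = k2 / (k2a + gamma) - 1.0
        pocc = 100.0 * (bpnd0 - bpnd_peak) / bpnd0
    ok = (k2a > 0) & (bpnd0 > 0) & (k2a + gamma > 0) & np.isfinite(pocc)
    pocc = np.where(ok, pocc, np.nan)
    bpnd0 = np.where(k2a > 0, bpnd0, np.nan)

    out = {}
    for name, arr in (("gamma", gamma), ("pOcc", pocc), ("BPND0", bpnd0)):
        vol = np.full(image.shape, np.nan)
        vol[idx[:, 0], idx[:, 1], idx[:, 2]] = arr
        out[name] = ParametricMap(vol, name, striatal_mask)
    out["n_excluded"] = int(np.sum(~ok))
    return out
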