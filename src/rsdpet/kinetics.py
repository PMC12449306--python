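"""Reference-tissue kinetic models for dynamic PET.

Implements the multilinear reference tissue model (MRTM), the linear
parametric neurotransmitter PET model (lp-ntPET) with basis-function
search and F-test detection, and the iterative MRTM (IMRTM) baseline
extrapolation used to predict a voxel's release-free time course from a
TAC that may contain a task-induced dip.

Model equations (time in minutes, WLS at frame mid-times):

    MRTM:      C_T(t) = R1 C_R(t) + k2 I[C_R](t) - k2a I[C_T](t)
    lp-ntPET:  MRTM - gamma * I[C_T h](t)

with I[f](t) the running integral from injection, and h(t) a unit-peak
gamma-variate response with start tD, peak tP and sharpness alpha.

IMRTM fits MRTM on the pre-task frames only and then repeatedly
substitutes the model curve into its own integral term:

    C^(n)(t) = R1_pre C_R + k2_pre I[C_R] - k2a_pre I[C^(n-1)],  C^(0) = C_T

which converges to (the MRTM fit of) the release-free baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import TAC, FrameSchedule, cumulative_integral_values

__all__ = [
    "MRTMParams",
    "BasisFunction",
    "LpntpetResult",
    "IMRTMBaseline",
    "DegenerateFitError",
    "fit_mrtm",
    "make_basis_set",
    "fit_lpntpet",
    "f_test",
    "imrtm",
]

# Nested-model degrees of freedom for the F-test: MRTM has 3 linear
# parameters, lp-ntPET adds gamma. The basis search is not penalized
# (standard lp-ntPET practice; anti-conservative).
P_MRTM = 3
P_LPNTPET = 4

FINE_DT = 0.1  # minutes; sampling grid for h(t) and predictor convolutions


class DegenerateFitError(ValueError):
    """Design matrix is rank deficient (e.g. too few frames in window)."""


# ---------------------------------------------------------------------------
# WLS core
# ---------------------------------------------------------------------------


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, float]:
    """Weighted least squares; returns (coefficients, weighted RSS).

    A rank-deficient design is tolerated only when the data are exactly
    representable (min-norm solution, e.g. a TAC identical to the
    reference); otherwise the fit is ambiguous and an error is raised.
    """
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    coef, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = y - X @ coef
    wrss = float(np.sum(w * resid**2))
    if rank < X.shape[1] and wrss > 1e-12 * float(np.sum(w * y**2) + 1e-300):
        raise DegenerateFitError("rank-deficient design matrix")
    return coef, wrss


def _batch_solve(X: np.ndarray, Y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve per-voxel WLS for stacked designs.

    X: (V, T, P) per-voxel design, Y: (V, T) data, w: (T,) weights.
    Returns coefficients (V, P) and weighted RSS (V,).
    """
    Xw = X * w[None, :, None]
    XtX = np.einsum("vtp,vtq->vpq", Xw, X)
    Xty = np.einsum("vtp,vt->vp", Xw, Y)
    coef = np.linalg.solve(XtX, Xty[..., None])[..., 0]
    resid = Y - np.einsum("vtp,vp->vt", X, coef)
    wrss = np.einsum("t,vt->v", w, resid**2)
    return coef, wrss


# ---------------------------------------------------------------------------
# MRTM
# ---------------------------------------------------------------------------


@dataclass
class MRTMParams:
    """MRTM coefficients with fit diagnostics and the full-length model TAC."""

    R1: float
    k2: float
    k2a: float
    wrss: float
    fitted: np.ndarray

    @property
    def bpnd(self) -> float:
        """Non-displaceable binding potential k2/k2a - 1."""
        return self.k2 / self.k2a - 1.0


def _mrtm_design(tac_values: np.ndarray, ref_values: np.ndarray, mid_times: np.ndarray) -> np.ndarray:
    icr = cumulative_integral_values(ref_values, mid_times)
    ict = cumulative_integral_values(tac_values, mid_times)
    return np.column_stack([ref_values, icr, -ict])


def _window_mask(schedule: FrameSchedule, window) -> np.ndarray:
    if window is None:
        return np.ones(schedule.n_frames, dtype=bool)
    t0, t1 = window
    mid = schedule.mid_times
    return (mid >= t0) & (mid < t1)


def fit_mrtm(tac: TAC, ref: TAC, window: tuple[float, float] | None = None) -> MRTMParams:
    """Fit MRTM by WLS, optionally restricted to a time window.

    The running integrals are always computed from injection (t = 0);
    ``window`` only restricts which frames enter the fit. The fitted TAC
    is extrapolated to all frames with the window's coefficients, with
    the measured-TAC integral retained in the k2a term (first IMRTM
    approximation when the window is pre-task).
    """
    sel = _window_mask(tac.schedule, window)
    if sel.sum() < 4:
        raise DegenerateFitError("need >= 4 frames inside the fit window")
    X = _mrtm_design(tac.values, ref.values, tac.mid_times)
    coef, wrss = _wls(X[sel], tac.values[sel], tac.weights[sel])
    fitted = X @ coef
    return MRTMParams(*map(float, coef), wrss=wrss, fitted=fitted)


# ---------------------------------------------------------------------------
# Basis functions (gamma-variate response h)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BasisFunction:
    """Unit-peak gamma-variate response h(t) with start tD and peak tP.

    h(t) = theta(t - tD) * ((t-tD)/(tP-tD))^alpha * exp(alpha (1 - (t-tD)/(tP-tD)))

    so h(tD) = 0, h(tP) = 1; alpha controls sharpness.
    """

    tD: float
    tP: float
    alpha: float

    def __post_init__(self) -> None:
        if not self.tP > self.tD >= 0:
            raise ValueError("require tP > tD >= 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        u = (t - self.tD) / (self.tP - self.tD)
        with np.errstate(invalid="ignore"):
            h = np.where(u > 0, np.power(np.clip(u, 0, None), self.alpha) * np.exp(self.alpha * (1.0 - u)), 0.0)
        return h

    def at_frames(self, schedule: FrameSchedule) -> np.ndarray:
        return self(schedule.mid_times)

    def fine_grid(self, t_end: float, dt: float = FINE_DT) -> tuple[np.ndarray, np.ndarray]:
        t = np.arange(0.0, t_end + dt / 2, dt)
        return t, self(t)


def make_basis_set(tD: float, tP_list, alpha: float = 1.0) -> list[BasisFunction]:
    """Library of response curves with shared tD/alpha and varied peak time.

    The detection default is 17 members, tP = 37..51 min at 1-min steps
    with tD = 36 min and alpha = 1.
    """
    basis = [BasisFunction(tD=float(tD), tP=float(tP), alpha=float(alpha)) for tP in tP_list]
    if not basis:
        raise ValueError("empty tP list")
    return basis


def default_detection_basis(tD: float = 36.0) -> list[BasisFunction]:
    """17-member detection library: tP evenly spaced over 37-51 min."""
    return make_basis_set(tD, np.linspace(37.0, 51.0, 17), alpha=1.0)


# ---------------------------------------------------------------------------
# F-test
# ---------------------------------------------------------------------------


def f_test(wrss0: float, wrss1: float, n_frames: int, p0: int = P_MRTM, p1: int = P_LPNTPET) -> tuple[float, float]:
    """Nested-model F-test of the richer model (p1 params) vs the null (p0).

    Returns (F, upper-tail p). F is clamped at 0 when the richer model
    fits worse numerically; a perfect richer fit returns (inf, 0).
    """
    if not (n_frames > p1 > p0):
        raise ValueError("require n_frames > p1 > p0")
    if wrss1 < 0:
        raise ValueError("wrss1 must be nonnegative")
    dof1, dof2 = p1 - p0, n_frames - p1
    if wrss1 == 0.0:
        if wrss0 <= 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = ((wrss0 - wrss1) / dof1) / (wrss1 / dof2)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, dof1, dof2))
    return float(F), p


# ---------------------------------------------------------------------------
# lp-ntPET
# ---------------------------------------------------------------------------


@dataclass
class LpntpetResult:
    R1: float
    k2: float
    k2a: float
    gamma: float
    best_basis: BasisFunction | None
    wrss: float
    F: float
    p: float
    fitted: np.ndarray = field(default=None, repr=False)
    mrtm: MRTMParams = field(default=None, repr=False)


def fit_lpntpet(
    tac: TAC,
    ref: TAC,
    basis_set: list[BasisFunction],
    clamp_gamma: bool = True,
) -> LpntpetResult:
    """Fit lp-ntPET over a basis library; score against MRTM with an F-test.

    For each basis the 4-column WLS problem is solved; if the gamma
    estimate is negative (and ``clamp_gamma``), that basis is scored by
    the nested gamma = 0 (MRTM) fit — dopamine release can only decrease
    binding. The basis minimizing weighted RSS wins. With an empty basis
    set the result degenerates exactly to MRTM.
    """
    if tac.schedule.n_frames < 5:
        raise DegenerateFitError("need >= 5 frames")
    mrtm = fit_mrtm(tac, ref)
    X3 = _mrtm_design(tac.values, ref.values, tac.mid_times)
    w = tac.weights
    best = None
    for basis in basis_set:
        h = basis.at_frames(tac.schedule)
        col = -cumulative_integral_values(tac.values * h, tac.mid_times)
        X = np.column_stack([X3, col])
        coef, wrss = _wls(X, tac.values, w)
        if clamp_gamma and coef[3] < 0:
            coef = np.array([mrtm.R1, mrtm.k2, mrtm.k2a, 0.0])
            wrss = mrtm.wrss
            fitted = mrtm.fitted
        else:
            fitted = X @ coef
        if best is None or wrss < best[1]:
            best = (coef, wrss, basis, fitted)
    if best is None:  # empty basis set
        F, p = 0.0, 1.0
        return LpntpetResult(mrtm.R1, mrtm.k2, mrtm.k2a, 0.0, None, mrtm.wrss, F, p,
                             fitted=mrtm.fitted, mrtm=mrtm)
    coef, wrss, basis, fitted = best
    # a "win" within numerical dust of the MRTM fit (noise-free nested
    # fits) is no improvement at all
    scale = float(np.sum(w * tac.values**2)) + 1e-300
    if mrtm.wrss - wrss < 1e-12 * scale:
        return LpntpetResult(mrtm.R1, mrtm.k2, mrtm.k2a, 0.0, None, mrtm.wrss, 0.0, 1.0,
                             fitted=mrtm.fitted, mrtm=mrtm)
    F, p = f_test(mrtm.wrss, wrss, tac.schedule.n_frames)
    return LpntpetResult(*map(float, coef), best_basis=basis, wrss=wrss, F=F, p=p,
                         fitted=fitted, mrtm=mrtm)


def batch_lpntpet(
    Y: np.ndarray,
    ref_values: np.ndarray,
    schedule: FrameSchedule,
    basis_set: list[BasisFunction],
    weights: np.ndarray | None = None,
    clamp_gamma: bool = True,
) -> dict[str, np.ndarray]:
    """Vectorized lp-ntPET + MRTM over a (V, T) voxel-TAC matrix.

    Returns per-voxel arrays: R1, k2, k2a, gamma, wrss, mrtm_wrss, F, p,
    basis_index (-1 where the gamma = 0 fit won), and the MRTM
    coefficients R1_m, k2_m, k2a_m.
    """
    V, T = Y.shape
    t = schedule.mid_times
    w = np.ones(T) if weights is None else np.asarray(weights, float)
    icr = cumulative_integral_values(ref_values, t)
    ict = cumulative_integral_values(Y, t)  # (V, T)

    X3 = np.empty((V, T, 3))
    X3[..., 0] = ref_values
    X3[..., 1] = icr
    X3[..., 2] = -ict
    coef_m, wrss_m = _batch_solve(X3, Y, w)

    best_wrss = wrss_m.copy()
    best_coef = np.concatenate([coef_m, np.zeros((V, 1))], axis=1)
    best_idx = np.full(V, -1)
    for bi, basis in enumerate(basis_set):
        h = basis(t)
        col = -cumulative_integral_values(Y * h, t)
        X4 = np.concatenate([X3, col[..., None]], axis=2)
        coef4, wrss4 = _batch_solve(X4, Y, w)
        if clamp_gamma:
            neg = coef4[:, 3] < 0
            coef4[neg] = np.concatenate([coef_m[neg], np.zeros((neg.sum(), 1))], axis=1)
            wrss4[neg] = wrss_m[neg]
        better = wrss4 < best_wrss
        best_wrss[better] = wrss4[better]
        best_coef[better] = coef4[better]
        best_idx[better] = bi

    # no-improvement guard against numerical dust on noise-free data
    scale = np.einsum("t,vt->v", w, Y**2) + 1e-300
    dust = (wrss_m - best_wrss) < 1e-12 * scale
    best_wrss[dust] = wrss_m[dust]
    best_coef[dust] = np.concatenate([coef_m[dust], np.zeros((dust.sum(), 1))], axis=1)
    best_idx[dust] = -1

    dof1, dof2 = P_LPNTPET - P_MRTM, T - P_LPNTPET
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((wrss_m - best_wrss) / dof1) / (best_wrss / dof2)
    F = np.where(best_wrss == 0, np.inf, F)
    F = np.where(dust, 0.0, F)
    F = np.clip(F, 0.0, None)
    p = np.where(np.isinf(F), 0.0, stats.f.sf(np.where(np.isinf(F), 0.0, F), dof1, dof2))
    return {
        "R1": best_coef[:, 0], "k2": best_coef[:, 1], "k2a": best_coef[:, 2],
        "gamma": best_coef[:, 3], "wrss": best_wrss, "mrtm_wrss": wrss_m,
        "F": F, "p": p, "basis_index": best_idx,
        "R1_m": coef_m[:, 0], "k2_m": coef_m[:, 1], "k2a_m": coef_m[:, 2],
    }


def batch_mrtm(
    Y: np.ndarray,
    ref_values: np.ndarray,
    schedule: FrameSchedule,
    window: tuple[float, float] | None = None,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized MRTM over (V, T) data; returns (coef (V,3), wrss (V,), fitted (V,T))."""
    V, T = Y.shape
    t = schedule.mid_times
    w = np.ones(T) if weights is None else np.asarray(weights, float)
    sel = _window_mask(schedule, window)
    if sel.sum() < 4:
        raise DegenerateFitError("need >= 4 frames inside the fit window")
    icr = cumulative_integral_values(ref_values, t)
    ict = cumulative_integral_values(Y, t)
    X = np.empty((V, T, 3))
    X[..., 0] = ref_values
    X[..., 1] = icr
    X[..., 2] = -ict
    wsel = w * sel
    coef, wrss = _batch_solve(X, Y, wsel)
    fitted = np.einsum("vtp,vp->vt", X, coef)
    return coef, wrss, fitted


# ---------------------------------------------------------------------------
# Iterative MRTM
# ---------------------------------------------------------------------------


@dataclass
class IMRTMBaseline:
    """IMRTM iterate history for one voxel TAC."""

    R1_pre: float
    k2_pre: float
    k2a_pre: float
    iterates: list[np.ndarray]  # iterate 0 is the measured TAC
    rmse_history: np.ndarray | None  # vs ground-truth baseline, if given

    @property
    def n_iterations(self) -> int:
        return len(self.iterates) - 1

    @property
    def baseline(self) -> np.ndarray:
        return self.iterates[-1]


def imrtm(
    tac: TAC,
    ref: TAC,
    tD: float,
    n_iter: int = 10,
    tol: float = 0.0,
    truth_baseline: np.ndarray | None = None,
) -> IMRTMBaseline:
    """Iterative MRTM baseline extrapolation.

    Fits MRTM on frames with mid-time < tD, then iterates the
    self-substitution update. Stops after ``n_iter`` iterations or when
    the relative change of the RMS difference between successive
    iterates falls below ``tol`` (0 disables early stopping). If a
    ground-truth baseline is supplied, records RMSE against it per
    iterate.
    """
    pre = fit_mrtm(tac, ref, window=(0.0, tD))
    t = tac.mid_times
    icr = cumulative_integral_values(ref.values, t)
    fixed = pre.R1 * ref.values + pre.k2 * icr
    iterates = [tac.values.copy()]
    prev_step = None
    for _ in range(n_iter):
        nxt = fixed - pre.k2a * cumulative_integral_values(iterates[-1], t)
        step = float(np.sqrt(np.mean((nxt - iterates[-1]) ** 2)))
        iterates.append(nxt)
        if tol > 0 and prev_step is not None and prev_step > 0:
            if abs(step - prev_step) / prev_step < tol:
                break
        prev_step = step
    rmse = None
    if truth_baseline is not None:
        rmse = np.array([np.sqrt(np.mean((it - truth_baseline) ** 2)) for it in iterates])
    return IMRTMBaseline(pre.R1, pre.k2, pre.k2a, iterates, rmse)


def batch_imrtm(
    Y: np.ndarray,
    ref_values: np.ndarray,
    schedule: FrameSchedule,
    tD: float,
    n_iter: int = 10,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized IMRTM: final baseline iterate for every row of Y (V, T)."""
    coef, _, _ = batch_mrtm(Y, ref_values, schedule, window=(0.0, tD), weights=weights)
    t = schedule.mid_times
    icr = cumulative_integral_values(ref_values, t)
    fixed = coef[:, 0:1] * ref_values[None, :] + coef[:, 1:2] * icr[None, :]
    cur = Y.copy()
    for _ in range(n_iter):
        cur = fixed - coef[:, 2:3] * cumulative_integral_values(cur, t)
    return cur
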