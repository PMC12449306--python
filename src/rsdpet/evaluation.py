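"""Detection and group-analysis metrics for simulated and human studies.

Covers: ROC curves from thresholded parametric maps against phantom
ground truth (TPR pooled over release clusters, FPR in the release-free
right caudate, in-plane edge voxels removed to limit partial-volume
false positives), quantitative DA-release tracking curves, sparsity
thresholding, dice overlap, one-sample T-maps, and a simplified
RSD-k-means comparator used as the data-driven-only reference method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import DynamicImage, Mask, ParametricMap, TAC, frame_weights, reference_tac, voxel_matrix
from .rsd import RSDConfig, make_predictor

__all__ = [
    "DetectionTruth",
    "ROCCurve",
    "remove_inplane_edges",
    "roc_from_maps",
    "tpr_at_fpr",
    "tracking_curve",
    "sparsity_binarize",
    "dice",
    "one_sample_tmap",
    "rsd_kmeans_comparator",
    "lpntpet_maps",
    "run_detection_experiment",
    "run_tracking_experiment",
    "partial_auc",
]


# ---------------------------------------------------------------------------
# Truth containers
# ---------------------------------------------------------------------------


@dataclass
class DetectionTruth:
    """Ground-truth release voxels and the region used to evaluate FPR."""

    truth: Mask  # binary release mask
    fpr_region: Mask  # release-free region (right caudate)

    def __post_init__(self) -> None:
        if np.any((self.truth.labels > 0) & (self.fpr_region.labels > 0)):
            raise ValueError("truth and FPR masks must be disjoint")


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    tpr: np.ndarray  # mean across realizations
    fpr: np.ndarray
    per_realization: tuple  # (tpr (R, K), fpr (R, K))


def remove_inplane_edges(mask: Mask) -> Mask:
    """One-voxel in-plane (4-neighbor) erosion of each axial slice.

    Mitigates partial-volume false positives at region boundaries. May
    return an empty mask (warned).
    """
    m = mask.labels > 0
    cross = np.zeros((3, 3, 1), dtype=bool)
    cross[1, :, 0] = True
    cross[:, 1, 0] = True
    eroded = ndimage.binary_erosion(m, structure=cross, border_value=0)
    if not eroded.any():
        warnings.warn("in-plane erosion produced an empty mask")
    return Mask(eroded.astype(int))


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


def roc_from_maps(maps: list[ParametricMap], truth: DetectionTruth, n_thresholds: int = 201) -> ROCCurve:
    """Empirical ROC from raw parametric maps across noisy realizations.

    Thresholds range from 0 to the maximum value across all realizations
    (values > threshold are detections). TPR is pooled over all truth
    voxels; FPR is evaluated inside the release-free region. Per-threshold
    TPR/FPR are averaged across realizations.
    """
    if not maps:
        raise ValueError("need at least one realization")
    tmask = truth.truth.labels > 0
    fmask = truth.fpr_region.labels > 0
    if not tmask.any() or not fmask.any():
        raise ValueError("empty truth or FPR mask")
    vals_t = np.stack([np.nan_to_num(m.values[tmask], nan=-np.inf) for m in maps])
    vals_f = np.stack([np.nan_to_num(m.values[fmask], nan=-np.inf) for m in maps])
    vmax = max(vals_t.max(initial=0.0), vals_f.max(initial=0.0))
    thr = np.linspace(0.0, vmax if vmax > 0 else 1.0, n_thresholds)
    tpr = (vals_t[:, :, None] > thr[None, None, :]).mean(axis=1)
    fpr = (vals_f[:, :, None] > thr[None, None, :]).mean(axis=1)
    return ROCCurve(thr, tpr.mean(axis=0), fpr.mean(axis=0), (tpr, fpr))


def tpr_at_fpr(roc: ROCCurve, fpr: float) -> float:
    """Mean TPR at a requested mean FPR, by linear interpolation."""
    f = roc.fpr
    t = roc.tpr
    order = np.argsort(f)
    fs, ts = f[order], t[order]
    if not (fs[0] - 1e-12 <= fpr <= fs[-1] + 1e-12):
        raise ValueError(f"FPR {fpr} outside achieved range [{fs[0]:.4g}, {fs[-1]:.4g}]")
    return float(np.interp(fpr, fs, ts))


# ---------------------------------------------------------------------------
# Tracking
# ---------------------------------------------------------------------------


def tracking_curve(maps_per_level: dict, cluster: Mask) -> dict:
    """Cluster-mean metric vs release level, with voxel/NR errors in quadrature.

    ``maps_per_level`` maps a DA_peak level to a list of ParametricMaps
    (one per noisy realization). Returns per-level mean and error bar
    sqrt(SD_voxels^2 + SD_NRs^2).
    """
    if len(maps_per_level) < 2:
        raise ValueError("need >= 2 release levels")
    cm = cluster.labels > 0
    out = {"level": [], "mean": [], "err": []}
    for level in sorted(maps_per_level):
        maps = maps_per_level[level]
        if not maps:
            raise ValueError(f"missing maps for level {level}")
        per_nr_vox = np.stack([m.values[cm] for m in maps])  # (R, Nvox)
        grand = float(np.nanmean(per_nr_vox))
        sd_vox = float(np.nanstd(np.nanmean(per_nr_vox, axis=0)))
        sd_nr = float(np.nanstd(np.nanmean(per_nr_vox, axis=1)))
        out["level"].append(float(level))
        out["mean"].append(grand)
        out["err"].append(float(np.hypot(sd_vox, sd_nr)))
    return {k: np.asarray(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------


def sparsity_binarize(pmap: ParametricMap, s: float) -> Mask:
    """Keep the top (1 - s) fraction of strictly positive map values.

    s = 0 keeps all positive voxels; s = 1 keeps none. Ties are broken
    by lexicographic voxel index (stable sort).
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError("sparsity must be in [0, 1]")
    vals = pmap.values
    pos_idx = np.argwhere(np.nan_to_num(vals, nan=0.0) > 0)
    out = np.zeros(pmap.mask.shape, dtype=int)
    n_pos = pos_idx.shape[0]
    if n_pos == 0:
        warnings.warn("no positive voxels to binarize")
        return Mask(out)
    n_keep = n_pos - int(np.floor(s * n_pos))
    if s >= 1.0:
        n_keep = 0
    v = vals[pos_idx[:, 0], pos_idx[:, 1], pos_idx[:, 2]]
    order = np.argsort(-v, kind="stable")  # ties keep lexicographic index order
    keep = pos_idx[order[:n_keep]]
    out[keep[:, 0], keep[:, 1], keep[:, 2]] = 1
    return Mask(out)


def dice(a: Mask, b: Mask) -> float:
    """Dice overlap 2|A & B| / (|A| + |B|); 0 when both masks are empty."""
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    am = a.labels > 0
    bm = b.labels > 0
    denom = am.sum() + bm.sum()
    if denom == 0:
        warnings.warn("dice of two empty masks defined as 0")
        return 0.0
    return float(2.0 * np.sum(am & bm) / denom)


def one_sample_tmap(maps: list[ParametricMap]) -> ParametricMap:
    """Voxelwise one-sample t (mean > 0) across subjects.

    Zero-variance voxels get an infinite-t sentinel (sign of the mean).
    """
    if len(maps) < 2:
        raise ValueError("need >= 2 subjects")
    stack = np.stack([m.values for m in maps])
    n = np.sum(np.isfinite(stack), axis=0).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = (sd == 0) & (n >= 2)
    t = np.where(zero_var, np.sign(mean) * np.inf, t)
    t = np.where(n < 2, np.nan, t)
    t = np.where(np.isinf(t) & (mean == 0), 0.0, t)
    mask = maps[0].mask
    vals = np.where(mask.labels > 0, t, np.nan)
    vals = np.where(np.isinf(vals), np.nan, vals)  # sentinel kept separately
    out = ParametricMap(vals, "t", mask)
    out.sentinel = Mask((zero_var & (mask.labels > 0)).astype(int))
    return out


# ---------------------------------------------------------------------------
# RSD-k-means comparator
# ---------------------------------------------------------------------------


def rsd_kmeans_comparator(
    image: DynamicImage,
    striatal_mask: Mask,
    ref_mask: Mask,
    config: RSDConfig = RSDConfig(),
    seed: int = 0,
    ref: TAC | None = None,
    removal_z: float = 2.0,
) -> ParametricMap:
    """Simplified data-driven RSD baseline method (the earlier approach).

    k = 3 k-means on area-normalized pre-task voxel TACs; cluster-mean
    full TACs plus the reference TAC (spill-in) serve as baseline
    regressors fit to each voxel's pre-task frames by nonnegative least
    squares and extrapolated. One removal iteration excludes voxels
    whose preliminary beta z-score exceeds ``removal_z`` from the
    regressor averages. Residuals and the GLM beta follow the same
    definitions as the hybrid pipeline. Because the regressors are
    averages of measured TACs, widespread release contaminates them —
    the comparator's documented failure mode.
    """
    from scipy.optimize import nnls as scipy_nnls
    from sklearn.cluster import KMeans

    schedule = image.schedule
    w = frame_weights(schedule, config.weight_mode)
    if ref is None:
        ref = reference_tac(image, ref_mask)
    Y, idx = voxel_matrix(image, striatal_mask)
    V, T = Y.shape
    tD = config.tD
    pre = schedule.mid_times < tD

    feats = Y[:, pre]
    area = feats.sum(axis=1, keepdims=True)
    area[area == 0] = 1.0
    feats = feats / area
    labels = None
    for attempt in range(5):
        km = KMeans(n_clusters=3, n_init=10, random_state=seed + attempt)
        lab = km.fit_predict(feats)
        if len(np.unique(lab)) == 3:
            labels = lab
            break
    if labels is None:
        raise RuntimeError("k-means cluster collapse after 5 reseeds")

    predictor = make_predictor(config.blocks, config.L, schedule, config.kernel)
    P = predictor.values

    def fit_pass(include: np.ndarray) -> np.ndarray:
        regs = []
        for c in range(3):
            sel = (labels == c) & include
            if not sel.any():
                sel = labels == c  # empty after removal: keep original members
            regs.append(Y[sel].mean(axis=0))
        R = np.column_stack([*regs, ref.values])  # (T, 4) incl. spill-in
        sw = np.sqrt(w[pre])
        A = R[pre] * sw[:, None]
        coefs = np.stack([scipy_nnls(A, Y[v, pre] * sw)[0] for v in range(V)], axis=1)
        baselines = (R @ coefs).T  # (V, T)
        floor = config.floor_frac * baselines.max(axis=1, keepdims=True)
        valid = baselines > floor
        with np.errstate(divide="ignore", invalid="ignore"):
            resid = 100.0 * (1.0 - Y / baselines)
        resid = np.nan_to_num(resid, nan=0.0, posinf=0.0, neginf=0.0)
        resid[~valid] = 0.0
        wP = w[None, :] * valid * P[None, :]
        denom = np.sum(wP * P[None, :], axis=1)
        beta = np.where(denom > 0, np.sum(wP * resid, axis=1) / np.where(denom > 0, denom, 1.0), np.nan)
        return beta

    beta0 = fit_pass(np.ones(V, dtype=bool))
    mu, sd = np.nanmean(beta0), np.nanstd(beta0)
    include = beta0 <= mu + removal_z * (sd if sd > 0 else 1.0)
    beta = fit_pass(include)

    vol = np.full(image.shape, np.nan)
    vol[idx[:, 0], idx[:, 1], idx[:, 2]] = beta
    return ParametricMap(vol, "beta", striatal_mask)


# ---------------------------------------------------------------------------
# Simulation experiments (phantom studies -> parametric maps per method)
# ---------------------------------------------------------------------------


def lpntpet_maps(
    image: DynamicImage,
    striatal_mask: Mask,
    ref_mask: Mask,
    basis_set,
    config: RSDConfig = RSDConfig(),
    ref: TAC | None = None,
) -> dict[str, ParametricMap]:
    """Voxelwise lp-ntPET F and gamma maps over the striatum."""
    from .kinetics import batch_lpntpet

    if ref is None:
        ref = reference_tac(image, ref_mask)
    Y, idx = voxel_matrix(image, striatal_mask)
    w = frame_weights(image.schedule, config.weight_mode)
    det = batch_lpntpet(Y, ref.values, image.schedule, basis_set, weights=w,
                        clamp_gamma=config.clamp_gamma)
    out = {}
    for name, key in (("F", "F"), ("gamma", "gamma"), ("p", "p")):
        vol = np.full(image.shape, np.nan)
        vol[idx[:, 0], idx[:, 1], idx[:, 2]] = det[key]
        out[name] = ParametricMap(vol, name, striatal_mask)
    return out


def run_detection_experiment(
    scenario: str,
    da_peak: float,
    n_realizations: int,
    seed: int,
    methods=("hybrid", "kmeans", "lpntpet"),
    spec=None,
    config: RSDConfig = RSDConfig(),
    noise_level: float | None = None,
) -> dict:
    """Simulate noisy phantom realizations and map each detection method.

    Returns per-method lists of ParametricMaps (beta for the RSD methods,
    F for lp-ntPET) plus the eroded DetectionTruth for ROC evaluation.
    """
    from .rsd import run_rsd_hybrid
    from .simulator import DEFAULT_NOISE_LEVEL, PhantomSpec, simulate_study

    if spec is None:
        spec = PhantomSpec()
    if noise_level is None:
        noise_level = DEFAULT_NOISE_LEVEL
    studies = simulate_study(spec, scenario, da_peak, n_realizations, seed,
                             noise_level=noise_level)
    ph = studies[0].phantom
    truth = DetectionTruth(
        remove_inplane_edges(ph.release_masks[scenario]),
        remove_inplane_edges(Mask((ph.striatum.labels == 2).astype(int))),
    )
    maps: dict[str, list] = {m: [] for m in methods}
    for st in studies:
        if "hybrid" in methods:
            r = run_rsd_hybrid(st.noisy, ph.striatum, ph.cerebellum, config)
            maps["hybrid"].append(r.beta_map)
        if "kmeans" in methods:
            maps["kmeans"].append(
                rsd_kmeans_comparator(st.noisy, ph.striatum, ph.cerebellum, config, seed=st.seed)
            )
        if "lpntpet" in methods:
            maps["lpntpet"].append(
                lpntpet_maps(st.noisy, ph.striatum, ph.cerebellum, config.basis_set(), config)["F"]
            )
    return {"maps": maps, "truth": truth, "phantom": ph}


def run_tracking_experiment(
    da_peaks,
    n_realizations: int,
    seed: int,
    spec=None,
    config: RSDConfig = RSDConfig(),
    noise_level: float | None = None,
    gamma_basis=None,
) -> dict:
    """Quantitative-tracking simulation: per-level beta and single-basis gamma maps.

    Uses the localized-cluster scenario; gamma comes from lp-ntPET with a
    single optimal basis (default tD=36, tP=42, alpha=1) to minimize
    variance, as in the source protocol.
    """
    from .kinetics import make_basis_set
    from .rsd import run_rsd_hybrid
    from .simulator import DEFAULT_NOISE_LEVEL, PhantomSpec, simulate_study

    if spec is None:
        spec = PhantomSpec()
    if noise_level is None:
        noise_level = DEFAULT_NOISE_LEVEL
    if gamma_basis is None:
        gamma_basis = make_basis_set(36.0, [42.0], 1.0)
    out: dict[float, dict] = {}
    phantom = None
    for peak in da_peaks:
        beta_maps, gamma_maps = [], []
        # common random numbers across levels: the same noise seeds pair
        # the realizations, so level-to-level comparisons (tracking
        # ratios) are not dominated by independent noise in each level
        studies = simulate_study(spec, "localized", float(peak), n_realizations,
                                 seed, noise_level=noise_level)
        phantom = studies[0].phantom
        for st in studies:
            r = run_rsd_hybrid(st.noisy, phantom.striatum, phantom.cerebellum, config)
            beta_maps.append(r.beta_map)
            gamma_maps.append(
                lpntpet_maps(st.noisy, phantom.striatum, phantom.cerebellum, gamma_basis, config)["gamma"]
            )
        out[float(peak)] = {"beta": beta_maps, "gamma": gamma_maps}
    return {"levels": out, "phantom": phantom}


def partial_auc(roc: ROCCurve, fpr_max: float) -> float:
    """Mean TPR over the FPR range [0, fpr_max] (normalized partial AUC)."""
    order = np.argsort(roc.fpr)
    f, t = roc.fpr[order], roc.tpr[order]
    hi = min(fpr_max, f.max())
    grid = np.linspace(0.0, hi, 101)
    return float(np.trapezoid(np.interp(grid, f, t), grid) / hi) if hi > 0 else 0.0
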