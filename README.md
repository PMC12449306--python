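# rsdpet

Voxel-level detection and semi-quantification of task-induced dopamine
release in dynamic PET, using residual-space detection with hybrid
data/model baseline prediction (RSD-Hybrid-IMRTM).

## The problem

In a single-scan [¹¹C]raclopride paradigm, a subject is scanned for
70+ minutes; about 36 minutes in, they perform a task (e.g. finger
tapping) intended to evoke striatal dopamine (DA) release. Released DA
competes with the tracer at D2/D3 receptors, producing a transient,
voxel-level *dip* in the time-activity curve (TAC). Detecting and
grading these dips — a percent-level effect buried in voxel noise — is
the job of this package. It is aimed at PET methodologists and
neuroimaging groups running task-based raclopride studies.

## Methods implemented

All models are reference-tissue based (cerebellum TAC C_R, no arterial
input), evaluated at frame mid-times with running integrals from
injection:

- **MRTM** — C_T(t) = R1·C_R(t) + k2·∫C_R − k2a·∫C_T, fit by WLS.
- **lp-ntPET** — MRTM plus a release term −γ·∫C_T·h over a library of
  unit-peak gamma-variate responses h(t; tD, tP, α); detection by
  nested-model F-test (17 bases, tD = 36 min, tP = 37–51 min, α = 1).
- **IMRTM** — iterative MRTM baseline extrapolation: fit MRTM on
  pre-task frames only, then repeatedly substitute the model curve into
  its own integral term, C⁽ⁿ⁾ = R1·C_R + k2·∫C_R − k2a·∫C⁽ⁿ⁻¹⁾,
  converging to the release-free baseline.
- **RSD-Hybrid-IMRTM** — per voxel j: z-scored pre-task kinetic
  coordinates (R̃1, k̃2, k̃2a) → non-local-means weights
  w_ij = exp(−‖d_j − d_i‖²/h²), h² = 0.5 → lp-ntPET pass replaces
  likely-release TACs (p_F < 0.05) with IMRTM baselines → NLM-weighted
  baseline average → nonnegative scale + reference spill-in fit on
  pre-task frames → percent residuals R_pct = 100(1 − C/Ĉ) → GLM
  R_pct(t) = β·P(t) with a unit-peak task predictor (block indicator ∗
  (t/L)e^(−t/L), L = 10 min). β is interpretable as the voxel's maximal
  percent TAC decrease from baseline.
- **Residual lp-ntPET** — R_abs = Ĉ − C obeys
  R_abs = γ·∫C·h − k2a·∫R_abs; a two-parameter linear fit yields γ and
  the peak occupancy pOcc = 100·(BPND0 − BPND|h=1)/BPND0 with
  BPND(t) = k2/(k2a + γ·h(t)) − 1.
- **Phantom simulator** — receptor-competition (ntPET-style) forward
  model on a 64×64×12 striatal phantom (bilateral ellipsoidal
  caudate/putamen, heterogeneous receptor density, localized/mid/global
  release clusters), with count-like noise and a Gaussian denoiser
  stand-in.
- **Evaluation** — empirical ROC against phantom ground truth,
  quantitative tracking curves, sparsity thresholding, dice overlap,
  one-sample T-maps, and a simplified RSD-k-means comparator (the
  earlier, purely data-driven baseline method).

## Worked example

Simulate five noisy realizations of low-amplitude (100 nM) localized
release, run the hybrid pipeline, and summarize:

```python
import numpy as np
from rsdpet import PhantomSpec, simulate_study, run_rsd_hybrid
from rsdpet.rsd import RSDConfig
from rsdpet.core_io import reference_tac
from rsdpet.residual_models import run_residual_lpntpet

studies = simulate_study(PhantomSpec(), "localized", 100.0, 5, seed=42)
cluster_beta, free_beta, replaced, pocc = [], [], [], []
for st in studies:
    ref = reference_tac(st.noisy, st.phantom.cerebellum)
    result = run_rsd_hybrid(st.noisy, st.phantom.striatum,
                            st.phantom.cerebellum, RSDConfig(), ref=ref)
    rel = st.phantom.release_masks["localized"].labels
    idx = result.voxel_indices
    in_cluster = rel[idx[:, 0], idx[:, 1], idx[:, 2]] > 0
    cluster_beta.append(np.nanmean(result.beta[in_cluster]))
    free_beta.append(np.nanmean(result.beta[~in_cluster]))
    replaced.append(result.diagnostics["replaced_fraction"])
    occ = run_residual_lpntpet(st.noisy, st.phantom.striatum, result, ref)
    pocc.append(np.nanmean(occ["pOcc"].values[rel > 0]))
```

which prints (seed 42):

```
realizations                 : 5
striatal voxels analyzed     : 1314
TACs replaced by IMRTM       : 34.9%
cluster-mean beta            : 1.21 %
release-free mean beta       : -0.50 %
cluster-mean peak occupancy  : 6.7 %
```

The 100-nM surge produces roughly a 1–2% maximal TAC dip after
smoothing; β resolves it from the near-zero background, about a third
of striatal TACs are flagged as release-containing and replaced by
model baselines, and the residual-space occupancy estimate grades the
binding change in the truth clusters.

## Command line

`rsdpet` exposes the same pipelines as subcommands operating on NIfTI
images plus a two-column frame-timing CSV (`start_min,duration_min`):

```
rsdpet simulate --scenario localized --da-peak 100 --realizations 5 --seed 1 --out sim/
rsdpet fit       --image sim/noisy_1.nii.gz --timing sim/frames.csv \
                 --striatum sim/mask_striatum.nii.gz --cerebellum sim/mask_cerebellum.nii.gz --out fit/
rsdpet rsd       ... --out rsd/          # beta map + diagnostics
rsdpet occupancy ... --out occ/          # gamma / pOcc / BPND0 maps
rsdpet evaluate-roc --maps rsd/beta.nii.gz --truth sim/mask_truth.nii.gz \
                    --fpr-mask sim/mask_fpr_region.nii.gz --out roc.csv
```

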