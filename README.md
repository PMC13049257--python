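# wfmra — self-gated, motion-corrected, model-based water-fat 3D MRA

`wfmra` is a desk-scale toolkit for reconstructing free-breathing dual-echo
Cartesian 3D MR angiography with 100 % data efficiency: instead of
prospectively rejecting heartbeats with a diaphragm navigator, every
heartbeat is kept, a respiratory surrogate is read off the repeated
ky=kz=0 self-navigator line, and the data are retrospectively binned,
motion-corrected and separated into water and fat images.  It is aimed at
MR-physics researchers who want a complete, testable reference
implementation of this reconstruction chain, exercised end-to-end on a
synthetic moving water-fat phantom with known ground truth.

The chain implements, in order:

1. **Sampling design** — overlay of three variable-density Poisson-disk
   patterns (fully sampled 5 % core, minimum peripheral density, elliptical
   corner cropping, partial Fourier 0.875) and a per-heartbeat center-out
   schedule of `nsegments` lines whose first line is always ky=kz=0.
2. **Self-gating** — PCA over the center lines' readout × coil samples
   gives a respiratory surrogate; windows are split into m=4 equal-count
   motion states with no data sharing.
3. **Respiratory-resolved CS reconstruction** (per-state second echo) with
   spatial TV plus TV along the state dimension
   (λ_TV = λ_TVT = 0.001, 15 L-BFGS iterations), used only to estimate
   **B-spline motion fields** (support spacing 6 voxels, Gaussian ROI
   decay), refined with Δms/2 interpolated intermediate states using the
   hepatic-to-cardiac scaling 0.57.
4. **Motion-compensated CG-SENSE** of both echoes,
   `E_moco,m = P_m F T_m C`.
5. **Image-based two-point Dixon**: per voxel the real-valued model
   `s_i = (w + dfat_i f) ∘ b_i` with `dfat = (0.70−0.37j, −0.58−0.20j)` at
   TE = 2.8/6.5 ms is solved in closed form (two candidate roots); the
   true/swapped labeling is chosen by smoothness of `b_2 conj(b_1)`, and
   the error phasors are Gaussian-smoothed (σ = 1.0, radius 4) preserving
   unit modulus and the inter-echo difference.
6. **Model-based water-fat reconstruction**: direct minimization of
   `Σ ‖E_m,i(w,f) − k_m,i‖² + λ_TV,w‖∇w‖₁ + λ_TV,f‖∇f‖₁`
   (λ = 0.0007, 10 L-BFGS iterations) with T and B held fixed.

A navigator-gating simulator (±4 mm acceptance window) quantifies the
scan-time predictability the self-gated acquisition buys, especially under
irregular breathing.  See `docs/methods.md` for models, parameters and
design rationale.

## Worked example

Simulate a moving phantom acquisition, reconstruct with and without motion
correction, and score against ground truth:

```python
import numpy as np
import wfmra as W

grid = (64, 64, 32)                        # 3 mm isotropic desk-scale matrix
phantom = W.make_phantom(grid, voxel_size=3.0, seed=11)
pattern = W.generate_pattern((64, 32), n_patterns=3,
                             target_lines=96 * 15, seeds=(21, 22, 23))
schedule = W.build_schedule(pattern, nsegments=16, seed=0)
trace = W.make_breathing_trace("regular", schedule.n_windows,
                               amplitude_mm=6.0, seed=7)
kset = W.simulate_acquisition(phantom, W.FatSpectralModel(), trace,
                              schedule, W.AcquisitionParams(noise_sigma=0.03),
                              seed=13)

config = W.PipelineConfig(liver_roi=phantom.diaphragm_roi)
moco = W.run_pipeline(kset, config, mode="selfgated")
nomoco = W.run_pipeline(kset, config, mode="gated-no-moco")

# compare against the ground truth expressed in the reference motion state
ref = moco.fields.reference_state
disp = [trace.displacement[moco.binning.assignment == m].mean()
        for m in range(4)][ref] if moco.binning.m == 4 else 0.0
w_truth, _ = W.phantom_at_displacement(phantom, disp)
print("water NRMSE, self-gated:", 
      W.compute_metrics(moco.waterfat.water, w_truth)["nrmse"])
print("water NRMSE, no moco:   ",
      W.compute_metrics(nomoco.waterfat.water, w_truth)["nrmse"])
print("recovered respiratory range [mm]:",
      moco.report["respiratory_range_mm"])
```

On this configuration the run prints (seeds as above):

```
water NRMSE, self-gated: 0.097
water NRMSE, no moco:    0.076
recovered respiratory range [mm]: 11.5
```

and `0.066` for the self-gated arm when the analytically known ground-truth
warps are injected (`run_pipeline(..., truth_fields=...)`) — the gap
between 0.097 and 0.066 is registration error (the respiratory-resolved
states carry millimetre-scale apparent-position biases from their
structured undersampling), and the gap from 0.066 to the no-moco 0.076 is
what motion correction buys on this 12 mm-range phantom.  Constraining the
fields to a torso ROI box (`PipelineConfig.roi_box`) tightens the
registered arm further; see `docs/methods.md`.  The surrogate correlates
with the true diaphragm trace at |r| ≈ 0.999.

A command-line interface wraps the same steps
(`wfmra simulate | pattern | recon | gate-sim | eval`); every run writes a
manifest with config hash, seed and versions.

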