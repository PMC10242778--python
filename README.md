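# smlm-register

Channel registration for multi-color single-molecule localization microscopy
(SMLM/STORM), operating directly on localization tables rather than on
rendered images.

## The problem

Multi-color STORM acquisitions are recorded sequentially, one channel at a
time. Between acquisitions the sample drifts and the optics shift, so the
channels end up misaligned by hundreds of nanometres to over a micrometre —
far above the ~20 nm resolution of the method — and any nanoscale
colocalization analysis on the overlay is meaningless without registration.

This package aligns channels using landmarks found directly in the
localization data:

* **Fiducial mode.** Fiducial beads (e.g. 100 nm TetraSpeck, visible in all
  channels) emit constantly, while genuine single-molecule signal blinks.
  For every candidate position `c` (seeded from the densest frame), the
  per-frame neighborhood occupancy over the `n` analyzed frames,
  `N_f = {x_f : d(x_f, c) < r}`, gives two statistics:

  - mean tolerance `MT = (1/n) Σ_f |N_f|`
  - variance limit `VL = (1/n) Σ_f (|N_f| − MT)²`

  A stable bead has `MT ≈ 1` and `VL ≈ 0`; blinking structure that is bright
  enough to pass an MT threshold has Poisson-scale count variance and fails
  the VL threshold. Candidates with `MT ≥ 0.5` and `VL ≤ 0.25` (defaults,
  with `r = 100` nm) are merged per bead and refined to neighborhood
  centroids.

* **Cluster mode.** When no beads are present, the densest localization
  clusters (e.g. multi-labeled nanoparticles) serve as landmarks: each
  localization is ranked by its neighbor count within a radius `r_c`
  (default 750 nm) pooled over all frames, and the top 25 spatially distinct
  localizations are retained.

Each moving channel's landmarks are then aligned to the reference channel's
by the Iterative Closest Point algorithm with a rigid model
`T(p) = R(θ) p + t` (least-squares rotation + translation via the closed-form
2-D Procrustes solution), recursive mean + 1 SD outlier rejection for
landmarks visible in only one channel, and a 1 nm convergence tolerance on
the mean pair distance. The resulting transform is applied to every
localization of the channel.

Registration quality is quantified by the Target Registration Error
(`TRE_i = ‖X_i − X_j‖₂` over index-matched landmark pairs, reported as
mean ± SD), by the Normalized Cross-Correlation of images rendered from the
two channels, and by a two-sided Wilcoxon signed-rank test on per-landmark
TRE before vs. after.

## Worked example

```python
import numpy as np
from smlm_register import (SimulationConfig, RigidTransform2D, simulate_channel,
                           detect_fiducials, icp, apply_transform)

# two simulated channels sharing 8 beads, misaligned by a known transform
misalignment = RigidTransform2D(theta=0.005, tx=800.0, ty=-400.0)
cfg = SimulationConfig(seed=7, n_fiducials=8, n_frames=2000)
rng = np.random.default_rng(7)
ref, truth = simulate_channel(cfg, "642", rng=rng)
mov, _ = simulate_channel(cfg, "488", transform=misalignment, rng=rng,
                          fiducial_positions=truth.fiducials)

beads_ref = detect_fiducials(ref)
beads_mov = detect_fiducials(mov)
print(f"landmarks: {len(beads_ref)} reference, {len(beads_mov)} moving")

result = icp(beads_mov, beads_ref)
t = result.transform
print(f"estimated: theta = {t.theta:.6f} rad, t = ({t.tx:.1f}, {t.ty:.1f}) nm "
      f"in {result.n_iterations} iterations")

corrected = apply_transform(mov, t)
err = np.linalg.norm(t.apply(misalignment.apply(truth.fiducials)) - truth.fiducials, axis=1)
print(f"residual TRE at the true bead positions: {err.mean():.2f} +/- {err.std(ddof=1):.2f} nm")
```

prints

```
landmarks: 8 reference, 8 moving
estimated: theta = -0.004991 rad, t = (-797.9, 403.7) nm in 3 iterations
residual TRE at the true bead positions: 0.21 +/- 0.08 nm
```

The estimated transform is the inverse of the injected misalignment
(θ = −0.005 rad, t = (−797.9, 403.7) nm against the exact (−798.0, 404.0) nm;
the sub-nanometre gap reflects the 10 nm per-frame localization jitter
averaged over ~1900 localizations per bead), and the residual alignment
error at the bead positions is three orders of magnitude below the initial
misalignment.

## Command line

```bash
smlm-register simulate --seed 3 --out-dir data/          # synthetic acquisition
smlm-register detect   --input data/ch0.csv --out lm.csv # landmarks only
smlm-register register --reference data/ch0.csv --moving data/ch1.csv --out-dir out/
smlm-register evaluate --before data/ch0.csv data/ch1.csv \
                       --after  data/ch0.csv out/ch1_registered.csv --report report.json
smlm-register run jobs.yaml                              # batch job list
```

`register` writes corrected localization CSVs (re-importable by
ThunderSTORM) plus a JSON sidecar per channel with the fitted θ, t and ICP
diagnostics. `run` executes a YAML list of registration jobs sequentially;
a failing job is reported without stopping the rest.

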