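# memprobe

Quantitative analytics for validating membrane **lipid biosensors** —
fluorescently tagged protein domains whose localization reports a specific
signaling lipid (e.g. PI(3,4)P₂) on the plasma membrane.  The package covers
the two measurement families such a validation needs, plus a synthetic-data
generator that provides ground truth for every analysis:

* **Single-molecule membrane kinetics** (`memprobe.spt`) — from tracked
  trajectories of individual membrane-bound probes:
  * time-averaged mean square displacement, pooled per cell and averaged
    across cells: for free 2D Brownian motion, MSD(τ) = 4Dτ + 4σ², where D
    is the diffusion coefficient and σ the localization error;
  * the **relative deviation ratio** rd = MSD(τ_test)/(4D̂τ_test + ĉ) from a
    short-lag fit — ≈1 for free diffusion, <1 confined, >1 directed;
  * **membrane lifetime**: dwell times are exponential with observed rate
    k_obs = k_off + β·P, where β·P is power-dependent photobleaching.  Fitting
    k_obs at several laser powers and extrapolating the line to P = 0 yields
    the true dissociation rate k_off and lifetime 1/k_off;
  * the **dwell displacement** r = √(2D/k_off), the typical distance a probe
    diffuses while lipid-bound — the scale over which free probe diffusion
    can blur a local lipid enrichment.
* **Image and time-course quantification** (`memprobe.quant`) —
  ROI-normalized channel subtraction (biosensor minus cytosolic reference,
  each divided by its own ROI mean, so membrane enrichment appears as a
  positive rim and the ROI mean is 0 by construction); Otsu-autothresholded
  compartment masks from a marker channel; and the time-course
  normalizations F_t/F_pre, min–max, and ΔF/|ΔF|_max with
  baseline-referenced area-under-curve summaries.
* **Synthetic data** (`memprobe.simkit`) — Brownian trajectory simulation
  with exponential dwells, frame quantization and localization noise, and
  confocal/TIRF/compartment image phantoms, all bit-reproducible from a seed.
* **Formats & CLI** (`memprobe.io`, `memprobe`) — TIFF stacks with µm
  calibration, tidy trajectory/trace CSVs, polygon-JSON or label-mask ROIs,
  YAML-configured pipeline runs.

## Worked example

Simulate ten cells per laser power under realistic conditions
(D = 0.3 µm²/s, 140 ms lifetime, 60 ms frames, 20 nm localization error,
bleach slope 0.2 s⁻¹ per power unit) and recover the probe parameters:

```python
import memprobe as mp
from memprobe.spt import (compute_msd, grand_msd, fit_diffusion,
                          fit_lifetime, extrapolate_off_rate,
                          diffusion_distance)

cfg = mp.SPTSimConfig(
    diffusion_coeff=0.3, k_off_true=1 / 0.140, bleach_coeff=0.2,
    powers=(25.0, 50.0, 75.0), n_cells=10, tracks_per_cell=300, seed=1,
)
cells = mp.simulate_membrane_spt(cfg)

grand = grand_msd([compute_msd(c, max_lag_frames=6) for c in cells])
est = fit_diffusion(grand)
print(f"D = {est.D:.3f} um^2/s (MSD intercept {est.intercept:+.4f} um^2)")

ext = extrapolate_off_rate(
    [(c.power, fit_lifetime(c), c.cell_id) for c in cells])
print(f"k_off(P=0) = {ext.intercept_k_off:.2f} /s -> true lifetime "
      f"{1000 * ext.true_lifetime:.0f} ms (bleach slope {ext.slope:.3f})")

r = diffusion_distance(est.D, ext.intercept_k_off)
print(f"membrane-bound excursion r = {1000 * r:.0f} nm")
```

Output:

```
D = 0.308 um^2/s (MSD intercept -0.0029 um^2)
k_off(P=0) = 7.27 /s -> true lifetime 137 ms (bleach slope 0.201)
membrane-bound excursion r = 291 nm
```

The fitted D and the extrapolated lifetime recover the simulation's ground
truth (0.3 µm²/s, 140 ms) to a few percent; the slope of k_obs versus power
recovers the bleach coefficient; and the dwell displacement lands at
≈0.29 µm — about the diffraction limit, meaning free diffusion of the
probe:lipid complex barely smears an optically resolvable lipid patch.
The small negative MSD intercept is sampling noise around the true
localization offset 4σ² = 0.0016 µm² and is reported, not clamped.

The same analyses run from the shell:

```sh
memprobe simulate-spt -c sim.yaml
memprobe spt-analyze  -c analyze.yaml
```

with YAML configs naming the task, output directory, and parameter blocks
(see `memprobe.io.RunConfig`); every run writes tidy CSVs, a JSON summary,
and a provenance block (config echo, package version, seed, input digests).

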