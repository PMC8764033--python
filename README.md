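# smor — single-molecule off-rate analysis

`smor` measures how long a fluorescent ligand stays bound to its
immobilized binding partner. In a single-molecule off-rate (SMOR)
experiment, receptors that cannot be purified in bulk — multi-subunit
ubiquitin ligases, for example — are tethered sparsely to a coverslip,
a dye-labeled peptide or substrate is flowed in at ≤1 nM, and TIRF
microscopy records each binding event as a diffraction-limited spot
blinking on and off. The mean bound dwell time τ gives the dissociation
rate constant directly:

    k_off = 1 / τ,        K_D = k_off / k_on,        k_on = k_off / K_D

so a single-molecule off-rate plus one ensemble equilibrium constant
(e.g. from a fluorescence-anisotropy titration) pins down the full
kinetic description of the interaction — including K_D values far too
tight to titrate directly.

The package provides the complete analysis chain and a ground-truth
simulator to validate it:

- `smor.simulate` — synthetic TIRF movies with known two-state kinetics,
  Gaussian PSFs, a centered excitation gradient, multimer and
  stuck-ligand contaminants, drift, shot + read noise, and a ground-truth
  channel (true dwells, site table, drift track).
- `smor.preprocess` — central crop, max/min intensity projections,
  flat-field correction from the movie itself, drift correction.
- `smor.peaks` — candidate sites as 3×3-pixel squares on local maxima of
  the corrected max projection; multimers rejected above median + 3 SD of
  the max-projection intensity, persistent background via the same rule
  on the min projection.
- `smor.traces` — per-peak intensity traces, a pooled double-Gaussian
  emission model, two-state HMM idealization (Viterbi), and rejection of
  traces whose RMSD from the two-level fit exceeds median + 2 SD.
- `smor.dwell` — dwell extraction with censoring and single-frame
  bookkeeping, exponential maximum-likelihood τ with SE = τ/√n, survival
  curves, and the τ ≥ 3·Δt reliability flag.
- `smor.kinetics` — k_off / k_on / K_D arithmetic, fold ratios, and
  ligand × receptor summary tables ("SF" / "No binding" conventions).
- `smor.anisotropy` — one-site equilibrium fits of anisotropy titrations,
  competition-format comparisons, and a synthetic-titration generator.
- `smor.pipeline` / `smor.cli` — end-to-end orchestration
  (`analyze_movie`) and the `smor` command-line tool.

## Worked example

Simulate a movie with known kinetics (τ = 0.5 s at 100 ms frames,
100 sites with multimer and stuck-ligand contaminants) and analyze it:

```python
import numpy as np
from smor import SimConfig, render_movie, RunConfig, analyze_movie

cfg = SimConfig(image_size=200, n_frames=600, frame_interval=0.1,
                n_sites=100, tau_bound=0.5, tau_unbound=10.0,
                min_separation=7.0, seed=11)
movie, truth = render_movie(cfg)
report = analyze_movie(movie, RunConfig(crop_size=200))
est = report.estimate
print(f"peaks: {report.n_peaks_detected} detected, "
      f"{report.n_rejected_bright} too bright, "
      f"{report.n_rejected_dim_background} on background, "
      f"{report.n_rejected_rmsd} poor HMM fit")
print(f"tau = {est.tau:.3f} +/- {est.se:.3f} s  (n = {est.n} dwells, "
      f"{est.single_frame_count} single-frame events)")
print(f"k_off = {est.k_off:.2f} 1/s   reliable = {est.reliable}")
print(f"true dwell mean = {truth.true_dwells().mean():.3f} s")
```

prints

```
peaks: 104 detected, 4 too bright, 2 on background, 1 poor HMM fit
tau = 0.481 +/- 0.025 s  (n = 378 dwells, 88 single-frame events)
k_off = 2.08 1/s   reliable = True
true dwell mean = 0.480 s
```

The brightness filter removed the simulated multimers, the min-projection
filter the stuck ligand, and the RMSD filter traces that do not look like
a clean two-level signal; the recovered τ agrees with the ground truth
within its standard error. Combining such an off-rate with an ensemble
K_D from the anisotropy module then yields k_on, or transfers it to a
tighter receptor variant:

```python
from smor.kinetics import infer_kon, infer_kd, round_sig
k_on = infer_kon(1 / 0.360, 3.5e-6)        # 8e5 /M/s
kd   = infer_kd(1 / 35.3, k_on)            # 3.6e-8 M, i.e. ~36 nM
```

The same steps are available from the shell:

```sh
smor simulate --config sim.yaml --out movie.tif
smor analyze movie.tif --frame-interval 0.1 --crop 300 --out results/
smor kinetics --tau 0.360 --kd 3.5e-6
smor anisotropy titration.csv
```

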