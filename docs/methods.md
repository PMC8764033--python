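# Methods

`smor` measures the dissociation kinetics of transient ligand–receptor
interactions from single-molecule TIRF movies: immobilized receptors are
sparsely distributed on a coverslip, a fluorescent ligand binds and
unbinds, and the distribution of bound dwell times yields the dissociation
rate constant, `k_off = 1/τ`. This note describes the model assumptions,
the algorithmic choices at each stage, what the synthetic-movie generator
does and does not emulate, and the known limitations.

## Kinetic model

Each binding site is an independent two-state continuous-time process:
bound intervals are exponential with mean `τ_bound`, unbound intervals
exponential with mean `τ_unbound = 1/(k_on·[L])`. The stationary bound
fraction is `τ_b/(τ_b+τ_u)`. Because the exponential is memoryless, a
trajectory started from the stationary state distribution needs no special
treatment of its first interval. Dwell times are measured per frame, so
everything downstream of the HMM lives on a grid of width `Δt` (the
acquisition interval).

The mean of the observed dwells is the exponential maximum-likelihood
estimate of `τ`, with standard error `τ/√n`. An estimate is flagged
*reliable* only when `τ ≥ 3·Δt`; the discretization analysis below shows
why shorter dwell times cannot be trusted.

## Synthetic movies

The generator (`smor.simulate`) renders what the analysis must defeat:

- **Spots.** Each site is a pixel-integrated 2-D Gaussian PSF
  (`psf_sigma`, default 1 px) at a subpixel position; pixel values are the
  exact Gaussian integral over the pixel area, so photon mass is conserved
  to ~1e-9 within the rendered patch.
- **Within-frame integration.** Occupancy is integrated over each exposure,
  not sampled at frame boundaries. An event shorter than a frame produces
  a genuinely attenuated single-frame spot; an event spanning `k` frames
  has two partial-brightness edge frames. This is the feature that makes
  single-frame bookkeeping and the reliability rule testable.
- **Illumination.** A centered 2-D Gaussian excitation profile
  (`illumination_sigma`, default 150 px on a 512-px sensor — brightness
  roughly halves within the field). Both the spots and the diffuse
  background scale with it.
- **Contaminants.** A fraction of sites are multimers at 2–3× the monomer
  amplitude (default 5%) and a fraction are bound for the entire movie
  ("stuck" ligand, default 2%).
- **Noise.** Per-pixel Poisson shot noise on signal + background (default
  background 5 photons/px/frame), Gaussian read noise (default 1.5
  counts), a camera offset (default 100 counts), and rounding to integer
  counts. With all noise disabled the analog expectation image is returned
  so conservation checks hold exactly.
- **Drift and bleaching.** Optional global drift (velocity + jitter,
  cumulative from frame 0) and a deterministic exponential bleaching
  envelope whose default time constant is 100× the movie duration, i.e.
  negligible, matching oxygen-scavenged imaging conditions.

Amplitude and background defaults describe an EMCCD at high gain imaging
a bright organic dye (monomer 1500 photons/frame at the field center);
they give a per-trace signal-to-noise ratio of roughly 15, comfortably in
the regime where state classification errors are confined to
partial-occupancy edge frames.

Not emulated: dye photophysics (blinking), EM-gain excess noise, 3-D PSF
structure, nonuniform site brightness beyond the illumination profile and
subpixel PSF sampling. Passing the recovery tests therefore demonstrates
correctness of the inference chain under idealized photophysics, not
robustness to blinking dyes or gain noise.

## Pipeline stages and numerical choices

Order: crop → max/min projections → flat-field → (optional) drift →
peak detection → intensity filtering → traces → pooled double-Gaussian →
per-trace HMM → RMSD filtering → dwell extraction → exponential MLE.

**Crop.** The central window (default 300×300 of a 512×512 sensor); for
odd remainders the extra pixel stays on the high-index side.

**Flat-field.** The filter is estimated from the maximum-intensity
projection. Pixels above a signal threshold — the `mask_quantile`
(default 0.75) of the projection OR a robust background floor
(median + 5 MAD-SD), whichever is higher — count as signal. Two regimes:

- *Dense fields* (signal covering ≥ 15% of pixels): each 20×20 bin is
  averaged over its own brightest pixels (half the global signal
  fraction). Ranking per bin keeps the statistic linear in local
  brightness; a single global threshold selects fewer, relatively brighter
  pixels in dim bins and compresses the estimated gradient by tens of
  percent. The bin image is smoothed on the bin grid (sigma =
  `bin_size/2` pixels), upsampled bilinearly between bin centers with
  linear edge extrapolation, and normalized to unit mean.
- *Sparse fields*: with of order one spot per bin, per-bin brightness is
  dominated by which sites (and which multimers) landed where, and the
  non-parametric estimate tracks occupancy instead of illumination. A
  quadratic polynomial in log-brightness — the family containing a
  Gaussian excitation profile — is fitted to the occupied bins with two
  rounds of 3-MAD outlier trimming, which removes multimers.

Correction divides each frame by the filter after subtracting the camera
offset and re-adds it, so the additive baseline is not warped.

**Drift.** Estimated from segment-wise maximum projections (default 50
frames per segment; single frames are too sparse in transient spots),
registered to the first segment by upsampled cross-correlation, linearly
interpolated between segment centers, extrapolated at the ends and pinned
to zero at frame 0. Correction uses a Fourier-domain subpixel shift —
spatial interpolation, even cubic, measurably flattens the peaks of
σ ≈ 1 px spots — with the wrapped margin blanked to the camera offset.
The pipeline enables drift correction automatically when the acquisition
interval exceeds 1 s.

**Peaks.** 3×3-pixel squares centered on local maxima of the corrected
max projection (non-maximum suppression at 3 px; border footprints
dropped). The default detection threshold is a robust background estimate
(median + 5 MAD-SD of the projection). Peak intensity is the footprint
mean, in both projections. Two population rules then apply: max-intensity
above median + 3 SD marks a multimer; min-intensity above its own
median + 3 SD marks stuck ligand or elevated background. SD is the plain
sample standard deviation by default, faithful to the rule as usually
stated; a MAD-based option exists because at ≳10% contamination the
contaminants inflate the plain SD enough to hide under their own
threshold.

**Emission model.** Intensities pooled over all selected traces are
histogrammed (256 bins) and fitted with a sum of two Gaussians by least
squares. Fitting the histogram rather than maximizing a two-component
mixture likelihood matters: partial-exposure frames form a smear between
the levels, and mixture EM absorbs it into an inflated "bound" component
while the histogram fit locks onto the two modes. Initialization splits
the sample at the Otsu threshold. When dwell times approach the frame
interval almost no full-occupancy frames exist and even the histogram fit
sinks into the smear; the fit is then retried with the bound component
anchored at the median of per-trace maxima (each trace's maximum is a
robust full-level sample). A fit is degenerate — "no two-state
structure" — when the separation is less than max(6 unbound widths, 1.5
bound widths). Mixture EM remains as a fallback if the curve fit fails to
converge.

**HMM idealization.** Two-state Gaussian-emission HMM per trace. State
means are fixed at the pooled double-Gaussian values; the transition
matrix (initial self-transition 0.95) is re-estimated by EM (≤100
iterations, tolerance 1e-6); the state path is the Viterbi path. By
default both emission widths are set to the *unbound* width: the fitted
bound width reflects brightness heterogeneity across molecules and
partial frames, not per-frame noise, and using it would drag the decision
boundary toward the baseline and count barely-occupied frames as bound.
With shared widths the boundary is the midpoint of the two levels, i.e.
a frame is called bound when the site was occupied for more than about
half the exposure — which makes a recorded duration approximately
`round(L/Δt)·Δt`. Full per-trace Baum–Welch re-estimation is available
behind a flag. RMSD is computed between the trace and the state means
along the Viterbi path; traces with RMSD above median + 2 SD of the
population are rejected (one-sided: an unusually good two-level fit is
not a defect).

**Dwells and MLE.** Maximal bound runs become dwells; runs touching the
movie boundary are censored (kept with a flag, excluded from the default
fit); uncensored one-frame runs are tallied as single-frame events —
real binding with unresolved sub-frame duration — and excluded from the
fit. Because events below ~1.5 frames are recorded as single-frame, the
multi-frame dwells are left-truncated at ~1.5·Δt; by memorylessness the
truncated-exponential MLE is the sample mean minus the truncation point,
and the pipeline applies this correction by default
(`truncation_correction`). The bare `mle_exponential` without
`min_dwell` is the plain closed form. An optional censored likelihood
(`Σ durations / n_uncensored`) is provided for long-dwell conditions
where much of the data is censored at realistic movie lengths. Movies
with fewer than `min_events` (default 5) bound events are classified
"no binding"; movies with only single-frame events are classified
"single frame".

**Discretization and the 3-frame rule.** With midpoint classification, an
event of true length `L` is recorded as `round(L/Δt)` frames, and
conditioning on ≥2 frames plus the rounding nonlinearity leaves a
residual upward bias of order `+10%` at `τ = Δt` that falls to the
percent level by `τ = 5·Δt`. The reliability flag `τ ≥ 3·Δt` marks the regime
where this bias and the single-frame losses are material — reproduced
empirically by the acceptance suite rather than assumed.

## Kinetics and equilibrium binding

`k_off = 1/τ`; combining with an ensemble `K_D` gives `k_on = k_off/K_D`;
transferring `k_on` between receptor variants gives an inferred
`K_D = k_off/k_on`, always carrying an explicit `kon_transferred` flag.
Reported values follow field conventions (k_off two significant figures,
inferred k_on and K_D one); stored values keep full precision.

Anisotropy titrations are fitted to the one-site hyperbola
`r = r_free + (r_bound−r_free)·[P]/(K_D+[P])` by weighted least squares
with both endpoints free; the probe (≈10 nM) is far below micromolar
K_D values so free ≈ total protein, and an exact quadratic
ligand-depletion form is available for tight binders.
`saturation_reached` requires the top concentration to be ≥ 5× the
fitted K_D; fits whose amplitude is indistinguishable from noise, or
whose K_D runs far beyond the titrated range, are reported as showing no
significant binding. The synthetic-titration generator emulates 10
plate-reader reads per reaction with Gaussian noise (default per-read SD
0.004 anisotropy units) over a 2-fold dilution series topping out at
30.6 µM.

## Validation problem sizes

The acceptance suite simulates 300×300-px, 2000-frame movies at
`Δt = 0.1 s` with 150 sites for dwell-time recovery (20 seeded movies at
`τ` of 0.4 s and 2 s); 200×200, 1500-frame movies for the discretization
analysis; an 800-frame contaminant panel (10% 3× multimers; hosts with a
dim slow-switching neighbor 2 px away for the RMSD rule); and a densely
covered calibration lawn (2500 sites, no contaminants) for flat-field
quality. 100 seeded titrations validate K_D recovery.

## Limitations

- The flat-field estimate assumes either dense coverage (rank-based bin
  statistic) or a smooth low-order illumination profile (sparse path); a
  sparse field under structured, non-quadratic-in-log illumination would
  be corrected only approximately.
- Fixed pooled emission means ignore residual site-to-site brightness
  variation (subpixel PSF sampling spreads the bound level by ~±8%),
  which slightly blurs the effective occupancy threshold per trace.
- Dwell histograms are fitted with a single exponential; mixtures of
  binding modes are out of scope, as is hierarchical pooling across
  replicate movies.
- Censored dwells are dropped by default; for conditions where `τ` is
  comparable to the movie length the censored-likelihood option should be
  used, and even it treats the truncation point as exact.
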