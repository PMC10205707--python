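# Methods

This note documents the models, estimators and numerical choices behind
vasculong, what the synthetic generators do and do not emulate, and the
design decisions taken where more than one reasonable option existed.

## Vessel diameter and flow from images

**Registration.** Repeat-visit angiograms are aligned with an in-plane
rigid transform (shift + rotation about the image centre). The search is a
coarse sweep over rotation (±15°, 1° steps; each angle scored by FFT phase
correlation for the best shift), followed by bounded scalar refinement of
the angle and sub-pixel shift estimation at 20× upsampling, then one more
pass on the aligned image to decouple large translations from the rotation
estimate. Images are mean-subtracted and Hann-windowed before correlation
— without this, the DC term and zero-fill edges pin the correlation peak
at zero lag. Quality is reported as the normalized cross-correlation over
the genuinely overlapping pixels; below 0.2 the result is flagged
low-confidence. On noiseless overlapping-field phantoms the recovery is
better than 0.1 voxel and 0.25° for shifts up to ~50 voxels and rotations
to ±10°.

**FWHM diameters.** A cross-sectional intensity profile is sampled along
the line orthogonal to the local vessel orientation (smallest-eigenvalue
eigenvector of the structure tensor), averaging 10 adjacent profiles along
the vessel to suppress local thickness fluctuation. The profile is fitted
with offset + A·exp(−(x−µ)²/2σ²) (initialized from the peak position and
second moment, refined by Levenberg–Marquardt), and the diameter is
2√(2 ln 2)·σ ≈ 2.3548σ. Fits are rejected — with the reason — when the
amplitude does not clear 3× the noise floor or the relative residual
exceeds 0.5. Penetrating vessels use an elliptical 2D Gaussian with free
orientation; the scalar diameter is the geometric mean of the two FWHMs
(the reduction to a single number is a package choice; an axis-ratio
diagnostic is available from the fit).

**Doppler flow.** Flow through a penetrating vessel is the area integral
Σ v_z ΔA over an en-face mask, converted to nL/min (1 nL = 10⁶ µm³). A
tilt θ reduces the axial velocity by cos θ and stretches the en-face
section by 1/cos θ, so the integral is tilt-independent; numerically the
deviation is <2% up to 30° on Poiseuille phantoms. "Noise reduction"
before integration is a median filter plus zeroing of sub-threshold |v_z|
pixels; the original study delegates this step to a separate method whose
exact operator is not public, so ours is a labelled stand-in with the
threshold exposed as a parameter. Flow sign (arteriole vs venule) is taken
from metadata, not inferred.

## Capillary network properties

Vessels are the unit of analysis. All graph metrics run on the
vessel-adjacency graph: vessels are nodes and two vessels are adjacent
when they share a junction, so path lengths count vessels (hops), not
micrometres.

- **Length**: centerline polyline arc length.
- **Diameter**: 2× the Euclidean distance transform of the binary
  segmentation sampled at centerline voxels (or 2× mean stored radius when
  no mask is given).
- **Tortuosity**: mean ‖dT/ds‖ of the unit tangent by finite differences
  along arc length, after dropping repeated points; 0 for straight
  segments, 1/R on a circle of radius R (verified to 1%).
- **Branching order**: multi-source BFS hop count from the penetrating
  vessels (order 0); unreachable capillaries are reported missing.
- **Betweenness**: shortest-path betweenness with fractional credit when
  several shortest paths tie (the standard convention; the source text is
  silent on ties).
- **Closeness**: 1/Σd(v,u) — the reciprocal *sum* of hop distances, not
  the (n−1)/Σd variant.
- **Shortest cycle**: for each vessel, 1 + the shortest junction-graph
  path between its endpoints after removing the edge; acyclic vessels are
  excluded from network means.

**Honeycomb normalization.** Betweenness and closeness depend strongly on
network size, so network means (and COVs) are divided by the matched-size
idealized honeycomb value. The honeycomb patch is grown as a hexagonal
lattice and trimmed to the exact vessel count by repeatedly removing the
removable edge farthest from the patch centroid (dangling chains first,
ties by node index), which keeps the patch compact; a honeycomb patch
therefore normalizes to exactly 1 by construction. References are computed
exactly (and cached) up to 600 vessels and linearly interpolated on a
cached size grid beyond that, the size dependence being smooth. Perfectly
symmetric patches (the single hexagon) have zero metric COV; their COV
reference falls back to the mean COV of the neighbouring patch sizes
(n±1, n±2), since coordinate jitter cannot break a purely topological
symmetry.

**Global measures.** Number density (capillaries/mm³), length density
(mm/mm³), and the box-counting fractal dimension: the least-squares slope
of log(occupied boxes) vs log(1/box size) over half-open boxes of 2–64
voxels; line/plane/cube phantoms recover 1/2/3 within 0.15.

**Skeletonization.** Binary masks are vectorized classically: 3D thinning,
26-connected voxel graph, junction voxels (≥3 neighbours) clustered into
junction nodes, degree-2 chains traced into segments with radii from the
distance transform, spurs shorter than 6 µm pruned, and pass-through
nodes merged. Degree-2 junctions of a generating lattice are geometrically
invisible to any image-based vectorization, so round-trip comparisons use
the degree-2-contracted ("canonical") segment count, which the skeleton
recovers exactly on clean phantoms.

## RBC flux

**Peak counting** counts local maxima above mean + 2 SD (threshold
configurable — the method's known weakness) per unit time. Transients
merge as flux grows, so the count saturates; the simulation sweep
reproduces the systematic high-flux undercount.

**Regressor.** A 1D CNN in the InceptionTime style: 2 inception blocks
(bottleneck to 8 channels, parallel kernels 9/19/39 plus a maxpool→1×1
path, 32 output channels), a residual 1×1 shortcut from the input, global
average pooling and a two-unit head: flux ŷ and log σ (σ by
exponentiation, guaranteeing positivity; ŷ clamped at 0 on output). The
cited architecture's exact depth/width is not published for this use;
these defaults are the canonical configuration scaled to the 512-sample
trace. Training minimizes the heteroscedastic Gaussian NLL
½ log 2π + log σ + (G − ŷ)²/(2σ²) with Adam (lr 8·10⁻⁴), global-norm
gradient clipping at 500, and time-reversal augmentation; data are split
70/20/10 after augmentation. Targets are standardized during training —
on raw RBC/s targets the NLL is badly conditioned (σ inflates and the
flux gradient vanishes) — and predictions are mapped back. The network
and its backpropagation are plain numpy; gradients match central finite
differences to ~10⁻⁸ relative (tested). Training labels come from the
simulator's realized arrival counts, standing in for the paired
two-photon ground truth that is not publicly available; no pretrained
weights ship with the package.

**Aggregation.** Confidence is 1/σ; "dropping the lowest 20% confidence"
removes the largest-σ quintile. Per-vessel flux is the inverse-variance
weighted mean Σ(ŷᵢ/σᵢ²)/Σ(1/σᵢ²) — the minimum-variance unbiased
combination, chosen because the weighting formula itself is not published.
Network summaries report the across-vessel mean and COV (sample SD/mean).

## Longitudinal statistics

**Model.** For each property, per-group trajectories — linear
(intercept + slope, age centred at 11 weeks) or sigmoid
y = c + L/(1 + exp(k(b − age))) — with per-animal random effects and
shared variance components, fitted by marginal maximum likelihood with
per-animal block covariances V = Z D Z′ + σ²I (log-Cholesky
parameterization). The linear-in-mean coefficients are profiled out by GLS
inside the optimizer, leaving a 2–6 dimensional Nelder–Mead problem;
balanced groups share a single Cholesky factor per evaluation. The same
fitter serves both families so their information criteria are directly
comparable; the linear case reproduces statsmodels MixedLM (ML) to ≥5
decimals in coefficients, SEs and log-likelihood (tested). The sigmoid
family uses a per-animal random intercept; the linear family selects
{intercept} vs {intercept, slope} by the information criterion. A third
conceivable structure, a per-animal random time-group interaction, is
collinear with the random slope because group is a between-animal factor,
so the selection is over the two identifiable structures.

**Normalization.** Each group's values are divided by the fitted group
baseline (the model value at the first measurement age), then refit; all
rates, bands and comparisons are on this normalized scale, so every fitted
trajectory starts at 1 by construction.

**Model selection.** The lower information criterion wins, ties to linear.
The default criterion is AICc, the small-sample corrected AIC: with ~91
observations, plain AIC admits the 4-extra-parameter sigmoid on truly
linear data at its asymptotic ~9% false-selection rate
(P(χ²₄ > 8) = 0.092), while AICc selects the generating family in 100% of
low-noise replicates in both directions. Plain AIC remains available as an
option.

**Outliers.** Before fitting, rows with Cook's distance above 3× the mean
(computed per group on the linearized intercept+slope design) are removed
and logged. Degenerate, numerically exact fits are skipped — their
residuals are pure rounding noise and the ratio rule would fire
arbitrarily.

**Rate of change with age (RCA).** Linear: slope × 4 weeks/month × 100,
in %/month (1 month = 4 weeks throughout, matching the imaging cadence).
Sigmoid: on the 11–35 week window, take the fitted curve's range Δ, find
the ages where the curve crosses 5% and 95% of Δ (by interpolation on a
0.01-week grid), and report 0.9Δ divided by that age span, signed by the
direction of change; "total change" is the fitted-curve range over the
measurement window, not the asymptotic L. The identical rule applied to
the 95% delta-method band curves gives the CI.

**Group comparison.** Linear fits: Wald test of the slope difference
(age×group interaction). Sigmoid fits: the same statistic on the amplitude
estimates L̂. The statistic is referred to t with (n_animals − 2) degrees
of freedom — a small-sample calibration for between-group contrasts;
simulated type-I error at 7-vs-6 animals × 7 ages is 0.06 at nominal 0.05.
The 25 raw p values are Benjamini–Hochberg corrected at α = 0.05.

**Age of significance (AOS).** For significant properties, 93% confidence
bands (Bonferroni 0.05/7 across the seven visits — the level at which
"just touching" bands correspond to a pointwise test at that rate) are
evaluated on a 0.1-week grid; the separation is the lower band of the
higher group minus the upper band of the lower group, and the AOS is the
earliest age from which that distance stays positive through 35 weeks —
persistence, not first touch, so a transient early separation does not
count.

**Cognition.** The NOL discrimination index is Z = T_SE/(T_NW + T_SE)
(chance 0.5; ≤0.5 flags decline). Correlations between vascular change
and cognition regress Z on each property's lagged fractional change with
a per-animal random intercept (statsmodels MixedLM); a significant slope
(p < 0.05, no multiplicity correction, matching the original analysis)
marks a correlation with the slope's sign, and Pearson r across lags
identifies the maximum-correlation lag. Lags default to 0/4/8/12 weeks;
a months-unit variant is exposed as an option because the source material
is internally inconsistent about the unit.

## Synthetic data: what it does and does not emulate

The generators provide every input class with known ground truth:
honeycomb patches; 3D beds (stacked jittered honeycomb layers with
vertical links at alternating junctions and flagged penetrating vessels —
the simplest 3-connected bed with the degree-3 junction signature);
angiogram volumes (tubes with a Gaussian cross-profile whose FWHM equals
the local diameter, so the half-maximum isophote is the wall; additive
Gaussian noise; paired ground-truth masks); RBC traces (Poisson arrivals,
one Gaussian transient per passage — the pulse shape is a convention, the
source does not specify an intensity model; FWHM default 7 ms ≈ 5 samples;
white noise at amplitude/SNR, the training dataset drawing each trace's
SNR uniformly from 1.5–8 to emulate capillary-to-capillary signal-quality
variation — without that heterogeneity the regressor's σ carries no
information beyond the flux level itself and confidence filtering has
nothing useful to remove); cohorts (trajectory + random effects +
residual noise per animal, ages 11–35 in 4-week steps, 7 AD vs 6 WT); and
NOL time pairs consistent with a target Z trajectory.

Not emulated: OCT speckle statistics, cardiac pulsation, motion artifacts,
capillary stalling, vessel-diameter/flux coupling, and any systematic
image artifact. Passing tests therefore demonstrate the correctness and
calibration of the estimators under the stated noise models — not
robustness to every property of real OCT data.

Default simulation sizes (beds of ~60 vessels for oracle comparisons,
2,000 traces / 15 epochs for the flux study, 100–150 replicates for the
calibration studies) were chosen so the full suite runs on a single CPU
in well under half an hour while leaving the Monte-Carlo standard errors
comfortably inside the asserted bands.

## Known limitations

- The sigmoid mixed model uses a random intercept only; random effects on
  L or k are not fitted (full nonlinear ML over those is substantially
  less stable at 6–7 animals per group).
- CI bands for the sigmoid are delta-method (Gauss–Newton covariance); a
  bootstrap alternative is not implemented.
- The honeycomb COV fallback for perfectly symmetric patches is a
  package convention; no published definition exists for that corner.
- `exclude_outliers` screens on the linearized design even when the
  sigmoid is ultimately selected, mirroring the practical rule it
  implements.
- The flux regressor is trained and validated on simulated passages; its
  absolute accuracy against two-photon ground truth is out of scope
  because that paired dataset is not deposited.
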