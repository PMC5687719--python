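# Methods

## The measurement problem

A fixed camera images an agar plate at regular intervals in three color
channels (R, G, B). Colonies of fluorescent-reporter strains appear as
bright, approximately circular blobs that expand and brighten. The goal
is to turn the pixel record into three per-colony quantities: the growth
parameters of the colony's area, the time course of its specific growth
rate, and the production rate of the fluorescent protein — plus, for
mixed plates, the strain identity of each colony.

All times are in hours, so rates carry h⁻¹; positions are (row, col),
0-based, pixel centers at integer coordinates; intensities are arbitrary
camera units ("au") after promotion to float.

## Background correction

The background is modeled as a per-channel scalar. The default estimator
is the per-channel median of frame 0 (`first_frame_median`): colonies
are absent or tiny at the start, and the median ignores the few bright
pixels. An alternative, `per_pixel_temporal_min`, takes the median over
pixels of the per-pixel temporal minimum; it tolerates colonies already
visible in frame 0 but is biased low by roughly 1.5 σ_noise for ~10
frames, since the minimum of several noise draws sits below their mean.
Subtracted values are clipped at 0 by default.

## Colony detection

Detection runs once on the *temporal sum projection* — all channels of
all frames summed per pixel — so that colonies appearing at any time are
visible in a single image. The projection is Gaussian-smoothed
(σ_smooth = 2 px default) and passed to a multiscale
Laplacian-of-Gaussian detector with a logarithmic scale ladder
(defaults σ ∈ [3, 30] px, 10 scales) and per-scale response
normalization. The response threshold defaults to 5% of the projection
maximum, making detection robust to exposure. Overlapping detections
keep the stronger response. Detection runs on the smoothed projection;
whether smoothing should precede detection is a free choice here and
smoothing won on noise robustness.

Each blob's scale σ sizes a square ROI of half-width
max(1, round(3σ)) — ±3σ covers ~99.7% of a Gaussian profile — clipped
to the image. Blobs are labeled in row-major center order with ties
broken by column then response, so labels are deterministic.

## Radius series and the smoothing correction

Per frame, the channel-summed ROI crop is lightly smoothed (σ = 1 px)
and blob-fit; the blob nearest the ROI center is kept if its refined
response clears an absolute threshold (default 4 au) and it lies within
half the ROI half-width of the center; otherwise the frame's radius is
missing (NaN), which is the normal state before the colony appears.

Two numerical choices matter for accuracy:

* **Scale refinement.** The discrete scale ladder quantizes σ too
  coarsely for a 15%-accurate radius, so the scale-normalized LoG
  response at the detected center is maximized continuously over σ by
  bounded 1-D search. The response at a single pixel is evaluated as a
  direct correlation with a truncated (4σ) LoG kernel, avoiding
  filtering the whole crop per iteration.
* **Smoothing deconvolution.** Pre-smoothing widens the blob; the
  colony's own scale is recovered as σ_colony² = σ_detected² −
  σ_smooth², exact for Gaussian profiles and a good approximation for
  discs near the response optimum.

The radius is then r = √2·σ_colony: the LoG response of a uniform disc
peaks when the disc edge sits at √2·σ. On simulated colonies this
estimator stays within ~8% of the true radius for r ≥ 3 px.

## Logistic growth fit

Areas A = πr² at the defined frames are fit with
A(t) = A_max / (1 + e^(−μ_max (t − t₀))) by bounded nonlinear least
squares (tolerances 1e−12). Initialization uses the data directly:
A_max⁰ = max area, t₀⁰ = earliest time area ≥ A_max⁰/2, and
μ_max⁰ = 4·(dA/dt at t₀⁰)/A_max⁰ from the logistic midpoint slope
identity dA/dt|_{t₀} = μ_max A_max / 4. Missing radii are excluded, not
imputed — zeros would bias t₀ early. Fits need ≥ 4 defined points;
non-convergence raises with the optimizer's diagnostics.

The specific growth rate uses the closed form
μ(t) = μ_max/(e^(μ_max(t−t₀))+1) rather than differentiating data; the
closed form is exactly (1/A)dA/dt of the fitted model.

## Expression rate

The colony mask at frame t is the disc of *fitted* radius
r(t) = √(A_fit(t)/π) centered on the detected blob — the fitted curve,
not the noisy per-frame radius, so early frames get sensible masks.
F(t) = (channel-summed intensity in mask)/(mask pixel count) is smoothed
with a cubic `UnivariateSpline`; its analytic derivative and the
closed-form μ(t) give

    K_F(t) = F′(t) + μ(t) F(t).

The μF term corrects for dilution: a growing colony dilutes its
fluorophore, so concentration alone underestimates production. The
default spline smoothing factor is n·(median |ΔF|)², using the median
absolute successive difference as a parameter-free noise scale.
Evaluation outside the fitted time range raises rather than
extrapolates.

## Strain classification

After background subtraction, zero protein means zero signal, so each
protein's (R_total, G_total) relation is a line through the origin;
its slope is fit as Σ(RG)/Σ(R²) from ≥ 2 single-strain colonies.
Colonies are assigned to the signature minimizing
|atan2(G, R) − atan(slope)| — an *angular* distance, chosen over
Euclidean point-to-line distance because colony brightness scales with
size and expression while the channel ratio is the protein's invariant;
the rule is therefore exactly scale-invariant. Ties go to the
lexicographically first label and are flagged by a zero runner-up
margin. Channel totals default to the final frame (`endpoint`); a
`time_sum` variant sums all frames. The blue channel is carried but
unused by the default two-channel rule.

## Synthetic plates

The simulator is the generative twin of the analysis models: disc
colonies with logistic area, per-pixel fluorescence from
dF/dt = K_F − μ(t)F integrated by fixed-step RK4 (step ≤ 0.01 h), RGB
splitting by per-protein emission vectors normalized to channel-sum 1
(so the channel-summed estimator targets K_F directly), uniform
per-channel background, additive seeded Gaussian noise, clipping to the
bit depth. Disc edges are antialiased by a linear coverage ramp of one
pixel. Defaults describe a realistic low-light 8-bit regime: background
(12, 9, 6), noise σ = 2, K_F = 25 au/px/h and μ_max = 0.5 h⁻¹ (giving a
steady-state F ≈ 50, far from clipping), A_max ∈ [1500, 3000] px²,
30-min frames over 24 h.

What the simulator does *not* emulate — lens PSF, filter spectra,
illumination nonuniformity, Poisson photon noise, non-disc colony
morphology, colony–colony interactions, photobleaching and fluorophore
maturation — bounds what a green test establishes: the pipeline recovers
the parameters of *this* stated world; systematic optical effects in
real data are uncorrected.

## Degenerate inputs and tie-breaks

Constant images yield no detections (empty list, not an error); blank
ROI frames yield missing radii; colonies with zero R and G totals are
reported unclassifiable with a null label; a signature whose colonies
have all signal in G gets slope ∞ and angle π/2. Rendering rejects
overlapping colony discs unless overlaps are explicitly allowed, in
which case intensities sum.

## Known limitations

* Fused or touching colonies are not split (no watershed); the stronger
  detection wins.
* The plate is assumed stationary; there is no registration.
* The radius estimator saturates near the ROI boundary; ROIs sized at
  3σ leave enough margin for the default scenarios.
* The per-frame radius threshold (4 au, channel-summed) is tuned to the
  σ = 2 noise regime; much noisier data needs a higher threshold and
  will lose more early frames.
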