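# Methods

This note records the models, numerical choices and limitations behind
each stage of `secafm`. Canonical units throughout: heights in Å,
lateral lengths in nm, time in s. Converters to SI (m, m³) are provided
for exported densities.

## Simulated AFM imaging

A structure is modelled as van der Waals spheres (Bondi radii; unknown
elements fall back to 1.70 Å with a warning; waters and, by default,
heteroatoms are excluded — whether ligands/detergent should contribute
to the imaged envelope is sample-dependent, so the flag is exposed).
The membrane is a pair of parallel planes along a unit normal, either
supplied explicitly or read from OPM-style dummy atoms (two layers of
`DUM` residues; plausible bilayer separation 25–45 Å is checked, with
the characteristic value near 40 Å).

The pre-tip surface height map assigns each lateral grid point the
maximum over atoms of the sphere's vertical extent above the viewed
side's plane, clamped at 0 (the bilayer). The cytoplasmic side is
mirrored so its protrusion points up.

The recorded image is the grey-scale morphological dilation of that
surface with the tip profile. The tip is a blunted cone built from the
stated parameters (inner sphere 4 nm at the apex; outer sphere 8 nm,
concentric, positioned so the two sphere surfaces intersect in a circle
of diameter 2.8 nm; a 17.5° half-angle cone from the outer sphere's
tangent point). The profile is the lower envelope of the two spheres
continued by the cone — the only construction consistent with nested
spheres sharing a stated overlap cross-section. Dilation is computed
with a structuring element truncated where the tip penalty exceeds the
surface's height range; such offsets can never beat the zero-offset
term, so the truncation is exact and the result equals the full
double-loop dilation to machine precision (asserted against a
brute-force oracle in the tests). Dilation is extensive, monotone and
max-preserving; protrusion metrics are the grid maximum and the
integrated positive height over the 8-connected region containing the
maximum (so in multi-protein complexes the dominant protrusion is
measured, not the whole footprint).

Default simulation pixel: 0.2 nm (well below the inner tip radius) with
a 2 nm margin.

## Particle detection and metrology

*Flattening.* Per scan line, an order-2 polynomial is fitted with three
rounds of iterative masking (residuals beyond 2 robust SD excluded; the
scale estimate is MAD-based, since a plain SD is inflated by the
particles themselves and leaves a visible height bias), then
subtracted; the image median is set to 0. Lines left with fewer than
order+2 background pixels fall back to median subtraction with a
warning.

*Detection.* Six logarithmic scales span blob radii of 1–20 px
(footprints ~2–40 px, tip-broadened monomer to small oligomer at the
default 3.9 nm pixel). For each scale σ the scale-normalised
determinant of Hessian σ⁴(Lxx·Lyy − Lxy²) is computed from Gaussian
derivatives, with non-bright regions (Lxx + Lyy ≥ 0) suppressed. Seeds
are 3×3×3 local maxima over (scale, row, col) that exceed a per-scale
robust threshold (median + 3·1.4826·MAD of that scale's response —
per-scale because the detH noise floor varies by orders of magnitude
across σ) *and* a height criterion (pixel height above 5× the image
noise SD, estimated from the median absolute along-row difference).
The height criterion is what controls false positives: detH of pixel
noise is heavy-tailed, so a response threshold alone admits spurious
fine-scale maxima. Each seed grows into the 8-connected region above
3× the noise SD (with an absolute 0.5 Å floor so noise-free images do
not threshold at rounding residue); growing down to the noise floor
makes the region span the particle's full footprint, which matters
because the background annulus must sit on bilayer, not on the
particle's own shoulder. Overlapping detections keep the stronger seed.

*Local background.* The baseline under a particle is the discrete
harmonic function (4-neighbour Laplacian, sparse direct solve) matching
the image just outside the region; it reproduces any harmonic
background exactly and obeys the maximum principle. Height is the
largest excess over the baseline, volume the integrated positive excess
times pixel area. Regions touching the border are measured but flagged
(stencil legs beyond the border are dropped), and edge particles are
excluded by default. Aggregates are removed with a 100 Å height cutoff.

Measured operating characteristics on the standard synthetic suite
(20 images, 20 particles each, 1 Å noise, scanner background): recall
100 %, false positives 0 %, mean height error ≈ 0.3 Å (≤ 0.5 Å bias on
noise-free images).

## Population models

Smoothed densities use the Epanechnikov kernel K(u) = 0.75(1−u²) on
|u| ≤ 1, bandwidth from Silverman's rule rescaled by the canonical
factor 15^{1/5}/(2√π)^{−1/5} ≈ 2.214, evaluated on [0, max+3h] and
renormalised to unit trapezoid area (mass smoothed below zero is folded
back). The bandwidth and the weighting of summed densities (default:
relative sample counts) are explicit parameters, since neither is
uniquely determined by convention.

Gamma mixtures capture the strict positivity and right skew of height
and volume data. EM uses responsibility-weighted gamma MLE per
component: the shape solves ln α − ψ(α) = ln(weighted mean) − weighted
mean-log by Newton iteration from Minka's closed-form start (vectorised
across components); the scale is mean/α. Ten restarts from
quantile-split initialisations (block boundaries jittered after the
first) are prescreened with 60 iterations each and the best is polished
to convergence (ΔlnL < 1e-8 relative, cap 500 iterations); the
log-likelihood is asserted non-decreasing at every step. A component
whose weight collapses below 1e-4 triggers a flagged refit with K−1.
Model selection minimises BIC = p ln n − 2 lnL with p = 3K − 1 (K
shapes, K scales, K−1 free weights); ties break toward smaller K.
Volumes should be rescaled to ~10⁶ Å³ units before fitting so the
digamma solver stays well-conditioned.

The synthetic mixture generator parameterises components by their modes
with a common shape, default 25 (component SD ≈ 21 % of the mode).
This keeps neighbouring conformational modes separated by ≳2 component
SDs — the identifiability regime that the observed multimodal
histograms themselves imply; with much wider components (shape ≲ 12)
adjacent subpopulations genuinely merge and no selection criterion can
resolve them.

## Kymograph analysis

Per line, the background is the median of pixels outside the feature
span (the longest run above background + 3× line noise, noise from the
Haar/MAD of along-line differences); the trace value is the line
maximum minus that background, 0 and flagged where no pixel clears the
threshold.

State identification: noise σ from the Haar/MAD of first differences
(robust to steps); recursive binary segmentation accepting the
best-t-statistic split while t > √(2 ln N) (the universal threshold;
exposed as a parameter), minimum segment length 3; then each retained
boundary is moved to its two-segment least-squares optimum (greedy
splitting routinely lands 1–2 points off a step, which drags segment
means off their state and corrupts the later grouping). Segment means
are merged agglomeratively (length-weighted) to give one candidate
grouping per state count, and the state count minimises

    MDL(K) = Σ (x_t − μ_{s(t)})² / (2σ²) + J ln N + 1.5·K ln N

with J the surviving change points. The per-state cost of 1.5 ln N
(½ ln N for the mean plus an existence/occupancy term) was calibrated
on synthetic two-state telegraphs: with ½ ln N per state, segments that
exist *because* a t-test found them significant are almost never merged
away and spurious third states survive in ~25 % of traces; 1.5 ln N
yields ≥ 90 % correct two-state recovery at step/noise = 5 while pure
noise still returns a single state in 40/40 seeds and well-separated
real states (tens of σ) are unaffected. Constant traces (σ = 0) take
an exact path: change points at value changes, states at distinct
values.

Transitions are counted between consecutive state assignments — no
dwell-time deconvolution — and the aggregate transition rate is total
transitions over total observation time (scan lines × line time),
alongside the modal state count. With per-state exit rates of 0.19 s⁻¹
(seconds-scale dwells against a 90 ms line time) the recovered rate on
33 synthetic kymographs is within ~15 % of the generator; missed
sub-line and sub-3-line dwells bias the count slightly downward, and
traces with 3-point dwells at very high SNR can still gain a spurious
intermediate state from a mixed boundary segment (a known limitation of
segment-level assignment).

## Synthetic data scope

The generators emulate the observables the analysis consumes: flat
bilayer baseline, compact smooth protrusions (laterally rescaled
hemispherical caps, footprint ≈ 2× the tip-contact half-width
√(2·R_tip·h), floored at 3 px) with gamma-mixture maximum heights,
per-line quadratic background with optional line-to-line drift, i.i.d.
Gaussian pixel noise (default 1 Å, consistent with ~1 Å vertical
resolution), and continuous-time Markov switching of a single
protrusion's height for kymographs (uniform jump among the other
states; the initial state is index 0, so a zero exit rate there means a
static record). They do not emulate tip contamination or tip shape
changes, 2-D thermal drift, bilayer defects/fluidity, correlated scan
noise, or partial-height mid-line transitions; passing tests therefore
demonstrate correctness of the algorithms under the stated noise model,
not robustness to every instrumental artefact of real recordings.

Placement is rejection-sampled for non-overlap (1000 attempts, then an
explicit failure). All generators are deterministic given an integer
seed.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run at desk scale chosen to
keep the full battery around a minute while leaving comfortable
statistical margins: 10–20 replicate images (400 particles total),
n = 5 000–16 000 samples for mixture selection, 20-seed telegraph and
noise sweeps, 33 kymographs (~636 s of trace), and 48×48 grids for the
brute-force dilation oracle. Every stochastic routine takes an explicit
seed; pipeline runs are byte-reproducible from their config, and every
output file carries the config hash.
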