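# Methods

## Scope and data model

The package analyses two kinds of observations from a stirred-suspension
hiPSC aggregate (hA) workflow: 8-bit single-channel brightfield images of
dark aggregates on a light background, and rheometer exports (steady
flow curves, oscillatory frequency/amplitude sweeps, post-flow recovery
traces) of jammed, wholly-cellular bioinks. No proprietary microscope or
rheometer formats are read; images enter as PNG/TIFF and rheograms as
plain CSV tables.

## Synthetic data

`aggrheo.synthetic` generates both observation kinds with exact ground
truth, so every stage can be validated without external data.

*Images.* Aggregates are rendered as filled ellipses (pixel-center
membership, boundary inclusive). Ellipses rather than circles: real hAs
are near-circular but not perfect, and the aspect ratio gives a
controllable handle for validating that both circularity scores fall
with elongation. The stated "radius" of a generated aggregate is the
geometric mean √(ab) of the semi-axes, so rendered area matches a disk
of that radius. Placement is rejection sampling with a hard cap of
10 000 attempts per aggregate (explicit `PlacementError` naming the
count achieved beyond that); bounding circles are separated by at least
`min_separation_px` and every ellipse lies fully inside the frame.
Defaults emulate a 4×/10× brightfield field: 1024 × 1024 px, background
intensity 200, foreground 60, Gaussian blur σ = 1.5 px, additive
Gaussian camera noise sd 10 — all configurable. The ground truth for
each ellipse carries the continuous isoperimetric circularity 4πA/P²
computed from πab and the exact elliptic-integral perimeter.

*Rheograms.* Forward-model evaluations times multiplicative lognormal
noise with unit mean and a stated coefficient of variation (rheometer
error scales with signal); G′ and G″ receive independent noise.
Everything is seeded through `numpy.random.default_rng`; equal specs
reproduce byte-identical outputs.

What the generator does **not** emulate: brightfield optics (halo and
defocus rings), aggregate–aggregate fusion or growth dynamics, uneven
illumination, or rheometer artefacts such as wall slip and inertia.
Passing the synthetic benchmarks therefore certifies the algorithmic
chain (thresholding, voting, scoring, fitting), not robustness to every
imaging or instrument pathology of real data.

## Segmentation

Binarization is a global threshold on normalised intensity
(foreground iff I/255 < τ). τ defaults to 0.5, the midpoint of the
admissible 0.4–0.6 window; values outside the window require an explicit
override flag.

The rough circular Hough transform treats every foreground pixel as a
candidate center (A, B); each foreground pixel at Euclidean distance d
casts a vote at integer radius R = round(d), i.e. within the half-pixel
annulus [R−½, R+½). Design decisions:

* **Acceptance threshold.** A (center, R) cell becomes a detection only
  when its votes reach `accept_frac` × 2πR (default 0.5 — at least half
  the ideal circle perimeter supported). This rejects speckle while
  still admitting partial circles at image borders when they clear the
  same bar.
* **Sensitivity rule.** Raw vote counts fluctuate by lattice effects, so
  the per-center radius choice uses a tolerance band: among acceptable
  radii, all with votes ≥ (1 − s)·max votes are candidates and the
  largest candidate is selected. s = 0 reduces to the pure arg-max
  (ties toward the larger radius); s = 1 always takes the largest
  acceptable radius; the chosen radius is monotone non-decreasing in s.
* **Candidate-center restriction.** Evaluating all foreground pixels is
  O(|fg|²) per radius range and intractable at 1024² with radii to
  200 px. Candidate centers are restricted to foreground pixels within a
  7 × 7 window of local maxima of the foreground distance transform
  (medial-axis peaks, minimum peak separation max(3, R_min/2)). Votes
  reported for those centers are exact; pixels far from a medial-axis
  peak cannot out-vote pixels near one for convex bodies. The tests
  validate the outcome against a literal all-centers accumulator on
  small images.
* **Deduplication.** Two detections describe the same aggregate when
  their center distance is below half the smaller radius, or the smaller
  disk's area lies ≥ 60% inside the larger (closed-form circle-overlap).
  Among duplicates the highest-voted detection is kept, ties broken
  toward the larger radius, then the earlier pass, then raster order —
  a total order that makes deduplication deterministic and idempotent.
  The same collapse is applied within a pass (neighbouring candidate
  centers of one aggregate) and across the stacked passes.
* **Default schedule.** Five passes with radius ranges 20–200, 40–200,
  60–200, 80–200, 90–200 px and sensitivities 0.72, 0.76, 0.80, 0.88,
  0.92.

Coordinates are (row, col), 0-based, pixel centers at integers; radii in
pixels. Radii are searched at integer values (votes are binned to
half-pixel annuli, so sub-pixel radius refinement is not meaningful at
this accumulator resolution).

## Morphometry

*Area* is the count of foreground pixels within distance R + offset of
the detected center.

*Harmonic circularity* (the default reporting score): with A₋ and A₊ the
areas at offsets −4 and +4 px, the score is
[2A₋A₊/(A₋+A₊)] / (πR²). For a perfect disk of radius r this converges
to 2(r−4)²/((r−4)² + r²) ≈ 0.92 at r = 50 — the score is a *relative*
quality measure, not normalised to 1.

*Isoperimetric circularity* 4πA/P² uses the connected component under
the detection center; A is its pixel count and P the length of the
marching-squares half-level contour after a circular moving average
(window 7 vertices) over the contour. The smoothing is essential: the
raw rasterised contour is a 45°-staircase that overestimates smooth
perimeters by up to ~6% (biasing a disk's circularity to ~0.89), while
integer-edge-count and Crofton-style estimators miss the 5% closed-form
band on disks or axis-aligned squares. Measured accuracy of the smoothed
estimator: disks r = 30/60/120 give circularity 0.998/0.997/0.996;
squares of side 60/120 give 0.821/0.803 against π/4 ≈ 0.785; a 2:1
ellipse gives 0.839 against the exact 0.841. Both scores are exactly
invariant under whole-pixel translation and 90° rotation.

*Diameter* is 2R of the Hough detection converted by `um_per_px`; the
pixel scale is a required calibration input, never inferred. The
summary gates — fraction of aggregates with diameter ≤ 300 µm and
fraction with circularity ≥ 0.73 — are inclusive. Quantiles use linear
interpolation (numpy default, type 7).

*Mann–Whitney U* (two-sided, tie-aware): exact by full enumeration of
rank assignments when the combined sample is ≤ 20 (p is twice the
smaller one-sided tail, capped at 1 — the convention shared by scipy
and R, robust to tie-induced asymmetry of the null), and the
tie-corrected normal approximation otherwise.

*Fold expansion* values each sampling withdrawal at the density measured
when it occurred: total(t) = density(t)·volume(t) + Σ density(tᵢ)·ΔVᵢ
over prior withdrawals, fold(t) = total(t)/total(0). With no sampling
and constant volume this is the plain density ratio; sampling at
unchanged density leaves the fold invariant.

## Rheology

*Thixotropic Herschel–Bulkley*: σ(γ̇) = σ₀/(1 + λγ̇) + Kγ̇ⁿ with
σ₀ ≥ 0 (Pa) the intrinsic yield stress of the intact packing, λ ≥ 0 (s)
a structural-reconstruction timescale, K ≥ 0 (Pa·sⁿ) and n ∈ (0, 2].
The flow curve is non-monotonic exactly where the derivative
−σ₀λ/(1+λγ̇)² + nKγ̇ⁿ⁻¹ changes sign; in log-rate space the sign is
governed by a unimodal function whose minimum sits at
γ̇\* = (1−n)/(λ(1+n)) for n < 1, so the negative region is a single
interval found by exact root bracketing — no grid scan, no tolerance.

*Fractional Jeffrey model*: two spring-pots (orders 0 ≤ β ≤ α ≤ 1,
quasi-properties V [Pa·s^α], G [Pa·s^β]) in series, Newtonian dashpot
η₀ in parallel. The storage/loss moduli are the real/imaginary parts of
G\*(ω) = V(iω)^α G(iω)^β/(V(iω)^α + G(iω)^β) + iωη₀, implemented in
explicit trigonometric form with denominator
(Vω^α)² + (Gω^β)² + 2VGω^(α+β)cos(π(α−β)/2); the complex form is kept
as an independent cross-check (they agree to ~10⁻¹⁵ relative). η₀
contributes exactly η₀ω to G″ and nothing to G′. The Maxwell model is
the α = 1, β = 0, η₀ = 0 special case.

*Fitting.* Both fitters minimise squared log-residuals — moduli and
stresses span decades, and multiplicative instrument noise is
homoscedastic in log space — under the type-invariant bound constraints,
using `scipy.optimize.least_squares` (trust-region reflective). The FJM
order constraint β ≤ α is enforced by fitting β = α·t with t ∈ [0, 1].
Multi-start runs a fixed 8-point lattice over the shape parameters
(flow index and λ on/off for the flow curve; α, t and η₀ on/off for the
FJM) with data-derived magnitude scales, so fits are deterministic given
the data. Diagnostics carry the residual norm and approximate 95%
confidence half-widths from the Jacobian; the FJM fit also reports
tan δ = G″/G′ at each frequency. Degenerate inputs (constant stress,
non-positive moduli, too few points or too narrow a rate span) raise an
explicit fit-failure error rather than returning parameters. Under
noise, λ–K–n retain a shallow trade-off valley (the model is
near-degenerate over a finite rate window); σ₀ — the quantity of
interest — remains well identified (median error ≈ 4–5% at 5% noise).

*Critical strain*: the linear plateau is the median G′ over the lowest
decade of strain; the critical strain is the log-interpolated strain at
which G′ first falls below (1 − drop_frac)·plateau, drop_frac default
0.1 (a yield outcome near 3% strain is an *output* of the data, not part
of the criterion). Scale-invariant; a never-dropping G′ raises a
no-yield report. The amplitude-sweep lower bound is a data property, not
fixed by the package.

*Flow recovery*: G′(t) = g∞ − (g∞ − g₀)e^(−t/τ_r) by least squares with
three deterministic τ starts; a flat trace returns g∞ = g₀ with τ_r
flagged unidentifiable.

*Parallel-plate correction*: the single-point rim-stress correction
σ_true = σ_app·(3 + d ln σ/d ln γ̇)/4, slope by central differences in
log-log (one-sided at the ends). Newtonian data are unchanged exactly;
pure power-law data of index n receive the uniform factor (3+n)/4
exactly (the log-log data are affine, so the finite differences are
exact). A `corrected` flag prevents double application.

*Hysteresis check*: descending and ascending rate sweeps are compared
pointwise at matched rates; a median relative discrepancy above 10%
flags history artefacts. This is a data-validation utility, not a model.

## Pipeline and benchmark

`PipelineConfig` round-trips losslessly through YAML and is hashed into
every run log (one JSON event per stage). The benchmark generates
seeded fields, segments them, and matches detections to ground truth
greedily by center distance with an admissibility gate of half the true
radius; unmatched truths are misses, unmatched detections false
positives. Reported: recall, precision, center RMSE, radius RMSE, and
the bias of measured isoperimetric circularity against the
continuous-ellipse truth (the harmonic score is not compared to the
continuous value because its disk limit is below 1 by construction).

## Problem sizes

The validation suite and `scripts/acceptance.py` use: 20 fields of
1024 × 1024 px with 10 aggregates each (radii 20–100 px, blur 1.5 px,
noise sd 10) for the segmentation benchmark; 1000 random parameter draws
for the FJM/complex-oracle identity; 20-point flow curves with 100 noisy
replicates at 5% CV for yield-stress recovery; 12-frequency sweeps for
FJM recovery; 100 random parameter sets against a 10⁵-point grid for
the monotonicity dichotomy; and exhaustive small-sample checks (sizes
≤ 8, with ties) for the statistics.

## Known limitations

* The accumulator quantises radii to integers; reported radii are
  accurate to ~1 px, which bounds diameter precision at 2·`um_per_px`.
* Fused or overlapping aggregates are not split (no watershed fallback);
  the deduplication criterion will keep the dominant circle.
* The harmonic circularity depends on the fixed ±4 px offsets and is
  only meaningful for R > 4 px; it is not comparable across very
  different magnifications without re-deriving its disk limit.
* The thixotropic model is steady-state only; no structural-kinetics ODE
  is fitted to transient stress data.
* Large-amplitude oscillatory analysis, ND2 reading, GPU accumulators
  and gradient-based Hough variants are out of scope.
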