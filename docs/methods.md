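# Methods

## Model

The non-rigid pRF treats a vertex's response field as a fixed unit Gaussian
(center 0, σ = 1) populated by the 18 cued body parts at fitted distances
dxᵢ ∈ [0, dx_max]. Distances are one-sided: a symmetric Gaussian makes the
sign of dxᵢ unidentifiable, so only non-negative values are fitted, and
dx_max = 10 caps them where the field is numerically zero (exp(−50)). The
forward model weights the binary condition × volume design matrix by the
field, convolves with the canonical HRF within each scanner run (the
hemodynamic response does not carry across run boundaries), and scales by a
single amplitude β carrying percent-signal units. Gaussian iid noise closes
the observation model; an optional AR(1) toggle in the simulator probes
robustness to temporally correlated noise but is off by default, matching
the unstructured-residual assumption of the fit.

Assumptions worth keeping in mind: the field shape is Gaussian by fiat;
one amplitude serves all conditions (amplitude differences between body
parts are absorbed into distances); and the HRF is common to all vertices.

## Fitting

The objective is non-convex chiefly through the discrete choice of which
body part anchors the field. We therefore run one start per candidate
center — part k at dx = 0, every other part at dx_max/2 — score all 18
starts by the closed-form profiled-β residual, and refine them in that
order with box-constrained trust-region least squares over (dx, β) jointly.
β is initialized at its profiled ordinary-least-squares value and the
Jacobian is analytic (∂r/∂dxᵢ = β Cᵢ dxᵢ gᵢ, ∂r/∂β = −C g), which is exact
and far cheaper than finite differences on a profiled residual. Refinement
stops early once a start explains all but 10⁻⁹ of the variance, since no
later start can improve on that meaningfully. β's sign is unconstrained;
negative-β solutions are flagged rather than forbidden. On small problems
the returned solution matches an exhaustive 0.25-step lattice search over
dx (tested), so the trust-region implementation is interchangeable with
any least-squares minimizer honoring the same bounds.

The conventional comparison model slides a Gaussian (center x₀ ∈ [1, 18],
width σ ∈ [0.1, 20]) along the rigid homunculus axis, with starts at every
integer center × σ ∈ {1, 3}.

**Degenerate inputs.** A constant (e.g. all-zero) timeseries returns a
flagged degenerate fit with R² = 0 and p = 1. Non-finite samples are
rejected outright — silent NaN propagation through an optimizer is worse
than an error.

## Center, size, identifiability

The pRF center is the arg-min distance; distances tying within 10⁻⁶
(absolute) resolve to the floor of the mean tied 1-based index. The floor
(rather than round-half-up) convention matters only for exact ties, which
the tolerance makes explicit instead of leaving to float luck.

The pRF size sums normalized proximities P(dx) = (dx_max − dx)/dx_max over
body parts within the half-width-at-half-maximum of the unit field
(FWHM = 2σ√(2 ln 2) ≈ 2.355; the window is FWHM/2 because parts occupy one
side of the symmetric field), scaled by FWHM/2. One body part at the
center gives size ≈ 1.18 — one body part's worth of field.

**Identifiability floor.** Beyond dx ≈ 4 the field value drops below 0.1 %
of peak, so such distances contribute essentially nothing to the
prediction and come back wherever the optimizer leaves them (typically a
plateau near 5–7.5). This is inherent to the model, not a defect of the
optimizer: the same data are equally well explained by any sufficiently
large distance. Consequences: distance errors for far parts are
meaningless, and qualitative properties of averaged fields (see below) are
asserted after clipping distances at 4. Centers, sizes and near-field
structure are unaffected.

## Goodness of fit and vertex selection

Timeseries enter the fit as mean-free percent-signal-change data (per run:
discrete-cosine high-pass at 0.01 Hz, then 100·(y−mean)/mean), so the
goodness-of-fit F statistic is computed against the zero-signal null with
no intercept: df_hypothesis = 19 (18 distances + β) and df_error = T − 19,
i.e. (19, 837) for the full 856-volume protocol. Two conservatisms follow
and are deliberate. First, the model's linear span has rank 18 while 19
parameters are counted, so even an unconstrained linear fit rejects at
3.6 % (closed form: P(F(18,837) > crit·19/18)) rather than 5 % at the
nominal α = 0.05. Second, the bound-constrained non-rigid fit spans a cone
inside that span and rejects less often still. The test is therefore valid
(type-I error at or below nominal) but not exact; the calibration tests
assert the Monte-Carlo rate against the closed-form value, not against a
naive 5 %. Vertex selection is Benjamini–Hochberg FDR at q = 0.05 on the
F-test p-values.

## Aggregation and graphs

Mean body-part response fields (per ROI, per center body part) average the
*untruncated* normalized proximities of selected vertices sharing a
center: distant body parts keep graded nonzero values, which is what gives
the averaged fields their informative tails; truncation at the HWHM is
reserved for the size metric. With several subjects, fields are computed
per subject and averaged with equal weights. A missing center is an error
naming the body part — silently dropping a row would corrupt the 18×18
structure downstream.

Graphs: edge weight = Pearson correlation of mean-field rows; negative
correlations removed, then the weakest floor(5 % · m) of the m remaining
positive edges (ties at the cutoff removed too, cutoff computed over
unique undirected edges); disconnection after thresholding is a warning,
not an error. Node metrics follow the standard weighted conventions:
degree kᵢ = Σⱼ wᵢⱼ; clustering = geometric-mean triangle intensity
2tᵢ/(kᵢᵇ(kᵢᵇ−1)) normalized by the *binary* neighbor count kᵢᵇ (a weighted
degree in the denominator would leave the coefficient unbounded for
degrees below 1; with weights in [0, 1] the binary-count form stays in
[0, 1]); path length = Dijkstra on inverse-weight edge lengths with
Brandes-style minimal-path counting, ties at relative tolerance 10⁻¹²;
betweenness over unordered pairs with the 1/((n−1)(n−2)) normalization
(hence values in [0, ½]); modularity Q = 1/l Σᵢⱼ (wᵢⱼ − kᵢkⱼ/l) δ(mᵢ,mⱼ)
with l the total weight counting both directions, resolution 1. Louvain
runs over seeded restarts and reports the partition whose directly
evaluated Q is best, making fixed (seed, restarts) bit-reproducible.
Every metric is verified against exhaustive enumeration on random small
graphs.

## Somatotopy statistics

Each ROI is rigidly rotated (determinant +1, about the ROI centroid) so
the vector from the leg-anchor centroid (toes/ankle/knee centers) to the
face-anchor centroid (lips/jaw/tongue) points along +y; the somatotopy
(or size-gradient) test then regresses pRF center (or size) on the rotated
vertical coordinate per subject and tests the slopes against zero across
subjects (one-sample t; the one-sided "greater" p is the headline, the
two-sided p is reported alongside). The design-bias test pools, over
selected vertices, non-center distances split by whether the part was cued
in the same run-part as the vertex's center, and compares the groups with
a Welch t-test (Welch–Satterthwaite df). Head-motion scoring sums absolute
first differences of the six rigid-body parameters (restarted at run
boundaries) over volumes starting within 3 s of each cue, converting
rotations to arc displacement at a 50 mm radius — the common framewise-
displacement convention; per condition, event scores are Welch-tested
against all other conditions pooled.

## Synthetic data: what it emulates and what it does not

The generator reproduces the protocol exactly — 18 conditions split into
two run-parts (torso/arm/hand vs leg + face), two scanner runs per part of
237 and 191 volumes at TR 2.1 s, 9 repetitions per condition, 10 s
inter-cue intervals with exactly one lengthened to 14.7 s per condition,
pseudo-randomized order with no immediate repeats (uniform shuffles
rejection-sampled; a count-weighted greedy construction backs up designs
where acceptable shuffles are too rare). Cue regressors default to a 3 s
boxcar from cue onset (1 s forward cue + 1 s gap + 1 s backward cue),
matching the head-motion window; impulse regressors are available by
shortening the boxcar below one TR.

Ground-truth maps lay each ROI on a flattened strip with the preferred
body part increasing from south (toes) to north (tongue), distances
growing with homunculus distance at an ROI-specific rate — 2.5 per step
for M1/S1-like areas (small fields), 0.8 for PMv-like (large fields), with
south-to-north spread gradients for SMA/Insula-like areas — plus
configurable center jitter (default sd 1 body part) and distance noise
(default sd 0.3). These defaults produce clearly somatotopic but
non-degenerate maps; the first 18 vertices of every ROI are pinned to
centers 1…18 so aggregation never hits a missing center. Noise levels for
simulated timeseries are calibrated by bisection on pilot fits so the
median fitted R² matches a target (default 0.15, the regime of real
motor-cortex data), starting from the closed-form value implied by the
median signal variance.

Not emulated: cortical geometry and curvature, physiological noise
spectra, spatial autocorrelation between vertices, HRF variability, or
motion artifacts. Passing tests therefore demonstrate correctness of the
estimation and graph machinery under the model's own assumptions, not
robustness to every property of real 7 T data.

## Problem sizes used in the automated checks

The test-suite and acceptance-script simulations use 100–500 vertices per
recovery experiment, 2000 null vertices for calibration, 100 random small
graphs for the metric oracles, and a 2-subject × 8-ROI × 24-vertex
noiseless dataset for the end-to-end structure checks — sizes chosen to
make the statistical assertions well-powered while keeping a full run in
the minutes range on one CPU.

## Known limitations

* Distances beyond ≈ 4 are unidentifiable (see above); consumers should
  treat large fitted distances as "absent", not as measurements.
* The F-test is conservative by construction under the printed df
  convention; it never overstates significance.
* The Gaussian field shape and common-HRF assumptions are untested within
  the package; alternative field shapes are out of scope.
* The rotation step needs both leg- and face-anchor centers present in an
  ROI and skips (with a warning) otherwise.
* Repeated-measures ANOVAs over subjects × body parts × ROIs are not
  implemented; the package exports the tidy per-subject tables such tests
  consume in external statistics software.
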