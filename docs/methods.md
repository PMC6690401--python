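# Methods

## Stimulus model

A stereogram pair is a left/right raster of square dots on a zero (gray)
background. Dots are placed one after another: luminance first (+1 or −1
with equal probability for mixed polarity), then a nominal position drawn
uniformly over the full image, then the dot's total disparity δ (uniform
mean plus optional per-dot noise, rounded to integer pixels) is applied to
the x coordinate before drawing. Footprints are clipped at image borders;
there is no exclusion zone, so empirical coverage falls short of the nominal
density d by the mean clipped fraction, ≈ (s−1)/W per axis for dot size s
and image width W.

**Dot counts.** To give each monocular pixel probability d of being covered:
N = d·A_im/A_dot without overlap (coverage is additive) and
N = ln(1−d)/ln(1−A_dot/A_im) with overlap (each dot independently misses a
pixel with probability 1−A_dot/A_im), rounded to the nearest integer. When
the two overlap modes are compared at the headline parameters, the overlap
condition scatters the *same count* as the no-overlap condition, so its
density is correspondingly lower; this keeps the dot numerosity cue fixed.

**Overlap rule.** In the no-overlap mode a candidate whose drawn footprint
would overwrite pixels of an existing dot in *either eye* is abandoned and
redrawn; 10⁴ consecutive failures abort with the achieved coverage (d = 0.4
with 4 px square dots packs reliably; the cap exists so denser requests fail
loudly rather than hang). The published generation procedure is one
sentence and does not say whether the test uses drawn (post-shift) or
nominal (pre-shift) footprints; both are implemented
(`StimulusParams.overlap_check`), with the post-shift reading as default
since the constraint is naturally a property of the drawn images.

**Disparity sign convention.** Disparity is the left-eye minus right-eye
feature position: a dot with disparity δ is drawn at x + ⌈δ/2⌉ in the left
eye and x − ⌊δ/2⌋ in the right (the extra pixel of an odd δ goes to the left
eye). This is forced by the energy-model receptive-field sums
v_Le(x0) = Σ f_e(x_j − x0/2) L_j / v_Re(x0) = Σ f_e(x_j + x0/2) R_j: with
this stimulus convention a neuron with position disparity x0 is maximally
driven by a stimulus of disparity x0, as the population tuning curves must
show. The cross-correlation displacement axis uses the same sign.

**Noise models.**

* *Gaussian*: per-dot disparity offsets ~ N(0, σ_noise), rounded to integer
  pixels (the raster admits only integer shifts). σ_noise = 0 is
  raster-identical to no noise because noise values are drawn from an RNG
  stream separate from placement.
* *Two planes*: exactly half the dots (random assignment) get one disparity
  offset, half the other — a transparent two-plane scene.
* *Decorrelate(f)*: a fraction f of dot slots is replaced by independently
  positioned (and independently colored) dots in each eye. Per-eye dot count
  and hence coverage are preserved. This is the noise type for which the
  closed-form correlation theory is exact.

**Polarity conditions.** Mixed-polarity pairs are the primitive. Same
polarity is an element-wise conversion of the *same* generated pair —
absolute value (white), negated absolute value (black), or mapping white
dots to dark-gray −0.5 with black dots kept at −1 ("dark/darker") — so every
polarity condition shares the identical dot layout and noise realisation.
The dark-gray level is not prescribed anywhere; −0.5 is used throughout.
Finally each monocular image is normalised to zero mean and unit variance,
a stand-in for early luminance/contrast adaptation that also equates
contrast energy across polarity conditions.

**Reproducibility.** One top-level seed; the RNG stream of pair i is derived
as SeedSequence(seed, spawn_key=(i,)), split into placement and noise
substreams, so ensembles are reproducible and order-independent.

## Pixel-pair statistics and closed forms

Aligned pixel pairs (left x paired with right x − δ_mean, overlap region
only) are classified *matched* — both background, or both covered by the
same correlated dot with zero noise offset — else *unmatched*. With
d = P(dot), m = P(matched), u = 1 − m, d_m = P(dot | matched),
d_u = P(dot in one eye | unmatched), x = P(dot in the other eye | unmatched
dot), the expected Pearson correlation is

    r_mixed = m·d_m / d
    r_same  = (m·d_m + u·(2·d_u − 1) − d²) / (d·(1 − d))

Free scatter forces d_u = 1/(2−d), collapsing both to
r = 1 − u/(d(2−d)); forbidding overlap pushes d_u toward its floor 1/2
(noise dots land only on background), where r_mixed = 1 − u/(2d) and
r_same = 1 − u/(2d(1−d)) < r_mixed. Empirical estimates symmetrise the two
eyes (d_u = p_both + (p_left + p_right)/2, x = p_both/d_u), which makes the
identities d = m·d_m + u·d_u and x·d_u = 2·d_u − 1 hold exactly on counts.
When an image has no unmatched pairs, d_u is reported at its theoretical
floor 0.5 and x = 0.

**Scope.** The dichotomy is exact for decorrelation noise. For Gaussian
disparity noise a displaced dot is booked wholly unmatched even where its
two footprints still overlap; those pixels carry *equal* luminance, so the
mixed-polarity closed form underestimates r there (measured: 0.10 predicted
vs 0.37 empirical at d = 0.4, noise = dot size), while the same-polarity
form — which books any two dots symmetrically — agrees to Monte-Carlo
precision. Quantitative validation of the closed forms therefore uses
decorrelation ensembles; Gaussian-noise effects are established empirically.

## Energy-model simulations

Receptive fields are x/y-separable Gabors
f(x, y) = exp(−(x²+y²)/2σ²)·{cos, sin}(2πx/λ), σ = 32 px, λ = 128 px,
truncated at |x|, |y| > 4σ (relative envelope 3.4·10⁻⁴, far below
Monte-Carlo noise). The RF pair of a neuron with position disparity x0 is
centred at image centre ±x0/2 (left +, right −; odd x0's extra pixel to the
left eye, switchable only by re-deriving shifts). Monocular inner products
feed five simple-cell rules — (v_Le+v_Re)², (v_Le−v_Re)², (v_Le+v_Ro)²,
(⌊v_Le⌋+⌊v_Re⌋)², ⌊⌊v_Lo⌋−⌊v_Re⌋⌋² with ⌊·⌋ half-wave rectification — and
the quadrature complex cell (v_Le+v_Re)² + (v_Lo+v_Ro)².

Because the Gabor factorises, responses for all position disparities come
from one vertical collapse of the image against the Gaussian envelope
followed by 1-D carrier correlations; this fast path equals the per-x0 2-D
inner-product definition to floating-point round-off and is tested against
an explicit pixel loop.

Population tuning curves average raw responses over trials and divide, per
neuron (model, x0), by that neuron's mean response to binocularly
uncorrelated stereograms of identical monocular statistics (own trial
budget, separate seed offset), so uncorrelated stimuli map to 1. Across-
trial SDs are stored on the same normalised scale.

## Neurometric task

Per trial one stereogram at +δ (δ = 6 px) is generated; the observer is
correct when the +δ-tuned neuron out-responds the −δ-tuned anti-neuron, with
exact ties (possible for the rectified RPC rules) broken by a fair coin from
a dedicated stream. Always presenting +δ with the fixed (+δ, −δ) decision
pair is equivalent to randomising the sign by stimulus symmetry and halves
bookkeeping. Polarity conditions are derived from the same generated
ensemble, so they differ only in dot color. The efficiency ratio between two
conditions is (probit(pc_a)/probit(pc_b))² — the squared sensitivity ratio.
Note the printed reference value 3.6 for the simple cell is not reproduced
by this formula even from the published percentages (73/63 → 3.41); the
complex-cell value 3.3 is (83/70 → 3.31). The ratio is reported as computed.

### Choice of noise SD

The source description of the headline stimulus is internally inconsistent:
the methods text implies disparity-noise SD 4 px (2 arcmin at 2 px/arcmin)
while the figure caption says 12 px. Empirically SD 4 px reproduces the
published task numbers almost exactly (≈72/63% simple, ≈83/70% complex at
10⁴ trials) and the published tuning-amplitude pattern (same-polarity
amplitude ≈ half of mixed without overlap — measured ratio 1.9; equal with
overlap — 0.97), whereas SD 12 px yields ≈58/54% and ≈65/56% and inverts the
amplitude pattern. SD 4 px is therefore the default; 12 px remains available
(`noise_sd_px`) and the task driver reports it as a sensitivity block.

## What the synthetic generator does and does not emulate

It reproduces the pixel-level construction of the psychophysical stimuli —
square dots, sequential placement with rejection, integer-pixel disparities,
polarity conversion of identical layouts, normalisation. It does not emulate
circular dots, anti-aliased or sub-pixel placement, luminance-additive
overlap, step-edge spatial layouts, vertical disparity, or any property of
human observers beyond the single-neuron-pair read-out. A green test
therefore establishes properties of this stimulus family and these model
cells, not of human vision.

## Numerical choices

* Pearson r and shifted correlations are computed over the overlap region
  only — no zero padding (biases r toward 0), no wraparound (fabricates
  structure). Degenerate (constant) images raise rather than return NaN.
* Ensemble uncertainty is reported as across-pattern SD; tests compare
  means at 3 SE (SD/√n) unless the published claim is itself a ±SD-band
  statement (dark/darker), which is asserted at its own scale.
* Default test scales are reduced (tens of patterns, hundreds to thousands
  of trials) with tolerances widened by the corresponding binomial/ensemble
  SE; the acceptance script runs the full 10⁴ trials.
* `required_dot_count` rounds to nearest; density ≥ 1 and dot-larger-than-
  image raise immediately.

## Known limitations

* The matched/unmatched bookkeeping of Gaussian-noise dots is a modelling
  convention (see Scope above); only decorrelation noise admits an exact
  closed form.
* Rejection sampling is sequential Python; generating 10⁴ headline-size
  no-overlap patterns takes a few minutes on one CPU.
* The dark/darker condition depends weakly on the unspecified dark-gray
  level; with −0.5 its correlation sits ≈0.01–0.03 above all-black,
  well inside the across-pattern SD band but resolvable at large n.
* Efficiency ratios inherit the probit convention; alternative definitions
  of efficiency would change the scalar but not the ordering.
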