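# Methods

This note documents the models, numerical conventions and design choices
behind `nirmap`, and what the synthetic phantom does and does not emulate.

## Phantom spectra generator

Each spectrum is a Beer–Lambert mixture of Gaussian absorbance bands,

    A(λ) = B(λ) + Σ_k c_k Σ_b a_b exp(−(λ − μ_b)² / 2σ_b²),

distorted per acquisition by a multiplicative gain `1 + N(0, sd_g)`, an
additive offset `N(0, sd_o)`, a linear baseline with slope `N(0, sd_s)`
(about the axis midpoint) and i.i.d. channel noise `N(0, sd_e)`. These are
precisely the distortions SNV/RNV/MSC and derivative filtering are designed
to remove, which makes the preprocessing stage testable end to end.

`B(λ)` is a constituent-independent matrix background (two broad bands,
0.40 AU at 1250 nm and 0.15 AU at 1750 nm). It is not cosmetic: without a
fixed baseline, the water signal is almost collinear with overall spectral
intensity, and any per-spectrum normalisation (SNV, RNV, MSC) removes the
intensity scale, leaving water structurally unidentifiable from shape ratios
alone. A fixed background anchors the absolute scale the way the constant
dry-matrix absorbance of real tissue does.

Band placement keeps every constituent band inside 1060–1840 nm so the crop
windows retain signal; water carries its dominant band at 1440 nm (the
shoulder of the strong 1400–1450 nm absorption, whose core falls in the
excluded 1366–1560 nm region) plus a secondary band at 1790 nm inside the
third optical window. Amplitudes are scaled so each constituent's signal
variation over its concentration range is of comparable order; uronic acid
spans only 0.2 percentage points, hence its much larger per-unit amplitude.

Default conditions mirror the study design: 115 training locations drawn
independently and uniformly within the bulk composition ranges (water
70–75%, hydroxyproline 20–22%, uronic acid 0.6–0.8% of wet weight), three
replicate acquisitions per location with independent scatter/noise, and one
gridded test specimen (9×14 cells) whose constituent fields are spatially
smoothed uniform noise (moving-average kernel, min–max rescaled back into
range, so containment is exact by construction). The 55 measured cells are
the cells closest to the grid centre — a deterministic stand-in for a probe
that cannot reach specimen edges. Default distortion magnitudes (gain sd
0.05, offset sd 0.02, slope sd 2×10⁻⁵ AU/nm, channel noise sd 10⁻³ AU) give
held-out performance in the ρ ≈ 0.97–0.99 range — a deliberately favourable
phantom; see *Limitations*.

What the phantom does **not** emulate: wavelength-dependent (non-linear)
scatter, detector saturation, instrument drift between sessions, replicate
correlations, reference-assay error in y, and donor-level clustering.
Passing tests therefore demonstrate the correctness and internal consistency
of the algorithms, not clinical-grade accuracy on real tissue.

## Preprocessing

Order is crop → scatter correction → Savitzky–Golay, matching a workflow in
which the noisy/saturated regions are discarded before any statistics are
computed from the spectrum. Crop intervals are closed; boundary channels are
kept. Scatter correction operates on the concatenated cropped channels (a
per-spectrum physical gain/offset does not respect segment boundaries), while
SG filtering is applied per contiguous segment — a filter must never mix
channels across a crop gap (asserted by a segment-isolation test). Segments
are detected from the wavelength axis itself: a gap wider than 1.5× the
median spacing starts a new segment.

* **SNV** z-scores each spectrum across its channels (sample sd, ddof 1).
* **RNV** centres on the 25th percentile and scales by the sd of the channels
  at or below it, making the correction insensitive to a few extreme
  channels; the percentile is a parameter.
* **MSC** regresses each spectrum on a reference (`x ≈ a + b·ref`) and
  returns `(x − a)/b`. The reference is the **training-set** channel mean and
  is stored so test spectra are corrected against it — correcting test
  spectra against their own mean would leak test information into the
  transform.
* **SG** uses polynomial-fit edge evaluation (`mode="interp"`), keeping the
  channel count constant so the wavelength axis stays aligned across
  configurations; derivatives are scaled by the mean channel spacing of the
  segment (units: intensity · nm⁻ᵈ).

The configuration grid is the Cartesian product of the 7 non-empty subsets
of the three wavelength windows, 4 scatter options (including "none" — the
no-correction arm belongs in a fair search), and the 48 valid SG triples
from windows {5…19}, polynomial orders {2, 3} and derivative orders
{0, 1, 2} (invalid triples with polyorder ≥ window or deriv > polyorder are
excluded): 1344 configurations, enumerated in a fixed deterministic order
that also serves as the tie-break in ranking. A window-19 filter cannot be
applied to the 17-channel 1060–1172 nm segment; such configurations fail
cleanly and are recorded as failed rather than aborting a search.

## NIPALS PLS1

Single-response PLS only, fitted independently per constituent. Predictors
are mean-centred but not variance-scaled (the standard chemometric choice
for spectra, where channel variance carries information). For one response
the NIPALS inner loop converges in a single pass, so there is no iteration
tolerance. The model stores the full coefficient path
`b_k = W_k (P_kᵀ W_k)⁻¹ q_k` for k = 1…n_comp, which makes cross-validation
over component counts a single fit per split. Contracts asserted in tests:
score orthogonality, deflation conservation, OLS equivalence at full rank,
monotone training error, and latent-route vs coefficient-route prediction
identity. If the residual covariance `X_resᵀ y_res` vanishes before n_comp
components, the model truncates rather than manufacturing numerically void
components.

RMSE is `sqrt(mean((y − ŷ)²))`; rank correlation is Spearman's ρ with
average ranks on ties.

## Component selection and outlier screening

**MCCV**: each iteration draws a uniform random train subset without
replacement of size `round(0.9·n)` (round-half-up: 104 of 115), fits once at
the maximal component count and evaluates every k on the held-out samples.
The chosen count is the global minimiser of mean RMSECV; counts within a
relative 10⁻⁹ of the minimum are treated as tied and the smallest wins
(necessary for noise-free data, where RMSECV is ~10⁻¹⁵ for all sufficient
counts and its argmin is floating-point noise). A one-standard-error
alternative rule is available behind a flag. The study convention is 1000
iterations; tests and the acceptance script use 100–200, which changes only
the Monte Carlo error of the RMSECV estimate (it shrinks as 1/√iterations;
asserted as a property test).

**Outlier screen**: the same resampling at a 75% ratio (study convention:
2500 iterations; scaled to 250 here), collecting per-sample held-out
absolute residuals. A sample is flagged when its residual mean exceeds the
cohort mean by more than `k_sd` (default 3) cohort standard deviations.
Screening on the residual-sd axis is implemented but **off by default**, a
deliberate departure from the mean+sd joint rule one might expect: on clean
data the per-sample residual-sd distribution is right-skewed and the sd axis
produces 2–3 false flags per 115 samples, while a gross response error
produces a residual that is large but *consistent* — high mean, low sd — so
requiring both axes misses it entirely. The mean-axis rule flags a planted
10×-range corruption in every seed while flagging ≤1 clean sample per 115.
The full per-sample table (mean, sd, held-out count) is always reported so
the rule can be audited or re-applied with other settings.

**Grid search** ranks configurations by mean RMSECV at each configuration's
chosen component count; ρ-based ranking was considered and rejected because
RMSECV is the quantity MCCV actually estimates with known Monte Carlo error.

## Wavelength selection

Five algorithms share a `SelectionResult` interface (sorted channel indices,
per-channel diagnostic score, logged hyperparameters, seed). The fidelity
target is the algorithmic skeleton of the originating literature, validated
by planted-signal recovery rather than numeric identity to any particular
implementation. Internal cross-validation is *paired* wherever subsets are
compared: candidate subsets are scored on one fixed set of random splits, so
split noise cancels out of every comparison.

* **UVE** augments X with artificial noise channels (amplitude 10⁻¹⁰ — large
  enough to receive coefficients, small enough not to perturb the fit),
  collects coefficients over Monte Carlo 90% subsample fits, and scores each
  channel by reliability `c_j = mean(b_j)/sd(b_j)`. Real channels must beat
  the largest |c| observed on any noise channel.
* **CARS** shrinks the retained set along the exponential schedule
  `r_i = a·e^(−k·i)` calibrated so r₁ keeps all p channels and r_N keeps 2
  (`k = ln(p/2)/(N−1)`, `a = e^k`), using forced selection (top weights)
  followed by adaptive reweighted sampling (scheduled-count draws with
  replacement, weights ∝ coefficient magnitude; the unique draws survive).
  Two implementation choices matter: the weight is the magnitude of the
  *mean* coefficient over 5 Monte Carlo subsample fits — a single fit's
  coefficients are dominated, after the first pruning, by noise channels that
  survived precisely because their coefficients were spuriously large — and
  the winner (minimum paired CV error over iterations) is restricted to
  proper subsets, since the unpruned ratio-1 iteration constitutes no
  selection.
* **Random frog** runs a Metropolis-style chain over subsets: candidate
  dimension `n* ~ round(N(|V|, θ|V|))`, shrink/grow proposals guided by PLS
  coefficient magnitude, acceptance of worse candidates damped by
  `η·err(V)/err(cand)` with η = 0.1 (undamped acceptance makes the chain a
  random walk). The chain starts from the top-|b| subset of the requested
  size: with a cold random start the chain spends its entire length
  re-discovering channels the full-data coefficient ranking already exposes.
  The score is visit frequency; the selected set is the `init_size`
  most-visited channels.
* **MWPLS** scores every contiguous window by paired cross-validated RMSE
  and selects the minimal-error window; deterministic given the CV seed.
* **IRIV** draws a balanced binary inclusion matrix per round (every
  surviving channel in exactly half the rows), scores each row's channel
  subset by paired CV error, and classifies each channel by the rank-sum
  test between rows including and excluding it: inclusion lowering the mean
  error ⇒ informative (strong if significant at α = 0.05, weak otherwise);
  inclusion raising it ⇒ uninformative/interfering, removed. One addition to
  the textbook scheme: a channel slated for removal is first re-examined by
  a paired drop-one test on the full retained set, and kept if its sole
  removal inflates the retained-set CV error by more than 2% (relative).
  This guards against a failure mode measured during development: on
  spectra whose informative channels each carry a small share of the signal,
  the half-inclusion rank test misclassifies a few of them every round, and
  the "repeat until no removals" loop turns that per-round error into
  geometric erosion of the true support. The drop-one test has the opposite
  regime — on a near-complete set, removing one genuinely informative
  channel inflates the error by tens of percent while removing a dead one
  changes it by a fraction of a percent — so the confirmation is essentially
  free of both error types. Rounds are followed by backward elimination of
  weakly informative channels on a paired split set.

The planted-signal benchmark gives each of its 20 informative channels an
*independent* latent contribution to the response (so the per-channel
"informative" label is true, not an artefact of redundancy) and makes dead
channels noisy at half the signal scale, emulating the detector-noise and
saturation regions of a real spectrum. The noise scale matters: nearly
noise-free dead channels act as free ridge-style shrinkage for a
high-component PLS model and are then genuinely worth retaining — an
error-driven selection method *should not* remove them, and no honest one
does.

`compare_methods` refits PLS on each selected channel set with an
MCCV-chosen component count and tabulates training ρ/RMSEC, RMSECV, test
ρ/RMSEP per method next to the all-channel base row; the best row (minimum
RMSEP, ties to fewer components) is flagged. A failing method is recorded
as failed and the comparison continues.

## Spatial mapping

Predictions are placed on the measurement lattice by exact (row, col)
coordinates; duplicate or out-of-range coordinates are errors. Neighbour-mean
imputation uses the 4-connected neighbourhood by default (8-connected behind
a flag) and sweeps until no unmeasured cell touches a valued cell; each sweep
reads only the previous state, so the result is order-independent, idempotent
and confined to the convex range of the measured values. Cells never reached
remain background.

The filled grid is placed in a square zero canvas at offset
`floor((canvas − grid)/2)` per axis (for 9×14 in 20×20: offsets 5 and 3) and
interpolated bilinearly on the 1-based node lattice 1…canvas_side sampled at
`spacing` per axis, giving `(canvas_side − 1)/spacing + 1` pixels per side —
1901×1901 for a 20-node canvas at spacing 0.01. Interpolated values at node
positions equal the canvas exactly (asserted). Background stays zero; masking
it out of a rendered figure is a display concern, not a data operation.

Error maps are `100·|pred − meas|/meas` on measured cells; zero-valued
measured cells are excluded and counted in the summary.

## Pipeline

`pipeline.run(PipelineConfig)` executes generate/load → average replicates →
preprocessing search → MCCV → outlier screen → method comparison → final fit
→ maps, per constituent, continuing past a failed constituent. Stage seeds
derive from the master seed by fixed offsets (recorded in the manifest), so
a rerun with the same config is bit-identical; the manifest lists every file
produced, the seeds, and per-stage summaries. Default iteration counts in
`PipelineConfig` (search 50, MCCV 200, outliers 250) are scaled-down working
values chosen so a full three-constituent run takes seconds; the study
conventions (1000/2500) are configuration values away.

## Limitations

* The phantom's favourable noise regime means absolute performance numbers
  (ρ ≈ 0.98) say nothing about real menisci, where reference-assay error and
  biological heterogeneity dominate; only the relative behaviour of the
  pipeline's stages transfers.
* RNV follows the percentile-centring convention; other RNV variants exist
  and would change results slightly.
* The outlier threshold rule is a convention, not an estimator with known
  error rates; its parameters are logged with every report.
* IRIV's drop-one confirmation adds O(removals) model fits per round; on
  problems with thousands of channels the rank-test-only variant
  (protect_tol = ∞) is cheaper but erodes redundant-support channels.
* MWPLS can only select one contiguous window; constituents with disjoint
  informative regions (all three, in this phantom) are structurally
  disfavoured by it, visible in the comparison tables.
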