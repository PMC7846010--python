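# Methods

`nanolayers` quantifies how two fluorescently labeled proteins organize at
and inside epithelial cells at the nanoscale: how a temporal stack of
diffraction-limited frames becomes a super-resolved image (SRRF), whether a
labeled protein's intensity field is clustered, dispersed or random
(intensity-weighted Ripley statistics), and how far apart two protein
layers sit across a membrane (carpet alignment with paired correlation
functions). A synthetic-data module generates ground-truth inputs with the
statistical structure each stage assumes, so every estimator is validated
by recovery of known quantities.

All lengths are nanometres internally. Images are `[row, column]`; the +y
direction (growing row index) points toward the gut lumen, −y toward the
cell cytoplasm. All stochastic stages take explicit integer seeds and are
pure functions of (parameters, seed).

## Synthetic data

**Blinking stacks.** Point emitters carry a brightness (expected
photons/frame) and an on-probability. The PSF is an isotropic 2-D Gaussian
(default σ 120 nm, typical of a 1.3 NA visible-light confocal) integrated
exactly over pixel areas via the separable error function, so a fully
contained emitter deposits exactly `brightness` expected photons — photon
conservation holds to float precision. Detection noise is Poisson shot
noise followed by additive Gaussian read noise (default σ 1 count).
Photobleaching is an optional absorbing state with exponential survival
(off by default).

Per-frame on-states are independent Bernoulli draws by default. This is a
deliberate simplification, and it has a consequence worth stating plainly:
the lag-1 temporal cumulant (TRAC2, below) has *zero expectation* for
frame-independent blinking, because consecutive frames are uncorrelated.
Real fluorophore on-times persist across frames; setting
`on_dwell_frames` switches the on-state to a two-state Markov (telegraph)
process with that mean on-dwell and the same stationary on-probability.
SRRF fixtures use a dwell of 3 frames at on-probability 0.3 — within the
regime where second-order temporal analysis is informative.

**Membrane pairs.** A membrane stripe is a single-valued centerline y0(x)
across a window (default 10 × 5 µm), displaced by a zero-mean Gaussian
process with squared-exponential covariance (amplitude 200 nm, correlation
length 1 µm by default) — the simplest smooth model of nanoscale
stretching and folding. Each of the two layers sits at a signed offset
along the local curve normal; negative offsets face the cytoplasm. Layer 0
is the reference. Emitters are Poisson-placed along the curve (default
50/µm per layer, a dense labeling; brightness 200 photons) and rendered
with a 40 nm PSF at 25 nm pixels, matching super-resolved imagery. The
generating centerline and offsets travel with the images.

**Point fields.** CSR is a homogeneous Poisson process; Thomas fields are
Poisson parents (with a 4σ guard margin outside the window) carrying
Poisson-distributed Gaussian-scattered offspring; hard-core fields are
Matérn-II dependent thinnings (uniform marks, smaller mark wins).
Realized points are rasterized either with the Gaussian PSF or, with
`psf_sigma_nm=0`, by delta deposition into the containing pixel. The
delta option matters for calibration: PSF rendering correlates
neighbouring pixel weights, and the pixel-permutation null (below)
correctly reads that instrumental correlation as small-radius clustering.
Fields meant to *be* null draws must therefore be delta-rasterized; fields
meant to emulate super-resolved imagery use a finite PSF.

## SRRF reconstruction

Per frame, a radiality map scores gradient convergence on a magnified
sub-pixel grid (defaults: ring radius 0.5 source pixels, magnification 10,
8 axes in ring = 16 ring samples). Gradients are central differences on
the source grid, sampled at ring positions by bicubic interpolation. Each
ring sample contributes `sign · (1 − d/r)²`, where `d` is the
perpendicular distance from the sub-pixel center to the line through the
sample along its gradient, and the sign is positive when the gradient
points toward the center. Flat regions (vanishing gradient) contribute
zero. The temporal reduction is TRAC2: per sub-pixel, the mean of
lag-1 products of the mean-subtracted radiality trace, floored at zero.
No drift correction is applied (fixed-tissue assumption); intensity
weighting of the radiality is off.

Two properties delimit what radiality can and cannot do. It sharpens: a
single spot's radiality peak is several times narrower than the optical
FWHM, and localizes the emitter to within a source pixel. It does not
split a *static* unresolved pair: gradients of a unimodal intensity field
converge at its single maximum, and a two-Gaussian sum only becomes
bimodal at ≈0.85 × FWHM separation — at which point the raw image is
bimodal too. Resolving a 0.6 × FWHM pair requires the temporal dimension:
independent blinking de-overlaps the emitters frame by frame, and TRAC2
accumulates their separated radiality peaks while suppressing static
signal. The acceptance checks encode exactly this division of labour.

## Intensity-weighted Ripley statistics

For an intensity field w (e.g. an 8-bit grayscale ROI) with pixel size
supplied as metadata,

    K(r) = A · Σ_{i≠j} w_i w_j e_i(r) 1(d_ij ≤ r) / (Σw)²

with A the masked window area, distances between pixel centers, and
e_i(r) the Besag edge weight of the center pixel: full-disc lattice count
over disc∩mask lattice count, exactly 1 for interior pixels, →2 at a
straight edge, →4 at a corner. Under CSR, K(r) ≈ πr² up to lattice
discretization (<2% relative for radii ≥10 pixels).

The CSR null permutes pixel intensities within the mask: the intensity
histogram is preserved exactly, spatial structure is destroyed. Each of
the (default 200, minimum 100) permutations is re-scored with the same
estimator; the per-radius mean and SD normalize the observed curve to
K̃ (≈ zero-mean, unit-variance under CSR — a field exchangeable with its
own permutations is, conditionally, one more draw from the null), and the
empirical 1st/99th quantiles form the envelope. Radii with K̃ above the
upper envelope are `clustered`, below the lower `dispersed`, otherwise
`random`. The scalar summary is argmax(K̃), ties broken toward the
smaller radius; groups of argmax values are compared by tie-corrected
Kruskal–Wallis with Dunn pairwise post-hoc tests (Holm adjustment).

Numerics: the interior part of the pair sum is an autocorrelation,
evaluated for all radii at once by FFT (padded to avoid wrap-around);
only boundary-band pixels need explicit Besag factors, and their disc
sums use row-cumulative-sum lookups in a compiled (numba) kernel. The
result equals the brute-force O(n²) pair sum to float precision — the
brute force is retained as the test oracle. One 400 × 400 field with a
200-permutation null and a 25-radius grid runs in ≈10 s on one core.

Default radius grid: 25 nm steps. For cluster-scale analyses
(~100 nm clusters) the grid runs to 625 nm; the argmax may land anywhere
on the grid, so the upper limit leaves ample room above the 300 nm scale
of interest. Analyses of micron-scale structure should extend `r_max`
(the estimator accepts any grid up to half the window side).

## Carpet alignment and inter-layer distances

A ROI (default 10 µm along the membrane × 5 µm across, per-ROI rotation
angle recorded; bicubic resampling) becomes an intensity carpet: columns
are membrane-perpendicular line profiles spaced ∂r = 25 nm. Columns are
aligned to the reference column (leftmost by default) by the paired
correlation function

    pCF(∂y) = ⟨F(y,0) F(y+∂y,∂r)⟩ / (⟨F(y,0)⟩⟨F(y,∂r)⟩) − 1,

averaged over overlapping samples only (no wrap-around; this
interpretation of the denominators is documented as a choice). The
argmax over lags (default search range ±1 µm), refined to sub-bin
precision by a quadratic through the peak and its two neighbours, gives
the per-column shift; columns whose correlation peak falls below 0.05 are
flagged unalignable and excluded with a logged count. Columns are
translated by minus the shift (cubic interpolation, out-of-range samples
filled with the column mean). The same shifts — computed on the
reference channel — are applied to both channels.

The signed inter-layer distance per column is the refined argmax of the
paired cross-correlation (pCCF, same form with F₁ the reference channel).
Negative distances point toward the cytoplasm. Summaries (mean, SEM) are
computed at the cellular-replicate level — one mean per cell, SEM over
cells — never over the (much larger) column count. Modes of the pooled
distribution are detected by Gaussian kernel density estimation
(Silverman bandwidth) with peaks of ≥10% relative prominence.

Accuracy: noiseless sub-bin shifts are recovered to <0.05 bin; with
per-pixel SNR 10 a single column's estimate jitters by ≈0.25 bin
(≈6 nm), so per-column distances scatter while their mean is accurate —
averaging ~30 columns brings the error below 0.2 bin. The overlap-mean
normalization skews the refined argmax by up to ~0.1 bin (≈2–3 nm) for
narrow peaks on a baseline; this bias is inherent to the correlation
definition and sits well inside the pipeline's ±5 nm recovery contract.
End to end (simulate → extract → align → pCCF), a 26 nm cytoplasm-facing
offset is recovered with |bias| ≤ 5 nm and per-column SD ≤ 10 nm at
default conditions; at sparse labeling (≈8–30 emitters/µm, low photon
budget) low-confidence columns are rejected and surviving distances
spread broadly across both signs, as real membranes show.

## Scalar quantifications

ROI fluorescence is the arithmetic mean over a square (default
20 × 20 µm) in arbitrary fluorescence units; condition groups are
compared by Kruskal–Wallis plus Dunn/Holm (conditions with <3 cells are
excluded with a warning). The degree of labeling is the dimensionally
consistent form (A/ε) / (c/MW) — molar dye over molar protein; published
variants that multiply where division is required do not survive unit
bookkeeping, so the standard form is used. The Tabashnik synergism
factor divides the additive-expectation mixture LC50,
`[ρ/LC50_a + (1−ρ)/LC50_b]⁻¹`, by the observed mixture LC50; it is
invariant to rescaling all LC50s. Probit/logit LC50 estimation is out of
scope; LC50s are inputs.

## What the synthetic tests do and do not show

The generators reproduce the *statistical* structure the estimators
assume: blinking photophysics with temporal persistence, smooth membrane
deformation with a known normal offset, and point processes with known
clustering scales. They do not model 3-D optical sectioning, chromatic
aberration, tissue autofluorescence, real gut geometry, or labeling
stoichiometry. Passing recovery tests therefore demonstrates estimator
correctness and calibration under the stated noise models — not that any
particular biological image would yield the same numbers.

## Problem sizes and runtime

Defaults are chosen so the full suite runs on one core in well under half
an hour: 30 membrane carpets (10 µm × 5 µm, ≈400 columns each) for
distance recovery; 50 Thomas fields (10 × 10 µm, 400 × 400 pixels,
200-permutation nulls) for cluster-scale recovery; 200 CSR fields
(1.6 × 1.6 µm, 100-permutation nulls) for envelope-coverage calibration;
SRRF fixtures of 100 frames at 20–32 pixel frames and magnification 10.
Larger windows, more permutations and longer radius grids scale linearly
to quadratically and are plain parameter changes.
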