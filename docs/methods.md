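# Methods

This note documents the models, the synthetic study design, and the
numerical choices behind `roastchem`, in the spirit of a model-description
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The analysis chain

The pipeline mirrors a three-stage chemometric workflow on paired
GC-MS / NIR measurements of roasted coffee:

1. **Volatile block.** The aligned peak table is cleaned by an abundance
   filter (drop a compound whose maximum area over all samples is below
   50,000 — peaks that never rise above integration noise) and a
   reproducibility filter (drop a compound not present, i.e. non-missing
   and > 0, in at least 80% of the readings of *any* origin × roast
   replicate group). The any-group rule is deliberate: a marker of one
   roast degree is legitimately absent at the others, and a global rule
   would delete exactly the discriminant compounds. Remaining missing
   values are set to zero (absence of a peak is informative) and columns
   are autoscaled (mean 0, SD 1, n−1 denominator). Exploratory PCA is
   followed by PLS-DA per origin, and VID marker selection.
2. **NIR block.** Analytical replicates are averaged to batch spectra,
   EMSC-corrected, and mean-centered (the centering lives inside the PLS
   model state so cross-validation refits it per fold). PLS-DA per origin;
   the LV1 loading vector locates the wavelengths driving the separation.
3. **Prediction.** For each VID-selected marker, a univariate PLS-R from
   batch-averaged EMSC-corrected spectra, calibrated on one origin and
   validated on the other. Instruments measured different aliquots, so
   pairing is at batch level: batch-mean spectra against batch-mean
   peak areas. With 3 roasts × 3 batches this gives 9 calibration and 9
   validation samples per direction.

## PLS implementation

NIPALS with X- and Y-deflation; inner-loop convergence on the weight
vector (tolerance 1e-10, cap 500 iterations; exceeding the cap raises,
naming the component). `B = W (P'W)^{-1} Q'` reproduces the training fit
`T Q'` exactly, scores are mutually orthogonal, and at full rank the
predictions coincide with ordinary least squares — all three are asserted
in tests, along with prediction-level agreement with an independent PLS
implementation.

Venetian-blinds cross-validation assigns sample *i* to fold `i mod s` on
the dataset's stored sample order (s = 5 for classification, 3 for the
9-sample prediction models; the method prescribes interleaving but not the
split count). Inside CV, a training fold may not support the requested
component count (rank exhaustion after deflation, or a NIPALS eigen-tie on
label-free noise); such folds saturate at the deepest fittable component
with a recorded warning rather than aborting — the user-facing `fit_pls`
keeps the strict error. A fold whose training labels collapse to a single
class yields intercept-only predictions, again with a warning. LV selection
is parsimonious: the smallest count whose criterion (RMSECV for regression,
misclassification rate for class responses) is within 2% of the global
minimum.

Classification metrics are one-vs-rest sensitivity and specificity per
class, overall and per-class accuracy, the mean balanced classification
error `((1−sens) + (1−spec))/2` averaged over classes, and R² on the dummy
response. Arg-max class assignment breaks exact ties toward the earlier
class and flags them.

## VID

`VID(c, k) = corr(x_c, ŷ_k)` with Pearson correlation (n−1), where `ŷ_k`
is the *continuous* fitted class-membership column of the calibration
PLS-DA model — correlating against hard labels is a special case, and the
continuous column is what a PLS-DA model actually predicts. Zero-variance
compounds get a flagged null rather than 0, so "no signal" and "no
variance" stay distinguishable. Signed selection (`VID > 0.8`) defines
per-roast markers; magnitude selection (`|VID| > 0.9`) defines the heatmap
set. The heatmap matrix holds roast-class means of autoscaled abundance,
rows ordered by class membership then descending |VID|.

## Synthetic study design

`RoastDesign` defaults encode the study layout: 2 origins × 3 roasts × 3
batch replicates, 3 GC-MS readings per batch (9 per roast level), 9 NIR
readings per batch (27 per roast level), 166 compounds, NIR grid 400–2500
nm at 2 nm.

**Abundances.** Log peak area = per-compound baseline (log-normal around
ln 3·10⁶, SD 1) + trend × effect + origin shift + batch effect +
replicate noise. Multiplicative lognormal replicate noise with CV 0.10 —
a typical analytical CV for HS-SPME peak areas — and batch effects of
0.05 log-units. Chemical classes follow the roast trends the field
reports: furans, ketones, phenols, pyrroles, esters, pyridines and
pyranones rise toward dark roast; aldehydes, alkanes and alkadienes fall;
imidazole-type compounds peak at medium. Monotone class effects default to
1.0 log-unit per roast step (~7× light→dark, the order of magnitude real
roast markers span); the peak class uses 1.5, reflecting how
α-diketone-like medium markers spike several-fold before degrading.
Monotone trends carry a per-compound curvature (±0.5) so some compounds
surge late (after second crack) and others accumulate gradually — this
convexity spread is what gives medium roasts their own direction in any
linear summary of the data. Compound roles: ~63% discriminant (trended and
spectrally linked), 25% flat (pure noise), 6% irregular (below the 50,000
floor), 6% sporadic (present in a fixed 60% of each group's readings —
below the 80% rule by construction).

**Spectra.** Ten fixed Gaussian bands, half centred in 500–1000 nm. Band
weights are `w0 + A (L d) + origin shift`, where `d` is the batch-mean
log-abundance deviation of the linked compounds and `L` a fixed rank-3
projection (rank 3 keeps the RMSECV minimum in the small-LV regime the
models select). The mixing `A` is weighted 1.5× for sub-1000 nm bands and
0.5× above, concentrating the roast signal in the visible/third-overtone
region where roast discrimination is known to live. Raw spectrum =
`b × clean + order-2 polynomial baseline + iid noise`, with per-sample
log-normal scatter `b` (σ = 0.10), baseline coefficients N(0, 0.05) and
noise SD 0.01 absorbance units. The generator records `b`, the baseline
coefficients, the mixing matrices and the artifact-free spectra for oracle
tests.

**Origin effect.** The second origin differs by a 0.03 log-unit
per-compound abundance shift and a 0.05 additive band-weight shift. These
are deliberately mild: the regime being emulated is one where the two
origins are similar enough that a model calibrated on one transfers to the
other, and no data exist to estimate the shift; larger shifts propagate
through the latent link into a collective spectral offset that calibration
cannot have learned and make transfer collapse wholesale. The magnitude is
a free knob of the generator, not an estimate.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: chromatographic co-elution and alignment errors,
instrument drift between blocks, nonlinear detector saturation, water- and
moisture-band interference, or origin differences beyond additive shifts
(different cultivar chemistry, different trend shapes). Real cross-origin
transfer is harder than this model; results here demonstrate correctness
of the chain, not field performance.

## Numerical choices and degenerate inputs

- EMSC design matrix: `[r, 1, λ̃, λ̃²]` with λ̃ the grid rescaled to
  [−1, 1]; one `lstsq` solve for all spectra; |b| < 1e-8 raises, naming
  the sample. The generator's baseline uses the same basis so stored
  coefficients reconstruct raw spectra exactly.
- Autoscaling refuses zero-variance columns by name; the filters guarantee
  this does not occur downstream of them.
- NRMSE normalises by the observed response range; the denominator is
  recorded per compound, and the choice (range vs mean) is a config-level
  declaration rather than a hidden constant.
- R²pred is the coefficient of determination (1 − SSE/SST with SST
  centered on the evaluation set's own mean), not a squared correlation —
  it is negative when predictions are worse than the validation mean.
- Screening is strict: validation R² exactly at the threshold fails.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng` seed sequences; equal seeds give bitwise
  equal outputs, asserted down to the written files.

## Problem sizes

The shipped worked fixture is 12 compounds × 54 GC-MS readings with
200-point spectra (full design: 166 compounds, 1051-point spectra); the
fixture keeps the whole suite and the acceptance script in the seconds
range while preserving every structural feature of the full design —
results on both sizes are produced by the same code paths.

## Known limitations

- The 80%-reproducibility rule's group scope (per origin × roast vs
  global) is an interpretation; both the rule and its scope are exposed as
  parameters.
- PLS-DA on 9 batch-averaged spectra per origin sits at the small-n edge;
  the unaveraged reading-level path (81 spectra per origin) is available
  via the averaging level.
- VID uses calibration (fitted) predictions, not cross-validated ones; a
  compound can therefore inherit optimism from an overfitted class model.
  With the 2-LV models selected here the two differ little.
- Peak-at-medium compounds have a smaller raw-scale dynamic range than
  monotone markers at equal log effect, and are accordingly the hardest
  prediction targets — mirroring the general experience that medium-roast
  markers are the marginal cases of NIR prediction screens.
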