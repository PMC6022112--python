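# Methods

`nirwood` implements a complete near-infrared (NIR) chemometric workflow for
predicting the modulus of elasticity in static bending (MOE, GPa) of wood
from diffuse-reflectance absorbance spectra:

    spectra -> MSC -> Savitzky-Golay 1st derivative -> Kennard-Stone 2:1 split
            -> SiPLS interval search -> SPA wavelength selection
            -> PLS1 / BPNN calibration -> r, RMSE, SECV, RPD

Because no public wood spectra ship with the package, a synthetic-spectra
generator provides the study conditions; it is first-class, tested code, and
everything downstream is agnostic to whether data came from it or from the
CSV readers.

## Synthetic spectra

Spectra are linear mixtures of latent "chemical components", each a sum of
Gaussian absorption bands (center, sigma in nm, peak amplitude in absorbance
units), sampled on a uniform 907–1864 nm grid with 117 points. The default
bank has six components:

| component            | bands (center/sigma/amp)              | role                |
|----------------------|---------------------------------------|---------------------|
| cellulose-like       | 960/16/0.45, 1345/16/0.50             | response-linked     |
| lignin-like          | 1540/16/0.50                          | response-linked     |
| hemicellulose-like   | 1725/16/0.45                          | response-linked     |
| water-like           | 1150/20/0.50, 1620/20/0.40            | nuisance            |
| extractives-like     | 1050/30/0.40, 1440/30/0.45            | nuisance            |
| matrix background    | 1250/450/1.6, 1900/300/0.8            | near-constant bulk  |

The response-linked bands sit inside intervals 1, 5, 7 and 9 of a 10-way
equal split of the grid, so roughly 4 of 10 intervals are informative in the
raw spectra — the premise of interval selection. The broad, nearly constant
matrix background mimics the bulk absorption/scattering continuum of wood;
without it the multiplicative-scatter fit is anchored by the chemistry
itself and couples the response into every wavelength.

Per-sample distortions, applied in a fixed draw order for seed
reproducibility: concentrations are multivariate normal (mean 1, SD 0.3 per
chemical component, 0.02 for the matrix), clipped at zero; each spectrum
gets affine scatter `b*s + a` (slope SD 0.08, offset SD 0.03) — exactly what
MSC removes — a random degree-2 polynomial baseline drift (amplitude 0.03 AU)
and white noise (SD 0.003 AU).

The response is

    MOE = 11 + u + 0.4 * ((u - mu_u)^2 - sigma_u^2) / sigma_u + eps,

with `u = (6, -5, 4, 0, 0, 0) . c` (GPa) and `eps ~ N(0, 0.25^2)`. Defaults
give mean ~15.5 GPa and SD ~2.7 GPa, in the range of oak structural timber.
The quadratic term deserves comment. It acts on the *linear predictor* `u`
rather than on a single component, so any wavelength window that sees the
response-linked chemistry carries the nonlinearity. Its weight (0.4, i.e.
roughly a quarter of the response variance) was set from a signal budget:
the improved Kennard-Stone split deliberately sends extreme samples to the
calibration set, which shrinks the quadratic term's dispersion within the
prediction set to roughly half its overall value; the weight keeps that
within-prediction-set dispersion (~0.5–0.9 GPa) a few times the 0.25 GPa
response noise, so a nonlinear calibration has something real to gain
exactly where it is evaluated.

What the generator does **not** emulate: instrument line shape, detector
nonlinearity, wavelength-grid irregularity (real diode-array grids are not
perfectly uniform), temperature/moisture band shifts, and heteroscedastic
noise. Passing tests therefore demonstrate the correctness and statistical
behaviour of the algorithms under a controlled model, not instrument-level
performance on real wood.

Two auxiliary constructors make ground truth explicit for the selection
algorithms: `planted_interval_dataset` (two of eight contiguous intervals
carry a latent factor; the rest are pure noise) and
`planted_columns_dataset` (three of twenty columns, with inflated variance,
determine the response).

## Bending formula

`moe_static_bending` evaluates `23 P l^3 / (108 b h^3 f)` with the load
difference P in newtons and all lengths in millimetres, yielding N/mm^2
(MPa), divided by 1000 to report GPa. The unit convention is the package's
own choice; the formula's source reports GPa values consistent with it.

## Pretreatment

MSC regresses each spectrum on a reference by least squares and replaces it
with `(s - a)/b`. The reference defaults to the mean spectrum of the data
the corrector was *fitted* on, so prediction-set spectra are always
corrected against the calibration-set mean — never their own mean — to avoid
information flow across the partition. Slopes below 1e-8 in magnitude raise
an error rather than amplifying a degenerate spectrum.

The Savitzky-Golay filter (scipy) uses window 11, polynomial order 3 and a
first derivative by default. Edge columns are handled by polynomial fits on
asymmetric windows (`mode="interp"`), keeping all 117 columns so interval
bookkeeping stays aligned. Derivatives are divided by the grid spacing, so
outputs are absorbance per nm and grid-independent. A first derivative of a
Gaussian band spreads its information into the band flanks (±4 sigma plus
half a window); on synthetic data this visibly widens the informative
regions relative to the raw spectra, which is faithful to how derivative
pretreatment behaves on real spectra.

## Partitioning

Pairwise Euclidean distances are normalized by the maximum pairwise distance
(largest entry exactly 1); the printed form of this normalization in the
source literature is self-referential and was interpreted this way.
Kennard-Stone then seeds with the two most distant samples and repeatedly
adds the sample maximizing the minimum distance to the chosen set, until
`ceil(n*r/(r+1))` calibration samples are reached (125 at 2:1 -> 84/41; the
ceiling, not rounding, reproduces that split). Ties break toward the lowest
sample index, making the split fully deterministic; normalization makes it
scale-invariant. The pipeline partitions *pretreated* spectra (the split is
defined by spectral difference); partitioning itself never reads responses.

## SiPLS

The spectrum is divided into N near-equal contiguous intervals (the first
`n mod N` intervals take the extra column). For every N in 5..15 and every
combination of 2, 3 or 4 intervals, a PLS1 model on the concatenated columns
is scored by leave-one-out RMSECV, with the component count chosen by the
inner LOO minimum (cap 10). The per-N winners form the search table; the
global minimum defines the retained columns. Note: with 117 columns and
N=10, the even-split convention makes a four-interval combination such as
[1 5 7 9] span 47 columns; a spectrometer's slightly non-uniform grid can
make that 46 — the package documents, and does not chase, this off-by-one.

PLS1 is implemented in-package (NIPALS on centred, unscaled data). The
reason is efficiency, not novelty: NIPALS latent variables are nested, so a
single LOO pass scores *every* component count at once, and the inner loop
is compiled with numba (pure-numpy fallback). This is what makes the
exhaustive search (~6700 combinations, each with an 84-fold LOO) run in
about a minute on one CPU. sklearn's PLSRegression (scale=False) serves as
an independent cross-check in the test suite, never as the implementation.

## SPA

The successive projections algorithm builds, from every possible start
column, a chain in which each added column maximizes the norm of its
projection onto the orthogonal complement of the span of the columns already
chosen (mean-centred; Gram-Schmidt with early stop at numerical rank).
Chain prefixes are scored by multiple linear regression:

* `spa_select` — RMSE on a user-supplied validation set; the chosen count
  strictly minimizes the curve (ties toward fewer variables).
* `spa_select_cv` — leave-one-out RMSE on the calibration set itself via the
  PRESS identity `e_i/(1-h_ii)`, with the one-standard-error rule for the
  variable count. The pipeline uses this mode: scoring on the held-out
  prediction set would leak its responses into selection, and an inner
  28-sample split proved too noisy to compare models downstream (it inflated
  the selected count to 9–10 and destabilized the PLSR/BPNN comparison).
  Minimizing a CV curve over hundreds of chain prefixes overfits the
  criterion; the 1-SE rule is the standard correction.

## Calibration models

**PLS1** (`PLS1Regression`): component count in the pipeline chosen by LOO
RMSECV (cap 10). With maximal components on full-rank data it coincides with
ordinary least squares, which the tests assert.

**BPNN** (`BPNNRegressor`): one sigmoid hidden layer (default `2*d+1` units,
11 for five inputs), linear output, inputs and target min-max scaled to
[0, 1]. Training is full-batch backpropagation with momentum 0.9 and an
adaptive learning rate: initial rate 0.01, grown 5% after an improving
epoch; an epoch that raises the loss by more than 4% is rejected (weights
restored), the rate shrinks by 30% and the momentum buffer resets. Hidden
weights use Nguyen-Widrow initialisation. Training stops at 2000 epochs or
after 100 consecutive epochs without a 1e-6 improvement of the best training
MSE (momentum makes a single-epoch improvement test trip spuriously). A
fixed constant rate of 0.01 does not converge within the epoch budget on
these problems; the adaptive schedule is the classic remedy and keeps every
run deterministic. Three seeded restarts are trained and the net with the
lowest training MSE kept, guarding against poor local minima; the seed is
required, so identical seeds give bit-identical weights. No weight decay or
other regularization is used, and no ensembling — the fitted object is a
single net.

## Metrics

r_c / r_p are Pearson correlations between measured and predicted MOE on the
calibration / prediction set ("coefficient of determination" with values
like 0.90 in this literature conventionally denotes r, and the reported
SD/RMSEP/RPD arithmetic is only consistent with that reading). RMSEC/RMSEP
are plain RMS errors; SD uses the n-1 denominator (2.23/0.76 then rounds to
the reported RPD 2.93); RPD = SD/RMSEP is asserted as an identity on every
emitted record. SECV is the bias-corrected standard error of the n
leave-one-out residuals, `sqrt(sum((e_i - mean e)^2)/(n-1))`, refitting the
full model spec per fold; for the BPNN each fold derives its seed as
`random_state + fold`, so the sweep is reproducible (and therefore not
permutation-invariant for the BPNN, unlike for PLS).

## Pipeline and reproducibility

`run_pipeline` wires the stages in order. The partition stage pretreats the
full set against its own mean (it sees spectra only); the modelling stages
re-pretreat with the calibration-set mean as MSC reference. Prediction-set
responses are read exactly once, by the final evaluation — deleting them
changes no artifact except the prediction-set metrics, which the tests
assert file-by-file.

One global seed fans out through `numpy.random.SeedSequence(seed)`: entry 0
(mod 2^31) seeds the synthetic generator, entry 1 the BPNN. Human-readable
outputs round to 2 decimals; full-precision sidecars keep every digit, and
the CSV dialect round-trips float64 exactly (`%.17g` writing, round-trip
parsing).

## Problem sizes used in the checks

The acceptance checks run the planted-interval and planted-column
simulations at 100 seeds each, the Kennard-Stone oracle comparison on 200
random sets of up to 8 samples, and the end-to-end PLSR-vs-BPNN comparison
as 100 full pipeline executions with the interval search restricted to N=10
(combinations of 2–4 intervals) — the full N=5..15 grid is exercised once
per run elsewhere; restricting the repeated comparison to one N keeps 100
executions to a few minutes without changing the data conditions.

## Known limitations

* Real spectrometer grids are slightly non-uniform; the package assumes a
  uniform grid for the SG derivative (and checks it).
* The BPNN comparison is a statistical statement over seeds, not a per-seed
  guarantee; individual runs can favour PLSR, as individual datasets can in
  practice.
* MSC's division by the fitted slope makes even a purely linear mixture
  slightly nonlinear in the concentrations (closure); this is faithful to
  real MSC behaviour and affects both calibration models equally.
* SECV for the BPNN depends on the derived per-fold seeds; it is
  reproducible but not permutation-invariant.
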