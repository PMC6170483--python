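# Methods

`ivspec` implements a complete chemometric workflow for calibrating a
scalar quality parameter — iodine value (IV, g I₂ / 100 g oil, a measure of
lipid unsaturation) — against vibrational spectra from portable NIR and
Raman instruments: PLS1 regression, four resampling-based wavelength
selectors, Kennard–Stone sample partitioning, a repeated-evaluation
benchmark, and a synthetic oil-blend generator with known ground truth.

## Calibration model

PLS1 decomposes the centered calibration matrix and response as
X = T Pᵀ + E and y = T qᵀ + f, extracting components by NIPALS deflation:
each weight vector w_a ∝ Xᵀy is the direction of maximal covariance with
the residual response. The regression coefficient vector in centered space
is b = W (PᵀW)⁻¹ q, accumulated incrementally so that the whole coefficient
path b(1), …, b(A) is available from one fit. Extraction stops early when
the weight norm collapses below 1e-12 relative to the first component
(rank-deficient X); the achieved component count is reported. With A equal
to the rank of a tall X, the PLS solution coincides with ordinary least
squares, which the test suite uses as an oracle.

The latent-variable count is chosen by k-fold cross-validation (default
k = 5): a seeded permutation is cut into near-equal contiguous blocks,
centering is re-estimated inside each training fold, and RMSECV is computed
from pooled out-of-fold residuals. Ties in the minimum break toward the
smaller count (parsimony). Q²cv is computed from the same pooled
out-of-fold predictions — the only reading under which it differs from the
calibration fit. RMSEC/RMSEP are root mean square errors of the refitted
model on the calibration and independent test blocks; across-run summaries
use the n−1 sample standard deviation.

All inner loops (NIPALS coefficient path, fold-wise CV predictions, and
population scoring of many channel subsets) are numba-compiled; the public
API wraps the same kernels, so there is exactly one PLS implementation.

## Sample partitioning

Kennard–Stone selects calibration samples by max–min Euclidean distance on
the raw (uncentered) spectra: seed with the most distant pair, then
repeatedly add the sample whose minimum distance to the selected set is
largest. The metric and space are a package choice (the canonical one);
ties break toward the lowest sample index so the split is fully
deterministic. The default calibration share is 36/59 ≈ 0.61.

## Wavelength selectors

All four selectors operate on the calibration block only, score candidate
subsets by 5-fold RMSECV with the latent-variable count re-chosen per
subset (capped at 10), and use seeded, reproducible randomness.

**MCUVE.** Artificial noise channels (default: one per real channel,
uniform noise at 1e-3 of the median column SD) are appended to the centered
calibration matrix. 500 Monte Carlo runs each fit PLS on 80% of the samples
drawn without replacement; the stability of channel j is
c_j = mean(β_j)/sd(β_j) over runs. Real channels with |c| below the largest
artificial |c| are eliminated; survivors are ranked by |c| and nested
prefixes of the ranking are scored by RMSECV, returning the best prefix.
The elimination-plus-ranking combination resolves the two descriptions of
the method in circulation; both stages are kept. Note the artificial
cutoff is essentially scale-free in the noise amplitude (a coefficient
t-statistic is invariant to column scaling in the small-amplitude limit),
so the amplitude mainly guards against the artificial block perturbing the
model, not the cutoff level.

**CARS.** 100 runs; in run i a PLS model is fitted on 80% of the samples
over the currently retained channels, then the channel set shrinks twice:
a forced step keeping the top round(r_i · p) channels by |coefficient|,
where r_i = a·e^(−ki) with a = (p/2)^(1/(N−1)), k = ln(p/2)/(N−1) (so
r_1 = 1 and r_N = 2/p identically), and a competitive step resampling
channels with replacement proportionally to |coefficient| (draw count =
current retained count), collapsed to the unique set. The EDF ratio is
applied to the original channel count, capped by the current survivor
count and floored at 2 channels throughout (if the competitive step would
leave fewer than 2, the top-2 weighted channels survive). Each run's
subset is scored on the full calibration block with one fixed fold
assignment and the lowest-RMSECV run wins.

**BOSS.** Weights start uniform; each iteration draws 1000 subsets by
weighted bootstrap (p draws with replacement, unique set), scores them, and
lets the best 10% vote: each best model's |b| is normalized to unit L1 mass
(so every best model contributes equally) and summed into the new weights.
Channels absent from all best models get weight zero and can never return.
Stopping — the method's literature leaves this open — is when the best
subset is no larger than its component count + 1, when the weight support
stops shrinking for 3 iterations, or after 30 iterations; the best subset
seen anywhere is returned.

**VCPA.** 50 EDF runs; each builds a 1000-row binary inclusion matrix over
the live channels (inclusion probability 0.5, rows with fewer than 2 ones
resampled), scores every row-subset, and ranks live channels by their
frequency in the best 10% of sub-models. The live set shrinks along a
geometric schedule n_i = round(p·(ω/p)^((i−1)/(runs−1))) from p down to
ω = 14 — the geometric form is the package's realization of "exponentially
shrinking variable space" with the stated endpoints, isolated in
`vcpa_edf_counts` so it can be swapped. The 14 survivors are then searched
exhaustively: all 2¹⁴ − 1 subsets are scored with one shared fold
assignment (paired comparisons) and the minimum wins; exact ties break to
fewer channels, then lexicographic order.

## Synthetic data

The oil-blend generator emulates the study conditions the package is
tested under: 59 samples, four components (soybean, olive, peanut, blend)
with fractions drawn uniformly on the simplex (flat Dirichlet, rejection
sampling) within per-component caps of 85.46%, 69.34%, 88.35% and 85.46%,
and three instrument profiles (125 channels over 900–1700 nm; 3108 over
1100–2100 nm; 3122 over 175–3200 cm⁻¹). Pure-component spectra are sums of
Gaussian bands at standard oil band positions (NIR C–H overtones and
combination bands; Raman C=O/C=C/CH₂/=C–H/C–C bands), with per-component
amplitude patterns making the mixture spectrally identifiable. Component
iodine values (130, 84, 96, 108) realize responses spanning roughly
86–126. Spectra add a fixed smooth baseline — one seeded low-order
polynomial shared by all samples, emulating a constant scatter/offset —
plus Gaussian channel noise (SD 0.002); responses add Gaussian noise
(SD 0.5, the scale of a titration reference). Because the baseline is
sample-independent it is removed by mean centering, and with all noise at
zero the data are exactly bilinear: full-rank PLS reproduces y to numerical
precision, which pins the generator to the calibration model.

What the generator does *not* emulate: per-sample multiplicative scatter,
instrument line-shape effects (Lorentzian/Voigt profiles), wavelength
calibration error, or band-position shifts with composition. Passing tests
therefore demonstrate algorithmic correctness under a faithful bilinear
model, not robustness to those real-data artifacts.

`planted_dataset` is the selector-scoring fixture: exactly 5 of 125
channels carry independent latent factors (uniform on [0, 1]) that drive
the response (affine map into the 86–126 IV range, response noise SD 0.3);
all other channels fluctuate around a constant baseline level with SD 0.1
— smaller than the factor SD of 0.29, as in real spectra where
uninformative regions carry only detector noise. The accompanying truth
mask makes selector recall and precision directly computable, and
`plant_uninformative_region` can overwrite any axis interval of the oil
data with pure noise for the same purpose.

## Benchmark protocol

The Kennard–Stone split is computed once (it is deterministic); each of
the repeats (default 50, reduced in the test suite to keep runtimes
proportionate) re-runs every stochastic selector with seed = base seed +
repeat index and re-selects the latent-variable count — which is why mean
nLV can be fractional — then evaluates the selected subset on the held-out
test block. Full-spectrum PLS is deterministic, so its across-repeat SD is
zero and its nVAR has no SD. Failed repeats are recorded and excluded from
the aggregates. Two runs with the same configuration and base seed produce
byte-identical reports.

## Numerical choices and limitations

- Ties everywhere break deterministically: lowest channel/sample index,
  smallest component count, fewest channels then lexicographic (VCPA).
- Rounding is half-away-from-zero where subset counts are derived from
  ratios; EDF-derived counts are floored at 2 channels.
- All randomness flows from one seed per operation through independent
  spawned substreams (sampling, noise, folds), so results are reproducible
  and substreams do not interact.
- The CSV dialect is fixed (comma, "." decimal, header of channel
  positions, leading id column, trailing response column) so round-trips
  are bit-identical for shortest-repr decimals; no instrument binary
  formats are read.
- Preprocessing is mean centering only — no SNV/MSC/derivatives — matching
  the calibration protocol the package implements.
- The selectors' hyperparameter defaults (500 MC runs; 100 CARS runs; 1000
  bootstrap subsets; 50 EDF runs × 1000 BMS rows, ω = 14, 10% best models;
  5-fold CV; 50 repeats) are the standard published settings for these
  methods and are all configurable.
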