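# Methods

## Problem and model

`spectox` regresses acute fish toxicity, expressed as log10 of the LC50
in millimolar (log-mM), on a feature vector consisting of the neutral
monoisotopic mass (Da) followed by binary molecular-fingerprint bits.
The learner is a gradient-boosted regression-tree ensemble with
DART-style dropout (trees are randomly dropped during boosting, which
regularizes the additive expansion), trained with per-chemical sample
weights. The scientific premise is that acute toxicity is dominated by a
nonspecific, mass/hydrophobicity-driven narcosis baseline which the
fingerprint bits fine-tune with substructure-specific (toxicophore)
effects; accordingly the package always fits two deliberately weak
baselines — ordinary least squares on exact mass alone or on log K_OW
alone — and quantifies the fingerprints' added value with a paired
bootstrap on test RMSE.

The same fitted model serves two input paths. For an identified
structure, fingerprints are computed by SMARTS substructure matching.
For an unidentified LC-HRMS feature, fingerprint *probabilities*
predicted from MS² spectra by an external fragmentation-tree/SVM tool
are binarized at 0.5 (values exactly at the threshold round up, a
declared convention) and pushed through the identical feature pipeline.
When a feature has several candidate molecular formulas, toxicity is
predicted per candidate and aggregated by one of three strategies:
highest-ranked formula only (`top1`, the default — the ranking is
usually right and the error from a wrong top formula is bounded by the
fingerprints' robustness to formula choice), the unweighted mean of the
top three, or the mean over all candidates. When both ionization modes
yield predictions for one feature, they are averaged and both retained.

## Data curation

Raw tables carry one measurement per row with a concentration and unit.
Curation proceeds in fixed order:

1. **Unit conversion.** mg/L is divided by the molar mass (g/mol) to
   obtain mM; mM passes through; everything becomes log10 mM. Unknown
   units are a hard error naming the unit. Log base 10 is the QSAR
   convention for LC50 work.
2. **Aggregation.** Replicate measurements per chemical collapse to the
   median (robust to single bad replicates); the sample SD over
   replicates is retained as `sd_exp` (absent for single measurements).
3. **Reliability filter.** Chemicals with `sd_exp` strictly greater
   than 1.5 log-mM are excluded (boundary value 1.5 is kept); both
   partitions are returned for audit, and their union always
   reconstitutes the input.
4. **Weights.** `w = 1 / max(sd_exp, 0.05)`, with single-measurement
   chemicals receiving `1 / mean(sd_exp over multi-replicate chemicals)`,
   then all weights rescaled to mean 1. The inverse-SD form realizes
   "more precise values count more"; the 0.05 log-mM floor stops a few
   near-zero SDs from dominating; mean-1 rescaling keeps the effective
   sample size interpretable. Inverse-variance weighting would be the
   main alternative; it punishes noisy chemicals harder and was rejected
   as too aggressive for SDs spanning an order of magnitude.
5. **Split.** Chemicals named in a validation-id list (those with
   library spectra, to be re-predicted from the spectrum path) are
   quarantined first; the remainder splits 80/20 train/test uniformly at
   random under the given seed.

## Cross-species harmonization

LC50 values of different fish species correlate strongly over common
chemicals but differ in sensitivity. The mapping from a source species'
scale to the target's is a Gaussian-family additive model with one
smooth term, implemented as a penalized cubic smoothing spline with
GCV-selected smoothing. The spline solver requires strictly increasing
abscissae, so tied source values are averaged first. Outside the fitted
source range the curve is clamped to its boundary value and the query
flagged as extrapolated — extrapolating a spline would be invisible
nonsense. Chemicals already present in the target dataset keep their
native values; mapped values only extend coverage (merging adds
information, never overwrites measurements). A minimum of 20 common
chemicals (configurable) is required to fit a mapping.

## Fingerprints and feature selection

The registry is data, not code: an ordered table of bit definitions
(SMARTS pattern, key family, optional match-count threshold, an
*absolute index* in the external tool's numbering, and a label). The
packaged default (~230 bits) combines the MACCS-derived SMARTS keys with
Klekota–Roth-style chemotype keys, named functional-group/toxicophore
SMARTS and ring-system keys; it is a synthetic stand-in for the larger
intersection of fingerprint families a production deployment would align
with its fingerprint predictor, and any replacement registry TSV can be
supplied. Structure bits are deterministic and invariant to the SMILES
spelling of a molecule; a registry/model mismatch is caught by a content
hash stamped into the trained model.

Feature selection runs on the training matrix only, in two stages:
near-zero-variance columns are dropped first (most-common to
second-most-common frequency ratio > 19 *and* unique values < 10% of
rows — the standard preprocessing rule, both cutoffs configurable), then
for each pair with |Pearson r| > 0.9 (the phi coefficient on 0/1
columns) the higher registry index is dropped, scanning pairs in index
order. The procedure is deterministic, leaves no kept pair above the
threshold, and is idempotent on its own output.

## Training, metrics, interpretation

Hyperparameters are chosen from a small grid — trees {200, 500}, depth
{3, 5, 7}, learning rate {0.05, 0.1}, dropout {0.0, 0.1} — by 10-fold
cross-validated RMSE, ties broken toward fewer trees then shallower
depth, followed by a refit on all training rows. The ensemble backend is
LightGBM (`boosting_type="dart"`, plain gradient boosting when the
dropout rate is 0), single-threaded and seeded, so training and
prediction are bit-reproducible; all arithmetic is double precision.
Rows with weight exactly 0 are removed before fitting, because
histogram binning and minimum-leaf counts are count-based and a
zero-weight row could otherwise still leave a fingerprint on the model.
The backend sits behind a four-method interface (fit / predict /
contributions / gain importances), so it is swappable for any boosted
ensemble with DART-style dropout.

R² is reported as the squared Pearson correlation of predicted vs
observed values. Q² is the external predictive squared correlation,
`1 − Σ(ŷ−y)² / Σ(y−ȳ_train)²`, with the *training* mean as reference, so
a model no better than that mean scores 0 on held-out data. Variable
importance is total gain rescaled so the top feature reads 100%. SHAP
values come from the ensemble's exact tree algorithm (deterministic; the
per-row decomposition reproduces the prediction to double-precision
rounding), and a binary feature's directionality is summarized as
mean(SHAP | bit = 1) − mean(SHAP | bit = 0): negative means the
substructure lowers predicted LC50, i.e. raises toxicity.
Applicability is assessed by cosine similarity of fingerprint vectors:
for each query, the number of training chemicals with similarity
strictly above 0.5, plus a 10-bin equal-width histogram of the full
training-vs-query similarity matrix. Similarity of a zero vector is
undefined and reported as NaN, never 0.

## Synthetic study conditions

The generator draws `n = 600` chemicals with masses log-uniform on
[26, 800] Da (log-uniform so the flat region above the breakpoint is
populated). Noiseless toxicity is a piecewise-linear mass effect —
falling 3 log-mM from 26 to 400 Da, flat above — plus sparse additive
bit effects, by default (−0.4, prevalence 0.30), (−0.6, 0.25),
(+0.5, 0.20) log-mM; remaining bits get random prevalences in
[0.02, 0.6], and a few trailing columns are exact duplicates or
constants so feature selection always has work to do. Each chemical
receives 1–5 replicate measurements (probabilities 0.35/0.25/0.20/
0.10/0.10, so the single-measurement weighting rule is exercised) with
N(0, 0.4²) noise per replicate, written as mM concentration records and
pushed through the *real* curation code. Spectrum-style corruption
flips each bit across the 0.5 boundary with probability 0.016 (i.e.
98.4% of bits correct) and draws probabilities Uniform(0.7, 1.0) or
Uniform(0.0, 0.3) on the resulting side, keeping binarization
unambiguous. A `mass_only_config` variant with a *linear* mass effect
and no planted bits serves as the negative control for the baseline
comparison: under it the mass-only linear baseline is correctly
specified, so any fingerprint "benefit" found there would be spurious.

What the generator deliberately does not emulate: chemistry-consistent
correlations between fingerprint bits (real substructures co-occur),
database bias toward toxic chemicals, heteroscedastic measurement error,
or realistic mass spectra. Passing recovery tests therefore demonstrates
that the pipeline's statistics and plumbing are correct at realistic
noise levels — not that the packaged default registry or any particular
trained model generalizes to real water samples.

## Numerical and design notes

* Binarization at exactly 0.5 maps to 1; the operation is idempotent.
* Candidate ordering is total: rank, then score descending, then
  formula lexicographically, so equal-score candidates are deterministic.
* Predictions are never clamped; values outside the training target
  range raise a warning instead.
* Problem sizes in tests and the acceptance script (600 chemicals, 96
  bits, 24-point grid, 1000 bootstrap replicates) are chosen as the
  smallest at which the planted effects are comfortably detectable.
* The bootstrap model comparison resamples test rows with predictions
  held fixed (paired), 1000 replicates, percentile 95% interval.
* Registry bits absent from a fingerprint predictor's output are filled
  with probability 0.0 and surfaced as reduced coverage rather than an
  error, so spectrum-path predictions degrade visibly instead of failing.

## Known limitations

* The tree ensemble approximates smooth trends with steps; against an
  exactly linear signal it is slightly but measurably worse than OLS,
  which is visible in the negative control's paired comparison.
* SHAP group-difference estimates of planted bit effects are mildly
  shrunk toward zero (boosting regularization), typically recovering
  60–85% of the planted magnitude at n = 600.
* The `.ms` writer and project parser target the external tool's 4.x
  layout; unknown layouts fail loudly rather than risk misaligned
  probabilities.
* Only fish LC50-style single-endpoint regression is modelled; no
  hazard classification, mixture effects, or concentration estimation.
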