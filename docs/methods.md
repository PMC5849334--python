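# Methods

This note records the models, defaults and numerical choices behind
`nmrpeaks`, and what the simulated studies do and do not demonstrate.

## Coordinate conventions

Spectra are stored index-ascending / ppm-descending (the ¹H plotting
convention); ascending input axes are flipped on read and the flip is
recorded.  Measurement indices are 0-based positions on the stored axis.
All window arithmetic ("512 measurement points", "within 10 points") is
done in index space, since acquisition settings determine how many points a
ppm spans; ppm spacing may be non-uniform.  Output tables always carry both
the index and the ppm value, so either convention can be recovered.

## Wavelet peak detection

The mother wavelet is the Mexican hat (negative normalized second
derivative of a Gaussian).  At scale *a* the discrete kernel spans ±8a
points, is re-centred to exact zero mean (so constant offsets contribute
exactly nothing despite truncation) and normalized to unit L2 norm.  Unit
L2 normalization makes white-noise coefficient variance identical across
scales, so coefficients — and therefore SNRs and reported peak values — are
comparable between scales.  A consequence worth knowing: the response to a
Gaussian line of width σ is maximal at scale √5·σ, not at σ, so the
reported scale is a width *proxy*, monotone in the true width.

Convolution uses edge-repeating reflective padding.  Defaults:

| parameter | default | meaning |
|---|---|---|
| scales | 1–16, 18, 20, 24, 28, 32 | covers line widths (in points) typical of 1D ¹H spectra at common digitization |
| baseline_threshold | 1000 (intensity) | raw apex floor; intended for untransformed spectra — lower it when spectra are scaled to max 100 or 1 |
| snr_threshold | 3 | ridge-maximum coefficient over local noise |
| ridge_gap_max | 3 scales | a ridge may skip this many scales |
| ridge_length_min | ⌈n_scales/4⌉ | minimum scales a ridge must span |

Ridges are built top-down from the largest scale: per-scale local maxima
(strictly positive, minimum separation one scale) are linked to the nearest
active ridge within a window of 2·scale columns, nearest pairs first; an
unmatched ridge survives up to `ridge_gap_max` scales; unmatched maxima
start new ridges only where they could still reach `ridge_length_min`.
Each ridge reports its maximum (scale, column, coefficient).  Two ridge
maxima on the same index keep the larger coefficient.

**Noise estimate.**  The local noise level is the 95 % quantile of
|scale-1 coefficients| under a Gaussian noise model, evaluated in a window
of min(P, 500) points centred on the peak.  The default estimator reaches
that quantile robustly via the median absolute coefficient
(σ̂ = median|c|/0.6745, noise = 1.96·σ̂): a direct 95th percentile
(available as `noise_method="percentile95"`) is inflated whenever tall
peaks sit inside the window, which silently suppresses small resonances
adjacent to 10× larger neighbours — a routine situation in crowded NMR
multiplet regions.  On pure noise the two estimators agree, so the
false-positive behaviour (no detections on white noise at SNR ≥ 3) is
unchanged.

## Grouping

Peaks from all samples are pooled, sorted by index, and split into segments
at gaps wider than `max_group_span` (default 10 points, deliberately the
same locality notion as peak filling).  Within a segment, average-linkage
hierarchical clustering runs on the Gower distance over the chosen
variables (default ppm only; SNR and peak value are opt-in, and are what
makes silhouette-triggered regrouping able to disentangle resonances whose
between-sample shift exceeds their separation).  The Gower distance
range-normalizes each variable to [0, 1] and averages absolute differences;
constant variables contribute 0 but still count in the mean.

The dendrogram is cut top-down.  A cluster is accepted when its index span
is within `max_group_span` and its same-sample duplicates are few (at most
10 % of the samples present); otherwise its children are visited.  Accepted
clusters with residual duplicates are repaired by deletion: the peak
nearest the group median index is kept, ties broken by larger peak value,
then lower index.  Deleted peaks are retained and can be re-adopted by a
different group during peak filling.  The duplicate *tolerance* (rather
than descending on any duplicate) is intentional: one double detection in
one sample should cost one deleted peak, not fragment a 20-member group;
conversely a cluster where most samples appear twice is two resonances and
is descended into.  Groups smaller than `min_samples` (default 1, i.e. keep
singletons) are dropped but reported.

## Silhouette quality control and regrouping

Per peak, a(i) is the mean |Δppm| to its own group (0 for singletons), b(i)
the smallest mean |Δppm| to another group, s(i) = (b−a)/max(a,b).  Groups
with mean silhouette below 0.6 (configurable; the value is this package's
choice) are pooled with the groups their members' b(i) point to (transitive
closure) and the grouper is re-run on the pooled peaks, deleted peaks
included.  Re-grouping with intensity-aware Gower variables and, if needed,
a wider span is how badly shifted regions get repaired.

## Peak filling

For each (feature, missing sample): a window of 512 points (1024 when the
group mean scale exceeds 32, so wide peaks stay inside) centred on the group
centre is searched with scales restricted to [⌈mean_scale/2⌉, 2·mean_scale]
and *no* SNR or intensity threshold — only the distance rule filters.  The
candidate nearest the centre is accepted iff it lies within `max_dist`
(default 10) points.  Fills are computed against the pre-fill group centres
and applied afterwards, so results are independent of feature order.
Filled peaks are flagged; group centres are recomputed afterwards as member
medians.

## Feature matrix, imputation, normalization, scaling

Cell (i, j) holds sample i's peak value in feature j; absent peaks are NaN
behind an explicit mask, never silent zeros.  Every transformation appends
to a provenance list; replaying the provenance on the raw matrix reproduces
the transformed matrix bit-for-bit.

- **Imputation**: zeros only (an absent peak is a zero quantity).  kNN or
  forest imputation are out of scope.  Scaling statistics use observed
  cells only, so impute-then-scale and scale-then-impute differ — the
  latter amounts to mean imputation for centred scalings; choose
  deliberately.
- **PQN**: reference = feature-wise median row; each row is divided by the
  median of its quotients to the reference (features with positive
  reference).  The quotient step is iterated to its fixed point (all median
  quotients 1, tolerance 1e-14; pure dilution converges on the first pass)
  and the global scale is anchored to preserve the mean row total.  This
  per-row normalization replaces an initial row-sum normalization, which
  would make repeated application non-idempotent; as implemented, PQN∘PQN =
  PQN to machine precision.  Recovered per-sample dilution factors are
  recorded in the provenance entry.
- **Scaling**: `center`, `unit` (centre, divide by σ_j), `pareto_sqrt`
  (divide by √σ_j — the conventional Pareto form, the default) and
  `pareto_printed` (divide by σ_j without centring), with σ_j the n−1
  sample standard deviation.  Both Pareto variants are exposed because the
  two definitions circulate in the literature; benchmarks here use centred
  `pareto_sqrt`.  Zero-variance columns are left unscaled with a warning.

## Differential analysis

Per feature, OLS of y_j on the response x **with an intercept**, t = β/se
on N−2 df, two-tailed.  The intercept matters: without it the claimed
equivalence to the pooled two-sample t-test for binary x fails, and that
equivalence (verified to 1e-10 in the tests) pins down the intended model.
Multi-level categorical responses must be coded numerically by the user
(e.g. a dose percentage); two-level responses are coded 0/1.  BH (default)
and Bonferroni corrections are implemented directly as the step-up and
min(1, K·p) rules — written so that p_adj ≥ p holds exactly in floating
point — and cross-checked against statsmodels in the tests.  Reported
significance uses adjusted p < 0.05.

## Identification support

Pearson correlation over the chosen feature columns; complete linkage on
1 − r, cut into the user's k clusters, so the reported per-cluster minimum
pairwise r maps directly onto merge heights (a cluster with min r > 0.75 is
a strong single-metabolite candidate).  Zero-variance features are excluded
with a warning; singleton clusters report r = 1 by convention.  Labels are
canonicalized by ascending minimum ppm, so they do not depend on input
order.  The HMDB 1D ¹H search URL is built deterministically (sorted ppm,
4 decimals, tolerance ±0.02 by default); querying, and HMDB's server-side
Jaccard ranking, are out of scope.

## The simulator

`simulate_spectra` renders n = 20 spectra (default) on a 0–10 ppm axis of
4096 points as a two-template Lorentzian mixture: spectrum_i =
A·[(1−m_i)·template_A + m_i·template_B] + N(0, noise_sd²), with m_i drawn
from a two-mode truncated-normal mixture (modes 0.25/0.75, sd 0.08, equal
weights — a clear case/control separation) and per-sample shift
(sd 0.005 ppm) plus per-line jitter (sd 0.001 ppm).  The default templates
are two phenolic-acid-like metabolites — an aliphatic CH₂ singlet each plus
an aromatic multiplet region — that deliberately share two coincident
equal-area lines (4.70 and 6.78 ppm), so those positions carry no group
information while every template-specific line does.  Amplitude 2·10⁴ and
noise sd 2000 put apexes (≈3·10⁴–2·10⁶) far above the default detection
floor of 1000, i.e. untransformed-spectrum conditions.  All randomness
flows through one seeded generator in a fixed draw order, so the
`aligned()` variant (shift and jitter off) reuses the same mixing factors
and noise — an oracle for perfect raw-spectrum alignment.

What the simulator does **not** emulate: multiplet fine structure and
J-coupling, peak-shape distortions (phasing, shimming), t₁ noise and water
suppression artifacts, baseline roll, correlated (pink) noise, and
pH-dependent *non-uniform* shifts (every line of a sample shares one global
shift).  Passing tests on simulated data therefore demonstrate the
machinery under controlled, favourable conditions; they do not certify
performance on crowded real spectra.

## Benchmark

The binning baseline sums intensities in uniform 0.018 ppm bins (the
classic bucketing width at this axis span).  Three arms are compared over
20 simulation replicates: the full peak workflow (detect → group →
silhouette-regroup → fill → zero-impute → centred Pareto → linear model),
raw-spectrum binning, and binning of the oracle-aligned spectra (standing
in for alignment-then-binning, an upper bound since real aligners distort).
Features/bins are scored positive when within half a bin width of a planted
discriminating line; sweeping the p-value threshold yields ROC and PR
curves with trapezoidal areas.  Problem sizes (20 spectra × 4096 points ×
20 replicates) are the package's desk-scale defaults, chosen so the whole
comparison runs in well under a minute on one CPU.

## Known limitations

- Ridge detection cannot see a small peak closer than ~2 scales to a much
  larger one at every usable scale; such shoulders are only recoverable via
  peak filling once the feature exists in other samples.
- The grouping cut is greedy top-down; pathological interleavings can in
  principle require the silhouette-repair pass with intensity-aware
  variables.
- PQN assumes most features are unchanged between samples; it is not
  appropriate when a majority of peaks respond to the condition.
- FID-domain processing (Fourier transform, phasing, apodization), raw
  spectral alignment and vendor formats are out of scope; input is a
  ppm-vs-intensity matrix.
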