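# Methods

This note documents the models and procedures implemented in `hrvrisk`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic cohort generator does and does not emulate.

## HRV parameters from short recordings

Input is an RR-interval series (seconds) of roughly 5 minutes; ECG
acquisition and R-peak detection are out of scope. An artifact filter
stands in for manual exclusion of noisy segments: intervals outside
[0.3 s, 2.0 s] are removed, as is any interval differing from the previous
retained one by more than 20% (`filter_rr`; all three thresholds
configurable). A recording left with fewer than two intervals is rejected
as unusable.

**Time domain.** aRR and STD are the mean and (population) SD of the
intervals; instantaneous heart rate is 60/RR, giving avHR and sdHR; RMSSD
is the root mean square of successive differences; NN50 counts successive
pairs differing by more than 50 ms and pNN50 expresses it per the n−1
successive pairs. Note avHR ≥ 60/aRR always (Jensen's inequality; equality
for a constant series) — the two carry correlated but not identical
information.

**Geometric domain.** The RR histogram uses fixed-width bins of 1/128 s
(the conventional short-recording discretization), edges aligned to
multiples of the bin width. The triangular index is N divided by the modal
bin count. TINN fits a triangle to the histogram by least squares: apex
fixed at the mode (bin-center, modal count), base endpoints (N′, M)
searched exhaustively over a grid of bin-edge positions extended 8 bins
beyond the histogram support, error summed over all bins (the triangle is
zero outside [N′, M]); TINN = M − N′. A single-occupied-bin histogram has
TINN = 0 by convention.

**Frequency domain.** The tachogram RR(t) at the beat times is unevenly
sampled. The default estimator is the Lomb-Scargle periodogram evaluated
on a 4× oversampled frequency grid, scaled to a one-sided density by
2T/n (a sinusoid of amplitude a then integrates to its variance a²/2 over
its peak; verified in tests). The alternative route resamples the
tachogram at 4 Hz with a cubic spline and applies Welch's method. Band
powers integrate the density over VLF 0.003–0.04 Hz (the short-recording
lower bound), LF 0.04–0.15 Hz, HF 0.15–0.40 Hz; total power is their sum,
so LF_norm = 100·LF/(total − VLF) and HF_norm sum to 100 by construction.
Powers are reported in s² (intervals are in seconds); normalized units and
the LF/HF ratio are scale-free. When total − VLF ≤ 0 or HF = 0 (e.g. a
constant series) the normalized quantities are reported as missing (NaN),
never as 0.

## Ensemble variable selection under class imbalance

With ~4% positives, a single forest fitted to the full cohort is dominated
by negatives. The selector therefore builds `n_subsets` (default 500)
balanced subsets — all positives plus an equal-size draw of negatives
without replacement (independent across subsets) — fits a random forest
(default 500 trees, √p features per split, unlimited depth, Gini
importance; permutation importance selectable) to each, and records its
top-k (default 8) variables. Variables are ranked by occurrence: the
number of subsets in whose top-k they appear. Occurrences are conserved
(Σ = k·n_subsets) and bounded by n_subsets. Ties in the occurrence ranking
break by better mean within-subset rank, then by fixed column order.

The top-k variables by occurrence are then refined: each is tested with a
two-sided Mann-Whitney test between outcome groups on the *full* cohort,
and candidates with p ≥ α (default 0.05) are excluded with an audit entry.
The Mann-Whitney p-value is exact (full enumeration) for tie-free combined
samples of n ≤ 20, otherwise the normal approximation with tie correction;
identical constant samples give p = 1.

Within one cohort, occurrence counts are positively correlated across
subsets through the shared positives, so "uniformity under the null" is a
statement about independent cohorts, not about a χ² test within one run —
the test suite checks it accordingly.

## Distance-based risk score

Selected variables are min-max normalized to [−1, 1] using training bounds;
test values are clipped into the interval so the distance geometry stays
bounded (out-of-range test values are otherwise undefined behavior).
Constant training variables are dropped with a warning. Class centroids
(one cluster per class) are the arithmetic means in the normalized space.
The initial score of a sample z is

    S0(z) = 100 · d−(z) / (d+(z) + d−(z)),

Euclidean distances to the positive/negative centroids; 100 at the positive
centroid, 0 at the negative one, 50 when equidistant (including the
degenerate coincident-centroid case). S0 is invariant to any affine
transform of the raw features (normalization absorbs it) and strictly
increasing along the segment from c₋ to c₊.

The refinement fits a soft-margin SVM (default RBF kernel, C = 1,
γ = 1/p, class weights inversely proportional to class frequency since the
full imbalanced training fold is used) on the normalized training data and
maps its decision values to probabilities with a Platt-style logistic
regression fitted on the training decision values; S1 = 100 × calibrated
probability. The emitted score is the blend S = (1−λ)·S0 + λ·S1 clipped to
[0, 100]. λ parameterizes a genuine ambiguity — whether the refinement
replaces, blends with, or re-ranks the geometric score — and defaults to
0.5; λ = 0 and λ = 1 reduce exactly to the component scores.

## Clinical comparators

TIMI (UA/NSTEMI variant) sums 7 binary items, one point each. MEWS sums
banded points over SBP, heart rate, respiratory rate, temperature and
consciousness; the default band table (SBP ≤70:3, 71–80:2, 81–100:1,
101–199:0, ≥200:2; HR <40:2, 40–50:1, 51–100:0, 101–110:1, 111–129:2,
≥130:3; RR <9:2, 9–14:0, 15–20:1, 21–29:2, ≥30:3; T <35:2, 35–38.4:0,
≥38.5:2; AVPU alert:0 / voice:1 / pain:2 / unresponsive:3) ships as data,
not code, and cohorts recording GCS are mapped to AVPU as 15→alert,
13–14→voice, 9–12→pain, ≤8→unresponsive. The logistic baseline adds
candidates forward by likelihood-ratio entry test (default entry p < 0.05,
no removal step); separation or an unstable ML fit falls back to an
L2-penalized refit with a warning.

## Evaluation

LOOCV refits the entire scoring pipeline (normalization bounds, centroids,
SVM, calibration) on n−1 patients for each held-out patient; the held-out
row never influences its own training fold (a deliberate-leakage comparison
in the tests guards the harness). AUC is the Mann-Whitney concordance
probability (ties count ½); its CI is DeLong by default (the CI method in
the source study is unnamed), with a class-stratified bootstrap percentile
interval (2000 replicates) selectable. The operating point minimizes the
Euclidean distance to the ROC upper-left corner over midpoint thresholds
(±∞ sentinels included), ties breaking toward higher sensitivity;
sensitivity/specificity intervals are Wald (p ± z·√(p(1−p)/n)), which is
the arithmetic that reproduces the reported intervals. Pairwise score
comparison uses a paired, class-stratified bootstrap of the AUC
difference with a two-sided normal-approximation p-value (percentile
variants were considered; the normal approximation matches the cited ROC
comparison methodology).

## Synthetic cohort generator

The generator emulates the reference study's *summary structure*, not its
patients: by default 702 patients with exactly 29 positives (prevalence is
conditioned on, matching the fixed cohort composition, not binomial), and
each of the 23 candidate predictors drawn from a group-conditional
truncated normal whose (mean, SD) are the published group summaries, within
physiological bounds (SBP [60, 260] mmHg, DBP [30, 160], heart rate
[30, 200] /min, respiratory rate [6, 50] /min, temperature [34, 41] °C,
SpO₂ [70, 100] %, and positive bounds for the HRV quantities). Locations
are recalibrated so the *truncated* mean equals the target — naive
truncation would bias skew-bounded variables (LF, NN50) by more than the
large-n sampling error the tests allow. GCS and pain score are discrete
draws whose medians match the published medians. Demographic, history and
outcome-subtype flags are assigned as exact scaled counts so composition
arithmetic is deterministic. TIMI item rates are not published; defaults
were fixed once so the median TIMI is 2–3 and the induced TIMI AUC on
default cohorts is ≈ 0.64, the only calibration the published TIMI
performance offers.

Structural couplings are enforced rather than sampled: avHR =
(60/aRR)·c_g·(1+ε) with a per-group constant c_g targeting the published
avHR mean (absorbing the Jensen gap) and 2% multiplicative jitter;
HF_norm = 100 − LF_norm; and, by default (`couple_spectral=True`),
LF = HF·LF_norm/HF_norm so that LF/HF = LF_norm/HF_norm holds exactly.
Variables outside `signal_variables` (default: the twelve with published
group-wise p < 0.05) share the negative-group distribution; derived
variables inherit signal status from their parents. The published LF/HF
group means cannot be matched simultaneously with the LF and HF means
under the ratio identity (mean-of-ratio ≠ ratio-of-means), so a decoupled
mode (`couple_spectral=False`) draws LF and LF/HF from their own published
summaries instead — useful when an experiment requires a precise set of
variables, and no others, to differ between groups.

Variables are drawn independently apart from these couplings (the source
tables print no correlations); a Gaussian-copula correlation hook exists
for sensitivity analyses. The `rr_series` mode synthesizes a 5-min
tachogram per patient — RR(t) = μ + a_LF·sin(2π·0.10·t) +
a_HF·sin(2π·0.25·t) + white noise, truncated positive, amplitudes split by
the patient's target STD and LF_norm with 20% of the variance assigned to
noise — and recomputes the HRV columns from those series through the full
feature extractor.

**What passing tests do and do not show.** The generator reproduces
marginal group-conditional structure, exact composition, and the coupling
identities; it does not reproduce inter-variable correlation among
clinical signs, missing data, non-normal tails, or the multi-system
co-derangement of truly sick patients. Results on synthetic cohorts
therefore validate the *machinery* (selection behavior, score geometry,
cross-validation hygiene, comparison statistics) and directional
orderings, not the absolute discriminative performance reported on any
real cohort. In particular, with only 29 positives each variable's
empirical effect size carries a standard error of roughly 0.19 SD, so
which borderline variables survive the top-8 occurrence filter and the
p < 0.05 refinement varies materially across cohort realizations: the
three leading predictors are all recovered in roughly three quarters of
seeds under the default effect sizes, and experiments should average over
seeds rather than rely on a single cohort draw.

## Problem sizes used in the shipped experiments

Unit and property tests run on reduced ensembles (tens of subsets, tens of
trees) and small cohorts. The end-to-end experiments use the reference
composition (702/29) with the ensemble reduced to 100 subsets × 100 trees
for selection recovery and 500 subsets × 50 trees for occurrence
bookkeeping; leave-one-out evaluation runs at the full n = 702. These sizes
were chosen as the package's standard desk-scale configuration; all are
parameters, and the full 500 × 500 ensemble is a single
`SelectionParams` change.

## Known limitations

* Independence between drawn variables limits generator realism (flagged
  above); the copula hook is provided but unparameterized.
* TINN's least-squares search is exhaustive over bin edges; histograms
  with thousands of bins would be slow (irrelevant at 5-min scale).
* The Lomb-Scargle density scaling (2T/n) is a first-order convention;
  absolute band powers depend on it, normalized indices do not.
* TIMI item flags are generated, not derived from the simulated vitals;
  item-level concordance (e.g. age ≥ 65 vs the drawn age) is not enforced.
* The forward-logistic fallback under separation changes the estimator
  (penalized) rather than reporting profile-likelihood intervals.
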