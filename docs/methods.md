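# Methods

This note documents the statistical procedures flyburst implements, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical decisions that a
maintainer or reviewer would otherwise have to reverse-engineer from the
code.

## Burst segmentation

A spike train is an ordered sequence of spike times on `[0, duration_s]`
(default recording length 180 s, the standard protocol for larval
motor-neuron loose-patch recordings). Burst detection uses the single-ISI
chain rule: spikes belong to the same burst while each successive
inter-spike interval is at most `max_isi_s` (default 0.100 s), and a run
qualifies as a burst when it contains at least `min_spikes` spikes
(default 3). This is the classic max-interval criterion with equal start
and continuation thresholds. Three conventions are fixed deliberately:

* **Chain rule, not pairwise.** "Within 100 ms of one another" is read as a
  condition on consecutive ISIs, which matches the termination rule ("the
  burst ends when no spike follows within 100 ms") and standard practice.
* **Inclusive boundary.** An ISI of exactly `max_isi_s` continues the
  burst. The choice is arbitrary at measurement precision (spike times
  are sampled at 20 kHz in the emulated protocol, so exact ties are
  measure-zero); it is fixed identically in both implementations.
* **First-to-last duration.** Burst duration is `t_last − t_first`, with no
  padding by the ISI threshold.

Two independent implementations are shipped: a linear scan
(`detect_bursts`) and a vectorised run-labelling oracle
(`detect_bursts_oracle`, grouping by the cumulative count of
above-threshold gaps). They are required to agree exactly — including at
the boundary — on randomised inputs; this equivalence is part of the test
suite and of the acceptance script.

Runs of two short-ISI spikes are not bursts; their spikes count only toward
the overall firing rate.

## Per-trace and per-genotype statistics

For each trace: mean and sample SD (ddof = 1) of burst durations, burst
frequency (`n_bursts / duration_s`), firing rate
(`n_spikes / duration_s`), mean spikes per burst, and AP frequency per
burst. The last is the **mean of per-burst ratios**
`mean_b(n_spikes_b / duration_b)`, not the ratio of totals: the two differ
under duration/rate covariance, and the mean-of-ratios is the conventional
per-burst statistic for reporting alongside per-burst counts. Zero-duration
bursts (possible only for degenerate inputs, since real bursts have ≥ 3
distinct spike times) are excluded from this mean and logged.

Rates always use the declared recording duration, not the last spike time,
so silent stretches at the end of a recording lower the rate as they
should. Traces with no bursts carry NaN ("flagged") burst statistics but
keep their firing rate; genotype aggregates are unweighted means over
traces, excluding flagged traces from burst-statistic columns only and
reporting both counts. The burst-duration SD column is the within-trace SD
averaged across traces (the alternative — the across-trace SD of means — is
a different quantity; the within-trace reading is used consistently and
exposed per trace so either can be recomputed).

Internally everything is seconds and Hz; report tables convert durations to
ms by an exact ×1000.

## Reference-band classification

The reference band is built from the **per-trace mean burst durations** of
the wild-type reference genotype: band = `mean ± k·SD` with sample SD and
default `k = 1.5`. Using per-trace means (rather than pooled individual
bursts) matches the unit of classification — a trace — and makes the band
statistic approximately normal by averaging (a trace contributes ~80 bursts
at wild-type rates), which underwrites the Φ(−1.5) ≈ 6.7% expected
elongated fraction among reference-like traces. Bounds are inclusive
(at-bound = normal); above-band traces are *elongated* (the phenotype of
interest), below-band *short* (reported, never folded into elongated
fractions), zero-burst traces *unclassifiable* and excluded from the
fraction's denominator. The reference genotype is a configuration key, so
mutant lines with matched genetic controls can be classified against either
the true wild type or their own control.

Classification is scale-equivariant and the elongated fraction is
non-increasing in `k`; both are property-tested.

## Bootstrap estimation statistics

Two-group comparisons are summarised by the unpaired mean difference
`mean(b) − mean(a)`, a 95% bootstrap CI, Cohen's *d* (pooled-SD form with
sample variances), and percent change relative to the control mean. No
hypothesis tests or multiple-comparison corrections are computed, by
design: the reporting philosophy is estimation-based.

The bootstrap resamples each group with replacement at its own size,
`n_boot = 5000` by default (minimum 1000 enforced). The default interval
is BCa: bias correction `z₀ = Φ⁻¹(#{θ* < θ̂}/B)` and acceleration from the
jackknife over all `n_a + n_b` observations,
`a = Σ(θ̄₋ − θ₋ᵢ)³ / (6[Σ(θ̄₋ − θ₋ᵢ)²]^{3/2})`. When the bias correction is
undefined (all bootstrap replicates on one side of the estimate) or the
jackknife spread is zero, the interval downgrades to the percentile method
with a logged notice; a fully degenerate bootstrap distribution (both
groups constant) yields the point interval. BCa can in pathological cases
fail to bracket the point estimate; this is flagged in the log rather than
silently corrected. The implementation is vectorised NumPy and is
cross-checked in the test suite against `scipy.stats.bootstrap(method="BCa")`
as an independent reference; simulation tests verify 92–98% empirical
coverage of the true mean difference for normal samples at n = 20 per group.

Reproducibility: one root seed; each comparison uses a child stream derived
from `SeedSequence([root, crc32(group and assay labels)])`, so results are
bit-stable and insensitive to the set or order of other comparisons.

Cross-assay agreement is an OLS line through per-genotype
(x = effect size in one assay, y = effect size in another) points, fitted
with `scipy.stats.linregress`; R² is the squared Pearson correlation, with
an optional CI bootstrapped by resampling genotypes. With only a handful of
genotypes this CI is wide and should be read qualitatively. The
heat-assay cumulative-incidence curve counts, at each checkpoint, the
fraction of the whole cohort whose onset is ≤ the checkpoint; censored
animals (no onset within the exposure window, default 120 s) stay in the
denominator permanently.

## Synthetic-data generator

`simulate_spike_train` draws an alternating renewal process: inter-burst
gap → burst duration → spikes filled at the within-burst ISI distribution
(≥ 3 spikes enforced by redrawing the burst), repeated to the end of the
recording; partial bursts at the boundary are discarded. Isolated noise
spikes are superposed as a thinned Poisson process. Distribution specs are
(family, mean, CV) with lognormal/gamma/exponential families.

Three guards make the returned ground-truth burst list exact against the
default detector, by construction rather than by probability:

* within-burst ISIs are redrawn above `isi_cap_s = 0.095 s` (< 0.100 s), so
  a generated burst cannot be split;
* inter-burst gaps are redrawn at or below `min_gap_s = 0.300 s`
  (> 0.100 s), so adjacent bursts cannot merge;
* candidate noise spikes within 1.05 × the ISI threshold of any existing
  spike are rejected, so noise cannot extend a burst, bridge two bursts, or
  (with another noise spike) seed a spurious one.

The cost is mild truncation of the stated distributions (negligible at the
default scales: the ISI cap sits ~7 SD above the mean ISI) and slightly
non-Poisson noise; both are accepted to keep ground-truth labels exact.

Preset conditions: the wild-type-like preset draws burst durations
lognormal(mean 175 ms, CV 0.30), within-burst ISIs lognormal(mean 13.5 ms,
CV 0.40) (≈ 14 spikes/burst) and gamma gaps (mean 1.955 s, CV 0.35), i.e.
≈ 0.47 bursts/s and ≈ 6.5 APs/s over 180 s — the regular, robust bursting
regime of wild-type larval motor neurons. The elongated preset lengthens
bursts to mean 600 ms with CV 0.50 and ISIs of mean 27 ms (≈ 23
spikes/burst), i.e. several reference SDs above the wild-type band —
mirroring the magnitude of the elongated-bursting phenotype in seizure
mutants, where mean burst durations several-fold above wild type are
typical. Noise spikes default to 0.01 Hz (a couple per recording).

The behavioral generator draws per-genotype lognormal samples; the fixture
suite uses electroshock control mean 97 s with mutants at ≈ 1.5–3.4× 
control, vortex seizures of tens-to-hundreds of seconds, and heat-assay
onsets censored at the 120-s exposure — the magnitudes typical of these
assays. Values and onset times are independent marginals; real data would
correlate onset with severity, so the fixture exercises the plumbing and
the censoring logic, not onset–severity dependence.

**What passing tests show — and don't.** Parameter-recovery and
classification-calibration tests demonstrate that the pipeline is unbiased
and correctly calibrated *under the generator's assumptions* (renewal
structure, lognormal/gamma families, homogeneous traces within genotype).
They cannot certify behaviour under features the generator omits: bursts
with internal pauses near the threshold, rate drift within a recording,
between-animal heterogeneity within genotype, or recording artifacts.

## Problem sizes and numerical choices

The packaged fixture suite is 13 wild-type-like and 12 elongated traces of
180 s (matching typical per-genotype trace counts for this kind of
recording series) plus 20–25 animals per behavioral group; calibration
checks use 200 reference traces and 500 bootstrap-coverage replicates at
`n_boot = 2000`. All delimited outputs are TSV with 12-significant-digit
floats, which round-trips doubles through text and makes pipeline outputs
byte-reproducible under a fixed root seed; the committed golden tables pin
this. The run log is the only timestamped (hence non-reproducible) output
and is excluded from byte-identity checks.

Degenerate inputs are handled explicitly rather than by exception where a
flagged value is meaningful: zero-burst traces (NaN statistics, label
`unclassifiable`), zero classifiable traces (NaN fraction), single-burst
traces (NaN SD), zero-variance bootstrap (point interval). Hard errors are
reserved for contract violations: fewer than two reference traces, all-equal
regression x, non-finite samples, unknown assay labels, spikes beyond the
declared duration.

## Known limitations

* The ISI-threshold detector is the implemented criterion; Poisson-surprise
  or two-threshold variants are out of scope.
* BCa intervals with n ≈ 5 per group are unstable; the percentile fallback
  triggers more often there, and is logged.
* Exact ISI ties at the threshold are resolved inclusively; time-shifting a
  train by a float offset can flip such ties by one ulp (a floating-point
  artifact, not a property of the rule).
* The generator's renewal process has no serial correlation between burst
  durations and following gaps, which real central-pattern-generator output
  may show.
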