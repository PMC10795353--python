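# Methods

## The paradigm and the decoding problem

`audibci` implements a binary auditory brain–computer interface for users
who cannot rely on gaze: two interleaved streams of spoken words — "yes"
in the right ear, "no" in the left — are presented in a duration-deviant
oddball design. Each *block* (one question) presents, per stream, 30
short standards (100 ms) and 6 long deviants (150 ms) in pseudo-random
order with at least two standards between consecutive deviants. The
listener attends one stream and counts its deviants; the decoder infers
the attended side from the EEG and that inference is the yes/no answer.

**SOA convention.** Throughout the package, *SOA* denotes the global
onset-to-onset interval between consecutive sounds regardless of stream
(250 ms by default). The two streams strictly alternate, so the
within-stream interval is 2×SOA, and the "yes" stream leads the "no"
stream by one SOA. This reading is forced by the block arithmetic: 72
stimuli at 250 ms yield exactly the 18 s block of the healthy protocol,
and 500 ms yields the 36 s block of the slowest patient protocol.

**Deviant placement.** Admissible orderings (gaps of ≥ 2 standards
between deviants) are sampled *exactly uniformly* using the standard
min-gap combinatorial bijection: positions `p_1 < … < p_k` with
`p_{i+1} − p_i ≥ 3` in `n` slots map one-to-one onto unconstrained
k-subsets of `n − 2(k−1)` slots. This replaces rejection sampling — it
is deterministic given the seed, exact, and needs no retry cap. A flag
optionally forbids deviants in the first/last slot of a stream (the
protocol description does not constrain those positions; both behaviours
are available, edges allowed by default).

## Online decoding chain

1. **Band-pass** 0.5–20 Hz, 4th-order Butterworth. The online path uses
   the causal direct form (only causal delay, so block-by-block replay
   reproduces batch decisions exactly); ERP analyses use the
   forward–backward zero-phase variant.
2. **Decimation ×10** (anti-aliased FIR) of the continuous filtered
   signal. The band ends at 20 Hz, so 100 Hz sampling is lossless for
   decoding; it is also what makes the xDAWN least-squares design
   tractable (the feature decimation is applied once, up front, rather
   than after epoching — numerically the same features).
3. **Per-kind epochs**: 500 ms (standards) and 750 ms (deviants) for the
   healthy preset; 800/1000 ms for the patient preset, which allows for
   the delayed responses typical of that population. Windows are
   half-open `[0, t)`, no baseline correction (the SOA is shorter than
   the window; overlap is intrinsic and deliberate).
4. **xDAWN spatial filters**, one bank per stimulus kind, trained on the
   attended-vs-ignored contrast: the evoked responses of both classes are
   estimated jointly by least squares with a stimulus-onset Toeplitz
   design (unbiased under overlap), and the filters maximise
   ‖Δw‖²/‖Xw‖², where Δ is the estimated class-difference response and X
   the continuous recording. The solve whitens with a Cholesky factor of
   XᵀX and takes the SVD of the whitened Δ — the numerically stable
   route. Filters are mutually orthogonal under the data covariance and
   ranked by their generalized Rayleigh quotient; rank-deficient designs
   fall back to a regularized solve with a logged warning.

   Identifiability note: a *strictly* periodic alternating stimulus
   train with window = period makes the two class designs collinear; in
   this paradigm the deviant slots and block boundaries break the
   periodicity, which is exactly what makes the class difference
   estimable.
5. **Per-subject filter count** (1–5) chosen by block leave-one-out
   cross-validation of the calibration; ties go to the smallest count.
   The offline re-analysis preset fixes n = 2 instead. When the count is
   "auto" inside cross-validation, selection runs on nested inner folds
   so no information leaks from the held-out block.
6. **Four condition classifiers** (standard-yes, standard-no,
   deviant-yes, deviant-no). Per block and condition the epochs are
   averaged, spatially filtered, and flattened; the classifier is a
   binary Gaussian model with shared covariance, shrunk by the
   Ledoit–Wolf coefficient (block counts are far below the feature
   dimension). The likelihood family is a package choice — the standard
   one for ERP classifiers of this type.
7. **Bayesian fusion**: with equal priors and conditional independence
   across the four response types, P(yes | block) is the normalized
   product of the four posteriors, `Πp / (Πp + Π(1−p))`. Pinning any
   classifier at 0.5 removes it from the product, which is how the
   stimulus-pool analyses (Total/STD/DEV/YES/NO) are obtained. A fused
   posterior of exactly 0.5 is resolved as NO and flagged "undecided"
   (deterministic and auditable). A cross-validation fold whose training
   set cannot be fit (e.g. single-class) yields an undecided tie rather
   than an error.

## Synthetic sessions

The generator produces the statistical structure the decoder assumes,
with defaults chosen to emulate a *well-performing healthy user* (block
accuracies comfortably above 90% with a 14-block calibration — the upper
half of the healthy range, where most users sit):

| parameter | default | meaning |
| --- | --- | --- |
| fs | 1000 Hz | digitization rate |
| montage | 32-channel 10-20 | actiCap-style layout |
| P1 / N1 | +2 / −3 µV at 65 / 115 ms | exogenous auditory response, central |
| P3a / P3b | 3 / 5 µV at 250 / 380 ms | attended deviants only (gain configurable) |
| attention effect | 1.5 µV | sustained sinusoid at the per-stream rate (2 Hz at SOA 250 ms), fronto-central, attended standards only, subject-specific phase |
| noise | 6 µV rms, 1/f + 10 Hz alpha | spatially correlated (distance-decaying mixing) |
| artifacts | off (healthy) | blinks, saccades, narrowband interference available |

The sustained sinusoid is the package's operationalisation of the
"attentional phase shift" on standards: the phenomenon is described
qualitatively (sustained, phase variable across subjects, invisible in
the group average), so its shape and amplitude are package choices; the
subject-specific `phase_shift` reproduces the group-level cancellation.
The patient preset adds +150 ms latencies, higher noise, 0.8 Hz
ventilation-style interference and ocular artifacts; its
"non-controller" profile removes the attention-dependent signal
entirely. The zero-effect preset makes attended and ignored templates
identical, so any decoder must perform at chance — the negative control.

What passing tests on these simulations show: the pipeline recovers the
attended stream whenever attention modulates the evoked responses in the
assumed (linear, time-locked or phase-locked) way, at realistic SNR, and
degrades to exact chance when it does not. What they cannot show:
robustness to real-EEG nonstationarities, electrode artifacts beyond the
modelled classes, or biophysically realistic topographies (parametric
scalp blobs, not leadfields).

## Statistics

* **Chance level**: exact inverse binomial CDF at p = 0.5 (binoinv
  convention, `smallest k with CDF(k; n, ½) ≥ 1 − α`); no normal
  approximation. At n = 100, α = 0.01 the threshold is 62%. Accuracies
  strictly above the threshold count are called above chance.
* **TFCE cluster permutation test**: per-sample t statistic
  (independent or paired design), threshold-free cluster enhancement
  with E = 0.5, H = 2, dh = max|stat|/100 (dh frozen at the observed
  map's value across permutations for comparability), spatio-temporal
  connectivity from Delaunay channel neighbourhoods (edges pruned at
  1.5× the median length) × consecutive samples. Family-wise correction
  by the max-|TFCE| null over label permutations / sign flips; p-values
  are permutation ranks in [1/(n_perm+1), 1]. Negative deflections are
  enhanced on the negated map and reported with sign. Degenerate
  variances are floored. Defaults: α = 0.01 for sensor-space contrasts,
  α = 0.05 for ICA-component contrasts, 10,000 permutations (tests use
  reduced counts; seeds are mandatory everywhere).
* **ICA cleanup** (offline ERP path only): FastICA (tanh), with
  blink/saccade/common-offset components scored by combining a spatial
  prior (frontal-pole blob, lateral-frontal antisymmetry, uniformity)
  with a temporal signature (source kurtosis, derivative kurtosis,
  sub-1 Hz power fraction), so broadband neural components score low on
  clean data. Scores are heuristics with default thresholds of 0.5;
  they are suggestions, not silent removals.
* **Epoch rejection**: per subject, the `⌊0.15 n⌋` epochs with the
  highest max-over-channels peak-to-peak amplitude are dropped, pooled
  over conditions (a flag is not provided per condition; pooling is the
  interpretation adopted). Ties break by epoch index, earlier kept.

## Problem sizes used in the shipped tests

End-to-end checks run the full healthy conditions (1000 Hz, 32 channels,
14-block calibration, 50-block test, 5 seeds). Re-analysis analogues use
14-block sessions for the stimulus-pool comparison (10 seeds), 24-block
sessions for the block-duration truncation (3 seeds; halving the
evidence per block must be offset by more blocks for stable classifier
estimates, so truncation is evaluated on the larger session size), and 3 seeds for the 15-vs-32
channel comparison. Permutation-test validity uses 100 null runs at
1,000 permutations. Unit tests use reduced rates/montages (250 Hz, 16 or
fewer channels) where only correctness, not the study conditions, is at
stake.

## Known limitations

* BrainVision support covers the written dialect (BINARY, MULTIPLEXED,
  IEEE_FLOAT_32) plus INT_16 reading via MNE; no EDF/FIF/GDF.
* The protocol fixes only the sizes of the reduced montages, so the
  16-channel and 15/7-channel subsets are documented stand-ins,
  overridable in the config.
* Backward electrode selection is greedy and uses calibration CV as its
  criterion; with saturated accuracy the removal order among equivalent
  channels is resolved alphabetically, which is deterministic but
  arbitrary.
* The decoder assumes stationarity across a session; no adaptive
  updating or transfer between sessions.
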