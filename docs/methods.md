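# Methods

## The assessment problem

The battery infers cognitive abilities without any motor response by
funnelling every answer through a single covert channel: counting one word
in an auditory stream.  Eight monosyllabic nouns are played in random order
with equal frequency (7–10 occurrences each, so streams are 56, 64, 72, or
80 words long; 400 ms per word plus a 100 ms gap).  Rare, attended,
task-relevant stimuli elicit a P300b — a positive deflection peaking around
450 ms over centro-parietal scalp — so the counted word can be identified
from EEG alone.  Three tasks share the mechanism:

* **AT (auditory attention)** — the target word is given; counting it
  demonstrates command following.
* **WM (working memory)** — a 4-, 6-, or 8-word list is presented, a
  serial-position probe is asked, and the participant counts the word they
  recalled.
* **AR (auditory reasoning)** — a relational sentence over two nouns
  (precede/follow × active/passive × positive/negative, eight types) must
  be solved; the participant counts the noun they believe occupied first
  position.

A session is six 12-trial blocks (AT, WM, AR, AT, WM, AR; 72 trials).  The
schedule is exactly balanced: each word is the AT target three times, each
WM set size occurs in eight trials, each sentence type occurs three times
with unique noun pairings.  Within each block the four admissible stream
lengths are each used three times; this balancing is a package choice — the
protocol only constrains the admissible lengths — made so that condition
epoch counts are stable across sessions.

## Statistical inference: cluster-mass permutation test

Conditions are compared pointwise over the 16-electrode × time grid with t
statistics (paired over participants at the group level; pooled-variance
two-sample over epochs at the single-participant level).  Points exceeding
the two-sided t critical value at point-level p = 0.05 are grouped into
clusters — same electrode at adjacent samples, or neighboring electrodes at
the same sample — and scored by summed t (mass).  Significance comes from
the permutation null of the maximum |mass| (participant-wise sign flips at
the group level; re-partitions of the pooled epochs at the single level),
with p = (count + 1)/(n_perm + 1) and n_perm = 1000 by default.  Instances
whose permutation space is no larger than n_perm are enumerated
exhaustively (p = count/total).  Ties in |mass| are broken toward the
earliest-onset cluster when selecting the region of interest.

Electrode adjacency uses standard 10-10 coordinates with a neighbor radius
of 0.6 normalized head-radius units — the smallest round radius at which no
electrode of this sparse montage is isolated (T7/T8/P7/P8 have no neighbor
below ≈0.55).  Clustering runs over the post-stimulus window (0–1000 ms)
in session analyses; the cluster-forming threshold, radius, and window are
configurable.

Condition binning is task-specific.  AT: target vs. the seven other words.
WM: the *correct* word (not the one the participant reported) vs. all
others — at chance performance the P300b falls in both bins equally and the
contrast is null by construction.  AR: correct noun vs. the *other sentence
noun only*, because an attentive but wrong participant plausibly counted
that noun; pooling it with six silent words would dilute the negative bin.
The attended/unattended partition keyed on the behavioral answer
(regardless of correctness) feeds the Monte Carlo analysis.  The
single-participant AT analysis pools attended epochs against unattended
epochs across trials.

## Normalized magnitude (NM)

If a participant answers a fraction *a* of trials correctly, the
correct-condition ERP mixes P300b epochs (weight *a*) with zero-mean
epochs, so its magnitude is *a* times the attended-condition magnitude from
the AT task: a 4 µV attended P300b at 75% performance predicts a 3 µV
correct-condition magnitude.  Magnitudes are plain means over the
spatiotemporal region of the largest significant cluster from the
group-level AT test (the one region guaranteed to exist for every
participant; per-participant regions are available by configuration).  NM =
correct magnitude / attended magnitude estimates *a* itself; participants
whose attended magnitude is non-positive are excluded because the ratio is
unstable.

Performance is modelled as a binomial proportion (8 trials per set-size
cell) in a GLM with logit link: set size as a factor, NM as covariate,
plus their interaction, tested by sequential likelihood-ratio chi-squares
(set size, then NM given set size, then the interaction); a Gaussian
identity-link variant is available for comparison.  Pearson correlations
between NM and performance are reported per set size and raise an error at
zero variance (ceiling performance), mirroring the interpretive caveat that
applies there.

## Monte Carlo sensitivity analysis

From one participant's attended/unattended pools: draw n attended and 7n
unattended epochs (with replacement once the pool is exhausted — sessions
cap attended epochs near 200 while the analysis extends to n = 600), swap
round((1−a)·n) attended epochs for unattended ones to emulate accuracy
*a* (nearest-integer rounding, ties to even), run a single-participant
cluster test (500 permutations per repetition by default), and average p
over 100 repetitions per n.  n grows in multiples of 25; accuracies span
0.3–1.0 in steps of 0.1.  Each attended target accounts for ≈4 s of stream
time (8 stimuli × 500 ms), so n converts directly to testing time: n = 75
is ≈5 minutes.  `required_targets` reports the smallest grid n whose mean p
falls below α; curves may be truncated early once that happens, since later
grid points do not change the answer.  Means are arithmetic, averaged
within participant first, then across participants when several are
available.

## Synthetic participants

The simulator is the package's test bed and defines its study conditions.
A behavioral agent answers WM probes correctly with a configurable per-set-
size probability (wrong answers are uniform over the other list members),
AR problems with probability `accuracy_ar` (wrong answer = the other noun),
and reports the true target count with probability `count_accuracy` (else
off by one within the 7–10 options).  The agent always counts the word it
answered, and counting does not modulate the EEG.

EEG is 16 channels at 256 Hz.  Every stream event whose word matches the
trial's attended word receives a raised-cosine P300b kernel — peak 4 µV at
450 ms, 300 ms support — scaled by a fixed posterior-maximal topography
(1.0 at CPz/Pz/POz, 0.6 at CP3/CP4/Oz, 0.3 elsewhere).  Unattended events
add nothing.  Background noise is AR(1) with coefficient 0.95 (low-
frequency-dominated, like resting EEG) scaled to `noise_sd`; white and 1/f
modes exist for oracle tests.  The default `noise_sd` = 10 µV was
calibrated so that, for a perfectly accurate participant, the mean single-
participant cluster-test p first crosses 0.05 between 50 and 100 attended
stimuli (it lands at 75 on the calibration run) — i.e., the simulated
effect-to-noise ratio matches the regime where ≈5 minutes of testing
establishes command following.

What the simulator deliberately omits: ocular/muscle artifacts beyond
optional amplitude outliers, volume conduction (channels carry independent
noise), latency/amplitude variability of the P300b across trials and
participants, and non-P300 components (N1/P2).  Passing tests therefore
show that the analysis chain is correct and calibrated under its stated
generative model, not that real recordings will reach the same
sensitivities.  One consequence of the shared stimulus grid is real,
however, and preserved: with stimuli 500 ms apart and a 300–600 ms kernel,
an attended stimulus bleeds into the window edges (and baselines) of
neighboring epochs.  The bleed is equally likely in both conditions, so
contrasts are unaffected, but individual "unattended" epochs are only
exactly flat when their immediate stream neighbors are also unattended.

## Preprocessing

Zero-phase 4th-order Butterworth band-pass, 0.5–10 Hz (forward–backward,
preserving P300 latency); epochs −200 to +1000 ms relative to word onset
(sample offsets round(−0.2·fs)..round(1.0·fs) inclusive: 308 samples at
256 Hz); per-channel subtraction of the mean prestimulus voltage.  Epoch-
level artifact rejection applies four statistics per epoch and channel:
absolute amplitude (> 100 µV), kurtosis, data improbability (epoch mean
square in units of the channel's pooled variance), and linear trend
(R² > 0.5 with a fitted drift > 75 µV across the window).  Kurtosis and
improbability are z-scored across epochs *on the log scale* — both
statistics are strongly right-skewed for band-limited data, and raw-scale
z-scores at the |z| > 5 threshold rejected ≈7% of clean synthetic epochs;
after stabilization clean-data retention is >99% with injected spikes and
drifts still caught.  Rejection runs before condition binning so both
conditions face identical criteria; thresholds are global, not
per participant.

## Numerical and I/O choices

Permutation t maps are computed in float32 after per-point mean centering
(numerically safe and BLAS-friendly); observed maps use float64.  Null
cluster masses use vectorized connected components on the supra-threshold
subgraph.  All randomness flows from explicit seeds; fixed seeds reproduce
recordings, permutations, and result files bit-identically (the EDF writer
stamps a fixed epoch date for this reason).  Continuous EEG is written as
16-bit EDF with per-channel physical ranges (quantization ≤ range/65535);
reading goes through MNE's EDF reader, which doubles as an independent
check on the writer.  Epoch sets travel in an HDF5 container (`/data`,
`/times`, `/channels`, `/metadata`); events and behavior as TSV; results
as sorted-key JSON.

## Known limitations

* The NM estimator is a ratio of noisy region means; its sampling noise at
  the calibrated SNR is ≈0.17 per participant (three set-size records
  averaged).  Combined with the binomial noise of 24 recall trials per
  participant, the expected correlation between NM and the *generative*
  accuracy across a cohort spanning 0.3–1.0 is ≈0.78 — performance recovery
  is informative but attenuated; see the acceptance suite for the exact
  measured values.
* Group-level inference assumes exchangeable participant difference maps;
  single-level inference assumes exchangeable epochs under the null, which
  the overlap structure of the stream satisfies only approximately.
* The sentence grammar models the eight binary template types; it does not
  parse free text.
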