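# p300battery

A motor-independent cognitive assessment battery built on the auditory
P300b.  Whether a person can attend a stimulus stream, hold items in
working memory, or solve grammatical reasoning problems is tested through
one covert response channel: counting a designated word inside a stream in
which eight words occur equally often.  Attended occurrences elicit a P300b
(a positive ERP deflection peaking ≈450 ms after onset, maximal over
centro-parietal scalp), so the counted word — and hence the answer — can be
decoded from EEG alone.  The design targets bedside assessment of people
with severe motor impairment or disorders of consciousness, prototyped and
validated here on synthetic recordings.

The package covers the full pipeline:

* **protocol** — balanced 72-trial session plans for the three tasks
  (attention / Sternberg-style memory span / relational reasoning),
  including the sentence grammar and its solver;
* **simulate** — a behavioral agent with configurable accuracy plus a
  16-channel, 256 Hz EEG synthesizer that injects a posterior-maximal
  P300b at attended events only;
* **preprocess** — zero-phase 0.5–10 Hz band-pass, −200..1000 ms epochs,
  baseline correction, epoch-level artifact rejection (kurtosis, amplitude,
  improbability, linear trend);
* **binning** — task-specific correct/incorrect and attended/unattended
  condition assignment;
* **cmpt** — spatiotemporal cluster-mass permutation tests at the group
  level (paired ERPs, sign-flip null) and single-participant level
  (unbalanced epoch samples, re-partition null), with exhaustive
  enumeration on tiny instances;
* **individual_differences** — normalized ERP magnitude (NM): the
  correct-condition magnitude divided by the attended-condition magnitude
  estimates the participant's accuracy (a 4 µV attended P300b at 75%
  performance predicts 3 µV), plus a binomial GLM of performance on set
  size and NM;
* **monte_carlo** — the testing-time/accuracy sensitivity analysis: mean
  cluster-test p as a function of the number of attended targets n (≈4 s
  of stream time each) and simulated accuracy, via subsampling and
  condition swaps.

See `docs/methods.md` for the models, assumptions, defaults, and
limitations.

## Worked example

Generate a schedule, simulate one accurate participant, preprocess, and
test command following in the attention task:

```sh
battery schedule --seed 1 --out schedule.json --events events.tsv
battery simulate --schedule schedule.json --seed 2 --out subj01.edf
battery preprocess --edf subj01.edf --events subj01.edf.events.tsv \
    --out subj01.h5 --report reject.json
battery analyze --epochs subj01.h5 --schedule schedule.json \
    --task at --n-perm 1000 --seed 3 --out at_result.json
```

which prints

```
wrote schedule.json: 72 trials, blocks ('AT', 'WM', 'AR', 'AT', 'WM', 'AR')
wrote subj01.edf (2664 s, 4896 events)
wrote subj01.h5: 4888 epochs (8 rejected)
AT cluster p = 0.002997
```

The session's 4896 stream words yield 4888 clean epochs; the cluster test
compares the ≈600 attended epochs against the rest and finds a significant
posterior cluster — in `at_result.json` the largest cluster spans
CPz/Cz/Pz/POz/Oz from 359 to 547 ms (mass 551.8, p = 0.003, the floor for
1000 permutations being 1/1001): the participant demonstrably attended the
instructed words.  `battery run` chains the same stages (plus group-level
tests, NM, and the Monte Carlo analysis) for multi-participant studies from
a single JSON config, with byte-identical outputs on reruns.

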