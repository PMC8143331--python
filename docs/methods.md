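# Methods

## Task model

The computerized Wisconsin Card Sorting Test presents four fixed key cards
(one red triangle, two green stars, three yellow crosses, four blue circles)
and a stream of stimulus cards sorted by color, shape, or number. We code
colors and shapes by the key-card position that carries them, so a stimulus
card is a triple *(number, color-position, shape-position)*; a card is
admitted only if those three positions are pairwise distinct. This is the
defining property of the unambiguous card set: each of the three categories
maps to a distinct response key, exactly one key matches the stimulus on no
dimension, and the applied category can be read off any key press. There are
24 such cards; the generator draws them uniformly, never repeating the
immediately preceding card.

Feedback is positive exactly when the applied category equals the prevailing
category. The prevailing category switches covertly once a run of correct
sorts is complete: each run's required length is drawn uniformly from
`run_length_support` and the successor category uniformly from the two
alternatives. Errors neither advance nor reset a run — a run completes after
the required number of correct sorts regardless of interleaved errors,
because a switch "announced" during an error would be undetectable by the
participant. A session comprises a practice block (6 switches) and an
experimental block (40 switches), jointly capped at 250 trials; all analyses
use experimental trials only.

**Run lengths.** The original task specifies only that runs comprise "two or
more" repetitions. We default to lengths 2 (probability 3/4) and 3
(probability 1/4). This choice is pinned down by session-length accounting:
every covert switch costs the responder at least one uninformative negative
trial (the announcement) and, on non-inference switch trials, an expected
half trial of guessing, so with mean run length ≈ 2.25 an error-free session
ends after 40 switches in roughly 160 trials and a realistically erring
cohort averages ≈ 170 — the scale of real sessions (mean 168.6 trials, and
roughly half of all trials following negative feedback). Longer default runs
(e.g. mean 4) would push sessions past 200 trials and are inconsistent with
that accounting. The support is configurable; repeated entries act as
weights.

**The 250-trial cap** counts practice plus experimental trials. The
originating description is grammatically ambiguous on this point; under the
default configuration the cap binds only for pathologically error-prone
responders, so the choice is inconsequential for realistic cohorts.

## Trial types and error scores

For trial *t* ≥ 2 of the experimental block (the first trial has no
preceding feedback and stays unlabeled):

- *switch* iff feedback at *t*−1 was negative; *repeat* otherwise;
- *inference* iff *t*−1 was a switch trial, the category applied at *t*−1
  differed from that at *t*−2, and feedback at *t*−1 was negative. Inference
  trials are a sub-type of switch trials: two categories stand disconfirmed,
  so the third is deducible.

Errors are independent predicates evaluated per trial: PE (switch trial,
applied category repeats the previous one), SLE (repeat trial, applied
category differs from the previous one), IE (inference trial, applied
category is not the prevailing one). Consequences we adopt explicitly:

- a perseverative response on an inference trial increments **both** PE and
  IE (no exclusion hierarchy is imposed; such trials are excluded only once
  in RT filtering);
- a press of the no-match key ("other") is an SLE on repeat trials and an IE
  on inference trials but never a PE — it repeats no category, even after a
  previous no-match press.

## Screening and RT filtering

The cohort validity screen computes, per category (color, shape, number,
other), the mean and SD of application counts across all participants and
excludes anyone deviating by more than 3 SD on any category. It is a single
pass: statistics are not recomputed after exclusions, so re-screening the
survivors with the original statistics changes nothing. Counts (not
proportions) are screened, matching the rule as stated for the original
cohort. With identical participants all SDs are zero and no one is excluded.

For RT analysis a trial is dropped if its RT is strictly below 100 ms, above
the participant's mean + 3 SD cut-off — computed over **all** experimental
trials before any exclusion, in the stated order of the rules — or carries
any PE/SLE/IE. Mean RTs are then computed per trial type; inference trials
contribute to both the switch and the inference mean (sub-type relation).
Sample SDs (ddof = 1) are used throughout, the convention in this
literature; `FilterConfig(ddof=0)` switches to population SDs. A trial type
with no valid trials yields an undefined (NaN) mean, never zero.

## Split-half reliability

A split assigns each experimental trial to half A or B, balanced to within
one trial; for odd counts the extra trial lands in either half with
probability 1/2. Because trial counts differ across participants, random
splits are drawn independently per participant (no shared index pattern is
possible). Half scores reuse the globally computed labels, error flags, and
RT masks — splitting never relabels trials. Error measures are raw counts
(halves are balanced by construction); conditional error probabilities
(errors per eligible trial) are available as additional measures; RT
measures are means over the half's valid trials of the type. All measures
are evaluated on the *same* split within an iteration, as a single
resampling run would.

Pearson correlations between half-score vectors use pairwise deletion of
participants with an undefined half score (reported as `n_pairs`); fewer
than 3 pairs or a constant half-score vector make *r* undefined, and such
iterations are counted and excluded from summaries rather than silently
dropped. The Spearman–Brown correction r_SB = 2r/(1+r) is strictly
increasing on (−1, 1], undefined at r = −1 (reported as NaN), and negative
values are reported as computed, never truncated.

The sampled distribution of r_SB (default 1000 splits) is summarized by its
median and 95% HDI. The HDI of a finite sample is computed by the
sorted-window algorithm: the narrowest window of ⌈0.95 n⌉ consecutive order
statistics, leftmost on ties. An optional stratified mode balances each
split within trial-type strata instead of over all trials; it is off by
default because the reference procedure splits the total of a participant's
completed trials.

## Generative cohort model

Each simulated participant is a memoryless stochastic policy: on switch
trials the previous category is repeated with probability `p_persev`;
otherwise, on inference trials the deducible category is applied with
probability 1 − `p_inferr`; on non-inference switch trials the agent guesses
uniformly between the two untried categories (a strategy choice, not an
error); on repeat trials the set is abandoned with probability `p_setloss`.
When erring by switching or failing inference, the no-match key is pressed
with probability `p_other`. RTs are log-normal with context-specific
location and scale (repeat / switch / inference); a shared person-level
factor shifts all three locations jointly, so slow participants are slow
everywhere. Optional linear drift adds `drift_error`·t to all error
log-odds and `drift_rt`·t to the log-RT location, emulating learning
(negative slopes) or fatigue (positive slopes); population drift slopes are
normal with mean zero and configurable SD.

Between-participant heterogeneity uses beta distributions for error
probabilities (moment-matched from mean and SD) and normal distributions
for log-RT locations. The defaults are calibrated so a screened default
cohort reproduces the descriptive moments of a young-adult
reference cohort (N = 375): ≈ 12.2 PE (SD 13.7), 5.0 SLE (7.1), 8.5 IE
(8.8) per participant, mean RTs ≈ 1835/1241/1700 ms on
switch/repeat/inference trials (SDs 694/441/636), ≈ 170 completed trials,
and ≈ 5% of participants failing the validity screen. The reliability
estimates the pipeline then produces (medians ≈ 0.93/0.90/0.87 for
PE/SLE/IE and ≈ 0.97/0.98/0.84 for switch/repeat/inference RT at one
default seed) are emergent, not calibrated.

What the generator deliberately omits: richer attentional or
reinforcement-learning structure (errors are per-trial Bernoulli), RT
sequential effects (post-error slowing), non-lognormal RT shapes, and any
fitting to real data. Passing tests therefore certify the analysis
machinery and its statistical behavior under a plausible data-generating
process, not the cognitive fidelity of the agent. The individual-level RT
distribution of real cWCST data is unknown to us; log-normality is a
synthetic stand-in chosen for positivity and right skew.

## The Monte-Carlo oracle and parameter recovery

`oracle_reliability` estimates the expected single-split r_SB of a measure
by brute force: it simulates many independent cohorts, applies one random
split per cohort, and re-derives trial types, error flags, RT masks, and
half scores with plain loops written directly from the definitions, sharing
nothing with the analysis modules beyond the Spearman–Brown formula. It
reports the mean, the cohort-to-cohort SD, and the MC standard error of the
mean. Recovery tests compare a pipeline's 1000-split median on one cohort
against the oracle mean within **two cohort-to-cohort SDs**: the pipeline
cohort is itself one draw from the oracle's cohort distribution, so the
spread (≈ 0.003–0.03 depending on heterogeneity), not the SE of the oracle
mean (≈ 10× smaller), is the right yardstick.

## First/second vs odd/even splits, and drift

Heterogeneous long-term trends (one participant learns, another fatigues)
decorrelate first and second halves but affect odd and even trials almost
equally, depressing first/second estimates relative to odd/even ones. The
drift scenario (`drift_rt_sd = 0.002` log-units/trial, `drift_error_sd =
0.008` logits/trial — a ±30–40% RT change and ±1–2 logit error-rate change
across a session at 1 SD) reproduces this ordering in essentially every
replicate cohort, while with zero drift the two RT estimates agree to well
within 0.01 on average.

A subtlety worth knowing: for **error counts** the two systematic splits
differ even without drift. Perseverative errors are serially dependent
through the task itself — each error produces negative feedback and hence
another switch trial, so errors arrive in streaks. Odd/even splits place
the members of a streak into opposite halves, sharing that local noise
across halves and inflating the correlation; first/second splits keep
streaks within one half. In default simulations the odd/even PE estimate
exceeds the first/second estimate by ≈ 0.02 with no drift at all. This is a
property of splitting serially dependent data, not of the implementation,
and it is why the zero-drift agreement check uses an RT measure, whose
trial-level noise is independent.

## Numerical and design choices

- All randomness flows from numpy `Generator`s; the pipeline derives
  simulation and split substreams from one master seed via `SeedSequence`,
  making every output byte-reproducible.
- The session runner is a fused scalar loop over pre-drawn random numbers
  (≈ 0.6 ms per session); the resampling engine evaluates all measures on
  all splits of a participant with one boolean matrix product per
  participant. These choices keep the Monte-Carlo recovery study (600+
  cohorts of 375 sessions) at the scale of minutes on one CPU.
- Correlations are clipped to [−1, 1] against floating-point overshoot.
- Degenerate inputs error loudly: splits need ≥ 2 trials, SDs need ≥ 2
  observations, correlations need ≥ 3 defined pairs, the HDI needs ≥ 20
  samples.
- Problem sizes in the test suite (200-log scorer equivalence; 3 × 200
  oracle cohorts for recovery; 50 replicate cohorts per drift scenario;
  10,000-draw HDI checks) were chosen as the smallest sizes at which the
  Monte-Carlo tolerances above are meaningful.

## Known limitations

- The validity screen is applied once, as in the reference procedure; a
  cohort with many extreme outliers could mask milder ones.
- Real cWCST key-press data may contain anticipations, double presses, or
  hardware timing jitter that the log model does not represent.
- The agent's uniform guessing on non-inference switch trials ignores
  documented human biases (e.g. returning to a recently reinforced set),
  which could shift trial-type frequencies slightly relative to real data.
- Reliability estimates from this package describe scores in a
  sample-and-procedure context; they are not portable constants of the task.
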