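# Methods

This note documents the models, parameters, and design decisions behind
`pafscreen`: what the detector assumes, what the synthetic generator does and
does not emulate, and where the genuinely open choices were made.

## 1. The rhythm-change screen

For beat *i* with six subsequent contiguous intervals RR*ᵢ* … RR*ᵢ₊₅*,

  Rc(i) = std(RRᵢ…RRᵢ₊₅) / mean(RRᵢ…RRᵢ₊₅),

the population standard deviation (divide by 6) over the arithmetic mean.
The sample form (divide by 5) is available through `screening.std_mode` for
sensitivity analysis; all defaults and calibration use the population form.
Rc is scale-invariant, so bradycardia or tachycardia per se never flags; only
*relative* irregularity does. Windows containing an exactly constant set of
intervals return exactly 0 rather than floating-point dust, honoring the
"zero iff identical" contract.

A beat is flagged when Rc strictly exceeds the threshold. Maximal runs of
flagged beats are merged when separated by fewer than `merge_gap_beats`
(default 6, one window span) unflagged beats; each merged candidate keeps its
longest pre-merge run for the single-PB rule. A detected segment closes six
beats after its last flagged beat because a beat's Rc describes the six
intervals that follow it.

### Threshold calibration

The threshold is the method's single binding free parameter. It is fixed
from the screen's operating curve measured on long synthetic sequences
(500,000 beats each of sinus rhythm and AF under the default generator
conditions): the calibrated value is the smallest grid point (0.030–0.120,
step 0.005) whose sinus false-flag rate is at most 10⁻⁴ per window, provided
at least 95% of AF windows remain flagged.

Two considerations shape that objective:

* the sinus false-alarm budget is not only about specificity — a stray sinus
  flag within the merge gap of a true AF run extends the candidate and
  smears the detected episode boundary, so boundary accuracy demands a very
  low sinus flag rate (10⁻⁴ per window is roughly one stray flag per two
  hours at 75 bpm);
* the AF sensitivity floor guarantees flagged AF runs stay long enough to
  pass the 10-beat single-PB rule.

Under the default generator conditions the calibration lands at **0.065**
for any calibration seed. The library default in `PipelineConfig` remains
0.10 and is always explicit in serialized run configurations; an earlier
cascade-level grid search (classify whole synthetic segments per class,
maximize the worst per-class accuracy) selected statistically equivalent
values but was noisier seed-to-seed, so the operating-curve form replaced it.

## 2. The rejection cascade

Candidates are explained away in order; AF is the verdict of last resort.

**Single-PB rule.** One premature beat contributes one short coupling
interval and one long pause; a 6-interval window slides across that pair
exactly seven times, so genuine single-PB disturbances produce flagged runs
of about 7 beats. Runs of at most `single_pb_max_run` = 10 beats are
rejected. The boundary reads "exceeds 10", so a run of exactly 10 is still
rejected.

**Clustering.** The candidate's intervals (the flagged beats' windows, i.e.
beats *s*…*e*−1 cover intervals *s*…*e*+4) are clustered into three groups
by K-Medoids on the two features (RRᵢ, ΔRRᵢ/RRᵢ), ΔRR of the first interval
taken as 0. Three deliberate choices:

* *Unscaled features.* In AF the difference ratio varies more than the
  interval itself, so the partition follows beat-to-beat jumps and the three
  groups keep nearly equal mean RRs with no clear boundaries; in premature
  rhythms the intervals separate into short/normal/long values that dominate
  the partition. Z-scoring the features per segment destroys this asymmetry
  (it lets the clustering carve AF into RR bands, after which the rechecks
  misread AF as premature rhythm and reject about half of it).
* *Exact solving at segment scale.* For up to 30 points the optimal medoid
  triple is found by enumerating all C(n,3) subsets — cheap, deterministic,
  and guaranteed; longer merged candidates use a deterministic PAM
  (greedy BUILD, best-improvement SWAP, ties to the lowest index). PAM is a
  local search and can miss the global optimum on small instances, which is
  why the exact path exists where exactness is affordable.
* *Gated fine-tuning.* Groups are then refined by greedy single-interval
  reassignment that strictly reduces the summed within-group RR standard
  deviation — but only when the groups actually form separated RR bands
  (adjacent group medians differing by more than twice the widest robust
  within-group spread, 1.4826·MAD). The gate matters: run unconditionally,
  any std-reducing local search provably sorts an *overlapping* partition
  into artificial RR bands, erasing exactly the within-group variability
  that lets AF survive the rechecks. Premature rhythms (separated bands
  with occasional stragglers from the Δ feature) are where fine-tuning has
  something real to fix. The summed within-group std never increases, and
  the pass terminates because it strictly decreases per move.

Groups are relabeled by ascending mean RR: group 0 = shortest (coupling
intervals), group 2 = longest (compensatory pauses). Fewer than three
distinct feature points give a degenerate result grouped by value.

**Bigeminy/trigeminy recheck.** The geminal signature is checked over the
whole candidate: *every* 6-consecutive-interval window must hold equally
many group-0 and group-2 intervals, both at least `geminy_min_count` = 2
times. Bigeminy puts 3 shorts + 3 longs in every window and trigeminy 2 + 2;
AF balances some windows by chance but essentially never all of them. Two
readings were possible here ("some window" vs "every window"); the
existential reading lets several percent of AF candidates fire the pattern
by chance and then be auto-rejected, so the universal reading is used. The
minimum count of 2 (not a strict "more than two") is forced by trigeminy
itself, whose windows contain exactly two of each. When the pattern is
present, the long group (the pauses, nearly uniform in geminal rhythm) is
re-screened.

**Multi-PB recheck.** Otherwise the group whose mean RR is closest to the
segment median is re-screened — with frequent premature beats the sinus
background still holds the majority, so the median group is the normal
beats. Ties go to the larger group, then the lower id (the tie matters for
bigeminy, where the median falls between the short and long bands and the
larger/shorter group wins, again yielding a quiet recheck and a rejection).

**Rechecks.** A recheck recomputes Rc over the selected intervals,
concatenated in original temporal order, and succeeds (rejects the
candidate) when every defined value is at or below the threshold. Subsets
of fewer than six intervals cannot form a window and count as quiet: a tiny
near-uniform group signals premature-beat structure, not AF.

Cascade order is geminy before multi-PB (`reject.order` configurable): the
geminal pattern is the more specific explanation, and the median-group
recheck would also fire on geminal rhythm with a different label.

## 3. The synthetic generator

The generator supplies the study conditions for every test; its defaults
are the assumed rhythm models, exposed as parameters.

| parameter | default | meaning |
| --- | --- | --- |
| `base_rr` | 0.8 s | mean interval (75 bpm) |
| `nsr_cv` | 0.03 | sinus coefficient of variation |
| `af_cv` | 0.20 | AF coefficient of variation |
| `coupling_fraction` | 0.6 | premature RR ÷ local 6-RR mean |
| `compensatory_fraction` | 1.4 | pause RR ÷ local 6-RR mean |
| `n_pb` | 4 | premature beats per multi-PB segment |

* **NSR** is AR(1) with coefficient 0.5 around `base_rr`, stationary sd
  `nsr_cv`·`base_rr`: mild short-range correlation keeps Rc well below
  threshold without being constant.
* **AF** is i.i.d. truncated normal — serially exchangeable, unimodal, so a
  3-way clustering finds no boundaries, which is the defining assumption
  the cascade exploits.
* **Premature beats** replace an interval pair with coupling then pause,
  both proportional to the local mean of the preceding (up to six) normal
  intervals, so they stay rate-adaptive. Single-PB places its beat at least
  3 beats from either end; multi-PB enforces a minimum spacing of 3 beats.
* **Bigeminy/trigeminy** alternate coupling/pause (every other beat
  premature) and normal/coupling/pause (every third beat premature), with
  sinus-level jitter on the underlying base.
* All intervals are truncated to [0.2, 2.5] s for physiological
  plausibility.

Recordings concatenate episodes; the interval bridging into an episode is
drawn from the entering episode's model, and the annotation marks each
episode's first beat, so ground truth is exactly recoverable.

`render_ecg` places one biphasic (Mexican-hat, ≈ 80 ms) template per beat at
the cumulative RR times and adds 0.3 Hz sinusoidal wander plus white noise.

**What this does not emulate** — and hence what passing tests do and do not
show: no P/T/f-wave morphology, no respiratory sinus arrhythmia beyond
AR(1), no heart-rate drift or circadian structure, no AF RR autocorrelation
(real AF has some), no noise bursts or electrode artifacts in the RR domain,
and premature beats with fixed (not variable) coupling fractions. Results on
the synthetic corpus demonstrate the internal logic of the cascade under its
own assumptions; clinical performance must be assessed on annotated
databases via the WFDB path.

## 4. Preprocessing

Waveform input goes through four stages, all configurable:

* **Baseline removal** — two-pass sliding median (200 ms then 600 ms,
  zero phase, `scipy.ndimage.median_filter` with nearest-edge padding); the
  short pass deletes QRS complexes from the estimate, the long pass smooths
  to the wander time scale.
* **Quality gating** — 2-second windows fail when flat (peak-to-peak
  < 50 µV), saturated (> 20% of samples at the recording rail), or
  structureless (max |x| < 6 × window MAD — i.e. no QRS-like spike above
  the noise floor; for Gaussian noise max |x| ≈ 5 × MAD, for windows with
  QRS the ratio is ≫ 6). Beats in failed windows are dropped, and intervals
  spanning a dropped beat or a quality boundary are marked non-contiguous
  so no Rc window straddles a gap.
* **QRS detection** — 5–15 Hz band-pass energy, 120 ms integration, peak
  picking with a 200 ms refractory period and an adaptive height threshold.
  Any detector meeting the noiseless-exactness contract is interchangeable,
  and the pipeline accepts externally supplied beats or plain RR input.
* **Refinement** — each beat moves to the maximum absolute amplitude within
  ± 50 ms (idempotent; clamped at signal edges). The radius must stay below
  half the refractory period.

## 5. Evaluation conventions

Durations are counted in beats (segments are beat-anchored; a time-based
variant would only rescale by the mean RR). The 3-beat boundary tolerance
applies to onset and offset independently and strictly (< 3), and only a
*single* overlapping detection can earn the shortcut — fragmented detections
always take the intersection-over-union branch. A detection overlapping two
labels is reused for each label's score; the detected-segment count is the
raw number of detections. Missed episodes score 0 and stay in the average.
Beat-level metrics with an absent class report `None` rather than NaN.

## 6. Problem sizes in the test suite

The behavioral suite measures rejection/retention on 1000 synthetic
31-beat segments per rhythm class and episode recovery on 100 recordings
(~500–1000 beats each, AF episodes of 150–250 beats so that the 6-beat
boundary slack cannot dominate the episode score), with threshold
calibration on 500k-beat sequences; the whole suite runs in well under a
minute on one core. Segment sizes mirror the 31-beat (30-RR) windows the
premature-beat analysis is defined on.

## 7. Known limitations

* The cascade depends on QRS timing quality; the bundled detector is
  adequate for clean and moderately noisy signals, not for heavily
  artifacted wearable data.
* Very short AF episodes (≲ 15 beats) cannot exceed the 10-beat run rule
  reliably and may be rejected as premature rhythm — the same short-episode
  weakness the evaluation framework is designed to expose.
* The WFDB layer covers single-segment records in formats 16 and 212 with
  MIT-format annotations; multi-segment and other signal formats are out of
  scope.
* `CosEn` (an entropy-based AF feature sometimes used for comparison) is
  not implemented; the screening module is the extension point for
  alternative statistics.
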