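# Methods

This note documents the models and procedures implemented in `falldet`, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not establish.

## Signal model and features

Streams are uniformly sampled triaxial acceleration in g (1 g =
9.80665 m/s²), with integer-millisecond timestamps from stream start and a
rate from the supported set {8, 50, 100, 250, 333, 500} Hz. Inputs in m/s²
are converted on read.

Three features drive the detector, all invariant under any fixed rigid
rotation of the device:

- **Total magnitude** ‖a‖.
- **Free-fall ratio** ‖a − g‖ / max(‖a‖, ε): the ratio of linear-acceleration
  magnitude to total magnitude. During free fall the total magnitude
  collapses toward 0 g while the linear magnitude tends to 1 g, so the ratio
  spikes; it is thresholded from above. The guard ε = 10⁻³ g keeps the
  feature finite at exact free fall.
- **Orientation-change angle**: the angle between the running mean
  acceleration of the Falling phase and the mean over a pre-fall buffer
  frozen at Falling entry. Near 1 g of quasi-static signal, mean acceleration
  is a good proxy for the gravity direction, so this angle measures the
  posture change a completed fall produces (standing → lying).

**Gravity estimation.** No orientation sensor is assumed, so gravity is
estimated per axis with a causal first-order IIR low-pass,
`g[n] = α·g[n−1] + (1−α)·a[n]`, `g[0] = a[0]`, with `α = exp(−2π f_c / f_s)`
and a default cutoff `f_c = 0.3 Hz` (time constant ≈ 0.53 s at 100 Hz). A
causal single-pole filter matches sample-by-sample embedded execution, rides
through a sub-second free-fall phase (keeping ‖a − g‖ large exactly when it
matters) and still tracks slow posture changes. The cutoff is a compromise:
much higher and gravity chases the free-fall signal, deflating the ratio;
much lower and slow posture changes masquerade as linear acceleration.

**Resampling.** Integer rate ratios decimate exactly (100 → 50 Hz keeps every
second sample, preserving the first); non-integer ratios (100 → 8 Hz)
linearly interpolate onto a uniform grid spanning the same duration. Output
duration is conserved within one target sample period. Upsampling is out of
scope.

## The state machine

States: Stable, Unstable, Falling, Impact/Watcher. One transition evaluation
per sample; all bookkeeping is O(1) per sample (ring buffer of
`pre_fall_window_s` = 0.4 s for the pre-fall reference, running sums for the
Falling-phase mean).

Parameters, with the packaged reference values (calibrated once on the
synthetic corpus — the original device thresholds were never published):

| field | unit | reference | role |
|---|---|---|---|
| `unstable_mag_dev` | g | 0.25 | Stable→Unstable magnitude deviation |
| `fall_ratio_min` | — | 1.2 | Unstable→Falling ratio threshold |
| `impact_mag_min` | g | 1.8 | Falling→Impact shock condition |
| `impact_angle_min` | deg | 40 | Falling→Impact posture-change condition |
| `watcher_move_dev` | g | 0.4 | movement detection during the watcher |
| `watcher_duration_s` | s | 5.0 (fixed) | no-movement window before broadcast |
| `pre_fall_window_s` | s | 0.4 (fixed) | pre-fall reference buffer |
| `falling_timeout_s` | s | 1.0 (fixed) | Falling → Unstable without impact |
| `unstable_quiet_s` | s | 2.0 (fixed) | Unstable → Stable after quiescence |
| `impact_settle_s` | s | 0.5 (fixed) | watcher blanking after impact |

Design decisions where the published description is silent or ambiguous:

- **Impact requires the magnitude AND angle condition jointly.** A real fall
  produces both a shock and a posture change; requiring both is what rejects
  the dominant false-alarm source (hard table drops: large shock, small
  orientation change).
- **`impact_settle_s`.** A physical impact rings for more than one sample; if
  the watcher's movement rule were armed immediately, the impact transient
  itself would always restart the machine and no fall could ever be
  broadcast. The watcher therefore ignores movement for 0.5 s after the
  impact transition; the 5 s broadcast countdown still runs from the impact
  sample. Within the monitored interval, a single sample beyond
  `watcher_move_dev` restarts the machine (no debouncing).
- **Timeouts.** Falling falls back to Unstable after 1 s without an impact,
  and Unstable relaxes to Stable after 2 s without a magnitude excursion;
  without these the machine could latch in an intermediate state
  indefinitely.
- **Single-crossing transitions.** Unstable→Falling fires on the first ratio
  crossing; no persistence requirement.

Two engines execute the identical algorithm: an incremental per-sample
`step()` (the reference semantics, plain Python) and a numba-compiled kernel
used by `process_stream` and the optimizer (~10⁴ candidate evaluations per
search would be infeasible otherwise). The suite asserts event-level
equivalence of both against an independent brute-force implementation that
recomputes all features over full arrays.

## Evaluation

Clip-level scoring treats each labeled movement clip as one binary trial
(any event ⇒ positive). Continuous scoring matches events (by impact time)
against non-overlapping ground-truth fall windows with a ±2 s tolerance
(default; the matching window is not specified in the source protocol): one
TP per matched window regardless of extra events inside it, FPs are events
matching no window, and TN is reported as undefined — on an hours-long
recording there is no meaningful negative-trial count, which is why false
alarms are instead normalized to a 16.5 h wear day. Percentages are kept at
full precision internally and rounded half-up to one decimal only for
presentation. ROC points are (1 − Spec/100, Sens/100); TOC points plot hits
against hits + false alarms, with the diagonal marking "no false alarms" and
a horizontal line the total fall count.

## Threshold optimization

10 stratified 70/30 splits × 10 majority-class undersamplings × 100 uniform
random threshold draws per undersampling; each draw is ranked on its balanced
train set by Youden J ("training" a fixed random set means evaluate-and-rank;
there is nothing to fit by gradient), the best 50 are re-evaluated on the
split's test partition, and the overall best 50 by test J are returned.
Undersampling targets the minority count. The per-class train size is
round(0.7·n_c), half-up. Seeding: one master seed spawns independent child
streams for splitting, undersampling and candidate generation, so every
subset of the pipeline is independently reproducible.

Level selection takes the 10 best candidates, builds their ROC, and picks
medium = maximum J (the standard reading of the "optimal ROC point" given
that J is the headline selection metric), low = maximum specificity, high =
maximum sensitivity; ties break on the other coordinate, then on candidate
order. The invariant high.sens ≥ medium.sens ≥ low.sens follows (a
max-specificity point with higher sensitivity than the max-J point would
itself have the higher J).

Default bounds (a design choice; the published pipeline prints no bound
values) are centered on the physically meaningful ranges the generator's
phases occupy: magnitude deviation 0.15–0.45 g, ratio 0.8–1.8, impact
1.3–1.9 g, angle 30–55°, watcher movement 0.15–0.5 g.

## Synthetic data: what it emulates and what it does not

The generator replaces two unpublished datasets: a clip corpus (1399
non-fall + 1009 fall clips over a 39-type taxonomy, three wear positions)
and continuous ~40-minute sessions (six 6-minute scripted activities —
standing still, sitting, walking, running, standing with freedom of
movement, lying — with four falls interleaved, two fall menus across subject
groups, ~37–40 min total including inter-task pauses).

Each movement is a piecewise **magnitude profile** with band-limited noise
(σ 0.01–0.1 g by activity, first-order-filtered white noise) riding on a
unit gravity direction that tilts at scripted orientation changes; the whole
clip is then rotated by a random mounting rotation drawn per clip. Fall
clips always contain a free-fall phase (0.12–0.30 g for 150–450 ms, free-fall
direction 45–90° off the prior gravity axis), an impact spike (2.5–5.5 g,
60–100 ms), an orientation change of 60–120°, and ≥ 5.5 s of post-impact
stillness. Quick table drops share the free fall and the hard spike but keep
the orientation change below ~25°; recovery-type falls share all fall phases
but move again 2–3.5 s after impact, inside the watcher window. Walking
magnitude stays in [0.65, 1.7] g; pocket wear adds 1.8× gait noise. These
ranges were chosen once, as plausible human-movement scales that exercise
every transition rule, and make the corpus **separable by construction**:
there exist threshold sets inside the default bounds that classify every
clip correctly.

Consequences for interpretation: passing the optimizer-recovery test shows
the search machinery finds and generalizes a separating region when one
exists — it says nothing about the detection rates achievable on real human
falls, where amplitude distributions overlap (real published clip-level
operating points sit near 95/95, not 100/100). The generator models no
biomechanics, no elderly-vs-young movement differences, no soft/hard floor
variation, and its noise is stationary within a phase.

## Numerical and scale choices

- All features and the FSM run in float64; threshold comparisons are strict
  (`>`), so boundary equality never fires a transition.
- `vector_angle` clamps the normalized dot product to [−1, 1] before the
  arccos; zero vectors are rejected with the offending vector named.
- The optimizer-recovery suite runs 20 searches at 50 Hz on ~206-clip
  corpora (the full taxonomy scaled row-wise by 200/2408, half-up) with 20
  random sets per undersampling — the corpus size and draw count the
  package's own validation protocol fixes for a single-CPU run; the search
  structure (10 splits × 10 undersamplings) is unchanged.
- Clip-level ties in candidate ranking resolve by Python's stable sort, so
  equal-J candidates keep generation order.

## Known limitations

- The free-fall ratio weakens when the free-fall residual acceleration stays
  aligned with gravity at magnitudes near 0.6 g; such falls can be missed at
  higher `fall_ratio_min` values (real corpora report a few percent of
  missed falls for exactly this kind of atypical execution).
- A fall whose victim is still within 0.5 s of impact but moves later than
  5 s post-impact broadcasts an alert; conversely a conscious person lying
  still for 5 s after a hard bump triggers a false alarm — inherent to the
  watcher design, mitigated only by threshold choice.
- Continuous specificity is undefined by construction; cross-study
  comparisons must use FA/day.
- Fixed-point arithmetic of the embedded build is not emulated; this is the
  floating-point reference implementation.
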