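# Methods

## Model and assumptions

`pmnet` simulates event-based prospective memory (PM) as interactive
activation with response competition. The ongoing task (classify which
side carries the upper-case letter) and the PM task (press the PM key
when both sides show the same letter) are realized as two input–output
pathways over a shared, localist stimulus representation: 12 input
units (6 letter tokens × 2 positions), 3 letter-detection units, 3
output units (Left, Right, PM), 1 monitoring unit. The ongoing pathway
is direct (upper-case input → its side's output); the PM pathway is
indirect (inputs → letter detector → PM output) and is therefore more
sensitive to input degradation. Lateral inhibition within the output
and detector layers makes response selection winner-take-all. Top-down
monitoring is a single clamped unit feeding all detectors equally — a
content-free gain control on the PM pathway, graded rather than
all-or-none.

Assumptions worth keeping in mind: representations are localist (one
unit = one token at one position); processing time is measured in
abstract cycles, not milliseconds, and no mapping to physical time is
fitted; all trials are independent (no sequential effects, no
fatigue or learning across trials except the explicit Hebbian encoding
step in the single-detector variant).

## Trial dynamics

All activations start at 0; the two active input units are clamped to
`input_activation` and the monitoring unit to `monitoring_activation`.
Each cycle:

1. net inputs of the six free units (detectors, outputs) are computed
   synchronously from the current activation vector; each detector
   additionally receives the negative `detector_bias`;
2. free units are updated with
   `Δact = step·net·(act_max − act)` for `net > 0`, else
   `Δact = step·net·(act − act_min)`;
3. input and monitoring units are re-clamped to their nominal levels;
4. i.i.d. Gaussian noise (SD `noise_sd`) is added to **every** unit —
   clamped units included, so the slightly noisy clamp values are what
   other units read on the next cycle;
5. activations outside `[act_min, act_max]` are reset to the nearest
   bound;
6. the response rule is tested: if the most active output exceeds the
   runner-up by strictly more than `response_threshold`, the trial ends
   and the cycle count is the RT. Exact ties or at-threshold
   differences keep cycling (a measure-zero event under noise; the
   strict rule is the conservative deterministic choice). After
   `max_cycles` (500) the trial is recorded as a timeout error without
   an RT.

Ordering notes: noise precedes clipping (so the bounds are hard);
re-clamping happens after the update and before the noise, which is
what lets clamped units carry their noise into the next cycle's net
inputs. With `noise_sd = 0` the dynamics are a pure function of the
stimulus and parameters — the basis of several tests.

## Parameters

All scalars live in `ModelParameters` (flat YAML round-trip via
`configs/*.yaml`). Units: activations and weights are dimensionless;
RTs are cycles.

| parameter | default | role |
|---|---|---|
| `step_size` | 0.0076 | gain per cycle; sets the RT scale (~50 cycles for ongoing responses) |
| `noise_sd` | 0.0085 | per-cycle, per-unit Gaussian noise; sets RT dispersion, error rates, and the stochastic race |
| `response_threshold` | 0.14 | top-vs-second output difference needed to respond |
| `act_max`, `act_min` | 1.0, −0.16 | activation bounds; the shallow floor lets losing units carry limited inhibitory influence |
| `input_activation` | 1.0 | clamp of active inputs (0.9 in the degraded preset) |
| `monitoring_activation` | 0.78 | standard monitoring clamp (0 = none, 1 = high) |
| `detector_bias` | −1.86 | keeps detectors silent unless two same-letter inputs (or strong monitoring) coincide |
| `w_input_ongoing` | 0.51 | direct stimulus–response weight |
| `w_input_detector` | 1.0 | input→detector weight; equals the Hebbian learned weight of the encoding variant, so hard-wired and learned intentions are commensurate |
| `w_detector_pm` | 3.26 | detector→PM output weight; large, so modest detector activation competes with the direct pathway |
| `w_monitor_detector` | 0.85 | top-down gain per unit of monitoring activation |
| `w_lateral_output`, `w_lateral_detector` | −1.23, −0.99 | winner-take-all inhibition |
| `max_cycles` | 500 | timeout |

The signs are structural: pathway weights positive, lateral weights and
the detector bias negative (validated on construction).

### Calibration

The defaults are a calibrated set. Calibration proceeded in two
stages: (1) randomized search plus local refinement on a composite
loss over the behavioural quantities the model should exhibit — mean
ongoing RT near 50 cycles and rising with monitoring, a positive
intention-maintenance cost at standard settings, a positive
intention-superiority effect that grows with monitoring and reverses
without it, rare no-monitoring hits, ongoing accuracy ≥ 99% with few
false alarms, no timeouts, and the CV ordering ongoing > PM miss > PM
hit; (2) hand refinement jointly with the intention-encoding variant,
which ties several parameters down sharply: the Hebbian update with
learning rate 1 fixes the learned weights near 1, so `w_input_detector
= 1.0` makes the hard-wired model's no-monitoring target drive
identical to the deactivation variant's commission drive (`2 +
detector_bias`), and the presence of two inactive sibling detectors in
the standard model (absent in the single-detector variant) then
naturally yields far fewer bottom-up hits than commission errors — the
qualitative asymmetry both simulations show. `detector_bias` trades
commission errors against bottom-up hits; `w_monitor_detector` and
`monitoring_activation` set the monitoring dynamic range subject to
keeping nontarget detector drive below zero at high monitoring (false
alarm control).

Known residual misfits of the calibrated set, stated so that nobody
mistakes them for bugs: the intention-superiority effect runs larger
than intended (≈ 6.7 cycles at standard settings, ≈ 11–12 at high
monitoring, ≈ −1.5 with none — the sign pattern, including the
reversal, is robust); bottom-up-only hits are ≈ 0.5–1% rather than a
few percent; the encoding variant's ongoing accuracy is ≈ 97.6% and its
PM-miss RT ≈ 42 cycles (the intention-superiority effect is again
over-expressed); commission errors after 50% weight decay are ≈ 0.3%.

## Experiments

`run_condition` runs every stimulus a fixed number of times (12
nontargets × n, 6 targets × 2n, so target and nontarget totals match),
fully determined by a seed; each condition re-seeds its own generator.
Timeouts count as errors in all rate denominators but never enter RT
statistics. The intention-superiority effect is mean ongoing-correct RT
minus mean PM-miss RT (both miss subclasses pooled; >99% of misses
carry the correct ongoing response); the maintenance cost is the
ongoing-RT difference from a zero-monitoring baseline at the same input
level.

The dual-task variant (instructions: ongoing response every trial, PM
response *in addition* on targets) zeroes the output-layer lateral
inhibition and decouples the response rules: Left/Right is selected
when the two ongoing outputs differ by more than `response_threshold`;
the PM response fires when the PM unit's absolute activation exceeds
its own threshold (default 0.3 — absolute, because the PM unit has no
competitor in this architecture) within a response window (default 150
cycles, the analog of "press the PM button before the next trial").
The variant is a configuration for exploration; no quantitative claims
are attached to its defaults, and under them it reverses the
intention-superiority effect and the CV ordering, as a noncompetitive
architecture should.

## Intention encoding and deactivation

The single-detector variant removes two detectors and all hard-wired
input→detector weights (17 units). Encoding presents the target (active
units at 1) with an i.i.d. Gaussian perturbation (SD 0.15) on **all
12** input units — modelling trial-to-trial perceptual/contextual
variability — clamps the detector to 1 (no noise on the detector), and
sets each input→detector weight to the product of the two activations
(learning rate 1; the update overwrites, so a new intention replaces
the old). At test every trial draws a fresh perturbation of the same SD
that is *fixed for that trial's duration* (per-cycle dynamic noise
still applies on top): a per-trial perceptual sample, which is what
makes a trial-level encoding–retrieval similarity well defined.
Similarity is the Pearson correlation between the perturbed 12-unit
clamp patterns at encoding and at test (clamp levels, not evolved
activations). Each repetition presents the 17 non-target stimuli n
times each and the target 17n times (equal target/nontarget totals);
hit/false-alarm/accuracy rates and RT statistics are pooled over
repetitions. Deactivation re-runs the block with monitoring at 0 and
the learned weights multiplied by a decay factor (1.0 or 0.5; 0 erases
the intention, making previous targets ordinary nontargets — a test
anchors this).

## RT statistics

CV is SD/mean with the sample (n−1) SD; at the simulated ns the
convention is numerically irrelevant but is fixed for exactness. The
sample-size-matched "unbiased" CV repeatedly subsamples the large
(ongoing) condition *without replacement* down to the rare condition's
n and averages the CVs (default 100,000 repetitions; analyses here use
10,000–20,000, which changes estimates by well under 1%). Vincentized
group distributions: per subject, the sorted RTs are partitioned into
equal-probability bins by fractional allocation (observation k of n
contributes to bin b in proportion to the overlap of [k/n, (k+1)/n)
with [b/B, (b+1)/B)), bin means are taken, then averaged across
subjects. This interpolating convention is one of several defensible
quantile rules; it is deterministic, order-invariant, and makes bin
means provably non-decreasing. A shifted-lognormal generator provides
synthetic right-skewed RT samples so the statistics module is testable
without any simulation.

## Problem sizes and reproducibility

The test suite runs conditions at 200–4,000 trials per stimulus and the
encoding simulations at 12–40 repetitions; `scripts/acceptance.py` uses
10,000/20,000 trials per nontarget/target stimulus, 250 encoding
repetitions × 25 presentations, and 20,000 unbiased-CV resamples —
sizes chosen to put Monte-Carlo error well inside the effects of
interest while keeping a full run in the minutes range on one core.
Every stochastic entry point takes an explicit seed; batch runs derive
per-condition seeds deterministically, and written artifacts carry a
JSON manifest (parameters, seed, counts, version) sufficient to
regenerate them.

## Limitations

Localist coding cannot express focal vs nonfocal cue overlap (that
would need distributed stimulus features); cycles are not calibrated to
milliseconds, so only patterns and ratios — not absolute durations —
are meaningful; the parameter set is one hand-plus-search calibrated
point, not a fitted posterior, and no systematic parameter-space
exploration is attempted; phenomena that arise in noncompetitive
paradigms (where PM responses accompany ongoing ones) are outside the
standard architecture's explanatory scope by design, as the dual-task
variant illustrates.
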