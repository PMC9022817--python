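# Methods

## Model

The decision model is a two-unit attractor network: each unit's activation
represents the momentary attractiveness of one option and suppresses the
other unit through a logistic squashing function. Per Euler step of length
`dt` (time in dimensionless cycles),

    a_i <- a_i + dt * ( -leak * a_i + input_gain * I_i
                        + self_excitation * f(a_i) - inhibition * f(a_j) )
           + noise_sd * sqrt(dt) * eps_i,      f(a) = 1 / (1 + exp(-g (a - c)))

A trial starts with both drives switched on and ends when either unit
reaches the choice threshold (the response time, in cycles) or the cycle
budget runs out (TIMEOUT, excluded from analyses with a logged count).
Between trials the input is off and the state relaxes deterministically
toward rest; noise during the interval can be enabled but is off by
default, since the between-trial decay is conceptually a passive return to
baseline. Experimental ITIs in seconds are converted to cycles by the free
constant `cycles_per_second`.

Drives are the hyperbolically discounted option values normalized to a
constant sum (`budget`, default 1): `I_sn = V_sn / (V_sn + V_lf)`. The
normalization keeps total excitation independent of the absolute value
scale, which is what makes the value-masked design (same subjective ratio,
varying absolute values) behave identically trial to trial.

## Default parameters and how they were chosen

One fixed parameter set is used everywhere; no parameter is fitted to
data, and none is changed between analyses.

| parameter | default | role |
| --- | --- | --- |
| `dt` | 0.1 | Euler step (cycles); RT resolution |
| `leak` | 0.3 | decay toward rest; passive time constant 1/0.3 ≈ 3.3 cycles |
| `self_excitation` | 0.08 | recurrent gain; below leak/max(f(a)/a) so no self-sustaining state without input |
| `inhibition` | 0.45 | cross-unit suppression; with the input gain puts the symmetric deadlock at the steepest point of f, making it maximally unstable |
| `input_gain` | 0.67 | equal drives (0.5 each) place the symmetric fixed point at the squash midpoint 0.5 |
| `noise_sd` | 0.2 | per-step noise; large enough that the unattractive option is occasionally chosen, small enough that strongly unequal drives decide almost deterministically |
| `threshold` | 1.2 | between the deadlock (~0.5) and the winner fixed point (~1.4) |
| `resting_level` | solved (≈ −0.0077) | zero-input fixed point, computed from the other constants |
| `max_cycles` | 200 | trial budget; equal-input noiseless trials deadlock and time out |
| `cycles_per_second` | 8 | seconds→cycles calibration (see below) |
| `logistic_gain`, `logistic_center` | 10, 0.5 | squashing slope and midpoint |

The structure was chosen so that the qualitative regimes are provable
rather than accidental: the no-input system has the resting state as its
only attractor (`self_excitation · max_a f(a)/a < leak`), the symmetric
state under equal drives sits where `f` is steepest and is therefore
unstable in the difference direction (winner-take-all), and under zero
noise exactly equal drives stay on the symmetric trajectory below
threshold forever (deadlock → TIMEOUT), which is the documented tie-break.
Simultaneous threshold crossing with noise on is resolved uniformly at
random; it is measure-zero and has never been observed in testing.

`cycles_per_second` is a free constant nothing in the task pins down. It
was calibrated once so that the experimentally used ITIs span the decay of
the winner's residual activation: at 8 cycles/s, a 1.0 s interval leaves a
strong residual (stay probability ≈ 0.88 under equal drives), 1.3 s a
moderate one (≈ 0.75), 2.5 s little (≈ 0.54), and 20 passive time
constants (the "long delay", ≈ 8.3 s) none (0.50 within Monte-Carlo
error). All sequential predictions follow with this single setting; a
stronger decay or longer intervals simply erase them, which is itself the
model's ITI prediction.

## Valuation and estimators

* **Hyperbolic value.** `V = A / (1 + kD)` with `k ≥ 0` per distance unit
  (playing-field steps for the spatial designs, days for the
  questionnaire). The default simulation `k` for spatial designs is 0.3
  per field, which places the fixed-value design's ratio grid on both
  sides of indifference.
* **Indifference point.** Logistic fit of P(choose SN) against the value
  ratio `v_s/v_l` by penalized maximum likelihood (ridge 1e-4, grid-seeded
  BFGS); the estimate is the ratio at P = 0.5. All-one-option responders
  are flagged degenerate and returned at the boundary of the observed
  ratios instead of being extrapolated.
* **Categories.** Sequences are split into attractive-SN / neutral /
  attractive-LF at the tertiles of their signed distance to the
  indifference point — the minimal deterministic three-way rule; a
  median-split-with-neutral-band variant is available
  (`method="median_band"`). Identical distances all map to neutral.
* **Discount rate.** Kirby-style consistency scoring: candidate k values
  are the geometric midpoints between consecutive item-implied boundaries
  `(L/S − 1)/D` plus one candidate beyond each end; the estimate is the
  candidate agreeing with the most responses, ties resolved by the
  geometric mean. Over replicate questionnaires the median is reported,
  since the estimator lives on a discrete grid.

On the bundled 27-item table the deterministic rule at k = 0.01 chooses
the smaller-sooner option on 15/27 items (55.6%); the script and tests
compare the model's long-delay arm against this internally computed rate.

## Sequence statistics

* `count_switches` is the number of adjacent unequal choices; its parity
  equals the independent endpoint oracle (odd iff first ≠ last), which is
  property-tested on random sequences.
* The parity table cross-classifies sequences by first choice ×
  attractiveness category × even/odd switches, with the even-minus-odd
  difference score per cell. Whole sequences are used for short designs;
  30-trial sequences are split into five 6-trial subsequences first
  (`split_subsequences`), trailing remainders dropped with a logged count.
* The Markov summary estimates the four conditional probabilities from
  transition counts that never cross sequence or subsequence boundaries;
  TIMEOUT breaks a chain. The default perseveration index is the symmetric
  two-term form ½[(P(SN|SN) − P(SN|LF)) + (P(LF|LF) − P(LF|SN))]; a pooled
  P(stay) − P(switch) variant is available. The symmetric form is zero in
  expectation for any memoryless chooser regardless of option bias —
  verified against synthetic agents with bias 0.2–0.8. If one option never
  occurs as a previous choice the summary is flagged incomplete.
* Per-ITI analysis computes the summary within each ITI level and reports
  the short-minus-long index difference. Aggregation is per run: indices
  are computed within a run and contrasted across runs with the paired
  t contrast (`paired_contrast`), mirroring dependent-samples testing.
* RT contrasts are restricted to clear-preference categories; "preferred"
  is the category-attractive option. Simulated RTs are in cycles,
  empirical logs in seconds; the statistic is agnostic.

## Synthetic agent

`simulate_agent` draws first choices from the marginal preference `p_sn`
and later choices from the previous choice's marginal probability plus
`stay_boost`, with additive RT effects and truncated-normal RT noise. Its
transition matrix is exactly computable, so the analyses' estimates have
closed-form targets (the symmetric index converges to `2 * stay_boost`).
`recover_parameters` inverts the Markov summary (method of moments) and
regresses RT on the preferred/stay indicators. What the agent does *not*
emulate: value-dependent choice probabilities, RT distributions of real
participants, any ITI dependence, and any coupling beyond first order —
so passing recovery tests validates the bookkeeping of the analyses, not
the attractor model or human behaviour.

## Experimental designs

* **Fixed-value design (exp 1).** Full crossing of SN distance {2, 5} ×
  LF offset {1, 4, 7} × five value pairs summing the grid 10/100 … 50/60;
  one sequence per cell, lengths uniform on {4, 5, 6} (30 sequences,
  150 trials in expectation), order shuffled, ITI 1.3 s.
* **Value-masked design (exp 2).** Four attractiveness levels (−20%, two
  near-neutral ±0.001%, +20% relative to the supplied indifference point)
  × LF offsets {2, 4, 7} = 12 sequences of 30 trials; LF values uniform
  integers in [50, 99], SN values rounded half-up to keep the subjective
  ratio constant, clamped into (0, v_l) with a warning if the anchor is
  extreme. Reading the "equally attractive" level as two near-neutral
  levels is what reconciles a three-category manipulation with 12
  sequences; a 3-level variant is available by configuration.
* **Ascending/descending design (exp 3).** Eight-trial sequences; value
  pairs sum to eleven credits and are drawn per trial; SN distance
  {2, 3}; the LF offset starts in 1..8 and walks ±1 per trial with
  clip-and-hold at the bounds, every structural combination appearing in
  both directions (so descending paths are the mirror images of ascending
  ones); each distinct sequence is instantiated at both ITIs, 1.0 s and
  2.5 s.
* **Questionnaire schedule.** The 27 items in fixed order, as immediate
  (distance 0) vs delayed offers; the short and long conditions differ
  only in the inter-item interval (defaults: 1.3 s and 20 passive time
  constants). Both arms share per-rep random seeds (common random
  numbers).

## Problem sizes

The shipped checks use: 1000 six-trial sequences per attractiveness
condition for the parity and RT statistics; 450 sequences per ITI level
(2250 transitions each) for the ITI comparison; 200 replicate
questionnaires per delay arm; 50,000 trials per bias level for the
memoryless-agent calibration; 20 seeds × 5000 trials for parameter
recovery. These sizes put the Monte-Carlo error well inside every margin
being asserted while keeping a full run in tens of seconds.

## Known limitations

* The exact functional form is the canonical leaky mutually-inhibitory
  pair with logistic squashing; other squashing choices or bounded
  activations would serve equally, and no claim rests on the specific
  constants beyond the qualitative regimes documented above.
* One input per option: multi-attribute valuation (weighing value and
  distance separately) is out of scope by design.
* No fitting of model parameters to human RT distributions, no
  within-trial kinematics, and no rendering of the game environment.
* Empirical test statistics of human samples (t, F, effect sizes from the
  original studies) are facts about those samples and are not
  recomputable here; the package reproduces the design counts and the
  model-level predictions only.
* The bundled item table is the standard 27-item instrument; a different
  transcription would shift the deterministic SS rate and the item grid,
  though not the direction of the delay bias.
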