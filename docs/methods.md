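# Methods

## Model

`hrlsim` simulates homeostatic behaviour as tabular reinforcement
learning in a homeostatic space. The agent carries an internal state
vector `H_t` (one component per regulated nutrient; abstract
internal-state units), a table of action values `Q(a)`, and one taste
predictor `K̂(a)` per action.

**Drive and reward.** The drive is the distance of the state from the
setpoint, `D(H) = (Σ_i |H*_i − H_i|^n)^(1/m)`. Reward is the drive
reduction across the trial's transition:
`r = D(H_t) − D((1 − 1/τ)H_t + K)`, where the decay factor `(1 − 1/τ_i)`
models per-trial nutrient loss and `K` is the intake vector that enters
the *reward* computation. Two reward modes exist:

* `actual_intake` — `K` is the taken action's true delivery; reward
  tracks the physical state change.
* `predicted_taste` — `K` is the taken action's learned taste predictor
  `K̂(a)`, plus an optional ambient oral stimulus. Taste then acts as a
  forecast of the internal change: a flavour can be rewarding without
  changing the state, and a gastric infusion changes the state without
  ever generating reward.

The ambient stimulus enters the reward prediction on **every** trial,
whatever the action, and never enters the state transition. This single
mechanism is what lets constant oral salt stimulation reinforce
*do-nothing* (its predicted next state moves toward the setpoint "for
free"), which is the heart of the oral-stimulation effect.

**Learning and choice.** Only the taken action learns:
`Q(a) ← Q(a) + α_Q (r − Q(a))` and `K̂(a) ← K̂(a) + α_K̂ (K(a) − K̂(a))`,
both one-step delta rules with fixed points at the reward and the true
intake respectively. Choices are softmax in the *effective* values
`Q'`: `P(a) ∝ exp(β Q'(a))`, computed with max-subtraction (numerically
identical by translation invariance). β is constant within an
experiment.

**Tonic bias.** When configured, a constant `lpbn ≥ 0` is subtracted
from one action's value at selection time only; with `dreadd_on` an
additive `drd` cancels it. The net offset is applied as a single sum so
that `drd = lpbn` restores the unbiased value *bit-for-bit* — the
cancellation equivalence (identical trajectories at identical seeds) is
exact, not approximate. Stored values never see the bias.

**Trial order.** Select (bias → softmax → draw), compute reward, update
Q and K̂ of the taken action, then transition the state with the true
intake. Decay applies on every trial including do-nothing. States are
validated, not clamped: with `τ ≥ 1` and `K ≥ 0` a non-negative state
stays non-negative, so a negative state signals a configuration error
rather than being silently clipped.

## Parameters and defaults

Every shipped value lives in `src/hrlsim/configs/*.yaml`; nothing is
defaulted at run time. The shared choices:

| parameter | value | meaning |
|---|---|---|
| `H*` | 50 | setpoint, internal-state units |
| `n`, `m` | 4, 3 | drive exponents, from the original HRL drive distance |
| `α_Q` | 0.07 | value learning rate (1/trials) |
| `α_K̂` | 0.2 | taste-predictor learning rate (predictors start pre-learned, so this is inert unless `K̂_0 ≠ K`) |
| `β` | 1.0 | softmax inverse temperature |
| `τ` | 150 trials (30 in the infusion test) | decay constant |

One trial is the time unit; the infusion test's 100 trials correspond to
a 600 s session (6 s/trial, metadata only).

The supplementary table holding the original simulations' exact
parameters is not available in the main text, so the shipped values were
fixed by calibration against the published regulation narrative: with
intake `K = 1` per trial, a 100-agent sodium-intake cohort reaches
P(intake) > 0.95 at median trial ≈ 19, first overshoots the setpoint at
≈ 67, and returns below it at ≈ 135 — the published ≈ 20 / ≈ 80 / ≈ 140
timeline within its stated ±30% tolerance. These medians are stable to
±2 trials across base seeds. Calibration trade-offs worth recording:
larger `β` or `α_Q` reaches the probability threshold too early; larger
`K` accelerates the climb (early overshoot); `τ` mostly stretches the
post-overshoot return.

Experiment-specific choices:

* **Infusion test (`sim2_infusion`).** `τ = 30`, `K = 2.5`. With slow
  decay the gastric pre-load simply saves the agent the climb-phase
  licks (`H*/2K` of them), producing a spurious control-vs-IG gap;
  faster decay makes maintenance intake dominate the totals, and the
  pre-load — which decays away — leaves total intake essentially
  unchanged, as observed in the modelled assay. The ambient oral
  stimulus is 40 (a "strong" salty taste, near-setpoint prediction from
  a depleted state); its magnitude is a config value.
* **Two-bottle tests (`sim3_two_bottle`, `sim4_dreadd`).** Water
  delivers (2.5, 0); saltwater delivers (1.0, 2.5) — a positive water
  component, since saltwater must partially relieve thirst for
  water-depleted agents to show the observed non-negligible saltwater
  intake. Depleted dimensions start at 0, fulfilled ones at the
  setpoint.
* **DREADD (`sim4_dreadd`).** `lpbn = drd = 4.0`, initial saltwater
  `Q = lpbn` (so effective values start level and the first choice is
  uniform). The bias only bites where Q-values are small — i.e. in the
  maintenance phase near the setpoint — so its strength sets the size of
  the DREADD contrast; 4.0 yields a robust saltwater contrast in both
  depletion conditions while leaving water intake of water-depleted
  agents within ~12% between DREADD and control.

## Seeding

Cohort member `i` draws its seed from numpy's
`SeedSequence([base_seed, i])`, and experiment group `g` derives its
cohort base seed from `SeedSequence([run_seed, g])` — disjoint,
platform-stable streams; each trial consumes exactly one uniform draw.
Reruns at the same seed are byte-identical down to the CSV output (CSV
floats are written as `%.17g` and parsed with the round-trip parser).

## What the simulations do and do not show

All experiments are self-contained simulations; there is no animal
data in the package. A passing ordinal pattern (e.g. DREADD >
control saltwater intake) shows the model mechanism reproduces the
qualitative published behaviour under the shipped parameters — not that
the parameters are physiological. Known simplifications:

* a single external state and discrete trials; no inter-trial interval,
  no separate timescales for taste, gut and blood compartments;
* water and sodium contribute symmetrically to the drive; no osmotic
  hierarchy between them;
* the DREADD manipulation is all-or-none (`drd = lpbn` exactly);
* one-step Rescorla–Wagner learning — no eligibility traces or
  multi-state bootstrapping, so preference reversals take learning time;
* the oral-stimulation group is strongly bimodal across agents (a
  first-trial lock-in between do-nothing and intake under the large
  ambient prediction), so its cohort *median* intake can sit at 0 for
  some seeds; the suppression relative to control holds for every seed
  tested.

## Numerical notes

Softmax uses max-subtraction; probabilities sum to 1 within 1e−12 and
sampling validates the distribution to 1e−9. `τ = 1` (total loss per
step) is the smallest legal decay constant; `τ < 1` is rejected rather
than allowed to oscillate the state's sign. `α_Q ∈ (0, 1]`;
`α_K̂ ∈ [0, 1]`, where 0 freezes a pre-learned taste predictor. Ties in
action values need no tie-breaking — sampling is from the softmax
distribution itself.
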