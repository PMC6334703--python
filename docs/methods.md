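# Methods

## The elicitation model

The engine implements the lead-time variant of the time trade-off (TTO)
task. Each iteration offers a choice between Life A (*a* years in full
health, then death) and a static Life B (*l* years in full health, then *t*
years in the health state under valuation, then death). At the indifference
point the health utility of the state is

> u = (a − l) / t,

an interval-scale score anchored at 1 (a = l + t, the state is as good as
full health), 0 (a = l, as good as death) and bounded below by −l/t (a = 0),
so states worse than death are measurable. The conventional (no lead time)
variant is provided as the standard u = a / t scoring convention for
completeness; the engine's interview loop itself always runs the lead-time
task.

### Parameters

| parameter | units | default | role |
|---|---|---|---|
| `lead_time_l` | years | 10 | full-health lead prepended to both lives; sets the utility floor −l/t |
| `disease_time_t` | years | 10 | time in the health state in Life B; held constant across iterations |
| `grid_step` | years | 0.5 | resolution of presentable Life A durations; must divide l + t |

With the defaults, Life A durations live on {0, 0.5, …, 20} years and
utilities on a 0.05 grid spanning [−1, 1].

### Iteration schedule

The search starts at the maximum a = l + t (20 years) and maintains a
bracket [lower, upper] of durations consistent with the choices so far:

* **Life A** chosen → the indifference point lies below → upper ← a;
* **Life B** chosen → lower ← a;
* **equivalent** → terminate (`EQUIVALENCE`) at the presented duration.

The next presented duration is the bracket midpoint snapped **down** to the
grid (a deterministic tie-break). When the bracket has shrunk to one grid
step the search terminates (`RESOLUTION`) and the indifference point is the
bracket midpoint — unbiased under a uniform prior within the bracket — with
one exception: a lower bound of zero that was never actually presented is
probed first. That terminal floor probe is what makes the censoring branch
reachable: a respondent who prefers Life A even at 0 years (immediate death
over Life B) terminates as `FLOOR`, is scored at the formula floor u = −l/t
rather than extrapolated beyond the formula's domain, and carries the
`FLOOR_CENSORED` flag. Every interview terminates within
⌈log₂((l+t)/grid_step)⌉ + 2 = 8 iterations for the default task; the driver
enforces this bound.

The schedule is deliberately isolated behind `begin_task`/`apply_choice`, so
an alternative published probe sequence (titration, ping-pong) could be
substituted without touching scoring, navigation or export. No such
alternative is included.

### Dominance handling

Choosing Life B when Life A offers the full l + t years in full health
implies the disease state beats full health — a logical inconsistency. The
default policy mirrors an interactive pop-up: warn and re-ask the same
duration once, then record the repeated choice with the
`DOMINANCE_VIOLATION` flag (the bracket then collapses at the top and the
task scores u = 1, flagged). Batch callers can select the `record` policy to
log the flagged choice silently. This is the only (duration, choice) pair
per task that triggers the check.

## Survey queue and randomization

Task order is controlled by one uniform draw `mod6 ∈ {1,…,6}` made when the
preliminary instrument completes, plus one boolean condition per task
instrument evaluated over completion flags coded 2 (complete) / 0
(incomplete). The conditions are stored verbatim in the project config and
parsed by a small grammar: `[variable]` references, numeric literals (curly
or straight quotes accepted; quoted numerals compare **numerically**, so
`[mod6]<"3"` means mod6 ∈ {1,2}), operators `=`, `<`, `+`, `and`, `or`, and
parentheses. Missing variables evaluate as 0, which makes every condition
total before any task has been done. Navigation is "auto start": the unique
instrument whose condition holds and whose own flag is 0 is presented next.
Ambiguous eligibility (two instruments at once) and deadlock (none, with
tasks remaining) are hard errors rather than silently resolved, so broken
user-supplied conditions surface immediately; `tto verify-queue` prints the
six induced orders and an eligibility table over every reachable flag state
as a mechanical proof that the shipped conditions produce all 3! orders with
exactly one eligible instrument at each step.

## Validation

Free-text fields validate by format (integer, number, email, ISO date) and
numeric range; choice fields accept only their listed codes. Errors are
returned as values — a stable kind (`FORMAT`/`RANGE`) plus a user-facing
message — never raised, so front ends can render or localize them. The
default age range 18–110 is a configurable choice; the email check requires
a single `@` with non-empty local and domain parts, deliberately short of
full address-grammar parsing. Pop-up wording throughout is original text.

## Simulated respondents

* **Threshold** (deterministic): true utility u*, answers *equivalent*
  whenever the presented utility is within eps of u*, Life A above, Life B
  below. The default eps = grid_step/(2t) = 0.025 ties equivalence to the
  measurement grid: any u* on the 0.05 utility grid is recovered exactly
  (the search provably visits its grid point), and any u* in [−1, 1] is
  recovered within half a grid step.
* **Logistic** (stochastic): P(Life A) = expit((u(a) − u*)/s); *equivalent*
  is never chosen, forcing resolution termination. The logistic link was
  chosen for its closed form; the respondent is a plain callable, so probit
  or any other model drops in.

The cohort simulator completes the full pipeline per record — random valid
demographics and EQ-5D-5L answers, the mod6 draw, queue navigation, one
interview per task — and is bitwise reproducible given a seed. Its default
true utilities are drawn per respondent from N(0.75, 0.15²), N(0.55, 0.15²)
and N(0.30, 0.15²) for the mild/moderate/severe states, clipped to [−1, 1]:
plausible dementia-severity values chosen once for realism, not fitted to
any dataset.

### What the simulations do and do not show

Simulated respondents obey a coherent underlying utility (up to logistic
noise); passing recovery tests therefore demonstrates that the *engine*
introduces at most half a grid step of error, not that human answers are
this well behaved. Real respondents exhibit framing effects, fatigue,
non-transitive choices and clustering at salient durations, none of which
the choice models emulate. EQ-5D-5L responses are captured but not
index-scored, and the simulator fills them uniformly at random — they carry
no association with the TTO utilities.

## Numerical choices

Durations are floats kept on the grid by rounding to 10 decimals after each
snap; comparisons use a 1e-9 tolerance. Midpoints between grid points snap
downward for determinism. Resolution-terminated tasks score at the bracket
midpoint (a half-grid point). Equality in queue conditions is numeric with
the same tolerance.

Problem sizes in the test suite — 41-point utility grids, 500 replicate
interviews for the noise-monotonicity check, 6000-draw chi-square uniformity
tests at α = 0.001 — were chosen as comfortably powered for the properties
checked; the whole suite runs in a few seconds.

## Design decisions and limitations

* The exact probe sequence of the original interactive implementation is not
  published; bisection-from-the-maximum with the terminal floor probe is
  this package's documented schedule, consistent with the printed anchors
  (start at 20 years; t constant), and is not claimed to match any
  particular deployment.
* Health-state vignettes ship as numbered placeholders ("Description 1–3");
  study-specific wording, and demographic category codings
  (education/income), are config-level content with sensible defaults.
* Completion flags are integers 2/0 (not booleans) because the queue
  conditions do arithmetic on them (`[part2_complete]+[part3_complete]="4"`).
* The data dictionary CSV carries the instrument/field layer plus the TTO
  parameters (as an `@TTO(l=…;t=…;step=…)` field annotation); completion-flag
  variable names and queue conditions are project-level settings that live in
  the JSON/YAML config, mirroring how survey platforms separate the two.
* Composite-TTO scoring (conventional for u ≥ 0, lead-time below) is not
  enabled as a mode; only the scoring functions for both variants are
  exposed. Visual-analogue and standard-gamble elicitation, alternative
  iteration methods, EQ-5D index scoring, and web hosting / user accounts
  are out of scope.
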