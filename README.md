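# ttocapi

A scriptable engine for **lead-time time trade-off (TTO) health-utility
elicitation** — the computer-assisted personal interview (CAPI) task used in
health-state valuation studies, rebuilt as a standalone Python package so the
whole pipeline can be driven interactively, from scripts, or by simulated
respondents with no survey platform and no human in the loop.

## The task

A TTO interview values a health state by offering repeated choices between
two hypothetical lives:

* **Life A** — *a* years in full health, then death;
* **Life B** — *l* years in full health, then *t* years living in the health
  state being valued, then death.

The *lead time* *l* prepended to both lives keeps states judged *worse than
death* on the scale. The interview starts at the longest Life A
(*a* = *l* + *t* = 20 years for the default *l* = *t* = 10 task) and adapts
*a* by bisection on a 0.5-year grid — choosing Life A moves the search down,
Life B moves it up — until the respondent declares the two lives equivalent
or the bracket closes. The health utility of the state is then

```
u = (a − l) / t
```

anchored at 1 (full health, *a* = 20), 0 (death, *a* = 10) and −*l*/*t* = −1
at the floor (*a* = 0).

The package ships the four-instrument Alzheimer's-disease (AD) valuation
project it was built around: a preliminary instrument (demographics, a
question about knowing someone with AD, EQ-5D-5L) followed by Mild, Moderate
and Severe AD task instruments. A single uniform draw `mod6 ∈ {1,…,6}` plus
one boolean survey-queue condition per instrument presents the three tasks in
one of the six possible orders, with exactly one eligible instrument at every
step. Inconsistent choices (preferring the disease life over an equally long
full-health life) trigger a logical-error warning and re-ask; free-text
fields carry format/range validation. Records and a REDCap-style data
dictionary export as CSV, independent of the randomized task order.

## Worked example

```python
from ttocapi import TTOParams, ThresholdRespondent, run_interview

params = TTOParams()            # l=10, t=10, 0.5-year grid
transcript = []
result = run_interview(params, ThresholdRespondent(u_star=0.35),
                       transcript=transcript)
for row in transcript:
    print(f"iteration {row['iteration']}: Life A = {row['a']:>4} years"
          f" -> {row['choice']}")
print(f"indifference at {result.indifference_a} years, "
      f"utility = {result.utility:.2f} ({result.termination_reason.value})")
```

prints

```
iteration 1: Life A = 20.0 years -> LIFE_A
iteration 2: Life A = 10.0 years -> LIFE_B
iteration 3: Life A = 15.0 years -> LIFE_A
iteration 4: Life A = 12.5 years -> LIFE_B
iteration 5: Life A = 13.5 years -> EQUIVALENT
indifference at 13.5 years, utility = 0.35 (equivalence)
```

The simulated respondent holds a true utility of 0.35; five iterations of
bisection reach the grid point whose utility matches it exactly
(13.5 = 10 + 0.35 × 10 years). A whole cohort runs the same way:

```python
from ttocapi import default_project, simulate_cohort
records = simulate_cohort(60, default_project(), seed=42)
```

gives 60 complete records (randomization draw, demographics, EQ-5D-5L and
all three AD utilities); with the default respondent model the mean
recovered utilities are 0.717 (mild), 0.560 (moderate) and 0.293 (severe).

## Command line

```
tto verify-queue                 # print the six task orders + uniqueness proof
tto run --seed 3 --out rec.csv   # interactive interview
tto simulate --n 60 --seed 7 --out sim/   # cohort + recovery table CSVs
tto export-dict --out dictionary.csv      # REDCap-style data dictionary
```

`--config` accepts a JSON/YAML project definition (see
`ttocapi.save_project` for the schema) or `default` for the shipped AD
project.

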