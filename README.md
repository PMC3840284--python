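# aeforage

A discrete-event simulator and analysis toolkit for the **adjusting-energy
(AE) reinforcement schedule** — an operant-foraging procedure in which the
controlling variable is the *energy expenditure* of a response rather than
a response count.

## The problem

Optimal foraging theory (OFT) predicts that animals forage so as to
maximize their net rate of energy intake, which makes energy expenditure a
first-class quantity. Classic operant simulations of foraging proxy
expenditure by response counts (fixed-ratio schedules) or response time,
neither of which converts directly to energy. The AE schedule closes that
gap on a touch surface: a subject pecks a circular response area twice, and
the pair is reinforced only if its **interresponse energy**

```
IRE = IRD² / IRT²        (J, per unit body mass)
```

exceeds the current requirement, where IRD is the straight-line distance
(m) between the two peck locations and IRT the elapsed time (s) between
them. This is the kinetic-energy form `E = M·D²/T²` with body mass `M`
held at 1 kg, since a single subject's mass is approximately constant over
an experiment. For example, a 0.25-J requirement demands an IRD greater
than 0.05 m when IRT = 0.1 s, and greater than 0.1 m when IRT = 0.2 s.

The AE requirement is **titrated** against a fixed-ratio (FR) alternative:
sessions run 60 trials (90-min cap) in 15 blocks of four — two
forced-choice trials (one per key, pseudorandom order) then two
free-choice trials. If both free choices in a block take the AE key the
requirement rises 0.001 J for the next block; both FR lowers it 0.001 J;
a split leaves it unchanged, and the last block's adjustment carries into
the next session. Forced AE failures re-run the AE schedule phase after
the 3-s ITI (up to five correction trials). A condition runs at least 18
sessions and ends when the session-mean requirement is stable (extremes
outside the last six sessions, no trend, and the last-six mean within
7.5 % of the preceding six). The stable **indifference point** — the mean
requirement over the last six sessions — estimates the energy value of
the FR requirement, and the **total energy per reinforcement (E/RFT)**
sums the IREs of every free-choice AE attempt (failures included) emitted
per reinforcer.

Because live subjects are not required, the package drives the schedule
with configurable synthetic agents: a logistic chooser with indifference
requirement `a*` and temperature τ, stationary lognormal/uniform peck
kinematics, plus deterministic (always-AE, always-FR, alternating) and
requirement-tracking (adaptive) variants.

## Worked example

```python
from pathlib import Path
from aeforage import load_config, run_experiment

Path("c.yml").write_text("seed: 11\nconditions: [15, 30, 60, 30, 15]\nmax_sessions: 120\n")
res = run_experiment(load_config("c.yml"))
print(res.table[["fr_requirement", "indifference_point", "mean_ire",
                 "e_per_rft", "n_reinforcers", "series"]].to_string(index=False))
print("pearson r=%.3f" % res.stats.pearson_r)
```

prints

```
 fr_requirement  indifference_point  mean_ire  e_per_rft  n_reinforcers     series
             15            0.020167  0.129715   0.160583             71  ascending
             30            0.040344  0.168521   0.250835             58  ascending
             60            0.080956  0.117615   0.271206             38  ascending
             30            0.039156  0.151328   0.218556             62 descending
             15            0.020356  0.117883   0.143720             73 descending
pearson r=0.872
```

Each row is one condition of the ascending-then-descending FR
series. The titration recovers the agent's built-in indifference map
(`a*` = 0.02/0.04/0.08 J for FR 15/30/60) from behavior alone, the
descending series confirms the ascending one, the mean IRE stays flat
across requirements (the stationary agent does not work harder per peck),
and E/RFT rises with the requirement because failed attempts accumulate —
the schedule controls *total* energy per reinforcer even when per-response
energy is uncontrolled.

## Command line

```bash
aeforage run --config c.yml --out out/          # simulate, write CSV event logs
aeforage analyze --logs out/ --out tables/      # stability + condition summaries
aeforage report --logs out/ --out figs/         # trajectory/indifference/IRE/E-RFT figures
aeforage fixtures --preset always-ae --out fix.csv   # tiny deterministic logs
```

Config files are YAML; only `seed` is required. Sections `schedule`
(`ae_step`, `iti`, `trials_per_session`, `session_time_cap`,
`max_correction_trials`, `min_sessions_per_condition`, ...), `geometry`
(`response_area_diameter`, `key_diameter`, `key_center_separation`) and
`agent` (`preset` plus any agent parameter) override the standard
defaults; top-level keys are `conditions`, `ae_start`, `output_dir`,
`max_sessions`, `trend_method`. Unknown keys are rejected by name. Event
logs are plain CSV with a version-stamped header and round-trip
losslessly.

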