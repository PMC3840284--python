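# Methods

## The energy statistic

The package measures the energy expended between two consecutive pecks as

    IRE = M · IRD² / IRT²

with the interresponse distance IRD in meters (straight-line distance
between the two peck locations), the interresponse time IRT in seconds,
and the body mass M fixed at 1 kg. Mass is approximately constant for one
subject across an experiment, so IRE is energy per unit body mass; it is
reported in joules by the field's convention. `energy_expenditure` keeps
mass as an explicit argument so the general form stays available;
`compute_ire` applies the unit-mass convention throughout the simulator.

Pecks are treated as dimensionless points in continuous planar meters
with the origin at the center of the circular response area. No touch
panel quantization is modeled, and whether a real measurement would use
touch centroid or first contact is irrelevant for point pecks.

**Reinforcement is strict**: an AE attempt succeeds iff IRE > requirement.
The boundary pair (IRE exactly equal to the requirement) fails, which is
why `min_ird_to_meet(a, irt) = irt·√a` is documented as an infimum — the
returned distance itself does not reinforce.

## The schedule state machine

A trial is: choice phase (forced trials light one key, free trials query
the agent; left/blue = AE, right/red = FR), schedule phase, reinforcer
access (4 s) if earned, ITI (3 s). FR consumes `fr_requirement` pecks and
always reinforces; AE consumes one peck pair and reinforces on strict
exceedance. On *forced* AE failures the AE schedule phase re-runs after
the ITI as a correction trial, at most five times; after the fifth failed
correction the trial ends unreinforced and the next trial's choice phase
follows. Free-choice AE failures end the trial unreinforced with no
correction — corrections exist to keep forced-trial exposure from
extinguishing responding, and are tied to forced trials only.

Sessions run `trials_per_session` (60) trials in blocks of four (two
forced — one per key, order shuffled per block from the session RNG —
then two free), ending early at the session time cap (5400 s), checked at
trial boundaries; a trial that starts before the cap runs to completion.
The titration applies after each completed block: both free choices AE →
+`ae_step` (0.001 J); both FR → −`ae_step`, clipped at the floor; mixed →
unchanged. A session that ends mid-block contributes no adjustment from
the incomplete block, and the carryover into the next session is the
requirement after the last *completed* block's adjustment.

Numerical choices:

- Requirements are snapped to 12 decimal places after every adjustment so
  that long chains of ±0.001 J steps remain exactly representable and
  logs diff cleanly.
- The requirement floor is 0.001 J (one step above zero). A zero
  requirement would make every moving peck pair reinforcing and the
  titration semantics vacuous; the floor keeps the schedule meaningful at
  the bottom of its range. (`AEState` accepts an explicit floor of 0 for
  degenerate-case testing.)
- The initial requirement of the first session defaults to `ae_start` =
  0.010 J, inside the band that titrated requirements occupy under the
  default agents; sensitivity to it is a test concern, not an assumption.
- A hard cap (`max_sessions`, default 200) guarantees termination; hitting
  it raises an error that carries the partial logs.

Timing: choice latency (default 0.5 s, fixed) precedes the choice peck
and, again, the first schedule-phase peck; schedule-phase pecks are
separated by sampled IRTs; reinforcer and ITI durations are fixed. This
makes the 90-min cap binding for slow agents while default sessions
finish in roughly 10 simulated minutes.

Randomness: each session's RNG stream is derived from
`(master seed, session index)` through `numpy.random.SeedSequence`, and
each condition of an experiment from `(master seed, condition index)`, so
sessions and conditions are individually reproducible and insertion-order
independent. All derived seeds stay below 2³¹.

## Synthetic agents

Agents emulate the behavioral regularities the schedule assumes, not any
particular animal:

- **Choice**: P(AE) = 1/(1 + exp((a − a\*)/τ)) — a logistic in the current
  requirement `a`, centered on the agent's indifference requirement `a*`
  (J) with temperature τ (J, default 0.005). `a*` is specified per FR
  requirement through a map (default 0.02/0.04/0.08 J for FR 15/30/60),
  monotone in the ratio because larger ratios are worth more energy; the
  map's values are a calibration, not an empirical claim.
- **Kinematics** (stationary agents): IRT ~ lognormal(ln 0.35 s, 0.4);
  peck coordinates uniform in the response circle (or an isotropic
  Gaussian truncated to it). These defaults put typical IREs in the
  0.01–0.2 J band that titrated requirements occupy. Crucially, the
  stationary agent's kinematics are independent of the requirement —
  the flat-mean-IRE regime in which the schedule controls total energy
  per reinforcer through the failure rate rather than per-response
  energy.
- **Deterministic variants** (always-AE, always-FR, alternating) exercise
  the titration mechanics exactly; the alternating agent is the
  immediately, perfectly stable subject.
- **Adaptive agent**: places its second peck at a distance aimed so IRE
  lands near `ire_gain·a + ire_base` with lognormal noise, for probing
  how analyses behave when subjects do track the requirement.

What the generator does **not** emulate: learning or autoshaping history,
within-session satiation or warm-up, body-mass drift, biomechanical peck
trajectories, inter-peck spatial correlation, or individual-subject
parameter differences beyond what the parameters express. Passing tests
therefore validate the schedule's mechanics and the analytics' estimands
under known ground truth — they do not certify that real pigeons satisfy
the agents' assumptions.

## Analytics

**Stability** (three criteria over session-mean requirements, evaluated
once a condition has at least 18 sessions; the check itself needs 12):

1. Neither the condition-wide maximum nor minimum session mean occurs in
   the last six sessions. Ties break toward failure, except that an
   exactly constant series — where every session is both extreme — passes:
   the criterion's intent is to exclude extremes, not punish flatness.
2. No systematic trend over the last six sessions. Default
   operationalisation: two-sided t-test on the least-squares slope,
   non-significant at α = 0.05; a strict-monotonicity check is available
   via `trend_method="monotone"` since both are defensible readings of
   "no systematic upward or downward trends".
3. The last-six mean differs from the preceding-six mean by at most
   7.5 % (denominator: the preceding-six mean). The comparison carries a
   1e-9 absolute tolerance so the exact boundary case is not decided by
   float rounding.

**Indifference point**: arithmetic mean of the last six session means.

**E/RFT**: over the free-choice AE trials of the last six sessions (the
analysis window the indifference point uses), consecutive AE free-choice
trials form runs terminated by a reinforced trial; a run's energy is the
sum of all its attempts' IREs, failures included, and E/RFT is the mean
run energy. Three boundary decisions: runs never span session boundaries;
interleaved FR trials neither break nor contribute to a run (runs are
defined on the within-session subsequence of free-choice AE trials); and
trailing failures with no terminating reinforcer in their session are
excluded from run totals — energy spent toward a reinforcer never earned
belongs to no reinforcement. If a condition earns no reinforcer at all,
E/RFT falls back to the total IRE of every attempt. For a stationary
agent this statistic has a renewal-process expectation
E[E/RFT] = E[IRE]/P(IRE > a) (Wald's identity with a geometric stopping
time), which the tests use as an independent oracle.

**Cross-condition statistics**: Pearson correlation of E/RFT with the
titrated requirement (absent with fewer than two conditions), and a
Friedman test of the FR effect on indifference points when at least three
FR levels have two or more replicates each (replicates as blocks,
truncated to the shallowest level). Under the default condition series
15-30-60-30-15 the middle level has a single visit, so the Friedman test
is reported as absent; both tests are standard routines from scipy, not
quantities this package defines.

## Problem sizes in the test suite

The suite's stochastic checks use sizes chosen to keep sampling error
well below the effects they measure while the whole suite runs in
seconds: indifference-point recovery uses 20 replicates of 40 sessions
(logistic agent, a\* = 0.03 J, τ = 0.005 J, ±3 SE across replicates);
E/RFT calibration uses 12 fixed-requirement sessions per level at
{0.01, 0.03, 0.05, 0.10} J against a 200 000-draw Monte-Carlo oracle;
IRE stationarity uses two-sample Kolmogorov–Smirnov tests at n = 2000
per requirement level (α = 0.01).

## Known limitations

- The E/RFT session-boundary rule introduces a small selection effect
  (runs completing inside a session are slightly shorter than the
  unconditional run length); with 30 free-choice AE trials per session it
  is far below the statistic's sampling error, and the tests bound the
  two jointly against the renewal oracle.
- The agents' indifference map is an input, not a fitted quantity; the
  package recovers it but cannot validate it against animals.
- Choice latency is fixed rather than sampled, so session durations vary
  only through IRTs and failure counts.
- The simulated clock omits hardware realities (hopper travel, panel
  force, lighting transitions); durations are the procedural constants
  only.
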