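# Methods

## The decision problem

During emergence from general anesthesia the anesthesiologist must keep
ventilating (mechanically or by bag) until spontaneous breathing (SB)
returns, then stop and extubate.  Stopping too early causes apnea and
desaturation; continuing against recovered respiratory effort causes
patient–ventilator asynchrony with airway-pressure spikes, tachycardia and
hypertension.  The package casts each second of the emergence phase as one
step of a Markov decision process with a binary action (ventilation on/off)
and learns a control policy offline from logged trajectories, then
quantifies how disagreement between the learned and the recorded clinician
policy relates to instability and postoperative outcomes.

## Synthetic cohort

Because real operating-room registries cannot ship with a package, a
simulator generates cohorts with known ground truth.  Its design goal is
not physiological fidelity but *identifiability*: every preprocessing rule,
reward term, and statistical analysis downstream has a planted signal it
can recover.

* **Timeline.** Recording starts 30 s before the FiO2 step to >= 70% that
  marks emergence start.  The latent SB recovery time is lognormal
  (median 240 s, log-sd 0.45) measured from emergence start, in line with
  emergence phases lasting a few hundred seconds.  Extubation follows 30 s
  of sustained SB with ventilation off; capnography (and hence the episode)
  ends 60 s after extubation, with other channels running ~30 s longer.
* **Dynamics** are piecewise linear with Gaussian observation noise — the
  simplest family that exposes every rule: apnea (EtCO2 < 2 mmHg) accrues
  while unventilated without SB, and SpO2 falls at 0.2 %/s once cumulative
  apnea exceeds a 30 s lag; ventilating against SB drives HR/SBP/PIP upward
  at 0.5/0.6/0.8 % of baseline per second (relaxing at 1 %/s otherwise) and
  superimposes patient efforts on the airway-pressure trace (excursions
  >= 5 cmH2O above the recent ventilator peak while ventilated, sustained
  dips >= 3 cmH2O below PEEP while not).  These thresholds are exactly the
  SB-detection criteria, so detection is exercised on both trigger types.
* **Rates.** Channels are synthesized at their native rates (62.5 Hz
  waveforms, 2 Hz vitals, 0.14 Hz ventilator scalars, 1 Hz recorded
  action), so the multi-rate harmonization path is not a mock.
* **Behavior policy.** The clinician schedule is the oracle (switch off at
  SB return) delayed by a per-case N(45, 20) s lag, clipped at zero, plus
  rare spurious flips (rate 0.005/s, geometric mean duration 8 s).  The lag
  causally produces asynchrony, so instability grows with the delay and a
  discrepancy–instability correlation is planted mechanically rather than
  painted on.
* **Postoperative columns** (length of stay, PACU stay, 48-h vitals, chest
  X-ray flags with ~48 % missingness, blood gases with ~80 % missingness,
  30-day death) are noisy monotone functions of the case's latent
  instability duration and conditionally independent of everything else
  given it.  This makes the correlation analyses identifiable but means the
  synthetic cohort cannot probe confounded outcome pathways; passing tests
  show the machinery recovers a planted monotone signal, not that real
  outcomes behave this way.
* What the simulator does **not** model: realistic pharmacokinetics (washout
  is single-exponential), pressure-controlled or assisted modes, airway
  artifacts (suction, coughing), measurement dropouts, or inter-channel
  physiologic coupling beyond the mechanisms above.

## Preprocessing

All channels are linearly interpolated to a common 10 Hz grid with
forward/backward edge fill; channels at or above 10 Hz, and the recorded
action, use last-observation-carried-forward at each tick (a step signal
must not be interpolated).  Per-second frames take the within-second
maximum of the ten grid samples.  SB detection runs on the 1 Hz frames: a
positive trigger needs the frame value to exceed the maximum over the
window [t-30 s, t-15 s] (inclusive) by 5 cmH2O — the window is read as
excluding the current breath while covering the prior ventilator cycle —
and a negative trigger needs a frame at or below PEEP - 3 cmH2O; because
frames are within-second maxima, a dip only registers when the effort
lasts a full second, which the simulator reproduces.  The SB flag latches
at the earliest trigger; the apnea counter starts at the first
ventilator-off second, adds one per second with EtCO2 < 2 mmHg, and never
resets — the cumulated total is both a state feature and a penalty input.
Ten exclusion criteria (metadata flags plus signal-derived ones: missing
critical tracks, no FiO2 rise, emergence duration outside 2–20 min, no
outcome track) produce a per-criterion attrition table.

## MDP and reward

The state collects 14 per-second scalars: propofol and remifentanil
effect-site concentrations, end-expiratory sevoflurane, PIP, tidal volume,
6-s trailing means of the AWP and EtCO2 frame envelopes, HR, SpO2, SBP, the
SB flag, cumulative apnea seconds, and ventilation/extubation status.
Ventilation status entering second t is derived from the *previous* action
(or absent SB), so a state never encodes the action chosen at t.  The
reward attached to the transition leaving s_t is computed from the next
frame's penalties and clipped below at -20:

    r_t = max(-20, -(v_apnea + a1 v_spo2 + a2 v_hr + a3 v_sbp + a4 v_pip))

In the default magnitude mode v_spo2 is the SpO2 shortfall below 97 %,
v_apnea the cumulative apnea excess over 6 s, and v_hr/v_sbp/v_pip the
percentage-point excess of each vital over 120 % of its baseline (the mean
over the 10 s after the FiO2 step).  The weights a1..a4 default to 1: the
expert-chosen values of the original clinical deployment are not public,
and equal weighting keeps every term active.  Magnitude mode is the
default because a floor of -20 only binds if raw penalties routinely exceed
20, which 0/1 indicators never would; an indicator mode is provided for
sensitivity analyses.  Continuous features are z-scored with dataset-level
parameters persisted on the dataset, so splits and new data reuse the same
scaling.

## Conservative Q-learning

The Q-function is a small two-headed MLP (default 64x64, ReLU) trained by
Adam on the discrete CQL(H) objective: squared TD error against a target
network plus `cql_weight * (logsumexp_a Q - Q(s, a_data))`, which depresses
out-of-distribution action values so the learned value lower-bounds the
truth.  Numerical choices that matter in practice here: rewards are scaled
by 1/20 into [-1, 0] for training (greedy policies are invariant to the
scale; reported Q-values are rescaled back); the learning rate decays
linearly to 5 % over training and the target network is updated by Polyak
averaging (tau = 0.005) when enabled — with clipped rewards large regions
of the state space share the floor value and the on/off advantage gap is
small, so the variance reduction from both is what stabilizes the greedy
policy near the decision boundary.  Everything is seeded; identical
configs give identical parameters.

A note on diagnosing conservatism: the CQL(H) gradient with respect to the
Q-row is `softmax(Q) - onehot(a_data)`, which *raises* fitted values of
logged actions while depressing out-of-distribution ones.  The mean fitted
Q over logged state–action pairs can therefore increase with the
conservatism weight; the quantity the method provably depresses — and the
one the test suite checks for monotonicity and for lower-bounding
Monte-Carlo rollout returns — is the learned policy's initial-state value
`E_s0[Q(s0, pi(s0))]`.

## Fitted-Q evaluation and bootstrap

Policies (learned and behavior) are evaluated by FQE in a linear function
class: phi(s, a) stacks one block per action of [1, standardized features,
one-hot coarse-abstraction indicator]; for logged tabular MDPs the basis
is the exact one-hot state encoding.  The ridge fixed point of the FQI
iteration is solved in closed form, and an iterative path (checked to
agree) exists as a safeguard.  Off-policy distribution mismatch can make
the LSTD system nearly singular (the greedy policy may select action
blocks rarely seen in the log), so the solver checks the implied value
against the hard feasible range `[r_min/(1-gamma), r_max/(1-gamma)]` and
escalates the ridge by factors of 100 (up to four times, then clips) until
the estimate is feasible — a bounded, conservative fallback that leaves
well-conditioned solves untouched.  The value reported is the mean of
Q_pi(s0, pi(s0)) over episode-initial states.  Confidence bounds come from
resampling *cases* (not transitions) with replacement — respecting
within-case correlation — and re-solving per resample; per-episode moment
matrices make each resample a single d x d solve, so the default 200
resamples cost milliseconds.  The behavior policy is evaluated directly on
its logged next actions; no behavior model is fitted for evaluation.
Values are also mapped to a normalized scale on which the derivation
cohort's empirical behavior returns span [-1, 1] with mean 0.

The ensemble splits cases once 85/15 into derivation-training and testing;
each of n models redraws an 82.3/17.7 inner split, trains on the inner
training cases, and is scored by bootstrapped FQE of both its greedy policy
and the behavior policy on the inner validation cases and on the outer
test cases (it is ambiguous which split the original selection used, so
both are recorded).  The best model maximizes the 95 % lower bound of its
own policy value, and the headline comparison is that bound against the
behavior policy's 95 % upper bound.

## The tabular abstraction as oracle

A coarse MDP on (SB, apnea bucket {0, (0,6], (6,30], >30} s, stress bucket
{<=2, (2,20], >20} % over baseline) plus a terminal state approximates the
simulator with geometric bucket-crossing probabilities and bucket-midpoint
penalties.  It is deliberately lossy (within-bucket position is dropped),
which creates exact value ties — e.g. with zero accumulated apnea, one
unventilated second is free in the abstraction — so "agreement with the
DP-optimal policy" is judged by membership in the optimal-action set
(abstract Q within 1e-9 of the optimal value), and a continuous-state
policy is compared via its modal action per visited abstract state.
Dynamic programming on this MDP supplies exact policy values for FQE
validation, the optimal policy for CQL recovery checks, and a brute-force
enumeration over all fixed switch-time policies confirms that no
non-reactive schedule beats the SB-reactive oracle.

## Outcome statistics

Per case, discrepancy is the count of seconds where the learned greedy
recommendation differs from the recorded action (an alternative switch-time
offset definition is available); instability is the union duration of
SpO2 < 95 %, |HR/HR0 - 1| > 0.2, |SBP/SBP0 - 1| > 0.2 (HR/SBP two-sided as
outcomes, one-sided in the reward — the two sections of the protocol state
them differently and each is implemented as stated), with PIP (> 20 %
increase only) and EtCO2 < 2 mmHg as secondary durations.  Kendall's tau-b
(tie-corrected, asymptotic p) handles continuous outcomes and the
point-biserial coefficient binary ones, both via scipy behind the module
surface with brute-force oracles in the test suite; significance uses
Bonferroni at family level 0.05 over 25 outcomes (per-test 0.002).  Trend
curves are fixed-bandwidth Gaussian local means (default bandwidth a tenth
of the predictor range) with case-level bootstrap percentile bands
(default 3000 resamples).  Feature attribution fits a lightgbm surrogate
(500 weak learners) to the policy's greedy action on raw features and
reports mean absolute tree-SHAP contributions; the clinicians' policy is
attributed by fitting the same surrogate to the logged actions.

## Problem sizes and determinism

Default experiment sizes are chosen so the full validation suite runs on a
single CPU: cohorts of 200 cases (~75k transitions), 20-30k gradient steps
per CQL fit, 30-model ensembles, 200-resample bootstraps, and
tens-of-thousands-episode logged datasets for tabular FQE checks (the
estimator's error against exact dynamic programming is dominated by
empirical-transition noise, which these sizes push below the 0.05
tolerance).  Every random draw descends from an explicit integer seed;
repeated runs are bit-identical, including ensemble splits and bootstrap
resamples.

## Known limitations

* The simulator's noise and dynamics are stylized; effect sizes (e.g. the
  discrepancy–instability tau) are properties of the generator, not of any
  hospital cohort, and headline numbers from real registries are not
  reproducible here by construction.
* The abstraction's transition probabilities are a geometric approximation;
  it serves as an oracle for *policies and values on itself*, not as a
  quantitative model of the simulator.
* FQE uses a linear class; it is exact on tabular logs and adequate for the
  planted dynamics, but richer real-data value surfaces may need a larger
  basis.
* Manual-bag ventilation periods are taken from the recorded action
  channel; inferring them from airway-pressure cycling on real data is out
  of scope.
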