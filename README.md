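# emervent

Offline reinforcement learning for **ventilation control during emergence
from general anesthesia**, with everything needed to validate the method on
synthetic cohorts with known ground truth.

When a patient wakes from general anesthesia, the anesthesiologist must keep
ventilating until spontaneous breathing (SB) returns and then stop: stopping
too early causes apnea and desaturation, continuing too long causes
patient–ventilator asynchrony with airway-pressure spikes and hemodynamic
stress.  `emervent` casts each second of the emergence phase as a step of a
Markov decision process with state
`s_t` = (drug effect-site concentrations, ventilator mechanics, 6-s moving
averages of airway pressure and capnogram, vitals, SB flag, cumulative apnea
time, ventilation/extubation status) and binary action
`a_t ∈ {vent on, vent off}`, and learns a policy offline from logged
trajectories by **discrete conservative Q-learning** (CQL).  The reward
penalizes cardiorespiratory derangement in the next frame,

    r_t = max(−20, −(v_apnea + α1 v_SpO2 + α2 v_HR + α3 v_SBP + α4 v_PIP)),

where each `v` is the excess beyond its clinical threshold (SpO2 < 97 %,
cumulative apnea > 6 s, HR/SBP/PIP > 120 % of the pre-emergence baseline).
Policies are valued by **fitted-Q evaluation** (FQE) with case-level
bootstrap 95 % bounds, an ensemble of models over random splits selects the
one maximizing the lower bound, and per-case **policy discrepancy** (seconds
of disagreement with the recorded clinician actions) is correlated with
instability durations and postoperative outcomes via Kendall's τ-b /
point-biserial coefficients under Bonferroni control.

Real registry data is not required: `emervent.simulate` generates multi-rate
cohorts (62.5 Hz waveforms, 2 Hz vitals, 0.14 Hz ventilator scalars) whose
"clinician" behavior policy lags the known-optimal switch-off time, causally
planting the instability signal every downstream analysis recovers.  See
`docs/methods.md` for the full model description and design decisions.

## Worked example

```python
import emervent as ev

cfg  = ev.SimulatorConfig(n_cases=200, seed=11)
raws, meta, postop, gts = ev.generate_cohort(cfg)      # synthetic cohort
episodes, attrition     = ev.preprocess_cohort(raws)   # 1 Hz emergence episodes
data = ev.build_transitions(episodes)                  # offline (s,a,r,s',done)

policy = ev.train_policy(data, ev.TrainingConfig(
    hidden_sizes=(64, 64), n_gradient_steps=20000,
    cql_weight=0.2, polyak=0.005, seed=0))

table  = ev.case_outcomes(episodes, policy, postop)
report = ev.correlate_outcomes(table, n_outcomes=25)
prim   = report.table[report.table.outcome == "instability_s"].iloc[0]
print(f"kept {len(episodes)} of {cfg.n_cases} cases")
print(f"discrepancy–instability tau = {prim['coefficient']:.3f}, "
      f"p = {prim['p']:.2e} (corrected level {report.corrected_level:.4f})")
```

prints (numbers from this exact seed):

```
kept 196 of 200 cases
discrepancy–instability tau = 0.639, p = 2.36e-36 (corrected level 0.0020)
```

i.e. 196 cases survive the ten exclusion criteria, and the seconds on which
the learned policy disagrees with the simulated clinicians rank-correlate
strongly with cardiorespiratory instability — the planted association the
correlation machinery is supposed to recover.  Under the learned policy the
simulator's mean instability drops to 0 s versus ~24 s under the clinician
policy (see `tests/test_acceptance.py`).

Each capability has a short narrative script under `examples/`
(`01_simulate_cohort.py`, `02_preprocess_and_mdp.py`,
`03_train_and_evaluate.py`, `04_outcome_analysis.py`), and
`emervent --help` exposes the same stages as a thin CLI
(`simulate`, `preprocess`, `build-mdp`, `ensemble`, `pipeline`).

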