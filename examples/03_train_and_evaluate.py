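"""Train a conservative-Q-learning policy and value it by bootstrapped FQE.

A small ensemble over random splits compares the learned policy's 95%
lower bound with the clinicians' 95% upper bound, the decision rule used
to select the deployed model.
"""

import emervent as ev

raws, *_ = ev.generate_cohort(ev.SimulatorConfig(n_cases=80, seed=2))
episodes, _ = ev.preprocess_cohort(raws)
data = ev.build_transitions(episodes)

cfg = ev.TrainingConfig(hidden_sizes=(32, 32), n_gradient_steps=4000,
                        cql_weight=0.2, polyak=0.005)
res = ev.run_ensemble(data, n_models=5, cfg=cfg, master_seed=0, n_boot=100)

d = res.decision
print(f"best of 5 models: #{d['best_model']}")
print(f"  learned policy 95% lower bound (validation): {d['best_aive_val_lb95']:8.1f}")
print(f"  clinician policy 95% upper bound:            {d['behavior_val_ub95']:8.1f}")
print(f"  learned policy better with 95% confidence:   {d['aive_exceeds_behavior_val']}")
# values are discounted sums of the clipped penalty reward (0 = no penalty,
# more negative = more cardiorespiratory derangement); a learned lower bound
# above the clinicians' upper bound is the conservative deployment criterion
norm = res.normalizer
print(f"  on the normalized [-1, 1] scale: learned lb "
      f"{norm(d['best_aive_val_lb95']):.2f} vs clinician ub {norm(d['behavior_val_ub95']):.2f}")
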