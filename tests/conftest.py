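import numpy as np
import pytest

import emervent as ev
from emervent import tabular, mdp as emdp


@pytest.fixture(scope="session")
def sim_config():
    """Default study conditions used across the suite."""
    return ev.SimulatorConfig(n_cases=200, seed=11)


@pytest.fixture(scope="session")
def cohort(sim_config):
    """200-case synthetic cohort under the delayed/noisy clinician policy."""
    raws, meta, postop, gts = ev.generate_cohort(sim_config)
    return {"raws": raws, "meta": meta, "postop": postop, "gts": gts}


@pytest.fixture(scope="session")
def episodes(cohort):
    eps, attrition = ev.preprocess_cohort(cohort["raws"])
    return {"episodes": eps, "attrition": attrition}


@pytest.fixture(scope="session")
def transitions(episodes):
    return ev.build_transitions(episodes["episodes"])


@pytest.fixture(scope="session")
def abstraction(sim_config):
    mdp_abs, info = tabular.tabular_abstraction(sim_config, gamma=0.99)
    return mdp_abs, info


@pytest.fixture(scope="session")
def trained_policy(transitions):
    """CQL policy trained on the full synthetic cohort."""
    cfg = ev.TrainingConfig(
        hidden_sizes=(64, 64), n_gradient_steps=20000,
        cql_weight=0.2, polyak=0.005, seed=0,
    )
    return ev.train_policy(transitions, cfg)


@pytest.fixture(scope="session")
def abstraction_log(abstraction):
    """Logged episodes from an epsilon-greedy oracle on the abstraction."""
    mdp_abs, info = abstraction
    probs = np.zeros((mdp_abs.n_states, 2))
    for s in range(mdp_abs.n_states):
        a = info["pi_oracle"][s]
        probs[s] = [0.3, 0.7] if a == 1 else [0.7, 0.3]
    rng = np.random.default_rng(5)
    data = emdp.dataset_from_tabular(mdp_abs, probs, 400, rng, max_len=400)
    return data


class TabularPolicy:
    """Deterministic tabular policy adapter for FQE on logged MDP data."""

    def __init__(self, pi):
        self.pi = np.asarray(pi, dtype=int)

    def next_actions(self, data):
        return self.pi[data.extras["next_state_id"].to_numpy()]

    def initial_actions(self, data):
        return self.pi[data.extras["state_id"].to_numpy()[data.episode_starts]]


@pytest.fixture(scope="session")
def tabular_policy_cls():
    return TabularPolicy
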