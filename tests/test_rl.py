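"""CQL loss arithmetic, FQE against exact oracles, bootstrap, ensemble."""

import numpy as np
import pytest

import emervent as ev
from emervent import tabular, rl, mdp as emdp


def _batch(Q_like, a):
    n = len(a)
    return {
        "obs": np.zeros((n, 3)), "actions": np.asarray(a),
        "rewards": np.zeros(n), "next_obs": np.zeros((n, 3)),
        "done": np.ones(n),
    }


class _ConstQ:
    def __init__(self, row):
        self.row = np.asarray(row, dtype=float)

    def values(self, X):
        return np.tile(self.row, (len(X), 1))


class TestCqlLoss:
    def test_symmetric_logits_give_ln2(self):
        cfg = ev.TrainingConfig(cql_weight=1.0, gamma=0.9)
        q = _ConstQ([0.0, 0.0])
        loss = rl.cql_loss(_batch(q, [0, 1, 0]), q, q, cfg)
        # TD term is 0 (Q=0, r=0, done): conservative term is ln 2
        assert loss == pytest.approx(np.log(2.0), abs=1e-12)

    def test_logsumexp_arithmetic(self):
        cfg = ev.TrainingConfig(cql_weight=1.0, gamma=0.9)
        q = _ConstQ([1.0, 0.0])
        loss = rl.cql_loss(_batch(q, [0]), q, q, cfg)
        td = (1.0 - 0.0) ** 2  # Q(s,0)=1 vs target r=0 (done)
        cons = np.log(np.exp(1.0) + 1.0) - 1.0
        assert loss == pytest.approx(td + cons, abs=1e-12)
        assert cons == pytest.approx(0.3133, abs=5e-5)

    def test_zero_weight_reduces_to_td(self):
        cfg = ev.TrainingConfig(cql_weight=0.0, gamma=0.9)
        q = _ConstQ([1.0, 0.0])
        assert rl.cql_loss(_batch(q, [0]), q, q, cfg) == pytest.approx(1.0)


class TestTraining:
    def test_same_seed_identical_parameters(self, abstraction_log):
        cfg = ev.TrainingConfig(n_gradient_steps=300, hidden_sizes=(16,), seed=7)
        p1 = ev.train_policy(abstraction_log, cfg)
        p2 = ev.train_policy(abstraction_log, cfg)
        for a, b in zip(p1.net.params(), p2.net.params()):
            np.testing.assert_array_equal(a, b)

    def test_empty_dataset_rejected(self, abstraction_log):
        empty = abstraction_log.subset_cases([])
        with pytest.raises(ValueError):
            ev.train_policy(empty)


class TestFqe:
    def test_gamma_zero_equals_mean_initial_reward(self, abstraction_log, tabular_policy_cls):
        data = abstraction_log
        pi = np.zeros(data.X.shape[1], dtype=int)
        pol = tabular_policy_cls(pi)
        est = ev.fqe(data, pol, ev.TrainingConfig(gamma=0.0, fqe_ridge=1e-8))
        # with gamma 0, Q(s, a) is the mean immediate reward at (s, a)
        sid = data.extras["state_id"].to_numpy()
        s0 = sid[data.episode_starts]
        expect = []
        for s in s0:
            m = (sid == s) & (data.actions == 0)
            expect.append(data.rewards[m].mean() if m.any() else 0.0)
        assert est == pytest.approx(np.mean(expect), abs=1e-6)

    def test_three_state_chain_matches_value_iteration(self, tabular_policy_cls):
        P = np.zeros((3, 2, 3))
        P[0, :, 1] = 1.0
        P[1, :, 2] = 1.0
        P[2, :, 2] = 1.0
        R = np.full((3, 2), -1.0)
        R[2] = 0.0
        m = tabular.TabularMDP(P=P, R=R, terminal=np.array([False, False, True]))
        rng = np.random.default_rng(0)
        data = emdp.dataset_from_tabular(m, np.full((3, 2), 0.5), 50, rng)
        pol = tabular_policy_cls(np.zeros(3, dtype=int))
        v = tabular.policy_evaluation(m, np.zeros(3, dtype=int), 0.9)
        est = ev.fqe(data, pol, ev.TrainingConfig(gamma=0.9))
        assert abs(est - v[0]) < 0.05

    def test_iterative_matches_closed_form(self, abstraction_log, tabular_policy_cls):
        mdp_abs_states = abstraction_log.X.shape[1]
        pol = tabular_policy_cls(np.zeros(mdp_abs_states, dtype=int))
        cfg = ev.TrainingConfig(gamma=0.95)
        a = ev.fqe(abstraction_log, pol, cfg, method="closed_form")
        b = ev.fqe(abstraction_log, pol, cfg, method="iterative")
        assert a == pytest.approx(b, abs=1e-5)

    def test_constant_reward_geometric_series(self, tabular_policy_cls):
        # absorbing-free loop with constant reward c, truncated at T
        P = np.zeros((2, 2, 2))
        P[0, :, 0] = 1.0
        P[1, :, 1] = 1.0
        m = tabular.TabularMDP(P=P, R=np.full((2, 2), -1.0),
                               terminal=np.array([False, True]))
        rng = np.random.default_rng(1)
        T = 200
        data = emdp.dataset_from_tabular(m, np.full((2, 2), 0.5), 20, rng, max_len=T)
        gamma = 0.9
        est = ev.fqe(data, tabular_policy_cls(np.zeros(2, dtype=int)),
                     ev.TrainingConfig(gamma=gamma))
        # c (1 - gamma^T) / (1 - gamma); a stationary Q spreads the horizon
        # haircut over all steps, so the agreement is approximate
        expected = -1.0 * (1 - gamma**T) / (1 - gamma)
        assert est == pytest.approx(expected, abs=0.5)

    def test_behavior_fqe_matches_empirical_return(self, transitions):
        """On-policy check: FQE of the logged policy on its own data agrees
        with the empirical mean discounted return within 3 bootstrap SEs."""
        cfg = ev.TrainingConfig(gamma=0.99)
        sub = transitions.subset_cases(transitions.cases[:80])
        est = ev.bootstrap_value(sub, ev.BehaviorPolicy(), cfg, n_boot=200, seed=0)
        emp = sub.episode_returns(0.99)
        se = (est.ub95 - est.lb95) / 3.92
        assert abs(est.point - emp.mean()) < 3 * se


class TestBootstrap:
    def test_identical_episodes_collapse(self, tabular_policy_cls):
        P = np.zeros((2, 2, 2))
        P[0, :, 1] = 1.0
        P[1, :, 1] = 1.0
        m = tabular.TabularMDP(P=P, R=np.array([[-1.0, -1.0], [0, 0]]),
                               terminal=np.array([False, True]))
        rng = np.random.default_rng(0)
        data = emdp.dataset_from_tabular(m, np.zeros(2, dtype=int), 10, rng)
        est = ev.bootstrap_value(data, tabular_policy_cls(np.zeros(2, dtype=int)),
                                 ev.TrainingConfig(gamma=0.9), n_boot=50)
        assert est.lb95 == pytest.approx(est.ub95, abs=1e-9)
        assert est.lb95 == pytest.approx(est.point, abs=1e-6)

    def test_bounds_bracket_point(self, abstraction_log, tabular_policy_cls):
        pi = np.zeros(abstraction_log.X.shape[1], dtype=int)
        est = ev.bootstrap_value(abstraction_log, tabular_policy_cls(pi),
                                 ev.TrainingConfig(gamma=0.95), n_boot=100)
        assert est.lb95 <= est.point <= est.ub95

    def test_single_case_warns(self, abstraction_log, tabular_policy_cls):
        one = abstraction_log.subset_cases(abstraction_log.cases[:1])
        pi = np.zeros(abstraction_log.X.shape[1], dtype=int)
        with pytest.warns(UserWarning):
            est = ev.bootstrap_value(one, tabular_policy_cls(pi),
                                     ev.TrainingConfig(gamma=0.9), n_boot=10)
        assert est.lb95 == est.ub95


class TestNormalization:
    def test_reference_maps_into_unit_interval(self):
        ref = np.array([-3.0, -1.0, 0.0, 2.0])
        z = ev.normalize_values(ref, ref)
        assert z.min() >= -1.0 - 1e-12 and z.max() <= 1.0 + 1e-12
        assert z.mean() == pytest.approx(0.0, abs=1e-12)

    def test_mean_maps_to_zero_and_max_to_one(self):
        ref = np.array([0.0, 1.0, 2.0, 9.0])
        n = ev.Normalizer.fit(ref)
        assert n(ref.mean()) == pytest.approx(0.0)
        assert n(ref.max()) == pytest.approx(1.0)  # max - mu >= mu - min here

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=50)
        n = ev.Normalizer.fit(ref)
        x = rng.normal(size=20)
        np.testing.assert_allclose(n.inverse(n(x)), x, atol=1e-12)

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError):
            ev.Normalizer.fit(np.ones(5))


class TestEnsemble:
    def test_split_arithmetic(self):
        rng = np.random.default_rng(0)
        train, test = rl.split_cases(np.arange(14306), 0.15, rng)
        assert len(test) == 2146
        assert len(train) + len(test) == 14306

    def test_defaults_echo_study_design(self):
        import inspect

        sig = inspect.signature(ev.run_ensemble)
        assert sig.parameters["n_models"].default == 300
        assert sig.parameters["inner_train_frac"].default == 0.823
        assert sig.parameters["outer_test_frac"].default == 0.15

    def test_fixed_master_seed_reproducible(self, transitions):
        sub = transitions.subset_cases(transitions.cases[:40])
        cfg = ev.TrainingConfig(hidden_sizes=(16,), n_gradient_steps=300,
                                cql_weight=0.2, polyak=0.005)
        r1 = ev.run_ensemble(sub, n_models=2, cfg=cfg, master_seed=5, n_boot=20)
        r2 = ev.run_ensemble(sub, n_models=2, cfg=cfg, master_seed=5, n_boot=20)
        assert r1.best_model == r2.best_model
        assert r1.models.equals(r2.models)

    def test_too_few_cases_rejected(self, transitions):
        tiny = transitions.subset_cases(transitions.cases[:4])
        with pytest.raises(ValueError):
            ev.run_ensemble(tiny, n_models=1)
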