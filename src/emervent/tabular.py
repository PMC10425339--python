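"""Exact small-MDP machinery: solvers, random MDPs, and the coarse
abstraction of the emergence process.

The abstraction collapses an emergence episode to (spontaneous breathing
present, cumulative-apnea bucket, cardiovascular-stress bucket) with a
single absorbing terminal state reached after extubation.  It is knowingly
non-Markov with respect to the full simulator (within-bucket position is
lost); it exists as a dynamic-programming oracle against which fitted-Q
evaluation and conservative Q-learning are validated, and as the default
discretization basis for linear FQE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# bucket edges for the abstraction grid
APNEA_EDGES = (0.0, 6.0, 30.0)    # buckets: ==0, (0,6], (6,30], >30  (s)
STRESS_EDGES = (2.0, 20.0)        # buckets: <=2, (2,20], >20  (% over baseline)
N_APNEA, N_STRESS = 4, 3


def apnea_bucket(cum: np.ndarray) -> np.ndarray:
    cum = np.asarray(cum, dtype=float)
    return np.digitize(cum, APNEA_EDGES, right=True)


def stress_bucket(pct: np.ndarray) -> np.ndarray:
    pct = np.asarray(pct, dtype=float)
    return np.digitize(pct, STRESS_EDGES, right=True)


def abstract_ids(sb: np.ndarray, apnea_cum: np.ndarray, stress_pct: np.ndarray) -> np.ndarray:
    """Map per-second (SB flag, cumulative apnea s, max excursion %) to
    abstract state indices on the sb x apnea x stress grid."""
    sb = np.asarray(sb).astype(int)
    return (
        sb * (N_APNEA * N_STRESS)
        + apnea_bucket(apnea_cum) * N_STRESS
        + stress_bucket(stress_pct)
    )


N_ABSTRACT = 2 * N_APNEA * N_STRESS  # non-terminal grid size (24)


@dataclass
class TabularMDP:
    """Finite MDP with explicit transition tensor and expected rewards.

    ``P`` has shape (S, A, S); ``R`` shape (S, A).  Terminal states are
    absorbing with zero reward.
    """

    P: np.ndarray
    R: np.ndarray
    terminal: np.ndarray
    labels: list | None = None

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.terminal = np.asarray(self.terminal, dtype=bool)
        s, a, s2 = self.P.shape
        assert s == s2 and self.R.shape == (s, a)
        if not np.allclose(self.P.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")

    @property
    def n_states(self) -> int:
        return self.P.shape[0]

    @property
    def n_actions(self) -> int:
        return self.P.shape[1]


def _policy_matrix(mdp: TabularMDP, policy) -> tuple[np.ndarray, np.ndarray]:
    """(P_pi, r_pi) for a deterministic (S,) or stochastic (S, A) policy."""
    pol = np.asarray(policy)
    if pol.ndim == 1:
        probs = np.zeros((mdp.n_states, mdp.n_actions))
        probs[np.arange(mdp.n_states), pol.astype(int)] = 1.0
    else:
        probs = pol
    P_pi = np.einsum("sa,sat->st", probs, mdp.P)
    r_pi = (probs * mdp.R).sum(axis=1)
    return P_pi, r_pi


def policy_evaluation(mdp: TabularMDP, policy, gamma: float) -> np.ndarray:
    """Exact discounted state values of a policy via a linear solve."""
    P_pi, r_pi = _policy_matrix(mdp, policy)
    P_pi = P_pi.copy()
    P_pi[mdp.terminal] = 0.0
    r_pi = np.where(mdp.terminal, 0.0, r_pi)
    return np.linalg.solve(np.eye(mdp.n_states) - gamma * P_pi, r_pi)


def q_from_v(mdp: TabularMDP, v: np.ndarray, gamma: float) -> np.ndarray:
    cont = np.where(mdp.terminal, 0.0, v)
    q = mdp.R + gamma * np.einsum("sat,t->sa", mdp.P, cont)
    q[mdp.terminal] = 0.0
    return q


def value_iteration(
    mdp: TabularMDP, gamma: float, tol: float = 1e-10, max_iter: int = 200_000
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal values and a greedy optimal policy."""
    v = np.zeros(mdp.n_states)
    for _ in range(max_iter):
        q = q_from_v(mdp, v, gamma)
        v_new = q.max(axis=1)
        v_new[mdp.terminal] = 0.0
        if np.max(np.abs(v_new - v)) < tol:
            v = v_new
            break
        v = v_new
    return v, q_from_v(mdp, v, gamma).argmax(axis=1)


def bellman_residual(mdp: TabularMDP, v: np.ndarray, gamma: float) -> float:
    q = q_from_v(mdp, v, gamma)
    v_target = np.where(mdp.terminal, 0.0, q.max(axis=1))
    return float(np.max(np.abs(v - v_target)))


def rollout(
    mdp: TabularMDP,
    policy,
    rng: np.random.Generator,
    s0: int | None = None,
    rho: np.ndarray | None = None,
    max_len: int = 500,
):
    """Sample one episode; returns (states, actions, rewards).

    ``policy`` may be a deterministic (S,) array, a stochastic (S, A)
    matrix, or a callable s -> a.
    """
    if s0 is None:
        nonterm = np.flatnonzero(~mdp.terminal)
        if rho is None:
            s0 = int(nonterm[0])
        else:
            s0 = int(rng.choice(mdp.n_states, p=rho))
    states, actions, rewards = [], [], []
    s = s0
    for _ in range(max_len):
        if mdp.terminal[s]:
            break
        if callable(policy):
            a = int(policy(s))
        else:
            pol = np.asarray(policy)
            a = int(pol[s]) if pol.ndim == 1 else int(rng.choice(mdp.n_actions, p=pol[s]))
        states.append(s)
        actions.append(a)
        rewards.append(mdp.R[s, a])
        s = int(rng.choice(mdp.n_states, p=mdp.P[s, a]))
    return np.array(states), np.array(actions), np.array(rewards)


def mc_policy_value(
    mdp: TabularMDP,
    policy,
    gamma: float,
    rng: np.random.Generator,
    n_episodes: int = 10_000,
    s0: int | None = None,
    rho: np.ndarray | None = None,
    max_len: int = 500,
) -> tuple[float, float]:
    """Monte-Carlo estimate (mean, standard error) of the discounted return."""
    returns = np.empty(n_episodes)
    for i in range(n_episodes):
        _, _, r = rollout(mdp, policy, rng, s0=s0, rho=rho, max_len=max_len)
        returns[i] = float(np.polyval(r[::-1], gamma)) if len(r) else 0.0
    return float(returns.mean()), float(returns.std(ddof=1) / np.sqrt(n_episodes))


def random_mdp(
    n_states: int,
    rng: np.random.Generator,
    n_actions: int = 2,
    p_term: float = 0.1,
    reward_scale: float = 1.0,
) -> TabularMDP:
    """Random episodic MDP: last state is absorbing terminal, every
    (s, a) reaches it with probability at least ``p_term``."""
    S = n_states + 1
    P = rng.dirichlet(np.ones(n_states), size=(n_states, n_actions))
    P = np.concatenate([P * (1 - p_term), np.full((n_states, n_actions, 1), p_term)], axis=2)
    P = np.concatenate([P, np.zeros((1, n_actions, S))], axis=0)
    P[-1, :, -1] = 1.0
    R = np.concatenate(
        [rng.normal(0.0, reward_scale, size=(n_states, n_actions)), np.zeros((1, n_actions))]
    )
    term = np.zeros(S, dtype=bool)
    term[-1] = True
    return TabularMDP(P=P, R=R, terminal=term)


# ---------------------------------------------------------------------------
# emergence abstraction


def _label(sb: int, ab: int, st: int) -> tuple:
    return (sb, ab, st)


def tabular_abstraction(config, gamma: float = 0.99) -> tuple[TabularMDP, dict]:
    """Coarse MDP of the emergence process derived from simulator parameters.

    States are (SB, apnea bucket, stress bucket) plus a terminal reached by
    keeping the ventilator off once spontaneous breathing is present (the
    extubation hold).  Per-second transition probabilities approximate the
    piecewise-linear simulator dynamics by geometric bucket-crossing times;
    rewards are the clipped negative penalties evaluated at bucket midpoints
    of the *next* state, matching the reward-attachment convention of the
    transition dataset.

    Returns the MDP together with an info dict carrying the optimal values
    and policy, the value of the oracle (switch-at-SB) policy, and the
    initial state index.
    """
    # per-second hazard of SB returning (geometric approximation of the
    # lognormal recovery time)
    mean_onset = float(
        np.exp(config.sb_recovery_logmean + 0.5 * config.sb_recovery_logsd**2)
    )
    p_sb = min(1.0, 1.0 / mean_onset)
    # apnea bucket promotion probabilities while apneic (1/width)
    p_ap = [1.0, 1.0 / 6.0, 1.0 / 24.0, 0.0]
    rate = (
        config.asynchrony_hr_rate
        + config.asynchrony_sbp_rate
        + config.asynchrony_pip_rate
    ) / 3.0
    # stress bucket promotion while asynchronous, decay otherwise
    p_st_up = [min(1.0, rate / 2.0), min(1.0, rate / 18.0), 0.0]
    p_st_dn = [0.0, min(1.0, config.stress_relax_rate / 2.0),
               min(1.0, config.stress_relax_rate / 18.0)]
    p_term = 1.0 / max(1, config.extubation_hold_s)

    # state penalties at bucket midpoints (magnitude mode, alpha = 1)
    apnea_pen = [0.0, 0.0, 12.0, 39.0 + 2.0]   # +2: desaturation below 97% deep in apnea
    stress_pen = [0.0, 0.0, 30.0]              # ~10 pts over the 20% line on HR+SBP+PIP

    S = N_ABSTRACT + 1
    TERM = N_ABSTRACT
    P = np.zeros((S, 2, S))
    pen = np.zeros(S)
    labels = []
    for sb in (0, 1):
        for ab in range(N_APNEA):
            for st in range(N_STRESS):
                labels.append(_label(sb, ab, st))
    labels.append("terminal")

    def idx(sb, ab, st):
        return sb * (N_APNEA * N_STRESS) + ab * N_STRESS + st

    for sb in (0, 1):
        for ab in range(N_APNEA):
            for st in range(N_STRESS):
                pen[idx(sb, ab, st)] = apnea_pen[ab] + stress_pen[st]

    def add(s, a, targets):
        """targets: list of ((sb, ab, st) or TERM, prob)."""
        for tgt, p in targets:
            j = TERM if tgt == "terminal" else idx(*tgt)
            P[s, a, j] += p

    for sb in (0, 1):
        for ab in range(N_APNEA):
            for st in range(N_STRESS):
                s = idx(sb, ab, st)
                for a in (0, 1):
                    apneic = sb == 0 and a == 0
                    asyn = sb == 1 and a == 1
                    # apnea bucket dynamics
                    ab_next = [(ab, 1.0)]
                    if apneic and ab < N_APNEA - 1:
                        q = p_ap[ab]
                        ab_next = [(ab, 1.0 - q), (ab + 1, q)]
                    # stress bucket dynamics
                    if asyn and st < N_STRESS - 1:
                        q = p_st_up[st]
                        st_next = [(st, 1.0 - q), (st + 1, q)]
                    elif not asyn and st > 0:
                        q = p_st_dn[st]
                        st_next = [(st, 1.0 - q), (st - 1, q)]
                    else:
                        st_next = [(st, 1.0)]
                    # SB hazard and termination
                    if sb == 0:
                        sb_next = [(0, 1.0 - p_sb), (1, p_sb)]
                        term_p = 0.0
                    else:
                        sb_next = [(1, 1.0)]
                        term_p = p_term if a == 0 else 0.0
                    for sbn, psb in sb_next:
                        for abn, pab in ab_next:
                            for stn, pst in st_next:
                                add(s, a, [((sbn, abn, stn), psb * pab * pst * (1 - term_p))])
                    if term_p > 0:
                        add(s, a, [("terminal", term_p)])

    P[TERM, :, TERM] = 1.0
    # reward = expected clipped negative penalty of the next state
    r_next = np.maximum(-20.0, -pen)
    r_next[TERM] = 0.0
    R = np.einsum("sat,t->sa", P, r_next)
    R[TERM] = 0.0
    term = np.zeros(S, dtype=bool)
    term[TERM] = True
    mdp = TabularMDP(P=P, R=R, terminal=term, labels=labels)

    v_opt, pi_opt = value_iteration(mdp, gamma)
    # oracle: ventilate iff spontaneous breathing absent
    pi_oracle = np.array(
        [0 if lab == "terminal" else (1 - lab[0]) for lab in labels], dtype=int
    )
    v_oracle = policy_evaluation(mdp, pi_oracle, gamma)
    info = {
        "v_opt": v_opt,
        "pi_opt": pi_opt,
        "pi_oracle": pi_oracle,
        "v_oracle": v_oracle,
        "s0": idx(0, 0, 0),
        "penalties": pen,
    }
    return mdp, info


def switch_time_values(mdp: TabularMDP, gamma: float, s0: int, max_k: int = 600) -> np.ndarray:
    """Initial-state values of every keep-ventilating-until-k-then-off policy.

    ``U_0`` is the always-off value; ``U_k = r_on + gamma P_on U_{k-1}``
    prepends one more ventilated second.  Used to brute-force the claim that
    no fixed switch time beats the SB-reactive oracle on the abstraction.
    """
    always_off = np.zeros(mdp.n_states, dtype=int)
    P_on, r_on = _policy_matrix(mdp, np.ones(mdp.n_states, dtype=int))
    P_on[mdp.terminal] = 0.0
    r_on = np.where(mdp.terminal, 0.0, r_on)
    u = policy_evaluation(mdp, always_off, gamma)
    out = np.empty(max_k + 1)
    out[0] = u[s0]
    for k in range(1, max_k + 1):
        u = r_on + gamma * P_on @ u
        u[mdp.terminal] = 0.0
        out[k] = u[s0]
    return out
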