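"""Offline RL core: discrete conservative Q-learning and fitted-Q evaluation.

Training uses the discrete CQL(H) objective on a small two-headed MLP:

    L = E[(Q(s,a) - (r + gamma (1-done) max_a' Q_target(s',a')))^2]
        + w * E[logsumexp_a Q(s,a) - Q(s, a_data)]

where the second term pushes fitted values of actions outside the logged
distribution down, so the learned value function lower-bounds the true one.
The network and its Adam optimizer are implemented directly in numpy; with
a ~14-dimensional state and two actions this trains in seconds on one CPU
and is bit-reproducible from the seed.

Policy evaluation uses fitted-Q evaluation in a linear function class: the
ridge fixed point of the FQI iteration

    Q_{k+1} = argmin ||Phi w - (r + gamma Phi'_pi w_k)||^2 + lam ||w||^2

is solved in closed form, (Phi'Phi + lam I - gamma Phi'Phi'_pi) w = Phi' r.
Because the solution depends on the data only through per-episode moment
matrices, bootstrap resampling at the case level costs one small linear
solve per resample, which makes percentile intervals over hundreds of
resamples cheap.  The default basis concatenates an intercept, the
standardized state features, and a one-hot encoding of the coarse
emergence abstraction; for logged tabular MDPs the basis is the exact
one-hot state encoding and FQE reproduces dynamic-programming values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mdp import TransitionDataset
from . import tabular


@dataclass
class TrainingConfig:
    gamma: float = 0.99
    cql_weight: float = 1.0
    hidden_sizes: tuple = (64, 64)
    learning_rate: float = 1e-3
    batch_size: int = 256
    n_gradient_steps: int = 5000
    target_update_interval: int = 200
    polyak: float = 0.0          # >0: soft target updates instead of periodic sync
    lr_decay: bool = True        # linear learning-rate decay to 5% over training
    seed: int = 0
    fqe_ridge: float = 1e-3
    fqe_max_iter: int = 400
    reward_scale: float = 20.0   # rewards divided by this during net training

    def __post_init__(self) -> None:
        if not (0 <= self.gamma < 1):
            raise ValueError("gamma must lie in [0, 1)")
        if self.cql_weight < 0:
            raise ValueError("cql_weight must be non-negative")


@dataclass
class PolicyValueEstimate:
    """FQE point estimate with case-level bootstrap percentile bounds."""

    point: float
    lb95: float
    ub95: float
    n_boot: int
    normalized: tuple | None = None


@dataclass
class EnsembleResult:
    models: pd.DataFrame
    best_model: int
    decision: dict
    normalizer: "Normalizer"
    policies: list | None = None


# ---------------------------------------------------------------------------
# Q-network


class QFunction:
    """Two-headed MLP Q(s, .) with manual forward/backward passes."""

    def __init__(self, n_in: int, hidden: tuple = (64, 64), seed: int = 0):
        rng = np.random.default_rng(seed)
        sizes = [n_in, *hidden, 2]
        self.W = [
            rng.normal(0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    def forward(self, X: np.ndarray, cache: bool = False):
        h = np.asarray(X, dtype=float)
        acts = [h]
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if i < len(self.W) - 1:
                h = np.maximum(h, 0.0)
            acts.append(h)
        return (h, acts) if cache else h

    def values(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)

    def greedy(self, X: np.ndarray) -> np.ndarray:
        return self.values(X).argmax(axis=1)

    def backward(self, acts, dout):
        """Gradients of a loss with upstream dL/dQ = dout."""
        gW, gb = [None] * len(self.W), [None] * len(self.b)
        delta = dout
        for i in range(len(self.W) - 1, -1, -1):
            gW[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i].T) * (acts[i] > 0)
        return gW, gb

    def copy(self) -> "QFunction":
        other = QFunction.__new__(QFunction)
        other.W = [w.copy() for w in self.W]
        other.b = [b.copy() for b in self.b]
        return other

    def params(self):
        return self.W + self.b


class _Adam:
    def __init__(self, shapes, lr: float):
        self.lr = lr
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mh = self.m[i] / (1 - b1**self.t)
            vh = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + eps)


def cql_loss(
    batch: dict, q: QFunction, q_target: QFunction, cfg: TrainingConfig
) -> float:
    """Scalar discrete-CQL(H) loss on a batch dict with keys
    obs, actions, rewards, next_obs, done (rewards already on the
    training scale)."""
    Q = q.values(batch["obs"])
    Qt = q_target.values(batch["next_obs"])
    target = batch["rewards"] + cfg.gamma * (1.0 - batch["done"]) * Qt.max(axis=1)
    qa = Q[np.arange(len(Q)), batch["actions"]]
    td = float(np.mean((qa - target) ** 2))
    m = Q.max(axis=1, keepdims=True)
    lse = (m + np.log(np.exp(Q - m).sum(axis=1, keepdims=True))).ravel()
    cons = float(np.mean(lse - qa))
    return td + cfg.cql_weight * cons


@dataclass
class QPolicy:
    """Greedy policy of a trained Q-network, bound to its feature scaling."""

    net: QFunction
    mean: np.ndarray
    sd: np.ndarray
    feature_names: list
    cfg: TrainingConfig
    loss_curve: np.ndarray | None = None

    def _z(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd

    def act(self, X: np.ndarray) -> np.ndarray:
        """Greedy actions for raw (unstandardized) feature rows."""
        X = np.atleast_2d(X)
        return self.net.greedy(self._z(X))

    def q_values(self, X: np.ndarray) -> np.ndarray:
        """Fitted Q-values on the reward scale of the dataset."""
        return self.net.values(self._z(np.atleast_2d(X))) * self.cfg.reward_scale

    def __call__(self, frame: dict) -> int:
        """Frame-dict interface for simulator rollouts."""
        x = np.array([[frame[name] for name in self.feature_names]])
        return int(self.act(x)[0])

    def fitted_value(self, data: TransitionDataset) -> float:
        """Conservative value estimate: mean greedy Q over episode-initial states."""
        s0 = data.episode_starts
        q = self.q_values(data.X[s0])
        return float(q.max(axis=1).mean())

    def mean_fitted_q(self, data: TransitionDataset) -> float:
        """Mean fitted Q over logged (s, a) pairs (conservatism diagnostic)."""
        q = self.q_values(data.X)
        return float(q[np.arange(len(q)), data.actions].mean())


def train_policy(data: TransitionDataset, cfg: TrainingConfig | None = None) -> QPolicy:
    """Gradient descent on the discrete CQL(H) loss with a target network.

    Fully seeded: two runs with the same config and data produce identical
    parameters.  Raises on divergence (NaN loss).
    """
    cfg = cfg or TrainingConfig()
    if len(data) == 0:
        raise ValueError("empty transition dataset")
    rng = np.random.default_rng(cfg.seed)
    Z = data.Z
    Zn = data.Z_next
    r = data.rewards / cfg.reward_scale
    done = data.done.astype(float)
    a = data.actions
    n = len(data)
    net = QFunction(Z.shape[1], cfg.hidden_sizes, seed=cfg.seed)
    target = net.copy()
    opt = _Adam([p.shape for p in net.params()], cfg.learning_rate)
    losses = np.empty(cfg.n_gradient_steps)
    B = min(cfg.batch_size, n)
    for step in range(cfg.n_gradient_steps):
        idx = rng.integers(0, n, size=B)
        obs, nxt = Z[idx], Zn[idx]
        Q, acts = net.forward(obs, cache=True)
        Qt = target.values(nxt)
        y = r[idx] + cfg.gamma * (1.0 - done[idx]) * Qt.max(axis=1)
        qa = Q[np.arange(B), a[idx]]
        td_err = qa - y
        # dL/dQ: TD term on the taken action, CQL term softmax minus one-hot
        dQ = np.zeros_like(Q)
        dQ[np.arange(B), a[idx]] += 2.0 * td_err / B
        if cfg.cql_weight > 0:
            m = Q.max(axis=1, keepdims=True)
            e = np.exp(Q - m)
            soft = e / e.sum(axis=1, keepdims=True)
            dQ += cfg.cql_weight * soft / B
            dQ[np.arange(B), a[idx]] -= cfg.cql_weight / B
        gW, gb = net.backward(acts, dQ)
        if cfg.lr_decay:
            frac = step / max(1, cfg.n_gradient_steps - 1)
            opt.lr = cfg.learning_rate * max(0.05, 1.0 - frac)
        opt.step(net.params(), gW + gb)
        m2 = Q.max(axis=1, keepdims=True)
        lse = (m2 + np.log(np.exp(Q - m2).sum(axis=1, keepdims=True))).ravel()
        losses[step] = float(np.mean(td_err**2) + cfg.cql_weight * np.mean(lse - qa))
        if not np.isfinite(losses[step]):
            raise FloatingPointError(f"training diverged at step {step}")
        if cfg.polyak > 0:
            for tp, p in zip(target.params(), net.params()):
                tp *= 1.0 - cfg.polyak
                tp += cfg.polyak * p
        elif (step + 1) % cfg.target_update_interval == 0:
            target = net.copy()
    return QPolicy(
        net=net, mean=data.mean, sd=data.sd,
        feature_names=list(data.feature_names), cfg=cfg, loss_curve=losses,
    )


def abstract_agreement(
    qpolicy: QPolicy,
    data: TransitionDataset,
    mdp_abs: "tabular.TabularMDP",
    info: dict,
    gamma: float = 0.99,
    tol: float = 1e-9,
) -> dict:
    """Agreement of a learned policy with the DP-optimal policy on the
    coarse emergence abstraction.

    A greedy action counts as optimal when its abstract Q-value is within
    ``tol`` of the abstract optimal value (ties at zero-penalty buckets make
    both actions optimal there).  ``state_fraction`` compares the policy's
    modal action per visited abstract state; ``visit_weighted`` scores every
    visited second.
    """
    q_opt = tabular.q_from_v(mdp_abs, info["v_opt"], gamma)
    aid = data.extras["abstract_id"].to_numpy()
    greedy = qpolicy.act(data.X)
    ok = np.abs(q_opt[aid, greedy] - info["v_opt"][aid]) < tol
    states = np.unique(aid)
    per_state = {}
    n_match = 0
    for s in states:
        m = aid == s
        modal = int(np.bincount(greedy[m], minlength=2).argmax())
        match = abs(q_opt[s, modal] - info["v_opt"][s]) < tol
        per_state[int(s)] = {"modal": modal, "optimal": bool(match),
                             "visits": int(m.sum()), "row_accuracy": float(ok[m].mean())}
        n_match += match
    return {
        "state_fraction": n_match / len(states),
        "visit_weighted": float(ok.mean()),
        "per_state": per_state,
    }


# ---------------------------------------------------------------------------
# policies for evaluation


class BehaviorPolicy:
    """The logged clinician policy: at s' it takes the next logged action."""

    def next_actions(self, data: TransitionDataset) -> np.ndarray:
        nxt = np.empty(len(data), dtype=int)
        nxt[:-1] = data.actions[1:]
        nxt[-1] = data.actions[-1]
        # at episode boundaries there is no next logged action; done rows
        # never bootstrap, so the value is irrelevant
        return nxt

    def initial_actions(self, data: TransitionDataset) -> np.ndarray:
        return data.actions[data.episode_starts]


class GreedyPolicy:
    """Evaluation wrapper around a QPolicy (or any raw-feature actor)."""

    def __init__(self, qpolicy: QPolicy):
        self.qpolicy = qpolicy

    def next_actions(self, data: TransitionDataset) -> np.ndarray:
        return self.qpolicy.act(data.X_next)

    def initial_actions(self, data: TransitionDataset) -> np.ndarray:
        return self.qpolicy.act(data.X[data.episode_starts])


# ---------------------------------------------------------------------------
# fitted-Q evaluation


def _auto_basis(data: TransitionDataset):
    """Feature map phi(s) -> (n, d) for the linear FQE class."""
    if data.extras is not None and "state_id" in data.extras.columns:
        S = len(data.feature_names)

        def basis(X, extras_col):
            return np.asarray(X, dtype=float)  # already one-hot

        return basis
    n_abs = tabular.N_ABSTRACT

    def basis(X, abstract_id):
        Z = data.standardize(np.asarray(X, dtype=float))
        one_hot = np.zeros((len(Z), n_abs))
        if abstract_id is not None:
            one_hot[np.arange(len(Z)), np.asarray(abstract_id, dtype=int)] = 1.0
        return np.hstack([np.ones((len(Z), 1)), Z, one_hot])

    return basis


def _phi_sa(phi_s: np.ndarray, actions: np.ndarray) -> np.ndarray:
    """Block encoding phi(s, a): one block of phi(s) per discrete action."""
    n, d = phi_s.shape
    out = np.zeros((n, 2 * d))
    a = np.asarray(actions, dtype=int)
    rows = np.arange(n)
    for k in (0, 1):
        mask = a == k
        out[np.ix_(mask, np.arange(k * d, (k + 1) * d))] = phi_s[mask]
    return out


def _fqe_matrices(data: TransitionDataset, policy, basis=None):
    """(Phi, Phi'_pi with done rows zeroed, rewards, Phi at s0)."""
    basis = basis or _auto_basis(data)
    ex = data.extras
    if ex is not None and "state_id" in ex.columns:
        phi_s = basis(data.X, None)
        phi_s2 = basis(data.X_next, None)
    else:
        aid = ex["abstract_id"].to_numpy() if ex is not None else None
        aid2 = ex["next_abstract_id"].to_numpy() if ex is not None else None
        phi_s = basis(data.X, aid)
        phi_s2 = basis(data.X_next, aid2)
    Phi = _phi_sa(phi_s, data.actions)
    Phi2 = _phi_sa(phi_s2, policy.next_actions(data))
    Phi2[data.done] = 0.0
    s0 = data.episode_starts
    Phi0 = _phi_sa(phi_s[s0], policy.initial_actions(data))
    return Phi, Phi2, data.rewards, Phi0


def _feasible_range(rewards: np.ndarray, gamma: float) -> tuple[float, float]:
    """Hard bounds on any discounted value given the observed reward range."""
    vmin = min(0.0, float(rewards.min())) / (1.0 - gamma)
    vmax = max(0.0, float(rewards.max())) / (1.0 - gamma)
    pad = 1.0 + 0.01 * (vmax - vmin)
    return vmin - pad, vmax + pad


def _solve_linear(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(A, b, rcond=None)[0]


def _solve_guarded(
    A0: np.ndarray,
    b: np.ndarray,
    phi0bar: np.ndarray,
    lam: float,
    vrange: tuple[float, float],
) -> tuple[float, np.ndarray]:
    """Solve the LSTD system, escalating the ridge when the implied value
    leaves the feasible range (off-policy distribution mismatch can make
    the system nearly singular; stronger regularization restores a bounded,
    conservative estimate).  As a last resort the value is clipped."""
    d = A0.shape[0]
    eye = np.eye(d)
    v = np.nan
    w = np.zeros(d)
    for k in range(4):
        A = A0 + lam * (100.0**k) * eye
        w = _solve_linear(A, b)
        v = float(phi0bar @ w)
        if np.isfinite(v) and vrange[0] <= v <= vrange[1]:
            return v, w
    return float(np.clip(v, *vrange)), w


def _solve_fqe(Phi, Phi2, r, gamma: float, lam: float) -> np.ndarray:
    d = Phi.shape[1]
    A = Phi.T @ Phi - gamma * (Phi.T @ Phi2) + lam * np.eye(d)
    return _solve_linear(A, Phi.T @ r)


def fqe(
    data: TransitionDataset,
    policy,
    cfg: TrainingConfig | None = None,
    basis=None,
    method: str = "closed_form",
) -> float:
    """Fitted-Q evaluation of ``policy``: mean Q_pi(s0, pi(s0)) over
    episode-initial states.

    ``method='closed_form'`` solves the ridge-FQI fixed point directly;
    ``method='iterative'`` runs the regression iteration until the fitted
    values stop changing (warning past the iteration cap) -- both converge
    to the same linear fixed point and the iterative path exists as a check.
    """
    cfg = cfg or TrainingConfig()
    Phi, Phi2, r, Phi0 = _fqe_matrices(data, policy, basis)
    if method == "closed_form":
        A0 = Phi.T @ Phi - cfg.gamma * (Phi.T @ Phi2)
        v, _ = _solve_guarded(
            A0, Phi.T @ r, Phi0.mean(axis=0), cfg.fqe_ridge,
            _feasible_range(r, cfg.gamma),
        )
        return v
    elif method == "iterative":
        d = Phi.shape[1]
        G = np.linalg.pinv(Phi.T @ Phi + cfg.fqe_ridge * np.eye(d))
        w = np.zeros(d)
        for i in range(cfg.fqe_max_iter):
            w_new = G @ (Phi.T @ (r + cfg.gamma * (Phi2 @ w)))
            if np.max(np.abs(w_new - w)) < 1e-9:
                w = w_new
                break
            w = w_new
        else:
            import warnings

            warnings.warn("FQE iteration cap reached; returning last iterate")
    else:
        raise ValueError("method must be 'closed_form' or 'iterative'")
    return float((Phi0 @ w).mean())


def bootstrap_value(
    data: TransitionDataset,
    policy,
    cfg: TrainingConfig | None = None,
    n_boot: int = 200,
    seed: int = 0,
    basis=None,
    normalizer: "Normalizer | None" = None,
) -> PolicyValueEstimate:
    """Case-level bootstrap of the FQE estimate (percentile 95% bounds).

    Episodes are resampled with replacement to respect within-case
    correlation; each resample reuses precomputed per-episode moment
    matrices, so the whole bootstrap costs ``n_boot`` small linear solves.
    """
    cfg = cfg or TrainingConfig()
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    Phi, Phi2, r, Phi0 = _fqe_matrices(data, policy, basis)
    d = Phi.shape[1]
    cases = data.cases
    n_cases = len(cases)
    # per-episode sufficient statistics
    A_e = np.empty((n_cases, d, d))
    b_e = np.empty((n_cases, d))
    phi0_e = np.empty((n_cases, d))
    starts = data.episode_starts
    for i, c in enumerate(cases):
        m = data.case_id == c
        P, P2 = Phi[m], Phi2[m]
        A_e[i] = P.T @ P - cfg.gamma * (P.T @ P2)
        b_e[i] = P.T @ r[m]
        phi0_e[i] = Phi0[i]
    vrange = _feasible_range(r, cfg.gamma)
    A0_full = Phi.T @ Phi - cfg.gamma * (Phi.T @ Phi2)
    point, _ = _solve_guarded(
        A0_full, Phi.T @ r, Phi0.mean(axis=0), cfg.fqe_ridge, vrange
    )
    if n_cases == 1:
        import warnings

        warnings.warn("single-case dataset: bootstrap bounds collapse to the point")
        vals = np.full(n_boot, point)
    else:
        rng = np.random.default_rng(seed)
        vals = np.empty(n_boot)
        for bidx in range(n_boot):
            pick = rng.integers(0, n_cases, size=n_cases)
            counts = np.bincount(pick, minlength=n_cases).astype(float)
            A0 = np.einsum("e,eij->ij", counts, A_e)
            b = counts @ b_e
            phi0bar = (counts @ phi0_e) / counts.sum()
            vals[bidx], _ = _solve_guarded(A0, b, phi0bar, cfg.fqe_ridge, vrange)
    lb, ub = np.percentile(vals, [2.5, 97.5])
    est = PolicyValueEstimate(point=point, lb95=float(lb), ub95=float(ub), n_boot=n_boot)
    if normalizer is not None:
        est.normalized = (
            normalizer(point), normalizer(float(lb)), normalizer(float(ub))
        )
    return est


# ---------------------------------------------------------------------------
# normalization


@dataclass
class Normalizer:
    """Affine map sending the reference (derivation-cohort behavior returns)
    into [-1, 1] with mean zero."""

    mu: float
    s: float

    def __call__(self, x):
        return (np.asarray(x, dtype=float) - self.mu) / self.s

    def inverse(self, y):
        return np.asarray(y, dtype=float) * self.s + self.mu

    @classmethod
    def fit(cls, reference) -> "Normalizer":
        ref = np.asarray(reference, dtype=float)
        if len(ref) == 0:
            raise ValueError("reference must be nonempty")
        mu = float(ref.mean())
        s = float(max(ref.max() - mu, mu - ref.min()))
        if s <= 0:
            raise ValueError("reference must not be constant")
        return cls(mu=mu, s=s)


def normalize_values(values, reference):
    """Normalize ``values`` to the [-1, 1] scale anchored by ``reference``."""
    return Normalizer.fit(reference)(values)


# ---------------------------------------------------------------------------
# ensemble


def split_cases(cases: np.ndarray, test_frac: float, rng: np.random.Generator):
    """Random case-level split; the test side gets round(test_frac * n)."""
    cases = np.asarray(cases)
    n_test = int(round(test_frac * len(cases)))
    perm = rng.permutation(cases)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def run_ensemble(
    data: TransitionDataset,
    n_models: int = 300,
    cfg: TrainingConfig | None = None,
    master_seed: int = 0,
    outer_test_frac: float = 0.15,
    inner_train_frac: float = 0.823,
    n_boot: int = 200,
    keep_policies: bool = False,
) -> EnsembleResult:
    """Train ``n_models`` CQL policies on random inner splits and evaluate
    each (and the clinician behavior policy) by bootstrapped FQE.

    The derivation data is split once at the case level into training
    (1 - outer_test_frac) and testing sets; each model then redraws an
    82.3/17.7 inner split of the training cases, trains on the inner
    training side, and is evaluated on both the inner validation cases and
    the held-out outer test cases.  The best model maximizes the 95% lower
    bound of its own (AIVE-style) policy value on the validation set, and
    the decision record compares that bound with the behavior policy's 95%
    upper bound.  Values are also reported on the normalized [-1, 1] scale
    anchored at the derivation cohort's behavior returns.
    """
    cfg = cfg or TrainingConfig()
    if n_models < 1:
        raise ValueError("n_models must be at least 1")
    rng = np.random.default_rng(master_seed)
    cases = data.cases
    if len(cases) < 10:
        raise ValueError("too few cases for ensemble splitting")
    train_cases, test_cases = split_cases(cases, outer_test_frac, rng)
    test_data = data.subset_cases(test_cases)
    behavior = BehaviorPolicy()
    normalizer = Normalizer.fit(data.episode_returns(cfg.gamma))
    beh_test = bootstrap_value(
        test_data, behavior, cfg, n_boot, seed=int(rng.integers(2**31)),
        normalizer=normalizer,
    )
    rows = []
    policies = []
    for m in range(n_models):
        seed_m = int(rng.integers(2**31))
        rng_m = np.random.default_rng(seed_m)
        fit_cases, val_cases = split_cases(
            train_cases, 1.0 - inner_train_frac, rng_m
        )
        fit_data = data.subset_cases(fit_cases)
        val_data = data.subset_cases(val_cases)
        qpol = train_policy(fit_data, replace(cfg, seed=seed_m))
        pol = GreedyPolicy(qpol)
        aive_val = bootstrap_value(val_data, pol, cfg, n_boot, seed=seed_m,
                                   normalizer=normalizer)
        beh_val = bootstrap_value(val_data, behavior, cfg, n_boot, seed=seed_m,
                                  normalizer=normalizer)
        aive_test = bootstrap_value(test_data, pol, cfg, n_boot, seed=seed_m,
                                    normalizer=normalizer)
        rows.append({
            "model": m, "seed": seed_m,
            "n_fit_cases": len(fit_cases), "n_val_cases": len(val_cases),
            "aive_val_point": aive_val.point, "aive_val_lb95": aive_val.lb95,
            "aive_val_ub95": aive_val.ub95,
            "behavior_val_point": beh_val.point, "behavior_val_lb95": beh_val.lb95,
            "behavior_val_ub95": beh_val.ub95,
            "aive_test_point": aive_test.point, "aive_test_lb95": aive_test.lb95,
            "aive_test_ub95": aive_test.ub95,
            "aive_val_lb95_norm": aive_val.normalized[1],
            "behavior_val_ub95_norm": beh_val.normalized[2],
        })
        policies.append(qpol)
    models = pd.DataFrame(rows)
    best = int(models["aive_val_lb95"].idxmax())
    decision = {
        "best_model": best,
        "best_aive_val_lb95": float(models.loc[best, "aive_val_lb95"]),
        "behavior_val_ub95": float(models.loc[best, "behavior_val_ub95"]),
        "best_aive_test_lb95": float(models.loc[best, "aive_test_lb95"]),
        "behavior_test_ub95": beh_test.ub95,
        "behavior_test_point": beh_test.point,
        "aive_exceeds_behavior_val": bool(
            models.loc[best, "aive_val_lb95"] > models.loc[best, "behavior_val_ub95"]
        ),
        "aive_exceeds_behavior_test": bool(
            models.loc[best, "aive_test_lb95"] > beh_test.ub95
        ),
        "n_test_cases": len(test_cases),
    }
    return EnsembleResult(
        models=models, best_model=best, decision=decision,
        normalizer=normalizer, policies=policies if keep_policies else [policies[best]],
    )
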