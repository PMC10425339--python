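"""State, reward, and transition-dataset construction for offline RL.

The decision problem is a discrete-time MDP sampled at 1 Hz: the state
collects drug effect-site concentrations, ventilator mechanics, 6-s moving
averages of the airway-pressure and capnogram envelopes, vitals, the
spontaneous-breathing flag, cumulative apnea time, and ventilation/
extubation status; the action is binary (ventilation on/off).  The reward
penalizes cardiorespiratory derangement in the *next* frame,

    r_t = max(floor, -r_CR),
    r_CR = v_apnea + a1*v_spo2 + a2*v_hr + a3*v_sbp + a4*v_pip,

with a floor of -20.  In the default magnitude mode each penalty is the
excess over its threshold: SpO2 below 97%, cumulative apnea beyond 6 s, and
HR/SBP/PIP more than 20% above the baseline averaged over the 10 s after
the FiO2 step.  An indicator mode (each v in {0, 1} by the same thresholds)
is available for sensitivity analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EmergenceEpisode
from . import tabular

FEATURES = [
    "ce_ppf", "ce_rftn", "sevo_exp", "pip", "tv", "awp_ma6", "etco2_ma6",
    "hr", "spo2", "sbp", "sb_flag", "apnea_cum", "vent_dependent", "intubated",
]
#: features standardized before learning (flags are left as 0/1)
CONTINUOUS = [f for f in FEATURES if f not in ("sb_flag", "vent_dependent", "intubated")]


@dataclass
class RewardConfig:
    """Weights and thresholds of the cardiorespiratory penalty."""

    alpha: tuple = (1.0, 1.0, 1.0, 1.0)
    floor: float = -20.0
    spo2_thresh: float = 97.0
    apnea_thresh: float = 6.0
    rel_thresh: float = 0.20
    baseline_window: int = 10
    penalty_mode: str = "magnitude"

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.alpha) or len(self.alpha) != 4:
            raise ValueError("alpha must be four non-negative weights")
        if self.floor >= 0:
            raise ValueError("reward floor must be negative")
        if self.penalty_mode not in ("magnitude", "indicator"):
            raise ValueError("penalty_mode must be 'magnitude' or 'indicator'")


@dataclass
class Baselines:
    """Pre-emergence reference vitals (mean over the window at FiO2 rise)."""

    hr0: float
    sbp0: float
    pip0: float

    def __post_init__(self) -> None:
        if min(self.hr0, self.sbp0, self.pip0) <= 0:
            raise ValueError("baselines must be positive")


def compute_baseline(episode: EmergenceEpisode, window: int = 10) -> Baselines:
    """Arithmetic means of HR, SBP, PIP over the first ``window`` seconds."""
    if window <= 0:
        raise ValueError("baseline window must be positive")
    if episode.duration < window:
        raise ValueError("episode shorter than the baseline window")
    w = episode.frames.iloc[:window]
    return Baselines(
        hr0=float(w["hr"].mean()),
        sbp0=float(w["sbp"].mean()),
        pip0=float(w["pip"].mean()),
    )


def build_states(episode: EmergenceEpisode) -> pd.DataFrame:
    """Per-second state table (one row per frame, columns = FEATURES).

    The 6-s moving averages are trailing means over [t-6, t), clipped at the
    episode start (the first frame uses its own value).  Ventilation status
    is dependent when ventilation is on or spontaneous breathing is absent.
    """
    f = episode.frames
    n = len(f)
    awp = f["awp"].to_numpy(dtype=float)
    etco2 = f["etco2"].to_numpy(dtype=float)

    def trailing6(x: np.ndarray) -> np.ndarray:
        c = np.concatenate([[0.0], np.cumsum(x)])
        out = np.empty(n)
        for t in range(n):
            lo = max(0, t - 6)
            out[t] = (c[t] - c[lo]) / (t - lo) if t > lo else x[t]
        return out

    # ventilation status entering second t: driven by the previous action so
    # the state never encodes the action chosen at t itself
    actions = episode.actions
    prev = np.concatenate([[1], actions[:-1]])
    vent_dep = ((prev == 1) | (episode.sb_flag == 0)).astype(float)
    if episode.extubation is None:
        intub = np.ones(n)
    else:
        intub = (f.index.to_numpy() < episode.extubation).astype(float)
    states = pd.DataFrame(
        {
            "ce_ppf": f["ce_ppf"].to_numpy(dtype=float),
            "ce_rftn": f["ce_rftn"].to_numpy(dtype=float),
            "sevo_exp": f["sevo"].to_numpy(dtype=float),
            "pip": f["pip"].to_numpy(dtype=float),
            "tv": f["tv"].to_numpy(dtype=float),
            "awp_ma6": trailing6(awp),
            "etco2_ma6": trailing6(etco2),
            "hr": f["hr"].to_numpy(dtype=float),
            "spo2": f["spo2"].to_numpy(dtype=float),
            "sbp": f["sbp"].to_numpy(dtype=float),
            "sb_flag": episode.sb_flag.astype(float),
            "apnea_cum": episode.apnea_cum.astype(float),
            "vent_dependent": vent_dep,
            "intubated": intub,
        },
        index=f.index,
    )
    return states


def compute_penalties(
    frame, base: Baselines, cfg: RewardConfig | None = None
) -> tuple[float, float, float, float, float]:
    """Penalty tuple (v_apnea, v_spo2, v_hr, v_sbp, v_pip) for one state.

    ``frame`` may be a Series/dict with spo2, apnea_cum, hr, sbp, pip.
    """
    cfg = cfg or RewardConfig()
    if min(base.hr0, base.sbp0, base.pip0) <= 0:
        raise ValueError("baselines must be positive")
    v_apnea = max(0.0, float(frame["apnea_cum"]) - cfg.apnea_thresh)
    v_spo2 = max(0.0, cfg.spo2_thresh - float(frame["spo2"]))
    lim = 1.0 + cfg.rel_thresh
    v_hr = max(0.0, 100.0 * (float(frame["hr"]) / base.hr0 - lim))
    v_sbp = max(0.0, 100.0 * (float(frame["sbp"]) / base.sbp0 - lim))
    v_pip = max(0.0, 100.0 * (float(frame["pip"]) / base.pip0 - lim))
    v = (v_apnea, v_spo2, v_hr, v_sbp, v_pip)
    if cfg.penalty_mode == "indicator":
        v = tuple(float(x > 0) for x in v)
    return v


def compute_reward(v, cfg: RewardConfig | None = None) -> float:
    """Clipped negative weighted penalty sum: ``max(floor, -r_CR)``."""
    cfg = cfg or RewardConfig()
    a1, a2, a3, a4 = cfg.alpha
    r_cr = v[0] + a1 * v[1] + a2 * v[2] + a3 * v[3] + a4 * v[4]
    return max(cfg.floor, -r_cr)


def _penalty_matrix(states: pd.DataFrame, base: Baselines, cfg: RewardConfig) -> np.ndarray:
    """Vectorized penalties, rows aligned with ``states``."""
    lim = 1.0 + cfg.rel_thresh
    v = np.column_stack([
        np.maximum(0.0, states["apnea_cum"].to_numpy() - cfg.apnea_thresh),
        np.maximum(0.0, cfg.spo2_thresh - states["spo2"].to_numpy()),
        np.maximum(0.0, 100.0 * (states["hr"].to_numpy() / base.hr0 - lim)),
        np.maximum(0.0, 100.0 * (states["sbp"].to_numpy() / base.sbp0 - lim)),
        np.maximum(0.0, 100.0 * (states["pip"].to_numpy() / base.pip0 - lim)),
    ])
    if cfg.penalty_mode == "indicator":
        v = (v > 0).astype(float)
    return v


@dataclass
class TransitionDataset:
    """Offline (s, a, r, s', done) tuples plus persisted standardization.

    ``X``/``X_next`` hold raw (unstandardized) features; ``standardize``
    applies the stored z-score parameters (flags pass through).  ``extras``
    carries per-row penalty components, abstract-state ids, and baselines
    for analysis and for the linear FQE basis.
    """

    X: np.ndarray
    actions: np.ndarray
    rewards: np.ndarray
    X_next: np.ndarray
    done: np.ndarray
    case_id: np.ndarray
    t: np.ndarray
    feature_names: list
    mean: np.ndarray
    sd: np.ndarray
    extras: pd.DataFrame | None = None
    reward_cfg: RewardConfig = field(default_factory=RewardConfig)

    def __len__(self) -> int:
        return len(self.actions)

    @property
    def n_cases(self) -> int:
        return len(np.unique(self.case_id))

    @property
    def cases(self) -> np.ndarray:
        return np.unique(self.case_id)

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd

    def unstandardize(self, Z: np.ndarray) -> np.ndarray:
        return Z * self.sd + self.mean

    @property
    def Z(self) -> np.ndarray:
        return self.standardize(self.X)

    @property
    def Z_next(self) -> np.ndarray:
        return self.standardize(self.X_next)

    @property
    def episode_starts(self) -> np.ndarray:
        """Row indices of each episode's first transition."""
        first = np.ones(len(self), dtype=bool)
        first[1:] = self.case_id[1:] != self.case_id[:-1]
        return np.flatnonzero(first)

    def subset_cases(self, cases) -> "TransitionDataset":
        """Row-subset by case id, keeping the parent standardization."""
        mask = np.isin(self.case_id, np.asarray(cases))
        return TransitionDataset(
            X=self.X[mask], actions=self.actions[mask], rewards=self.rewards[mask],
            X_next=self.X_next[mask], done=self.done[mask],
            case_id=self.case_id[mask], t=self.t[mask],
            feature_names=self.feature_names, mean=self.mean, sd=self.sd,
            extras=self.extras.loc[mask].reset_index(drop=True)
            if self.extras is not None else None,
            reward_cfg=self.reward_cfg,
        )

    def episode_returns(self, gamma: float) -> np.ndarray:
        """Empirical discounted return of each logged episode."""
        out = []
        for c in self.cases:
            r = self.rewards[self.case_id == c]
            out.append(float(np.polyval(r[::-1], gamma)))
        return np.array(out)

    # -- persistence (plain text) ------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        nxt = pd.DataFrame(self.X_next, columns=[f"next_{c}" for c in self.feature_names])
        head = pd.DataFrame({
            "case_id": self.case_id, "t": self.t, "action": self.actions,
            "reward": self.rewards, "done": self.done.astype(int),
        })
        parts = [head, df, nxt]
        if self.extras is not None:
            parts.append(self.extras.add_prefix("x_"))
        return pd.concat(parts, axis=1)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        schema = {
            "feature_names": list(self.feature_names),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "reward_cfg": asdict(self.reward_cfg),
        }
        path.with_suffix(".schema.json").write_text(json.dumps(schema, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TransitionDataset":
        path = Path(path)
        df = pd.read_csv(path)
        schema = json.loads(path.with_suffix(".schema.json").read_text())
        names = schema["feature_names"]
        extras_cols = [c for c in df.columns if c.startswith("x_")]
        rc = schema.get("reward_cfg", {})
        rc["alpha"] = tuple(rc.get("alpha", (1, 1, 1, 1)))
        return cls(
            X=df[names].to_numpy(float),
            actions=df["action"].to_numpy(int),
            rewards=df["reward"].to_numpy(float),
            X_next=df[[f"next_{c}" for c in names]].to_numpy(float),
            done=df["done"].to_numpy(bool),
            case_id=df["case_id"].to_numpy(int),
            t=df["t"].to_numpy(int),
            feature_names=names,
            mean=np.array(schema["mean"]),
            sd=np.array(schema["sd"]),
            extras=df[extras_cols].rename(columns=lambda c: c[2:]) if extras_cols else None,
            reward_cfg=RewardConfig(**rc),
        )


def build_transitions(
    episodes: list[EmergenceEpisode],
    cfg: RewardConfig | None = None,
) -> TransitionDataset:
    """One transition per second across all episodes.

    The reward of the transition leaving frame t is computed from the
    penalties of frame t+1 ("penalties in the next time step"); the final
    transition of each episode carries ``done``.  Continuous features are
    z-scored with dataset-level mean/sd; the parameters are stored on the
    dataset so any split or new data reuses them.
    """
    cfg = cfg or RewardConfig()
    Xs, As, Rs, Xn, Dn, Cs, Ts = [], [], [], [], [], [], []
    ex_rows = []
    for ep in episodes:
        if ep.duration < 2:
            import warnings

            warnings.warn(f"case {ep.meta.get('case_id')}: episode too short, skipped")
            continue
        base = compute_baseline(ep, cfg.baseline_window)
        states = build_states(ep)
        pen = _penalty_matrix(states, base, cfg)
        rewards = np.maximum(
            cfg.floor,
            -(pen[1:, 0] + pen[1:, 1:] @ np.asarray(cfg.alpha)),
        )
        n = len(states) - 1
        X = states.to_numpy(float)
        Xs.append(X[:-1])
        Xn.append(X[1:])
        As.append(ep.actions[:-1])
        Rs.append(rewards)
        d = np.zeros(n, dtype=bool)
        d[-1] = True
        Dn.append(d)
        cid = int(ep.meta.get("case_id", -1))
        Cs.append(np.full(n, cid))
        Ts.append(states.index.to_numpy()[:-1])
        stress = 100.0 * np.maximum.reduce([
            states["hr"].to_numpy() / base.hr0 - 1.0,
            states["sbp"].to_numpy() / base.sbp0 - 1.0,
            states["pip"].to_numpy() / base.pip0 - 1.0,
        ])
        aid = tabular.abstract_ids(
            states["sb_flag"].to_numpy(), states["apnea_cum"].to_numpy(), stress
        )
        ex = pd.DataFrame(pen[:-1], columns=["v_apnea", "v_spo2", "v_hr", "v_sbp", "v_pip"])
        ex["abstract_id"] = aid[:-1]
        ex["next_abstract_id"] = aid[1:]
        ex["hr0"], ex["sbp0"], ex["pip0"] = base.hr0, base.sbp0, base.pip0
        ex_rows.append(ex)
    if not Xs:
        raise ValueError("no usable episodes")
    X = np.vstack(Xs)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    # flags and near-constant columns pass through unscaled
    flag_idx = [FEATURES.index(f) for f in FEATURES if f not in CONTINUOUS]
    mean[flag_idx] = 0.0
    sd[flag_idx] = 1.0
    sd[sd < 1e-9] = 1.0
    return TransitionDataset(
        X=X, actions=np.concatenate(As).astype(int),
        rewards=np.concatenate(Rs), X_next=np.vstack(Xn),
        done=np.concatenate(Dn), case_id=np.concatenate(Cs).astype(int),
        t=np.concatenate(Ts).astype(int), feature_names=list(FEATURES),
        mean=mean, sd=sd,
        extras=pd.concat(ex_rows, ignore_index=True), reward_cfg=cfg,
    )


def dataset_from_tabular(
    mdp: tabular.TabularMDP,
    policy,
    n_episodes: int,
    rng: np.random.Generator,
    rho: np.ndarray | None = None,
    max_len: int = 500,
) -> TransitionDataset:
    """Roll out a tabular MDP and package the log as a TransitionDataset.

    All episodes are stepped synchronously (vectorized over episodes), so
    collecting tens of thousands of short episodes is cheap.  States are
    encoded one-hot, which makes the linear FQE basis exact and gives the
    Q-network a well-scaled input.  ``policy`` is a deterministic (S,)
    action array or a stochastic (S, A) probability matrix.
    """
    S, A = mdp.n_states, mdp.n_actions
    pol = np.asarray(policy, dtype=float)
    if pol.ndim == 1:
        probs = np.zeros((S, A))
        probs[np.arange(S), pol.astype(int)] = 1.0
    else:
        probs = pol
    cum_pol = probs.cumsum(axis=1)
    cum_P = mdp.P.cumsum(axis=2)
    if rho is None:
        s = np.full(n_episodes, int(np.flatnonzero(~mdp.terminal)[0]))
    else:
        s = rng.choice(S, size=n_episodes, p=rho)
    st_cols, ac_cols, active_cols = [], [], []
    alive = ~mdp.terminal[s]
    for _ in range(max_len):
        if not alive.any():
            break
        a = np.argmax(rng.random(n_episodes)[:, None] < cum_pol[s], axis=1)
        st_cols.append(s.copy())
        ac_cols.append(a)
        active_cols.append(alive.copy())
        nxt = np.empty(n_episodes, dtype=int)
        u = rng.random(n_episodes)
        # vectorized categorical draw from P[s, a]
        nxt = (u[:, None] < cum_P[s, a]).argmax(axis=1)
        s = np.where(alive, nxt, s)
        alive = alive & ~mdp.terminal[s]
    st = np.column_stack(st_cols)        # (n_ep, T)
    ac = np.column_stack(ac_cols)
    act_mask = np.column_stack(active_cols)
    lengths = act_mask.sum(axis=1)
    keep = lengths > 0
    st, ac, act_mask, lengths = st[keep], ac[keep], act_mask[keep], lengths[keep]
    n_ep, T = st.shape
    # flatten row-major so each episode's rows stay contiguous
    flat = act_mask.ravel()
    states = st.ravel()[flat]
    actions = ac.ravel()[flat]
    nxt = np.empty_like(states)
    # successor within the padded grid: shift left, last active row keeps self
    st_next = np.empty_like(st)
    st_next[:, :-1] = st[:, 1:]
    st_next[:, -1] = st[:, -1]
    last = np.zeros_like(act_mask)
    last[np.arange(n_ep), lengths - 1] = True
    nxt = st_next.ravel()[flat]
    done = last.ravel()[flat]
    case = np.repeat(np.arange(n_ep), T).reshape(n_ep, T).ravel()[flat]
    tt = np.tile(np.arange(T), n_ep).reshape(n_ep, T).ravel()[flat]
    rewards = mdp.R[states, actions]
    eye = np.eye(S)
    extras = pd.DataFrame({"state_id": states, "next_state_id": nxt})
    return TransitionDataset(
        X=eye[states], actions=actions.astype(int),
        rewards=rewards, X_next=eye[nxt],
        done=done, case_id=case.astype(int),
        t=tt.astype(int),
        feature_names=[f"state_{i}" for i in range(S)],
        mean=np.zeros(S), sd=np.ones(S), extras=extras,
    )
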