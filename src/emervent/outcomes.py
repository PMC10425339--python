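"""Policy-discrepancy and clinical-outcome statistics.

Per case, the discrepancy is the number of seconds on which the learned
policy's greedy ventilation recommendation differs from the clinician's
recorded action; cardiorespiratory instability is the combined duration of
SpO2 < 95%, or HR/SBP deviating more than 20% (either direction) from
their pre-emergence baselines, with PIP (> 20% increase) and apnea
(EtCO2 < 2 mmHg) tracked as secondary per-parameter durations.  Discrepancy
is correlated with the primary/secondary outcomes using Kendall's tau-b
for continuous columns and the point-biserial coefficient for binary ones,
at a Bonferroni-corrected significance level; trend curves with bootstrap
bands and a tree-SHAP feature attribution of the policy round out the
analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mdp import Baselines, build_states, compute_baseline
from .preprocess import EmergenceEpisode

#: postoperative columns treated as binary
BINARY_OUTCOMES = ("xray_atelectasis", "xray_pulm_edema", "death_30d")


def policy_discrepancy(actions: np.ndarray, recommended: np.ndarray) -> int:
    """Seconds on which recorded and recommended actions differ."""
    actions = np.asarray(actions).astype(int)
    recommended = np.asarray(recommended).astype(int)
    if actions.shape != recommended.shape:
        raise ValueError("action sequences must have equal length")
    return int(np.sum(actions != recommended))


def instability_duration(
    episode: EmergenceEpisode, base: Baselines, rel_thresh: float = 0.20
) -> dict:
    """Composite and per-parameter violation durations (seconds).

    The composite counts each second once if any of SpO2 < 95%,
    |HR/HR0 - 1| > 0.2, |SBP/SBP0 - 1| > 0.2 holds; PIP (increase only)
    and EtCO2 < 2 mmHg are secondary.
    """
    f = episode.frames
    spo2 = f["spo2"].to_numpy(float) < 95.0
    hr = np.abs(f["hr"].to_numpy(float) / base.hr0 - 1.0) > rel_thresh
    sbp = np.abs(f["sbp"].to_numpy(float) / base.sbp0 - 1.0) > rel_thresh
    pip = (f["pip"].to_numpy(float) / base.pip0 - 1.0) > rel_thresh
    etco2 = f["etco2"].to_numpy(float) < 2.0
    return {
        "instability_s": int(np.sum(spo2 | hr | sbp)),
        "spo2_lt95_s": int(spo2.sum()),
        "hr_gt20_s": int(hr.sum()),
        "sbp_gt20_s": int(sbp.sum()),
        "pip_gt20_s": int(pip.sum()),
        "apnea_etco2_lt2_s": int(etco2.sum()),
    }


def case_outcomes(
    episodes: list[EmergenceEpisode],
    qpolicy,
    postop: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-case discrepancy and instability table, joined with
    postoperative outcome columns when provided."""
    rows = []
    for ep in episodes:
        base = compute_baseline(ep)
        states = build_states(ep)
        rec = qpolicy.act(states.to_numpy(float))
        row = {
            "case_id": int(ep.meta.get("case_id", -1)),
            "discrepancy_s": policy_discrepancy(ep.actions, rec),
            "episode_s": ep.duration,
            **instability_duration(ep, base),
        }
        for key in ("age_band", "sex", "surgery_type"):
            if key in ep.meta:
                row[key] = ep.meta[key]
        rows.append(row)
    df = pd.DataFrame(rows)
    if postop is not None:
        df = df.merge(postop, on="case_id", how="left")
    return df


# ---------------------------------------------------------------------------
# correlation statistics


def kendall_tau_b(x, y) -> tuple[float, float]:
    """Kendall's tau-b with tie correction; p from the tie-adjusted normal
    approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("inputs must have equal length of at least 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau-b undefined for an all-tied input")
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def point_biserial(b, y) -> tuple[float, float]:
    """Point-biserial correlation: Pearson r of y with 0/1-coded b, p from
    the t transform on n-2 degrees of freedom."""
    b = np.asarray(b, dtype=float)
    y = np.asarray(y, dtype=float)
    classes = np.unique(b)
    if len(classes) != 2:
        raise ValueError("binary variable must contain exactly two classes")
    code = (b == classes[1]).astype(float)
    res = stats.pointbiserialr(code, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CorrelationReport:
    table: pd.DataFrame
    family_alpha: float
    n_outcomes: int

    @property
    def corrected_level(self) -> float:
        return self.family_alpha / self.n_outcomes


def correlate_outcomes(
    table: pd.DataFrame,
    outcome_cols: list[str] | None = None,
    family_alpha: float = 0.05,
    n_outcomes: int | None = None,
    predictor: str = "discrepancy_s",
    by: str | None = None,
) -> CorrelationReport:
    """Correlate policy discrepancy with every outcome column.

    Continuous outcomes use Kendall's tau-b, binary ones the point-biserial
    coefficient; per-outcome n excludes missing values and significance is
    declared at ``family_alpha / n_outcomes`` (Bonferroni).  ``by`` runs the
    same analysis within subgroups (age band, sex, surgery type).
    """
    if predictor not in table.columns:
        raise ValueError(f"predictor column '{predictor}' missing")
    if outcome_cols is None:
        skip = {predictor, "case_id", "episode_s", "age_band", "sex", "surgery_type"}
        outcome_cols = [
            c for c in table.columns
            if c not in skip and pd.api.types.is_numeric_dtype(table[c])
        ]
    n_out = n_outcomes if n_outcomes is not None else len(outcome_cols)
    level = family_alpha / n_out
    groups = [("all", table)] if by is None else list(table.groupby(by))
    rows = []
    for gname, g in groups:
        for col in outcome_cols:
            sub = g[[predictor, col]].dropna()
            n = len(sub)
            row = {"group": gname, "outcome": col, "n": n,
                   "coefficient": np.nan, "p": np.nan, "significant": False}
            if n >= 3:
                x = sub[predictor].to_numpy()
                y = sub[col].to_numpy()
                try:
                    if col in BINARY_OUTCOMES or set(np.unique(y)) <= {0.0, 1.0}:
                        coef, p = point_biserial(y, x)
                    else:
                        coef, p = kendall_tau_b(x, y)
                    row.update(coefficient=coef, p=p, significant=bool(p < level))
                except ValueError:
                    pass
            rows.append(row)
    return CorrelationReport(
        table=pd.DataFrame(rows), family_alpha=family_alpha, n_outcomes=n_out
    )


# ---------------------------------------------------------------------------
# trend curves


def bootstrap_trend_curve(
    discrepancy,
    outcome,
    n_boot: int = 3000,
    n_grid: int = 50,
    bandwidth: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Smoothed conditional mean of outcome vs discrepancy with a
    case-level bootstrap 95% band.

    The smoother is a fixed-bandwidth Gaussian local mean (Nadaraya-
    Watson); the default bandwidth is a tenth of the predictor range.
    """
    x = np.asarray(discrepancy, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 cases for a trend curve")
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    span = x.max() - x.min()
    h = bandwidth if bandwidth is not None else max(span / 10.0, 1e-9)
    grid = np.linspace(x.min(), x.max(), n_grid)

    def smooth(xs, ys):
        w = np.exp(-0.5 * ((grid[:, None] - xs[None, :]) / h) ** 2)
        return (w @ ys) / np.maximum(w.sum(axis=1), 1e-300)

    curve = smooth(x, y)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, n_grid))
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[i] = smooth(x[idx], y[idx])
    lb, ub = np.percentile(boots, [2.5, 97.5], axis=0)
    return pd.DataFrame({"discrepancy_s": grid, "mean": curve, "lb95": lb, "ub95": ub})


# ---------------------------------------------------------------------------
# feature attribution


def feature_attribution(
    qpolicy,
    states: pd.DataFrame | np.ndarray,
    n_learners: int = 500,
    seed: int = 0,
    actions: np.ndarray | None = None,
) -> pd.Series:
    """Mean absolute tree-SHAP attribution of each state feature.

    A gradient-boosted surrogate with ``n_learners`` weak learners is fit
    to predict the policy's greedy action from raw (unstandardized)
    features; per-feature importances are the mean absolute additive
    contributions, descending.  Passing ``actions`` attributes a logged
    policy (the clinicians') instead of a Q-policy.
    """
    import lightgbm as lgb

    if isinstance(states, pd.DataFrame):
        X = states.to_numpy(float)
        names = list(states.columns)
    else:
        X = np.asarray(states, dtype=float)
        names = list(getattr(qpolicy, "feature_names", None) or
                     [f"f{i}" for i in range(X.shape[1])])
    Xf = pd.DataFrame(X, columns=names)
    if len(X) < 100:
        raise ValueError("need at least 100 states for attribution")
    y = np.asarray(actions) if actions is not None else qpolicy.act(X)
    if len(np.unique(y)) < 2:
        warnings.warn("degenerate policy (single action): uniform importances")
        return pd.Series(np.ones(X.shape[1]) / X.shape[1], index=names)
    model = lgb.LGBMClassifier(
        n_estimators=n_learners, random_state=seed, verbose=-1,
        deterministic=True, force_row_wise=True,
    )
    model.fit(Xf, y)
    contrib = model.predict_proba(Xf, pred_contrib=True)
    imp = np.abs(contrib[:, : X.shape[1]]).mean(axis=0)
    return pd.Series(imp, index=names).sort_values(ascending=False)
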