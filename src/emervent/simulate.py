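"""Synthetic emergence-cohort generator with known ground truth.

Each case models the emergence phase of a general-anesthesia patient on
volume-controlled ventilation.  A latent lognormal time marks the return of
spontaneous breathing (SB); the single control decision each second is
whether ventilation (mechanical or manual) is on.  Piecewise-linear
dynamics with Gaussian observation noise expose every downstream
preprocessing rule and reward term:

* ventilated without SB: stable vitals, cycling airway pressure, normal
  capnogram;
* unventilated without SB: apnea (EtCO2 < 2 mmHg) accrues and, beyond a
  lag, SpO2 declines;
* ventilated against SB (patient-ventilator asynchrony): HR, SBP, and PIP
  drift upward and the airway-pressure trace shows superimposed patient
  efforts (excursions >= 5 cmH2O above the recent maximum, sustained dips
  >= 3 cmH2O below PEEP);
* unventilated with SB: stable, normal capnogram.

Extubation occurs after a fixed hold of sustained SB with ventilation off;
capnography stops 60 s later, which ends the episode.  The "clinician"
behavior policy is the oracle (switch off exactly at SB return) delayed by
a per-case lag and perturbed by occasional spurious toggles, so its
mismatch with the optimum causally drives instability.  Postoperative
outcome columns are noisy monotone functions of each case's instability
duration, planting a recoverable correlation signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import Channel, RawSignalSet
from . import tabular

DEFAULT_NOISE = {
    "awp": 0.3,
    "etco2": 0.15,
    "hr": 1.0,
    "spo2": 0.3,
    "sbp": 2.0,
    "pip": 0.3,
    "tv": 10.0,
    "rr": 0.3,
    "compliance": 2.0,
    "sevo": 0.05,
    "ce_ppf": 0.02,
    "ce_rftn": 0.05,
}

SURGERY_TYPES = (
    "general", "urologic", "orthopedic", "gynecological",
    "neurosurgery", "plastic", "thoracic", "others",
)
SURGERY_PROBS = (0.623, 0.133, 0.084, 0.055, 0.045, 0.043, 0.007, 0.010)


@dataclass
class SimulatorConfig:
    """All knobs of the synthetic emergence cohort.

    Times are seconds, rates per second; the seed fully determines every
    generated byte.  ``sb_recovery_*`` parameterize the lognormal latent SB
    recovery time measured from emergence start (median 240 s by default,
    in line with emergence durations of a few hundred seconds).
    """

    n_cases: int = 200
    seed: int = 0
    # latent spontaneous-breathing recovery time (lognormal, s)
    sb_recovery_logmean: float = math.log(240.0)
    sb_recovery_logsd: float = 0.45
    # drug washout time constants (single-exponential, s)
    drug_halflife_propofol: float = 300.0
    drug_halflife_remifentanil: float = 200.0
    sevo_washout_tau: float = 120.0
    # apnea -> desaturation dynamics
    desat_rate: float = 0.2        # SpO2 %/s decline beyond the lag
    desat_lag: float = 30.0        # s of cumulative apnea before decline
    spo2_recovery_rate: float = 0.5
    # asynchrony -> hemodynamic/pressure stress (% of baseline per s)
    asynchrony_hr_rate: float = 0.5
    asynchrony_sbp_rate: float = 0.6
    asynchrony_pip_rate: float = 0.8
    stress_relax_rate: float = 1.0
    obs_noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE))
    # clinician behavior policy
    behavior_delay_mean: float = 45.0
    behavior_delay_sd: float = 20.0
    behavior_toggle_prob: float = 0.005   # per-second chance a spurious flip starts
    behavior_toggle_dur_mean: float = 8.0
    # episode structure
    episode_max_s: int = 1200
    frame_hz: tuple = (62.5, 2.0, 0.14)
    lead_in_s: int = 30           # recording before the FiO2 step
    extubation_hold_s: int = 30
    etco2_tail_s: int = 60
    # nominal physiology
    hr_baseline: float = 75.0
    sbp_baseline: float = 120.0
    pip_baseline: float = 15.0
    peep: float = 5.0
    tv_baseline: float = 450.0
    rr_baseline: float = 12.0
    compliance_baseline: float = 40.0
    spo2_baseline: float = 99.0
    etco2_plateau: float = 35.0
    fio2_low: float = 50.0
    fio2_high: float = 80.0
    sevo_initial: float = 1.8
    ppf_initial: float = 1.5
    rftn_initial: float = 2.5
    exclusion_flag_rate: float = 0.02  # total probability mass of exclusion flags

    def validate(self) -> None:
        nonneg = [
            self.desat_rate, self.desat_lag, self.spo2_recovery_rate,
            self.asynchrony_hr_rate, self.asynchrony_sbp_rate,
            self.asynchrony_pip_rate, self.stress_relax_rate,
            self.behavior_delay_sd, self.behavior_toggle_prob,
        ]
        if any(v < 0 for v in nonneg):
            raise ValueError("rates and lags must be non-negative")
        if any(sd < 0 for sd in self.obs_noise_sd.values()):
            raise ValueError("observation noise SDs must be non-negative")
        if self.n_cases < 1:
            raise ValueError("n_cases must be at least 1")
        if not (0 < math.exp(self.sb_recovery_logmean) < self.episode_max_s):
            raise ValueError("SB recovery time must lie within the episode cap")
        for tau in (self.drug_halflife_propofol, self.drug_halflife_remifentanil,
                    self.sevo_washout_tau):
            if tau <= 0:
                raise ValueError("washout time constants must be positive")


@dataclass
class GroundTruth:
    """Latent truth for one simulated case (times relative to emergence start)."""

    sb_onset: int
    oracle_actions: np.ndarray
    oracle_return: float
    instability_s: int          # latent composite instability duration
    emergence_start: int        # absolute s of the FiO2 step
    extubation: int | None      # absolute s, None if never extubated
    tabular_value: np.ndarray | None = None


# ---------------------------------------------------------------------------
# policies


class OraclePolicy:
    """Ventilate until spontaneous breathing returns, then stop."""

    def __init__(self, sb_onset: int):
        self.sb_onset = sb_onset

    def __call__(self, frame: dict) -> int:
        return 1 if frame["t_rel"] < self.sb_onset else 0


class SchedulePolicy:
    """Replay a precomputed per-second action schedule (emergence-relative)."""

    def __init__(self, actions: np.ndarray):
        self.actions = np.asarray(actions, dtype=int)

    def __call__(self, frame: dict) -> int:
        t = int(np.clip(frame["t_rel"], 0, len(self.actions) - 1))
        return int(self.actions[t])


def behavior_schedule(
    config: SimulatorConfig, sb_onset: int, rng: np.random.Generator
) -> np.ndarray:
    """Clinician action schedule: oracle delayed by a sampled lag, with
    occasional spurious flips of geometric duration."""
    n = config.episode_max_s
    delay = max(0.0, rng.normal(config.behavior_delay_mean, config.behavior_delay_sd))
    acts = (np.arange(n) < sb_onset + delay).astype(int)
    if config.behavior_toggle_prob > 0:
        t = 0
        while t < n:
            if rng.random() < config.behavior_toggle_prob:
                dur = 1 + rng.geometric(1.0 / config.behavior_toggle_dur_mean)
                acts[t : t + dur] = 1 - acts[t : t + dur]
                t += dur
            t += 1
    return acts


# ---------------------------------------------------------------------------
# latent dynamics


@dataclass
class _Latent:
    """Per-second latent trajectory (absolute time indexing)."""

    T: int
    te: int
    action: np.ndarray
    sb: np.ndarray
    etco2: np.ndarray
    apnea_cum: np.ndarray
    spo2: np.ndarray
    hr: np.ndarray
    sbp: np.ndarray
    pip: np.ndarray
    stress_pct: np.ndarray      # max of HR/SBP/PIP excursions, %
    awp_lo: np.ndarray
    awp_hi: np.ndarray
    extubation: int | None
    instability_s: int


def _latent_run(config: SimulatorConfig, policy, sb_onset: int) -> _Latent:
    """Step the piecewise-linear dynamics under ``policy`` (deterministic)."""
    te = config.lead_in_s
    cap = te + config.episode_max_s
    n = cap + config.etco2_tail_s + 40
    a = np.zeros(n, dtype=int)
    sb = np.zeros(n, dtype=int)
    etco2 = np.zeros(n)
    apnea = np.zeros(n)
    spo2 = np.zeros(n)
    hr = np.zeros(n)
    sbp = np.zeros(n)
    pip = np.zeros(n)
    stress = np.zeros(n)
    awp_lo = np.zeros(n)
    awp_hi = np.zeros(n)

    apnea_cum = 0.0
    s_spo2 = config.spo2_baseline
    r_hr = r_sbp = r_pip = 0.0
    prev_act = 1
    sb_consec = 0
    extub: int | None = None
    ma_awp: list[float] = []
    ma_etco2: list[float] = []
    instab = 0
    T = n
    for t in range(n):
        sb_t = int(t - te >= sb_onset)
        intub = extub is None
        if t < te:
            act = 1
        elif not intub:
            act = 0
        else:
            frame = {
                "t_rel": t - te,
                "ce_ppf": config.ppf_initial * math.exp(-max(0, t - te) / config.drug_halflife_propofol),
                "ce_rftn": config.rftn_initial * math.exp(-max(0, t - te) / config.drug_halflife_remifentanil),
                "sevo_exp": config.sevo_initial * math.exp(-max(0, t - te) / config.sevo_washout_tau),
                "pip": config.pip_baseline * (1 + r_pip / 100),
                "tv": config.tv_baseline,
                "awp_ma6": float(np.mean(ma_awp[-6:])) if ma_awp else config.peep,
                "etco2_ma6": float(np.mean(ma_etco2[-6:])) if ma_etco2 else config.etco2_plateau,
                "hr": config.hr_baseline * (1 + r_hr / 100),
                "spo2": s_spo2,
                "sbp": config.sbp_baseline * (1 + r_sbp / 100),
                "sb_flag": sb_t,
                "apnea_cum": apnea_cum,
                "vent_dependent": int(prev_act == 1 or sb_t == 0),
                "intubated": 1,
            }
            act = int(policy(frame))
        prev_act = act
        vent = act == 1 and intub
        apneic = intub and (not vent) and (sb_t == 0)
        if apneic:
            etco2_t = 0.8
            apnea_cum += 1.0
        else:
            etco2_t = config.etco2_plateau
        if apneic and apnea_cum > config.desat_lag:
            s_spo2 -= config.desat_rate
        else:
            s_spo2 = min(config.spo2_baseline, s_spo2 + config.spo2_recovery_rate)
        s_spo2 = max(70.0, s_spo2)
        asyn = vent and sb_t == 1
        if asyn:
            r_hr += config.asynchrony_hr_rate
            r_sbp += config.asynchrony_sbp_rate
            r_pip += config.asynchrony_pip_rate
        else:
            r_hr = max(0.0, r_hr - config.stress_relax_rate)
            r_sbp = max(0.0, r_sbp - config.stress_relax_rate)
            r_pip = max(0.0, r_pip - config.stress_relax_rate)
        hr_t = config.hr_baseline * (1 + r_hr / 100)
        sbp_t = config.sbp_baseline * (1 + r_sbp / 100)
        pip_t = config.pip_baseline * (1 + r_pip / 100)
        # airway-pressure frame envelope
        if not intub:
            lo, hi = 0.0, 0.5
        elif vent and not sb_t:
            if t % 4 == 0:          # inspiratory peak second of the cycle
                lo, hi = config.peep, pip_t
            else:
                lo, hi = config.peep, config.peep + 2.0
        elif asyn:                  # superimposed patient effort
            lo, hi = config.peep, pip_t + 8.0
        elif intub and not vent and sb_t:
            if t % 3 != 2:          # ~2 s inspiratory effort every 3 s; the
                                    # pair guarantees one boundary-clean frame
                lo = hi = config.peep - 4.0
            else:
                lo = hi = config.peep
        else:                       # vent off, no SB: circuit holds PEEP
            lo = hi = config.peep

        a[t] = act
        sb[t] = sb_t
        etco2[t] = etco2_t
        apnea[t] = apnea_cum
        spo2[t] = s_spo2
        hr[t] = hr_t
        sbp[t] = sbp_t
        pip[t] = pip_t
        stress[t] = max(r_hr, r_sbp, r_pip)
        awp_lo[t] = lo
        awp_hi[t] = hi
        ma_awp.append(hi)
        ma_etco2.append(etco2_t)
        if t >= te and (s_spo2 < 95.0 or r_hr > 20.0 or r_sbp > 20.0):
            instab += 1
        if intub and sb_t and act == 0:
            sb_consec += 1
        else:
            sb_consec = 0
        if intub and sb_consec >= config.extubation_hold_s:
            extub = t
        if extub is not None and t >= extub + config.etco2_tail_s + 29:
            T = t + 1
            break
        if t >= cap:
            T = t + 1
            break

    return _Latent(
        T=T, te=te, action=a[:T], sb=sb[:T], etco2=etco2[:T], apnea_cum=apnea[:T],
        spo2=spo2[:T], hr=hr[:T], sbp=sbp[:T], pip=pip[:T], stress_pct=stress[:T],
        awp_lo=awp_lo[:T], awp_hi=awp_hi[:T], extubation=extub, instability_s=instab,
    )


def _latent_return(config: SimulatorConfig, lat: _Latent, gamma: float) -> float:
    """Discounted clipped reward of a latent run (magnitude penalties,
    alpha = 1), attached to the transition entering each state."""
    te = lat.te
    pen = (
        np.maximum(0.0, lat.apnea_cum[te:] - 6.0)
        + np.maximum(0.0, 97.0 - lat.spo2[te:])
        + np.maximum(0.0, (lat.hr[te:] / config.hr_baseline - 1.2) * 100)
        + np.maximum(0.0, (lat.sbp[te:] / config.sbp_baseline - 1.2) * 100)
        + np.maximum(0.0, (lat.pip[te:] / config.pip_baseline - 1.2) * 100)
    )
    r = np.maximum(-20.0, -pen[1:])
    return float(np.polyval(r[::-1], gamma)) if len(r) else 0.0


# ---------------------------------------------------------------------------
# channel synthesis


def _bump(frac: np.ndarray) -> np.ndarray:
    return np.sin(np.pi * frac) ** 2


def _plateau(frac: np.ndarray) -> np.ndarray:
    return np.clip(1.4 * np.sin(np.pi * frac), 0.0, 1.0)


def _synth_channels(
    config: SimulatorConfig, lat: _Latent, rng: np.random.Generator
) -> dict[str, Channel]:
    noise = config.obs_noise_sd
    wav_hz, vit_hz, dev_hz = config.frame_hz
    T = lat.T
    etco2_end = T if lat.extubation is None else min(T, lat.extubation + config.etco2_tail_s)

    def sec_of(ts):
        return np.clip(ts.astype(int), 0, T - 1)

    # waveforms
    n_w = int(T * wav_hz)
    ts_w = np.arange(n_w) / wav_hz
    sec = sec_of(ts_w)
    frac = ts_w - np.floor(ts_w)
    awp = lat.awp_lo[sec] + (lat.awp_hi[sec] - lat.awp_lo[sec]) * _bump(frac)
    awp = awp + rng.normal(0, noise["awp"], n_w)
    mask_e = ts_w < etco2_end
    etco2 = lat.etco2[sec] * _plateau(frac) + rng.normal(0, noise["etco2"], n_w)
    etco2 = np.clip(etco2, 0.0, None)

    # 2 Hz vitals
    n_v = int(T * vit_hz)
    ts_v = np.arange(n_v) / vit_hz
    sv = sec_of(ts_v)
    hr = lat.hr[sv] + rng.normal(0, noise["hr"], n_v)
    spo2 = np.clip(lat.spo2[sv] + rng.normal(0, noise["spo2"], n_v), 0, 100)
    sbp = lat.sbp[sv] + rng.normal(0, noise["sbp"], n_v)

    # 0.14 Hz ventilator/device scalars
    n_d = int(T * dev_hz) + 1
    ts_d = np.arange(n_d) / dev_hz
    ts_d = ts_d[ts_d < T]
    sd = sec_of(ts_d)
    te = lat.te
    decay = np.maximum(0.0, sd - te)
    pip = lat.pip[sd] + rng.normal(0, noise["pip"], len(sd))
    tv = config.tv_baseline + rng.normal(0, noise["tv"], len(sd))
    rr = config.rr_baseline + rng.normal(0, noise["rr"], len(sd))
    peep = np.full(len(sd), config.peep)
    compl = config.compliance_baseline + rng.normal(0, noise["compliance"], len(sd))
    fio2 = np.where(sd < te, config.fio2_low, config.fio2_high)
    sevo = config.sevo_initial * np.exp(-decay / config.sevo_washout_tau)
    sevo = np.clip(sevo + rng.normal(0, noise["sevo"], len(sd)), 0, None)
    ce_ppf = config.ppf_initial * np.exp(-decay / config.drug_halflife_propofol)
    ce_ppf = np.clip(ce_ppf + rng.normal(0, noise["ce_ppf"], len(sd)), 0, None)
    ce_rftn = config.rftn_initial * np.exp(-decay / config.drug_halflife_remifentanil)
    ce_rftn = np.clip(ce_rftn + rng.normal(0, noise["ce_rftn"], len(sd)), 0, None)

    chans = {
        "awp": Channel("awp", wav_hz, ts_w, awp),
        "etco2": Channel("etco2", wav_hz, ts_w[mask_e], etco2[mask_e]),
        "hr": Channel("hr", vit_hz, ts_v, hr),
        "spo2": Channel("spo2", vit_hz, ts_v, spo2),
        "sbp": Channel("sbp", vit_hz, ts_v, sbp),
        "pip": Channel("pip", dev_hz, ts_d, pip),
        "tv": Channel("tv", dev_hz, ts_d, tv),
        "rr": Channel("rr", dev_hz, ts_d, rr),
        "peep": Channel("peep", dev_hz, ts_d, peep),
        "compliance": Channel("compliance", dev_hz, ts_d, compl),
        "fio2": Channel("fio2", dev_hz, ts_d, fio2.astype(float)),
        "sevo": Channel("sevo", dev_hz, ts_d, sevo),
        "ce_ppf": Channel("ce_ppf", dev_hz, ts_d, ce_ppf),
        "ce_rftn": Channel("ce_rftn", dev_hz, ts_d, ce_rftn),
        "action": Channel("action", 1.0, np.arange(T, dtype=float),
                          lat.action.astype(float), step=True),
    }
    return chans


# ---------------------------------------------------------------------------
# public API


def _case_rngs(config: SimulatorConfig, case_seed: int):
    latent = np.random.default_rng([config.seed, int(case_seed), 1])
    obs = np.random.default_rng([config.seed, int(case_seed), 2])
    beh = np.random.default_rng([config.seed, int(case_seed), 3])
    meta = np.random.default_rng([config.seed, int(case_seed), 4])
    return latent, obs, beh, meta


def _sample_sb_onset(config: SimulatorConfig, rng: np.random.Generator) -> int:
    onset = rng.lognormal(config.sb_recovery_logmean, config.sb_recovery_logsd)
    return int(np.clip(onset, 60, 0.75 * config.episode_max_s))


def simulate_episode(
    config: SimulatorConfig,
    policy,
    case_seed: int,
    gamma: float = 0.99,
) -> tuple[RawSignalSet, GroundTruth]:
    """Simulate one case under ``policy`` (a callable frame -> {0, 1}).

    The frame dict passed to the policy carries the same quantities as the
    downstream state space (drug concentrations, PIP, moving-averaged AWP
    and EtCO2, vitals, SB flag, cumulative apnea, ventilation/extubation
    status) plus ``t_rel``, seconds since emergence start.  Identical
    (config, policy, case_seed) triples produce bit-identical output.
    """
    config.validate()
    rng_lat, rng_obs, _, _ = _case_rngs(config, case_seed)
    sb_onset = _sample_sb_onset(config, rng_lat)
    lat = _latent_run(config, policy, sb_onset)
    chans = _synth_channels(config, lat, rng_obs)
    oracle = OraclePolicy(sb_onset)
    lat_oracle = _latent_run(config, oracle, sb_onset)
    n_act = config.episode_max_s
    oracle_actions = (np.arange(n_act) < sb_onset).astype(int)
    gt = GroundTruth(
        sb_onset=sb_onset,
        oracle_actions=oracle_actions,
        oracle_return=_latent_return(config, lat_oracle, gamma),
        instability_s=lat.instability_s,
        emergence_start=lat.te,
        extubation=lat.extubation,
    )
    raw = RawSignalSet(
        channels=chans,
        meta={
            "case_id": int(case_seed),
            "extubation_s": lat.extubation,
            "peep_set": config.peep,
        },
    )
    return raw, gt


def _case_meta(config: SimulatorConfig, case_id: int, rng: np.random.Generator) -> dict:
    p = config.exclusion_flag_rate / 6.0
    meta = {
        "case_id": case_id,
        "age": int(rng.integers(20, 86)) if rng.random() >= p else int(rng.integers(5, 18)),
        "sex": "F" if rng.random() < 0.505 else "M",
        "surgery_type": str(rng.choice(SURGERY_TYPES, p=SURGERY_PROBS)),
        "pressure_controlled": bool(rng.random() < p),
        "general_anesthesia": bool(rng.random() >= p),
        "laryngeal_mask": bool(rng.random() < p),
        "double_lumen_tube": bool(rng.random() < p),
        "or_extubation": bool(rng.random() >= p),
        "fio2_raised": bool(rng.random() >= p),
    }
    meta["age_band"] = ">50" if meta["age"] > 50 else "<=50"
    return meta


def _postop_outcomes(instab: float, rng: np.random.Generator) -> dict:
    """Noisy monotone functions of instability duration; postoperative
    columns are conditionally independent of everything else given it."""
    I = float(instab)
    out = {
        "los_days": max(0.5, 3.0 + 0.02 * I + rng.normal(0, 1.5)),
        "pacu_min": max(10.0, 45.0 + 0.30 * I + rng.normal(0, 12.0)),
        "hr_48h": 80.0 + 0.05 * I + rng.normal(0, 6.0),
        "sbp_48h": 125.0 + 0.05 * I + rng.normal(0, 8.0),
        "rr_48h": 14.0 + 0.02 * I + rng.normal(0, 2.0),
        "spo2_48h": min(100.0, 97.0 - 0.01 * I + rng.normal(0, 1.0)),
        "pao2": 90.0 - 0.05 * I + rng.normal(0, 8.0),
        "paco2": 40.0 + 0.02 * I + rng.normal(0, 3.0),
        "xray_atelectasis": float(rng.random() < 1 / (1 + math.exp(3.0 - 0.02 * I))),
        "xray_pulm_edema": float(rng.random() < 1 / (1 + math.exp(3.5 - 0.015 * I))),
        "death_30d": float(rng.random() < 1 / (1 + math.exp(6.0 - 0.01 * I))),
    }
    # observational missingness: X-rays and blood gases are not universal
    if rng.random() > 0.523:
        out["xray_atelectasis"] = np.nan
        out["xray_pulm_edema"] = np.nan
    if rng.random() > 0.20:
        out["pao2"] = np.nan
        out["paco2"] = np.nan
    return out


def generate_cohort(
    config: SimulatorConfig, gamma: float = 0.99, with_tabular_value: bool = True
) -> tuple[list[RawSignalSet], pd.DataFrame, pd.DataFrame, list[GroundTruth]]:
    """Generate ``config.n_cases`` cases under the clinician behavior policy.

    Returns raw signal sets, a case metadata table, a postoperative outcome
    table, and per-case ground truth.  Identical configs yield identical
    cohorts; configs differing only in seed yield identical schemas.
    """
    config.validate()
    raws, gts = [], []
    meta_rows, out_rows = [], []
    v_abs = None
    if with_tabular_value:
        _, info = tabular.tabular_abstraction(config, gamma)
        v_abs = info["v_opt"]
    for i in range(config.n_cases):
        rng_lat, _, rng_beh, rng_meta = _case_rngs(config, i)
        sb_onset = _sample_sb_onset(config, rng_lat)
        policy = SchedulePolicy(behavior_schedule(config, sb_onset, rng_beh))
        raw, gt = simulate_episode(config, policy, case_seed=i, gamma=gamma)
        gt.tabular_value = v_abs
        meta = _case_meta(config, i, rng_meta)
        raw.meta.update(meta)
        if not meta["fio2_raised"]:
            # FiO2 never increased before SB recovery: flatten the channel
            ch = raw.channels["fio2"]
            raw.channels["fio2"] = Channel("fio2", ch.rate, ch.timestamps,
                                           np.full_like(ch.values, config.fio2_low))
        out = {"case_id": i, **_postop_outcomes(gt.instability_s, rng_meta)}
        raws.append(raw)
        gts.append(gt)
        meta_rows.append(meta)
        out_rows.append(out)
    return raws, pd.DataFrame(meta_rows), pd.DataFrame(out_rows), gts


__all__ = [
    "SimulatorConfig", "GroundTruth", "OraclePolicy", "SchedulePolicy",
    "behavior_schedule", "simulate_episode", "generate_cohort",
]
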