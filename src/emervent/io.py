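"""Plain-text persistence for cohorts and episodes.

A cohort directory holds one subdirectory per case with each channel as a
two-column CSV (timestamp, value), case metadata and postoperative outcome
tables as single CSVs, per-case ground truth as JSON, and a manifest JSON
listing every path.  Episodes are written as one frame-per-row CSV plus a
JSON sidecar (start, end, SB onset, extubation).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Channel, EmergenceEpisode, RawSignalSet
from .simulate import GroundTruth

_STEP_CHANNELS = {"action"}


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v


def write_cohort(
    out_dir: str | Path,
    raws: list[RawSignalSet],
    meta: pd.DataFrame,
    outcomes: pd.DataFrame,
    gts: list[GroundTruth] | None = None,
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"cases": []}
    for raw in raws:
        cid = raw.meta["case_id"]
        cdir = out / f"case_{cid:05d}"
        cdir.mkdir(exist_ok=True)
        entry = {"case_id": int(cid), "dir": cdir.name, "channels": {}}
        for name, ch in raw.channels.items():
            path = cdir / f"{name}.csv"
            pd.DataFrame({"timestamp": ch.timestamps, "value": ch.values}).to_csv(
                path, index=False
            )
            entry["channels"][name] = {"file": path.name, "rate": ch.rate}
        (cdir / "meta.json").write_text(
            json.dumps({k: _jsonable(v) for k, v in raw.meta.items()}, indent=2)
        )
        manifest["cases"].append(entry)
    meta.to_csv(out / "case_metadata.csv", index=False)
    outcomes.to_csv(out / "postop_outcomes.csv", index=False)
    manifest["case_metadata"] = "case_metadata.csv"
    manifest["postop_outcomes"] = "postop_outcomes.csv"
    if gts is not None:
        for raw, gt in zip(raws, gts):
            cid = raw.meta["case_id"]
            gt_dict = {
                "sb_onset": int(gt.sb_onset),
                "oracle_actions": gt.oracle_actions.tolist(),
                "oracle_return": float(gt.oracle_return),
                "instability_s": int(gt.instability_s),
                "emergence_start": int(gt.emergence_start),
                "extubation": None if gt.extubation is None else int(gt.extubation),
                "tabular_value": None if gt.tabular_value is None
                else np.asarray(gt.tabular_value).tolist(),
            }
            (out / f"case_{cid:05d}" / "ground_truth.json").write_text(
                json.dumps(gt_dict)
            )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def read_cohort(cohort_dir: str | Path):
    """Load a cohort directory back into raw signal sets and tables."""
    root = Path(cohort_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    meta = pd.read_csv(root / manifest["case_metadata"])
    outcomes = pd.read_csv(root / manifest["postop_outcomes"])
    raws = []
    for entry in manifest["cases"]:
        cdir = root / entry["dir"]
        channels = {}
        for name, info in entry["channels"].items():
            df = pd.read_csv(cdir / info["file"])
            channels[name] = Channel(
                name, info["rate"], df["timestamp"].to_numpy(),
                df["value"].to_numpy(), step=name in _STEP_CHANNELS,
            )
        case_meta = json.loads((cdir / "meta.json").read_text())
        raws.append(RawSignalSet(channels=channels, meta=case_meta))
    return raws, meta, outcomes


def write_episodes(out_dir: str | Path, episodes: list[EmergenceEpisode]) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ep in episodes:
        cid = ep.meta.get("case_id", 0)
        f = ep.frames.copy()
        f["sb_flag"] = ep.sb_flag
        f["apnea_cum"] = ep.apnea_cum
        f.to_csv(out / f"episode_{cid:05d}.csv", index_label="second")
        sidecar = {
            "case_id": int(cid), "start": ep.start, "end": ep.end,
            "sb_onset": ep.sb_onset,
            "extubation": ep.extubation,
            "meta": {k: _jsonable(v) for k, v in ep.meta.items()},
        }
        (out / f"episode_{cid:05d}.json").write_text(json.dumps(sidecar, indent=2))
    return out


def read_episodes(ep_dir: str | Path) -> list[EmergenceEpisode]:
    out = []
    for sidecar_path in sorted(Path(ep_dir).glob("episode_*.json")):
        sc = json.loads(sidecar_path.read_text())
        frames = pd.read_csv(sidecar_path.with_suffix(".csv"), index_col="second")
        sb_flag = frames.pop("sb_flag").to_numpy()
        apnea = frames.pop("apnea_cum").to_numpy(dtype=float)
        out.append(
            EmergenceEpisode(
                start=sc["start"], end=sc["end"], frames=frames,
                sb_onset=sc["sb_onset"], sb_flag=sb_flag, apnea_cum=apnea,
                extubation=sc["extubation"], meta=sc.get("meta", {}),
            )
        )
    return out
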