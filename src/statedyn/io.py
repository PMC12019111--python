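"""Flat-text I/O: scan and confound TSVs, templates/truth JSON, subject
tables, generator configs (YAML/JSON)."""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import GeneratorConfig, SyntheticCohort
from .types import CONFOUND_COLUMNS, NetworkTemplates, RoiTimeSeries, SubjectRecord


def write_scan_tsv(ts: RoiTimeSeries, path: str | Path) -> None:
    cols = [f"roi_{i:03d}" for i in range(ts.n_rois)]
    pd.DataFrame(ts.data, columns=cols).to_csv(path, sep="\t", index=False)


def read_scan_tsv(path: str | Path, tr_seconds: float,
                  subject_id: str = "", condition: str = "",
                  confounds_path: str | Path | None = None) -> RoiTimeSeries:
    data = pd.read_csv(path, sep="\t").to_numpy(dtype=float)
    confounds = None
    if confounds_path is not None:
        confounds = pd.read_csv(confounds_path, sep="\t")
        missing = set(CONFOUND_COLUMNS) - set(confounds.columns)
        if missing:
            raise ValueError(f"confounds file lacks columns: {sorted(missing)}")
        confounds = confounds[list(CONFOUND_COLUMNS)]
    return RoiTimeSeries(data=data, tr_seconds=tr_seconds,
                         subject_id=subject_id, condition=condition,
                         confounds=confounds)


def write_confounds_tsv(ts: RoiTimeSeries, path: str | Path) -> None:
    if ts.confounds is None:
        raise ValueError("scan has no confounds")
    ts.confounds.to_csv(path, sep="\t", index=False)


def write_censor_tsv(mask: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"keep": np.asarray(mask, dtype=int)}).to_csv(path, sep="\t", index=False)


def read_censor_tsv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")["keep"].to_numpy(dtype=bool)


def write_templates_json(templates: NetworkTemplates, path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        {"roi_network": list(map(str, templates.roi_network))}, indent=0))


def read_templates_json(path: str | Path) -> NetworkTemplates:
    payload = json.loads(Path(path).read_text())
    return NetworkTemplates(roi_network=np.array(payload["roi_network"], dtype=object))


def subjects_to_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        row = {"subject_id": s.subject_id, "iq": s.iq,
               "d1r_mean": float(np.mean(s.d1r)),
               "d2r_pl_mean": float(np.mean(s.d2r_pl)),
               "d2r_mp_mean": float(np.mean(s.d2r_mp))}
        for name in ("rt_2ball_pl", "rt_2ball_mp", "rt_3ball_pl", "rt_3ball_mp",
                     "acc_2ball_pl", "acc_2ball_mp", "acc_3ball_pl", "acc_3ball_mp"):
            row[name] = getattr(s, name)
        for i, v in enumerate(s.d1r):
            row[f"d1r_roi_{i:02d}"] = float(v)
        rows.append(row)
    return pd.DataFrame(rows)


def write_config_yaml(config: GeneratorConfig, path: str | Path) -> None:
    payload = dataclasses.asdict(config)
    payload["acc_probe_p"] = {f"{task}_{cond}": p for (task, cond), p
                              in payload["acc_probe_p"].items()}
    Path(path).write_text(yaml.safe_dump(payload))


def read_config_yaml(path: str | Path) -> GeneratorConfig:
    payload = yaml.safe_load(Path(path).read_text())
    if "acc_probe_p" in payload:
        payload["acc_probe_p"] = {tuple(k.rsplit("_", 1)): v
                                  for k, v in payload["acc_probe_p"].items()}
    return GeneratorConfig(**payload)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write a cohort as flat text: one data + confounds TSV per scan,
    templates and truth JSON, subject table TSV, and the config YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ts in cohort.scans:
        stem = f"{ts.subject_id}_{ts.condition}"
        write_scan_tsv(ts, out / f"{stem}_bold.tsv")
        write_confounds_tsv(ts, out / f"{stem}_confounds.tsv")
    write_templates_json(cohort.templates, out / "templates.json")
    truth = {
        "state_names": cohort.truth.state_names,
        "sensitivity": cohort.truth.sensitivity,
        "delta_dwell_fpn_plus": cohort.truth.delta_dwell_fpn_plus,
        "sequences": {f"{sid}_{cond}": seq.tolist()
                      for (sid, cond), seq in cohort.truth.sequences.items()},
    }
    (out / "truth.json").write_text(json.dumps(truth))
    subjects_to_frame(cohort.subjects).to_csv(out / "subjects.tsv", sep="\t", index=False)
    write_config_yaml(cohort.config, out / "config.yaml")
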