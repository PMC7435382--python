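"""Plain-text trace files and session/model/report (de)serialization.

Traces travel as two-column CSV: a comment line carrying the sampling
metadata, a header naming the unit, then ``time,value`` rows printed with
17 significant digits so a write/read round trip is exact to double
precision.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .analytics import BreathSegment, FvcVitals
from .synth import RootLaw, SessionDataset, SubjectProfile
from .traces import FlowTrace, PressureTrace, Trace

__all__ = ["read_trace", "write_trace", "write_session", "read_session"]

_UNIT_COLUMNS = {"Pa": "value_Pa", "L/s": "value_Lps"}
_COLUMN_UNITS = {v: k for k, v in _UNIT_COLUMNS.items()}


def write_trace(trace: Trace, path: str | Path) -> Path:
    path = Path(path)
    col = _UNIT_COLUMNS.get(trace.units, "value")
    rate = "" if trace.sample_rate is None else f"{trace.sample_rate!r}"
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz={rate} label={trace.label}\n")
        fh.write(f"time_s,{col}\n")
        for t, v in zip(trace.times, trace.values):
            fh.write(f"{t:.17g},{v:.17g}\n")
    return path


def read_trace(path: str | Path) -> Trace:
    """Read a trace CSV; the unit column decides the returned trace type.

    Rejects missing headers, NaN rows and non-monotone times with
    row-numbered diagnostics.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("#"):
        raise ValueError(f"{path}: missing metadata comment line")
    meta = dict(
        kv.split("=", 1) for kv in first.lstrip("#").strip().split() if "=" in kv
    )
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.shape[1] != 2 or df.columns[0] != "time_s":
        raise ValueError(f"{path}: expected header 'time_s,<value column>'")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    bad = df.index[df.isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: NaN values at data rows {list(bad[:5])}")
    times = df.iloc[:, 0].to_numpy(dtype=float)
    if times.size >= 2:
        step_bad = np.nonzero(np.diff(times) <= 0)[0]
        if step_bad.size:
            raise ValueError(f"{path}: non-monotone time at data row {int(step_bad[0]) + 1}")
    unit = _COLUMN_UNITS.get(df.columns[1], "")
    rate_s = meta.get("sample_rate_hz", "")
    rate = float(rate_s) if rate_s else None
    cls = PressureTrace if unit == "Pa" else FlowTrace if unit == "L/s" else Trace
    return cls(
        times=times,
        values=df.iloc[:, 1].to_numpy(dtype=float),
        sample_rate=rate,
        label=meta.get("label", ""),
    )


def write_session(session: SessionDataset, out_dir: str | Path) -> Path:
    """Write one session: a CSV per trace plus a JSON sidecar with the
    subject profile, ground-truth vitals and segment labels."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_trace(session.inside, out / "inside.csv")
    write_trace(session.outside, out / "outside.csv")
    write_trace(session.reference_flow, out / "reference_flow.csv")
    write_trace(session.truth_flow, out / "truth_flow.csv")
    prof = session.profile
    sidecar = {
        "subject_id": session.subject_id,
        "profile": {
            "tidal_volume": prof.tidal_volume,
            "respiratory_rate": prof.respiratory_rate,
            "fvc_total": prof.fvc_total,
            "peak_expiratory_flow": prof.peak_expiratory_flow,
            "peak_inspiratory_flow": prof.peak_inspiratory_flow,
            "expiratory_decay_tau": prof.expiratory_decay_tau,
            "pressure_gain": prof.pressure_gain.as_dict(),
            "seed": prof.seed,
        },
        "truth_vitals": [v.as_dict() for v in session.truth_vitals],
        "segment_labels": [
            {
                "kind": s.kind,
                "start_time": s.start_time,
                "end_time": s.end_time,
                "expiratory_onset": s.expiratory_onset,
            }
            for s in session.segment_labels
        ],
    }
    (out / "session.json").write_text(json.dumps(sidecar, indent=1))
    return out


def read_session(session_dir: str | Path) -> SessionDataset:
    d = Path(session_dir)
    sidecar = json.loads((d / "session.json").read_text())
    p = sidecar["profile"]
    profile = SubjectProfile(
        tidal_volume=p["tidal_volume"],
        respiratory_rate=p["respiratory_rate"],
        fvc_total=p["fvc_total"],
        peak_expiratory_flow=p["peak_expiratory_flow"],
        peak_inspiratory_flow=p["peak_inspiratory_flow"],
        expiratory_decay_tau=p["expiratory_decay_tau"],
        pressure_gain=RootLaw(**p["pressure_gain"]),
        seed=p["seed"],
    )
    return SessionDataset(
        subject_id=sidecar["subject_id"],
        profile=profile,
        inside=read_trace(d / "inside.csv"),
        outside=read_trace(d / "outside.csv"),
        reference_flow=read_trace(d / "reference_flow.csv"),
        truth_flow=read_trace(d / "truth_flow.csv"),
        truth_vitals=[FvcVitals(**v) for v in sidecar["truth_vitals"]],
        segment_labels=[BreathSegment(**s) for s in sidecar["segment_labels"]],
    )
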