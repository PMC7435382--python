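"""Agreement evaluation between the reference spirometer and the
barometer-predicted flow: the δ metric and the subject-division schemes.

δ is a range-normalized RMSE between paired quantities measured by the two
instruments:

    δ = rmse(q_ref − q_pred) / max(range(q_ref), range(q_pred))

where range is max − min over the evaluation cohort.  Applied to the FVC
vitals across maneuvers it yields per-vital agreement; applied sample-wise
to the continuous airflow or the sliding-window volume it yields the
signal-level agreement.

Three calibration scopes ("division schemes") are compared:

* ``individual`` — one model per subject, evaluated on that subject;
* ``inclusive`` — one model on the pooled cohort, evaluated on everyone;
* ``exclusive`` — subjects split into folds; each fold is predicted by a
  model trained on the other folds (the model never saw the wearer).

When a scheme produces several models (per subject or per fold), the
per-model δ values are aggregated by root mean square.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analytics import (
    VITAL_NAMES,
    FvcVitals,
    compute_fvc_vitals,
    segment_breaths,
    sliding_window_volume,
)
from .conditioning import ConditioningConfig, make_conditioned_pair
from .models import fit_by_name, predict
from .synth import SessionDataset
from .traces import ConditionedPair, FlowTrace

__all__ = [
    "DivisionScheme",
    "DeltaReport",
    "delta_vitals",
    "delta_signal",
    "run_scheme",
    "prepare_sessions",
]


@dataclass(frozen=True)
class DivisionScheme:
    kind: str  # "individual" | "inclusive" | "exclusive"
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("individual", "inclusive", "exclusive"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.kind == "exclusive" and self.n_folds < 2:
            raise ValueError("exclusive scheme needs at least 2 folds")


@dataclass
class DeltaReport:
    scheme: str
    model_name: str
    vitals: dict[str, float]  # aggregated per-vital δ
    airflow: float
    volume: float
    per_unit: list[dict] = field(default_factory=list)  # per-subject or per-fold breakdown


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(a) - np.asarray(b)) ** 2)))


def _delta(ref: np.ndarray, pred: np.ndarray, ranges: tuple[float, float] | None = None) -> float:
    ref, pred = np.asarray(ref, dtype=float), np.asarray(pred, dtype=float)
    r = max(np.ptp(ref), np.ptp(pred)) if ranges is None else max(ranges)
    if r == 0.0:
        raise ValueError("δ undefined: zero value range in both instruments")
    return _rmse(ref, pred) / r


def delta_vitals(ref: list[FvcVitals], pred: list[FvcVitals], vital: str) -> float:
    """δ for one vital over paired maneuvers (range from the inputs)."""
    if len(ref) != len(pred):
        raise ValueError("reference and predicted vitals lists must pair up")
    if len(ref) < 2:
        raise ValueError("need at least two maneuvers for a nonzero range")
    a = np.array([getattr(v, vital) for v in ref])
    b = np.array([getattr(v, vital) for v in pred])
    return _delta(a, b)


def delta_signal(ref: np.ndarray, pred: np.ndarray) -> float:
    """δ applied sample-wise to continuous signals on a common grid."""
    ref, pred = np.asarray(ref, dtype=float), np.asarray(pred, dtype=float)
    if ref.shape != pred.shape:
        raise ValueError("signals must share one grid")
    return _delta(ref, pred)


# ---------------------------------------------------------------------------
# scheme runner


@dataclass
class _Prepared:
    """Per-session cache: conditioned pair, maneuver segments from the
    reference flow, reference vitals and reference sliding-window volume."""

    subject_id: int
    pair: ConditionedPair
    segments: list
    ref_vitals: list[FvcVitals]
    ref_volume: np.ndarray
    volume_times: np.ndarray


def prepare_sessions(
    sessions: list[SessionDataset],
    conditioning: ConditioningConfig = ConditioningConfig(),
) -> list[_Prepared]:
    """Condition every session once and extract the reference-side quantities
    (segments, vitals, windowed volume) reused by each scheme."""
    prepared = []
    for s in sessions:
        pair = make_conditioned_pair(s.inside, s.outside, s.reference_flow, conditioning)
        ref_trace = FlowTrace(times=pair.grid_times, values=pair.flow, sample_rate=None)
        segments = [seg for seg in segment_breaths(ref_trace) if seg.kind == "fvc"]
        if not segments:
            raise ValueError(f"subject {s.subject_id}: no FVC maneuvers found")
        ref_vitals = [compute_fvc_vitals(ref_trace, seg) for seg in segments]
        vol = sliding_window_volume(ref_trace)
        prepared.append(
            _Prepared(
                subject_id=s.subject_id,
                pair=pair,
                segments=segments,
                ref_vitals=ref_vitals,
                ref_volume=vol.values,
                volume_times=vol.times,
            )
        )
    return prepared


def _predict_unit(model, prep: _Prepared) -> dict:
    """Predicted flow, vitals and windowed volume for one subject session."""
    flow_pred = predict(model, prep.pair.dp)
    trace = FlowTrace(times=prep.pair.grid_times, values=flow_pred, sample_rate=None)
    pred_vitals = [compute_fvc_vitals(trace, seg) for seg in prep.segments]
    vol = sliding_window_volume(trace)
    n = min(vol.values.size, prep.ref_volume.size)
    return {
        "subject_id": prep.subject_id,
        "ref_vitals": prep.ref_vitals,
        "pred_vitals": pred_vitals,
        "ref_flow": prep.pair.flow,
        "pred_flow": flow_pred,
        "ref_volume": prep.ref_volume[:n],
        "pred_volume": vol.values[:n],
    }


def _fit_on(preps: list[_Prepared], model_name: str, robust: bool, seed: int):
    x = np.concatenate([p.pair.dp for p in preps])
    y = np.concatenate([p.pair.flow for p in preps])
    model, _ = fit_by_name((x, y), model_name, robust=robust, seed=seed)
    return model


def run_scheme(
    sessions: list[SessionDataset] | list[_Prepared],
    scheme: DivisionScheme,
    model_name: str = "root4",
    seed: int = 0,
    conditioning: ConditioningConfig = ConditioningConfig(),
    robust: bool = False,
    range_scope: str = "global",
) -> DeltaReport:
    """Fit and evaluate one model family under a division scheme.

    ``range_scope`` controls the δ denominator: ``"global"`` (default) uses
    the vital/signal range over the whole evaluated cohort — the published
    definition ("from all participants") — while ``"local"`` uses each
    model's own evaluation unit (subject or fold).
    """
    if range_scope not in ("global", "local"):
        raise ValueError("range_scope must be 'global' or 'local'")
    if sessions and isinstance(sessions[0], SessionDataset):
        prepared = prepare_sessions(sessions, conditioning)
    else:
        prepared = list(sessions)

    # units: list of (test_preps, model)
    units: list[tuple[list[_Prepared], object]] = []
    if scheme.kind == "individual":
        for p in prepared:
            units.append(([p], _fit_on([p], model_name, robust, seed)))
    elif scheme.kind == "inclusive":
        units.append((prepared, _fit_on(prepared, model_name, robust, seed)))
    else:  # exclusive
        if len(prepared) < scheme.n_folds:
            raise ValueError("exclusive scheme needs at least n_folds subjects")
        rng = np.random.default_rng(scheme.seed)
        order = rng.permutation(len(prepared))
        folds = [sorted(order[i::scheme.n_folds].tolist()) for i in range(scheme.n_folds)]
        for fold in folds:
            train = [prepared[i] for i in range(len(prepared)) if i not in fold]
            test = [prepared[i] for i in fold]
            units.append((test, _fit_on(train, model_name, robust, seed)))

    unit_results = []
    for test, model in units:
        preds = [_predict_unit(model, p) for p in test]
        unit_results.append(preds)

    # global ranges over the whole evaluated cohort
    all_preds = [d for preds in unit_results for d in preds]

    def _vital_arrays(dicts, key):
        return {
            v: np.array([getattr(vi, v) for d in dicts for vi in d[key]])
            for v in VITAL_NAMES
        }

    g_ref, g_pred = _vital_arrays(all_preds, "ref_vitals"), _vital_arrays(all_preds, "pred_vitals")
    g_rng = {v: (float(np.ptp(g_ref[v])), float(np.ptp(g_pred[v]))) for v in VITAL_NAMES}
    g_flow_rng = (
        float(np.ptp(np.concatenate([d["ref_flow"] for d in all_preds]))),
        float(np.ptp(np.concatenate([d["pred_flow"] for d in all_preds]))),
    )
    g_vol_rng = (
        float(np.ptp(np.concatenate([d["ref_volume"] for d in all_preds]))),
        float(np.ptp(np.concatenate([d["pred_volume"] for d in all_preds]))),
    )

    per_unit = []
    for preds in unit_results:
        ref_v, pred_v = _vital_arrays(preds, "ref_vitals"), _vital_arrays(preds, "pred_vitals")
        entry = {"subjects": [d["subject_id"] for d in preds], "vitals": {}}
        for v in VITAL_NAMES:
            ranges = g_rng[v] if range_scope == "global" else None
            entry["vitals"][v] = _delta(ref_v[v], pred_v[v], ranges)
        rf = np.concatenate([d["ref_flow"] for d in preds])
        pf = np.concatenate([d["pred_flow"] for d in preds])
        rv = np.concatenate([d["ref_volume"] for d in preds])
        pv = np.concatenate([d["pred_volume"] for d in preds])
        entry["airflow"] = _delta(rf, pf, g_flow_rng if range_scope == "global" else None)
        entry["volume"] = _delta(rv, pv, g_vol_rng if range_scope == "global" else None)
        per_unit.append(entry)

    def _rms(vals):
        return float(np.sqrt(np.mean(np.square(vals))))

    vitals = {v: _rms([u["vitals"][v] for u in per_unit]) for v in VITAL_NAMES}
    return DeltaReport(
        scheme=scheme.kind,
        model_name=model_name,
        vitals=vitals,
        airflow=_rms([u["airflow"] for u in per_unit]),
        volume=_rms([u["volume"] for u in per_unit]),
        per_unit=per_unit,
    )
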