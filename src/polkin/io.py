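"""File formats: TSV for tabular data, JSON sidecars/parameters.

Traces are TSV with columns frame, I0, I45, I90, I135 (integer counts) plus
a ``<name>.json`` sidecar holding frame interval, condition metadata, seed
and calibration.  Events are TSV; rate sets, ground truths, models and
calibrations are JSON with canonical transition names like ``k_1_5``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .changepoint import PolarizedTrace
from .dwellkin import RateSet
from .polarimetry import Calibration, SphericalOrientation

TRACE_COLUMNS = ["frame", "I0", "I45", "I90", "I135"]
EVENT_COLUMNS = ["start", "end", "n_frames", "I0", "I45", "I90", "I135",
                 "theta", "phi", "omega_vs_C1", "state"]


class SchemaError(ValueError):
    pass


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_trace(path, trace: PolarizedTrace, seed: int | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(trace.counts, columns=TRACE_COLUMNS[1:])
    df.insert(0, "frame", np.arange(trace.n_frames))
    df.to_csv(path, sep="\t", index=False)
    meta = {
        "frame_interval": trace.frame_interval,
        "condition": trace.condition,
        "seed": seed,
        "calibration": calibration_to_dict(trace.calibration),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_trace(path) -> PolarizedTrace:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace file not found: {path}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TRACE_COLUMNS:
            raise SchemaError(f"{path}:1: expected columns {TRACE_COLUMNS}, got {header}")
        rows = []
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(TRACE_COLUMNS):
                raise SchemaError(f"{path}:{ln}: expected {len(TRACE_COLUMNS)} columns, "
                                  f"got {len(parts)}")
            try:
                rows.append([int(p) for p in parts])
            except ValueError as exc:
                raise SchemaError(f"{path}:{ln}: non-integer count: {exc}") from None
    counts = np.asarray(rows, dtype=int)[:, 1:]
    meta_path = _sidecar(path)
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    cal = calibration_from_dict(meta.get("calibration")) if meta.get("calibration") \
        else Calibration()
    return PolarizedTrace(counts=counts,
                          frame_interval=meta.get("frame_interval", 0.010),
                          calibration=cal, condition=meta.get("condition", {}))


def write_events(path, events: pd.DataFrame) -> None:
    cols = [c for c in EVENT_COLUMNS if c in events.columns] \
        + [c for c in events.columns if c not in EVENT_COLUMNS and c != "degenerate"]
    events[cols].to_csv(Path(path), sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"events file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("start", "end", "I0", "I45", "I90", "I135") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def calibration_to_dict(cal: Calibration) -> dict:
    return {"delta_deg": cal.delta_deg, "gains": list(cal.gains),
            "backgrounds": list(cal.backgrounds)}


def calibration_from_dict(d: dict) -> Calibration:
    return Calibration(delta_deg=d.get("delta_deg", 0.0),
                       gains=tuple(d.get("gains", (1, 1, 1, 1))),
                       backgrounds=tuple(d.get("backgrounds", (0, 0, 0, 0))))


def _branch_to_dict(branch: dict) -> dict:
    return {f"k_{i}_{j}": v for (i, j), v in sorted(branch.items())}


def _branch_from_dict(d: dict) -> dict:
    out = {}
    for key, v in d.items():
        _, i, j = key.split("_")
        out[(int(i), int(j))] = float(v)
    return out


def rateset_to_dict(rates: RateSet) -> dict:
    return {
        "apo": _branch_to_dict(rates.apo),
        "arg": _branch_to_dict(rates.arg),
        "agm": _branch_to_dict(rates.agm),
        "khalf": {lig: _branch_to_dict(kh) for lig, kh in rates.khalf.items()},
    }


def rateset_from_dict(d: dict) -> RateSet:
    return RateSet(apo=_branch_from_dict(d["apo"]),
                   arg=_branch_from_dict(d["arg"]),
                   agm=_branch_from_dict(d["agm"]),
                   khalf={lig: _branch_from_dict(kh)
                          for lig, kh in d.get("khalf", {}).items()})


def write_rateset(path, rates: RateSet, kd: dict | None = None,
                  extra: dict | None = None) -> None:
    doc = rateset_to_dict(rates)
    if kd is not None:
        doc["kd"] = {lig: {str(s): v for s, v in kds.items()} for lig, kds in kd.items()}
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=1))


def read_rateset(path) -> tuple[RateSet, dict | None]:
    doc = json.loads(Path(path).read_text())
    rates = rateset_from_dict(doc)
    kd = None
    if "kd" in doc:
        kd = {lig: {int(s): float(v) for s, v in kds.items()}
              for lig, kds in doc["kd"].items()}
    return rates, kd


def ground_truth_to_dict(truth) -> dict:
    return {
        "rates": rateset_to_dict(truth.rates),
        "kd": {lig: {str(s): v for s, v in kds.items()} for lig, kds in truth.kd.items()},
        "orientations": [[o.theta_deg, o.phi_deg] for o in truth.orientations],
        "delta_deg": truth.delta_deg,
        "seed": truth.seed,
    }


def ground_truth_from_dict(d: dict):
    from .synthgen import GroundTruth
    return GroundTruth(
        rates=rateset_from_dict(d["rates"]),
        kd={lig: {int(s): float(v) for s, v in kds.items()}
            for lig, kds in d["kd"].items()},
        orientations=tuple(SphericalOrientation(t, p) for t, p in d["orientations"]),
        delta_deg=d["delta_deg"], seed=d["seed"])


def write_ground_truth(path, truth) -> None:
    Path(path).write_text(json.dumps(ground_truth_to_dict(truth), indent=1))


def read_ground_truth(path):
    return ground_truth_from_dict(json.loads(Path(path).read_text()))
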