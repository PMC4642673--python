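"""Patient-record and report I/O.

Records travel as CSV (one header row, columns named after the profile
fields, blanks for missing values) or JSON (a single object or an array
of objects; absent keys are missing).  Prediction reports are versioned
JSON with full-precision probabilities; the human-readable rendering
rounds to whole percent.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List

import pandas as pd

from .model_core import PatientProfile, PredictionPair

REPORT_SCHEMA = "strokedam/prediction-v1"


def read_patient_records(path) -> List[PatientProfile]:
    """Read one or many patient records from a CSV or JSON file."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            data = json.load(fh)
        records = data if isinstance(data, list) else [data]
    else:
        records = pd.read_csv(path).to_dict("records")
    return [PatientProfile.from_dict(r) for r in records]


def prediction_report(profile: PatientProfile, pair: PredictionPair) -> dict:
    return {
        "schema": REPORT_SCHEMA,
        "patient": profile.to_dict(),
        "prediction": pair.as_dict(),
    }


def render_report_text(report: dict) -> str:
    """Whole-percent rendering of one prediction report."""
    pred = report["prediction"]
    lines = ["Three-month outcome forecast (per 100 such patients):"]
    for arm in ("untreated", "treated"):
        d = pred[arm]
        lines.append(
            f"  {arm:9s}  independent {100 * d['p_independent']:3.0f} %   "
            f"dependent {100 * d['p_dependent']:3.0f} %   "
            f"dead {100 * d['p_dead']:3.0f} %"
        )
    lines.append(f"  SICH risk if treated: {100 * pred['p_sich']:.2f} %")
    lines.append(
        f"  net benefit (independence gained by treating): "
        f"{100 * pred['net_benefit']:+.1f} percentage points"
    )
    return "\n".join(lines)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
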