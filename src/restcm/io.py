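"""Text-based I/O: recordings as delimited matrices with JSON sidecars.

A recording is stored as a CSV whose header row holds the channel labels and
whose rows are time samples (so the file is the transpose of the in-memory
channels x samples array), alongside ``<name>.json`` recording the sampling
rate, reference tag and start time.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .referencing import ScalpRecording

__all__ = ["write_recording", "read_recording", "read_events", "write_leadfield",
           "read_leadfield_gain"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: ScalpRecording, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=list(rec.labels))
    df.to_csv(path, index=False, float_format="%.10g")
    meta = {"sfreq": rec.sfreq, "reference": rec.reference, "tmin": rec.tmin,
            "units": "uV"}
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_recording(path) -> ScalpRecording:
    path = Path(path)
    df = pd.read_csv(path)
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(f"missing sidecar {side}")
    meta = json.loads(side.read_text())
    return ScalpRecording(
        data=df.to_numpy().T, labels=tuple(df.columns),
        sfreq=float(meta["sfreq"]), reference=str(meta["reference"]),
        tmin=float(meta.get("tmin", 0.0)),
    )


def read_events(path) -> pd.DataFrame:
    ev = pd.read_csv(path)
    missing = {"onset_s", "condition"} - set(ev.columns)
    if missing:
        raise ValueError(f"events file lacks columns {sorted(missing)}")
    return ev


def write_leadfield(lf, out_dir, name="leadfield") -> Path:
    """Persist a lead field as a delimited matrix plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / f"{name}.csv", lf.gain, delimiter=",")
    meta = {
        "reference_tag": lf.reference_tag,
        "labels": list(lf.montage.labels),
        "model": {"radii": list(lf.model.radii),
                  "conductivities": list(lf.model.conductivities)},
        "grid": {"spacing": lf.grid.spacing, "radius_limit": lf.grid.radius_limit,
                 "hemisphere_only": lf.grid.hemisphere_only,
                 "n_dipoles": len(lf.grid)},
    }
    (out / f"{name}.json").write_text(json.dumps(meta, indent=1))
    return out / f"{name}.csv"


def read_leadfield_gain(path):
    """Load a persisted gain matrix and its sidecar metadata."""
    path = Path(path)
    gain = np.loadtxt(path, delimiter=",")
    meta = json.loads(_sidecar(path).read_text())
    return gain, meta
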