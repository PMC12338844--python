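"""CSV time-series interchange and surrogate serialization.

Time series travel as plain CSV with a ``#``-prefixed header comment carrying
units and provenance, then a header row with at least ``t`` and ``s`` plus any
of ``f``, ``y``, ``f_smooth``.  The time grid must be uniform.  Surrogates
serialize to a single JSON archive (weights, normalization statistics, spec,
seed), so a saved model evaluates identically after reload.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from runtumble.nets import NetSpec, TrainedSurrogate, make_surrogate
from runtumble.preprocess import TimeSeriesRecord

__all__ = ["read_timeseries", "write_timeseries", "save_surrogate", "load_surrogate"]

_GRID_RTOL = 1e-6
_OPTIONAL_COLUMNS = (
    "f", "y", "f_smooth", "f_prime", "f_doubleprime",
    "s_prime", "s_doubleprime", "valid_mask",
)


def write_timeseries(record: TimeSeriesRecord, path) -> None:
    """Lossless CSV dump of all present columns."""
    path = Path(path)
    cols = {"t": record.t, "s": record.s}
    for name in _OPTIONAL_COLUMNS:
        v = getattr(record, name)
        if v is not None:
            cols[name] = v
    frame = pd.DataFrame(cols)
    with path.open("w") as fh:
        meta = {
            "units": record.units,
            "jump_times": list(map(float, record.jump_times)),
            "kink_times": list(map(float, record.kink_times)),
            "provenance": record.provenance,
        }
        fh.write("# runtumble time series " + json.dumps(meta) + "\n")
        frame.to_csv(fh, index=False, float_format="%.17g")


def read_timeseries(path) -> TimeSeriesRecord:
    """Read a CSV time series; rejects missing columns and non-uniform grids."""
    path = Path(path)
    meta = {}
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("#"):
            try:
                meta = json.loads(first.split("time series", 1)[1])
            except (json.JSONDecodeError, IndexError):
                meta = {}
        else:
            fh.seek(0)
        frame = pd.read_csv(fh)
    for col in ("t", "s"):
        if col not in frame.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    if not any(c in frame.columns for c in ("f", "y")):
        raise ValueError(f"need at least one of columns 'f' or 'y' in {path}")
    t = frame["t"].to_numpy(float)
    dts = np.diff(t)
    if np.any(dts <= 0):
        raise ValueError("t must be strictly increasing")
    if not np.allclose(dts, dts[0], rtol=_GRID_RTOL, atol=0.0):
        raise ValueError(
            f"non-uniform time grid (relative spacing spread exceeds {_GRID_RTOL})"
        )
    kwargs = {}
    for name in _OPTIONAL_COLUMNS:
        if name in frame.columns:
            v = frame[name].to_numpy()
            kwargs[name] = v.astype(bool) if name == "valid_mask" else v.astype(float)
    return TimeSeriesRecord(
        t=t,
        s=frame["s"].to_numpy(float),
        units=meta.get("units", "uM"),
        jump_times=np.asarray(meta.get("jump_times", []), float),
        kink_times=np.asarray(meta.get("kink_times", []), float),
        provenance=meta.get("provenance", {}),
        **kwargs,
    )


def save_surrogate(surrogate: TrainedSurrogate, path) -> None:
    """Serialize a surrogate (weights + normalization + spec) to JSON."""
    payload = {
        "kind": surrogate.kind,
        "seed": surrogate.seed,
        "spec": dataclasses.asdict(surrogate.spec),
        "x_mean": surrogate.x_mean.tolist(),
        "x_std": surrogate.x_std.tolist(),
        "scale_a": surrogate.scale_a,
        "scale_b": surrogate.scale_b,
        "flags": sorted(surrogate.flags),
        "best_epoch": surrogate.best_epoch,
        "history": surrogate.history,
        "net_a": {"W": [w.tolist() for w in surrogate.net_a.W],
                  "b": [b.tolist() for b in surrogate.net_a.b]},
        "net_b": {"W": [w.tolist() for w in surrogate.net_b.W],
                  "b": [b.tolist() for b in surrogate.net_b.b]},
    }
    Path(path).write_text(json.dumps(payload))


def load_surrogate(path) -> TrainedSurrogate:
    payload = json.loads(Path(path).read_text())
    spec = NetSpec(**payload["spec"])
    surrogate = make_surrogate(payload["kind"], spec, rng_seed=payload["seed"])
    for net, key in ((surrogate.net_a, "net_a"), (surrogate.net_b, "net_b")):
        net.W = [np.asarray(w, float) for w in payload[key]["W"]]
        net.b = [np.asarray(b, float) for b in payload[key]["b"]]
    surrogate.x_mean = np.asarray(payload["x_mean"], float)
    surrogate.x_std = np.asarray(payload["x_std"], float)
    surrogate.scale_a = float(payload["scale_a"])
    surrogate.scale_b = float(payload["scale_b"])
    surrogate.flags = set(payload["flags"])
    surrogate.best_epoch = payload["best_epoch"]
    surrogate.history = payload["history"]
    return surrogate
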