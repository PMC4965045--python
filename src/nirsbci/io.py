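"""Run-file readers/writers: CSV series plus a JSON metadata sidecar.

The dialect is one row per sample with columns ``time_s, block, label,
ch01_hbo .. chNN_hbo, ch01_hbr .. chNN_hbr`` and a sidecar ``<stem>.json``
carrying the sampling rate, layout parameters and hash, run schedule, task
type and seed, so a run round-trips losslessly (series to float text
precision, metadata exactly).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import build_checkerboard_layout
from .protocol import RunSpec, sample_timeline
from .synth import HemoParams, RunData


class FormatError(ValueError):
    """A run file or its sidecar is malformed."""


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def write_run(run: RunData, path, delimiter: str = ",") -> None:
    path = Path(path)
    n_ch = run.n_channels
    cols = {"time_s": run.time_s, "block": run.block_kind, "label": run.label}
    for n in range(n_ch):
        cols[f"ch{n + 1:02d}_hbo"] = run.hbo[:, n]
    for n in range(n_ch):
        cols[f"ch{n + 1:02d}_hbr"] = run.hbr[:, n]
    pd.DataFrame(cols).to_csv(path, sep=delimiter, index=False, float_format="%.17g")

    grid = run.layout.grids[0]
    meta = {
        "fs": run.fs,
        "n_channels": n_ch,
        "layout": {
            "grid_rows": grid.rows,
            "grid_cols": grid.cols,
            "n_grids": len(run.layout.grids),
            "spacing_mm": grid.spacing_mm,
        },
        "layout_hash": run.layout.layout_hash(),
        "task_type": run.task_type,
        "seed": run.seed,
        "spec": run.spec.to_dict(),
        "params": run.params.to_dict() if run.params is not None else None,
    }
    with open(sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=2)


def read_run(path, delimiter: str = ",") -> RunData:
    path = Path(path)
    side = sidecar_path(path)
    if not side.exists():
        raise FormatError(f"missing metadata sidecar {side}")
    try:
        with open(side) as fh:
            meta = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed sidecar {side}: {exc}") from exc

    try:
        lay = meta["layout"]
        layout = build_checkerboard_layout(
            lay["grid_rows"], lay["grid_cols"], lay["n_grids"], lay["spacing_mm"]
        )
        spec = RunSpec.from_dict(meta["spec"])
        fs = float(meta["fs"])
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"sidecar {side} is missing or corrupts required keys: {exc}") from exc

    if meta.get("layout_hash") and meta["layout_hash"] != layout.layout_hash():
        raise FormatError(f"sidecar {side}: layout hash does not match declared geometry")

    try:
        df = pd.read_csv(path, sep=delimiter)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path} is empty") from exc
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed table: {exc}") from exc

    for col in ("time_s", "block", "label"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")

    n_ch = layout.n_channels
    hbo_cols = [f"ch{n + 1:02d}_hbo" for n in range(n_ch)]
    hbr_cols = [f"ch{n + 1:02d}_hbr" for n in range(n_ch)]
    present_hbo = [c for c in df.columns if c.endswith("_hbo")]
    if len(present_hbo) != n_ch:
        raise FormatError(
            f"{path}: found {len(present_hbo)} HbO channel columns but the "
            f"declared layout has {n_ch} channels"
        )
    missing = [c for c in hbo_cols + hbr_cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing channel columns {missing[:4]}...")

    t, kind, label, block_idx = sample_timeline(spec, fs)
    if len(df) != len(t):
        raise FormatError(
            f"{path}: {len(df)} rows but the declared schedule at {fs} Hz "
            f"implies {len(t)} samples"
        )

    params = HemoParams(**meta["params"]) if meta.get("params") else None
    return RunData(
        spec=spec,
        layout=layout,
        fs=fs,
        time_s=df["time_s"].to_numpy(dtype=float),
        hbo=df[hbo_cols].to_numpy(dtype=float),
        hbr=df[hbr_cols].to_numpy(dtype=float),
        block_kind=df["block"].to_numpy(dtype=object),
        label=df["label"].to_numpy(dtype=object),
        block_index=block_idx,
        task_type=meta.get("task_type", spec.task_type),
        seed=meta.get("seed"),
        params=params,
    )
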