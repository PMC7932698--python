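"""File I/O: TIFF stacks, CSV tables, JSON sidecars, run provenance."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .force import ForceExtensionCurve
from .tracking import CompactionFit, EndTrack


def write_tiff(path, stack: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32))


def read_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def endtrack_to_frame(track: EndTrack) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frame": track.frame_index,
            "time_s": track.frame_index * track.frame_interval,
            "position_px": track.end_position,
            "raw_position_px": track.raw_position,
            "flag": [f.value for f in track.flags],
        }
    )


def write_endtrack(path, track: EndTrack) -> None:
    endtrack_to_frame(track).to_csv(path, index=False)


def write_compaction_fit(path, fit: CompactionFit) -> None:
    write_json(path, fit)


def write_force_curve(path, curve: ForceExtensionCurve) -> None:
    pd.DataFrame(
        {
            "extension_um": curve.extension,
            "force_pN": curve.force,
            "direction": curve.direction,
            "cycle": curve.cycle_index,
        }
    ).to_csv(path, index=False)


def read_force_curves(path) -> list[ForceExtensionCurve]:
    df = pd.read_csv(path)
    curves = []
    for (direction, cycle), grp in df.groupby(["direction", "cycle"], sort=True):
        grp = grp.sort_values("extension_um")
        curves.append(
            ForceExtensionCurve(
                extension=grp["extension_um"].to_numpy(),
                force=grp["force_pN"].to_numpy(),
                direction=direction,
                cycle_index=int(cycle),
            )
        )
    return curves
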