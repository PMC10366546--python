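"""Reading and writing movie stacks, metadata and event tables.

A movie is stored as a multi-page 32-bit-float TIFF of heights in nm, a
sidecar JSON with pixel size, frame interval, seed and the full generator
configuration, and (for synthetic movies) the ground-truth event log as CSV
with columns frame, stripe_id, event, slots, length_nm.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile

from .core import Topograph

__all__ = ["write_movie", "read_movie", "write_topograph", "read_topograph"]


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        if obj.dtype == bool:
            return {"__bool_array_shape__": list(obj.shape),
                    "packed": np.packbits(obj).tolist()}
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_movie(
    out_dir,
    stack: Sequence[Topograph],
    config: Any = None,
    log: Optional[pd.DataFrame] = None,
    seed: Optional[int] = None,
) -> Path:
    """Write stack + sidecar JSON (+ optional event log) into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = np.stack([f.heights for f in stack]).astype(np.float32)
    tifffile.imwrite(out / "movie.tif", data)
    timestamps = [f.timestamp for f in stack]
    meta = {
        "pixel_size": stack[0].pixel_size,
        "timestamps": timestamps,
        "frame_interval": (timestamps[1] - timestamps[0]) if len(stack) > 1 else None,
        "seed": seed,
        "config": _jsonable(config) if config is not None else None,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    if log is not None:
        log.to_csv(out / "events.csv", index=False)
    return out


def read_movie(in_dir) -> Tuple[List[Topograph], dict]:
    """Read a movie directory written by :func:`write_movie`."""
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "meta.json").read_text())
    data = tifffile.imread(in_dir / "movie.tif")
    if data.ndim == 2:
        data = data[None]
    ts = meta.get("timestamps") or [i for i in range(len(data))]
    stack = [
        Topograph(frame.astype(float), meta["pixel_size"], float(t))
        for frame, t in zip(data, ts)
    ]
    return stack, meta


def write_topograph(path, topo: Topograph) -> None:
    tifffile.imwrite(path, topo.heights.astype(np.float32))


def read_topograph(path, pixel_size: float, timestamp: float = 0.0) -> Topograph:
    data = tifffile.imread(path)
    return Topograph(np.asarray(data, dtype=float), pixel_size, timestamp)
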