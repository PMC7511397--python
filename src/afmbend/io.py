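"""File I/O: TIFF height maps, trace/angle tables, config snapshots.

Pixel size is always taken from the configuration, never from TIFF tags —
AFM exports rarely carry reliable resolution metadata.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .config import PipelineConfig
from .image_ops import HeightMap
from .tracing import FilamentTrace

__all__ = [
    "read_height_map", "write_height_map",
    "write_traces", "write_trace_summary",
    "write_config_snapshot", "load_config",
]


def read_height_map(path: str | Path, pixel_size_nm: float) -> HeightMap:
    """Read a single-channel 8/16-bit (or float) grayscale TIFF."""
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel grayscale TIFF, got shape "
            f"{arr.shape}")
    if arr.dtype not in (np.uint8, np.uint16, np.float32, np.float64):
        raise ValueError(f"{path}: unsupported sample format {arr.dtype}")
    return HeightMap(arr.astype(float), pixel_size_nm)


def write_height_map(path: str | Path, hm: HeightMap,
                     dtype: str = "uint16") -> None:
    """Write a height map as 16-bit grayscale TIFF (min-max scaled)."""
    v = hm.values
    vmin, vmax = float(v.min()), float(v.max())
    scale = (vmax - vmin) or 1.0
    if dtype == "uint16":
        out = np.round((v - vmin) / scale * 65535).astype(np.uint16)
    elif dtype == "uint8":
        out = np.round((v - vmin) / scale * 255).astype(np.uint8)
    else:
        raise ValueError("dtype must be uint16 or uint8")
    tifffile.imwrite(str(path), out)


def write_traces(path: str | Path, traces: Sequence[FilamentTrace]) -> None:
    rows = []
    for t in traces:
        for i, (x, y) in enumerate(t.points):
            rows.append((t.trace_id, i, x, y))
    pd.DataFrame(rows, columns=["trace_id", "node", "x_nm", "y_nm"]) \
        .to_csv(path, index=False)


def write_trace_summary(path: str | Path,
                        traces: Sequence[FilamentTrace]) -> None:
    from .tracing import end_to_end
    pd.DataFrame(
        [(t.trace_id, t.contour_length_nm, end_to_end(t)) for t in traces],
        columns=["trace_id", "contour_length_nm", "end_to_end_nm"],
    ).to_csv(path, index=False)


def write_config_snapshot(path: str | Path, config: PipelineConfig) -> None:
    Path(path).write_text(json.dumps(config.model_dump(), indent=2,
                                     sort_keys=True))


def load_config(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from YAML or JSON."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return PipelineConfig(**data)
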