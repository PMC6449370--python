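"""File I/O: TIFF stacks, AFM float maps, trace/localization CSVs, JSON sidecars.

Fluorescence stacks are written as unsigned 16-bit TIFF (values clipped to the
camera range), AFM maps as 32-bit float TIFF in nm.  Every simulation output
can be accompanied by a JSON sidecar holding the full configuration, the seed
and the random-generator name, so any dataset can be regenerated bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

from .afm import HeightMap
from .vesicles import FrameStack


def write_fluorescence_tiff(path: str | Path, stack: FrameStack) -> None:
    data = np.clip(np.round(stack.data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        path,
        data,
        metadata={
            "pixel_size_nm": stack.pixel_size_nm,
            "exposure_ms": stack.exposure_ms,
            "phase": stack.phase,
        },
    )


def read_fluorescence_tiff(
    path: str | Path,
    phase: str,
    pixel_size_nm: float = 100.0,
    exposure_ms: float = 50.0,
) -> FrameStack:
    data = tifffile.imread(path).astype(float)
    if data.ndim == 2:
        data = data[None, :, :]
    return FrameStack(data=data, pixel_size_nm=pixel_size_nm, exposure_ms=exposure_ms, phase=phase)


def write_height_map_tiff(path: str | Path, hmap: HeightMap) -> None:
    tifffile.imwrite(
        path,
        hmap.heights.astype(np.float32),
        metadata={"pixel_size_nm": hmap.pixel_size_nm, "flattened": hmap.flattened},
    )


def read_height_map_tiff(path: str | Path, pixel_size_nm: float) -> HeightMap:
    return HeightMap(heights=tifffile.imread(path).astype(float), pixel_size_nm=pixel_size_nm)


def write_trace_csv(path: str | Path, donor: np.ndarray, acceptor: np.ndarray) -> None:
    pd.DataFrame(
        {"bin": np.arange(len(donor)), "donor": donor, "acceptor": acceptor}
    ).to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["donor"].to_numpy(np.int64), df["acceptor"].to_numpy(np.int64)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_sidecar(path: str | Path, metadata: dict) -> None:
    """Write the full config + seed + RNG name next to a simulated dataset."""
    Path(path).write_text(json.dumps(_jsonable(metadata), indent=2, default=str))
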