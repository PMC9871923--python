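"""TIFF / CSV / JSON persistence for stacks, masks, and tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from campariq.synthetic import TwoChannelStack


def save_stack(stack: TwoChannelStack, outdir: str | Path, prefix: str = "stack") -> dict:
    """Write one channel per multi-page TIFF plus a JSON metadata sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "green": outdir / f"{prefix}_green.tif",
        "red": outdir / f"{prefix}_red.tif",
        "meta": outdir / f"{prefix}_meta.json",
    }
    # photometric is explicit so 3-frame stacks are not stored as RGB planes
    tifffile.imwrite(paths["green"], stack.green.astype(np.float32),
                     photometric="minisblack")
    tifffile.imwrite(paths["red"], stack.red.astype(np.float32),
                     photometric="minisblack")
    meta = {
        "layout": "one series per channel",
        "wavelength_nm": stack.wavelength,
        "power_mW": stack.power,
        "frame_rate_hz": stack.frame_rate,
        "n_frames": stack.n_frames,
    }
    paths["meta"].write_text(json.dumps(meta, indent=2))
    return {k: str(v) for k, v in paths.items()}


def load_stack(outdir: str | Path, prefix: str = "stack") -> TwoChannelStack:
    outdir = Path(outdir)
    meta = json.loads((outdir / f"{prefix}_meta.json").read_text())
    green = np.asarray(tifffile.imread(outdir / f"{prefix}_green.tif"), dtype=float)
    red = np.asarray(tifffile.imread(outdir / f"{prefix}_red.tif"), dtype=float)
    if green.ndim == 2:
        green, red = green[None], red[None]
    return TwoChannelStack(
        green=green,
        red=red,
        wavelength=int(meta["wavelength_nm"]),
        power=float(meta["power_mW"]),
        frame_rate=float(meta["frame_rate_hz"]),
    )


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), np.asarray(mask, dtype=np.int32))


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)))


def save_traces(traces: np.ndarray, path: str | Path) -> None:
    """Trace matrix as CSV, one row per cell, columns are frames."""
    pd.DataFrame(traces).to_csv(Path(path), index_label="cell")


def load_traces(path: str | Path) -> np.ndarray:
    return pd.read_csv(Path(path), index_col="cell").to_numpy(dtype=float)
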