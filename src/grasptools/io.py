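"""File round-trips: multi-page TIFF images with JSON sidecars, and CSV
tables for curves, events and fit reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import CalibratedImage, EventTable

__all__ = [
    "write_image",
    "read_image",
    "write_curve_csv",
    "read_curve_csv",
    "write_events_csv",
    "read_events_csv",
]


def write_image(img: CalibratedImage, path: str | Path, extra_meta: dict | None = None) -> Path:
    """Write a calibrated image as a 16-bit multi-page TIFF + JSON sidecar.

    One TIFF page per channel; the sidecar records the channel order and
    pixel size (plus any caller metadata such as seeds or ground truth).
    """
    path = Path(path)
    names = list(img.channels)
    stack = np.stack([img.channels[n] for n in names])
    tifffile.imwrite(path, np.clip(stack, 0, 65535).astype(np.uint16))
    meta = {"channels": names, "pixel_size_um": img.pixel_size_um}
    if extra_meta:
        meta.update(extra_meta)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def read_image(path: str | Path) -> tuple[CalibratedImage, dict]:
    """Read a TIFF written by :func:`write_image` with its sidecar."""
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    channels = {name: stack[i].astype(float) for i, name in enumerate(meta["channels"])}
    return CalibratedImage(channels, float(meta["pixel_size_um"])), meta


def write_curve_csv(xy: np.ndarray, path: str | Path, x_name: str = "x", y_name: str = "y") -> Path:
    path = Path(path)
    pd.DataFrame({x_name: xy[:, 0], y_name: xy[:, 1]}).to_csv(path, index=False)
    return path


def read_curve_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    return df.iloc[:, :2].to_numpy(dtype=float)


def write_events_csv(events: EventTable, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"intensity": events.intensity, "label": events.label, "source": events.source}
    ).to_csv(path, index=False)
    return path


def read_events_csv(path: str | Path) -> EventTable:
    df = pd.read_csv(path)
    label = (
        df["label"].astype(object).to_numpy()
        if "label" in df
        else np.full(len(df), "unassigned", dtype=object)
    )
    source = str(df["source"].iloc[0]) if "source" in df and len(df) else ""
    return EventTable(intensity=df["intensity"].to_numpy(float), label=label, source=source)
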