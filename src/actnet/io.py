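"""TIFF stack, CSV table, and config file IO."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import DataError, ImageStack

__all__ = [
    "read_stack",
    "write_stack",
    "write_table",
    "read_table",
    "load_config_file",
    "SEGMENT_TABLE_SCHEMA",
]

SEGMENT_TABLE_SCHEMA = "actnet.segment_measurement.v1"


def write_stack(stack: ImageStack, path, dtype=None) -> None:
    """Write an ImageStack as a multi-page TIFF (axes TCYX).

    The native dtype is preserved unless ``dtype`` is given (e.g.
    ``np.uint16`` for camera-like output, with clipping and rounding).
    Pixel size, frame interval and channel names travel in the shaped
    metadata and are restored by :func:`read_stack`.
    """
    data = stack.data
    if dtype is not None:
        dtype = np.dtype(dtype)
        if np.issubdtype(dtype, np.integer):
            info = np.iinfo(dtype)
            data = np.clip(np.rint(data), info.min, info.max)
        data = data.astype(dtype)
    arr = np.moveaxis(data, -1, 1)  # (T, C, Y, X)
    tifffile.imwrite(
        str(path),
        arr,
        metadata={
            "axes": "TCYX",
            "channels": list(stack.channels),
            "pixel_size_um": stack.pixel_size,
            "frame_interval_s": stack.frame_interval,
        },
    )


def read_stack(
    path,
    channel_map: dict[str, int] | None = None,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
) -> ImageStack:
    """Read a multi-page TIFF into a (T, Y, X, C) ImageStack.

    ``channel_map`` names the channels by axis index, e.g.
    ``{"actin": 0, "abp": 1}``; referencing an index the file does not
    have is an error naming the channel.  Bit depth is preserved.
    Metadata written by :func:`write_stack` provides defaults for pixel
    size, frame interval and channel names.
    """
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        arr = series.asarray()
        axes = series.axes
        meta = {}
        if tf.shaped_metadata:
            meta = dict(tf.shaped_metadata[0])

    arr = _normalize_axes(arr, axes, channel_map)
    n_chan = arr.shape[-1]

    if channel_map:
        for name, idx in channel_map.items():
            if not 0 <= idx < n_chan:
                raise DataError(
                    f"channel {name!r} mapped to index {idx} but stack has "
                    f"{n_chan} channel(s)"
                )
        channels = tuple(
            sorted(channel_map, key=channel_map.get)  # type: ignore[arg-type]
        )
        if len(channels) != n_chan:
            # keep unnamed channels addressable
            named = {v: k for k, v in channel_map.items()}
            channels = tuple(
                named.get(i, f"ch{i}") for i in range(n_chan)
            )
    elif "channels" in meta and len(meta["channels"]) == n_chan:
        channels = tuple(meta["channels"])
    else:
        channels = tuple(f"ch{i}" for i in range(n_chan))

    return ImageStack(
        data=arr,
        channels=channels,
        pixel_size=pixel_size or float(meta.get("pixel_size_um", 0.267)),
        frame_interval=frame_interval
        or float(meta.get("frame_interval_s", 2.0)),
    )


def _normalize_axes(arr, axes, channel_map):
    """Coerce a TIFF series to (T, Y, X, C)."""
    if arr.ndim == 2:
        return arr[None, :, :, None]
    if arr.ndim == 3:
        lead_is_channel = ("C" in axes and axes.index("C") == 0) or (
            "C" not in axes
            and "T" not in axes
            and channel_map is not None
            and len(channel_map) == arr.shape[0]
        )
        if lead_is_channel:
            return np.moveaxis(arr, 0, -1)[None]
        return arr[:, :, :, None]
    if arr.ndim == 4:
        # default layout written by write_stack is (T, C, Y, X)
        if axes in ("TCYX", "QQYX", "IYXS"):
            return np.moveaxis(arr, 1, -1)
        if axes == "TYXC":
            return arr
        if axes == "CTYX":
            return np.moveaxis(arr, 0, -1)
        return np.moveaxis(arr, 1, -1)
    raise DataError(f"cannot interpret TIFF with {arr.ndim} dimensions")


def write_table(df: pd.DataFrame, path, schema: str = SEGMENT_TABLE_SCHEMA) -> None:
    """Write a CSV table with a versioned schema comment header."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"# schema={schema}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a CSV table written by :func:`write_table`."""
    return pd.read_csv(path, comment="#")


def load_config_file(path) -> dict:
    """Load a YAML or JSON config file into a dict."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise DataError(f"config file {path} did not parse to a mapping")
    return data
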