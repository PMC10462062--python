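"""Shared containers and errors for the actnet pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ActnetError", "ParameterError", "DataError", "ImageStack"]


class ActnetError(Exception):
    """Base class for all actnet errors."""


class ParameterError(ActnetError, ValueError):
    """An argument violates a documented precondition."""


class DataError(ActnetError, ValueError):
    """Input data is malformed or inconsistent with the configuration."""


@dataclass
class ImageStack:
    """A time-lapse, multi-channel fluorescence image stack.

    Attributes
    ----------
    data:
        ``(T, Y, X, C)`` array of intensities.  Integer dtypes are kept
        as recorded by the camera; conversion to floating point happens
        on demand in the measurement code.
    channels:
        Channel semantics in axis order, e.g. ``("actin", "abp")``.
    pixel_size:
        Lateral pixel size in micrometres.
    frame_interval:
        Time between frames in seconds (2 s for the emulated TIRF
        acquisitions).
    """

    data: np.ndarray
    channels: tuple[str, ...] = ("actin", "abp")
    pixel_size: float = 0.267
    frame_interval: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise DataError(
                f"ImageStack data must be (T, Y, X, C); got shape {self.data.shape}"
            )
        if self.data.shape[-1] != len(self.channels):
            raise DataError(
                f"{self.data.shape[-1]} channels in data but "
                f"{len(self.channels)} channel names {self.channels}"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise DataError(
                f"no channel named {name!r}; stack has {self.channels}"
            ) from None

    def channel(self, name: str) -> np.ndarray:
        """Return the ``(T, Y, X)`` sub-stack for one named channel."""
        return self.data[..., self.channel_index(name)]

    def frame(self, t: int) -> np.ndarray:
        """Return the ``(Y, X, C)`` image at frame ``t``."""
        return self.data[t]

    def astype(self, dtype) -> "ImageStack":
        return replace(self, data=self.data.astype(dtype))
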