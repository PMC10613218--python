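"""Reading, writing and intensity normalization of multi-channel image stacks.

The pipeline works on confocal fluorescence stacks stored as TIFF.  All
quantification downstream (line profiles, the cutoff-100 signal rule) is
defined on 8-bit images, so this module also owns the linear display-range
mapping used to convert raw acquisitions to 8-bit, applied with identical
settings across every image of a condition set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import DimensionError, FormatError, ParameterError

__all__ = [
    "ImageStack",
    "DisplayRange",
    "read_stack",
    "write_stack",
    "to_8bit",
    "display_ranges_from_stack",
]


@dataclass
class ImageStack:
    """Multi-channel pixel array indexed (channel, z, y, x).

    Parameters
    ----------
    pixels:
        Intensity array of shape ``(n_channels, n_z, height, width)``.
        2D acquisitions carry a singleton z axis.
    pixel_size_um:
        Physical size of one pixel in micrometres; must be positive.
    bit_depth:
        One of 8, 12, 16 or the string ``"float"``.
    channel_names:
        One label per channel, e.g. ``["CD63", "Exo84", "CoxIV", "DAPI"]``.
    """

    pixels: np.ndarray
    pixel_size_um: float = 0.1
    bit_depth: int | str = 16
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise DimensionError(
                f"pixels must be (channel, z, y, x); got shape {self.pixels.shape}"
            )
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.pixels.shape[0])]
        if len(self.channel_names) != self.pixels.shape[0]:
            raise DimensionError(
                f"{len(self.channel_names)} channel names for "
                f"{self.pixels.shape[0]} channels"
            )
        if self.bit_depth == 8 and self.pixels.size:
            lo, hi = self.pixels.min(), self.pixels.max()
            if lo < 0 or hi > 255:
                raise ParameterError("8-bit stack contains values outside [0, 255]")

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixels.shape[2], self.pixels.shape[3]

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            try:
                return self.channel_names.index(channel)
            except ValueError:
                raise ParameterError(f"no channel named {channel!r}") from None
        return int(channel)

    def channel(self, channel: int | str) -> np.ndarray:
        """Return one channel as a (z, y, x) array."""
        return self.pixels[self.channel_index(channel)]

    def plane(self, channel: int | str, z: int = 0) -> np.ndarray:
        """Return a single 2D plane (y, x)."""
        return self.pixels[self.channel_index(channel), z]


@dataclass(frozen=True)
class DisplayRange:
    """Fixed linear display mapping [low, high] -> [0, 255].

    The same range must be reused across all images of a condition set so
    that 8-bit intensities are comparable between conditions.
    """

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.high > self.low:
            raise ParameterError(
                f"DisplayRange requires high > low; got ({self.low}, {self.high})"
            )


def read_stack(
    path,
    layout: str | None = None,
    pixel_size_um: float = 0.1,
    channel_names: list[str] | None = None,
) -> ImageStack:
    """Read a TIFF file into an :class:`ImageStack`.

    ``layout`` names each axis of the stored array with characters from
    ``czyx`` (e.g. ``"cyx"`` for a 2D multichannel image, ``"zyx"`` for a
    single-channel z-stack).  Missing axes become singletons.  When omitted,
    2D arrays are read as ``yx``, 3D as ``cyx`` and 4D as ``czyx``.
    """
    try:
        arr = np.asarray(tifffile.imread(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if layout is None:
        layout = {2: "yx", 3: "cyx", 4: "czyx"}.get(arr.ndim)
        if layout is None:
            raise DimensionError(f"cannot infer layout for {arr.ndim}-D array")
    layout = layout.lower()
    if len(layout) != arr.ndim or len(set(layout)) != len(layout):
        raise DimensionError(
            f"layout {layout!r} inconsistent with array of shape {arr.shape}"
        )
    if any(ax not in "czyx" for ax in layout):
        raise DimensionError(f"layout {layout!r} contains axes other than czyx")
    if "y" not in layout or "x" not in layout:
        raise DimensionError("layout must include y and x axes")
    # reorder present axes to (c, z, y, x), inserting singletons for absent ones
    order = [ax for ax in "czyx" if ax in layout]
    arr = np.transpose(arr, [layout.index(ax) for ax in order])
    for i, ax in enumerate("czyx"):
        if ax not in layout:
            arr = np.expand_dims(arr, axis=i)
    bit_depth: int | str
    if arr.dtype == np.uint8:
        bit_depth = 8
    elif arr.dtype == np.uint16:
        bit_depth = 16
    else:
        bit_depth = "float"
    return ImageStack(
        pixels=arr,
        pixel_size_um=pixel_size_um,
        bit_depth=bit_depth,
        channel_names=channel_names or [],
    )


def write_stack(stack: ImageStack, path) -> None:
    """Write an :class:`ImageStack` to a multi-page TIFF (czyx order)."""
    tifffile.imwrite(path, stack.pixels, metadata={"axes": "CZYX"})


def display_ranges_from_stack(stack: ImageStack) -> list[DisplayRange]:
    """Per-channel (min, max) display ranges of one stack.

    Used to freeze the 8-bit mapping on the first image of a batch and then
    reuse it unchanged for every other image of the batch.
    """
    ranges = []
    for c in range(stack.n_channels):
        lo = float(stack.pixels[c].min())
        hi = float(stack.pixels[c].max())
        if hi <= lo:
            hi = lo + 1.0
        ranges.append(DisplayRange(lo, hi))
    return ranges


def to_8bit(stack: ImageStack, ranges: DisplayRange | list[DisplayRange]) -> ImageStack:
    """Convert a stack to 8-bit with a fixed linear display mapping.

    Values at or below ``low`` map to 0, at or above ``high`` to 255, and in
    between to ``round(255 * (v - low) / (high - low))`` with round-half-up
    (peak areas downstream depend on this rounding convention, so it is fixed
    here rather than left to the platform).
    """
    if isinstance(ranges, DisplayRange):
        ranges = [ranges] * stack.n_channels
    if len(ranges) != stack.n_channels:
        raise ParameterError(
            f"{len(ranges)} display ranges for {stack.n_channels} channels"
        )
    out = np.empty(stack.pixels.shape, dtype=np.uint8)
    for c, rng in enumerate(ranges):
        scaled = (
            (stack.pixels[c].astype(np.float64) - rng.low) / (rng.high - rng.low)
        ) * 255.0
        out[c] = np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)
    return ImageStack(
        pixels=out,
        pixel_size_um=stack.pixel_size_um,
        bit_depth=8,
        channel_names=list(stack.channel_names),
    )
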