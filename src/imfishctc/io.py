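"""Reading, writing and bundling of imFISH channel images.

A field is acquired as four aligned single-channel rasters: DAPI (nuclei),
CD45 (pan-leukocyte antigen), CEP8 and CEP17 (centromere enumeration
probes for chromosomes 8 and 17).  The lossless on-disk representation is
one grayscale TIFF or PNG per channel plus a small JSON manifest; an RGB
composite (as produced by merge-view microscope software) can instead be
decomposed by hue into approximate channels.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "ChannelRole",
    "ChannelImage",
    "ChannelStack",
    "FormatError",
    "AlignmentError",
    "DEFAULT_HUE_WINDOWS",
    "read_channel",
    "write_channel",
    "load_field",
    "decompose_composite",
    "render_composite",
    "write_overlay",
]


class ChannelRole(str, enum.Enum):
    """Fluorescence channel roles used throughout the pipeline."""

    DAPI = "DAPI"
    CD45 = "CD45"
    CEP8 = "CEP8"
    CEP17 = "CEP17"


class FormatError(ValueError):
    """Raised when an image file does not match the expected layout."""


class AlignmentError(ValueError):
    """Raised when channels of one field disagree in shape."""


@dataclass
class ChannelImage:
    """One single-channel raster with its bit depth and role.

    Coordinates are 0-based, row-major ``(row, col)``.  Intensities are
    kept in native units; 16-bit data is never rescaled.
    """

    pixels: np.ndarray
    bit_depth: int
    role: ChannelRole

    def __post_init__(self) -> None:
        self.role = ChannelRole(self.role)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise FormatError("channel raster must be a non-empty 2-D array")
        if self.bit_depth not in (8, 16):
            raise FormatError(f"bit depth must be 8 or 16, got {self.bit_depth}")
        if self.pixels.max(initial=0) > self.max_intensity:
            raise FormatError("intensities exceed the declared bit depth")

    @property
    def max_intensity(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class ChannelStack:
    """All channels of one microscopy field, dimension-checked.

    DAPI is mandatory (nuclei are segmented from it); CD45/CEP8/CEP17 are
    optional but required for full CTC calling.
    """

    field_id: str
    channels: dict[ChannelRole, ChannelImage] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = {ChannelRole(k): v for k, v in self.channels.items()}
        if ChannelRole.DAPI not in self.channels:
            raise ValueError(f"field {self.field_id!r}: DAPI channel is required")
        shapes = {role: img.shape for role, img in self.channels.items()}
        ref = shapes[ChannelRole.DAPI]
        bad = [r.value for r, s in shapes.items() if s != ref]
        if bad:
            raise AlignmentError(
                f"field {self.field_id!r}: channels {bad} do not match DAPI shape {ref}"
            )

    @property
    def height(self) -> int:
        return self.channels[ChannelRole.DAPI].shape[0]

    @property
    def width(self) -> int:
        return self.channels[ChannelRole.DAPI].shape[1]

    @property
    def missing_roles(self) -> frozenset[ChannelRole]:
        return frozenset(set(ChannelRole) - set(self.channels))

    def __contains__(self, role: ChannelRole | str) -> bool:
        return ChannelRole(role) in self.channels

    def get(self, role: ChannelRole | str) -> ChannelImage | None:
        return self.channels.get(ChannelRole(role))


def _bit_depth_of(arr: np.ndarray, path: Path) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    raise FormatError(f"{path}: unsupported dtype {arr.dtype}; expected uint8 or uint16")


def read_channel(path: str | Path, role: ChannelRole | str) -> ChannelImage:
    """Read a single-channel 8/16-bit TIFF or PNG as the given role.

    16-bit data is preserved without rescaling.  A multi-channel file is
    rejected with an error naming its channel count.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        raise FormatError(
            f"{path}: expected a single-channel image, got {arr.shape[-1]} channels"
        )
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    return ChannelImage(pixels=arr, bit_depth=_bit_depth_of(arr, path), role=ChannelRole(role))


def write_channel(image: ChannelImage, path: str | Path) -> Path:
    """Write a channel to TIFF or PNG, bit-exactly."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels)
    else:
        iio.imwrite(path, image.pixels)
    return path


def load_field(manifest: str | Path | Mapping) -> ChannelStack:
    """Load a field from a JSON manifest mapping roles to image paths.

    The manifest is ``{"field_id": ..., "channels": {"DAPI": path, ...}}``;
    paths are resolved relative to the manifest file's directory.  All
    channels are dimension-checked against DAPI.
    """
    base = Path(".")
    if isinstance(manifest, (str, Path)):
        mpath = Path(manifest)
        base = mpath.parent
        with open(mpath) as fh:
            manifest = json.load(fh)
    field_id = str(manifest.get("field_id", "field"))
    entries = manifest.get("channels", {})
    if "DAPI" not in entries:
        raise ValueError(f"manifest for {field_id!r} lacks the required DAPI entry")
    channels = {}
    for role_name, rel in entries.items():
        role = ChannelRole(role_name)
        p = Path(rel)
        if not p.is_absolute():
            p = base / p
        channels[role] = read_channel(p, role)
    return ChannelStack(field_id=field_id, channels=channels)


# Hue windows (degrees, half-open, wrap-around allowed) used to split an RGB
# merge view into channels.  Orange and red shade into each other in RGB
# space, so the red window ends exactly where orange begins; the defaults
# are pairwise disjoint.
DEFAULT_HUE_WINDOWS: dict[ChannelRole, tuple[float, float]] = {
    ChannelRole.DAPI: (200.0, 260.0),   # blue
    ChannelRole.CD45: (330.0, 15.0),    # red (wraps through 0)
    ChannelRole.CEP8: (15.0, 45.0),     # orange
    ChannelRole.CEP17: (90.0, 150.0),   # green
}


def _window_arcs(lo: float, hi: float) -> list[tuple[float, float]]:
    lo, hi = lo % 360.0, hi % 360.0
    if lo < hi:
        return [(lo, hi)]
    return [(lo, 360.0), (0.0, hi)]


def _windows_overlap(w1: tuple[float, float], w2: tuple[float, float]) -> bool:
    for a0, a1 in _window_arcs(*w1):
        for b0, b1 in _window_arcs(*w2):
            if max(a0, b0) < min(a1, b1):
                return True
    return False


def decompose_composite(
    rgb: np.ndarray,
    hue_windows: Mapping[ChannelRole | str, tuple[float, float]] | None = None,
    field_id: str = "composite",
) -> ChannelStack:
    """Split an RGB composite into per-role grayscale channels by hue.

    For each role a pixel keeps its HSV value (brightness) where its hue
    falls inside the role's window and is zero elsewhere.  Windows must be
    pairwise disjoint on the hue circle.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise FormatError(f"composite must be H x W x 3, got shape {rgb.shape}")
    windows = {
        ChannelRole(k): tuple(v)
        for k, v in (hue_windows or DEFAULT_HUE_WINDOWS).items()
    }
    roles = list(windows)
    for i, r1 in enumerate(roles):
        for r2 in roles[i + 1 :]:
            if _windows_overlap(windows[r1], windows[r2]):
                raise ValueError(
                    f"hue windows for {r1.value} and {r2.value} overlap"
                )
    bit_depth = 16 if rgb.dtype == np.uint16 else 8
    rgbf = rgb.astype(np.float64)
    value = rgbf.max(axis=2)
    cmin = rgbf.min(axis=2)
    delta = value - cmin
    r, g, b = rgbf[..., 0], rgbf[..., 1], rgbf[..., 2]
    hue = np.zeros_like(value)
    nz = delta > 0
    rmax = nz & (value == r)
    gmax = nz & ~rmax & (value == g)
    bmax = nz & ~rmax & ~gmax
    hue[rmax] = (60.0 * (g[rmax] - b[rmax]) / delta[rmax]) % 360.0
    hue[gmax] = 60.0 * (b[gmax] - r[gmax]) / delta[gmax] + 120.0
    hue[bmax] = 60.0 * (r[bmax] - g[bmax]) / delta[bmax] + 240.0
    channels = {}
    for role, window in windows.items():
        inside = np.zeros(value.shape, dtype=bool)
        for lo, hi in _window_arcs(*window):
            inside |= (hue >= lo) & (hue < hi)
        inside &= nz  # gray/black pixels have undefined hue
        plane = np.where(inside, value, 0.0).astype(rgb.dtype)
        channels[role] = ChannelImage(pixels=plane, bit_depth=bit_depth, role=role)
    if ChannelRole.DAPI not in channels:
        raise ValueError("hue windows must include a DAPI window")
    return ChannelStack(field_id=field_id, channels=channels)


# Display colors (RGB weights per channel) used for merge views and overlays.
_DISPLAY_RGB = {
    ChannelRole.DAPI: (0.0, 0.0, 1.0),
    ChannelRole.CD45: (1.0, 0.0, 0.0),
    ChannelRole.CEP8: (1.0, 0.5, 0.0),
    ChannelRole.CEP17: (0.0, 1.0, 0.0),
}


def render_composite(stack: ChannelStack) -> np.ndarray:
    """Merge the channels of a field into an 8-bit RGB display image."""
    out = np.zeros((stack.height, stack.width, 3), dtype=np.float64)
    for role, img in stack.channels.items():
        w = _DISPLAY_RGB[role]
        norm = img.pixels.astype(np.float64) / img.max_intensity
        for c in range(3):
            if w[c]:
                out[..., c] += w[c] * norm
    return (np.clip(out, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def write_overlay(stack: ChannelStack, calls: Sequence, path: str | Path) -> Path:
    """Write the merged field with red boxes around CTC-positive nuclei.

    Mirrors the review view in which identified CTCs are marked with a red
    rectangle on the merge image.  Byte output is deterministic for fixed
    input.
    """
    from .caller import CallLabel  # local import to avoid a cycle

    rgb = render_composite(stack)
    h, w = rgb.shape[:2]
    for call in calls:
        r0, r1, c0, c1 = call.nucleus.bbox
        if not (0 <= r0 <= r1 <= h and 0 <= c0 <= c1 <= w):
            raise ValueError(
                f"call for nucleus {call.nucleus.label} lies outside the field bounds"
            )
        if call.label is not CallLabel.CTC_POSITIVE:
            continue
        rr0, rr1 = max(r0 - 2, 0), min(r1 + 2, h)
        cc0, cc1 = max(c0 - 2, 0), min(c1 + 2, w)
        red = np.array([255, 0, 0], dtype=np.uint8)
        rgb[rr0:rr1, [cc0, cc1 - 1]] = red
        rgb[[rr0, rr1 - 1], cc0:cc1] = red
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, rgb)
    else:
        iio.imwrite(path, rgb)
    return path
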