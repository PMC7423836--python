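"""FISH signal-point detection and merging within a nucleus.

CEP8 and CEP17 centromere probes appear as small bright spots.  Spots are
detected per nucleus with a white top-hat filter and an Otsu cut on its
response, then nearby detections are merged: two points closer than one
spot diameter count as a single signal point.  Counts of merged points
feed the >= 3 aneuploidy condition of the cell caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from skimage import measure, morphology

from .io import ChannelImage, ChannelRole, ChannelStack
from .segmentation import NucleusRegion, otsu_threshold

__all__ = [
    "SignalPoint",
    "SpotParams",
    "detect_spots",
    "merge_spots",
    "count_signals",
    "spots_to_frame",
]

SPOT_ROLES = (ChannelRole.CEP8, ChannelRole.CEP17)


@dataclass(frozen=True)
class SignalPoint:
    """One detected FISH spot."""

    centroid: tuple[float, float]
    area: int
    channel: ChannelRole
    peak_intensity: float

    @property
    def equiv_diameter(self) -> float:
        """Diameter of the circle with the same area, 2*sqrt(area/pi)."""
        return 2.0 * math.sqrt(self.area / math.pi)


@dataclass(frozen=True)
class SpotParams:
    """Spot detector and merge-rule settings.

    ``max_spot_radius_px`` bounds the top-hat structuring element; probe
    features are small (on the order of <= 10 px at native scale).
    ``merge_diameter_mode`` resolves how "the diameter of one point" is read
    for unequal spots: the mean of the pair's equivalent diameters by
    default, with min/max as alternatives.
    """

    max_spot_radius_px: int = 8
    min_spot_area_px: int = 4
    margin_px: int = 5
    merge_diameter_mode: Literal["mean", "min", "max"] = "mean"


def detect_spots(
    channel: ChannelImage,
    region: NucleusRegion,
    params: SpotParams | None = None,
) -> list[SignalPoint]:
    """Detect raw (pre-merge) signal points inside a nucleus.

    The search area is the nucleus mask dilated by ``margin_px``.  A white
    top-hat (disk of radius ``max_spot_radius_px``) isolates features
    smaller than the structuring element; an Otsu threshold on the top-hat
    response restricted to the search area separates spots from residual
    background, and connected components of at least ``min_spot_area_px``
    pixels become signal points, sorted by (row, col).
    """
    params = params or SpotParams()
    if channel.role not in SPOT_ROLES:
        raise ValueError(
            f"spot detection expects a CEP8 or CEP17 channel, got {channel.role.value}"
        )
    h, w = channel.shape
    pad = params.margin_px + 2 * params.max_spot_radius_px
    r0, r1, c0, c1 = region.bbox
    R0, R1 = max(0, r0 - pad), min(h, r1 + pad)
    C0, C1 = max(0, c0 - pad), min(w, c1 + pad)
    search = np.zeros((R1 - R0, C1 - C0), dtype=bool)
    search[r0 - R0 : r1 - R0, c0 - C0 : c1 - C0] = region.mask
    if params.margin_px > 0:
        search = morphology.dilation(search, morphology.disk(params.margin_px))
    crop = channel.pixels[R0:R1, C0:C1]
    tophat = morphology.white_tophat(crop, morphology.disk(params.max_spot_radius_px))
    vals = tophat[search]
    if vals.size == 0:
        return []
    t = otsu_threshold(vals)
    binary = (tophat > t) & search
    labels = measure.label(binary, connectivity=2)
    points = []
    for p in measure.regionprops(labels, intensity_image=crop):
        if p.area < params.min_spot_area_px:
            continue
        points.append(
            SignalPoint(
                centroid=(float(p.centroid[0] + R0), float(p.centroid[1] + C0)),
                area=int(p.area),
                channel=channel.role,
                peak_intensity=float(p.intensity_max),
            )
        )
    points.sort(key=lambda s: s.centroid)
    return points


def _pair_diameter(a: float, b: float, mode: str) -> float:
    if mode == "mean":
        return 0.5 * (a + b)
    if mode == "min":
        return min(a, b)
    if mode == "max":
        return max(a, b)
    raise ValueError(f"unknown merge_diameter_mode {mode!r}")


def _collapse_once(points: list[SignalPoint], mode: str) -> tuple[list[SignalPoint], bool]:
    n = len(points)
    cent = np.array([p.centroid for p in points])
    diam = np.array([p.equiv_diameter for p in points])
    d2 = np.sum((cent[:, None, :] - cent[None, :, :]) ** 2, axis=-1)
    dist = np.sqrt(d2)
    if mode == "mean":
        pair = 0.5 * (diam[:, None] + diam[None, :])
    elif mode == "min":
        pair = np.minimum(diam[:, None], diam[None, :])
    else:
        pair = np.maximum(diam[:, None], diam[None, :])
    adj = dist < pair
    np.fill_diagonal(adj, False)
    if not adj.any():
        return points, False
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n_comp, comp = connected_components(csr_matrix(adj), directed=False)
    merged: list[SignalPoint] = []
    for k in range(n_comp):
        idx = np.flatnonzero(comp == k)
        if len(idx) == 1:
            merged.append(points[idx[0]])
            continue
        areas = np.array([points[i].area for i in idx], dtype=float)
        cents = cent[idx]
        total = float(areas.sum())
        centroid = tuple((areas[:, None] * cents).sum(axis=0) / total)
        merged.append(
            SignalPoint(
                centroid=(float(centroid[0]), float(centroid[1])),
                area=int(round(total)),
                channel=points[idx[0]].channel,
                peak_intensity=max(points[i].peak_intensity for i in idx),
            )
        )
    return merged, True


def merge_spots(points: Sequence[SignalPoint], params: SpotParams | None = None) -> list[SignalPoint]:
    """Merge signal points closer than one spot diameter.

    Closeness links points transitively: connected components of the
    "closer than the (mean) pair diameter" graph collapse to a single
    point with summed area and area-weighted centroid.  Collapsing is
    repeated until no pair remains mergeable, so the operation is
    idempotent and independent of input order.  All points must come from
    one channel.
    """
    params = params or SpotParams()
    points = list(points)
    if len(points) <= 1:
        return sorted(points, key=lambda s: s.centroid)
    channels = {p.channel for p in points}
    if len(channels) > 1:
        raise ValueError(
            f"merge_spots mixes channels {sorted(c.value for c in channels)}; merge per channel"
        )
    changed = True
    while changed and len(points) > 1:
        points, changed = _collapse_once(points, params.merge_diameter_mode)
    return sorted(points, key=lambda s: s.centroid)


def count_signals(
    stack: ChannelStack,
    region: NucleusRegion,
    channel_role: ChannelRole | str,
    params: SpotParams | None = None,
) -> int | None:
    """Number of merged signal points for one probe in one nucleus.

    Returns ``None`` when the probe channel is absent from the field — a
    missing probe must not silently read as diploid.
    """
    role = ChannelRole(channel_role)
    channel = stack.get(role)
    if channel is None:
        return None
    return len(merge_spots(detect_spots(channel, region, params), params))


def spots_to_frame(points: Sequence[SignalPoint], field_id: str = "", nucleus_label: int = -1):
    """Spot table as a pandas DataFrame (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "field_id": [field_id] * len(points),
            "nucleus_label": [nucleus_label] * len(points),
            "channel": [p.channel.value for p in points],
            "row": [p.centroid[0] for p in points],
            "col": [p.centroid[1] for p in points],
            "area": [p.area for p in points],
            "equiv_diameter": [p.equiv_diameter for p in points],
        }
    )
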