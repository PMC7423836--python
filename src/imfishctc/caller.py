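"""Rule-based CTC calling per nucleus.

The manual interpretation standard, made executable.  A segmented nucleus
is called CTC-positive when it (1) is not an aggregated/superposed or
otherwise QC-flagged region, (2) is DAPI-positive, (3) is CD45-negative —
at most 30% of its pixels above the CD45 positivity threshold — and
(4) carries three or more merged CEP8 or CEP17 signal points.  Every call
records the outcome of each condition in order, so a decision can be
audited cell by cell.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .io import ChannelImage, ChannelRole, ChannelStack
from .segmentation import (
    NucleusRegion,
    QcFlag,
    SegmentationParams,
    otsu_threshold,
    segment_dapi,
)
from .spots import SpotParams, count_signals

__all__ = [
    "CallLabel",
    "CallerParams",
    "CellFeatures",
    "CellCall",
    "red_proportion",
    "classify_nucleus",
    "call_field",
    "calls_to_frame",
]


class CallLabel(str, enum.Enum):
    CTC_POSITIVE = "CTC_POSITIVE"
    CTC_NEGATIVE = "CTC_NEGATIVE"
    EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class CallerParams:
    """Decision thresholds of the interpretation standard.

    ``red_proportion_cutoff``: a nucleus with strictly more than this
    fraction of CD45-positive pixels is a leukocyte (0.30).
    ``min_signal_points``: hyperdiploidy requires at least this many merged
    probe signals (3).  ``signal_logic`` joins the two probes: OR calls
    aneuploidy of either chromosome sufficient (the conventional reading of
    a dual-probe panel), AND demands both.
    """

    red_proportion_cutoff: float = 0.30
    min_signal_points: int = 3
    signal_logic: Literal["OR", "AND"] = "OR"
    cd45_threshold_mode: Literal["otsu", "fixed"] = "otsu"
    cd45_fixed_threshold: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.red_proportion_cutoff < 1.0):
            raise ValueError("red_proportion_cutoff must be in (0, 1)")
        if self.min_signal_points < 1:
            raise ValueError("min_signal_points must be >= 1")
        if self.signal_logic not in ("OR", "AND"):
            raise ValueError("signal_logic must be 'OR' or 'AND'")


@dataclass(frozen=True)
class CellFeatures:
    """Per-nucleus evidence entering the decision rule.

    A ``None`` count (or red proportion) means the probe (or CD45) channel
    was unavailable; it participates in the rule as a failed condition.
    """

    dapi_positive: bool
    red_proportion: float | None
    cep8_count: int | None
    cep17_count: int | None

    def __post_init__(self) -> None:
        if self.red_proportion is not None and not (0.0 <= self.red_proportion <= 1.0):
            raise ValueError("red_proportion must lie in [0, 1]")


@dataclass
class CellCall:
    """Decision for one nucleus with its audit trail."""

    nucleus: NucleusRegion
    features: CellFeatures
    label: CallLabel
    reasons: list[str] = field(default_factory=list)


def cd45_threshold(cd45: ChannelImage, params: CallerParams | None = None) -> int:
    """Global CD45 positivity threshold for a field (Otsu or fixed)."""
    params = params or CallerParams()
    if params.cd45_threshold_mode == "fixed":
        return params.cd45_fixed_threshold
    return otsu_threshold(cd45.pixels)


def red_proportion(
    cd45: ChannelImage,
    region: NucleusRegion,
    params: CallerParams | None = None,
    threshold: int | None = None,
) -> float:
    """Fraction of nucleus pixels whose CD45 intensity exceeds the threshold.

    The threshold defaults to a global Otsu cut over the whole CD45
    channel; pass ``threshold`` to reuse one field-level cut across nuclei.
    """
    params = params or CallerParams()
    if region.area == 0 or not region.mask.any():
        raise ValueError("red_proportion of an empty nucleus mask is undefined")
    if threshold is None:
        threshold = cd45_threshold(cd45, params)
    r0, r1, c0, c1 = region.bbox
    vals = cd45.pixels[r0:r1, c0:c1][region.mask]
    return float(np.count_nonzero(vals > threshold)) / float(vals.size)


def _counts_pass(count: int | None, minimum: int) -> bool:
    return count is not None and count >= minimum


def classify_nucleus(
    features: CellFeatures,
    qc_flags: frozenset[QcFlag] | Sequence[QcFlag] = frozenset(),
    params: CallerParams | None = None,
    nucleus: NucleusRegion | None = None,
) -> CellCall:
    """Apply the four conditions in order and return an audited call.

    Pure function of (features, qc_flags, params).  The CD45 gate is
    strict: a red proportion of exactly the cutoff still passes, only
    strictly higher flags a leukocyte.
    """
    params = params or CallerParams()
    flags = frozenset(qc_flags)
    reasons: list[str] = []
    if flags:
        reasons.append(
            "condition 1 fail: region excluded (" + ", ".join(sorted(f.value for f in flags)) + ")"
        )
        return CellCall(nucleus=nucleus, features=features, label=CallLabel.EXCLUDED, reasons=reasons)
    reasons.append("condition 1 pass: single intact nucleus")

    if features.dapi_positive:
        reasons.append("condition 2 pass: DAPI positive")
    else:
        reasons.append("condition 2 fail: DAPI negative")

    rp = features.red_proportion
    if rp is None:
        cd45_ok = False
        reasons.append("condition 3 fail: CD45 channel unavailable")
    elif rp > params.red_proportion_cutoff:
        cd45_ok = False
        reasons.append(
            f"condition 3 fail: CD45 positive (red proportion {rp:.3f} > "
            f"{params.red_proportion_cutoff:.2f})"
        )
    else:
        cd45_ok = True
        reasons.append(
            f"condition 3 pass: CD45 negative (red proportion {rp:.3f} <= "
            f"{params.red_proportion_cutoff:.2f})"
        )

    p8 = _counts_pass(features.cep8_count, params.min_signal_points)
    p17 = _counts_pass(features.cep17_count, params.min_signal_points)
    if params.signal_logic == "OR":
        signals_ok = p8 or p17
    else:
        signals_ok = p8 and p17
    c8 = "n/a" if features.cep8_count is None else str(features.cep8_count)
    c17 = "n/a" if features.cep17_count is None else str(features.cep17_count)
    if features.cep8_count is None and features.cep17_count is None:
        reasons.append("condition 4 fail: no probe channel available")
    elif signals_ok:
        reasons.append(
            f"condition 4 pass: signal points CEP8={c8} CEP17={c17} "
            f"({params.signal_logic} >= {params.min_signal_points})"
        )
    else:
        reasons.append(
            f"condition 4 fail: signal points CEP8={c8} CEP17={c17} "
            f"({params.signal_logic} >= {params.min_signal_points})"
        )

    positive = features.dapi_positive and cd45_ok and signals_ok
    label = CallLabel.CTC_POSITIVE if positive else CallLabel.CTC_NEGATIVE
    return CellCall(nucleus=nucleus, features=features, label=label, reasons=reasons)


def call_field(
    stack: ChannelStack,
    seg_params: SegmentationParams | None = None,
    caller_params: CallerParams | None = None,
    spot_params: SpotParams | None = None,
    regions: Sequence[NucleusRegion] | None = None,
) -> list[CellCall]:
    """Segment a field and call every nucleus.

    Deterministic end-to-end: segmentation, per-nucleus red proportion
    (one global CD45 threshold per field), per-nucleus merged CEP8/CEP17
    counts, then the four-condition rule.  Pre-computed ``regions`` may be
    supplied to reuse an existing segmentation.
    """
    caller_params = caller_params or CallerParams()
    if regions is None:
        regions = segment_dapi(stack, seg_params)
    cd45 = stack.get(ChannelRole.CD45)
    thr = cd45_threshold(cd45, caller_params) if cd45 is not None else None
    calls = []
    for region in regions:
        rp = None
        if cd45 is not None and region.mask.any():
            rp = red_proportion(cd45, region, caller_params, threshold=thr)
        features = CellFeatures(
            dapi_positive=True,  # segmented from DAPI by construction
            red_proportion=rp,
            cep8_count=count_signals(stack, region, ChannelRole.CEP8, spot_params),
            cep17_count=count_signals(stack, region, ChannelRole.CEP17, spot_params),
        )
        calls.append(classify_nucleus(features, region.qc_flags, caller_params, nucleus=region))
    return calls


def calls_to_frame(calls: Sequence[CellCall], field_id: str = ""):
    """Call list as a pandas DataFrame (CSV-ready)."""
    import pandas as pd

    def _i(v):
        return -1 if v is None else v

    return pd.DataFrame(
        {
            "field_id": [field_id] * len(calls),
            "nucleus_label": [c.nucleus.label if c.nucleus else -1 for c in calls],
            "centroid_row": [c.nucleus.centroid[0] if c.nucleus else float("nan") for c in calls],
            "centroid_col": [c.nucleus.centroid[1] if c.nucleus else float("nan") for c in calls],
            "label": [c.label.value for c in calls],
            "red_proportion": [
                float("nan") if c.features.red_proportion is None else c.features.red_proportion
                for c in calls
            ],
            "cep8_count": [_i(c.features.cep8_count) for c in calls],
            "cep17_count": [_i(c.features.cep17_count) for c in calls],
            "reasons": ["; ".join(c.reasons) for c in calls],
        }
    )
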