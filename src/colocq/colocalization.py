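"""Intensity-weighted Manders overlap coefficients and group summaries.

For a pair of co-registered channels A and B with binary masks ``mask_a`` and
``mask_b``, the per-channel coefficient is

    M_A = Σ_{v ∈ mask_a ∩ mask_b} I_A(v) / Σ_{v ∈ mask_a} I_A(v)

and symmetrically for M_B — the fraction of a channel's in-mask intensity that
lies inside the intersection of the two masks.  Raw (unfiltered) intensities
enter both sums; the DoG-filtered image is used only to build the masks.  A
zero denominator (mask empty or zero in-mask intensity) yields an *undefined*
coefficient carried with a reason code, never a silent zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .segmentation import DoGParams, SegmentationMask, VoxelGrid, segment_channel

__all__ = [
    "ChannelPair",
    "ColocalizationResult",
    "GroupSummary",
    "manders_pair",
    "analyze_pair",
    "summarize_groups",
]

logger = logging.getLogger(__name__)


@dataclass
class ChannelPair:
    """Two co-registered single-channel stacks from one field/cell."""

    channel_a: VoxelGrid
    channel_b: VoxelGrid
    pair_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        if self.channel_a.shape != self.channel_b.shape:
            raise ValueError(
                f"channel shapes differ: {self.channel_a.shape} vs "
                f"{self.channel_b.shape}"
            )


@dataclass
class ColocalizationResult:
    """Manders coefficients plus mask bookkeeping for one channel pair.

    ``m_a``/``m_b`` are ``None`` when undefined (zero denominator); the
    corresponding reason is appended to ``flags``.
    """

    m_a: Optional[float]
    m_b: Optional[float]
    n_mask_a: int
    n_mask_b: int
    n_intersection: int
    threshold_a: float = float("nan")
    threshold_b: float = float("nan")
    pair_id: str = ""
    group: str = ""
    flags: List[str] = field(default_factory=list)


@dataclass
class GroupSummary:
    """Descriptive statistics of one group's coefficients (boxplot data).

    ``stats`` maps coefficient name (``"m_a"``/``"m_b"``) to a dict with keys
    ``n, mean, median, sd, sem, min, max``; ``values`` retains the raw defined
    coefficients for plotting.  ``n_undefined`` counts excluded results.
    """

    group: str
    stats: Dict[str, Dict[str, float]]
    values: Dict[str, List[float]]
    n_undefined: Dict[str, int]


def manders_pair(
    channel_a: VoxelGrid,
    channel_b: VoxelGrid,
    mask_a: SegmentationMask,
    mask_b: SegmentationMask,
    pair_id: str = "",
    group: str = "",
) -> ColocalizationResult:
    """Compute both Manders coefficients from raw channels and their masks."""
    shapes = {
        channel_a.shape,
        channel_b.shape,
        mask_a.shape,
        mask_b.shape,
    }
    if len(shapes) != 1:
        raise ValueError(f"all grids must share one shape, got {sorted(shapes)}")
    if (channel_a.data < 0).any() or (channel_b.data < 0).any():
        raise ValueError("raw channel intensities must be non-negative")

    inter = mask_a.data & mask_b.data
    flags: List[str] = []

    def one_side(raw: np.ndarray, mask: np.ndarray, name: str) -> Optional[float]:
        denom = float(raw[mask].sum())
        if denom == 0.0:
            flags.append(f"undefined_{name}:zero_in_mask_intensity")
            return None
        return float(raw[inter].sum()) / denom

    m_a = one_side(channel_a.data, mask_a.data, "m_a")
    m_b = one_side(channel_b.data, mask_b.data, "m_b")
    return ColocalizationResult(
        m_a=m_a,
        m_b=m_b,
        n_mask_a=mask_a.n_true,
        n_mask_b=mask_b.n_true,
        n_intersection=int(inter.sum()),
        threshold_a=mask_a.threshold_used,
        threshold_b=mask_b.threshold_used,
        pair_id=pair_id,
        group=group,
        flags=flags,
    )


def analyze_pair(
    pair: ChannelPair, params: DoGParams | None = None
) -> ColocalizationResult:
    """Segment both channels with identical parameters, then score overlap.

    Deterministic for fixed input: DoG filter → mean + 2·SD threshold → mask,
    independently per channel, followed by :func:`manders_pair` on the raw
    intensities.
    """
    params = params or DoGParams()
    mask_a = segment_channel(pair.channel_a, params)
    mask_b = segment_channel(pair.channel_b, params)
    return manders_pair(
        pair.channel_a,
        pair.channel_b,
        mask_a,
        mask_b,
        pair_id=pair.pair_id,
        group=pair.group,
    )


def _describe(values: Sequence[float]) -> Dict[str, float]:
    arr = np.asarray(values, dtype=float)
    n = arr.size
    sd = float(arr.std(ddof=1)) if n >= 2 else float("nan")
    return {
        "n": float(n),
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
        "sd": sd,
        "sem": sd / math.sqrt(n) if n >= 2 else float("nan"),
        "min": float(arr.min()),
        "max": float(arr.max()),
    }


def summarize_groups(
    results: Sequence[ColocalizationResult],
) -> List[GroupSummary]:
    """Aggregate per-pair coefficients into per-group boxplot statistics.

    Undefined coefficients are excluded from the statistics and counted per
    group (and logged); groups are returned in stable sorted order by label.
    An empty input yields an empty list.
    """
    by_group: Dict[str, List[ColocalizationResult]] = {}
    for res in results:
        by_group.setdefault(res.group, []).append(res)

    summaries: List[GroupSummary] = []
    for group in sorted(by_group):
        stats: Dict[str, Dict[str, float]] = {}
        values: Dict[str, List[float]] = {}
        n_undefined: Dict[str, int] = {}
        for name in ("m_a", "m_b"):
            defined = [
                getattr(r, name)
                for r in by_group[group]
                if getattr(r, name) is not None
            ]
            n_undefined[name] = len(by_group[group]) - len(defined)
            if n_undefined[name]:
                logger.warning(
                    "group %r: excluded %d undefined %s value(s) from summary",
                    group,
                    n_undefined[name],
                    name,
                )
            values[name] = [float(v) for v in defined]
            stats[name] = (
                _describe(defined)
                if defined
                else {k: float("nan") for k in
                      ("n", "mean", "median", "sd", "sem", "min", "max")}
            )
        summaries.append(
            GroupSummary(
                group=group, stats=stats, values=values, n_undefined=n_undefined
            )
        )
    return summaries
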