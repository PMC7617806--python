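"""Gel-lane densitometry: band integration, normalization, replicate stats.

Implements the pulldown quantification readout: the PCNA band's integrated
intensity is normalized to the ORF2p band's in each lane, and the normalized
ratios are summarized as mean ± SEM over replicates (the study design uses
technical triplicates, n = 3).

The integration rule is the standard lane-profile workflow: within a
user-supplied band window, a straight baseline joins the profile values at the
window endpoints, the baseline-corrected signal is clipped at zero, and the
remainder is integrated by the trapezoid rule.  Band windows are supplied, not
auto-detected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "LaneProfile",
    "BandWindow",
    "BandQuant",
    "LaneSpec",
    "BandSpec",
    "quantify_band",
    "normalize_to_reference",
    "replicate_stats",
    "generate_lane",
]


@dataclass
class LaneProfile:
    """A 1D gel-lane intensity profile along the migration coordinate."""

    positions: np.ndarray
    intensities: np.ndarray
    lane_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.shape != self.intensities.shape or self.positions.ndim != 1:
            raise ValueError("positions and intensities must be equal-length 1D arrays")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if (self.intensities < 0).any():
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class BandWindow:
    """Start/end migration positions bracketing one band."""

    start: float
    end: float
    band_label: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"require start < end, got ({self.start}, {self.end})")


@dataclass
class BandQuant:
    """Replicate-level summary of normalized band ratios."""

    mean: float
    sem: float  # NaN for n = 1
    n: int
    ratios: List[float] = field(default_factory=list)
    band_label: str = ""
    condition: str = ""


def quantify_band(profile: LaneProfile, window: BandWindow) -> float:
    """Background-corrected integrated band intensity.

    The baseline is the straight line joining the (interpolated) profile
    values at the window endpoints; corrected intensity is clipped at zero
    before trapezoidal integration, so the returned area is always ≥ 0.
    """
    p, y = profile.positions, profile.intensities
    if window.start < p[0] or window.end > p[-1]:
        raise ValueError(
            f"window ({window.start}, {window.end}) outside profile range "
            f"({p[0]}, {p[-1]})"
        )
    inner = (p > window.start) & (p < window.end)
    if inner.sum() < 3:
        raise ValueError(
            f"window ({window.start}, {window.end}) contains fewer than 3 samples"
        )
    xs = np.concatenate(([window.start], p[inner], [window.end]))
    ys = np.interp(xs, p, y)
    baseline = ys[0] + (ys[-1] - ys[0]) * (xs - xs[0]) / (xs[-1] - xs[0])
    corrected = np.clip(ys - baseline, 0.0, None)
    return float(np.trapezoid(corrected, xs))


def normalize_to_reference(band_area: float, reference_area: float) -> Optional[float]:
    """Ratio of a band's area to a reference band's area.

    Returns ``None`` (undefined, to be flagged by the caller) when the
    reference area is zero or negative.
    """
    if reference_area <= 0:
        return None
    return band_area / reference_area


def replicate_stats(
    ratios: Sequence[float], band_label: str = "", condition: str = ""
) -> BandQuant:
    """Mean and SEM (sample SD / √n) of replicate ratios; SEM NaN for n = 1."""
    arr = np.asarray(list(ratios), dtype=float)
    if arr.size == 0:
        raise ValueError("replicate_stats requires at least one ratio")
    n = int(arr.size)
    sem = float(arr.std(ddof=1) / math.sqrt(n)) if n >= 2 else float("nan")
    return BandQuant(
        mean=float(arr.mean()),
        sem=sem,
        n=n,
        ratios=[float(v) for v in arr],
        band_label=band_label,
        condition=condition,
    )


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian band: migration center, integrated area, width sigma."""

    center: float
    area: float
    sigma: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("band sigma must be > 0")
        if self.area < 0:
            raise ValueError("band area must be >= 0")


@dataclass(frozen=True)
class LaneSpec:
    """Synthetic-lane parameters: Gaussian bands over a linear baseline."""

    bands: Tuple[BandSpec, ...] = ()
    n_points: int = 1000
    x_range: Tuple[float, float] = (0.0, 100.0)
    baseline_intercept: float = 0.0
    baseline_slope: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0


def generate_lane(
    spec: LaneSpec, lane_id: str = "", condition: str = ""
) -> LaneProfile:
    """Render a synthetic lane: Gaussian bands of known integrated area on a
    smooth baseline, plus seeded additive Gaussian noise, clipped at zero.

    Deterministic per seed.
    """
    x = np.linspace(spec.x_range[0], spec.x_range[1], spec.n_points)
    y = spec.baseline_intercept + spec.baseline_slope * x
    for band in spec.bands:
        y += (
            band.area
            / (band.sigma * math.sqrt(2.0 * math.pi))
            * np.exp(-((x - band.center) ** 2) / (2.0 * band.sigma**2))
        )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, spec.noise_sd, size=x.size)
    return LaneProfile(
        positions=x,
        intensities=np.clip(y, 0.0, None),
        lane_id=lane_id,
        condition=condition,
    )
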