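"""Synthetic two-channel 3D scenes with known puncta and colocalized fraction.

Each scene emulates a two-colour confocal field of cytoplasmic puncta: channel
A carries ``n_puncta_a`` isotropic Gaussian spots at random interior positions,
and a controllable fraction of channel B's spots is placed (with optional
positional jitter) at randomly chosen channel-A centers, the rest at
independent positions.  A constant background and additive Gaussian noise are
applied last and intensities are clipped at zero.  The generator returns the
exact ground truth (centers and colocalized pairs), so segmentation and
overlap scoring can be validated end to end: a high-colocalization scene
stands in for a wild-type-like condition, a low-colocalization scene for a
binding-deficient (5xPIE-like) condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .colocalization import ChannelPair
from .segmentation import DEFAULT_VOXEL_SIZE, VoxelGrid

__all__ = [
    "SyntheticSceneSpec",
    "GroundTruth",
    "render_puncta",
    "generate_scene",
]


@dataclass(frozen=True)
class SyntheticSceneSpec:
    """Parameters of one synthetic two-channel scene.

    All lengths are in voxel units (the segmenter operates purely in pixels).
    ``coloc_fraction`` is the fraction of channel-B puncta seeded at channel-A
    centers; ``jitter_sd`` perturbs those colocalized partners.
    ``min_separation`` (default ``4·punctum_sigma``) is the minimum Euclidean
    center-to-center distance enforced between independently placed puncta,
    so spots stay discrete and resolvable.
    """

    shape: Tuple[int, int, int] = (16, 256, 256)
    voxel_size: Tuple[float, float] = DEFAULT_VOXEL_SIZE
    n_puncta_a: int = 40
    n_puncta_b: int = 40
    coloc_fraction: float = 0.5
    punctum_sigma: float = 1.5
    amplitude: float = 100.0
    background: float = 10.0
    noise_sd: float = 2.0
    jitter_sd: float = 0.5
    min_separation: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.coloc_fraction <= 1.0):
            raise ValueError(f"coloc_fraction must be in [0,1], got {self.coloc_fraction}")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.punctum_sigma <= 0:
            raise ValueError("punctum_sigma must be > 0")
        if len(self.shape) != 3 or any(int(d) < 1 for d in self.shape):
            raise ValueError(f"shape must be 3 positive dimensions, got {self.shape}")
        if self.n_puncta_a < 0 or self.n_puncta_b < 0:
            raise ValueError("puncta counts must be >= 0")

    @property
    def effective_min_separation(self) -> float:
        if self.min_separation is not None:
            return self.min_separation
        return 4.0 * self.punctum_sigma

    @property
    def n_coloc(self) -> int:
        return int(round(self.coloc_fraction * self.n_puncta_b))


@dataclass
class GroundTruth:
    """True puncta placements behind a synthetic scene.

    ``coloc_pairs`` lists ``(a_index, b_index)`` for every channel-B punctum
    generated at a channel-A center.
    """

    centers_a: np.ndarray  # (n_a, 3) fractional voxel coordinates (z, y, x)
    centers_b: np.ndarray  # (n_b, 3)
    coloc_pairs: List[Tuple[int, int]] = field(default_factory=list)
    punctum_sigma: float = 1.5
    shape: Tuple[int, int, int] = (16, 256, 256)

    def __post_init__(self) -> None:
        self.centers_a = np.asarray(self.centers_a, dtype=float).reshape(-1, 3)
        self.centers_b = np.asarray(self.centers_b, dtype=float).reshape(-1, 3)
        for a_i, b_j in self.coloc_pairs:
            if not (0 <= a_i < len(self.centers_a) and 0 <= b_j < len(self.centers_b)):
                raise ValueError(f"coloc pair ({a_i}, {b_j}) indexes out of range")

    def true_mask(self, channel: str) -> np.ndarray:
        """Boolean grid of voxels within ``2·punctum_sigma`` of any center."""
        centers = {"a": self.centers_a, "b": self.centers_b}[channel]
        mask = np.zeros(self.shape, dtype=bool)
        radius = 2.0 * self.punctum_sigma
        r = int(math.ceil(radius))
        for cz, cy, cx in centers:
            zlo, zhi = max(0, int(cz) - r - 1), min(self.shape[0], int(cz) + r + 2)
            ylo, yhi = max(0, int(cy) - r - 1), min(self.shape[1], int(cy) + r + 2)
            xlo, xhi = max(0, int(cx) - r - 1), min(self.shape[2], int(cx) + r + 2)
            zz, yy, xx = np.meshgrid(
                np.arange(zlo, zhi), np.arange(ylo, yhi), np.arange(xlo, xhi),
                indexing="ij",
            )
            d2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
            mask[zlo:zhi, ylo:yhi, xlo:xhi] |= d2 <= radius**2
        return mask


def render_puncta(
    centers: Sequence[Sequence[float]] | np.ndarray,
    punctum_sigma: float,
    amplitude: float,
    shape: Tuple[int, int, int],
) -> VoxelGrid:
    """Render a sum of isotropic 3D Gaussians, each peaking at ``amplitude``.

    The Gaussians are evaluated exactly over the full grid (no truncation),
    so rendering is additive across puncta and total intensity equals the
    analytic sum of the sampled Gaussians.
    """
    centers = np.asarray(centers, dtype=float).reshape(-1, 3)
    nz, ny, nx = (int(d) for d in shape)
    out = np.zeros((nz, ny, nx), dtype=np.float64)
    if centers.size == 0:
        return VoxelGrid(out)
    for cz, cy, cx in centers:
        if not (0 <= cz <= nz - 1 and 0 <= cy <= ny - 1 and 0 <= cx <= nx - 1):
            raise ValueError(
                f"center ({cz}, {cy}, {cx}) outside grid bounds {shape}"
            )
        s2 = 2.0 * punctum_sigma**2
        gz = np.exp(-((np.arange(nz) - cz) ** 2) / s2)
        gy = np.exp(-((np.arange(ny) - cy) ** 2) / s2)
        gx = np.exp(-((np.arange(nx) - cx) ** 2) / s2)
        out += amplitude * gz[:, None, None] * (gy[:, None] * gx[None, :])[None, :, :]
    return VoxelGrid(out)


def _place_separated(
    rng: np.random.Generator,
    n: int,
    shape: Tuple[int, int, int],
    margin: float,
    min_sep: float,
    existing: List[np.ndarray],
    max_attempts: int = 20000,
) -> List[np.ndarray]:
    """Uniform interior placement with rejection sampling for min separation."""
    m = np.minimum(margin, (np.asarray(shape, dtype=float) - 1) / 2.0)
    lo = m
    hi = np.asarray(shape, dtype=float) - 1 - m
    placed: List[np.ndarray] = []
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n} puncta with min separation {min_sep} in "
                f"grid {shape}; lower the count or the separation"
            )
        cand = rng.uniform(lo, hi)
        others = existing + placed
        if others and min_sep > 0:
            d = np.linalg.norm(np.asarray(others) - cand, axis=1)
            if (d < min_sep).any():
                continue
        placed.append(cand)
    return placed


def generate_scene(
    spec: SyntheticSceneSpec, pair_id: str = "", group: str = ""
) -> Tuple[ChannelPair, GroundTruth]:
    """Generate one two-channel scene and its ground truth.

    Channel A receives ``n_puncta_a`` puncta at uniformly random interior
    positions; ``round(coloc_fraction · n_puncta_b)`` channel-B puncta are
    jittered copies of distinct randomly chosen A centers (sampling without
    replacement) and the remainder are placed independently.  Background and
    clipped additive Gaussian noise are applied last.  Identical specs
    (including the seed) produce bit-identical stacks.
    """
    min_dim = min(spec.shape)
    if min_dim < 4 * spec.punctum_sigma:
        raise ValueError(
            f"grid {spec.shape} too small for punctum_sigma={spec.punctum_sigma}: "
            f"every dimension must be >= 4·sigma = {4 * spec.punctum_sigma}"
        )
    if spec.n_coloc > spec.n_puncta_a:
        raise ValueError(
            f"cannot colocalize {spec.n_coloc} B puncta with only "
            f"{spec.n_puncta_a} A puncta"
        )

    rng = np.random.default_rng(spec.seed)
    margin = 2.0 * spec.punctum_sigma
    min_sep = spec.effective_min_separation

    centers_a = _place_separated(rng, spec.n_puncta_a, spec.shape, margin, min_sep, [])

    n_coloc = spec.n_coloc
    coloc_pairs: List[Tuple[int, int]] = []
    centers_b: List[np.ndarray] = []
    if n_coloc:
        partner_idx = rng.choice(spec.n_puncta_a, size=n_coloc, replace=False)
        for b_j, a_i in enumerate(partner_idx):
            c = np.asarray(centers_a[a_i], dtype=float)
            if spec.jitter_sd > 0:
                c = c + rng.normal(0.0, spec.jitter_sd, size=3)
            c = np.clip(c, 0.0, np.array(spec.shape, dtype=float) - 1.0)
            centers_b.append(c)
            coloc_pairs.append((int(a_i), b_j))
    centers_b.extend(
        _place_separated(
            rng,
            spec.n_puncta_b - n_coloc,
            spec.shape,
            margin,
            min_sep,
            centers_a + centers_b,
        )
    )

    arr_a = np.asarray(centers_a, dtype=float).reshape(-1, 3)
    arr_b = np.asarray(centers_b, dtype=float).reshape(-1, 3)

    def finish(centers: np.ndarray, label: str) -> VoxelGrid:
        img = render_puncta(
            centers, spec.punctum_sigma, spec.amplitude, spec.shape
        ).data
        img += spec.background
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=spec.shape)
        np.clip(img, 0.0, None, out=img)
        return VoxelGrid(img, voxel_size=spec.voxel_size, channel_label=label)

    pair = ChannelPair(
        channel_a=finish(arr_a, "A"),
        channel_b=finish(arr_b, "B"),
        pair_id=pair_id,
        group=group,
    )
    truth = GroundTruth(
        centers_a=arr_a,
        centers_b=arr_b,
        coloc_pairs=coloc_pairs,
        punctum_sigma=spec.punctum_sigma,
        shape=spec.shape,
    )
    return pair, truth


def spec_for_condition(
    base: SyntheticSceneSpec, coloc_fraction: float, seed: int
) -> SyntheticSceneSpec:
    """Convenience: the base spec with a new colocalized fraction and seed."""
    return replace(base, coloc_fraction=coloc_fraction, seed=seed)
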