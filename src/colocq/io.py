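"""File I/O: TIFF / OME-TIFF stacks, ground-truth and results CSVs.

Conventions: voxel indices are 0-based, axis order ``(z, y, x)`` with z the
acquisition order; two-channel stacks are written as OME-TIFF with axes
``CZYX`` and physical voxel sizes in µm.  When a file carries no voxel-size
metadata, the confocal acquisition defaults (0.3977 µm axial, 0.2636 µm
in-plane) are used with a logged warning.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
import tifffile

from .colocalization import ChannelPair
from .segmentation import DEFAULT_VOXEL_SIZE, SegmentationMask, VoxelGrid
from .synthetic import GroundTruth

__all__ = [
    "write_scene",
    "read_stack",
    "write_mask",
    "write_ground_truth",
    "read_ground_truth",
    "read_lane_profile",
]

logger = logging.getLogger(__name__)


def write_scene(pair: ChannelPair, path: Union[str, Path]) -> Path:
    """Write a two-channel stack as OME-TIFF (axes CZYX, float64).

    Physical voxel sizes are embedded so :func:`read_stack` round-trips the
    metadata as well as the data.
    """
    path = Path(path)
    axial, inplane = pair.channel_a.voxel_size
    data = np.stack([pair.channel_a.data, pair.channel_b.data], axis=0)
    tifffile.imwrite(
        path,
        data,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": inplane,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": inplane,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": axial,
            "PhysicalSizeZUnit": "µm",
        },
    )
    return path


def _voxel_size_from_ome(tif: tifffile.TiffFile) -> Optional[Tuple[float, float]]:
    xml = tif.ome_metadata
    if not xml:
        return None
    sizes = {}
    for axis in ("Z", "X"):
        m = re.search(rf'PhysicalSize{axis}="([0-9.eE+-]+)"', xml)
        if m:
            sizes[axis] = float(m.group(1))
    if "Z" in sizes and "X" in sizes:
        return (sizes["Z"], sizes["X"])
    return None


def read_stack(
    path: Union[str, Path],
    channels: Union[int, Tuple[int, int], None] = (0, 1),
    voxel_size: Optional[Tuple[float, float]] = None,
    pair_id: str = "",
    group: str = "",
) -> Union[ChannelPair, VoxelGrid]:
    """Read a TIFF / OME-TIFF stack into a ChannelPair or single VoxelGrid.

    ``channels`` selects either a pair ``(index_a, index_b)`` or one channel
    index; files without a channel axis are treated as single-channel.  Axis
    order is normalized to ``(z, y, x)``; 2D images are accepted as one-slice
    stacks with a warning; RGB/samples data without an explicit channel
    request is rejected as ambiguous.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes  # e.g. "CZYX", "ZYX", "YX", "YXS"
        meta_vs = _voxel_size_from_ome(tif)

    if "S" in axes and channels is None:
        raise ValueError(
            f"{path.name}: RGB/multi-sample TIFF is ambiguous; pass an explicit "
            "channel selection"
        )
    # fold samples axis into the channel axis if present
    axes = axes.replace("S", "C")
    if "Q" in axes:  # unknown axis from plain multi-page TIFFs: treat as Z
        axes = axes.replace("Q", "Z")

    order = [ax for ax in "CZYX" if ax in axes]
    if set(axes) - set("CZYX"):
        raise ValueError(f"{path.name}: unsupported axes {axes!r}")
    data = np.moveaxis(data, [axes.index(ax) for ax in order], range(len(order)))

    if "Z" not in order:
        logger.warning("%s: 2D image read as a single-slice stack", path.name)
        data = np.expand_dims(data, axis=-3)
        order = order[:-2] + ["Z", "Y", "X"] if "C" in order else ["Z", "Y", "X"]
    if "C" not in order:
        data = data[np.newaxis]
    n_channels = data.shape[0]

    if voxel_size is not None:
        vs = voxel_size
    elif meta_vs is not None:
        vs = meta_vs
    else:
        vs = DEFAULT_VOXEL_SIZE
        logger.warning(
            "%s: no voxel-size metadata; falling back to default %s µm",
            path.name,
            vs,
        )

    def one(idx: int, label: str) -> VoxelGrid:
        if not (0 <= idx < n_channels):
            raise IndexError(
                f"{path.name}: channel {idx} out of range (file has {n_channels})"
            )
        return VoxelGrid(
            np.asarray(data[idx], dtype=np.float64),
            voxel_size=vs,
            channel_label=label,
        )

    if channels is None or isinstance(channels, int):
        return one(0 if channels is None else channels, "")
    ia, ib = channels
    return ChannelPair(one(ia, "A"), one(ib, "B"), pair_id=pair_id, group=group)


def write_mask(mask: SegmentationMask, path: Union[str, Path]) -> Path:
    """Write a binary mask as an 8-bit TIFF (0/255)."""
    path = Path(path)
    tifffile.imwrite(path, (mask.data.astype(np.uint8) * 255), photometric="minisblack")
    return path


def write_ground_truth(truth: GroundTruth, path: Union[str, Path]) -> Path:
    """Write ground truth as CSV: one row per punctum.

    Columns: channel, z, y, x, colocalized (0/1), partner_index (index into
    the other channel's center list, -1 if none).
    """
    rows = []
    b_partner = {b_j: a_i for a_i, b_j in truth.coloc_pairs}
    a_partner = {a_i: b_j for a_i, b_j in truth.coloc_pairs}
    for i, (z, y, x) in enumerate(truth.centers_a):
        rows.append(("A", z, y, x, int(i in a_partner), a_partner.get(i, -1)))
    for j, (z, y, x) in enumerate(truth.centers_b):
        rows.append(("B", z, y, x, int(j in b_partner), b_partner.get(j, -1)))
    df = pd.DataFrame(
        rows, columns=["channel", "z", "y", "x", "colocalized", "partner_index"]
    )
    df.to_csv(path, index=False)
    return Path(path)


def read_ground_truth(path: Union[str, Path]) -> pd.DataFrame:
    """Read a ground-truth CSV back into a DataFrame (schema-checked)."""
    df = pd.read_csv(path)
    expected = ["channel", "z", "y", "x", "colocalized", "partner_index"]
    if list(df.columns) != expected:
        raise ValueError(f"unexpected ground-truth columns: {list(df.columns)}")
    return df


def read_lane_profile(
    path: Union[str, Path], lane_id: str = "", condition: str = ""
):
    """Read a lane profile CSV with columns ``position,intensity``."""
    from .densitometry import LaneProfile

    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "position" not in cols or "intensity" not in cols:
        raise ValueError(
            f"{Path(path).name}: expected columns position,intensity; "
            f"got {list(df.columns)}"
        )
    return LaneProfile(
        positions=df[cols["position"]].to_numpy(dtype=float),
        intensities=df[cols["intensity"]].to_numpy(dtype=float),
        lane_id=lane_id or Path(path).stem,
        condition=condition,
    )
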