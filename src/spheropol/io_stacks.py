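"""Reading and writing spheroid image data, labels, and rating tables.

Stacks travel as multi-page TIFF files.  The default page layout interleaves
channels fastest (page = z * 4 + channel); OME-style axis metadata written
by :func:`write_stack` is honoured on read, and the order can be overridden
with ``dimension_order`` ("zc": z slowest/channel fastest, the default;
"cz": channel slowest).  Intensities round-trip bit-exactly.

For the CNN branch, equatorial projections are reduced to 8-bit RGB:
basolateral marker in green, nuclei in blue, and either the apical marker
or actin in red, each channel independently min-max rescaled to 0-255.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import CHANNEL_ROLES, EquatorialImage, PolarityLabel, RGBImage, SpheroidStack, warn

N_CHANNELS = 4


def _validate_channel_map(channel_map: Mapping[str, int]) -> Dict[str, int]:
    if set(channel_map) != set(CHANNEL_ROLES):
        raise ValueError(
            f"channel_map must map exactly the roles {CHANNEL_ROLES}; "
            f"got {sorted(channel_map)}"
        )
    return dict(channel_map)


def read_channel_map(path) -> Dict[str, int]:
    """Load a role -> channel-index map from a YAML/JSON config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if "channel_map" in cfg:
        cfg = cfg["channel_map"]
    return _validate_channel_map({str(k): int(v) for k, v in cfg.items()})


def write_stack(stack: SpheroidStack, path) -> None:
    """Write a stack as a multi-page TIFF (z slowest, channel fastest)."""
    pages = np.transpose(stack.voxels, (1, 0, 2, 3))  # (Z, C, Y, X)
    tifffile.imwrite(
        path,
        pages,
        photometric="minisblack",
        metadata={
            "axes": "ZCYX",
            "spheroid_id": stack.spheroid_id,
            "pixel_size_um": stack.pixel_size_um,
            "z_step_um": stack.z_step_um,
        },
    )


def read_stack(
    path,
    channel_map: Mapping[str, int],
    dimension_order: str = "zc",
    pixel_size_um: float = 0.25,
    z_step_um: float = 0.24,
    spheroid_id: Optional[str] = None,
) -> SpheroidStack:
    """Read a multi-page TIFF into a :class:`SpheroidStack`.

    ``dimension_order`` describes how the flat page sequence factors into
    (z, channel): "zc" (default) means z varies slowest and channel fastest;
    "cz" means all pages of channel 0 come first.  Axis metadata recorded by
    :func:`write_stack` (or OME-TIFF "ZCYX"/"CZYX" axes) takes precedence.
    """
    channel_map = _validate_channel_map(channel_map)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack file not found: {path}")
    order = dimension_order.lower()
    if order == "czyx":  # accept axis-style spellings
        order = "cz"
    elif order == "zcyx":
        order = "zc"
    if order not in ("zc", "cz"):
        raise ValueError("dimension_order must be 'zc' or 'cz'")

    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes.upper()

    meta_id = spheroid_id if spheroid_id is not None else path.stem

    if data.ndim == 4:
        if axes in ("ZCYX", "QCYX"):
            voxels = np.transpose(data, (1, 0, 2, 3))
        elif axes in ("CZYX", "CQYX"):
            voxels = data
        else:
            raise ValueError(f"unsupported 4D TIFF axes {axes!r}")
    elif data.ndim == 3:
        n_pages = data.shape[0]
        if n_pages % N_CHANNELS != 0:
            raise ValueError(
                f"page count not divisible by {N_CHANNELS} channels: {n_pages} pages"
            )
        z = n_pages // N_CHANNELS
        if order == "zc":
            voxels = np.transpose(
                data.reshape(z, N_CHANNELS, *data.shape[1:]), (1, 0, 2, 3)
            )
        else:
            voxels = data.reshape(N_CHANNELS, z, *data.shape[1:])
    elif data.ndim == 2:
        raise ValueError(
            f"page count not divisible by {N_CHANNELS} channels: 1 page"
        )
    else:
        raise ValueError(f"unsupported TIFF dimensionality {data.ndim}")

    y, x = voxels.shape[2], voxels.shape[3]
    if y != x:
        raise ValueError(f"non-square frames: Y={y} differs from X={x}")

    return SpheroidStack(
        voxels=voxels,
        channel_map=channel_map,
        pixel_size_um=pixel_size_um,
        z_step_um=z_step_um,
        spheroid_id=meta_id,
    )


def split_rois(
    multi_stack: SpheroidStack,
    boxes: Sequence[Tuple[int, int, int]],
) -> List[SpheroidStack]:
    """Crop square ROIs (one spheroid each) out of a multi-spheroid stack.

    Each box is ``(x0, y0, size)`` in pixel coordinates; crops are verbatim
    across all channels and z-planes.
    """
    out = []
    frame = multi_stack.frame_size
    for i, (x0, y0, size) in enumerate(boxes):
        if size <= 0:
            raise ValueError(f"box {i}: size must be positive")
        if x0 < 0 or y0 < 0 or x0 + size > frame or y0 + size > frame:
            raise ValueError(
                f"box {i} ({x0}, {y0}, {size}) extends outside the "
                f"{frame}x{frame} frame"
            )
        crop = multi_stack.voxels[:, :, y0 : y0 + size, x0 : x0 + size].copy()
        out.append(
            SpheroidStack(
                voxels=crop,
                channel_map=dict(multi_stack.channel_map),
                pixel_size_um=multi_stack.pixel_size_um,
                z_step_um=multi_stack.z_step_um,
                spheroid_id=f"{multi_stack.spheroid_id}_roi{i}",
            )
        )
    return out


def _rescale_to_uint8(channel: np.ndarray, name: str) -> np.ndarray:
    lo, hi = float(channel.min()), float(channel.max())
    if hi == lo:
        warn(f"channel {name!r} has zero intensity range; mapped to zeros")
        return np.zeros(channel.shape, dtype=np.uint8)
    scaled = np.floor(255.0 * (channel - lo) / (hi - lo))
    return scaled.astype(np.uint8)


def to_rgb(eq: EquatorialImage, apical_source: str = "apical") -> RGBImage:
    """Reduce a four-channel equatorial projection to an 8-bit RGB image.

    Green carries the basolateral marker, blue the nuclei, and red either
    the apical marker or actin (they colocalise on distinctly polarised
    spheroids).  Channels are independently min-max rescaled with floor
    rounding, so the result is invariant to per-channel gain.
    """
    if apical_source not in ("apical", "actin", "apical_marker"):
        raise ValueError("apical_source must be 'apical' (gp135) or 'actin'")
    red_role = "actin" if apical_source == "actin" else "apical"
    h, w = eq.projections.shape[1:]
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    rgb[:, :, 0] = _rescale_to_uint8(eq.projection(red_role), red_role)
    rgb[:, :, 1] = _rescale_to_uint8(eq.projection("basolateral"), "basolateral")
    rgb[:, :, 2] = _rescale_to_uint8(eq.projection("nuclei"), "nuclei")
    return RGBImage(pixels=rgb, image_id=eq.spheroid_id)


def write_rgb(image: RGBImage, path) -> None:
    """Write an RGB image as 8-bit PNG."""
    iio.imwrite(Path(path), image.pixels, extension=".png")


def read_rgb(path, label: Optional[str] = None) -> RGBImage:
    pixels = iio.imread(Path(path))
    if pixels.ndim == 3 and pixels.shape[2] == 4:  # drop alpha
        pixels = pixels[:, :, :3]
    return RGBImage(
        pixels=pixels,
        label=PolarityLabel(label) if label else None,
        image_id=Path(path).stem,
    )


def write_labels(labels: Mapping[str, str], path) -> None:
    """Write a sidecar label CSV with columns ``spheroid_id,fine_label``."""
    pd.DataFrame(
        {"spheroid_id": list(labels), "fine_label": list(labels.values())}
    ).to_csv(path, index=False)


def read_labels(path) -> Dict[str, PolarityLabel]:
    df = pd.read_csv(path, dtype=str)
    for col in ("spheroid_id", "fine_label"):
        if col not in df.columns:
            raise ValueError(f"label CSV must have a {col!r} column")
    return {
        row.spheroid_id: PolarityLabel(row.fine_label) for row in df.itertuples()
    }


def write_ratings(ratings: pd.DataFrame, path) -> None:
    """Write a long-form rating table (``spheroid_id,rater,label``)."""
    for col in ("spheroid_id", "rater", "label"):
        if col not in ratings.columns:
            raise ValueError(f"rating table must have a {col!r} column")
    ratings.to_csv(path, index=False)


def read_ratings(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    for col in ("spheroid_id", "rater", "label"):
        if col not in df.columns:
            raise ValueError(f"rating table must have a {col!r} column")
    return df


def write_features(features: Sequence, path) -> None:
    """Write feature vectors to CSV (``spheroid_id,f1..f15``), losslessly."""
    rows = [f.as_dict() for f in features]
    df = pd.DataFrame(rows)
    cols = ["spheroid_id"] + [c for c in df.columns if c != "spheroid_id"]
    df[cols].to_csv(path, index=False)  # shortest-repr floats: lossless


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if "spheroid_id" not in df.columns:
        raise ValueError("feature CSV must have a 'spheroid_id' column")
    return df
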