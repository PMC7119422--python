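"""Core containers shared across the spheroid-polarity pipeline.

The pipeline classifies monolayered epithelial spheroids (cysts) grown in 3D
culture into polarity phenotypes:

* group ``1_regular`` — regular apicobasal polarity: a single central lumen,
  apical membrane (gp135/podocalyxin) and the contractile actin belt lining
  the lumen, basolateral membrane (gp58) facing outward;
* group ``2_inverse`` — inverse polarity: apical surface and actin ring on
  the spheroid periphery, basolateral/matrix-filled interior;
* group ``3a_aggregate`` — aggregate without a lumen, undefined polarity;
* group ``3b_multilumen`` — aggregate with several small lumina.

Coarse labels collapse 3a/3b into group 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Tuple

import numpy as np

CHANNEL_ROLES = ("basolateral", "apical", "actin", "nuclei")

FINE_LABELS = ("1_regular", "2_inverse", "3a_aggregate", "3b_multilumen")

#: fine label -> coarse polarity group
FINE_TO_COARSE = {
    "1_regular": 1,
    "2_inverse": 2,
    "3a_aggregate": 3,
    "3b_multilumen": 3,
}


@dataclass(frozen=True)
class PolarityLabel:
    """A spheroid polarity call at fine (4-class) granularity."""

    fine_label: str

    def __post_init__(self) -> None:
        if self.fine_label not in FINE_TO_COARSE:
            raise ValueError(
                f"unknown fine label {self.fine_label!r}; expected one of {FINE_LABELS}"
            )

    @property
    def coarse_label(self) -> int:
        return FINE_TO_COARSE[self.fine_label]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.fine_label


def coarse_of(fine_label: str) -> int:
    """Collapse a fine label (3a/3b -> 3) to its coarse polarity group."""
    return FINE_TO_COARSE[fine_label]


@dataclass
class SpheroidStack:
    """One spheroid's four-channel fluorescence z-stack.

    ``voxels`` has shape ``(4, Z, Y, X)`` with ``Y == X`` (square ROI).
    ``channel_map`` maps each of the four marker roles (basolateral, apical,
    actin, nuclei) to its channel index.
    """

    voxels: np.ndarray
    channel_map: Mapping[str, int]
    pixel_size_um: float = 0.25
    z_step_um: float = 0.24
    spheroid_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4 or self.voxels.shape[0] != 4:
            raise ValueError(
                f"voxels must be (4, Z, Y, X); got shape {self.voxels.shape}"
            )
        _, z, y, x = self.voxels.shape
        if z < 1:
            raise ValueError("Z must be >= 1")
        if y != x:
            raise ValueError(f"ROI must be square; got Y={y}, X={x}")
        if set(self.channel_map) != set(CHANNEL_ROLES):
            raise ValueError(
                f"channel_map must map exactly the roles {CHANNEL_ROLES}; "
                f"got {sorted(self.channel_map)}"
            )
        idx = sorted(self.channel_map.values())
        if idx != [0, 1, 2, 3]:
            raise ValueError(
                f"channel_map must use each index 0..3 exactly once; got {idx}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel intensities must be finite")
        if np.any(self.voxels < 0):
            raise ValueError("voxel intensities must be non-negative")

    @property
    def n_z(self) -> int:
        return self.voxels.shape[1]

    @property
    def frame_size(self) -> int:
        return self.voxels.shape[2]

    def channel(self, role: str) -> np.ndarray:
        """Return the ``(Z, Y, X)`` sub-stack for one marker role."""
        return self.voxels[self.channel_map[role]]


@dataclass
class EquatorialImage:
    """Per-channel 2D projection of the central z-slices of one spheroid.

    ``projections`` has shape ``(4, H, W)`` and is indexed through
    ``channel_map`` exactly like :class:`SpheroidStack.voxels`.  ``com`` is
    the intensity-weighted spheroid centre of mass in ``(x, y)`` pixel
    coordinates (sub-pixel), ``r_max`` the largest integer radius bin any
    mask pixel falls into.
    """

    projections: np.ndarray
    mask: np.ndarray
    com: Tuple[float, float]
    r_max: int
    z_index: int
    channel_map: Mapping[str, int]
    pixel_size_um: float = 0.25
    spheroid_id: str = ""

    def __post_init__(self) -> None:
        self.projections = np.asarray(self.projections, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.projections.ndim != 3 or self.projections.shape[0] != 4:
            raise ValueError("projections must be (4, H, W)")
        if self.mask.shape != self.projections.shape[1:]:
            raise ValueError("mask shape must match projections")
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        ys, xs = np.nonzero(self.mask)
        if ys.size:
            cx, cy = self.com
            if not (xs.min() <= cx <= xs.max() and ys.min() <= cy <= ys.max()):
                raise ValueError("centre of mass lies outside the mask bounding box")

    def projection(self, role: str) -> np.ndarray:
        return self.projections[self.channel_map[role]]


@dataclass
class RGBImage:
    """8-bit RGB rendering of an equatorial projection for the CNN branch.

    ``pixels`` is ``(H, W, 3)`` uint8; green carries the basolateral marker,
    blue the nuclei, red the chosen apical source (apical marker or actin).
    """

    pixels: np.ndarray
    label: Optional[PolarityLabel] = None
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be (H, W, 3); got {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("pixel values must lie within 0-255")
            self.pixels = self.pixels.astype(np.uint8)


@dataclass
class ShapeParams:
    """Descriptive shape parameters of one spheroid's equatorial plane."""

    spheroid_area_px2: float
    spheroid_circularity: float
    nuclei_circularity: float
    nuclei_count: int
    com_nuclei: Tuple[float, float]
    com_distance_rel: float
    actin_rel_area: float
    actin_particle_count: int
    actin_circularity: float

    def __post_init__(self) -> None:
        for name in ("spheroid_circularity", "nuclei_circularity", "actin_circularity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]; got {v}")
        if not 0.0 <= self.actin_rel_area <= 1.0:
            raise ValueError("actin_rel_area must lie in [0, 1]")
        if self.nuclei_count < 0 or self.actin_particle_count < 0:
            raise ValueError("counts must be >= 0")
        if self.com_distance_rel < 0:
            raise ValueError("com_distance_rel must be >= 0")


@dataclass
class RadialProfile:
    """Angle-independent radial intensity profile of one channel.

    ``mean_intensity_per_radius[r]`` is the mean per-pixel intensity in the
    integer radius bin ``r`` (0..r_max); ``normalized_cumulative[r]`` the
    running sum of those means normalised by their total, i.e. the fraction
    of the channel's (circumference-corrected) signal found within radius r.
    """

    channel: str
    mean_intensity_per_radius: np.ndarray
    normalized_cumulative: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.mean_intensity_per_radius = np.asarray(
            self.mean_intensity_per_radius, dtype=float
        )
        self.normalized_cumulative = np.asarray(self.normalized_cumulative, dtype=float)
        if self.mean_intensity_per_radius.shape != self.normalized_cumulative.shape:
            raise ValueError("profile arrays must have equal length")
        if np.any(self.mean_intensity_per_radius < 0):
            raise ValueError("mean intensities must be >= 0")
        if not self.degenerate:
            if np.any(np.diff(self.normalized_cumulative) < -1e-12):
                raise ValueError("normalized_cumulative must be non-decreasing")

    @property
    def r_max(self) -> int:
        return len(self.mean_intensity_per_radius) - 1


@dataclass(frozen=True)
class RadialConfig:
    """Readout positions on the cumulative radial curves.

    ``position_fraction`` — the cumulative-intensity fraction whose radius
    position summarises a marker's radial location (0.60: the approximate
    centre of the rising part of the curve).  ``slope_cutoff_fraction`` —
    the fraction of the spheroid radius used for the nuclear initial slope
    (0.30: the expected luminal zone).
    """

    position_fraction: float = 0.60
    slope_cutoff_fraction: float = 0.30

    def __post_init__(self) -> None:
        for name in ("position_fraction", "slope_cutoff_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


FEATURE_NAMES = (
    "f1_delta_gp58_gp135",
    "f2_delta_actin_gp135",
    "f3_relpos60_gp58",
    "f4_relpos60_gp135",
    "f5_relpos60_actin",
    "f6_relpos60_nuclei",
    "f7_spheroid_circularity",
    "f8_nuclei_circularity",
    "f9_nuclear_initial_slope",
    "f10_actin_rel_area",
    "f11_actin_particle_count",
    "f12_actin_circularity",
    "f13_nuclei_count",
    "f14_com_distance_rel",
    "f15_r_max_um",
)

#: training subset used for the primary classifier: features 1, 2 and 6-15
DEFAULT_TREE_SUBSET = tuple(
    n for n in FEATURE_NAMES if n.split("_")[0] not in ("f3", "f4", "f5")
)

#: lumen/nuclei descriptors used by the secondary group-1-vs-3 classifier
DEFAULT_SECONDARY_SUBSET = (
    "f8_nuclei_circularity",
    "f9_nuclear_initial_slope",
    "f13_nuclei_count",
    "f14_com_distance_rel",
)


@dataclass
class FeatureVector:
    """The 15 numerical features describing one spheroid.

    f1/f2 are the marker-position differences (gp58-gp135 and actin-gp135
    relative 60%-positions): a positive f1 indicates regular apicobasal
    polarity, a negative one inverse polarity; f2 near zero indicates a
    distinct (consistent) polarity.  f3-f6 are the per-channel radius
    positions at 60% cumulative intensity, f9 the initial slope of the
    nuclear curve inside 30% of the radius (nuclei in the expected lumen),
    and the remainder are equatorial shape descriptors.
    """

    f1_delta_gp58_gp135: float
    f2_delta_actin_gp135: float
    f3_relpos60_gp58: float
    f4_relpos60_gp135: float
    f5_relpos60_actin: float
    f6_relpos60_nuclei: float
    f7_spheroid_circularity: float
    f8_nuclei_circularity: float
    f9_nuclear_initial_slope: float
    f10_actin_rel_area: float
    f11_actin_particle_count: float
    f12_actin_circularity: float
    f13_nuclei_count: float
    f14_com_distance_rel: float
    f15_r_max_um: float
    spheroid_id: str = ""

    def __post_init__(self) -> None:
        values = self.as_array()
        if not np.all(np.isfinite(values)):
            bad = [n for n, v in zip(FEATURE_NAMES, values) if not np.isfinite(v)]
            raise ValueError(f"non-finite feature values: {bad}")
        if not np.isclose(
            self.f1_delta_gp58_gp135, self.f3_relpos60_gp58 - self.f4_relpos60_gp135
        ):
            raise ValueError("f1 must equal f3 - f4")
        if not np.isclose(
            self.f2_delta_actin_gp135, self.f5_relpos60_actin - self.f4_relpos60_gp135
        ):
            raise ValueError("f2 must equal f5 - f4")
        if not 0.0 <= self.f10_actin_rel_area <= 1.0:
            raise ValueError("f10 must lie in [0, 1]")
        for name in ("f11_actin_particle_count", "f13_nuclei_count"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    def as_dict(self) -> dict:
        d = {n: getattr(self, n) for n in FEATURE_NAMES}
        d["spheroid_id"] = self.spheroid_id
        return d


def warn(message: str) -> None:
    """Emit a pipeline warning (kept in one place so tests can assert on it)."""
    warnings.warn(message, stacklevel=3)
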