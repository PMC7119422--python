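"""Synthetic four-channel spheroid z-stacks for all polarity groups.

The generator emulates the equatorial geometry of the polarity phenotypes:

* group 1 (regular): a single central lumen whose boundary carries the
  apical marker and a pronounced actin belt; the basolateral marker on the
  outer membrane with a faint lateral component; nuclei arranged on a ring
  between lumen and outer boundary; an empty lumen.
* group 2 (inverse): apical marker and actin ring on the outer boundary,
  basolateral marker filling the matrix-filled interior, nuclei on a
  mid-ring.
* group 3a (aggregate): nuclei scattered over the whole disc including the
  centre (no lumen), markers drawn as low-contrast incoherent blob
  mixtures so the polarity-difference features concentrate near zero.
* group 3b (multilumen): 2-4 small apical/actin-ringed lumina at random
  interior positions inside an otherwise regular-looking spheroid.

The axial extent follows a spherical-cap intensity profile; images are
degraded by an isotropic in-plane Gaussian PSF, a constant background, and
Poisson-Gaussian camera noise.  Everything is driven by a single seed, so
datasets are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .types import FINE_LABELS, PolarityLabel, SpheroidStack, coarse_of

DEFAULT_CHANNEL_MAP = {"basolateral": 0, "apical": 1, "actin": 2, "nuclei": 3}


@dataclass(frozen=True)
class SyntheticParams:
    """Geometry and noise settings of the generator.

    Linear sizes are in pixels of the synthetic frame; the defaults describe
    a 256 px ROI with 50 z-planes, spheroids of 40-80 px radius (12-24
    cells), a group-1 lumen of 30-50% of the radius, and a standard
    fluorescence camera noise model (Poisson shot noise plus Gaussian read
    noise over a constant background).
    """

    image_size: int = 256
    z_planes: int = 50
    spheroid_radius_px: Tuple[float, float] = (40.0, 80.0)
    lumen_radius_frac: Tuple[float, float] = (0.3, 0.5)
    n_nuclei: Tuple[int, int] = (12, 24)
    n_lumina: Tuple[int, int] = (2, 4)
    membrane_width_px: float = 3.0
    actin_width_px: float = 2.5
    nucleus_sigma_px: float = 3.0
    psf_sigma_px: float = 2.0
    amplitude: float = 150.0
    background: float = 10.0
    gaussian_noise_sigma: float = 5.0
    poisson_gain: float = 1.0
    pixel_size_um: float = 0.25
    z_step_um: float = 0.24

    def __post_init__(self) -> None:
        if self.lumen_radius_frac[1] >= 1.0:
            raise ValueError("lumen radius must stay below the spheroid radius")
        if self.spheroid_radius_px[1] > self.image_size / 2:
            raise ValueError("spheroid radius range exceeds the frame half-size")
        for name in ("membrane_width_px", "actin_width_px", "nucleus_sigma_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_nuclei[0] < 1:
            raise ValueError("n_nuclei must be >= 1")

    def noiseless(self) -> "SyntheticParams":
        """Copy of the parameters with all noise sources switched off."""
        d = asdict(self)
        d.update(gaussian_noise_sigma=0.0, poisson_gain=0.0, background=0.0)
        return SyntheticParams(**d)


#: geometry settings scaled down for fast simulation studies (96 px frames,
#: thin stacks); proportions match the full-size defaults
SCALED_PARAMS = SyntheticParams(
    image_size=96,
    z_planes=5,
    spheroid_radius_px=(16.0, 30.0),
    n_nuclei=(8, 14),
    membrane_width_px=2.0,
    actin_width_px=1.8,
    nucleus_sigma_px=2.0,
    psf_sigma_px=1.2,
)


@dataclass
class LabelledDataset:
    """A generated collection of stacks with labels and a draw manifest."""

    stacks: List[SpheroidStack]
    labels: List[PolarityLabel]
    manifest: pd.DataFrame
    params: SyntheticParams

    def __post_init__(self) -> None:
        if len(self.stacks) != len(self.labels) or len(self.stacks) != len(
            self.manifest
        ):
            raise ValueError("stacks, labels and manifest must align")


def _ring(d: np.ndarray, radius: float, width: float) -> np.ndarray:
    """Gaussian annulus of given mean radius and width on a distance map."""
    return np.exp(-0.5 * ((d - radius) / width) ** 2)


def _blobs(
    shape: Tuple[int, int],
    centers: np.ndarray,
    sigma: float,
) -> np.ndarray:
    """Sum of unit-height Gaussian blobs at the given (x, y) centres."""
    out = np.zeros(shape, dtype=float)
    yy, xx = np.indices(shape)
    for cx, cy in centers:
        out += np.exp(-0.5 * (((xx - cx) ** 2 + (yy - cy) ** 2) / sigma**2))
    return out


def _ring_positions(
    rng: np.random.Generator, n: int, ring_radius: float, center: Tuple[float, float]
) -> np.ndarray:
    """n points evenly spread on a ring with angular and radial jitter."""
    base = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    angles = base + rng.uniform(-0.25, 0.25, n) * (2.0 * np.pi / max(n, 1))
    radii = ring_radius * (1.0 + rng.uniform(-0.06, 0.06, n))
    cx, cy = center
    return np.stack([cx + radii * np.cos(angles), cy + radii * np.sin(angles)], axis=1)


def _equatorial_templates(
    group: str, params: SyntheticParams, rng: np.random.Generator
) -> Tuple[Dict[str, np.ndarray], Dict[str, float]]:
    """Noise-free per-channel equatorial templates plus the draw record."""
    s = params.image_size
    amp = params.amplitude
    center = (
        s / 2 + rng.uniform(-2.0, 2.0),
        s / 2 + rng.uniform(-2.0, 2.0),
    )
    radius = rng.uniform(*params.spheroid_radius_px)
    n_nuc = int(rng.integers(params.n_nuclei[0], params.n_nuclei[1] + 1))
    yy, xx = np.indices((s, s))
    d = np.hypot(xx - center[0], yy - center[1])
    disc = d < radius
    w_m, w_a = params.membrane_width_px, params.actin_width_px

    ch = {k: np.zeros((s, s)) for k in DEFAULT_CHANNEL_MAP}
    draw: Dict[str, float] = {
        "radius_px": radius,
        "center_x": center[0],
        "center_y": center[1],
        "n_nuclei": n_nuc,
        "lumen_radius_px": 0.0,
        "n_lumina": 0,
    }

    if group == "1_regular":
        lumen = radius * rng.uniform(*params.lumen_radius_frac)
        draw["lumen_radius_px"] = lumen
        draw["n_lumina"] = 1
        ch["apical"] = amp * _ring(d, lumen, w_m)
        ch["actin"] = 1.2 * amp * _ring(d, lumen, w_a) + 0.1 * amp * _ring(d, radius, w_a)
        ch["basolateral"] = amp * _ring(d, radius, w_m) + 0.12 * amp * (
            (d > lumen) & disc
        )
        ring_r = 0.5 * (lumen + radius)
        nuclei_pos = _ring_positions(rng, n_nuc, ring_r, center)
        ch["nuclei"] = amp * _blobs((s, s), nuclei_pos, params.nucleus_sigma_px)

    elif group == "2_inverse":
        ch["apical"] = amp * _ring(d, radius, w_m)
        ch["actin"] = 1.2 * amp * _ring(d, radius, w_a)
        ch["basolateral"] = 0.7 * amp * (d < 0.88 * radius) + 0.1 * amp * _ring(
            d, radius, w_m
        )
        ring_r = 0.62 * radius
        nuclei_pos = _ring_positions(rng, n_nuc, ring_r, center)
        ch["nuclei"] = amp * _blobs((s, s), nuclei_pos, params.nucleus_sigma_px)

    elif group == "3a_aggregate":
        # incoherent low-contrast marker blobs; no lumen, centre occupied
        for role in ("basolateral", "apical", "actin"):
            k = int(rng.integers(4, 8))
            r_blob = rng.uniform(0.0, 0.8 * radius, k)
            th = rng.uniform(0.0, 2.0 * np.pi, k)
            pos = np.stack(
                [center[0] + r_blob * np.cos(th), center[1] + r_blob * np.sin(th)],
                axis=1,
            )
            ch[role] = 0.45 * amp * _blobs(
                (s, s), pos, 2.5 * params.nucleus_sigma_px
            ) + 0.25 * amp * disc
        r_nuc = rng.uniform(0.0, 0.75 * radius, n_nuc)
        th = rng.uniform(0.0, 2.0 * np.pi, n_nuc)
        pos = np.stack(
            [center[0] + r_nuc * np.cos(th), center[1] + r_nuc * np.sin(th)], axis=1
        )
        ch["nuclei"] = amp * _blobs((s, s), pos, params.nucleus_sigma_px)

    elif group == "3b_multilumen":
        k = int(rng.integers(params.n_lumina[0], params.n_lumina[1] + 1))
        draw["n_lumina"] = k
        lum_r = radius * rng.uniform(0.13, 0.2, k)
        # rejection-sample well-separated lumen centres in the interior
        centers: List[Tuple[float, float]] = []
        guard = 0
        while len(centers) < k and guard < 400:
            guard += 1
            rr = rng.uniform(0.0, 0.55 * radius)
            th = rng.uniform(0.0, 2.0 * np.pi)
            cand = (center[0] + rr * np.cos(th), center[1] + rr * np.sin(th))
            i = len(centers)
            if all(
                np.hypot(cand[0] - ox, cand[1] - oy) > lum_r[i] + lum_r[j] + 4 * w_a
                for j, (ox, oy) in enumerate(centers)
            ):
                centers.append(cand)
        lum_r = lum_r[: len(centers)]
        draw["n_lumina"] = len(centers)
        for (lx, ly), lr in zip(centers, lum_r):
            dl = np.hypot(xx - lx, yy - ly)
            ch["apical"] += amp * _ring(dl, lr, w_m)
            ch["actin"] += 1.2 * amp * _ring(dl, lr, w_a)
        ch["basolateral"] = amp * _ring(d, radius, w_m) + 0.12 * amp * disc
        r_nuc = rng.uniform(0.25 * radius, 0.85 * radius, n_nuc)
        th = rng.uniform(0.0, 2.0 * np.pi, n_nuc)
        pos = np.stack(
            [center[0] + r_nuc * np.cos(th), center[1] + r_nuc * np.sin(th)], axis=1
        )
        ch["nuclei"] = amp * _blobs((s, s), pos, params.nucleus_sigma_px)

    else:
        raise ValueError(f"unknown polarity group {group!r}; expected {FINE_LABELS}")

    return ch, draw


def _axial_profile(z_planes: int, rng: np.random.Generator) -> np.ndarray:
    """Spherical-cap intensity weights across z, peaking at the equator."""
    if z_planes == 1:
        return np.ones(1)
    zc = (z_planes - 1) / 2 + rng.uniform(-1.0, 1.0)
    half_extent = 0.55 * z_planes
    z = np.arange(z_planes)
    w = 1.0 - ((z - zc) / half_extent) ** 2
    return np.sqrt(np.clip(w, 0.0, None))


def _generate_with_draw(
    group: str,
    params: SyntheticParams,
    rng: np.random.Generator,
    spheroid_id: str,
) -> Tuple[SpheroidStack, PolarityLabel, Dict[str, float]]:
    templates, draw = _equatorial_templates(group, params, rng)

    # PSF blur commutes with the axial intensity modulation, so blur the
    # equatorial template once instead of every plane
    blurred = {
        role: ndi.gaussian_filter(img, params.psf_sigma_px)
        for role, img in templates.items()
    }
    axial = _axial_profile(params.z_planes, rng)

    voxels = np.empty(
        (4, params.z_planes, params.image_size, params.image_size), dtype=float
    )
    for role, idx in DEFAULT_CHANNEL_MAP.items():
        voxels[idx] = blurred[role][None, :, :] * axial[:, None, None]
    voxels += params.background

    if params.poisson_gain > 0:
        voxels = rng.poisson(voxels * params.poisson_gain) / params.poisson_gain
    if params.gaussian_noise_sigma > 0:
        voxels = voxels + rng.normal(0.0, params.gaussian_noise_sigma, voxels.shape)
    voxels = np.clip(voxels, 0.0, None)

    stack = SpheroidStack(
        voxels=voxels,
        channel_map=dict(DEFAULT_CHANNEL_MAP),
        pixel_size_um=params.pixel_size_um,
        z_step_um=params.z_step_um,
        spheroid_id=spheroid_id or f"syn_{group}",
    )
    return stack, PolarityLabel(group), draw


def generate_spheroid(
    group: str,
    params: SyntheticParams = SyntheticParams(),
    seed: int | np.random.Generator = 0,
    spheroid_id: str = "",
) -> Tuple[SpheroidStack, PolarityLabel]:
    """Generate one labelled four-channel z-stack of the given fine group."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    stack, label, _ = _generate_with_draw(group, params, rng, spheroid_id)
    return stack, label


def generate_dataset(
    class_counts: Dict[str, int],
    params: SyntheticParams = SyntheticParams(),
    seed: int = 0,
) -> LabelledDataset:
    """Generate a labelled dataset with exact per-class counts.

    Each spheroid gets its own child seed derived from ``seed`` and its
    position, so the dataset is reproducible and insensitive to the dict's
    key order.
    """
    for label, n in class_counts.items():
        if label not in FINE_LABELS:
            raise ValueError(f"unknown fine label {label!r}")
        if n < 0:
            raise ValueError("class counts must be >= 0")

    stacks: List[SpheroidStack] = []
    labels: List[PolarityLabel] = []
    rows = []
    i = 0
    for label in FINE_LABELS:  # fixed order, independent of dict order
        for _ in range(class_counts.get(label, 0)):
            rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
            sid = f"sph_{i:04d}_{label}"
            stack, pol, draw = _generate_with_draw(label, params, rng, sid)
            stacks.append(stack)
            labels.append(pol)
            row = {
                "spheroid_id": sid,
                "fine_label": label,
                "coarse_label": coarse_of(label),
                "seed": seed,
                "index": i,
            }
            row.update(draw)
            rows.append(row)
            i += 1
    manifest = pd.DataFrame(rows)
    return LabelledDataset(stacks=stacks, labels=labels, manifest=manifest, params=params)
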