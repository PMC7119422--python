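"""Radial intensity profiles and the 15-feature vector.

The polarity of an epithelial spheroid is radially symmetric at its
equatorial plane, so marker positions can be summarised angle-independently:
every pixel is assigned an integer radius bin

    radius(x_i, y_i) = round(sqrt((x_i - X_CoM)^2 + (y_i - Y_CoM)^2))

(rounding half away from zero).  Per channel, intensities in each bin are
averaged per pixel (dividing by the bin's pixel count removes the
circumference growth with radius), normalised by the channel total, and
accumulated into a cumulative curve over relative radius r/r_max.  The
radius position at 60% cumulative intensity localises a marker; the sign of
the gp58-gp135 position difference separates regular from inverse polarity,
and the initial slope of the nuclear curve inside 30% of the radius reports
nuclei in the expected luminal zone.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

from .types import (
    CHANNEL_ROLES,
    EquatorialImage,
    FeatureVector,
    RadialConfig,
    RadialProfile,
    ShapeParams,
    warn,
)


def polar_radius(x, y, com: Tuple[float, float]) -> np.ndarray:
    """Integer radius bin of pixel(s) ``(x, y)`` about the centre of mass.

    Rounds half away from zero (``round(2.5) -> 3``), the convention that
    keeps bin membership stable across platforms; distances are
    non-negative, so this is ``floor(d + 0.5)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cx, cy = com
    d = np.sqrt((x - cx) ** 2 + (y - cy) ** 2)
    r = np.floor(d + 0.5).astype(np.int64)
    return r if r.ndim else int(r)


def radial_profile(
    channel_projection: np.ndarray,
    com: Tuple[float, float],
    r_max: int,
    channel: str = "",
) -> RadialProfile:
    """Per-radius mean intensity and normalised cumulative curve.

    Pixels whose radius bin exceeds ``r_max`` are excluded.  Bins that
    contain no pixel (possible only at r = 0 for a fractional centre) get
    mean 0.  An all-zero channel yields a flat degenerate profile with a
    warning.
    """
    proj = np.asarray(channel_projection, dtype=float)
    if proj.ndim != 2:
        raise ValueError("channel projection must be 2D")
    if r_max < 1:
        raise ValueError("r_max must be >= 1")
    if np.any(proj < 0):
        raise ValueError("projection intensities must be non-negative")

    yy, xx = np.indices(proj.shape)
    r = polar_radius(xx, yy, com)
    valid = r <= r_max
    rv = r[valid]
    sums = np.bincount(rv, weights=proj[valid], minlength=r_max + 1)
    counts = np.bincount(rv, minlength=r_max + 1)
    mean = np.zeros(r_max + 1, dtype=float)
    np.divide(sums, counts, out=mean, where=counts > 0)

    total = mean.sum()
    if total <= 0:
        warn(f"channel {channel!r} carries no signal; flat cumulative profile")
        return RadialProfile(channel, mean, np.zeros_like(mean), degenerate=True)
    cum = np.cumsum(mean) / total
    return RadialProfile(channel, mean, cum)


def radius_at_fraction(profile: RadialProfile, fraction: float) -> float:
    """Relative radius at which the cumulative curve reaches ``fraction``.

    Finds the smallest radius bin whose cumulative value is >= fraction and
    refines it by linear interpolation between the bracketing bins, so a
    cumulative curve that is exactly linear in relative radius returns the
    fraction itself.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if profile.degenerate:
        raise ValueError("no signal: cannot locate a radius on a flat profile")
    cum = profile.normalized_cumulative
    r_max = profile.r_max
    idx = int(np.searchsorted(cum, fraction, side="left"))
    if idx >= len(cum):  # numerical guard; final value is 1 > fraction
        idx = len(cum) - 1
    if idx == 0:
        return 0.0
    c0, c1 = cum[idx - 1], cum[idx]
    if c1 == c0:  # flat stretch; fall back to the first attaining bin
        return idx / r_max
    return ((idx - 1) + (fraction - c0) / (c1 - c0)) / r_max


def nuclear_initial_slope(profile: RadialProfile, cutoff: float = 0.30) -> float:
    """Chord slope of the nuclear cumulative curve inside ``cutoff`` * r_max.

    Returns cumulative(cutoff * r_max) / cutoff, the slope per unit relative
    radius of the chord from the origin; 0 when no signal lies inside the
    cutoff, 1/cutoff when all of it does.  A value well above 1 flags nuclei
    inside the expected luminal zone (aggregates without a lumen).
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")
    if profile.degenerate:
        return 0.0
    cum = profile.normalized_cumulative
    r_max = profile.r_max
    r_cut = cutoff * r_max
    # cumulative value at the (generally fractional) cutoff radius,
    # linearly interpolated between neighbouring bins
    value = float(np.interp(r_cut, np.arange(r_max + 1), cum))
    return value / cutoff


def marker_deltas(relpos60: Dict[str, float]) -> Tuple[float, float]:
    """Marker-position differences (f1, f2) from per-channel 60% positions.

    f1 = pos(gp58/basolateral) - pos(gp135/apical): positive for regular
    apicobasal polarity, negative for inverse polarity.
    f2 = pos(actin) - pos(gp135): near zero when actin and the apical
    marker colocalise, i.e. when the polarity is distinct.
    """
    for role in ("basolateral", "apical", "actin"):
        v = relpos60[role]
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"relative position for {role!r} outside [0, 1]: {v}")
    f1 = relpos60["basolateral"] - relpos60["apical"]
    f2 = relpos60["actin"] - relpos60["apical"]
    return f1, f2


def radial_profiles(eq: EquatorialImage) -> Dict[str, RadialProfile]:
    """Radial profile of every channel of an equatorial image."""
    return {
        role: radial_profile(eq.projection(role), eq.com, eq.r_max, channel=role)
        for role in CHANNEL_ROLES
    }


def feature_vector(
    eq: EquatorialImage,
    shapes: ShapeParams,
    profiles: Dict[str, RadialProfile],
    cfg: RadialConfig = RadialConfig(),
) -> FeatureVector:
    """Assemble the 15-feature description of one spheroid.

    A channel with no signal (degenerate profile) contributes a relative
    position of 0 rather than propagating an error, so that pathological
    stacks still yield a finite vector.
    """
    relpos: Dict[str, float] = {}
    for role in CHANNEL_ROLES:
        p = profiles[role]
        relpos[role] = 0.0 if p.degenerate else radius_at_fraction(p, cfg.position_fraction)
    f1, f2 = marker_deltas(relpos)
    f9 = nuclear_initial_slope(profiles["nuclei"], cfg.slope_cutoff_fraction)
    return FeatureVector(
        f1_delta_gp58_gp135=f1,
        f2_delta_actin_gp135=f2,
        f3_relpos60_gp58=relpos["basolateral"],
        f4_relpos60_gp135=relpos["apical"],
        f5_relpos60_actin=relpos["actin"],
        f6_relpos60_nuclei=relpos["nuclei"],
        f7_spheroid_circularity=shapes.spheroid_circularity,
        f8_nuclei_circularity=shapes.nuclei_circularity,
        f9_nuclear_initial_slope=f9,
        f10_actin_rel_area=shapes.actin_rel_area,
        f11_actin_particle_count=float(shapes.actin_particle_count),
        f12_actin_circularity=shapes.actin_circularity,
        f13_nuclei_count=float(shapes.nuclei_count),
        f14_com_distance_rel=shapes.com_distance_rel,
        f15_r_max_um=eq.r_max * eq.pixel_size_um,
        spheroid_id=eq.spheroid_id,
    )
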