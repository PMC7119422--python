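"""End-to-end convenience wrappers: stack -> equatorial plane -> features."""

from __future__ import annotations

from typing import Iterable, List

from .equatorial import equatorial_projection, shape_params
from .radial_features import feature_vector, radial_profiles
from .types import EquatorialImage, FeatureVector, RadialConfig, SpheroidStack


def extract_features(
    stack: SpheroidStack,
    n_slices: int = 5,
    cfg: RadialConfig = RadialConfig(),
) -> FeatureVector:
    """Compute the 15-feature vector of one spheroid stack."""
    n = min(n_slices, stack.n_z)
    if n % 2 == 0:
        n -= 1
    eq = equatorial_projection(stack, n_slices=max(n, 1))
    return features_from_equatorial(eq, cfg)


def features_from_equatorial(
    eq: EquatorialImage, cfg: RadialConfig = RadialConfig()
) -> FeatureVector:
    shapes = shape_params(eq)
    profiles = radial_profiles(eq)
    return feature_vector(eq, shapes, profiles, cfg)


def extract_features_batch(
    stacks: Iterable[SpheroidStack],
    n_slices: int = 5,
    cfg: RadialConfig = RadialConfig(),
) -> List[FeatureVector]:
    return [extract_features(s, n_slices=n_slices, cfg=cfg) for s in stacks]
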