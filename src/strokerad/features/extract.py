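"""The full feature grid and per-subject extraction.

Default configuration yields exactly 396 named features:

    histogram 42 + formfactor 9 + haralick 10
    + GLCM   8 bases x (4 angles x 3 offsets + 2 aggregations x 3 offsets) = 144
    + RLM   10 bases x (4 angles x 3 steps   + 2 aggregations x 3 steps)  = 180
    + GLSZM 11

Per-direction names render as ``Base_angleA_offsetK``; the AllDirection
aggregations as ``Base_AllDirection_offsetK`` (mean over the four angles)
and ``Base_AllDirection_offsetK_SD`` (population SD over them).
"""

from __future__ import annotations

from ..config import FeatureConfig, PreprocessingConfig
from ..preprocessing import CTVolume, VOIMask, preprocess
from . import matrices, texture
from .firstorder import HISTOGRAM_NAMES, histogram_features
from .shape import SHAPE_NAMES, shape_features


def _directional_names(bases, angles, offsets):
    names = []
    for base in bases:
        for angle in angles:
            for off in offsets:
                names.append(f"{base}_angle{angle}_offset{off}")
        for off in offsets:
            names.append(f"{base}_AllDirection_offset{off}")
            names.append(f"{base}_AllDirection_offset{off}_SD")
    return names


def feature_names(config: FeatureConfig | None = None) -> list[str]:
    """Deterministic ordered name list for the configured grid."""
    config = config or FeatureConfig()
    names: list[str] = []
    if "histogram" in config.families:
        names += list(HISTOGRAM_NAMES)
    if "formfactor" in config.families:
        names += list(SHAPE_NAMES)
    if "haralick" in config.families:
        names += list(texture.HARALICK_NAMES)
    if "GLCM" in config.families:
        names += _directional_names(texture.GLCM_BASES, config.angles, config.offsets)
    if "RLM" in config.families:
        names += _directional_names(texture.RLM_BASES, config.angles, config.offsets)
    if "GLSZM" in config.families:
        names += list(texture.GLSZM_NAMES)
    return names


SIGNATURE_FEATURES = (
    "LongRunEmphasis_angle135_offset4",
    "SurfaceArea",
    "Inertia_AllDirection_offset7_SD",
    "ClusterShade_AllDirection_offset1_SD",
    "Percentile20",
    "LongRunLowGreyLevelEmphasis_angle90_offset7",
)


def _directional_family(disc, config, bases, matrix_fn, feature_fn):
    out = {}
    for off in config.offsets:
        per_angle = {base: [] for base in bases}
        for angle in config.angles:
            try:
                feats = feature_fn(matrix_fn(disc, angle, off))
            except matrices.UndefinedMatrixError as err:
                raise matrices.UndefinedMatrixError(
                    f"{bases[0]} family undefined at angle {angle}, offset {off}: {err}"
                ) from err
            for base in bases:
                out[f"{base}_angle{angle}_offset{off}"] = feats[base]
                per_angle[base].append(feats[base])
        for base in bases:
            mean, sd = texture.aggregate_directions(per_angle[base])
            out[f"{base}_AllDirection_offset{off}"] = mean
            out[f"{base}_AllDirection_offset{off}_SD"] = sd
    return out


def extract_all(
    volume: CTVolume,
    mask: VOIMask,
    pre_config: PreprocessingConfig | None = None,
    feat_config: FeatureConfig | None = None,
) -> dict[str, float]:
    """Preprocess one subject and compute the whole feature vector."""
    pre_config = pre_config or PreprocessingConfig()
    feat_config = feat_config or FeatureConfig()
    feat_config.validate()
    nvol, rmask, disc = preprocess(volume, mask, pre_config)

    values: dict[str, float] = {}
    if "histogram" in feat_config.families:
        values.update(histogram_features(nvol, rmask, pre_config.n_bins))
    if "formfactor" in feat_config.families:
        values.update(shape_features(rmask))
    if "haralick" in feat_config.families:
        values.update(texture.haralick_features(disc))
    if "GLCM" in feat_config.families:
        values.update(
            _directional_family(
                disc, feat_config, texture.GLCM_BASES,
                matrices.cooccurrence_matrix, texture.glcm_features,
            )
        )
    if "RLM" in feat_config.families:
        values.update(
            _directional_family(
                disc, feat_config, texture.RLM_BASES,
                matrices.run_length_matrix, texture.rlm_features,
            )
        )
    if "GLSZM" in feat_config.families:
        values.update(texture.glszm_features(matrices.size_zone_matrix(disc)))

    return {name: values[name] for name in feature_names(feat_config)}
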