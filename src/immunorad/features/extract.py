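"""Feature-vector assembly and the versioned feature registry."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from immunorad.features.geometric import geometric_features
from immunorad.features.intensity import intensity_features
from immunorad.features.texture import build_texture_matrices, quantize, textural_features
from immunorad.volumes import CTVolume, ROIMask, extract_voi

_REGISTRY_CACHE: dict | None = None

EXPECTED_COUNTS = {"intensity": 24, "geometric": 20, "textural": 53}


def load_registry() -> dict:
    """Load the versioned registry: the single source of truth for the bank."""
    global _REGISTRY_CACHE
    if _REGISTRY_CACHE is None:
        text = resources.files("immunorad.features").joinpath("registry.json").read_text()
        _REGISTRY_CACHE = json.loads(text)
    return _REGISTRY_CACHE


def feature_names() -> list[str]:
    """The 97 feature names in canonical extraction order."""
    return [f["name"] for f in load_registry()["features"]]


def feature_categories() -> dict[str, str]:
    return {f["name"]: f["category"] for f in load_registry()["features"]}


@dataclass(frozen=True)
class FeatureVector:
    """Ordered map of the 97 feature names to values, with category tags."""

    values: dict[str, float]
    categories: dict[str, str] = field(default_factory=feature_categories)

    def __post_init__(self) -> None:
        expected = feature_names()
        if list(self.values) != expected:
            raise ValueError(
                f"feature vector must contain exactly the {len(expected)} "
                "registry features in canonical order"
            )

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=np.float64)

    def by_category(self, category: str) -> dict[str, float]:
        return {k: v for k, v in self.values.items() if self.categories[k] == category}

    def __len__(self) -> int:
        return len(self.values)


def extract_all(
    volume: CTVolume,
    mask: ROIMask,
    n_bins: int = 64,
    offsets=None,
) -> FeatureVector:
    """Extract all 97 features: 24 intensity + 20 geometric + 53 textural.

    The VOI is first cropped to the mask bounding box; features are computed
    on the native grid (no resampling).
    """
    voi, voi_mask = extract_voi(volume, mask, margin_voxels=0)
    out: dict[str, float] = {}
    out.update(intensity_features(voi, voi_mask, n_bins=n_bins))
    out.update(geometric_features(voi_mask))
    q = quantize(voi, voi_mask, n_bins=n_bins)
    matrices = build_texture_matrices(q, voi_mask, offsets=offsets)
    out.update(textural_features(matrices))
    ordered = {name: float(out[name]) for name in feature_names()}
    bad = [k for k, v in ordered.items() if not np.isfinite(v)]
    if bad:
        raise AssertionError(f"non-finite features: {bad}")
    return FeatureVector(values=ordered)
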