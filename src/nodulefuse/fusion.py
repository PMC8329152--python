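"""Tile-and-append fusion of deep image features with auxiliary features.

A short auxiliary vector (biomarkers and/or volumetric radiomics) is
repeated a fixed number of times and concatenated to the 64-dim deep image
feature vector, so the auxiliary block carries comparable weight in
tree-based downstream models.  The three standard recipes:

=================  ===========  =======  ============
recipe             aux length   repeats  fused length
=================  ===========  =======  ============
image_only         —            —        64
image+biomarker    8            8        128
image+radiomic     3            21       127
image+both         11           6        130
=================  ===========  =======  ============

For ``image+both`` the auxiliary vector is the 8 biomarkers followed by
the 3 radiomics (diameter, surface area, volume).  No scaling is applied
before fusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cnn import DEEP_FEATURE_LENGTH
from .exceptions import ConfigurationError

#: recipe name -> (aux length, repeats); image_only has no aux block.
RECIPES = {
    "image_only": (0, 0),
    "image+biomarker": (8, 8),
    "image+radiomic": (3, 21),
    "image+both": (11, 6),
}

#: recipe name -> total fused vector length.
RECIPE_LENGTHS = {
    name: DEEP_FEATURE_LENGTH + m * r for name, (m, r) in RECIPES.items()
}


@dataclass
class FusedVector:
    """One fused feature vector with its recipe bookkeeping."""

    values: np.ndarray
    recipe: str
    tiling: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.recipe not in RECIPE_LENGTHS:
            raise ConfigurationError(f"unknown recipe {self.recipe!r}")
        expected = RECIPE_LENGTHS[self.recipe]
        if self.values.shape != (expected,):
            raise ValueError(
                f"recipe {self.recipe!r} requires length {expected}, "
                f"got {self.values.shape}"
            )


def tile_append(
    image_feat: np.ndarray, aux: np.ndarray, repeats: int
) -> np.ndarray:
    """Concatenate ``aux`` repeated ``repeats`` times onto ``image_feat``.

    Output length is ``len(image_feat) + len(aux) * repeats``; the aux
    order is preserved within each repetition.
    """
    if repeats < 1:
        raise ConfigurationError(f"repeats must be >= 1, got {repeats}")
    image_feat = np.asarray(image_feat, dtype=float).ravel()
    aux = np.asarray(aux, dtype=float).ravel()
    return np.concatenate([image_feat, np.tile(aux, repeats)])


def fuse_cohort(
    features: np.ndarray,
    biomarkers: np.ndarray | None = None,
    radiomics: np.ndarray | None = None,
    recipe: str = "image+biomarker",
    plain_concat: bool = False,
) -> np.ndarray:
    """Row-wise fusion of aligned feature matrices under a named recipe.

    ``plain_concat=True`` appends the auxiliary block once instead of
    tiling (an ablation option outside the standard recipes).
    """
    features = np.asarray(features, dtype=float)
    if recipe not in RECIPES:
        raise ConfigurationError(f"unknown recipe {recipe!r}")
    if recipe == "image_only":
        return features.copy()
    need_bio = "biomarker" in recipe or recipe == "image+both"
    need_rad = "radiomic" in recipe or recipe == "image+both"
    blocks = []
    if need_bio:
        if biomarkers is None:
            raise ConfigurationError(f"recipe {recipe!r} requires biomarkers")
        blocks.append(np.asarray(biomarkers, dtype=float))
    if need_rad:
        if radiomics is None:
            raise ConfigurationError(f"recipe {recipe!r} requires radiomics")
        blocks.append(np.asarray(radiomics, dtype=float))
    aux = np.hstack(blocks)
    m, repeats = RECIPES[recipe]
    if aux.shape[1] != m:
        raise ConfigurationError(
            f"recipe {recipe!r} expects aux width {m}, got {aux.shape[1]}"
        )
    if aux.shape[0] != features.shape[0]:
        raise ValueError(
            f"row-count mismatch: {features.shape[0]} features vs {aux.shape[0]} aux"
        )
    if plain_concat:
        repeats = 1
    return np.hstack([features, np.tile(aux, (1, repeats))])
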