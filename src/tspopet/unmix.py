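"""Voxel-wise NNLS decomposition onto the SVCA kinetic classes and
extraction of the subject-specific pseudo-reference region.

Each brain voxel's normalized TAC is decomposed as a non-negative linear
combination of the four class curves. Voxels whose non-specific grey matter
weight dominates (ratio > 0.9 of the total weight) form the subject's ad hoc
reference region; the reference TAC is then averaged from the **raw**
(un-normalized) image over those voxels, since kinetic modelling needs
activity units rather than z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .core import TAC, DynamicImage, extract_tac
from .svca import CLASS_NAMES, KineticClassSet


@dataclass(frozen=True)
class WeightMaps:
    """Non-negative class weight maps. Voxels outside the brain mask hold
    NaN ("not computed"), distinct from a genuine zero weight."""

    blood: np.ndarray
    specific_gm: np.ndarray
    nonspecific_gm: np.ndarray
    white_matter: np.ndarray
    residual: np.ndarray
    brain_mask: np.ndarray

    def as_stack(self) -> np.ndarray:
        """(x, y, z, 4) array in canonical class order."""
        return np.stack([getattr(self, n) for n in CLASS_NAMES], axis=-1)


def nnls_unmix(
    norm_image: DynamicImage, classes: KineticClassSet, brain_mask: np.ndarray
) -> WeightMaps:
    """Per voxel, solve min ||tac - A w||_2 s.t. w >= 0 where A holds the four
    class curves; store the weights and the minimal residual norm."""
    if classes.schedule != norm_image.schedule:
        raise ValueError("class curves and image do not share a schedule")
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != norm_image.shape:
        raise ValueError("brain mask grid does not match image grid")
    design = classes.as_matrix()  # (n_frames, 4)
    shape = norm_image.shape
    weights = np.full(shape + (4,), np.nan)
    residual = np.full(shape, np.nan)
    tacs = norm_image.values[brain_mask]
    w_out = np.empty((len(tacs), 4))
    r_out = np.empty(len(tacs))
    for i, tac in enumerate(tacs):
        w_out[i], r_out[i] = nnls(design, tac)
    weights[brain_mask] = w_out
    residual[brain_mask] = r_out
    per_class = {n: weights[..., j] for j, n in enumerate(CLASS_NAMES)}
    return WeightMaps(residual=residual, brain_mask=brain_mask, **per_class)


def reference_mask(weights: WeightMaps, threshold: float = 0.9) -> np.ndarray:
    """Voxels whose non-specific-GM weight ratio (weight over the sum of all
    four class weights) strictly exceeds ``threshold``. Voxels with zero
    total weight are excluded."""
    stack = weights.as_stack()
    total = stack.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = weights.nonspecific_gm / total
    mask = weights.brain_mask & (total > 0) & (ratio > threshold)
    if not mask.any():
        raise ValueError(
            f"no voxel exceeds the weight-ratio threshold {threshold}; "
            "consider relaxing it"
        )
    return mask


def reference_tac(raw_image: DynamicImage, mask: np.ndarray) -> TAC:
    """Subject's ad hoc reference curve: mean raw-activity TAC over the
    reference mask."""
    return extract_tac(raw_image, mask)
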