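"""Fiber-lesion compartmentalization.

A fiber is *lesional* when any of its original vertices falls in a lesion
voxel (nearest-voxel lookup; masks are binary, interpolation would invent
partial lesions). A hemisphere is *no-lesion* when no fiber is lesional,
*complete* when every fiber is, and *partial* otherwise — the fiber-level
operationalization of a lesion occupying the entire tract cross-section.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
from scipy import ndimage

from .io import ScalarVolume, StreamlineBundle, world_to_voxel

__all__ = [
    "FiberLabeling",
    "LesionInventory",
    "classify_fibers",
    "split_bundle",
    "select_hemisphere",
    "tract_mask",
    "lesion_volumes",
]

log = logging.getLogger(__name__)

CATEGORY_NO_LESION = "no-lesion"
CATEGORY_PARTIAL = "partial"
CATEGORY_COMPLETE = "complete"


@dataclass
class FiberLabeling:
    """Per-fiber lesional labels and the derived hemisphere category."""

    lesional: np.ndarray  # bool per fiber
    category: str

    @property
    def n_lesional(self) -> int:
        return int(self.lesional.sum())

    @property
    def n_non_lesional(self) -> int:
        return int((~self.lesional).sum())


@dataclass
class LesionInventory:
    """Connected lesion components and tract-relative volume partition."""

    labels: np.ndarray          # component id per voxel, 0 = background
    component_ids: np.ndarray
    component_voxels: np.ndarray
    component_volumes_mm3: np.ndarray
    volume_inside_mm3: float
    volume_outside_mm3: float

    @property
    def n_components(self) -> int:
        return len(self.component_ids)

    @property
    def total_volume_mm3(self) -> float:
        return self.volume_inside_mm3 + self.volume_outside_mm3


def _vertices_in_mask(streamline: np.ndarray, mask: ScalarVolume) -> bool:
    vox = np.rint(world_to_voxel(mask, streamline)).astype(int)
    shape = np.asarray(mask.data.shape)
    inside = ((vox >= 0) & (vox < shape)).all(axis=1)
    if not inside.any():
        return False
    v = vox[inside]
    return bool(mask.data[v[:, 0], v[:, 1], v[:, 2]].any())


def classify_fibers(bundle: StreamlineBundle,
                    lesion_mask: ScalarVolume) -> FiberLabeling:
    """Label each fiber lesional/non-lesional against a binary lesion mask.

    Uses the original (pre-resampling) vertices for full spatial fidelity.
    The label does not depend on fiber point ordering.
    """
    if len(bundle) == 0:
        raise ValueError("empty bundle")
    if not lesion_mask.is_binary():
        raise ValueError("lesion mask must be binary (0/1 only)")
    lesional = np.array([_vertices_in_mask(s, lesion_mask) for s in bundle])
    if not lesional.any():
        category = CATEGORY_NO_LESION
    elif lesional.all():
        category = CATEGORY_COMPLETE
    else:
        category = CATEGORY_PARTIAL
    return FiberLabeling(lesional, category)


def split_bundle(bundle: StreamlineBundle, labeling: FiberLabeling
                 ) -> tuple[StreamlineBundle, StreamlineBundle]:
    """Partition into (lesional, non-lesional) bundles; counts conserved."""
    if len(labeling.lesional) != len(bundle):
        raise ValueError("labeling does not match bundle size")
    les = [s for s, is_l in zip(bundle, labeling.lesional) if is_l]
    non = [s for s, is_l in zip(bundle, labeling.lesional) if not is_l]
    lesional = StreamlineBundle(les, anchor=bundle.anchor) if les else _empty(bundle)
    non_lesional = StreamlineBundle(non, anchor=bundle.anchor) if non else _empty(bundle)
    return lesional, non_lesional


def _empty(bundle: StreamlineBundle) -> StreamlineBundle:
    out = StreamlineBundle.__new__(StreamlineBundle)
    out.streamlines = []
    out.anchor = bundle.anchor
    return out


def select_hemisphere(left_category: str, right_category: str,
                      seed: int) -> tuple[str, str]:
    """Pick the analysis hemisphere from the two category labels.

    Rules: equal categories -> random (seeded); no-lesion beats partial;
    partial beats complete. The unobserved (no-lesion, complete) pairing
    selects the no-lesion side with a warning, maximizing usable
    non-lesional fibers.
    Returns (side, rationale_code) with side in {"left", "right"}.
    """
    order = {CATEGORY_NO_LESION: 0, CATEGORY_PARTIAL: 1, CATEGORY_COMPLETE: 2}
    for cat in (left_category, right_category):
        if cat not in order:
            raise ValueError(f"unknown hemisphere category '{cat}'")
    if left_category == right_category:
        rng = np.random.default_rng(seed)
        side = "left" if rng.integers(2) == 0 else "right"
        return side, f"random-{left_category}"
    pair = {left_category, right_category}
    if pair == {CATEGORY_NO_LESION, CATEGORY_COMPLETE}:
        log.warning("unobserved (no-lesion, complete) pairing; "
                    "selecting the no-lesion side")
        side = "left" if left_category == CATEGORY_NO_LESION else "right"
        return side, "no-lesion-over-complete"
    side = "left" if order[left_category] < order[right_category] else "right"
    winner = left_category if side == "left" else right_category
    return side, f"prefer-{winner}"


def tract_mask(bundle: StreamlineBundle,
               reference: ScalarVolume) -> ScalarVolume:
    """Binary mask of voxels visited by any fiber vertex (nearest voxel)."""
    mask = np.zeros(reference.data.shape)
    shape = np.asarray(reference.data.shape)
    for s in bundle:
        vox = np.rint(world_to_voxel(reference, s)).astype(int)
        inside = ((vox >= 0) & (vox < shape)).all(axis=1)
        v = vox[inside]
        mask[v[:, 0], v[:, 1], v[:, 2]] = 1.0
    return reference.like(mask)


def lesion_volumes(lesion_mask: ScalarVolume,
                   tract: ScalarVolume) -> LesionInventory:
    """Partition lesion volume into inside-tract and outside-tract parts.

    Connected components use 6-connectivity (face neighbors only), a
    conservative separation on coarse grids. Volumes are voxel count times
    voxel volume; inside + outside = total by construction.
    """
    if lesion_mask.data.shape != tract.data.shape or \
            not np.allclose(lesion_mask.affine, tract.affine):
        raise ValueError("lesion and tract masks are on different grids")
    if not lesion_mask.is_binary() or not tract.is_binary():
        raise ValueError("masks must be binary")
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labels, n = ndimage.label(lesion_mask.data > 0, structure=structure)
    ids = np.arange(1, n + 1)
    counts = np.array([(labels == i).sum() for i in ids], dtype=int)
    vv = lesion_mask.voxel_volume
    inside = float((lesion_mask.data * tract.data).sum() * vv)
    outside = float((lesion_mask.data * (1 - tract.data)).sum() * vv)
    return LesionInventory(labels, ids, counts, counts * vv, inside, outside)
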