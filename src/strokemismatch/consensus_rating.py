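"""Expert-consensus lesion mask from multiple rater masks.

Raters each provide a binary mask (1 = lesion, 0 = normal) on the same grid.
The consensus keeps every voxel whose summed rating reaches the cutoff
(default 3, i.e. at least 3 of 4 raters).  The cutoff comparison is ``>=``:
a "cutoff score of 3" among four raters means three or more votes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .image_io import GeometryError
from .lesion_segmentation import LesionMask


def consensus_mask(masks: Sequence[LesionMask], cutoff: int = 3) -> LesionMask:
    """Voxelwise vote: consensus voxel iff sum of ratings >= cutoff.

    cutoff=1 gives the union of the rater masks, cutoff=n_raters the
    intersection; the consensus always lies between the two and its volume is
    monotone non-increasing in the cutoff.
    """
    if len(masks) < 1:
        raise ValueError("consensus requires at least one rater mask")
    if not 1 <= cutoff <= len(masks):
        raise ValueError(f"cutoff must be in [1, {len(masks)}], got {cutoff}")
    first = masks[0]
    for m in masks[1:]:
        first.mask.check_same_grid(m.mask, "rater masks")
        if m.modality != first.modality:
            raise ValueError(
                f"rater masks mix modalities: {first.modality} vs {m.modality}"
            )
    votes = np.zeros(first.mask.shape, dtype=np.int32)
    for m in masks:
        votes += m.mask.data.astype(np.int32)
    return LesionMask.from_binary(votes >= cutoff, first.mask, first.modality)
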