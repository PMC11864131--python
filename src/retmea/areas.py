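"""Graft-relative electrode labeling by binary dilation of the graft mask.

The fluorescence footprint of the graft (area 1) is dilated in nested
shells; electrodes are labeled area 1-4 by the innermost shell that
contains them.  Default shells use 1, 5, 10 and 15 dilation iterations of
a 3x3 square structuring element (a Chebyshev metric in pixel space), with
the µm scale set by the mask's pixel size; everything beyond the outermost
shell is the catch-all area 4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
from scipy import ndimage

from .core import ElectrodeGrid, MaskImage

__all__ = ["AreaAssignment", "binarize_mask", "dilate_mask", "assign_areas",
           "DEFAULT_LEVELS"]

DEFAULT_LEVELS = (1, 5, 10, 15)

_SQUARE3 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class AreaAssignment:
    """Electrode -> area map plus which dilation shell supplied each label."""

    areas: dict[int, int]            # electrode_id -> {1, 2, 3, 4}
    shell_iterations: dict[int, int]  # electrode_id -> innermost containing level (0 = beyond)
    levels: tuple[int, ...]

    def counts(self) -> dict[int, int]:
        out = {1: 0, 2: 0, 3: 0, 4: 0}
        for a in self.areas.values():
            out[a] += 1
        return out


def binarize_mask(image: np.ndarray, threshold: float, um_per_px: float = 20.0,
                  origin_um: tuple[float, float] = (0.0, 0.0)) -> MaskImage:
    """Threshold a grayscale fluorescence image: foreground iff >= threshold."""
    img = np.asarray(image, dtype=float)
    fg = img >= threshold
    if not fg.any():
        warnings.warn("binarized mask has no foreground pixels; "
                      "area assignment will refuse it", stacklevel=2)
    return MaskImage(fg, um_per_px, origin_um)


def dilate_mask(mask: MaskImage, iterations: int,
                structure: np.ndarray = _SQUARE3) -> MaskImage:
    """Iterated morphological binary dilation; 0 iterations is the identity."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return mask
    out = ndimage.binary_dilation(mask.data, structure=structure,
                                  iterations=iterations)
    return MaskImage(out, mask.um_per_px, mask.origin_um)


def assign_areas(mask: MaskImage, grid: ElectrodeGrid,
                 levels: Sequence[int] = DEFAULT_LEVELS,
                 structure: np.ndarray = _SQUARE3) -> AreaAssignment:
    """Label every electrode with its graft-relative area.

    Area 1 is the graft plus its 1-iteration border, areas 2-3 the shells
    out to ``levels[1]`` and ``levels[2]`` iterations, and area 4 the
    ``levels[3]`` shell together with everything farther out.  Each
    electrode is mapped to the mask pixel under its center point.
    """
    levels = tuple(int(v) for v in levels)
    if len(levels) != 4 or any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError("levels must be 4 strictly increasing iteration counts")
    if not mask.data.any():
        raise ValueError("cannot assign areas from an empty mask")

    shells = [dilate_mask(mask, lv, structure).data for lv in levels]
    areas: dict[int, int] = {}
    shell_of: dict[int, int] = {}
    for i, eid in enumerate(grid.ids):
        r, c = mask.um_to_pixel(grid.positions_um[i])
        if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]):
            raise ValueError(
                f"electrode {eid} maps outside the mask image (pixel {(r, c)})")
        for k, shell in enumerate(shells):
            if shell[r, c]:
                areas[eid] = k + 1
                shell_of[eid] = levels[k]
                break
        else:
            areas[eid] = 4
            shell_of[eid] = 0
    return AreaAssignment(areas, shell_of, levels)
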