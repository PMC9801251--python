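"""Magnetization-transfer enhancement image.

The MT enhancement image is the voxelwise ratio of the MT-weighted
acquisition to the pulse-free (non-MT) acquisition. Voxels where
macromolecules such as neuromelanin are concentrated attenuate the
non-MT-referenced signal differently and appear hyperintense in the
ratio. The division is performed only inside the brain mask and only
where the denominator is safely away from zero; everything else is set
to a sentinel value outside the physiological range and excluded from
the returned validity mask.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateInputError
from .volume import Mask, VolumeGrid, check_same_grid

__all__ = ["SENTINEL", "compute_enhancement", "default_min_denominator"]

#: Sentinel written at voxels excluded from the enhancement map.
#: Enhancement ratios are strictly positive, so -1 is unambiguous.
SENTINEL = -1.0


def default_min_denominator(non_mt: VolumeGrid, brain: Mask) -> float:
    """1e-6 x the median in-brain non-MT intensity."""
    inside = non_mt.values[brain.values]
    if inside.size == 0:
        raise DegenerateInputError("brain mask is empty")
    return 1e-6 * float(np.median(inside))


def compute_enhancement(
    mt: VolumeGrid,
    non_mt: VolumeGrid,
    brain: Mask,
    min_denominator: float | None = None,
) -> tuple[VolumeGrid, Mask]:
    """Divide the MT image by the non-MT image within the brain mask.

    Parameters
    ----------
    mt, non_mt
        Coregistered volumes sharing shape and voxel size.
    brain
        Binary brain mask on the same grid.
    min_denominator
        Non-MT intensities below this are treated as unusable. Defaults
        to ``1e-6 * median(non_mt within brain)``.

    Returns
    -------
    (enh, valid)
        ``enh`` carries the ratio at valid voxels and :data:`SENTINEL`
        elsewhere; ``valid`` marks in-brain voxels with a usable
        denominator.
    """
    check_same_grid(mt, non_mt, brain)
    if min_denominator is None:
        min_denominator = default_min_denominator(non_mt, brain)

    valid_arr = brain.values & (non_mt.values >= min_denominator)
    if not valid_arr.any():
        raise DegenerateInputError("no valid voxels: empty brain mask or denominator everywhere below threshold")

    out = np.full(mt.shape, SENTINEL, dtype=np.float64)
    out[valid_arr] = mt.values[valid_arr] / non_mt.values[valid_arr]
    if not np.isfinite(out[valid_arr]).all():
        raise DegenerateInputError("non-finite enhancement values inside the valid mask")

    enh = VolumeGrid(out, mt.voxel_size_mm, id=f"enh({mt.id or 'mt'})")
    return enh, Mask(valid_arr, mt.voxel_size_mm, id="valid")
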