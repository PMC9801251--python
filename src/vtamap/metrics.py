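"""ROI volume/intensity metrics, whole-brain normalization, and
test-retest reliability (overlap and intraclass correlation).

Reliability conventions: "percentage overlap" is reported as 100 x Dice
(the Jaccard alternative is also emitted, since the overlap definition
used for the original figures is not recoverable); the default ICC form
is two-way random effects, absolute agreement, single measurement —
ICC(A,1) in Shrout–Fleiss terms — with the consistency form ICC(C,1)
also available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ParameterError
from .volume import Mask, VolumeGrid, check_same_grid

__all__ = [
    "RoiMetrics",
    "roi_volume",
    "roi_mean_intensity",
    "normalize_by_brain",
    "dice",
    "jaccard",
    "icc_test_retest",
    "reliability_report",
    "compute_roi_metrics",
]


@dataclass
class RoiMetrics:
    """Per-subject, per-ROI volume and intensity, raw and normalized."""

    subject_id: str
    roi: str
    volume_mm3: float
    mean_intensity: float
    volume_norm: float
    intensity_norm: float
    brain_volume_mm3: float
    flags: list = field(default_factory=list)


def roi_volume(mask: Mask) -> float:
    """Voxel count times voxel volume, in mm^3 (0 for an empty mask)."""
    return mask.n_voxels * mask.voxel_volume_mm3


def roi_mean_intensity(mask: Mask, enh: VolumeGrid) -> float:
    """Arithmetic mean of the enhancement over the ROI."""
    check_same_grid(mask, enh)
    if not mask.values.any():
        warnings.warn("mean intensity of an empty ROI is undefined", stacklevel=2)
        return float("nan")
    return float(enh.values[mask.values].mean())


def normalize_by_brain(value: float, brain_volume_mm3: float, reference_brain_volume_mm3: float) -> float:
    """Ratio-scale a per-subject measure to a common reference brain volume.

    normalized = value * reference / subject_brain_volume, so a subject
    with exactly the reference brain volume is unchanged and a subject
    with twice the reference has the value halved.
    """
    if brain_volume_mm3 <= 0 or reference_brain_volume_mm3 <= 0:
        raise ParameterError("brain volumes must be positive")
    return value * reference_brain_volume_mm3 / brain_volume_mm3


def dice(a: Mask, b: Mask) -> float:
    """2|A∩B| / (|A|+|B|); two empty masks agree perfectly (1, flagged)."""
    check_same_grid(a, b)
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        warnings.warn("Dice of two empty masks defined as 1", stacklevel=2)
        return 1.0
    inter = int((a.values & b.values).sum())
    return 2.0 * inter / (na + nb)


def jaccard(a: Mask, b: Mask) -> float:
    check_same_grid(a, b)
    union = int((a.values | b.values).sum())
    if union == 0:
        warnings.warn("Jaccard of two empty masks defined as 1", stacklevel=2)
        return 1.0
    inter = int((a.values & b.values).sum())
    return inter / union


def _icc_mean_squares(table: np.ndarray) -> tuple[float, float, float, int, int]:
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((table - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, max(mse, 0.0), n, k


def icc_test_retest(values, form: str = "absolute_agreement") -> float:
    """Single-measurement intraclass correlation from a subjects x
    sessions table, via two-way ANOVA mean squares.

    form="absolute_agreement": ICC(A,1) = (MSR-MSE)/(MSR+(k-1)MSE+k(MSC-MSE)/n)
    form="consistency":        ICC(C,1) = (MSR-MSE)/(MSR+(k-1)MSE)

    Negative estimates are possible and returned as-is (with a warning).
    """
    table = np.asarray(values, dtype=np.float64)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ParameterError("ICC requires a table of >= 2 subjects x >= 2 sessions")
    if not np.isfinite(table).all():
        raise ParameterError("ICC table must have no missing cells")
    if np.allclose(table, table.flat[0]):
        raise DegenerateInputError("constant table: zero between-subject variance, ICC undefined")
    msr, msc, mse, n, k = _icc_mean_squares(table)
    if form == "absolute_agreement":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "consistency":
        denom = msr + (k - 1) * mse
    else:
        raise ParameterError(f"unknown ICC form {form!r}")
    if denom <= 0:
        raise DegenerateInputError("non-positive ICC denominator")
    icc = (msr - mse) / denom
    if icc < 0:
        warnings.warn(f"negative ICC estimate ({icc:.3f})", stacklevel=2)
    return float(icc)


def reliability_report(mask_pairs, value_table=None) -> dict:
    """Test-retest summary: per-pair Dice/Jaccard overlap and, if a
    subjects x sessions table of scalar measures is given, both ICC
    forms."""
    rep: dict = {"pairs": []}
    for a, b in mask_pairs:
        d = dice(a, b)
        rep["pairs"].append(
            {"dice": d, "overlap_percent": 100.0 * d, "jaccard": jaccard(a, b)}
        )
    if value_table is not None:
        rep["icc_absolute_agreement"] = icc_test_retest(value_table, "absolute_agreement")
        rep["icc_consistency"] = icc_test_retest(value_table, "consistency")
    return rep


def compute_roi_metrics(
    subject_id: str,
    roi: str,
    mask: Mask,
    enh: VolumeGrid,
    brain_volume_mm3: float,
    reference_brain_volume_mm3: float,
) -> RoiMetrics:
    """Bundle volume, mean intensity and their brain-normalized versions."""
    flags = []
    vol = roi_volume(mask)
    if mask.n_voxels == 0:
        flags.append("empty_roi")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mi = roi_mean_intensity(mask, enh)
    else:
        mi = roi_mean_intensity(mask, enh)
    return RoiMetrics(
        subject_id=subject_id,
        roi=roi,
        volume_mm3=vol,
        mean_intensity=mi,
        volume_norm=normalize_by_brain(vol, brain_volume_mm3, reference_brain_volume_mm3),
        intensity_norm=normalize_by_brain(mi, brain_volume_mm3, reference_brain_volume_mm3)
        if np.isfinite(mi)
        else float("nan"),
        brain_volume_mm3=brain_volume_mm3,
        flags=flags,
    )
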