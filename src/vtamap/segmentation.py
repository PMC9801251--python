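"""VTA/SN delineation from the enhancement image.

Stage order, mirroring the imaging procedure the pipeline implements:

1. k=3 mixture fit on enhancement intensities inside the analysis mask,
   classifying voxels into cerebrospinal fluid, white matter and a
   neuromelanin-related class (highest mean).
2. k=4 refinement fit restricted to the neuromelanin-class voxels,
   separating the subtle intensity contributions of the VTA (lower
   enhancement) from the SN proper (higher enhancement).
3. Anatomical constraints: candidates are clipped to the midbrain mask
   and to a maximal lateral distance from the sagittal midline plane
   (a coordinate stand-in for "medial-lateral boundary parallel to the
   4th ventricle").
4. Bilateral connected-component extraction: the largest component on
   each side of the midline is retained per nucleus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, DegeneracyError, ParameterError
from .gmm import MixtureModel, fit_gmm_em
from .volume import Mask, VolumeGrid, check_same_grid

__all__ = [
    "LabelVolume",
    "AnatomicalConstraints",
    "classify_voxels",
    "select_component",
    "split_vta_sn",
    "apply_constraints",
    "bilateral_components",
    "segment_vta_sn",
    "SegmentationResult",
]

TISSUE_ROLES = ("csf", "wm", "neuromelanin")


@dataclass
class LabelVolume:
    """Hard component assignment per voxel; -1 outside the analysis mask."""

    labels: np.ndarray
    legend: dict
    voxel_size_mm: tuple

    def mask_for(self, label: int) -> Mask:
        return Mask(self.labels == label, self.voxel_size_mm)


@dataclass
class AnatomicalConstraints:
    """Spatial restrictions applied to nucleus candidates.

    midline_x: sagittal plane position in voxel coordinates along axis
    0; if None it is estimated as the midbrain mask's center of mass
    along that axis (the phantom's symmetry plane).
    """

    midbrain: Mask
    midline_x: float | None = None
    max_lateral_distance_mm: float = 8.0

    def __post_init__(self):
        if self.max_lateral_distance_mm < 0:
            raise ParameterError("max_lateral_distance_mm must be >= 0")

    def resolved_midline(self) -> float:
        if self.midline_x is not None:
            return float(self.midline_x)
        vals = self.midbrain.values
        if not vals.any():
            raise DegenerateInputError("midbrain mask is empty; cannot estimate midline")
        xs = np.nonzero(vals)[0]
        return float(xs.mean())


def classify_voxels(model: MixtureModel, enh: VolumeGrid, mask: Mask) -> LabelVolume:
    """Assign each masked voxel to its maximum-posterior component.

    Posterior ties are broken toward the higher-mean component (the
    rarer, brighter nucleus class), which makes the assignment
    deterministic.
    """
    check_same_grid(enh, mask)
    if not mask.values.any():
        raise DegenerateInputError("classification mask is empty")
    vals = enh.values[mask.values]
    resp = model.responsibilities(vals)
    # Scan components from highest mean down; argmax picks the first
    # (i.e. highest-mean) component among exact ties.
    order = np.argsort(-model.means)
    winners = order[np.argmax(resp[:, order], axis=1)]
    labels = np.full(enh.shape, -1, dtype=np.int32)
    labels[mask.values] = winners
    legend = {int(i): f"component_{i}" for i in range(model.k)}
    return LabelVolume(labels=labels, legend=legend, voxel_size_mm=enh.voxel_size_mm)


def select_component(model: MixtureModel, role: str) -> int:
    """Map a 3-component fit to tissue roles by mean ordering.

    neuromelanin = highest mean, csf = lowest, wm = middle.
    """
    if model.k != 3:
        raise ParameterError(f"tissue-role selection requires k=3, got k={model.k}")
    if role not in TISSUE_ROLES:
        raise ParameterError(f"unknown role {role!r}; expected one of {TISSUE_ROLES}")
    order = np.argsort(model.means)
    return int({"csf": order[0], "wm": order[1], "neuromelanin": order[2]}[role])


def _weighted_two_partition(means: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Partition sorted component means into a low and a high group.

    Exact weighted 1-D 2-means over the k-1 contiguous split points;
    returns a boolean array, True for the high (SN-side) group.
    """
    order = np.argsort(means)
    m, w = means[order], np.maximum(weights[order], 1e-12)
    k = m.size
    best_cost, best_split = np.inf, 1
    for s in range(1, k):
        cost = 0.0
        for seg in (slice(0, s), slice(s, k)):
            ww, mm = w[seg], m[seg]
            mu = float((ww * mm).sum() / ww.sum())
            cost += float((ww * (mm - mu) ** 2).sum())
        if cost < best_cost:
            best_cost, best_split = cost, s
    high = np.zeros(k, dtype=bool)
    high[order[best_split:]] = True
    return high


def split_vta_sn(
    enh: VolumeGrid,
    nm_mask: Mask,
    seed: int = 0,
    k: int = 4,
    n_init: int = 10,
    grouping: str = "gap",
    **em_kwargs,
) -> tuple[Mask, Mask, MixtureModel]:
    """Refine the neuromelanin class into VTA and SN candidates.

    A k-component mixture (default 4) is fitted to enhancement
    intensities inside ``nm_mask``; components are then grouped into a
    low-mean (VTA) and a high-mean (SN) set.

    grouping
        ``"gap"`` (default): exact weighted two-partition of the sorted
        component means — robust when the neuromelanin mask holds only
        the two nuclei and the fit places several components per
        nucleus. ``"top_two"``: the two highest-mean components are the
        nuclei (second-highest = VTA, highest = SN), matching the
        reading that lower components are non-nucleus tissue.
    """
    check_same_grid(enh, nm_mask)
    if not nm_mask.values.any():
        raise DegenerateInputError("neuromelanin mask is empty")
    vals = enh.values[nm_mask.values]
    if np.unique(vals).size < k:
        raise DegeneracyError(
            f"fewer than {k} distinct intensity values in the neuromelanin mask"
        )
    model = fit_gmm_em(vals, k=k, seed=seed, n_init=n_init, **em_kwargs)

    if grouping == "gap":
        high = _weighted_two_partition(model.means, model.weights)
    elif grouping == "top_two":
        high = np.zeros(model.k, dtype=bool)
        order = np.argsort(model.means)
        high[order[-1]] = True
        vta_comps = np.zeros(model.k, dtype=bool)
        if model.k >= 2:
            vta_comps[order[-2]] = True
    else:
        raise ParameterError(f"unknown grouping rule {grouping!r}")

    resp = model.responsibilities(vals)
    order_desc = np.argsort(-model.means)
    winners = order_desc[np.argmax(resp[:, order_desc], axis=1)]
    is_high_voxel = high[winners]
    if grouping == "top_two":
        is_vta_voxel = vta_comps[winners]
    else:
        is_vta_voxel = ~is_high_voxel

    vta_arr = np.zeros(enh.shape, dtype=bool)
    sn_arr = np.zeros(enh.shape, dtype=bool)
    idx = np.nonzero(nm_mask.values)
    vta_arr[idx] = is_vta_voxel
    sn_arr[idx] = is_high_voxel
    if not vta_arr.any() or not sn_arr.any():
        warnings.warn("one nucleus candidate is empty after the split", stacklevel=2)
    return (
        Mask(vta_arr, enh.voxel_size_mm, id="vta_candidate"),
        Mask(sn_arr, enh.voxel_size_mm, id="sn_candidate"),
        model,
    )


def apply_constraints(candidate: Mask, constraints: AnatomicalConstraints) -> Mask:
    """Clip a candidate to the midbrain and to the lateral bound.

    Voxels farther than ``max_lateral_distance_mm`` from the midline
    sagittal plane (along axis 0) are removed. An empty result is
    allowed and raises a warning, not an error.
    """
    check_same_grid(candidate, constraints.midbrain)
    midline = constraints.resolved_midline()
    nx = candidate.shape[0]
    dist_mm = np.abs(np.arange(nx) - midline) * candidate.voxel_size_mm[0]
    lateral_ok = dist_mm <= constraints.max_lateral_distance_mm
    out = candidate.values & constraints.midbrain.values & lateral_ok[:, None, None]
    if not out.any():
        warnings.warn("anatomical constraints removed every candidate voxel", stacklevel=2)
    return Mask(out, candidate.voxel_size_mm, id=(candidate.id or "candidate") + "_constrained")


_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


def bilateral_components(
    mask: Mask, connectivity: int = 26, midline_x: float | None = None
) -> tuple[Mask, Mask, dict]:
    """Keep the largest connected component on each side of the midline.

    Components are assigned to a side by the sign of their centroid's
    offset from the midline plane; smaller same-side components are
    discarded and reported.
    """
    if connectivity not in _CONNECTIVITY:
        raise ParameterError(f"connectivity must be one of {sorted(_CONNECTIVITY)}")
    if midline_x is None:
        midline_x = (mask.shape[0] - 1) / 2.0
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    labeled, n = ndimage.label(mask.values, structure=structure)
    report = {"n_components": int(n), "discarded": [], "empty_sides": []}
    left = np.zeros(mask.shape, dtype=bool)
    right = np.zeros(mask.shape, dtype=bool)
    if n > 0:
        sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
        centroids = ndimage.center_of_mass(mask.values, labeled, index=np.arange(1, n + 1))
        side_of = ["left" if c[0] < midline_x else "right" for c in centroids]
        for side, arr in (("left", left), ("right", right)):
            cand = [i for i in range(n) if side_of[i] == side]
            if not cand:
                report["empty_sides"].append(side)
                continue
            keep = max(cand, key=lambda i: sizes[i])
            arr[labeled == keep + 1] = True
            for i in cand:
                if i != keep:
                    report["discarded"].append({"side": side, "size_voxels": int(sizes[i])})
    else:
        report["empty_sides"] = ["left", "right"]
    return (
        Mask(left, mask.voxel_size_mm, id="left"),
        Mask(right, mask.voxel_size_mm, id="right"),
        report,
    )


@dataclass
class SegmentationResult:
    """Masks and fit diagnostics from the full segmentation stage."""

    vta: Mask
    sn: Mask
    labels: LabelVolume
    model_k3: MixtureModel
    model_k4: MixtureModel
    report: dict = field(default_factory=dict)


def segment_vta_sn(
    enh: VolumeGrid,
    analysis_mask: Mask,
    constraints: AnatomicalConstraints,
    seed: int = 0,
    n_init: int = 10,
    connectivity: int = 26,
    grouping: str = "gap",
    **em_kwargs,
) -> SegmentationResult:
    """Run the full delineation: k=3 fit, k=4 refinement, constraints,
    bilateral extraction.

    If the neuromelanin class carries fewer than 4 distinct intensity
    values (e.g. a noiseless phantom), the refinement is refitted with
    k reduced to the number of distinct values and the reduction is
    flagged in the report.
    """
    vals = enh.values[analysis_mask.values]
    m3 = fit_gmm_em(vals, k=3, seed=seed, n_init=n_init, **em_kwargs)
    labels = classify_voxels(m3, enh, analysis_mask)
    nm_idx = select_component(m3, "neuromelanin")
    nm_mask = Mask(labels.labels == nm_idx, enh.voxel_size_mm, id="neuromelanin")
    labels.legend = {
        select_component(m3, "csf"): "csf",
        select_component(m3, "wm"): "wm",
        nm_idx: "neuromelanin",
    }

    report: dict = {"k4_reduced_to": None}
    try:
        vta_c, sn_c, m4 = split_vta_sn(
            enh, nm_mask, seed=seed, k=4, n_init=n_init, grouping=grouping, **em_kwargs
        )
    except DegeneracyError:
        n_distinct = int(np.unique(enh.values[nm_mask.values]).size)
        if n_distinct < 2:
            # Single-tier neuromelanin class: no split is possible; the
            # whole class becomes the VTA candidate and SN stays empty.
            warnings.warn("neuromelanin class has a single intensity tier; SN candidate empty", stacklevel=2)
            vta_c = Mask(nm_mask.values.copy(), enh.voxel_size_mm, id="vta_candidate")
            sn_c = Mask(np.zeros(enh.shape, dtype=bool), enh.voxel_size_mm, id="sn_candidate")
            m4 = fit_gmm_em(enh.values[nm_mask.values], k=1)
            report["k4_reduced_to"] = 1
            report["single_tier"] = True
            return _finish(enh, analysis_mask, constraints, connectivity, vta_c, sn_c, m3, m4, labels, report)
        k_red = max(2, min(4, n_distinct))
        vta_c, sn_c, m4 = split_vta_sn(
            enh, nm_mask, seed=seed, k=k_red, n_init=n_init, grouping=grouping, **em_kwargs
        )
        report["k4_reduced_to"] = k_red

    return _finish(enh, analysis_mask, constraints, connectivity, vta_c, sn_c, m3, m4, labels, report)


def _model_summary(m: MixtureModel) -> dict:
    return {
        "weights": m.weights.tolist(),
        "means": m.means.tolist(),
        "variances": m.variances.tolist(),
        "loglik": m.loglik,
        "n_iter": m.n_iter,
        "converged": bool(m.converged),
    }


def _finish(enh, analysis_mask, constraints, connectivity, vta_c, sn_c, m3, m4, labels, report) -> SegmentationResult:
    midline = constraints.resolved_midline()
    vta_con = apply_constraints(vta_c, constraints)
    with warnings.catch_warnings():
        if not sn_c.values.any():
            warnings.simplefilter("ignore")  # empty SN already flagged upstream
        sn_con = apply_constraints(sn_c, constraints)
    vta_l, vta_r, rep_v = bilateral_components(vta_con, connectivity, midline)
    sn_l, sn_r, rep_s = bilateral_components(sn_con, connectivity, midline)
    vta = Mask(vta_l.values | vta_r.values, enh.voxel_size_mm, id="vta")
    sn = Mask(sn_l.values | sn_r.values, enh.voxel_size_mm, id="sn")
    report["vta_components"] = rep_v
    report["sn_components"] = rep_s
    report["k3"] = _model_summary(m3)
    report["k4"] = _model_summary(m4)
    return SegmentationResult(vta=vta, sn=sn, labels=labels, model_k3=m3, model_k4=m4, report=report)
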