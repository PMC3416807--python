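"""Meta-analytic connectivity modeling (MACM).

Functional connectivity of a seed region is inferred meta-analytically:
select every experiment reporting at least one focus inside the seed
ROI(s), then run the full ALE chain (statistic, permutation null,
FDR + cluster thresholding) over the selected experiments' pooled foci.

Selection rule: by default an experiment qualifies if any focus falls
in any ROI (``require_all=False``); ``require_all=True`` demands at
least one focus in *each* ROI.  Focus-in-ROI membership is tested at
the focus's nearest voxel; an optional ``dilate_mm`` pads the ROIs
before testing, as published MACM analyses often do with small seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .ale import AleParams, ale_map, build_null, threshold_map
from .corpus_io import FociExperiment, VolumeMap

__all__ = ["MacmSelection", "select_coactivating", "macm_map"]


@dataclass
class MacmSelection:
    """Selected experiments plus a per-experiment ROI-match report."""

    experiments: list[FociExperiment]
    #: experiment_id -> sorted list of ROI indices with >= 1 focus inside
    report: dict[str, list[int]] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.experiments)

    def __len__(self):
        return len(self.experiments)


def _dilate(roi: VolumeMap, dilate_mm: float) -> np.ndarray:
    """Pad an ROI to all voxels within dilate_mm of it (edt in mm)."""
    binary = roi.values > 0
    if dilate_mm <= 0:
        return binary
    dist = ndimage.distance_transform_edt(~binary, sampling=roi.voxel_size)
    return dist <= dilate_mm


def select_coactivating(
    experiments: list[FociExperiment],
    rois: list[VolumeMap],
    require_all: bool = False,
    dilate_mm: float = 0.0,
) -> MacmSelection:
    """Experiments with >= 1 focus inside the seed ROI(s), order preserved."""
    if not rois:
        raise ValueError("at least one ROI required")
    ref = rois[0]
    for roi in rois[1:]:
        if not ref.same_grid(roi):
            raise ValueError("ROIs are not on a common grid")
    roi_masks = [_dilate(roi, dilate_mm) for roi in rois]
    selected = []
    report: dict[str, list[int]] = {}
    for exp in experiments:
        hit: set[int] = set()
        for f in exp.foci:
            xyz = (f.x, f.y, f.z)
            if not ref.in_grid(xyz):
                continue
            ijk = ref.nearest_voxel(xyz)
            for r, m in enumerate(roi_masks):
                if m[ijk]:
                    hit.add(r)
        qualifies = len(hit) == len(rois) if require_all else bool(hit)
        if qualifies:
            selected.append(exp)
            report[exp.experiment_id] = sorted(hit)
    return MacmSelection(experiments=selected, report=report)


def macm_map(
    experiments: list[FociExperiment],
    rois: list[VolumeMap],
    params: AleParams,
    grid: VolumeMap,
    require_all: bool = False,
    dilate_mm: float = 0.0,
):
    """Thresholded co-activation map of the seed ROI(s).

    Returns ``(thresholded_map, provenance)``; provenance records the
    selection rule and per-experiment matches alongside the unthresholded
    ALE map.  Raises if no experiment co-activates the seed.
    """
    selection = select_coactivating(experiments, rois, require_all=require_all, dilate_mm=dilate_mm)
    if not selection.experiments:
        raise ValueError("empty selection: no experiment reports a focus in the seed ROI(s)")
    ale = ale_map(selection.experiments, params, grid)
    null = build_null(selection.experiments, params, grid)
    thresholded = threshold_map(ale, null, params)
    provenance = {
        "n_candidates": len(experiments),
        "n_selected": len(selection),
        "require_all": require_all,
        "dilate_mm": dilate_mm,
        "selection_report": selection.report,
        "ale_map": ale,
    }
    return thresholded, provenance
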