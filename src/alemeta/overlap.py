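"""Multi-network overlap, strict conjunction, and low-overlap extraction.

Given N thresholded (binary) network maps on one grid, the probability
overlap map assigns each voxel the fraction of networks active there
(values 0, 1/N, ..., 1).  The conjunction keeps voxels where the count
is exactly N of N — a logical AND, no float tolerance.  The low-overlap
extraction returns the lowest-overlap fraction of nonzero voxels,
admitted whole value-stratum by value-stratum so ties are never split.

Binarized inputs are the default reading; averaging raw (continuous)
statistic values instead is available via ``binarize=False``.
"""

from __future__ import annotations

import warnings

import numpy as np

from .corpus_io import VolumeMap

__all__ = ["probability_overlap", "conjunction", "low_overlap_region"]


class OverlapMap(VolumeMap):
    """Probability-overlap map; carries the contributing network names."""

    def __init__(self, values, voxel_size, origin, mask, network_names, counts):
        super().__init__(values, voxel_size, origin, mask)
        self.network_names = list(network_names)
        #: integer per-voxel count of active networks (exact, no floats)
        self.counts = np.asarray(counts, dtype=int)

    @property
    def n_networks(self) -> int:
        return len(self.network_names)


def probability_overlap(
    thresholded_maps: list[VolumeMap],
    network_names: list[str] | None = None,
    binarize: bool = True,
) -> OverlapMap:
    """Voxelwise mean of N binary maps: value = (#active networks)/N.

    All maps must share one grid and mask.  With ``binarize=False`` the
    raw map values are averaged instead (the integer counts then count
    voxels with value > 0).
    """
    if len(thresholded_maps) < 2:
        raise ValueError("need at least 2 maps")
    ref = thresholded_maps[0]
    for m in thresholded_maps[1:]:
        if not ref.same_grid(m):
            raise ValueError("maps are not on a common grid/mask")
    if network_names is None:
        network_names = [f"map{i}" for i in range(len(thresholded_maps))]
    stack = np.stack([m.values for m in thresholded_maps])
    counts = (stack > 0).sum(axis=0)
    if binarize:
        values = counts / len(thresholded_maps)
    else:
        values = stack.mean(axis=0)
    return OverlapMap(values, ref.voxel_size, ref.origin, ref.mask, network_names, counts)


def conjunction(overlap: OverlapMap) -> VolumeMap:
    """Voxels where 100% of the networks are represented (exact count
    N of N; equivalent to the logical AND of the binary input maps)."""
    binary = overlap.counts == overlap.n_networks
    return overlap.like(binary.astype(float))


def low_overlap_region(overlap: OverlapMap, fraction: float = 0.20) -> VolumeMap:
    """The lowest-overlap ``fraction`` of nonzero voxels, by whole strata.

    Among voxels with overlap > 0, value strata (1/N, 2/N, ...) are
    admitted low-to-high while the cumulative count stays within the
    quota ceil(fraction * n_nonzero); the first stratum that would
    overshoot the quota is excluded entirely, so tied voxels always
    share one fate.  Degenerate case: if all nonzero voxels sit in a
    single stratum no selection is possible and the whole stratum is
    returned with a warning.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    counts = overlap.counts
    nonzero = counts > 0
    n_nonzero = int(nonzero.sum())
    out = np.zeros(overlap.shape, dtype=bool)
    if n_nonzero == 0:
        warnings.warn("overlap map has no nonzero voxels; returning empty map")
        return overlap.like(out.astype(float))
    strata = np.unique(counts[nonzero])
    if len(strata) == 1:
        warnings.warn("overlap is uniform across nonzero voxels; returning all of them")
        return overlap.like(nonzero.astype(float))
    quota = int(np.ceil(fraction * n_nonzero))
    admitted = 0
    for value in strata:
        stratum = counts == value
        size = int(stratum.sum())
        if admitted + size > quota:
            break
        out |= stratum
        admitted += size
    return overlap.like(out.astype(float))
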