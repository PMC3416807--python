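"""Activation likelihood estimation: kernels, union statistic,
permutation null and FDR/cluster thresholding.

Each reported peak is blurred with an isotropic 3-D Gaussian kernel of
fixed FWHM (default 10 mm, so sigma = FWHM / (2 * sqrt(2 ln 2)) ≈ 4.25 mm).
Per experiment, the kernels of its foci combine into a modeled-activation
(MA) map, MA(v) = 1 - prod_f (1 - k_f(v)); the ALE statistic is the same
probabilistic union across experiments, ALE(v) = 1 - prod_i (1 - MA_i(v)).
Significance is assessed against a permutation null built by relocating
every focus uniformly over in-mask voxels, pooling all in-mask voxel
values; voxelwise empirical p-values are corrected by Benjamini-Hochberg
FDR and surviving voxels are filtered by a minimum cluster extent
(strictly greater than ``min_cluster_mm3``).

The experiment-grouped union is the default; a pure per-focus union
(no experiment grouping) is available via ``group_by_experiment=False``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from statsmodels.stats.multitest import multipletests

from .corpus_io import FociExperiment, Focus, VolumeMap, flag_out_of_mask

__all__ = [
    "AleParams",
    "NullDistribution",
    "sigma_from_fwhm",
    "gaussian_kernel_map",
    "ale_map",
    "build_null",
    "p_value_map",
    "bh_reject",
    "threshold_map",
]


def sigma_from_fwhm(fwhm: float) -> float:
    """Gaussian sigma for a given full width at half maximum."""
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    return fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class AleParams:
    """Tunable parameters of the ALE chain.

    fwhm : kernel full width at half maximum, mm (default 10)
    n_permutations : randomizations for the null (default 1000)
    q_fdr : Benjamini-Hochberg false-discovery level (default 0.05)
    min_cluster_mm3 : clusters must strictly exceed this volume (default 100)
    connectivity : 26 (vertex) or 6 (face) neighborhood for clusters
    group_by_experiment : experiment-grouped union vs per-focus union
    """

    fwhm: float = 10.0
    n_permutations: int = 1000
    q_fdr: float = 0.05
    min_cluster_mm3: float = 100.0
    connectivity: int = 26
    group_by_experiment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if not 0.0 < self.q_fdr < 1.0:
            raise ValueError("q_fdr must be in (0, 1)")
        if self.min_cluster_mm3 < 0:
            raise ValueError("min_cluster_mm3 must be >= 0")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")


class NullDistribution:
    """Pooled-voxel ALE values under focus randomization, sorted ascending."""

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float).ravel()
        if values.size == 0:
            raise ValueError("empty null sample")
        if np.any(values < 0):
            raise ValueError("null ALE values must be non-negative")
        self.values = np.sort(values)

    @property
    def n_samples(self) -> int:
        return self.values.size

    def p_values(self, observed: np.ndarray) -> np.ndarray:
        """Empirical p = (1 + #null >= obs) / (1 + n_samples).

        The +1 convention never yields p = 0; an observed value of 0 has
        p = 1 and a value above the null maximum has p = 1/(n+1).
        """
        observed = np.asarray(observed, dtype=float)
        n_ge = self.n_samples - np.searchsorted(self.values, observed, side="left")
        return (1.0 + n_ge) / (1.0 + self.n_samples)


# ---------------------------------------------------------------------
# Kernels and the ALE statistic
# ---------------------------------------------------------------------


def _kernel_values(xyz: np.ndarray, sigma: float, grid: VolumeMap) -> np.ndarray:
    """Unnormalized per-voxel kernel: Gaussian density at voxel centers
    times voxel volume.  Separable over axes."""
    xs, ys, zs = grid.axis_coords()
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    gx = np.exp(-((xs - xyz[0]) ** 2) * inv2s2)
    gy = np.exp(-((ys - xyz[1]) ** 2) * inv2s2)
    gz = np.exp(-((zs - xyz[2]) ** 2) * inv2s2)
    dens = gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
    norm = (2.0 * math.pi) ** 1.5 * sigma**3
    return dens / norm * grid.voxel_volume


def gaussian_kernel_map(focus: Focus | np.ndarray, fwhm: float, grid: VolumeMap) -> VolumeMap:
    """Probability map of one focus: isotropic Gaussian density at voxel
    centers x voxel volume, renormalized to sum to 1 over the in-mask grid.
    """
    sigma = sigma_from_fwhm(fwhm)
    xyz = focus.as_array() if isinstance(focus, Focus) else np.asarray(focus, dtype=float)
    if not grid.in_mask(xyz):
        raise ValueError(f"focus {tuple(xyz)} outside the mask")
    k = _kernel_values(xyz, sigma, grid)
    total = k[grid.mask].sum()
    return grid.like(k / total)


def _one_minus_ma(foci_xyz: np.ndarray, sigma: float, grid: VolumeMap) -> np.ndarray:
    """1 - MA for one experiment: product over foci of (1 - kernel)."""
    out = np.ones(grid.shape)
    for xyz in foci_xyz:
        k = _kernel_values(xyz, sigma, grid)
        k /= k[grid.mask].sum()
        out *= 1.0 - k
    return out


def _ale_values(per_experiment_foci: list[np.ndarray], sigma: float, grid: VolumeMap, grouped: bool) -> np.ndarray:
    if grouped:
        one_minus = np.ones(grid.shape)
        for foci_xyz in per_experiment_foci:
            one_minus *= _one_minus_ma(foci_xyz, sigma, grid)
    else:
        all_foci = np.concatenate(per_experiment_foci, axis=0)
        one_minus = _one_minus_ma(all_foci, sigma, grid)
    ale = 1.0 - one_minus
    ale[~grid.mask] = 0.0
    return ale


def ale_map(experiments: list[FociExperiment], params: AleParams, grid: VolumeMap) -> VolumeMap:
    """ALE statistic over a set of experiments.

    Out-of-mask foci are excluded from kernel placement (they are
    reported by :func:`alemeta.corpus_io.flag_out_of_mask`, which
    callers can use for QC).  Values lie in [0, 1); voxels outside the
    mask are exactly 0.
    """
    if not experiments:
        raise ValueError("ale_map requires at least one experiment")
    kept, _ = flag_out_of_mask(experiments, grid)
    if not kept:
        raise ValueError("no experiment has an in-mask focus")
    sigma = sigma_from_fwhm(params.fwhm)
    per_exp = [e.foci_array() for e in kept]
    return grid.like(_ale_values(per_exp, sigma, grid, params.group_by_experiment))


# ---------------------------------------------------------------------
# Permutation null and thresholding
# ---------------------------------------------------------------------


def build_null(experiments: list[FociExperiment], params: AleParams, grid: VolumeMap) -> NullDistribution:
    """Permutation null for the ALE statistic.

    Each permutation relocates every focus independently and uniformly
    over in-mask voxel centers (preserving per-experiment focus counts),
    recomputes the ALE map, and pools all in-mask voxel values into one
    null sample.  Deterministic given ``params.seed``.
    """
    kept, _ = flag_out_of_mask(experiments, grid)
    if not kept:
        raise ValueError("no experiment has an in-mask focus")
    sigma = sigma_from_fwhm(params.fwhm)
    rng = np.random.default_rng(params.seed)
    counts = [e.n_foci for e in kept]
    in_mask_idx = np.argwhere(grid.mask)
    pooled = np.empty((params.n_permutations, int(grid.mask.sum())))
    for p in range(params.n_permutations):
        per_exp = []
        for c in counts:
            picks = in_mask_idx[rng.integers(0, len(in_mask_idx), size=c)]
            per_exp.append(grid.voxel_to_mm(picks))
        ale = _ale_values(per_exp, sigma, grid, params.group_by_experiment)
        pooled[p] = ale[grid.mask]
    return NullDistribution(pooled)


def p_value_map(ale: VolumeMap, null: NullDistribution) -> VolumeMap:
    """Voxelwise empirical p-values (1 outside the mask by convention
    of the mask-zeroing container; out-of-mask voxels are never tested)."""
    p = np.ones(ale.shape)
    p[ale.mask] = null.p_values(ale.values[ale.mask])
    return ale.like(p)


def bh_reject(pvals: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at level q.

    Standard largest-k rule; equal p-values share the decision of their
    largest index.
    """
    reject, *_ = multipletests(np.asarray(pvals, dtype=float), alpha=q, method="fdr_bh")
    return reject


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    return ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def cluster_extent_filter(binary: np.ndarray, grid: VolumeMap, min_cluster_mm3: float, connectivity: int = 26) -> np.ndarray:
    """Drop connected components whose volume is <= min_cluster_mm3
    (strict 'greater than' survival rule)."""
    labels, n = ndimage.label(binary, structure=_connectivity_structure(connectivity))
    if n == 0:
        return np.zeros_like(binary, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes * grid.voxel_volume > min_cluster_mm3) + 1
    return np.isin(labels, keep)


def threshold_map(ale: VolumeMap, null: NullDistribution, params: AleParams) -> VolumeMap:
    """Binary significance map: BH-FDR on voxelwise empirical p-values,
    then cluster-extent filtering."""
    pmap = p_value_map(ale, null)
    pvals = pmap.values[ale.mask]
    reject = bh_reject(pvals, params.q_fdr)
    binary = np.zeros(ale.shape, dtype=bool)
    binary[ale.mask] = reject
    binary = cluster_extent_filter(binary, ale, params.min_cluster_mm3, params.connectivity)
    return ale.like(binary.astype(float))
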