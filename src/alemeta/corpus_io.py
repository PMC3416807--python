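"""Data model and I/O for activation-foci corpora and volume maps.

Coordinate-based meta-analysis works from tables of activation peaks
("foci") reported in stereotactic millimeter space (MNI convention),
grouped into experiments, and from scalar maps defined on a regular
voxel grid.  This module holds the shared containers — :class:`Focus`,
:class:`FociExperiment`, :class:`NetworkCollection`, :class:`VolumeMap`
— plus readers/writers for Sleuth-style foci text, a flat CSV dialect,
and NIfTI-1 volumes (diagonal affines only).

All public APIs speak millimeters; voxel indices never leak out except
through the explicit ``mm_to_voxel`` / ``voxel_to_mm`` helpers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Focus",
    "FociExperiment",
    "NetworkCollection",
    "VolumeMap",
    "read_foci_table",
    "write_foci_table",
    "read_volume",
    "write_volume",
    "flag_out_of_mask",
]


@dataclass(frozen=True)
class Focus:
    """A single reported activation peak, in mm (MNI convention)."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for c in (self.x, self.y, self.z):
            if not math.isfinite(c):
                raise ValueError(f"focus coordinate not finite: {(self.x, self.y, self.z)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class FociExperiment:
    """One neuroimaging experiment: an ordered list of peak coordinates.

    ``domain_labels`` carries the task / behavioral-domain tags used to
    assemble networks; ``subject_group`` is free-text metadata (e.g. the
    subject-selection clause of the originating database query).
    """

    experiment_id: str
    study_id: str
    foci: list[Focus]
    domain_labels: set[str] = field(default_factory=set)
    subject_group: str = ""

    @property
    def n_foci(self) -> int:
        return len(self.foci)

    def foci_array(self) -> np.ndarray:
        """(n_foci, 3) array of mm coordinates."""
        if not self.foci:
            return np.empty((0, 3), dtype=float)
        return np.stack([f.as_array() for f in self.foci])


@dataclass
class NetworkCollection:
    """All experiments belonging to one task-related network."""

    name: str
    experiments: list[FociExperiment]

    def __post_init__(self) -> None:
        if not self.experiments:
            raise ValueError(f"network {self.name!r} has no experiments")
        ids = [e.experiment_id for e in self.experiments]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate experiment_id in network {self.name!r}")

    @property
    def n_experiments(self) -> int:
        return len(self.experiments)


class VolumeMap:
    """Scalar field on a regular, axis-aligned voxel grid.

    Parameters
    ----------
    values : (nx, ny, nz) array
    voxel_size : mm per axis (scalar or length-3)
    origin : mm coordinate of the *center* of voxel (0, 0, 0)
    mask : boolean array, same shape; values outside the mask are
        forced to exactly 0 on construction.
    """

    def __init__(self, values, voxel_size, origin, mask=None):
        self.values = np.asarray(values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        vs = np.asarray(voxel_size, dtype=float)
        self.voxel_size = np.broadcast_to(vs, (3,)).copy()
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be positive")
        self.origin = np.asarray(origin, dtype=float).reshape(3)
        if mask is None:
            mask = np.ones(self.values.shape, dtype=bool)
        self.mask = np.asarray(mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape differs from values shape")
        self.values = np.where(self.mask, self.values, 0.0)

    # -- geometry -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    @property
    def affine(self) -> np.ndarray:
        """Diagonal 4x4 voxel-to-mm affine (voxel centers)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = self.origin
        return aff

    def voxel_to_mm(self, ijk) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return self.origin + ijk * self.voxel_size

    def mm_to_voxel(self, xyz) -> np.ndarray:
        """Continuous voxel coordinate of an mm point."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - self.origin) / self.voxel_size

    def nearest_voxel(self, xyz) -> tuple[int, int, int]:
        """Index of the voxel whose center is nearest to ``xyz`` (mm)."""
        ijk = np.rint(self.mm_to_voxel(xyz)).astype(int)
        return tuple(int(i) for i in ijk)

    def in_grid(self, xyz) -> bool:
        ijk = np.rint(self.mm_to_voxel(xyz)).astype(int)
        return bool(np.all(ijk >= 0) and np.all(ijk < np.array(self.shape)))

    def in_mask(self, xyz) -> bool:
        """True if the nearest voxel to an mm point is inside the mask."""
        if not self.in_grid(xyz):
            return False
        return bool(self.mask[self.nearest_voxel(xyz)])

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis mm coordinates of voxel centers."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.voxel_size[a] for a in range(3)
        )

    # -- construction helpers -----------------------------------------

    def like(self, values=None) -> "VolumeMap":
        """New map on the same grid/mask (zeros if no values given)."""
        if values is None:
            values = np.zeros(self.shape)
        return VolumeMap(values, self.voxel_size, self.origin, self.mask)

    def copy(self) -> "VolumeMap":
        return VolumeMap(self.values.copy(), self.voxel_size, self.origin, self.mask.copy())

    def same_grid(self, other: "VolumeMap") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size)
            and np.allclose(self.origin, other.origin)
            and np.array_equal(self.mask, other.mask)
        )

    def __eq__(self, other) -> bool:  # value equality, used by tests
        if not isinstance(other, VolumeMap):
            return NotImplemented
        return self.same_grid(other) and np.allclose(self.values, other.values, atol=1e-6)


# ---------------------------------------------------------------------
# Foci tables
# ---------------------------------------------------------------------

_SLEUTH_STUDY = "// Study:"
_SLEUTH_EXPERIMENT = "// Experiment:"
_SLEUTH_DOMAIN = "// Domain:"
_SLEUTH_SUBJECTS = "// Subjects:"


def _parse_sleuth(lines: list[str], path: str) -> list[FociExperiment]:
    experiments: list[FociExperiment] = []
    cur: dict | None = None

    def flush():
        nonlocal cur
        if cur is not None:
            experiments.append(
                FociExperiment(
                    experiment_id=cur["experiment_id"],
                    study_id=cur["study_id"],
                    foci=cur["foci"],
                    domain_labels=cur["domains"],
                    subject_group=cur["subjects"],
                )
            )
            cur = None

    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        stripped = line.strip()
        if not stripped:
            flush()
            continue
        if stripped.startswith(_SLEUTH_STUDY):
            if cur is not None and cur["foci"]:
                flush()
            if cur is None:
                cur = {"study_id": "", "experiment_id": "", "domains": set(), "subjects": "", "foci": []}
            cur["study_id"] = stripped[len(_SLEUTH_STUDY):].strip()
        elif stripped.startswith(_SLEUTH_EXPERIMENT):
            if cur is None:
                cur = {"study_id": "", "experiment_id": "", "domains": set(), "subjects": "", "foci": []}
            cur["experiment_id"] = stripped[len(_SLEUTH_EXPERIMENT):].strip()
        elif stripped.startswith(_SLEUTH_DOMAIN):
            if cur is None:
                raise ValueError(f"{path}:{lineno}: Domain line before any experiment header")
            labels = stripped[len(_SLEUTH_DOMAIN):].strip()
            cur["domains"] = {t.strip() for t in labels.split(",") if t.strip()}
        elif stripped.startswith(_SLEUTH_SUBJECTS):
            if cur is None:
                raise ValueError(f"{path}:{lineno}: Subjects line before any experiment header")
            cur["subjects"] = stripped[len(_SLEUTH_SUBJECTS):].strip()
        elif stripped.startswith("//"):
            continue  # other comment lines are ignored
        else:
            if cur is None:
                raise ValueError(f"{path}:{lineno}: coordinate line before any experiment header")
            parts = stripped.replace(",", "\t").split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 coordinates, got {stripped!r}")
            try:
                x, y, z = (float(p) for p in parts)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinate line {stripped!r}") from exc
            cur["foci"].append(Focus(x, y, z))
    flush()
    if not experiments:
        raise ValueError(f"{path}: no experiments found (empty or header-only file)")
    return experiments


def _parse_csv(path: str) -> list[FociExperiment]:
    table = pd.read_csv(path, skipinitialspace=True)
    required = {"study_id", "experiment_id", "domain", "x", "y", "z"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing CSV columns {sorted(missing)}")
    if table.empty:
        raise ValueError(f"{path}: empty foci table")
    for col in ("x", "y", "z"):
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 one-based
            raise ValueError(f"{path}: malformed coordinate in column {col!r} at line {row}")
        table[col] = coerced
    experiments = []
    # duplicated experiment_id rows pool into a single experiment
    for exp_id, group in table.groupby("experiment_id", sort=False):
        foci = [Focus(r.x, r.y, r.z) for r in group.itertuples()]
        domains: set[str] = set()
        for d in group["domain"].dropna():
            domains |= {t.strip() for t in str(d).split(";") if t.strip()}
        experiments.append(
            FociExperiment(
                experiment_id=str(exp_id),
                study_id=str(group["study_id"].iloc[0]),
                foci=foci,
                domain_labels=domains,
            )
        )
    return experiments


def read_foci_table(path, dialect: str = "sleuth_text") -> list[FociExperiment]:
    """Read a foci table.

    ``sleuth_text``: ``// Study:`` / ``// Experiment:`` / ``// Domain:``
    header lines followed by one ``x<tab>y<tab>z`` per focus, blank line
    between experiments.  ``csv``: columns study_id, experiment_id,
    domain, x, y, z (rows sharing an experiment_id pool their foci).
    """
    path = str(path)
    if dialect == "sleuth_text":
        with open(path) as fh:
            return _parse_sleuth(fh.readlines(), path)
    if dialect == "csv":
        return _parse_csv(path)
    raise ValueError(f"unsupported dialect {dialect!r}")


def write_foci_table(experiments: list[FociExperiment], path, dialect: str = "sleuth_text") -> None:
    """Write experiments so that :func:`read_foci_table` re-reads them equal."""
    path = str(path)
    if dialect == "sleuth_text":
        with open(path, "w") as fh:
            for exp in experiments:
                fh.write(f"{_SLEUTH_STUDY} {exp.study_id}\n")
                fh.write(f"{_SLEUTH_EXPERIMENT} {exp.experiment_id}\n")
                if exp.domain_labels:
                    fh.write(f"{_SLEUTH_DOMAIN} {', '.join(sorted(exp.domain_labels))}\n")
                if exp.subject_group:
                    fh.write(f"{_SLEUTH_SUBJECTS} {exp.subject_group}\n")
                for f in exp.foci:
                    fh.write(f"{f.x:g}\t{f.y:g}\t{f.z:g}\n")
                fh.write("\n")
    elif dialect == "csv":
        rows = []
        for exp in experiments:
            for f in exp.foci:
                rows.append(
                    {
                        "study_id": exp.study_id,
                        "experiment_id": exp.experiment_id,
                        "domain": ";".join(sorted(exp.domain_labels)),
                        "x": f.x,
                        "y": f.y,
                        "z": f.z,
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported dialect {dialect!r}")


def flag_out_of_mask(experiments: list[FociExperiment], grid: VolumeMap):
    """Partition foci into in-mask and out-of-mask.

    Out-of-mask foci are excluded from kernel placement downstream but
    never silently dropped: the QC report lists every flagged focus.

    Returns ``(kept_experiments, qc_report)`` where the report is a list
    of ``(experiment_id, focus)`` pairs.  Experiments left with no
    in-mask focus are omitted from ``kept_experiments`` (and appear in
    the report).
    """
    kept: list[FociExperiment] = []
    report: list[tuple[str, Focus]] = []
    for exp in experiments:
        inside = [f for f in exp.foci if grid.in_mask((f.x, f.y, f.z))]
        outside = [f for f in exp.foci if not grid.in_mask((f.x, f.y, f.z))]
        report.extend((exp.experiment_id, f) for f in outside)
        if inside:
            kept.append(
                FociExperiment(
                    experiment_id=exp.experiment_id,
                    study_id=exp.study_id,
                    foci=inside,
                    domain_labels=set(exp.domain_labels),
                    subject_group=exp.subject_group,
                )
            )
    return kept, report


# ---------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------


def write_volume(vmap: VolumeMap, path) -> None:
    """Write a map as NIfTI-1 with a diagonal affine."""
    img = nib.Nifti1Image(vmap.values.astype(np.float64), vmap.affine)
    nib.save(img, str(path))


def read_volume(path, mask: np.ndarray | None = None) -> VolumeMap:
    """Read a NIfTI-1 volume written by :func:`write_volume`.

    Only diagonal affines are supported; anything else is rejected
    rather than silently resampled.  An optional boolean ``mask``
    restores the mask (NIfTI carries only the values).
    """
    img = nib.load(str(path))
    aff = img.affine
    offdiag = aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))
    if not np.allclose(offdiag, 0):
        raise ValueError(f"{path}: non-diagonal affine is unsupported")
    voxel_size = np.diag(aff[:3, :3])
    if np.any(voxel_size < 0):
        raise ValueError(f"{path}: negative voxel sizes (flipped axes) unsupported")
    values = np.asarray(img.dataobj, dtype=float)
    return VolumeMap(values, voxel_size, aff[:3, 3], mask=mask)
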