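"""Readers, writers and validated containers shared by the whole pipeline.

Conventions used throughout the package:

* voxel indices are 0-based, axis order ``(x, y, z)``;
* world coordinates are obtained through the 4x4 voxel-to-world affine;
* diffusivities are expressed in mm^2/s;
* gradient tables use the common plain-text interchange dialect: a
  single whitespace-separated row of b-values and a three-row b-vector
  file (x, y, z components).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "GradientTable",
    "Volume4D",
    "ScalarMap",
    "CohortTable",
    "ValidationError",
    "read_gradients",
    "write_gradients",
    "read_volume",
    "write_volume",
    "read_cohort",
    "write_cohort",
]

SCALAR_KINDS = ("FA", "MD", "FW", "meanFA")

#: tolerance on |norm - 1| for b>0 gradient directions
UNIT_NORM_TOL = 1e-6

COHORT_COLUMNS = ("id", "group", "age", "education", "hama", "mtwv")
GROUP_LEVELS = ("NIHL", "HC")

#: diagnostic thresholds for the better-ear monaural threshold weighted value
MTWV_NIHL_MIN = 26.0  # dB; NIHL diagnosis requires MTWV >= 26


class ValidationError(ValueError):
    """An input file or container violates a documented invariant."""


# ---------------------------------------------------------------------------
# Gradient tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GradientTable:
    """b-values (s/mm^2) and unit gradient directions of an acquisition.

    Invariants (enforced at construction): equal lengths; every direction
    with b > 0 has unit Euclidean norm within ``UNIT_NORM_TOL``; at least
    one b == 0 entry; enough non-collinear b > 0 directions to determine
    a full symmetric tensor (rank-6 quadratic-form design).
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValidationError(f"bvecs must be (n, 3), got {bvecs.shape}")
        if len(bvals) != len(bvecs):
            raise ValidationError(
                f"length mismatch: {len(bvals)} b-values vs {len(bvecs)} directions"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

        norms = np.linalg.norm(bvecs, axis=1)
        bad = np.where((bvals > 0) & (np.abs(norms - 1.0) > UNIT_NORM_TOL))[0]
        if bad.size:
            i = int(bad[0])
            raise ValidationError(
                f"gradient direction {i} has norm {norms[i]:.6g} != 1 at b={bvals[i]:g}"
            )
        if not np.any(bvals == 0):
            raise ValidationError("gradient table contains no b=0 entry")

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > 0

    def require_tensor_fit_capable(self) -> None:
        """Raise unless >= 6 pairwise non-collinear b>0 directions are present.

        Checked where a full tensor is actually estimated; a table may be
        valid for mere bookkeeping with fewer directions.
        """
        if np.linalg.matrix_rank(self.design_quadratic()) < 6:
            raise ValidationError(
                "fewer than 6 pairwise non-collinear nonzero gradient directions: "
                "the quadratic-form design is rank deficient"
            )

    def design_quadratic(self) -> np.ndarray:
        """Per-gradient quadratic forms ``b * (gx^2, gy^2, gz^2, 2gxgy, 2gxgz, 2gygz)``.

        Row i dotted with the six unique tensor components
        (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) gives ``b_i * g_i^T D g_i``.
        """
        g = self.bvecs
        q = np.stack(
            [
                g[:, 0] ** 2,
                g[:, 1] ** 2,
                g[:, 2] ** 2,
                2 * g[:, 0] * g[:, 1],
                2 * g[:, 0] * g[:, 2],
                2 * g[:, 1] * g[:, 2],
            ],
            axis=1,
        )
        return self.bvals[:, None] * q


def read_gradients(bval_path: str | Path, bvec_path: str | Path) -> GradientTable:
    """Read a plain-text bval/bvec pair into a validated :class:`GradientTable`."""
    bvals = np.loadtxt(bval_path, ndmin=1, dtype=float)
    if bvals.ndim != 1:
        raise ValidationError("bval file must contain a single row of values")
    rows = np.loadtxt(bvec_path, ndmin=2, dtype=float)
    if rows.shape[0] != 3:
        raise ValidationError(f"bvec file must have three rows, got {rows.shape[0]}")
    return GradientTable(bvals=bvals, bvecs=rows.T)


def write_gradients(gtab: GradientTable, bval_path: str | Path, bvec_path: str | Path) -> None:
    """Write a gradient table in the one-row/three-row text dialect (full precision)."""
    with open(bval_path, "w") as fh:
        fh.write(" ".join(repr(float(v)) for v in gtab.bvals) + "\n")
    with open(bvec_path, "w") as fh:
        for axis in range(3):
            fh.write(" ".join(repr(float(v)) for v in gtab.bvecs[:, axis]) + "\n")


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------


def _check_voxel_size(voxel_size) -> np.ndarray:
    vs = np.asarray(voxel_size, dtype=float).ravel()
    if vs.shape != (3,) or np.any(vs <= 0):
        raise ValidationError(f"voxel_size must be 3 strictly positive values, got {voxel_size}")
    return vs


@dataclass
class Volume4D:
    """A 4-D diffusion-weighted signal array; last axis indexes the gradients."""

    data: np.ndarray
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValidationError(f"Volume4D requires 4-D data, got {self.data.ndim}-D")
        if np.any(self.data < 0):
            raise ValidationError("diffusion signal data must be non-negative")
        self.voxel_size = _check_voxel_size(self.voxel_size)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class ScalarMap:
    """A 3-D scalar map (FA, MD, FW or group mean FA)."""

    data: np.ndarray
    kind: str | None = None
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"ScalarMap requires 3-D data, got {self.data.ndim}-D")
        if self.kind is not None and self.kind not in SCALAR_KINDS:
            raise ValidationError(f"unknown scalar kind {self.kind!r}; expected one of {SCALAR_KINDS}")
        finite = np.isfinite(self.data)
        if self.kind in ("FA", "FW", "meanFA"):
            vals = self.data[finite]
            if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
                raise ValidationError(f"{self.kind} values must lie in [0, 1]")
        if self.kind == "MD":
            vals = self.data[finite]
            if vals.size and vals.min() < -1e-12:
                raise ValidationError("MD values must be non-negative")
        self.voxel_size = _check_voxel_size(self.voxel_size)
        self.affine = np.asarray(self.affine, dtype=float)


def write_volume(vol: Volume4D | ScalarMap, path: str | Path) -> None:
    """Write a volume or scalar map as NIfTI-1, preserving data exactly.

    The scalar ``kind`` is stored in the header ``descrip`` field so that
    :func:`read_volume` can restore it.
    """
    img = nib.Nifti1Image(np.asarray(vol.data), vol.affine)
    zooms = list(vol.voxel_size) + ([1.0] if vol.data.ndim == 4 else [])
    img.header.set_zooms(zooms)
    if isinstance(vol, ScalarMap) and vol.kind is not None:
        img.header["descrip"] = f"kind={vol.kind}".encode()
    nib.save(img, str(path))


def read_volume(path: str | Path, kind: str | None = None) -> Volume4D | ScalarMap:
    """Read a NIfTI file as :class:`Volume4D` (4-D) or :class:`ScalarMap` (3-D)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    affine = np.asarray(img.affine, dtype=float)
    if data.ndim == 4:
        return Volume4D(data=data, voxel_size=voxel_size, affine=affine)
    if data.ndim == 3:
        if kind is None:
            descrip = img.header["descrip"].tobytes().split(b"\x00")[0].decode(errors="ignore")
            if descrip.startswith("kind="):
                candidate = descrip[5:].strip()
                if candidate in SCALAR_KINDS:
                    kind = candidate
        return ScalarMap(data=data, kind=kind, voxel_size=voxel_size, affine=affine)
    raise ValidationError(f"unsupported image dimensionality {data.ndim}; expected 3-D or 4-D")


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------


@dataclass
class CohortTable:
    """Per-subject demographics and clinical scores.

    Columns: ``id, group, age, education, hama, mtwv``. ``group`` has the
    two levels NIHL / HC.  MTWV (dB) is recorded numerically for NIHL
    subjects only (diagnosis requires >= 26 dB); controls were screened as
    MTWV < 25 dB but no numeric value was recorded, so HC rows carry NaN.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.frame).copy()
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"cohort table missing required columns: {missing}")
        if len(df) == 0:
            raise ValidationError("cohort table is empty")
        bad_groups = sorted(set(df["group"]) - set(GROUP_LEVELS))
        if bad_groups:
            raise ValidationError(f"unknown group labels {bad_groups}; expected {GROUP_LEVELS}")
        errors: list[str] = []
        for idx, row in df.iterrows():
            mtwv = row["mtwv"]
            has_mtwv = pd.notna(mtwv)
            if row["group"] == "NIHL":
                if not has_mtwv or float(mtwv) < MTWV_NIHL_MIN:
                    errors.append(
                        f"row {idx} (id={row['id']}): NIHL requires numeric MTWV >= "
                        f"{MTWV_NIHL_MIN:g} dB, got {mtwv!r}"
                    )
            else:
                if has_mtwv:
                    errors.append(
                        f"row {idx} (id={row['id']}): HC rows carry no numeric MTWV "
                        f"(screened as < 25 dB), got {mtwv!r}"
                    )
        if errors:
            raise ValidationError("cohort validation failed:\n" + "\n".join(errors))
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def group_sizes(self) -> dict[str, int]:
        counts = self.frame["group"].value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUP_LEVELS}

    def subset(self, group: str) -> pd.DataFrame:
        return self.frame[self.frame["group"] == group]


def read_cohort(path: str | Path) -> CohortTable:
    """Read and validate a cohort CSV (columns id,group,age,education,hama,mtwv)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"cohort file {path} is empty") from exc
    return CohortTable(frame=df)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.frame.to_csv(path, index=False)
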