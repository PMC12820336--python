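"""DTI-ALPS: ROI placement, tensor-component extraction, and the index.

The ALPS (analysis along the perivascular space) index measures water
diffusivity along the x axis — perpendicular to both the projection
fibers (running along z) and the association fibers (running along y)
at the level of the lateral ventricles, where medullary veins and their
perivascular spaces run left-right.  Per hemisphere,

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

with a whole-brain mean index formed as the 4-component-over-4-component
ratio (not the average of the two hemispheric indices).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.linalg import polar

from .core_io import ValidationError
from .tensor_model import TensorMap, tensor_from_components

__all__ = [
    "ROISpec",
    "ALPSComponents",
    "ALPSResult",
    "ROI_NAMES",
    "default_roi_specs",
    "sphere_roi",
    "apply_affine_tensor",
    "extract_components",
    "compute_alps",
]

ROI_NAMES = ("L_proj", "L_assoc", "R_proj", "R_assoc")

#: ROI centers on the 182x218x182 1-mm FA template grid (0-based voxel indices)
TEMPLATE_GRID = (182, 218, 182)
TEMPLATE_ROI_CENTERS = {
    "L_proj": (116, 110, 99),
    "L_assoc": (128, 110, 99),
    "R_proj": (64, 110, 99),
    "R_assoc": (51, 110, 99),
}

DEFAULT_ROI_DIAMETER_MM = 5.0

#: minimum center-to-center spacing (voxels) kept between the projection and
#: association ROI of one hemisphere on scaled-down grids, so the two 5-mm
#: spheres never overlap
_MIN_PROJ_ASSOC_SPACING = 6


@dataclass(frozen=True)
class ROISpec:
    """A named spherical ROI: 0-based voxel center and diameter in mm."""

    name: str
    center: tuple[int, int, int]
    diameter_mm: float = DEFAULT_ROI_DIAMETER_MM

    def __post_init__(self) -> None:
        if self.name not in ROI_NAMES:
            raise ValidationError(f"ROI name {self.name!r} not in {ROI_NAMES}")
        if self.diameter_mm <= 0:
            raise ValidationError("ROI diameter must be positive")


def default_roi_centers(grid_shape: tuple[int, int, int]) -> dict[str, tuple[int, int, int]]:
    """ROI centers for a given grid.

    On the full 182x218x182 template grid the published template-space
    coordinates are used verbatim.  On any other (phantom) grid the
    centers are scaled from the template pattern: projection/association
    pairs sit symmetrically about the mid-sagittal plane with at least
    ``_MIN_PROJ_ASSOC_SPACING`` voxels between the pair so that the
    spheres stay disjoint.
    """
    if tuple(grid_shape) == TEMPLATE_GRID:
        return dict(TEMPLATE_ROI_CENTERS)
    nx, ny, nz = grid_shape
    mid = nx // 2
    # template offsets from midline (x=91): proj ~25-27, assoc ~37-40
    proj_off = max(4, round(26 / 182 * nx))
    assoc_off = max(proj_off + _MIN_PROJ_ASSOC_SPACING, round(38.5 / 182 * nx))
    # keep full 5-mm spheres inside the grid on small phantoms
    cap = min(nx - 3 - mid, mid - 2)
    assoc_off = min(assoc_off, cap)
    proj_off = min(proj_off, assoc_off - 5)
    if proj_off < 3:
        raise ValidationError(
            f"grid x-extent {nx} too small to host the four ALPS ROIs (need >= 24)"
        )
    yc = round(110 / 218 * ny)
    zc = round(99 / 182 * nz)
    return {
        "L_proj": (mid + proj_off, yc, zc),
        "L_assoc": (mid + assoc_off, yc, zc),
        "R_proj": (mid - proj_off, yc, zc),
        "R_assoc": (mid - assoc_off, yc, zc),
    }


def default_roi_specs(
    grid_shape: tuple[int, int, int], diameter_mm: float = DEFAULT_ROI_DIAMETER_MM
) -> dict[str, ROISpec]:
    return {
        name: ROISpec(name=name, center=tuple(c), diameter_mm=diameter_mm)
        for name, c in default_roi_centers(grid_shape).items()
    }


def sphere_roi(
    spec: ROISpec,
    grid_shape: tuple[int, int, int],
    voxel_size=(1.0, 1.0, 1.0),
) -> np.ndarray:
    """Boolean mask of voxels whose center lies within ``diameter/2`` of the ROI center.

    Distances are Euclidean in mm (voxel index offsets scaled by voxel
    size).  Raises if the sphere's bounding box leaves the grid.
    """
    vs = np.asarray(voxel_size, dtype=float)
    radius = spec.diameter_mm / 2.0
    center = np.asarray(spec.center, dtype=float)
    half = radius / vs  # in voxels, per axis
    if np.any(center - half < -0.5) or np.any(center + half > np.asarray(grid_shape) - 0.5):
        raise ValidationError(
            f"ROI {spec.name} at {spec.center} (radius {radius:g} mm) exceeds grid {grid_shape}"
        )
    lo = np.maximum(np.floor(center - half).astype(int), 0)
    hi = np.minimum(np.ceil(center + half).astype(int) + 1, grid_shape)
    mask = np.zeros(grid_shape, dtype=bool)
    xs, ys, zs = [np.arange(lo[a], hi[a]) for a in range(3)]
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    d2 = (
        ((gx - center[0]) * vs[0]) ** 2
        + ((gy - center[1]) * vs[1]) ** 2
        + ((gz - center[2]) * vs[2]) ** 2
    )
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = d2 <= radius**2
    return mask


def apply_affine_tensor(tensor: TensorMap, transform: np.ndarray) -> TensorMap:
    """Resample a tensor map through a rigid/affine voxel-space transform.

    ``transform`` maps source voxel coordinates to target voxel
    coordinates (homogeneous 4x4).  Components are resampled by trilinear
    interpolation; tensors are then reoriented as ``D' = R D R^T`` with
    ``R`` the rotation factor from the polar decomposition of the linear
    block (finite-strain reorientation).
    """
    t = np.asarray(transform, dtype=float)
    if t.shape != (4, 4):
        raise ValidationError(f"transform must be 4x4, got {t.shape}")
    if abs(np.linalg.det(t)) < 1e-12:
        raise ValidationError("transform is not invertible")
    inv = np.linalg.inv(t)
    rot, _stretch = polar(t[:3, :3])

    out = np.empty_like(tensor.data)
    for c in range(6):
        out[..., c] = ndimage.affine_transform(
            tensor.data[..., c], inv[:3, :3], offset=inv[:3, 3], order=1, prefilter=False
        )
    # reorient: D' = R D R^T
    mats = np.einsum("ij,...jk,lk->...il", rot, TensorMap(data=out).as_matrices(), rot)
    data = tensor_from_components(mats)
    mask = (
        ndimage.affine_transform(
            tensor.mask.astype(float), inv[:3, :3], offset=inv[:3, 3], order=0, prefilter=False
        )
        > 0.5
    )
    s0 = None
    if tensor.s0 is not None:
        s0 = ndimage.affine_transform(
            tensor.s0, inv[:3, :3], offset=inv[:3, 3], order=1, prefilter=False
        )
    return TensorMap(
        data=data, s0=s0, mask=mask, voxel_size=tensor.voxel_size, affine=tensor.affine
    )


@dataclass(frozen=True)
class ALPSComponents:
    """ROI-mean diffusivities entering the ALPS ratios (mm^2/s)."""

    Dxxproj_L: float
    Dxxassoc_L: float
    Dyyproj_L: float
    Dzzassoc_L: float
    Dxxproj_R: float
    Dxxassoc_R: float
    Dyyproj_R: float
    Dzzassoc_R: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class ALPSResult:
    """Left, right and mean DTI-ALPS indices (dimensionless)."""

    left: float
    right: float
    mean: float


def extract_components(
    tensor: TensorMap,
    rois: dict[str, ROISpec] | None = None,
    min_coverage: float = 0.9,
) -> ALPSComponents:
    """ROI-mean Dxx/Dyy/Dzz components for the four ALPS spheres.

    Each field is the arithmetic mean of the named tensor component over
    the ROI's voxels intersected with the fit mask.  ROIs with mask
    coverage below ``min_coverage`` raise a warning-grade flag via
    ``ValidationError`` only when the intersection is empty.
    """
    if rois is None:
        rois = default_roi_specs(tensor.grid_shape)
    means: dict[str, dict[str, float]] = {}
    import warnings

    for name in ROI_NAMES:
        spec = rois[name]
        roi = sphere_roi(spec, tensor.grid_shape, tensor.voxel_size)
        covered = roi & tensor.mask
        n_roi, n_cov = int(roi.sum()), int(covered.sum())
        if n_cov == 0:
            raise ValidationError(f"ROI {name} has empty intersection with the fit mask")
        if n_cov < min_coverage * n_roi:
            warnings.warn(
                f"ROI {name}: only {n_cov}/{n_roi} voxels inside the fit mask",
                stacklevel=2,
            )
        vox = tensor.data[covered]
        means[name] = {
            "Dxx": float(vox[:, 0].mean()),
            "Dyy": float(vox[:, 1].mean()),
            "Dzz": float(vox[:, 2].mean()),
        }
    return ALPSComponents(
        Dxxproj_L=means["L_proj"]["Dxx"],
        Dxxassoc_L=means["L_assoc"]["Dxx"],
        Dyyproj_L=means["L_proj"]["Dyy"],
        Dzzassoc_L=means["L_assoc"]["Dzz"],
        Dxxproj_R=means["R_proj"]["Dxx"],
        Dxxassoc_R=means["R_assoc"]["Dxx"],
        Dyyproj_R=means["R_proj"]["Dyy"],
        Dzzassoc_R=means["R_assoc"]["Dzz"],
    )


def compute_alps(c: ALPSComponents) -> ALPSResult:
    """The three ALPS ratios, composed exactly as ratios of component means.

    left  = mean(Dxxproj_L, Dxxassoc_L) / mean(Dyyproj_L, Dzzassoc_L)
    right = mean(Dxxproj_R, Dxxassoc_R) / mean(Dyyproj_R, Dzzassoc_R)
    mean  = 4-component numerator mean / 4-component denominator mean
    """
    den_l = (c.Dyyproj_L + c.Dzzassoc_L) / 2.0
    den_r = (c.Dyyproj_R + c.Dzzassoc_R) / 2.0
    den_m = (c.Dyyproj_L + c.Dzzassoc_L + c.Dyyproj_R + c.Dzzassoc_R) / 4.0
    for label, den in (("left", den_l), ("right", den_r), ("mean", den_m)):
        if den == 0:
            raise ValidationError(f"zero denominator in {label} ALPS ratio")
    left = (c.Dxxproj_L + c.Dxxassoc_L) / 2.0 / den_l
    right = (c.Dxxproj_R + c.Dxxassoc_R) / 2.0 / den_r
    mean = (c.Dxxproj_L + c.Dxxassoc_L + c.Dxxproj_R + c.Dxxassoc_R) / 4.0 / den_m
    return ALPSResult(left=left, right=right, mean=mean)
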