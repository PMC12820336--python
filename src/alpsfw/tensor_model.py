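"""Single diffusion-tensor fitting and FA/MD scalar maps.

The estimator is the classic log-linear weighted least squares: an
ordinary least-squares solve of ``log S = log S0 - b g^T D g`` followed
by one reweighting pass with weights equal to the squared predicted
signals (the first-order optimal weights for log-transformed Rician/
Gaussian noise at reasonable SNR).  On noiseless single-compartment data
the log model is exact, so recovery is at machine precision; this is the
module's oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import GradientTable, ScalarMap, ValidationError, Volume4D

__all__ = ["TensorMap", "fit_tensor_wls", "fa_md", "tensor_from_components", "COMPONENT_NAMES"]

#: component order used everywhere in this package
COMPONENT_NAMES = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")

#: smallest admissible eigenvalue (mm^2/s); keeps downstream ratios finite
EIGENVALUE_FLOOR = 1e-6

#: signals are clamped to this fraction of S0 before taking logs
SIGNAL_FLOOR_FRACTION = 1e-6


@dataclass
class TensorMap:
    """Per-voxel symmetric diffusion tensor (six unique components, mm^2/s).

    ``data`` has shape ``grid + (6,)`` in the order
    (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz).
    """

    data: np.ndarray
    s0: np.ndarray | None = None
    mask: np.ndarray | None = None
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[-1] != 6:
            raise ValidationError(f"TensorMap data must be (nx, ny, nz, 6), got {self.data.shape}")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def as_matrices(self) -> np.ndarray:
        """Return the tensors as a ``grid + (3, 3)`` symmetric-matrix array."""
        d = self.data
        m = np.empty(d.shape[:-1] + (3, 3), dtype=float)
        m[..., 0, 0] = d[..., 0]
        m[..., 1, 1] = d[..., 1]
        m[..., 2, 2] = d[..., 2]
        m[..., 0, 1] = m[..., 1, 0] = d[..., 3]
        m[..., 0, 2] = m[..., 2, 0] = d[..., 4]
        m[..., 1, 2] = m[..., 2, 1] = d[..., 5]
        return m

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues, ascending, shape ``grid + (3,)``."""
        return np.linalg.eigvalsh(self.as_matrices())


def tensor_from_components(matrices: np.ndarray) -> np.ndarray:
    """Collapse ``(..., 3, 3)`` symmetric matrices to the 6-component order."""
    m = np.asarray(matrices)
    return np.stack(
        [m[..., 0, 0], m[..., 1, 1], m[..., 2, 2], m[..., 0, 1], m[..., 0, 2], m[..., 1, 2]],
        axis=-1,
    )


def _otsu_threshold(values: np.ndarray) -> float:
    """Otsu's between-class-variance threshold on a 1-D sample."""
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(values))


def default_mask(dwi: Volume4D, gtab: GradientTable) -> np.ndarray:
    """Foreground mask: mean b0 above an Otsu-derived threshold.

    Falls back to an all-true mask when the b0 image is (near-)uniform,
    as on noiseless phantoms.
    """
    b0 = dwi.data[..., gtab.b0_mask].mean(axis=-1)
    if np.ptp(b0) <= 1e-12 * max(b0.max(), 1.0):
        return np.ones(b0.shape, dtype=bool)
    try:
        thr = _otsu_threshold(b0.ravel())
    except Exception:
        return np.ones(b0.shape, dtype=bool)
    return b0 > thr


def _clip_eigenvalues(comp: np.ndarray, lo: float, hi: float | None = None) -> np.ndarray:
    """Clip eigenvalues of 6-component tensors ``(n, 6)`` into [lo, hi].

    Tensors already inside the bounds are returned untouched (bitwise),
    preserving exactness on clean data.
    """
    # Gershgorin screen: diag +- sum|offdiag| brackets the spectrum, so
    # voxels passing it cannot violate the bounds and skip the eigh.
    radius = np.abs(comp[..., 3]) + np.abs(comp[..., 4]) + np.abs(comp[..., 5])
    diag_min = comp[..., :3].min(axis=-1)
    diag_max = comp[..., :3].max(axis=-1)
    suspect = diag_min - radius < lo
    if hi is not None:
        suspect |= diag_max + radius > hi
    if not np.any(suspect):
        return comp
    sub = comp[suspect]
    m = np.empty(sub.shape[:-1] + (3, 3))
    m[..., 0, 0] = sub[..., 0]
    m[..., 1, 1] = sub[..., 1]
    m[..., 2, 2] = sub[..., 2]
    m[..., 0, 1] = m[..., 1, 0] = sub[..., 3]
    m[..., 0, 2] = m[..., 2, 0] = sub[..., 4]
    m[..., 1, 2] = m[..., 2, 1] = sub[..., 5]
    w, v = np.linalg.eigh(m)
    needs = (w[..., 0] < lo) if hi is None else ((w[..., 0] < lo) | (w[..., -1] > hi))
    if not np.any(needs):
        return comp
    rebuilt_all = sub.copy()
    wc = np.clip(w[needs], lo, hi)
    vn = v[needs]
    rebuilt = np.einsum("...ij,...j,...kj->...ik", vn, wc, vn)
    rebuilt_all[needs] = tensor_from_components(rebuilt)
    out = comp.copy()
    out[suspect] = rebuilt_all
    return out


def fit_tensor_wls(
    dwi: Volume4D,
    gtab: GradientTable,
    mask: np.ndarray | None = None,
) -> TensorMap:
    """Fit the single-tensor model per voxel (log-linear OLS + one WLS pass).

    Parameters
    ----------
    dwi : Volume4D
        4-D signal volume paired with ``gtab``.
    gtab : GradientTable
        Acquisition table; needs >= 6 non-collinear b>0 directions and a b0.
    mask : bool array, optional
        Voxels to fit.  Default: mean-b0 Otsu foreground.

    Returns
    -------
    TensorMap with eigenvalues clipped to ``EIGENVALUE_FLOOR`` and the
    estimated S0 map.
    """
    if dwi.data.shape[3] != len(gtab):
        raise ValidationError(
            f"volume has {dwi.data.shape[3]} gradients but table has {len(gtab)}"
        )
    # design: log S = [1, -q] @ (log S0, D)
    design = np.column_stack([np.ones(len(gtab)), -gtab.design_quadratic()])
    if np.linalg.matrix_rank(design) < 7:
        raise ValidationError(
            "rank-deficient gradient design: fewer than 6 independent non-collinear "
            "b>0 directions plus a b0 are required for tensor fitting"
        )
    if mask is None:
        mask = default_mask(dwi, gtab)
    mask = np.asarray(mask, dtype=bool)

    grid = dwi.grid_shape
    signals = dwi.data.reshape(-1, len(gtab))[mask.ravel()].astype(float)  # (v, k)
    s0_ref = signals[:, gtab.b0_mask].mean(axis=1)
    floor = SIGNAL_FLOOR_FRACTION * np.maximum(s0_ref, np.finfo(float).tiny)
    log_s = np.log(np.maximum(signals, floor[:, None]))

    # OLS pass
    beta, *_ = np.linalg.lstsq(design, log_s.T, rcond=None)  # (7, v)
    # one WLS reweighting pass: weights = predicted squared signals
    pred_log = design @ beta  # (k, v)
    w = np.exp(2.0 * pred_log).T  # (v, k)
    xtwx = np.einsum("ki,vk,kj->vij", design, w, design)
    xtwy = np.einsum("ki,vk,vk->vi", design, w, log_s)
    beta_w = np.linalg.solve(xtwx, xtwy[..., None])[..., 0]  # (v, 7)

    comp = _clip_eigenvalues(beta_w[:, 1:], EIGENVALUE_FLOOR)
    s0 = np.exp(beta_w[:, 0])

    data = np.zeros(grid + (6,))
    data.reshape(-1, 6)[mask.ravel()] = comp
    s0_map = np.zeros(grid)
    s0_map.ravel()[mask.ravel()] = s0
    return TensorMap(
        data=data, s0=s0_map, mask=mask, voxel_size=dwi.voxel_size, affine=dwi.affine
    )


def fa_md(tensor: TensorMap) -> tuple[ScalarMap, ScalarMap]:
    """Fractional anisotropy and mean diffusivity of a tensor map.

    MD = (l1+l2+l3)/3;  FA = sqrt(3/2) * ||l - MD|| / ||l||, which lies in
    [0, 1].  An all-zero tensor gets FA = 0 by convention.
    """
    evals = tensor.eigenvalues()
    md = evals.mean(axis=-1)
    dev = evals - md[..., None]
    num = np.sqrt((dev**2).sum(axis=-1))
    den = np.sqrt((evals**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    fa = np.clip(fa, 0.0, 1.0)
    fa[~tensor.mask] = 0.0
    md = np.where(tensor.mask, md, 0.0)
    fa_map = ScalarMap(data=fa, kind="FA", voxel_size=tensor.voxel_size, affine=tensor.affine)
    md_map = ScalarMap(data=np.maximum(md, 0.0), kind="MD", voxel_size=tensor.voxel_size, affine=tensor.affine)
    return fa_map, md_map
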