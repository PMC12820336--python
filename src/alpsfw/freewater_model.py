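"""Regularized bi-tensor (free-water elimination) model fitting.

Per voxel the signal is modeled as a mixture of a hindered tissue
compartment and an isotropic free-water compartment:

    S(b, g) / S0 = (1 - f) * exp(-b g^T D g) + f * exp(-b * d_csf)

with f the free-water volume fraction and d_csf fixed at the diffusivity
of free water at body temperature.  With a single nonzero shell the
per-voxel problem is degenerate (a family of (f, D) pairs fits equally
well), which is why the default fit couples neighboring voxels through a
spatial smoothness penalty on f and starts from a mean-diffusivity-based
initialization; two-shell data makes the per-voxel problem well posed
and is used for sharp parameter-recovery tests.

The optimizer is projected gradient descent on the total objective

    sum_v sum_k (m_vk - A_vk)^2  +  lambda_spatial * sum ||grad f||^2

with analytic gradients, a backtracking step size (so the objective is
non-increasing by construction), and a projection that clamps f to
[0, 1] and the tissue eigenvalues to [floor, d_csf] after every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import GradientTable, ScalarMap, ValidationError, Volume4D
from .tensor_model import (
    EIGENVALUE_FLOOR,
    TensorMap,
    _clip_eigenvalues,
    default_mask,
    fa_md,
    fit_tensor_wls,
)

__all__ = ["FWFit", "FWOptions", "fit_bitensor", "DEFAULT_D_CSF"]

#: free-water diffusivity at body temperature, mm^2/s
DEFAULT_D_CSF = 3.0e-3

#: mean diffusivity of typical healthy white matter, used to initialize f
MD_TISSUE_PRIOR = 0.6e-3


@dataclass(frozen=True)
class FWOptions:
    """Tunable knobs of the bi-tensor fit."""

    lambda_spatial: float = 0.1  # weight of ||grad f||^2 on the normalized signal scale
    max_iter: int = 200
    tol: float = 1e-6  # relative total-cost change declaring convergence
    d_csf: float = DEFAULT_D_CSF
    step0: float = 0.02  # initial gradient step (dimensionless parameter scale)

    def __post_init__(self) -> None:
        if self.lambda_spatial < 0:
            raise ValidationError("lambda_spatial must be >= 0")
        if self.d_csf <= 0:
            raise ValidationError("d_csf must be positive")


@dataclass
class FWFit:
    """Result of the bi-tensor fit."""

    f: ScalarMap
    tissue: TensorMap
    converged: np.ndarray
    degenerate: np.ndarray
    cost: np.ndarray  # per-voxel final data cost (normalized signal units)
    n_iter: int
    cost_history: list = field(default_factory=list)  # total objective per iteration


def _neighbor_pairs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (into the masked-voxel vector) of 6-connected neighbors."""
    idx = -np.ones(mask.shape, dtype=np.int64)
    idx[mask] = np.arange(int(mask.sum()))
    pairs_a, pairs_b = [], []
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        a = idx[tuple(sl_a)]
        b = idx[tuple(sl_b)]
        ok = (a >= 0) & (b >= 0)
        pairs_a.append(a[ok])
        pairs_b.append(b[ok])
    return np.concatenate(pairs_a), np.concatenate(pairs_b)


def fit_bitensor(
    dwi: Volume4D,
    gtab: GradientTable,
    mask: np.ndarray | None = None,
    opts: FWOptions | None = None,
) -> FWFit:
    """Fit the regularized bi-tensor model to a DWI volume.

    Returns an :class:`FWFit` whose ``f`` map lies in [0, 1] and whose
    tissue tensor has eigenvalues in ``[EIGENVALUE_FLOOR, d_csf]``.
    Non-converged voxels are flagged, never raised; voxels whose tissue
    compartment collapses onto free water (MD within 5% of d_csf) are
    flagged degenerate since f is unidentifiable there.
    """
    opts = opts or FWOptions()
    if mask is None:
        mask = default_mask(dwi, gtab)
    mask = np.asarray(mask, dtype=bool)
    d_csf = opts.d_csf
    n_vox = int(mask.sum())
    if n_vox == 0:
        raise ValidationError("empty fit mask")

    # --- normalized attenuations -------------------------------------------
    signals = dwi.data.reshape(-1, len(gtab))[mask.ravel()].astype(float)
    s0 = signals[:, gtab.b0_mask].mean(axis=1)
    s0 = np.maximum(s0, np.finfo(float).tiny)
    atten = signals / s0[:, None]  # (v, k)

    q = gtab.design_quadratic() / np.where(gtab.bvals[:, None] == 0, 1.0, gtab.bvals[:, None])
    # q rows: (gx^2, gy^2, gz^2, 2gxgy, 2gxgz, 2gygz); exponent = -b*d_csf*(q . dt)
    bscale = gtab.bvals * d_csf  # (k,)
    e_csf = np.exp(-bscale)  # (k,)

    # --- initialization -----------------------------------------------------
    single = fit_tensor_wls(dwi, gtab, mask=mask)
    _, md_map = fa_md(single)
    md = md_map.data[mask]
    f = np.clip((md - MD_TISSUE_PRIOR) / (d_csf - MD_TISSUE_PRIOR), 0.05, 0.95)
    # tissue init: strip the estimated free-water signal, then log-linear solve
    at_t = np.clip((atten - f[:, None] * e_csf[None, :]) / (1.0 - f)[:, None], 1e-6, None)
    design = np.column_stack([np.ones(len(gtab)), -gtab.design_quadratic()])
    beta, *_ = np.linalg.lstsq(design, np.log(at_t).T, rcond=None)
    dt = beta[1:].T / d_csf  # dimensionless tissue tensor, (v, 6)

    lo, hi = EIGENVALUE_FLOOR / d_csf, 1.0
    dt = _clip_eigenvalues(dt, lo, hi)

    lam = opts.lambda_spatial
    if lam > 0:
        nb_a, nb_b = _neighbor_pairs(mask)

    def total_cost(fv: np.ndarray, dtv: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        expo = np.exp(-(dtv @ q.T) * bscale[None, :])  # (v, k) tissue attenuation
        m = (1.0 - fv)[:, None] * expo + fv[:, None] * e_csf[None, :]
        r = m - atten
        data_cost = (r**2).sum(axis=1)
        c = float(data_cost.sum())
        if lam > 0:
            diff = fv[nb_a] - fv[nb_b]
            c += lam * float((diff**2).sum())
        return c, r, expo

    def gradients(fv, dtv, r, expo):
        g_f = 2.0 * ((e_csf[None, :] - expo) * r).sum(axis=1)
        # d m / d dt_j = -(1-f) * b*d_csf * q_j * expo
        w = -2.0 * (1.0 - fv)[:, None] * r * expo * bscale[None, :]
        g_dt = w @ q
        if lam > 0:
            diff = fv[nb_a] - fv[nb_b]
            np.add.at(g_f, nb_a, 2.0 * lam * diff)
            np.add.at(g_f, nb_b, -2.0 * lam * diff)
        return g_f, g_dt

    cost, r, expo = total_cost(f, dt)
    prev_data_cost = (r**2).sum(axis=1)  # data cost one accepted step ago
    history = [cost]
    step = opts.step0
    n_done = 0
    for it in range(opts.max_iter):
        g_f, g_dt = gradients(f, dt, r, expo)
        accepted = False
        for _ in range(30):
            f_try = np.clip(f - step * g_f, 0.0, 1.0)
            dt_try = _clip_eigenvalues(dt - step * g_dt, lo, hi)
            cost_try, r_try, expo_try = total_cost(f_try, dt_try)
            if cost_try <= cost:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        rel_change = (cost - cost_try) / max(cost, np.finfo(float).tiny)
        prev_data_cost = (r**2).sum(axis=1)
        f, dt, r, expo = f_try, dt_try, r_try, expo_try
        cost = cost_try
        history.append(cost)
        step *= 1.2
        n_done = it + 1
        if rel_change < opts.tol:
            break

    data_cost = (r**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        voxel_rel = np.abs(prev_data_cost - data_cost) / np.maximum(prev_data_cost, 1e-30)
    converged_v = voxel_rel < max(opts.tol * 10, 1e-5)
    md_tissue = dt[:, :3].mean(axis=1)  # scaled by d_csf
    degenerate_v = md_tissue > 0.95

    grid = dwi.grid_shape
    f_map = np.zeros(grid)
    f_map[mask] = f
    tissue = np.zeros(grid + (6,))
    tissue[mask] = dt * d_csf
    conv = np.zeros(grid, dtype=bool)
    conv[mask] = converged_v
    degen = np.zeros(grid, dtype=bool)
    degen[mask] = degenerate_v
    cost_map = np.zeros(grid)
    cost_map[mask] = data_cost
    return FWFit(
        f=ScalarMap(data=f_map, kind="FW", voxel_size=dwi.voxel_size, affine=dwi.affine),
        tissue=TensorMap(
            data=tissue, mask=mask, voxel_size=dwi.voxel_size, affine=dwi.affine
        ),
        converged=conv,
        degenerate=degen,
        cost=cost_map,
        n_iter=n_done,
        cost_history=history,
    )
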