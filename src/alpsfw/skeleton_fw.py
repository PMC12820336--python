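"""Group mean-FA skeleton and skeleton-projected free water.

A simplified tract-skeleton dialect: candidate voxels are those with
group mean FA at or above a threshold (default 0.2); a candidate is kept
on the skeleton iff its mean FA is a local maximum along the local FA
gradient direction (the direction perpendicular to the tract sheet),
sampled at the nearest-neighbor offsets.  Projection then walks each
subject's FA along that stored direction within a capped radius and
copies the free-water value from the subject's FA maximum — the
classic "project onto the tract center" step.

Plateaus (zero FA gradient or exact ties) are kept and flagged
degenerate rather than broken arbitrarily.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import ScalarMap, ValidationError

__all__ = ["Skeleton", "mean_fa", "make_skeleton", "project_fw", "skeleton_mean"]

DEFAULT_FA_THRESHOLD = 0.2
DEFAULT_SEARCH_RADIUS = 3


def _check_same_grid(maps: list[ScalarMap]) -> tuple[int, int, int]:
    shapes = {m.data.shape for m in maps}
    if len(shapes) != 1:
        raise ValidationError(f"scalar maps live on different grids: {sorted(shapes)}")
    return maps[0].data.shape


def mean_fa(fa_maps: list[ScalarMap], mask: np.ndarray | None = None) -> ScalarMap:
    """Voxelwise arithmetic mean of per-subject FA maps."""
    if not fa_maps:
        raise ValidationError("no FA maps given")
    shape = _check_same_grid(fa_maps)
    acc = np.zeros(shape)
    for m in fa_maps:
        acc += m.data
    acc /= len(fa_maps)
    if mask is not None:
        acc = np.where(mask, acc, 0.0)
    return ScalarMap(
        data=acc, kind="meanFA", voxel_size=fa_maps[0].voxel_size, affine=fa_maps[0].affine
    )


@dataclass
class Skeleton:
    """Binary skeleton with per-voxel search directions.

    ``directions`` stores, at skeleton voxels, the unit local FA-gradient
    direction along which the perpendicular-maximum rule was evaluated
    (zero where degenerate); ``degenerate`` marks plateau voxels kept by
    the tie rule.
    """

    mask: np.ndarray
    directions: np.ndarray  # shape grid + (3,)
    threshold: float
    degenerate: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        norms = np.linalg.norm(self.directions, axis=-1)
        active = self.mask & ~self.degenerate
        if np.any(np.abs(norms[active] - 1.0) > 1e-6):
            raise ValidationError("stored search directions must be unit-norm")


def _neighbor_value(data: np.ndarray, offsets: np.ndarray, fill: float = -np.inf) -> np.ndarray:
    """Value of each voxel's neighbor at a per-voxel integer offset."""
    grid = np.indices(data.shape).reshape(3, -1).T
    nb = grid + offsets.reshape(-1, 3)
    inside = np.all((nb >= 0) & (nb < np.asarray(data.shape)), axis=1)
    out = np.full(data.size, fill)
    ok = nb[inside]
    out[inside] = data[ok[:, 0], ok[:, 1], ok[:, 2]]
    return out.reshape(data.shape)


def make_skeleton(mean_fa_map: ScalarMap, threshold: float = DEFAULT_FA_THRESHOLD) -> Skeleton:
    """Extract the skeleton from a mean FA map by the perpendicular-maximum rule.

    A candidate voxel (mean FA >= threshold) survives iff its value is >=
    its two neighbors along the rounded local FA-gradient direction.
    Voxels with a vanishing gradient are kept and flagged degenerate.
    """
    fa = np.asarray(mean_fa_map.data, dtype=float)
    candidates = fa >= threshold
    if not np.any(candidates):
        raise ValidationError(f"no voxels at or above FA threshold {threshold:g}")

    grads = np.stack(np.gradient(fa), axis=-1)  # grid + (3,)
    norms = np.linalg.norm(grads, axis=-1)
    degenerate = norms < 1e-12
    unit = np.zeros_like(grads)
    np.divide(grads, norms[..., None], out=unit, where=~degenerate[..., None])

    offsets = np.rint(unit).astype(int)  # nearest-neighbor sampling of the direction
    zero_off = np.all(offsets == 0, axis=-1)
    degenerate = degenerate | zero_off

    fwd = _neighbor_value(fa, offsets)
    bwd = _neighbor_value(fa, -offsets)
    local_max = (fa >= fwd) & (fa >= bwd)

    keep = candidates & (local_max | degenerate)
    directions = np.where(keep[..., None], unit, 0.0)
    return Skeleton(
        mask=keep, directions=directions, threshold=threshold, degenerate=degenerate & keep
    )


def project_fw(
    fw: ScalarMap,
    fa: ScalarMap,
    skeleton: Skeleton,
    search_radius: int = DEFAULT_SEARCH_RADIUS,
) -> ScalarMap:
    """Project a subject's FW map onto the skeleton.

    At each skeleton voxel the subject's FA is sampled at integer steps
    t = -radius..radius along the stored search direction (rounded to the
    nearest-neighbor offset); the FW value at the FA-argmax is copied.
    Ties prefer the smallest |t| (in-place sampling wins).
    """
    _check_same_grid([fw, fa])
    if fw.data.shape != skeleton.mask.shape:
        raise ValidationError("skeleton and subject maps live on different grids")
    out = np.zeros_like(np.asarray(fw.data, dtype=float))
    idx = np.argwhere(skeleton.mask)
    offsets = np.rint(skeleton.directions[skeleton.mask]).astype(int)
    shape = np.asarray(fw.data.shape)
    fa_d = np.asarray(fa.data, dtype=float)
    fw_d = np.asarray(fw.data, dtype=float)

    best_fa = np.full(len(idx), -np.inf)
    best_fw = np.zeros(len(idx))
    # visit t in order of increasing |t| so ties keep the closest sample
    for t in sorted(range(-search_radius, search_radius + 1), key=abs):
        pos = idx + t * offsets
        inside = np.all((pos >= 0) & (pos < shape), axis=1)
        vals = np.full(len(idx), -np.inf)
        p = pos[inside]
        vals[inside] = fa_d[p[:, 0], p[:, 1], p[:, 2]]
        better = vals > best_fa
        best_fa[better] = vals[better]
        sel = pos[better]
        best_fw[better] = fw_d[sel[:, 0], sel[:, 1], sel[:, 2]]
    out[skeleton.mask] = best_fw
    return ScalarMap(data=out, kind="FW", voxel_size=fw.voxel_size, affine=fw.affine)


def skeleton_mean(fw_skel: ScalarMap, skeleton: Skeleton) -> float:
    """Subject-level scalar: arithmetic mean FW over the skeleton voxels."""
    if not np.any(skeleton.mask):
        raise ValidationError("empty skeleton")
    return float(np.asarray(fw_skel.data)[skeleton.mask].mean())
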