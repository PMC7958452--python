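"""Post-registration intensity pipeline: z-score, background removal, clipping.

The pipeline assumes volumes are already linearly registered to a common
template (registration is an external precondition).  It then applies, in
order:

1. **z-score normalization** over *all* voxels (background included), so each
   volume has mean 0 and SD 1;
2. **background removal** by an explicit-stack depth-first search seeded at
   the eight corner voxels, expanding through voxels below a shell threshold
   until the bright scalp signal blocks it; visited voxels are set to the
   background fill value.  Interior voxels that are dim but enclosed by the
   scalp shell are never reached and stay untouched;
3. **outlier clipping** of every voxel to ``[clip_low, clip_high]``.

The background fill equals the clip floor, so the composition is stable and
re-clipping is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .types import DegenerateInputError, ValidationError, Volume


@dataclass
class PreprocessConfig:
    """Knobs of the intensity pipeline.

    ``shell_threshold`` is in z-units: a voxel at or above it blocks the
    flood search.  The default 0.5 sits far below the scalp shell (the
    brightest structure, typically > 2 z-units) and above typical background.
    ``connectivity`` is the DFS neighborhood: 6 (faces; conservative against
    leaks through diagonal gaps) or 26 (faces+edges+corners).
    """

    clip_low: float = -1.0
    clip_high: float = 2.5
    background_value: float = -1.0
    shell_threshold: float = 0.5
    connectivity: int = 6

    def validate(self) -> None:
        if not self.clip_low < self.clip_high:
            raise ValidationError("clip_low must be < clip_high")
        if self.background_value < self.clip_low:
            raise ValidationError(
                "background_value must be >= clip_low so clipping never alters it"
            )
        if self.connectivity not in (6, 26):
            raise ValidationError("connectivity must be 6 or 26")


def zscore_normalize(vol: Volume) -> Volume:
    """Standardize to mean 0, SD 1 over all voxels (population SD)."""
    data = vol.data.astype(np.float64)
    sd = float(data.std())
    if sd == 0.0:
        raise DegenerateInputError("constant volume: standard deviation is zero")
    out = (data - data.mean()) / sd
    return vol.with_data(out, provenance="normalized")


def _neighbor_offsets(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
            dtype=np.int64,
        )
    offs = [
        [i, j, k]
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    return np.array(offs, dtype=np.int64)


@njit(cache=True)
def _dfs_background(data, threshold, offsets):  # pragma: no cover - numba
    nx, ny, nz = data.shape
    visited = np.zeros((nx, ny, nz), dtype=np.uint8)
    # explicit stack: recursion on a 96^3 grid would overflow the call stack
    stack = np.empty((nx * ny * nz, 3), dtype=np.int64)
    top = 0
    for ci in (0, nx - 1):
        for cj in (0, ny - 1):
            for ck in (0, nz - 1):
                if visited[ci, cj, ck] == 0 and data[ci, cj, ck] < threshold:
                    visited[ci, cj, ck] = 1
                    stack[top, 0] = ci
                    stack[top, 1] = cj
                    stack[top, 2] = ck
                    top += 1
    while top > 0:
        top -= 1
        i = stack[top, 0]
        j = stack[top, 1]
        k = stack[top, 2]
        for o in range(offsets.shape[0]):
            ni = i + offsets[o, 0]
            nj = j + offsets[o, 1]
            nk = k + offsets[o, 2]
            if 0 <= ni < nx and 0 <= nj < ny and 0 <= nk < nz:
                if visited[ni, nj, nk] == 0 and data[ni, nj, nk] < threshold:
                    visited[ni, nj, nk] = 1
                    stack[top, 0] = ni
                    stack[top, 1] = nj
                    stack[top, 2] = nk
                    top += 1
    return visited


def remove_background(
    vol: Volume, cfg: PreprocessConfig | None = None
) -> tuple[Volume, Volume]:
    """Flood the exterior from the corners and fill it with the background value.

    Returns ``(volume, mask)`` where ``mask`` is 1 on background voxels.
    Raises if any corner voxel is at or above the shell threshold, which
    signals that the scalp shell touches the volume boundary and the search
    cannot be seeded.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    data = vol.data.astype(np.float64)
    nx, ny, nz = data.shape
    corners = [
        (i, j, k) for i in (0, nx - 1) for j in (0, ny - 1) for k in (0, nz - 1)
    ]
    blocked = [c for c in corners if data[c] >= cfg.shell_threshold]
    if blocked:
        raise ValidationError(
            f"corner voxel {blocked[0]} is >= shell_threshold "
            f"({cfg.shell_threshold}): shell touches the volume boundary, "
            "DFS cannot be seeded"
        )
    visited = _dfs_background(
        data, float(cfg.shell_threshold), _neighbor_offsets(cfg.connectivity)
    )
    mask = visited.astype(bool)
    out = data.copy()
    out[mask] = cfg.background_value
    return vol.with_data(out), Volume(mask, vol.affine, vol.provenance)


def clip_outliers(vol: Volume, cfg: PreprocessConfig | None = None) -> Volume:
    """Clamp every voxel into ``[clip_low, clip_high]`` (closed interval)."""
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    return vol.with_data(np.clip(vol.data, cfg.clip_low, cfg.clip_high))


def preprocess_volume(
    vol: Volume, cfg: PreprocessConfig | None = None, *, return_mask: bool = False
):
    """z-score -> background removal -> clipping, in that order.

    With ``return_mask=True`` also returns the background mask Volume, which
    downstream stages use as (the complement of) the brain mask.
    """
    cfg = cfg or PreprocessConfig()
    z = zscore_normalize(vol)
    nobg, mask = remove_background(z, cfg)
    out = clip_outliers(nobg, cfg)
    out.provenance = "normalized"
    if return_mask:
        return out, mask
    return out
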