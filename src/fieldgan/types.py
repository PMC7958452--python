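"""Core in-memory containers shared across the pipeline.

A :class:`Volume` is a 3D scalar intensity grid in voxel order (x, y, z),
0-based indexing, with a NIfTI-style affine mapping voxel indices to world
coordinates.  A :class:`PhantomPair` holds the two same-subject renderings of
one anatomy at the two simulated field strengths together with the exact
voxelwise difference between them (the ground-truth transformation mask).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Integer codes for the two diagnostic classes.  NC (normal cognition /
#: control) is 0, AD (disease) is 1, matching the manifest label strings.
LABEL_CONTROL = 0
LABEL_DISEASE = 1
LABEL_NAMES = {LABEL_CONTROL: "NC", LABEL_DISEASE: "AD"}
LABEL_CODES = {v: k for k, v in LABEL_NAMES.items()}


class FieldganError(Exception):
    """Base class for all package errors."""


class ValidationError(FieldganError):
    """A domain object violates one of its invariants."""


class DegenerateInputError(FieldganError):
    """Input is structurally valid but degenerate (e.g. constant volume)."""


class ShapeError(FieldganError):
    """An array has a shape incompatible with the requested operation."""


def _default_affine() -> np.ndarray:
    return np.eye(4)


@dataclass
class Volume:
    """A 3D scalar field with spatial metadata.

    Parameters
    ----------
    data : ndarray, shape (X, Y, Z)
        Voxel intensities.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform (NIfTI convention).
    provenance : str
        One of ``raw``, ``normalized``, ``generated`` — which pipeline stage
        produced the volume.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=_default_affine)
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeError(f"Volume data must be 3D, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ShapeError(f"affine must be 4x4, got {self.affine.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Voxel edge lengths derived from the affine."""
        return tuple(np.linalg.norm(self.affine[:3, i]) for i in range(3))

    def with_data(self, data: np.ndarray, provenance: str | None = None) -> "Volume":
        """Copy of this volume with new voxel data, same affine."""
        return replace(
            self, data=data, provenance=self.provenance if provenance is None else provenance
        )


@dataclass
class PhantomPair:
    """A same-subject pair of renderings at two quality levels.

    ``true_mask`` equals ``high - low`` voxelwise, so ``low + true_mask``
    reconstructs ``high`` exactly — the ground truth a residual generator is
    asked to recover.
    """

    subject_id: str
    low: Volume
    high: Volume
    label: int
    true_mask: Volume

    def __post_init__(self) -> None:
        if not (self.low.shape == self.high.shape == self.true_mask.shape):
            raise ValidationError(
                "low, high and true_mask must share identical grid dimensions"
            )
        if self.label not in LABEL_NAMES:
            raise ValidationError(f"label must be one of {sorted(LABEL_NAMES)}")

    @property
    def label_name(self) -> str:
        return LABEL_NAMES[self.label]


@dataclass
class Patch:
    """A cubic subvolume plus its origin in the parent volume."""

    data: np.ndarray
    origin: tuple[int, int, int]
    subject_id: str | None = None
    label: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeError("Patch data must be 3D")
        s = self.data.shape[0]
        if self.data.shape != (s, s, s):
            raise ShapeError(f"Patch must be cubic, got {self.data.shape}")

    @property
    def side(self) -> int:
        return self.data.shape[0]
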