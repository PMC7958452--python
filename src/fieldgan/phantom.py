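"""Synthetic paired-field-strength brain phantoms with known ground truth.

Real training data for field-strength translation consists of same-subject
T1 scan pairs acquired at 1.5 T and 3 T.  Such data cannot ship with a
package, so this module builds an analytic stand-in: concentric-ellipsoid
"head" phantoms (bright scalp shell, cortical gray shell, white-matter core,
a dark centered spherical ventricle) rendered twice —

* the **low-field** rendering adds strong Gaussian noise to the anatomy;
* the **high-field** rendering adds weak noise and a contrast gain applied
  around the interior mean, so the voxelwise difference between the two
  renderings (the true transformation mask) is smooth structure plus noise,
  not pure noise.

Disease status is encoded morphologically: "disease" subjects carry an
enlarged ventricle, so a classifier must learn a size/shape feature, and the
noise-free anatomies are perfectly separable by ventricle voxel count.
Because the pair is constructed as ``true_mask = high - low`` exactly, every
downstream stage (generator recovery, quality ordering, classification) can
be tested against analytic ground truth.

Geometry is deliberately simple (Non-goal: MRI physics).  Noise is injected
only inside the head so the exterior background stays exactly at
``background_level`` — background removal then behaves deterministically,
mimicking registered scans whose air background is near-constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (

    LABEL_CONTROL,
    LABEL_DISEASE,
    LABEL_NAMES,
    PhantomPair,
    ValidationError,
    Volume,
)

#: Outer-shell semi-axes as fractions of the grid size (x, y, z).
_SHELL_AXES = (0.45, 0.42, 0.40)
#: Scale of the gray-matter ellipsoid relative to the outer shell.
_GRAY_SCALE = 0.92
#: Scale of the white-matter ellipsoid relative to the outer shell.
_WHITE_SCALE = 0.78
#: Maximum per-axis jitter of ellipsoid semi-axes (fraction).
_JITTER = 0.05


@dataclass
class PhantomSpec:
    """Parameters of the phantom cohort generator.

    Defaults define the package's study conditions: a 96-voxel grid on a
    [0, 1] raw intensity scale, a bright scalp shell at 1.0, low-field noise
    SD 0.15 versus high-field 0.02, and a 1.1 contrast gain on the
    high-field rendering.  The noise/gain combination is chosen so the
    high-field rendering has the higher in-brain SNR: with structural
    in-head SD sigma_s ~ 0.23, the ordering requires
    (gain^2 - 1) * sigma_s^2 < sigma_low^2 - sigma_high^2, satisfied here
    with a twofold margin.  Ventricle radii 6 (control) versus 10 (disease)
    voxels give a clear but spatially local class signal.
    """

    grid_size: int = 96
    background_level: float = 0.0
    shell_level: float = 1.0
    tissue_levels: dict[str, float] = field(
        default_factory=lambda: {"gray": 0.40, "white": 0.55, "ventricle": 0.12}
    )
    ventricle_radius_by_class: dict[str, float] = field(
        default_factory=lambda: {"control": 6.0, "disease": 10.0}
    )
    noise_sigma_low: float = 0.15
    noise_sigma_high: float = 0.02
    contrast_gain_high: float = 1.1
    seed: int = 0

    def validate(self) -> None:
        if self.grid_size < 48:
            raise ValidationError(
                f"grid_size must be >= 48 to contain a 47^3 patch, got {self.grid_size}"
            )
        if not self.noise_sigma_low > self.noise_sigma_high:
            raise ValidationError(
                "noise_sigma_low must exceed noise_sigma_high "
                f"({self.noise_sigma_low} vs {self.noise_sigma_high})"
            )
        if self.noise_sigma_high < 0:
            raise ValidationError("noise_sigma_high must be >= 0")
        rc = self.ventricle_radius_by_class.get("control")
        rd = self.ventricle_radius_by_class.get("disease")
        if rc is None or rd is None or not rd > rc:
            raise ValidationError(
                "ventricle_radius_by_class must satisfy disease > control, got "
                f"{self.ventricle_radius_by_class}"
            )
        levels = list(self.tissue_levels.values()) + [self.background_level]
        if not all(self.shell_level > v for v in levels):
            raise ValidationError(
                "shell_level must strictly exceed all tissue levels and background"
            )


_CLASS_ALIASES = {
    "control": "control", "disease": "disease",
    LABEL_NAMES[LABEL_CONTROL]: "control", LABEL_NAMES[LABEL_DISEASE]: "disease",
    LABEL_CONTROL: "control", LABEL_DISEASE: "disease",
}


def _class_key(label) -> str:
    """Map any accepted label form (0/1, NC/AD, control/disease) to a key."""
    try:
        return _CLASS_ALIASES[label]
    except (KeyError, TypeError):
        raise ValidationError(f"unknown label {label!r}") from None


def make_anatomy(
    spec: PhantomSpec, label, rng: np.random.Generator | None = None
) -> Volume:
    """Noise-free anatomy for one subject.

    Concentric ellipsoids (scalp shell / gray / white) with a centered
    spherical ventricle whose radius depends on the class label.  ``rng``
    supplies the per-subject anatomical jitter (each ellipsoid semi-axis
    scaled by an independent uniform factor within ±5%); pass ``None`` for
    the unjittered reference geometry.
    """
    spec.validate()
    label_key = _class_key(label)
    n = spec.grid_size
    if rng is None:
        jitter = np.ones(3)
    else:
        jitter = rng.uniform(1.0 - _JITTER, 1.0 + _JITTER, size=3)
    axes = np.array(_SHELL_AXES) * n * jitter
    c = (n - 1) / 2.0
    coords = np.arange(n) - c
    x = coords[:, None, None]
    y = coords[None, :, None]
    z = coords[None, None, :]

    def inside(scale: float) -> np.ndarray:
        a = axes * scale
        return (x / a[0]) ** 2 + (y / a[1]) ** 2 + (z / a[2]) ** 2 <= 1.0

    vol = np.full((n, n, n), spec.background_level, dtype=np.float64)
    vol[inside(1.0)] = spec.shell_level
    vol[inside(_GRAY_SCALE)] = spec.tissue_levels["gray"]
    vol[inside(_WHITE_SCALE)] = spec.tissue_levels["white"]
    r = spec.ventricle_radius_by_class[label_key]
    vent = x**2 + y**2 + z**2 <= r**2
    vol[vent] = spec.tissue_levels["ventricle"]
    return Volume(vol, provenance="raw")


def head_mask(anatomy: Volume, spec: PhantomSpec) -> np.ndarray:
    """Boolean mask of head voxels (anything above the background level)."""
    return anatomy.data > spec.background_level


def render_pair(
    anatomy: Volume,
    spec: PhantomSpec,
    rng: np.random.Generator,
    *,
    subject_id: str = "S0000",
    label: int = LABEL_CONTROL,
) -> PhantomPair:
    """Render the low-/high-field pair of one anatomy.

    The high-field rendering applies ``contrast_gain_high`` around the head
    interior mean (background untouched) and adds weak noise; the low-field
    rendering adds strong noise.  Noise fields are drawn inside the head
    only, low first then high, so pairs are bit-reproducible for a given
    generator state.
    """
    spec.validate()
    mask = head_mask(anatomy, spec)
    a = anatomy.data.astype(np.float64)
    low = a.copy()
    low[mask] += spec.noise_sigma_low * rng.standard_normal(int(mask.sum()))
    high = a.copy()
    m = float(a[mask].mean())
    high[mask] = spec.contrast_gain_high * (a[mask] - m) + m
    high[mask] += spec.noise_sigma_high * rng.standard_normal(int(mask.sum()))
    true_mask = high - low
    high = low + true_mask  # enforce the exact identity low + mask == high
    return PhantomPair(
        subject_id=subject_id,
        low=Volume(low, anatomy.affine, "raw"),
        high=Volume(high, anatomy.affine, "raw"),
        label=int(label),
        true_mask=Volume(true_mask, anatomy.affine, "raw"),
    )


def _subject_seed(base_seed: int, index: int) -> int:
    # deterministic, collision-free at cohort scale, < 2**31
    return (base_seed + 1000003 * (index + 1)) % (2**31 - 1)


def make_cohort(spec: PhantomSpec, n_per_class: int, seed: int | None = None) -> list[PhantomPair]:
    """Balanced cohort of ``2 * n_per_class`` phantom pairs.

    Labels alternate control/disease over subject index; each subject draws
    its anatomy jitter and noise from its own derived seed, so any subject
    can be regenerated independently.
    """
    if n_per_class < 1:
        raise ValidationError(f"n_per_class must be >= 1, got {n_per_class}")
    spec.validate()
    base = spec.seed if seed is None else seed
    pairs = []
    for i in range(2 * n_per_class):
        label = LABEL_CONTROL if i % 2 == 0 else LABEL_DISEASE
        rng = np.random.default_rng(_subject_seed(base, i))
        anatomy = make_anatomy(spec, label, rng)
        pairs.append(
            render_pair(anatomy, spec, rng, subject_id=f"S{i:04d}", label=label)
        )
    return pairs


def write_cohort(pairs: list[PhantomPair], out_dir: str | Path, *, seed: int | None = None) -> Path:
    """Write one NIfTI per subject per field strength plus a CSV manifest.

    Returns the manifest path.  Manifest columns: subject_id, path_low,
    path_high, label, seed.
    """
    from .io import write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, p in enumerate(pairs):
        path_low = out / f"{p.subject_id}_low.nii"
        path_high = out / f"{p.subject_id}_high.nii"
        write_volume(p.low, path_low, overwrite=True)
        write_volume(p.high, path_high, overwrite=True)
        rows.append(
            {
                "subject_id": p.subject_id,
                "path_low": path_low.name,
                "path_high": path_high.name,
                "label": p.label_name,
                "seed": "" if seed is None else _subject_seed(seed, i),
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
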