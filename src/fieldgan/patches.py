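"""Random cubic patch sampling and subject-level score aggregation.

Training is patch-wise: cubic subvolumes (47^3 by default) drawn uniformly
over all valid positions of the parent volume, which doubles as a light form
of data augmentation.  Paired sampling extracts the low- and high-field
patch at the *same* origin so spatial correspondence is preserved.  At
inference, a subject's disease probability is the mean classifier
probability over ``n_patches`` randomly sampled patches.
"""

from __future__ import annotations

import numpy as np

from .nets import disease_probability
from .types import Patch, PhantomPair, ShapeError, Volume

DEFAULT_PATCH_SIDE = 47
MIN_PATCH_SIDE = 7


def _data(vol) -> np.ndarray:
    return vol.data if isinstance(vol, Volume) else np.asarray(vol)


def _draw_origin(shape, s: int, rng: np.random.Generator) -> tuple[int, int, int]:
    if any(dim < s for dim in shape):
        raise ShapeError(f"volume shape {shape} smaller than patch side {s}")
    return tuple(int(rng.integers(0, dim - s + 1)) for dim in shape)


def extract_patch(vol, origin, s: int, **meta) -> Patch:
    """Copy out the cubic subvolume at ``origin`` (mutation-safe)."""
    data = _data(vol)
    i, j, k = origin
    if any(o < 0 for o in origin) or i + s > data.shape[0] or j + s > data.shape[1] or k + s > data.shape[2]:
        raise ShapeError(f"origin {origin} + side {s} exceeds volume shape {data.shape}")
    return Patch(data[i : i + s, j : j + s, k : k + s].copy(), (i, j, k), **meta)


def sample_patch(
    vol, s: int = DEFAULT_PATCH_SIDE, rng: np.random.Generator | None = None, **meta
) -> Patch:
    """Draw one patch with origin uniform over all valid positions."""
    if s < MIN_PATCH_SIDE:
        raise ShapeError(f"patch side must be >= {MIN_PATCH_SIDE}, got {s}")
    rng = rng or np.random.default_rng()
    origin = _draw_origin(_data(vol).shape, s, rng)
    return extract_patch(vol, origin, s, **meta)


def sample_paired_patch(
    pair: PhantomPair, s: int = DEFAULT_PATCH_SIDE, rng: np.random.Generator | None = None
) -> tuple[Patch, Patch]:
    """Draw low/high patches of one pair at a single shared origin."""
    if pair.low.shape != pair.high.shape:
        raise ShapeError(
            f"pair volumes differ in shape: {pair.low.shape} vs {pair.high.shape}"
        )
    rng = rng or np.random.default_rng()
    origin = _draw_origin(pair.low.shape, s, rng)
    low = extract_patch(pair.low, origin, s, subject_id=pair.subject_id, label=pair.label)
    high = extract_patch(pair.high, origin, s, subject_id=pair.subject_id, label=pair.label)
    return low, high


def subject_score(
    vol,
    classifier,
    s: int = DEFAULT_PATCH_SIDE,
    n_patches: int = 20,
    rng: np.random.Generator | None = None,
) -> float:
    """Mean disease probability over ``n_patches`` sampled patches, in [0, 1].

    Deterministic for a fixed generator state.  ``classifier`` is the FCN
    network (or a ModelBundle, whose classifier is used).
    """
    from .nets import ModelBundle

    if isinstance(classifier, ModelBundle):
        classifier = classifier.classifier
    rng = rng or np.random.default_rng()
    batch = np.stack(
        [sample_patch(vol, s, rng).data for _ in range(int(n_patches))]
    )
    probs = disease_probability(classifier, batch)
    return float(np.mean(probs))
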