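"""Network definitions: residual generator, FCN discriminator, FCN classifier.

The generator is a 3-block 3D conv stack (kernel 3, stride 1, paddings
2/0/1) whose per-block spatial deltas are +2, -2, 0 — net zero, so the
output matches the input size for any side >= 3 and the predicted
"transformation mask" can be added directly onto the input patch
(``generated = input + mask``, residual learning).  The final block is a
plain convolution (no normalization or rectifier) so the mask can take
negative values, and it is zero-initialized so training starts at the
identity mapping.

The discriminator is a 5-block fully convolutional stack (conv + batch norm
+ leaky rectifier) whose spatial score map is mean-pooled to a single logit.
The classifier is a fully convolutional stack whose receptive field equals
the configured patch side by construction: three conv/pool blocks followed
by a final convolution whose kernel spans whatever spatial extent remains,
leaving exactly one spatial position with 2 class logits.

Channel widths, the leaky slope and the discriminator stride schedule are
configurable defaults sized for CPU-scale experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .types import ShapeError, Volume, FieldganError


@dataclass
class GeneratorSpec:
    kernel: int = 3
    stride: int = 1
    paddings: tuple[int, int, int] = (2, 0, 1)
    channels: tuple[int, int, int] = (16, 16, 1)

    def __post_init__(self) -> None:
        self.paddings = tuple(self.paddings)  # type: ignore[assignment]
        self.channels = tuple(self.channels)  # type: ignore[assignment]
        deltas = [2 * p - (self.kernel - 1) for p in self.paddings]
        if sum(deltas) != 0:
            raise ShapeError(
                f"paddings {self.paddings} with kernel {self.kernel} give a net "
                f"size change of {sum(deltas)}; the generator must be size-preserving"
            )
        if self.channels[-1] != 1:
            raise ShapeError("final generator channel count must be 1 (the mask)")


@dataclass
class DiscriminatorSpec:
    kernel: int = 3
    strides: tuple[int, ...] = (2, 2, 2, 2, 1)
    paddings: tuple[int, ...] = (0, 0, 0, 0, 1)
    channels: tuple[int, ...] = (8, 16, 32, 64, 1)
    leaky_slope: float = 0.2

    def __post_init__(self) -> None:
        self.strides = tuple(self.strides)  # type: ignore[assignment]
        self.paddings = tuple(self.paddings)  # type: ignore[assignment]
        self.channels = tuple(self.channels)  # type: ignore[assignment]
        if not (len(self.strides) == len(self.paddings) == len(self.channels)):
            raise ShapeError("strides, paddings and channels must align per block")
        if self.channels[-1] != 1:
            raise ShapeError("final discriminator channel count must be 1 (the score map)")


@dataclass
class ClassifierSpec:
    patch_side: int = 47
    channels: tuple[int, ...] = (8, 16, 32)

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)  # type: ignore[assignment]
        s = self.patch_side
        for _ in self.channels:
            s = s - 2
            if s < 2:
                raise ShapeError(
                    f"patch side {self.patch_side} too small for "
                    f"{len(self.channels)} conv/pool blocks"
                )
            s = s // 2
        self.final_kernel = s  # conv spanning the remaining extent -> 1^3 output


def build_generator(spec: GeneratorSpec, rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    in_ch = 1
    n = len(spec.channels)
    for bi, (out_ch, pad) in enumerate(zip(spec.channels, spec.paddings)):
        last = bi == n - 1
        layers.append(
            nn.Conv3d(
                in_ch, out_ch, spec.kernel, spec.stride, pad,
                zero_init=last, rng=rng, name=f"G{bi}",
            )
        )
        if not last:
            layers.append(nn.BatchNorm3d(out_ch, name=f"G{bi}.bn"))
            layers.append(nn.ReLU())
        in_ch = out_ch
    return nn.Sequential(layers)


def build_discriminator(spec: DiscriminatorSpec, rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    in_ch = 1
    n = len(spec.channels)
    for bi, (out_ch, stride, pad) in enumerate(
        zip(spec.channels, spec.strides, spec.paddings)
    ):
        last = bi == n - 1
        layers.append(
            nn.Conv3d(in_ch, out_ch, spec.kernel, stride, pad, rng=rng, name=f"D{bi}")
        )
        if not last:
            # the final block stays linear: normalizing the logit map would
            # erase the overall real/fake score
            layers.append(nn.BatchNorm3d(out_ch, name=f"D{bi}.bn"))
            layers.append(nn.LeakyReLU(spec.leaky_slope))
        in_ch = out_ch
    layers.append(nn.GlobalAvgPool())
    return nn.Sequential(layers)


def build_classifier(spec: ClassifierSpec, rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    in_ch = 1
    for bi, out_ch in enumerate(spec.channels):
        layers.append(nn.Conv3d(in_ch, out_ch, 3, 1, 0, rng=rng, name=f"C{bi}"))
        layers.append(nn.BatchNorm3d(out_ch, name=f"C{bi}.bn"))
        layers.append(nn.ReLU())
        layers.append(nn.AvgPool3d())
        in_ch = out_ch
    layers.append(
        nn.Conv3d(in_ch, 2, spec.final_kernel, 1, 0, rng=rng, name="Chead")
    )
    return nn.Sequential(layers)


def _as_batch(patch: np.ndarray) -> np.ndarray:
    x = np.asarray(patch, dtype=nn.DTYPE)
    if x.ndim == 3:
        x = x[None, None]
    elif x.ndim == 4:
        x = x[:, None]
    elif x.ndim != 5:
        raise ShapeError(f"expected 3D/4D/5D array, got shape {x.shape}")
    return x


def generator_forward(
    G: nn.Sequential, low_patch: np.ndarray, *, train: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Predict the transformation mask and the generated patch.

    Returns ``(mask, generated)`` with ``generated = low + mask`` and the
    same spatial shape as the input (any side >= 3).
    """
    x = _as_batch(low_patch)
    if min(x.shape[2:]) < 3:
        raise ShapeError(f"generator input side must be >= 3, got {x.shape[2:]}")
    mask = G.forward(x, train)
    if mask.shape != x.shape:
        raise ShapeError(
            f"generator produced shape {mask.shape} for input {x.shape}"
        )  # pragma: no cover - guarded by spec invariants
    generated = x + mask
    if np.asarray(low_patch).ndim == 3:
        return mask[0, 0], generated[0, 0]
    return mask, generated


def discriminator_forward(
    D: nn.Sequential, patch: np.ndarray, *, train: bool = False
) -> np.ndarray:
    """Scalar real/fake logit per batch element (mean over the score map)."""
    x = _as_batch(patch)
    logit = D.forward(x, train)[:, 0]
    if np.asarray(patch).ndim == 3:
        return float(logit[0])  # type: ignore[return-value]
    return logit


def classifier_forward(
    C: nn.Sequential, patch: np.ndarray, *, train: bool = False
) -> np.ndarray:
    """Two class logits per batch element; softmax gives disease probability."""
    x = _as_batch(patch)
    out = C.forward(x, train)
    if out.shape[2:] != (1, 1, 1):
        raise ShapeError(
            f"classifier output spatial size {out.shape[2:]} != 1^3: patch side "
            "does not match the configured receptive field"
        )
    logits = out[:, :, 0, 0, 0]
    if np.asarray(patch).ndim == 3:
        return logits[0]
    return logits


def disease_probability(C: nn.Sequential, patch: np.ndarray) -> np.ndarray:
    logits = classifier_forward(C, patch, train=False)
    return nn.softmax(logits)[..., 1]


def count_parameters(model: nn.Sequential) -> int:
    """Total trainable scalar count."""
    return int(sum(p.data.size for p in model.params()))


@dataclass
class ModelBundle:
    """The three networks plus the specs and loss weights that bind them."""

    generator: nn.Sequential
    discriminator: nn.Sequential
    classifier: nn.Sequential
    gen_spec: GeneratorSpec
    disc_spec: DiscriminatorSpec
    clf_spec: ClassifierSpec
    loss_weights: dict = field(
        default_factory=lambda: {"w_adv": 1.0, "w_l1": 10.0, "w_cls": 1.0}
    )

    @classmethod
    def build(
        cls,
        rng: np.random.Generator,
        gen_spec: GeneratorSpec | None = None,
        disc_spec: DiscriminatorSpec | None = None,
        clf_spec: ClassifierSpec | None = None,
        loss_weights: dict | None = None,
    ) -> "ModelBundle":
        gen_spec = gen_spec or GeneratorSpec()
        disc_spec = disc_spec or DiscriminatorSpec()
        clf_spec = clf_spec or ClassifierSpec()
        return cls(
            generator=build_generator(gen_spec, rng),
            discriminator=build_discriminator(disc_spec, rng),
            classifier=build_classifier(clf_spec, rng),
            gen_spec=gen_spec,
            disc_spec=disc_spec,
            clf_spec=clf_spec,
            loss_weights=dict(loss_weights or {"w_adv": 1.0, "w_l1": 10.0, "w_cls": 1.0}),
        )

    def snapshot(self) -> dict:
        return {
            "G": self.generator.snapshot(),
            "D": self.discriminator.snapshot(),
            "C": self.classifier.snapshot(),
        }

    def load_snapshot(self, snap: dict) -> None:
        self.generator.load_state_arrays(snap["G"])
        self.discriminator.load_state_arrays(snap["D"])
        self.classifier.load_state_arrays(snap["C"])


def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    """Serialize a bundle as a self-describing npz (JSON spec header + weights)."""
    header = json.dumps(
        {
            "format": "fieldgan-checkpoint-v1",
            "gen_spec": asdict(bundle.gen_spec),
            "disc_spec": asdict(bundle.disc_spec),
            "clf_spec": {
                "patch_side": bundle.clf_spec.patch_side,
                "channels": list(bundle.clf_spec.channels),
            },
            "loss_weights": bundle.loss_weights,
        }
    )
    arrays = {}
    for net_name, net in (
        ("G", bundle.generator),
        ("D", bundle.discriminator),
        ("C", bundle.classifier),
    ):
        for key, arr in net.state_arrays().items():
            arrays[f"{net_name}/{key}"] = arr
    np.savez(path, __spec__=np.array(header), **arrays)


def load_bundle(path: str | Path) -> ModelBundle:
    with np.load(path, allow_pickle=False) as data:
        try:
            header = json.loads(str(data["__spec__"]))
        except KeyError as exc:
            raise FieldganError(f"{path}: not a fieldgan checkpoint") from exc
        arrays = {k: data[k] for k in data.files if k != "__spec__"}
    gen_spec = GeneratorSpec(**{
        k: tuple(v) if isinstance(v, list) else v for k, v in header["gen_spec"].items()
    })
    disc_spec = DiscriminatorSpec(**{
        k: tuple(v) if isinstance(v, list) else v for k, v in header["disc_spec"].items()
    })
    clf_spec = ClassifierSpec(
        patch_side=header["clf_spec"]["patch_side"],
        channels=tuple(header["clf_spec"]["channels"]),
    )
    bundle = ModelBundle.build(
        np.random.default_rng(0), gen_spec, disc_spec, clf_spec, header["loss_weights"]
    )
    for net_name, net in (
        ("G", bundle.generator),
        ("D", bundle.discriminator),
        ("C", bundle.classifier),
    ):
        net.load_state_arrays(
            {k.split("/", 1)[1]: v for k, v in arrays.items() if k.startswith(net_name + "/")}
        )
    return bundle


def generate_volume(G: nn.Sequential, vol: Volume) -> Volume:
    """Apply the (size-agnostic) generator to a whole volume in eval mode."""
    _, gen = generator_forward(G, vol.data.astype(nn.DTYPE), train=False)
    return vol.with_data(np.asarray(gen, dtype=np.float64), provenance="generated")
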