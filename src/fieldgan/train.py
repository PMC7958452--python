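"""Joint GAN + classifier training, decoupled variants, splits, checkpoints.

The main method trains three networks simultaneously on randomly sampled
paired patches:

* the **discriminator** takes one binary-cross-entropy step per batch on
  (real = high-field, fake = generated) patches;
* the **generator and classifier** then take one joint step minimizing
  ``w_adv * adversarial + w_l1 * mean|generated - high| + w_cls *
  cross-entropy(classifier(generated), labels)``.  The classification
  gradient flows through the generated patch back into the generator, which
  is what lets disease-relevant information shape the translation.

The decoupled variant (``train_simple``) trains the GAN alone first
(``w_cls = 0``), then the classifier on patches generated by the frozen
generator.  Checkpoint selection follows validation metrics: the GAN state
with the highest validation SNR of generated volumes, the classifier state
with the highest validation subject-level accuracy.

Splits are by subject (never by patch) in a 3:1:1 ratio with floor sizes
for validation/test and the remainder assigned to training, stratified by
label where possible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .nets import (
    ClassifierSpec,
    DiscriminatorSpec,
    GeneratorSpec,
    ModelBundle,
    generate_volume,
)
from .patches import extract_patch, subject_score
from .preprocess import PreprocessConfig, preprocess_volume
from .quality import snr_center_slice
from .types import FieldganError, PhantomPair, ValidationError, Volume


class DivergenceError(FieldganError):
    """A loss component became non-finite during training."""

    def __init__(self, component: str, value: float) -> None:
        super().__init__(f"non-finite loss component {component!r}: {value}")
        self.component = component


@dataclass
class LossWeights:
    """Relative weights of the three generator-side loss terms."""

    w_adv: float = 1.0
    w_l1: float = 10.0
    w_cls: float = 1.0

    def validate(self) -> None:
        ws = (self.w_adv, self.w_l1, self.w_cls)
        if any(w < 0 for w in ws):
            raise ValidationError("loss weights must be >= 0")
        if not any(w > 0 for w in ws):
            raise ValidationError("at least one loss weight must be > 0")

    def as_dict(self) -> dict:
        return {"w_adv": self.w_adv, "w_l1": self.w_l1, "w_cls": self.w_cls}


@dataclass
class SplitPlan:
    """Subject-level train/validation/test membership."""

    train: list[str]
    val: list[str]
    test: list[str]
    seed: int = 0

    def __post_init__(self) -> None:
        parts = [set(self.train), set(self.val), set(self.test)]
        total = sum(len(p) for p in parts)
        union = set().union(*parts)
        if total != len(union):
            raise ValidationError("split parts must be disjoint")

    def part_of(self, subject_id: str) -> str:
        for name in ("train", "val", "test"):
            if subject_id in getattr(self, name):
                return name
        raise KeyError(subject_id)


def split_cohort(
    subjects, ratios: tuple[int, int, int] = (3, 1, 1), seed: int = 0
) -> SplitPlan:
    """Random stratified subject split with the floor rule.

    Validation and test receive ``floor(n * r / sum(ratios))`` subjects each;
    the remainder goes to training (n = 151 with 3:1:1 gives 91/30/30).
    ``subjects`` may be subject-id strings, (id, label) tuples, or objects
    with ``subject_id``/``label`` attributes; labels enable stratification.
    """

    def _id_label(s):
        if isinstance(s, str):
            return s, 0
        if isinstance(s, tuple):
            return s[0], int(s[1])
        return s.subject_id, int(getattr(s, "label", 0))

    items = [_id_label(s) for s in subjects]
    n = len(items)
    if n < 5:
        raise ValidationError(f"need >= 5 subjects to split 3:1:1, got {n}")
    total = sum(ratios)
    n_val = n * ratios[1] // total
    n_test = n * ratios[2] // total
    rng = np.random.default_rng(seed)
    by_label: dict[int, list[str]] = {}
    for sid, lab in sorted(items):
        by_label.setdefault(lab, []).append(sid)
    for lab in by_label:
        rng.shuffle(by_label[lab])
    # round-robin over classes (largest first) so small parts see every class
    order: list[tuple[str, int]] = []
    queues = sorted(by_label.items(), key=lambda kv: -len(kv[1]))
    idx = 0
    while any(q for _, q in queues):
        lab, q = queues[idx % len(queues)]
        if q:
            order.append((q.pop(), lab))
        idx += 1
    ids = [sid for sid, _ in order]
    labs = {sid: lab for sid, lab in order}
    val = ids[:n_val]
    test = ids[n_val : n_val + n_test]
    train = ids[n_val + n_test :]
    present = {lab for _, lab in items}
    for name, part in (("train", train), ("val", val), ("test", test)):
        missing = present - {labs[sid] for sid in part}
        if missing:
            warnings.warn(
                f"split part {name!r} received no subject of class(es) {sorted(missing)}",
                stacklevel=2,
            )
    return SplitPlan(train=sorted(train), val=sorted(val), test=sorted(test), seed=seed)


@dataclass
class PreparedSubject:
    """One subject after preprocessing, ready for patch sampling."""

    subject_id: str
    low: Volume
    high: Volume
    label: int
    brain_mask: np.ndarray  # True on brain voxels (complement of background)


def prepare_cohort(
    pairs: list[PhantomPair], cfg: PreprocessConfig | None = None
) -> list[PreparedSubject]:
    """Preprocess both renderings of every pair independently."""
    cfg = cfg or PreprocessConfig()
    out = []
    for p in pairs:
        low, bg = preprocess_volume(p.low, cfg, return_mask=True)
        high = preprocess_volume(p.high, cfg)
        out.append(
            PreparedSubject(
                subject_id=p.subject_id,
                low=low,
                high=high,
                label=p.label,
                brain_mask=~bg.data.astype(bool),
            )
        )
    return out


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    Defaults mirror the reference conditions (47-voxel patches, Adam with
    learning rate 2e-4 and betas (0.5, 0.999), loss weights 1/10/1);
    CPU-scale experiments shrink ``patch_side``, channel widths and step
    counts.
    """

    epochs: int = 5
    steps_per_epoch: int = 40
    batch_size: int = 4
    patch_side: int = 47
    lr: float = 2e-4
    betas: tuple[float, float] = (0.5, 0.999)
    loss_weights: LossWeights = field(default_factory=LossWeights)
    gen_channels: tuple[int, int, int] = (16, 16, 1)
    disc_channels: tuple[int, ...] = (8, 16, 32, 64, 1)
    clf_channels: tuple[int, ...] = (8, 16, 32)
    n_patches_eval: int = 20
    threshold: float = 0.5
    seed: int = 0

    def build_bundle(self, rng: np.random.Generator) -> ModelBundle:
        return ModelBundle.build(
            rng,
            GeneratorSpec(channels=self.gen_channels),
            DiscriminatorSpec(channels=self.disc_channels),
            ClassifierSpec(patch_side=self.patch_side, channels=self.clf_channels),
            self.loss_weights.as_dict(),
        )


def _check_finite(name: str, value: float) -> float:
    if not np.isfinite(value):
        raise DivergenceError(name, value)
    return value


def joint_step(
    low: np.ndarray,
    high: np.ndarray,
    labels: np.ndarray,
    bundle: ModelBundle,
    weights: LossWeights,
    opt_g: nn.Adam,
    opt_d: nn.Adam,
    opt_c: nn.Adam,
) -> dict:
    """One alternating update: discriminator first, then generator+classifier.

    Returns every loss component plus the weighted generator total.  The
    classifier sees only generated patches, and its gradient reaches the
    generator through the residual addition.
    """
    weights.validate()
    G, D, C = bundle.generator, bundle.discriminator, bundle.classifier
    low = np.asarray(low, dtype=nn.DTYPE)
    high = np.asarray(high, dtype=nn.DTYPE)
    mask = G.forward(low, train=True)
    fake = low + mask

    loss_d = 0.0
    if weights.w_adv > 0:
        d_real = D.forward(high, train=True)[:, 0]
        l_real, g_real = nn.bce_with_logits(d_real, 1.0)
        D.backward(g_real[:, None])
        d_fake = D.forward(fake, train=True)[:, 0]
        l_fake, g_fake = nn.bce_with_logits(d_fake, 0.0)
        D.backward(g_fake[:, None])
        opt_d.step()
        D.zero_grad()
        loss_d = _check_finite("adv_D", l_real + l_fake)

    grad_fake = np.zeros_like(fake)
    adv = l1v = clsv = 0.0
    if weights.w_adv > 0:
        d_fake2 = D.forward(fake, train=True)[:, 0]
        adv, g_adv = nn.bce_with_logits(d_fake2, 1.0)
        grad_fake += weights.w_adv * D.backward(g_adv[:, None])
        D.zero_grad()  # discriminator is not updated on the generator step
        _check_finite("adv_G", adv)
    if weights.w_l1 > 0:
        l1v, g_l1 = nn.l1_loss(fake, high)
        grad_fake += weights.w_l1 * g_l1
        _check_finite("l1", l1v)
    if weights.w_cls > 0:
        logits = C.forward(fake, train=True)
        clsv, g_ce = nn.softmax_cross_entropy(logits[:, :, 0, 0, 0], labels)
        grad_fake += weights.w_cls * C.backward(g_ce[:, :, None, None, None])
        _check_finite("cls", clsv)

    G.backward(grad_fake)  # d(fake)/d(mask) is the identity
    opt_g.step()
    G.zero_grad()
    if weights.w_cls > 0:
        opt_c.step()
        C.zero_grad()
    total_g = weights.w_adv * adv + weights.w_l1 * l1v + weights.w_cls * clsv
    return {
        "adv_D": loss_d,
        "adv_G": adv,
        "l1": l1v,
        "cls": clsv,
        "total_G": total_g,
    }


@dataclass
class TrainResult:
    """Outcome of one training run.

    ``bundle`` carries the checkpoint-selected states: the generator (and
    discriminator) at the epoch of highest validation SNR and the classifier
    at the epoch of highest validation accuracy.
    """

    bundle: ModelBundle
    step_log: pd.DataFrame
    epoch_log: pd.DataFrame
    best_val_snr: float
    best_val_accuracy: float


def _classifier_step(
    patches: np.ndarray, labels: np.ndarray, C: nn.Sequential, opt_c: nn.Adam
) -> float:
    logits = C.forward(np.asarray(patches, dtype=nn.DTYPE), train=True)
    loss, g = nn.softmax_cross_entropy(logits[:, :, 0, 0, 0], labels)
    C.backward(g[:, :, None, None, None])
    opt_c.step()
    C.zero_grad()
    return _check_finite("cls", loss)


def _sample_batch(
    subjects: list[PreparedSubject], cfg: TrainConfig, rng: np.random.Generator
):
    idx = rng.integers(0, len(subjects), size=cfg.batch_size)
    lows, highs, labels = [], [], []
    side = cfg.patch_side
    for i in idx:
        s = subjects[i]
        origin = tuple(
            int(rng.integers(0, dim - side + 1)) for dim in s.low.shape
        )
        lows.append(extract_patch(s.low, origin, side).data)
        highs.append(extract_patch(s.high, origin, side).data)
        labels.append(s.label)
    return (
        np.stack(lows)[:, None],
        np.stack(highs)[:, None],
        np.array(labels, dtype=int),
    )


def _validate_epoch(
    bundle: ModelBundle,
    val_subjects: list[PreparedSubject],
    cfg: TrainConfig,
    rng: np.random.Generator,
    *,
    identity_generator: bool = False,
) -> tuple[float, float]:
    """Mean validation SNR of generated volumes and subject-level accuracy."""
    snrs, correct = [], []
    for s in val_subjects:
        gen = s.low if identity_generator else generate_volume(bundle.generator, s.low)
        snrs.append(snr_center_slice(gen, ~s.brain_mask))
        score = subject_score(
            gen, bundle.classifier, cfg.patch_side, cfg.n_patches_eval, rng
        )
        correct.append((score >= cfg.threshold) == bool(s.label))
    return float(np.mean(snrs)), float(np.mean(correct))


def _run_epochs(
    bundle: ModelBundle,
    train_subjects: list[PreparedSubject],
    val_subjects: list[PreparedSubject],
    cfg: TrainConfig,
    weights: LossWeights,
    rng: np.random.Generator,
    *,
    train_gan: bool,
    train_cls: bool,
    identity_generator: bool = False,
    phase: str = "joint",
):
    opt_g = nn.Adam(bundle.generator.params(), cfg.lr, cfg.betas)
    opt_d = nn.Adam(bundle.discriminator.params(), cfg.lr, cfg.betas)
    opt_c = nn.Adam(bundle.classifier.params(), cfg.lr, cfg.betas)
    step_rows, epoch_rows = [], []
    best_snr, best_acc = -np.inf, -np.inf
    best_gan_state, best_clf_state = None, None
    for epoch in range(cfg.epochs):
        for step in range(cfg.steps_per_epoch):
            low, high, labels = _sample_batch(train_subjects, cfg, rng)
            if train_gan:
                losses = joint_step(
                    low, high, labels, bundle, weights, opt_g, opt_d, opt_c
                )
            else:
                if identity_generator:
                    fake = low
                else:
                    m = bundle.generator.forward(low, train=False)
                    fake = low + m
                cls = _classifier_step(fake, labels, bundle.classifier, opt_c)
                losses = {"adv_D": 0.0, "adv_G": 0.0, "l1": 0.0, "cls": cls,
                          "total_G": weights.w_cls * cls}
            step_rows.append({"phase": phase, "epoch": epoch, "step": step, **losses})
        val_snr, val_acc = _validate_epoch(
            bundle, val_subjects, cfg, rng, identity_generator=identity_generator
        )
        if train_gan and val_snr > best_snr:
            best_snr = val_snr
            best_gan_state = {
                "G": bundle.generator.snapshot(),
                "D": bundle.discriminator.snapshot(),
            }
        if train_cls and val_acc > best_acc:
            best_acc = val_acc
            best_clf_state = bundle.classifier.snapshot()
        epoch_rows.append(
            {
                "phase": phase,
                "epoch": epoch,
                "val_snr": val_snr,
                "val_accuracy": val_acc,
                "best_val_snr": best_snr if train_gan else np.nan,
                "best_val_accuracy": best_acc if train_cls else np.nan,
            }
        )
    if best_gan_state is not None:
        bundle.generator.load_state_arrays(best_gan_state["G"])
        bundle.discriminator.load_state_arrays(best_gan_state["D"])
    if best_clf_state is not None:
        bundle.classifier.load_state_arrays(best_clf_state)
    return step_rows, epoch_rows, best_snr, best_acc


def _resolve_split(cohort: list[PreparedSubject], split: SplitPlan):
    by_id = {s.subject_id: s for s in cohort}
    missing = (set(split.train) | set(split.val) | set(split.test)) - set(by_id)
    if missing:
        raise ValidationError(f"split references unknown subjects: {sorted(missing)}")
    train = [by_id[i] for i in split.train]
    val = [by_id[i] for i in split.val]
    if not train or not val:
        raise ValidationError("train and validation parts must be non-empty")
    return train, val


def train_joint(
    cohort: list[PreparedSubject],
    split: SplitPlan,
    cfg: TrainConfig,
    seed: int | None = None,
) -> TrainResult:
    """Simultaneous GAN + classifier training with checkpoint selection.

    One discriminator update and one generator+classifier update per batch;
    after each epoch the generator is scored by validation SNR and the
    classifier by validation accuracy, and the best states are kept.
    """
    weights = cfg.loss_weights
    weights.validate()
    run_seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(run_seed)
    bundle = cfg.build_bundle(rng)
    train_subjects, val_subjects = _resolve_split(cohort, split)
    step_rows, epoch_rows, best_snr, best_acc = _run_epochs(
        bundle, train_subjects, val_subjects, cfg, weights, rng,
        train_gan=True, train_cls=weights.w_cls > 0, phase="joint",
    )
    return TrainResult(
        bundle=bundle,
        step_log=pd.DataFrame(step_rows),
        epoch_log=pd.DataFrame(epoch_rows),
        best_val_snr=best_snr,
        best_val_accuracy=best_acc,
    )


def train_simple(
    cohort: list[PreparedSubject],
    split: SplitPlan,
    cfg: TrainConfig,
    seed: int | None = None,
    *,
    generator: str = "train",
) -> TrainResult:
    """Decoupled two-phase training (simpleGAN then simpleFCN).

    Phase 1 trains the GAN alone (``w_cls`` forced to 0); phase 2 trains the
    classifier on patches produced by the frozen phase-1 generator.  With
    ``generator="identity"`` phase 1 is skipped and the classifier sees the
    raw low-field patches through an untouched zero-initialized generator —
    the baseline analog of classifying the original low-field scans.
    """
    if generator not in ("train", "identity"):
        raise ValidationError("generator must be 'train' or 'identity'")
    weights = cfg.loss_weights
    weights.validate()
    run_seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(run_seed)
    bundle = cfg.build_bundle(rng)
    train_subjects, val_subjects = _resolve_split(cohort, split)
    identity = generator == "identity"
    step_rows: list[dict] = []
    epoch_rows: list[dict] = []
    best_snr = np.nan
    if not identity:
        gan_weights = LossWeights(weights.w_adv, weights.w_l1, 0.0)
        s1, e1, best_snr, _ = _run_epochs(
            bundle, train_subjects, val_subjects, cfg, gan_weights, rng,
            train_gan=True, train_cls=False, phase="simpleGAN",
        )
        step_rows += s1
        epoch_rows += e1
    s2, e2, _, best_acc = _run_epochs(
        bundle, train_subjects, val_subjects, cfg, weights, rng,
        train_gan=False, train_cls=True,
        identity_generator=identity, phase="simpleFCN",
    )
    step_rows += s2
    epoch_rows += e2
    return TrainResult(
        bundle=bundle,
        step_log=pd.DataFrame(step_rows),
        epoch_log=pd.DataFrame(epoch_rows),
        best_val_snr=float(best_snr),
        best_val_accuracy=best_acc,
    )


def repeat_runs(train_fn, n_runs: int = 25, base_seed: int = 0, **kwargs):
    """Repeat a training function over consecutive seeds.

    Returns ``(results, failures)``: results keyed by seed, diverged runs
    recorded (and excluded) in failures keyed by seed.
    """
    if n_runs < 2:
        raise ValidationError(f"n_runs must be >= 2, got {n_runs}")
    results: dict[int, TrainResult] = {}
    failures: dict[int, str] = {}
    for seed in range(base_seed, base_seed + n_runs):
        try:
            results[seed] = train_fn(seed=seed, **kwargs)
        except DivergenceError as exc:
            warnings.warn(f"run with seed {seed} diverged: {exc}", stacklevel=2)
            failures[seed] = str(exc)
    return results, failures


def test_scores(
    result: TrainResult,
    cohort: list[PreparedSubject],
    split: SplitPlan,
    cfg: TrainConfig,
    rng: np.random.Generator,
    *,
    identity_generator: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Subject-level disease scores and labels on the held-out test part."""
    by_id = {s.subject_id: s for s in cohort}
    scores, labels = [], []
    for sid in split.test:
        s = by_id[sid]
        gen = (
            s.low
            if identity_generator
            else generate_volume(result.bundle.generator, s.low)
        )
        scores.append(
            subject_score(gen, result.bundle.classifier, cfg.patch_side,
                          cfg.n_patches_eval, rng)
        )
        labels.append(s.label)
    return np.array(scores), np.array(labels, dtype=int)
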