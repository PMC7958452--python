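"""NIfTI I/O, cohort manifests, run configuration and the end-to-end pipeline.

Volumes are stored as NIfTI-1 files (float32 data, affine preserved
bit-exact on round trip).  A cohort is a flat directory plus a CSV manifest
with columns ``subject_id, path_low, path_high, label, seed``; labels are
the strings ``NC``/``AD``, mapped internally to 0/1.  The run configuration
is a single schema-validated document (YAML or JSON) whose unknown keys are
rejected by name.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import pydantic
import yaml

from .phantom import PhantomSpec, make_cohort, write_cohort
from .preprocess import PreprocessConfig
from .quality import fit_niqe_model, quality_report, rescale_to_255, center_slice_index
from .train import (
    LossWeights,
    TrainConfig,
    prepare_cohort,
    split_cohort,
    test_scores,
    train_joint,
    train_simple,
)
from .evaluate import classification_report
from .types import FieldganError, LABEL_CODES, PhantomPair, Volume

logger = logging.getLogger("fieldgan")


def read_volume(path: str | Path) -> Volume:
    """Load a NIfTI-1/2 file as a Volume (voxel order (x, y, z), 0-based)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such volume file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # corrupt file
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    return Volume(np.asarray(img.dataobj, dtype=np.float64), img.affine)


def write_volume(vol: Volume, path: str | Path, *, overwrite: bool = False) -> None:
    """Write a Volume as float32 NIfTI-1, preserving the affine."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise IOError(f"refusing to overwrite existing file {path} (pass overwrite=True)")
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    nib.save(img, str(path))


def read_manifest(path: str | Path) -> list[PhantomPair]:
    """Load a cohort manifest and the volumes it references.

    The returned pairs carry ``true_mask = high - low``; rows without a
    high-field path get a zero mask (classification-only cohorts).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such manifest: {path}")
    df = pd.read_csv(path, dtype={"subject_id": str, "label": str})
    if df["subject_id"].duplicated().any():
        raise FieldganError("manifest subject_ids must be unique")
    root = path.parent
    pairs = []
    for row in df.itertuples():
        if row.label not in LABEL_CODES:
            raise FieldganError(
                f"unknown label {row.label!r}; expected one of {sorted(LABEL_CODES)}"
            )
        low = read_volume(root / row.path_low)
        if isinstance(row.path_high, str) and row.path_high:
            high = read_volume(root / row.path_high)
        else:
            high = low.with_data(low.data.copy())
        pairs.append(
            PhantomPair(
                subject_id=row.subject_id,
                low=low,
                high=high,
                label=LABEL_CODES[row.label],
                true_mask=low.with_data(high.data - low.data),
            )
        )
    return pairs


class RunConfig(pydantic.BaseModel):
    """Every pipeline hyperparameter in one validated document."""

    model_config = pydantic.ConfigDict(extra="forbid")

    # phantom
    n_per_class: int = 10
    grid_size: int = 96
    noise_sigma_low: float = 0.15
    noise_sigma_high: float = 0.02
    contrast_gain_high: float = 1.1
    ventricle_radius_control: float = 6.0
    ventricle_radius_disease: float = 10.0
    # preprocessing
    shell_threshold: float = 0.5
    connectivity: int = 6
    # training
    mode: str = "joint"  # "joint" or "simple"
    epochs: int = 5
    steps_per_epoch: int = 40
    batch_size: int = 4
    patch_side: int = 47
    lr: float = 2e-4
    w_adv: float = 1.0
    w_l1: float = 10.0
    w_cls: float = 1.0
    gen_channels: tuple[int, int, int] = (16, 16, 1)
    disc_channels: tuple[int, ...] = (8, 16, 32, 64, 1)
    clf_channels: tuple[int, ...] = (8, 16, 32)
    n_patches_eval: int = 20
    threshold: float = 0.5
    # quality
    niqe_patch_size: int = 32
    seed: int = 0

    def phantom_spec(self) -> PhantomSpec:
        return PhantomSpec(
            grid_size=self.grid_size,
            noise_sigma_low=self.noise_sigma_low,
            noise_sigma_high=self.noise_sigma_high,
            contrast_gain_high=self.contrast_gain_high,
            ventricle_radius_by_class={
                "control": self.ventricle_radius_control,
                "disease": self.ventricle_radius_disease,
            },
            seed=self.seed,
        )

    def preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(
            shell_threshold=self.shell_threshold, connectivity=self.connectivity
        )

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            steps_per_epoch=self.steps_per_epoch,
            batch_size=self.batch_size,
            patch_side=self.patch_side,
            lr=self.lr,
            loss_weights=LossWeights(self.w_adv, self.w_l1, self.w_cls),
            gen_channels=self.gen_channels,
            disc_channels=self.disc_channels,
            clf_channels=self.clf_channels,
            n_patches_eval=self.n_patches_eval,
            threshold=self.threshold,
            seed=self.seed,
        )


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML/JSON config; defaults fill missing keys, unknown keys fail."""
    doc: dict = {}
    if path is not None:
        text = Path(path).read_text()
        doc = yaml.safe_load(text) or {}
        if not isinstance(doc, dict):
            raise FieldganError(f"config root must be a mapping, got {type(doc)}")
    doc.update(overrides)
    try:
        cfg = RunConfig(**doc)
    except pydantic.ValidationError as exc:
        bad = ", ".join(str(e["loc"][0]) for e in exc.errors())
        raise FieldganError(f"invalid config key(s): {bad}") from exc
    logger.info("resolved config: %s", cfg.model_dump())
    return cfg


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """simulate -> preprocess -> train -> generate -> quality -> evaluate.

    Writes every artifact under ``out_dir`` (resolved config, cohort,
    checkpoints, histories, reports) and returns the report dictionary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(cfg.model_dump(), default=list, indent=2))

    def stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        stage("simulate")
        spec = cfg.phantom_spec()
        pairs = make_cohort(spec, cfg.n_per_class, cfg.seed)
        write_cohort(pairs, out / "cohort", seed=cfg.seed)
    except Exception as exc:
        raise FieldganError(f"stage 'simulate' failed: {exc}") from exc

    try:
        stage("preprocess")
        prepared = prepare_cohort(pairs, cfg.preprocess_config())
    except Exception as exc:
        raise FieldganError(f"stage 'preprocess' failed: {exc}") from exc

    try:
        stage("train")
        split = split_cohort(pairs, seed=cfg.seed)
        tcfg = cfg.train_config()
        train_fn = train_joint if cfg.mode == "joint" else train_simple
        result = train_fn(prepared, split, tcfg)
        result.step_log.to_csv(out / "step_log.csv", index=False)
        result.epoch_log.to_csv(out / "epoch_log.csv", index=False)
        from .nets import save_bundle

        save_bundle(result.bundle, out / "checkpoint.npz")
    except FieldganError:
        raise
    except Exception as exc:
        raise FieldganError(f"stage 'train' failed: {exc}") from exc

    try:
        stage("generate+quality")
        from .nets import generate_volume

        by_id = {s.subject_id: s for s in prepared}
        pristine = []
        for s in prepared:
            z = center_slice_index(s.brain_mask)
            pristine.append(rescale_to_255(s.high.data[:, :, z]))
        niqe_model = fit_niqe_model(pristine, patch_size=cfg.niqe_patch_size)
        niqe_model.to_json(out / "niqe_model.json")
        rows = []
        for sid in split.test:
            s = by_id[sid]
            gen = generate_volume(result.bundle.generator, s.low)
            write_volume(gen, out / f"{sid}_generated.nii", overwrite=True)
            for tag, vol in (("low", s.low), ("high", s.high), ("generated", gen)):
                rep = quality_report(
                    vol, niqe_model, mask=~s.brain_mask, scan_id=f"{sid}_{tag}"
                )
                rows.append(
                    {"subject_id": sid, "volume": tag, "snr": rep.snr,
                     "niqe": rep.niqe, "slice_index": rep.slice_index}
                )
        quality_df = pd.DataFrame(rows)
        quality_df.to_csv(out / "quality.csv", index=False)
    except FieldganError:
        raise
    except Exception as exc:
        raise FieldganError(f"stage 'generate+quality' failed: {exc}") from exc

    try:
        stage("evaluate")
        rng = np.random.default_rng(cfg.seed + 7)
        scores, labels = test_scores(result, prepared, split, tcfg, rng)
        report = classification_report(scores, labels, cfg.threshold)
        report_dict = {
            "classification": report.__dict__,
            "quality_mean": quality_df.groupby("volume")["snr"].mean().to_dict(),
            "best_val_snr": result.best_val_snr,
            "best_val_accuracy": result.best_val_accuracy,
            "seed": cfg.seed,
        }
        (out / "report.json").write_text(json.dumps(report_dict, indent=2))
    except FieldganError:
        raise
    except Exception as exc:
        raise FieldganError(f"stage 'evaluate' failed: {exc}") from exc
    return report_dict
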