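# fieldgan

**GAN-based field-strength translation and patch-wise classification for 3D
brain MRI, with synthetic phantoms that make every stage testable.**

Structural MRI acquired at 1.5 T is noisier and lower-contrast than the same
anatomy scanned at 3 T, and downstream analyses (for example automated
dementia classification) suffer for it.  `fieldgan` implements a
conditional-adversarial approach to this problem: a **residual generator**
*G* maps a lower-field volume *x* to a learned **transformation mask**
*M = G(x)*, so that the generated volume

&nbsp;&nbsp;&nbsp;&nbsp;*x\* = x + M*

approximates the higher-field scan *y* of the same subject.  *G* is trained
jointly with a fully convolutional **discriminator** *D* (real *y* vs
generated *x\**) and a patch-wise fully convolutional **classifier** *C*
(disease vs control on *x\**), minimizing

&nbsp;&nbsp;&nbsp;&nbsp;L = w_adv·L_adv(D, x\*) + w_L1·‖x\* − y‖₁ + w_cls·CE(C(x\*), label)

with the classification gradient flowing back into the generator, so the
translation is shaped by diagnostic information, not just image fidelity.
Training is patch-wise (47³ patches by default) on same-subject volume pairs
that are already linearly registered to a common template.

Since paired clinical scans cannot ship with a package, the `phantom` module
generates paired ellipsoid head phantoms — bright scalp shell, cortical and
white-matter compartments, and a class-dependent ventricle — whose
low-/high-field difference (the true transformation mask) is known exactly.
All properties of the method (mask recovery, SNR improvement, classifier
accuracy) are demonstrated and tested on these phantoms.

The package also provides the surrounding pipeline the method needs:

* `preprocess` — z-score intensity normalization, corner-seeded depth-first
  background removal blocked by the scalp signal, outlier clipping to
  [−1, 2.5];
* `patches` — uniform paired patch sampling and subject-level score
  aggregation;
* `quality` — center-slice SNR, BRISQUE (MSCN/AGGD) feature extraction and
  full NIQE fitting and scoring;
* `evaluate` — sensitivity-specificity and precision-recall AUCs, F1, MCC,
  and t-based 95% confidence intervals over repeated runs;
* `io`/`cli` — NIfTI I/O, CSV cohort manifests, validated YAML configs and a
  thin command-line interface (`fieldgan simulate|preprocess|train|...|run`).

The networks run on a compact numpy engine with hand-written
backpropagation (`fieldgan.nn`), verified against finite differences; no GPU
or deep-learning framework is required.

## Worked example

```bash
python examples/03_train_joint.py
```

trains the joint model on a 16-subject phantom cohort (48³ grids, 31³
patches, narrow channels) and prints:

```
split: 10 train / 3 val / 3 test
 epoch  val_snr  val_accuracy
     0 1.330134      0.666667
     1 1.372254      0.666667
     2 1.399931      0.666667
     3 1.416395      1.000000
     4 1.435963      1.000000
     5 1.474383      1.000000
best val SNR 1.474, best val accuracy 1.00
  S0005 (1): SNR 1.00 -> 1.07, disease score 0.49
  S0007 (1): SNR 1.04 -> 1.12, disease score 0.57
  S0010 (0): SNR 1.33 -> 1.51, disease score 0.24
```

Validation SNR of the generated volumes climbs epoch by epoch as the
generator learns to remove the simulated low-field noise, and validation
accuracy reaches 1.0 once the classifier picks up the ventricle-size
signal.  On the three held-out subjects the center-slice SNR rises from the
noisy input to the generated volume, and the subject-level disease scores
(mean classifier probability over 20 random patches) rank the enlarged-
ventricle subjects (label 1) above the control.  The other
examples (`examples/01...05`) demonstrate phantom simulation,
preprocessing, the quality metrics and the evaluation utilities in the same
way.

## Layout

```
src/fieldgan/    phantom, preprocess, patches, nets, train, quality,
                 evaluate, io, cli, nn (numpy conv-net engine)
examples/        one short narrative script per capability
tests/           pytest suite (unit, property and end-to-end checks)
scripts/         acceptance.py
docs/methods.md  models, parameters, numerical choices, limitations
```
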