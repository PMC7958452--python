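"""No-reference image quality on phantom slices: SNR and NIQE.

A pristine NIQE model is fitted from clean anatomy slices; adding noise to
a slice moves its natural-scene statistics away from the model, raising the
score (lower = better quality).
"""

import numpy as np

from fieldgan import PhantomSpec, fit_niqe_model, make_anatomy, niqe_score
from fieldgan.quality import rescale_to_255

spec = PhantomSpec()  # 96-voxel grid
slices = [
    make_anatomy(spec, "control", np.random.default_rng(s)).data[:, :, 48]
    for s in range(12)
]
model = fit_niqe_model([rescale_to_255(s) for s in slices], patch_size=24)
print(f"pristine model: {model.mean.size}-dim features, "
      f"{model.patch_size}-pixel tiles")

rng = np.random.default_rng(0)
sl = slices[0]
for sd in (0.0, 0.1, 0.3):
    noisy = sl + rng.normal(0, sd, sl.shape) if sd else sl
    print(f"  noise SD {sd:.1f}: NIQE {niqe_score(rescale_to_255(noisy), model):8.2f}")
# scores increase with distortion: the clean slice sits closest to the model
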