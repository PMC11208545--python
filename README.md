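# ecggen

Conditional transformer-GAN synthesis of ECG heartbeats for rebalancing
arrhythmia datasets.

## The problem

Beat-level arrhythmia datasets are dominated by normal beats; clinically
critical classes — atrial premature beats (A), premature ventricular
contractions (V), left/right bundle-branch-block beats (L/R) — can be a few
percent of the data, and classifiers trained on them quietly lose recall on
exactly the beats that matter.  `ecggen` attacks this with a conditional
generative model: learn a reversible mapping between 300-sample heartbeat
windows and a low-dimensional latent sequence, train a class-conditioned
generator adversarially in that space, synthesize beats for the scarce
classes, and admit them into training data only if they demonstrably improve
a reference classifier.

The pipeline covers:

- **WFDB I/O** — reading annotated records (`.hea`/`.dat`/`.atr`, signal
  formats 212 and 16) with beat-symbol filtering, plus HDF5/CSV beat
  datasets;
- **wavelet denoising** — db5, 9 levels, soft thresholding at the universal
  threshold λ = σ√(2 ln N) with σ = MAD/0.6745 pooled over detail subbands;
- **segmentation** — windows of 100 samples before / 200 after each
  annotated R-peak, class mapping, strided downsampling, imbalance reports,
  stratified and K-fold splits;
- **the generative model** — encoder, decoder, generator and discriminator,
  each a multi-scale-convolution + multi-head-attention transformer block,
  trained in three phases (autoencoding → class-conditional latent moment
  matching → adversarial with a 2:1 generator:discriminator schedule) and
  sampled class-conditionally;
- **metrics** — PRD, discrete Fréchet distance, RMSE, MAE for generation
  fidelity; precision/recall/F1 (macro-averaged, confusion matrix) for
  classification; augmentation ratios;
- **a classifier harness** — PCA front end into a 1-D residual network —
  and the screening loop that accepts synthetic batches only when held-out
  macro F1 strictly improves;
- **a synthetic fixture generator** so the whole pipeline runs and is tested
  without any data download.

## Worked example

Train the desk-scale model on a synthetic imbalanced fixture and synthesize
scarce atrial-premature beats:

```python
import numpy as np
from ecggen.simulate import make_imbalanced_dataset, nearest_template_labels
from ecggen.segmentation import downsample
from ecggen.networks import GANConfig
from ecggen.training import fit, generate_scarce
from ecggen.metrics import prd

ds = downsample(make_imbalanced_dataset(
    {"N": 120, "A": 40, "V": 50, "L": 50, "R": 40}, seed=11), 3)
model, state = fit(ds, GANConfig.desk(), epochs=30, seed=11)
print(f"reconstruction loss {state.history['reconstruction'][0]:.3f} "
      f"-> {state.history['reconstruction'][-1]:.3f}")

names = list(ds.class_names)
templates = np.stack([ds.beats[ds.labels == c].mean(axis=0) for c in range(5)])
synth = generate_scarce(model, {n: 30 for n in names}, names, seed=12)
gen_prd = np.mean([prd(templates[c], b)
                   for b, c in zip(synth.beats, synth.labels)])
acc = (nearest_template_labels(synth.beats, templates) == synth.labels).mean()
print(f"PRD vs class templates {gen_prd:.1f}%  conditioning accuracy {acc:.2f}")
```

Output (seed 11):

```
reconstruction loss 1.494 -> 0.046
PRD vs class templates 11.5%  conditioning accuracy 1.00
```

The reconstruction loss falling ~30× means the encoder/decoder pair has
learned the beat manifold; PRD of 11.5% against the class-mean templates
says generated beats lie close to the morphology of their class (Gaussian
noise scores ~140% on the same reference); conditioning accuracy 1.00
against 0.20 chance means the requested class label fully controls the
generated morphology.

The same stages are available from the shell:

```sh
ecggen simulate --counts N=300,A=12,V=40,L=25,R=15 --seed 7 \
    --out beats.h5 --wfdb-out rec
ecggen denoise --record rec --out rec_dn --report snr.csv
ecggen segment --record rec_dn --interval 3 --out beats.h5
ecggen train --data beats.h5 --epochs 30 --seed 7 --out ckpt/
ecggen generate --ckpt ckpt/ --data beats.h5 --counts A=100 --seed 7 --out synth.h5
ecggen evaluate --real beats.h5 --synth synth.h5
ecggen run --config pipeline.json      # the whole chain + manifest
```

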