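# octl — label-free OCT lymphangiography

Lymphatic vessels and aqueous veins carry optically transparent fluid, so
they show up in OCT scans of the eye as tubes of markedly *low* signal —
the opposite contrast of OCT angiography. This package segments them from
3-D log-intensity OCT volumes two ways:

- **Conventional OCTL** — a physics-based pipeline: the axial system
  response (confocal function x sensitivity roll-off) is removed using a
  calibration scan of a homogeneous phantom, every A-scan is fitted to the
  single-scattering model `I(z) = I0 · H(z) · exp(−2µz)` (a line in dB vs
  depth, so `µ = −slope·ln10/20`), the fitted decay is compensated back,
  and a constant dB threshold below the Canny-detected tissue surface
  yields a binary vessel mask. The mask and the intensity volume are
  surface-flattened and cropped to the superficial ~500 µm.
- **DL-OCTL** — a U-Net (encoder widths 32/64/128/256, paired 3×3
  convolutions, 2×2 max pooling and up-convolutions, skip connections,
  1×1 final layer to 2 classes) trained on the conventional masks with
  Dice loss and Adam (lr 1e−4), segmenting 8-bit B-scans directly. The
  network and its training loop are implemented in numpy with explicit
  backpropagation.

Agreement and abundance are quantified per B-scan by Intersection over
Union (mean ± SD over a volume) and by vessel area/volume density; en face
projections (binary or weighted by the reversed signal) visualize the
vessel network. Since the original porcine-eye scans are not public, a
synthetic speckle-phantom generator with geometric ground truth
(`octl.phantom`) makes every stage testable, including the superficial
low-signal layer that breaks the depth-homogeneity assumption of the
attenuation fit and causes the conventional method's characteristic
superficial artifacts.

Intended users: researchers in OCT image analysis who want a reproducible,
dependency-light reference implementation of attenuation-compensated
vessel thresholding and of its learned replacement.

## Worked example

```python
from octl.pipeline import run_scaled_study

study = run_scaled_study(seed=1)
print(f"label IOU vs geometric truth : {study['label_iou_vs_truth']:.3f}")
print(f"epochs to convergence        : {study['epochs_run']}")
print(f"final train loss / mean IOU  : "
      f"{study['train_loss'][-1]:.3f} / {study['train_acc'][-1]:.3f}")
print(f"held-out mean IOU vs labels  : {study['heldout_mean_iou']:.3f}")
print(f"superficial FP, conv vs DL   : "
      f"{study['superficial_fp_conv']:.4f} vs {study['superficial_fp_dl']:.4f}")
```

prints (about five minutes on one CPU):

```
label IOU vs geometric truth : 0.929
epochs to convergence        : 49
final train loss / mean IOU  : 0.050 / 0.910
held-out mean IOU vs labels  : 0.834
superficial FP, conv vs DL   : 0.0697 vs 0.0004
```

Reading: the conventional labels capture the true vessel geometry well
(IOU 0.93); the U-Net converges to near-zero Dice loss within ~50 epochs
and reproduces the conventional segmentation on a held-out volume (mean
IOU 0.83 across its B-scans); on a phantom with a 10 dB superficial layer
the conventional method mislabels a large superficial area (its fit
assumes depth-homogeneous tissue) while the network, trained on clean
labels only, does not.

The same flow is scriptable from the shell:

```bash
octl simulate --seed 1 --out data/
octl conventional --volume data/phantom_train.tif \
    --calibration data/calibration.tif --out data/labels.tif
octl train --volume data/labels.tif.aligned.tif --labels data/labels.tif \
    --seed 1 --out data/model.ckpt.npz
octl predict --model data/model.ckpt.npz \
    --volume data/labels.tif.aligned.tif --out data/mask_dl.tif
octl metrics --a data/mask_dl.tif --b data/labels.tif --out data/report.json
octl run --seed 1 --out run/          # everything end to end
```

Volumes travel as multi-page float32 TIFF stacks (one page per B-scan)
with JSON sidecars; masks as 8-bit 0/1 TIFF; raw interferograms as HDF5.
A YAML config (schema-validated; unknown keys rejected) drives `octl run`.

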