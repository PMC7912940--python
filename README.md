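# msbrainseg

Multiscale three-pathway CNN for pixel-wise brain-tumor segmentation and
slice-level tumor-type classification of 2D contrast-enhanced MRI slices.

## What this package does

Given a single T1-CE MRI slice, the method classifies **every pixel** from its
65 × 65 neighborhood into one of four labels — healthy, meningioma, glioma,
pituitary tumor — using a CNN that processes each window in three parallel
convolutional pathways at different kernel scales (11 × 11, 7 × 7, 3 × 3 with
128, 96, 64 feature maps).  The pathway features are concatenated, reduced by
a 3 × 3 convolution, and fed through a dropout-regularized fully connected
softmax head; the reference configuration has exactly **2,856,932** trainable
parameters.  No skull stripping is performed: the model sees — and must learn
to reject — bright non-cerebral structures.

The per-pixel label map P is then reduced to a slice-level tumor-type call by
the classification function

    f_l  = |{P = l}| / |{P > 0}|,        l ∈ {1, 2, 3}
    l_p  = argmax { f_l : f_l > τ_c },   or −1 (non-classified) if none survive

where τ_c is a confidence threshold.  Segmentation quality is scored per slice
against the expert mask T with P1 = {P = l_gt}:

    Dice        = 2·TP / (2·TP + FP + FN)
    Sensitivity = TP / (TP + FN)
    pttas       = |P1| / |{P > 0}|       (precision of the predicted type)

The package provides the full pipeline — elastic-deformation augmentation,
150/325 tumor/healthy window sampling, global pixel standardization, SGD
training with the published 80-epoch schedule, sliding-window inference,
confusion-matrix/threshold-curve evaluation, and overlay rendering — plus a
**seeded phantom generator** that emulates the real dataset's record
structure (image, class label, binary mask, border polyline, patient id) so
every stage is exercisable without downloading anything.  The real dataset's
HDF5 per-slice containers (a `cjdata` group with `pid`, `label`, `image`,
`tumorBorder`, `tumorMask`) are read natively and drop in unchanged.

It is written for researchers who want a tested, inspectable reference
implementation of this family of sliding-window multiscale classifiers — the
network is pure NumPy with explicit forward and backward passes, so every
design detail (ceiling-mode pooling, padding, tie-breaks, the parameter
budget) is visible and unit-tested rather than hidden behind a framework.

## Worked example

Train and evaluate the scaled-down profile (60 phantom slices at 128 px, a
[16, 12, 8]-map toy network, 10 epochs, stride-8 inference — about two
minutes on one CPU):

```python
from msbrainseg.phantom import generate_dataset
from msbrainseg.dataset_io import make_stratified_folds
from msbrainseg.profiles import desk_profile
from msbrainseg.train import run_cross_validation, aggregate_report

profile = desk_profile(seed=1)
records = generate_dataset(profile.phantom)            # 60 slices, 20 per class
folds = make_stratified_folds([r.label for r in records],
                              [r.pid for r in records], k=5, seed=1)
results = run_cross_validation(records, folds, profile.network, profile.train,
                               profile.elastic, tau_c=profile.tau_c,
                               stride=profile.stride)
report = aggregate_report(results)
print("accuracy:", round(report.confusion.accuracy, 3))
print(report.confusion.confusion)
```

Output:

```
accuracy: 0.867
[[14  0  6]
 [ 0 20  0]
 [ 2  0 18]]
```

The 3 × 3 matrix counts slices by (true class × predicted class) over all five
test folds; the accuracy is the diagonal sum over all 60 slices (with τ_c = 0
no slice is left non-classified).  Row/column order is meningioma, glioma,
pituitary: the two bright-lesion classes (1 and 3) account for all the
confusions, while the heterogeneous glioma-like class is never missed —
mirroring, at phantom scale, the published observation that meningioma
detection is the most demanding.

The same experiment is scriptable from the shell, with the network and
schedule described by a YAML file:

```yaml
# profile.yaml
network: {window_size: 13, pathway_kernels: [5, 3, 3], pathway_maps: [16, 12, 8],
          concat_maps: 24, dropout_rate: 0.25}
train:   {epochs: 10, lr0: 0.01, batch_size: 64, n_pos: 20, n_neg: 45}
elastic: {alpha: 12.8, sigma: 2.56}
```

```bash
msbrainseg generate --out data/ --n-per-class 20 --image-size 128 --seed 1
msbrainseg train    --data data/ --out ckpt/   --config profile.yaml --seed 1
msbrainseg evaluate --data data/ --checkpoints ckpt/ --out report/ --tau-c 0 --stride 8
```

which writes `report/report.{json,csv}` and a threshold–precision sweep
`report/threshold_curve.csv`.

The architecture itself can be checked in one line:

```python
>>> from msbrainseg.network import NetworkConfig, count_parameters
>>> count_parameters(NetworkConfig())
2856932
```

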