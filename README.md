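# afmsnet

Volumetric brain-lesion segmentation with adaptive attention encoders,
implemented end-to-end in NumPy and exercisable entirely on synthetic
3-D lesion phantoms — no clinical data or GPU required.

## Who this is for

Researchers and engineers who need a fully inspectable, CPU-runnable
reference implementation of an attention-augmented 3-D encoder–decoder
segmentation network: every block, the loss, and every evaluation
metric is verified against an independent brute-force oracle in the
test suite, and a seeded phantom generator stands in for datasets such
as multi-modal brain-tumor or stroke-lesion MRI.

## The model

Two interchangeable encoder units drive a U-shaped 3-D network:

* **SAEB** — squeeze-and-excitation channel attention with a *softmax*
  channel distribution: conv3×3×3 → BN → GAP → 1×1×1 reduce/restore
  (ratio r) → softmax over channels → rescale → ReLU. Cheaper in
  parameters.
* **DAEB** — dual attention: the conv output T is rescaled in parallel
  by a sigmoid channel map (GAP → reduce/restore → σ) and a sigmoid
  spatial map (channel max/avg-pool concat → 7×7×7 conv → σ), and the
  two rescaled tensors are summed. Heavier, finer-grained.

Skip connections pass through **SegPath**: n parallel iterations of
ReLU(BN(conv1×1×1)) + ReLU(BN(conv3×3×3)) accumulated by addition,
bridging the encoder–decoder semantic gap. Decoding uses stride-2
transpose convolutions, skip concatenation and conv refinement, ending
in a 1×1×1 softmax head over K classes.

Training minimizes `L_total = L_dice + L_focal`,

    L_dice  = 1 − (2 Σ_c Σ_i w_c G_ci P_ci + ε) / (Σ w_c G_ci + Σ w_c P_ci + ε)
    L_focal = − Σ_c Σ_i G_ci log(P_ci) (1 − P_ci)^γ        (γ = 1)

with Adam (lr 1e-4, L2 kernel penalty 5e-4). Evaluation reports
accuracy, precision, recall, DSC, IoU and the average Hausdorff
distance AHD(P, L) = ½[mean_p min_l d(p,l) + mean_l min_p d(p,l)] at
binarization threshold 0.5, per class and per nested region
(WT/TC/ET), macro and micro. See `docs/methods.md` for the full
account.

## Worked example

Train the miniature SAEB network on one seeded 32³ two-channel phantom
and evaluate it against its own ground truth:

```python
import tempfile
import afmsnet as af
from afmsnet.train import TrainConfig, train, evaluate

spec = af.PhantomSpec(grid=(32, 32, 32), n_channels=2, n_lesions=(1, 1),
                      radii=(6.0, 9.0), nested_classes=(1,),
                      shell_fractions=(1.0,), noise_sd=0.1, seed=7)
manifest = af.generate_dataset(spec, 1, tempfile.mkdtemp())

cfg = TrainConfig(epochs=150, seed=1, patience=10**9, label_remap={0: 0, 1: 1},
                  network=af.NetworkSpec(variant="SAEB", n_stages=2,
                                         base_channels=4,
                                         segpath_iterations=[1, 1],
                                         n_classes=2, input_channels=2))
net, hist = train(cfg, manifest)
report, agg = evaluate(net, manifest, cfg)
```

This prints (per-epoch logging at INFO level), after 150 epochs on one
CPU core:

```
epoch   1: train loss 8819.3  Dice 0.076
epoch 150: train loss 4369.4  Dice 0.619
   name  accuracy  precision  recall   dsc  iou   ahd         case
class_1     0.957       0.48   0.841 0.612 0.44 2.119 phantom_0000
```

The loss falls by half and the lesion Dice rises from 0.08 to 0.62
after 150 steps; the average Hausdorff distance of 2.1 voxels says the
predicted boundary is on average two voxels off. Run longer (about 500
epochs) and the same configuration overfits the phantom past Dice 0.9
— the capacity benchmark in the acceptance suite does exactly that.
This miniature network has 14,989 trainable parameters; the DAEB
variant of the same shape has more (the spatial-attention convolution
dominates), and the test suite asserts this ordering across the
configuration grid.

## Command line

```bash
afms synth --config run.yaml --n-volumes 10 --out data/
afms train --config run.yaml --manifest data/manifest.csv --out runs/exp1
afms predict --checkpoint runs/exp1/checkpoint.npz --image vol.nii.gz --out-labels seg.nii.gz
afms eval  --config run.yaml --checkpoint runs/exp1/checkpoint.npz \
           --manifest data/manifest.csv --out runs/exp1/eval
```

The YAML config mirrors the library dataclasses (`phantom`, `network`,
`loss`, `train`, `regions`); every run writes a manifest with the
config hash and seed beside its outputs.

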