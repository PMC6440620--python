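# bhcnet

Small squeeze-and-excitation (SE) residual networks with an erf-shaped
learning-rate scheduler, plus a self-contained NumPy training and
evaluation stack for histopathology-style image classification.

The package provides:

* **`bhcnet.schedulers`** — closed-form per-epoch learning-rate schedules:
  the erf (Gauss error) schedule, step schedules (explicit changepoints or
  derived from a single ratio `R`), cosine and exponential comparators.
* **`bhcnet.se_blocks`** — the SE block pipeline (squeeze / excitation /
  recalibration / residual sum) as pure array functions, and three
  trainable residual module variants (`basic` 3×3+3×3, `bottleneck`
  1×1+3×3+1×1(×4), `small` with factorized 1×3/3×1 convolution pairs),
  with an explicit-loop reference implementation used as a test oracle.
* **`bhcnet.param_accounting`** — analytic convolution-weight counts
  (18C², 17C², 12C² per module kind) and itemized audits of built
  networks against them.
* **`bhcnet.architectures`** — declarative specs and builders for the
  `se_resnet-{18,26,34,50,66}` family (32×32 inputs) and `bhcnet-N`
  (three blocks of N small modules at widths 16/32/64).
* **`bhcnet.data`** — dataset indexing for the standard
  `class/subtype/patient/magnification` histology layout (8 subtypes,
  4 magnifications), stratified train/test splitting, zero-mean/unit-std
  preprocessing, shift+flip augmentation, and a seeded synthetic dataset
  generator whose two classes differ in texture statistics.
* **`bhcnet.train_eval`** — Nesterov-momentum SGD with the per-epoch
  scheduler contract, the training loop, and evaluation (confusion
  matrix, accuracy, macro precision/recall/F-measure, MCC, macro
  one-vs-rest AUC).

The neural-network core (convolution, batch norm, SE gating, pooling,
backprop) is implemented in NumPy in `bhcnet.nn` — no deep-learning
framework is required.

## CLI

```sh
bhcnet generate-data --out data/ --count 10 --image-size 32   # synthetic dataset
bhcnet schedule --type erf --epochs 300                        # per-epoch LR CSV
bhcnet count-params --arch bhcnet-3                            # parameter audit
bhcnet train --data-root data/ --arch bhcnet-1 --image-size 32 \
             --epochs 20 --out runs/demo                       # train + evaluate
bhcnet evaluate --data-root data/ --weights runs/demo/weights.npz \
             --arch bhcnet-1 --image-size 32 --out eval.json
```

Scheduler and training options can also be supplied through a flat YAML
config (`--config`), with keys such as `type`, `lr_max`, `lr_min`,
`alpha`, `beta`, `epochs`, `R`, `lambda`, `batch_size`, `momentum`,
`weight_decay`.

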