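# gppwvgg

Lightweight VGG11-derived convolutional networks for classifying crop
varieties from field canopy images, built for CPU- and mobile-scale budgets.

Distinguishing wheat (or other crop) varieties from top-down canopy
photographs is hard: the morphological differences between varieties are
subtle, and the models accurate enough to separate them are usually far too
large to deploy on a phone in a field. This package implements a family of
progressively lightened VGG11 variants — ending in **G-PPW-VGG11**, a
~0.47 M-parameter (1.79 MiB) network — together with exact parameter/MAC
budget accounting, the dataset protocol (augmentation, stratified splits,
mobile preprocessing), a seeded synthetic canopy-image generator, and a
training/evaluation harness with a scikit-learn style classifier.

## The model family

Starting from classic VGG11 (configuration A), the family applies four
cumulative modifications, each available as a preset:

| preset        | change over the previous                         | options |
|---------------|--------------------------------------------------|---------|
| `vgg11`       | baseline: 8 conv stages, three FC layers (4096)  | —       |
| `re_vgg11`    | channel plan 32,64,64,64,128,128,256,256; FC 1024; BN | — |
| `scheme1`     | partial convolution (PConv) in stages 2–8        | a       |
| `scheme2`     | FL2PWConv head: two 1×1 convs + global avg pool  | a b     |
| `scheme3`     | mixed-kernel partial conv (PMConv) in stages 7–8 | a b c   |
| `g_ppw_vgg11` | efficient channel attention (ECA) after every stage | a b c d |

The bespoke operators:

* **PConv** — convolve only the first `cp = ⌊r·C⌋` channels (r = 1/4) with a
  k×k kernel, pass the rest through, then mix all channels with a 1×1
  convolution. Attacks inter-channel feature redundancy at a fraction of the
  dense cost.
* **PMConv** — the `cp` subset is split into contiguous near-equal groups,
  each convolved with a different odd kernel (3/5/7), then concatenated and
  pointwise-mixed: partial convolution with mixed receptive fields.
* **ECA** — per-channel global average pool, a k-wide 1-D convolution across
  the channel axis, sigmoid gate. The kernel width adapts to the channel
  count: `k = |log2(C) + b| / γ` rounded to the nearest odd integer
  (γ = 2, b = 1), clamped below at 3. Adds only k ≈ 3–5 weights per block.
* **FL2PWConv head** — `PW(256→1024) → ReLU → PW(1024→K) → GAP` replaces the
  three fully connected layers, which hold 92% of the reduced baseline's
  parameters.

Evaluation uses the confusion matrix: accuracy `ACC = (TP+TN)/(TP+FP+TN+FN)`,
precision `P = TP/(TP+FP)`, recall `R = TP/(TP+FN)`, `F1 = 2PR/(P+R)`
(one-vs-rest per class, macro-averaged), macro one-vs-rest AUC, and the
relative-reduction rule `(x − x1)/x` for comparing inference time, memory
and complexity between a baseline and an improved model.

## Worked example

Model budgets are computed by tensor enumeration (memory = parameter count
× 4 bytes, in binary MiB):

```sh
$ gppw budget --model g_ppw_vgg11
{
  "model": "g_ppw_vgg11",
  "total_params": 469556,
  "param_memory_mib": 1.79,
  "macs_m": 192.92,
  "head_params": 268288,
  "head_fraction_pct": 57.14,
  "mac_convention": "macs+bias_adds+activations"
}

$ gppw compare --a vgg11 --b g_ppw_vgg11 --metric params
{
  "metric": "params",
  "baseline": "vgg11",
  "improved": "g_ppw_vgg11",
  "x": 128790918,
  "x1": 469556,
  "reduction_pct": 99.64
}
```

The final model keeps 0.36% of the baseline's 128.8 M parameters
(491.3 MiB → 1.79 MiB). From Python, the same pipeline end to end on
synthetic canopy images:

```python
import gppwvgg as g

X, y = g.generate_arrays(g.SyntheticSpec(num_classes=6, n_per_class=50,
                                         size=64, seed=1, difficulty="easy"))
tr, te = g.split_dataset(y, g.SplitSpec(seed=1))          # stratified 60/40
clf = g.CanopyClassifier(preset="g_ppw_vgg11", input_size=32,
                         epochs=12, batch_size=32, seed=1)
clf.fit(X[tr], y[tr])
print(clf.score(X[te], y[te]))                            # 1.0
```

which prints `1.0`: the six synthetic classes (distinct stripe orientation,
frequency and hue) are fully separated after a dozen desk-scale epochs.
Real field images are harder — see `docs/methods.md` for what the synthetic
benchmark does and does not show.

The CLI also provides `synth`, `train`, `eval`, `cv`, `summarize` and
`preprocess`; run `gppw --help`.

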