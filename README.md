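# stackseg

Cell segmentation from **hyper-labeled microscope stacks** via
**loading codes**.

## The problem

Automated cell segmentation is usually trained against one fixed
labeling strategy — a particular fluorescent marker, or label-free
brightfield.  That makes strategies hard to compare (each lives on its
own dataset) and leaves models brittle when labeling is inconsistent:
a model trained on perfectly labeled cells collapses the moment a marker
is missing.  Because microscope channels are independent co-registered
images, a subset of channels from a richer source stack is itself a
valid microscope image — so one *hyper-labeled* dataset (three
fluorescence markers: cytoplasm `cyto`, membrane `mem`, mitochondria
`mito`, plus brightfield planes at focal offsets −10…+10 µm) can stand
in for many labeling conditions.

`stackseg` implements that methodology end to end:

* a **synthetic microscopy simulator** producing hyper-labeled stacks
  with cytoplasmic fill, membrane rims, interior mitochondrial speckle,
  defocus-sign-dependent brightfield edge rims, touching neighbors, and
  cell-free negatives — so the whole pipeline is testable without
  external data;
* **loading codes** — per-channel assembly instructions (simple load,
  random choice, merge, channel dropout, merge dropout) that build each
  3-channel training input from a stack at load time;
* a **U-Net** with a ResNet34-topology encoder and a pixel-shuffle
  decoder, implemented from scratch in numpy with hand-derived
  backpropagation (gradient-checked);
* the **training regimen**: class-weighted cross entropy
  `loss(x, cls) = weight[cls]·(−x[cls] + log Σⱼ e^{x[j]})` with
  background weight 0.5, a two-phase 1-cycle schedule (frozen encoder,
  then discriminative per-group learning rates), an LR finder, and
  seeded 80:20 splits;
* **evaluation protocols**: pixel accuracy with a 10-epoch rolling
  final score, paired strategy comparisons with a paired t-test, and
  train×validate dropout-rate robustness sweeps.

## Worked example

Simulate a dataset, train two models, and compare them:

```python
import numpy as np
import stackseg as ss
from stackseg.presets import (desk_scale_sim_config,
                              desk_scale_model_config,
                              desk_scale_train_config)

man = ss.generate_dataset(desk_scale_sim_config(), 60, "demo_data")

codes = ss.builtin_codes()
table = ss.compare_strategies(
    [codes[n] for n in ("cytoplasm", "membrane", "mitochondria",
                        "brightfield", "all_black")],
    man, desk_scale_model_config(), desk_scale_train_config(),
    n_replicates=3, reference="brightfield", base_seed=7)
print(table.frame.to_string(index=False))
```

Output (one CPU, ~6 minutes):

```
        code  mean_accuracy      sem  n  p_vs_reference
   cytoplasm       0.966836 0.013826  3        0.004805
    membrane       0.976981 0.005700  3        0.003149
mitochondria       0.917680 0.015962  3        0.208993
 brightfield       0.899951 0.009257  3             NaN
   all_black       0.850873 0.019232  3        0.047839
```

Reading it: each row is a labeling strategy trained on identical cells
(paired splits and initializations within each replicate);
`mean_accuracy` is the validation pixel accuracy averaged over the final
10 epochs and over 3 replicates.  Markers that touch the cell boundary
(cytoplasm, membrane, ~97%) outrank the mitochondrial marker (~92%) and
label-free brightfield (~90%); the all-black control (~85%) is what
position alone can achieve, and the p-values are paired t-tests against
brightfield.

The same machinery runs from the shell:

```bash
stackseg simulate --config sim.yaml --n 60 --out data/ --seed 7
stackseg compose  --stack data/img_00000.tiff --code merge_br.yaml --seed 3 --out sub.tiff
stackseg train    --data data/ --code merge_br --config train.yaml --out run/ --seed 7
stackseg compare  --codes cytoplasm --codes brightfield --data data/ --reps 3 --out cmp/
stackseg sweep    --code merge_br --data data/ --train-rates 0:1:0.5 --val-rates 0:1:0.5 --out sweep/
stackseg lrfind   --data data/ --code fluorescence --out lr/
```

A loading code in YAML — one merged fluorescence channel with 50% merge
dropout, the in-focus brightfield, and a random out-of-focus plane
(the `merge_br` model):

```yaml
- {merge: [cyto, mem, mito], merge_dropout: 0.5}
- {simple: bf0}
- {random: [bf-10, bf-5, bf-3, bf+3, bf+5, bf+10]}
```

## Layout

| module | contents |
| --- | --- |
| `stackseg.synthetic` | hyper-labeled stack simulator |
| `stackseg.stack_io` | TIFF stacks, PNG masks, CSV manifests, channel-name contract |
| `stackseg.loading_codes` | loading-code types, resolution, builtin recipes, YAML grammar |
| `stackseg.augmentation` | synchronized image/mask augmentation, validation standardization |
| `stackseg.nn` | numpy layers with explicit backprop; SGD and Adam |
| `stackseg.model` | the encoder-decoder network, prediction, checkpoints |
| `stackseg.training` | loss, splits, 1-cycle schedule, LR finder, training loop |
| `stackseg.evaluation` | metrics, strategy comparison, dropout sweeps |
| `stackseg.presets` | full-scale defaults and the desk-scale reproduction protocol |
| `stackseg.cli` | `stackseg` command-line entry point |

See `docs/methods.md` for the model, the simulator's assumptions, and
the design decisions.
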