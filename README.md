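# musemap

Deep-UV surface-excitation microscopy (MUSE) can image the cut surface of an
unfixed surgical specimen in minutes, but pathologists cannot reliably label
such images, so a supervised metastasis classifier cannot be trained on them
directly. `musemap` implements the diagnostic pipeline that works around
this: a **CycleGAN** translates unfixed-specimen images into the appearance
of formalin-fixed paraffin-embedded (**FFPE**) sections — the domain where
labelled training data exists — and a CNN patch classifier trained only on
FFPE-domain patches then maps metastases across the whole image.

The pipeline stages, each its own module:

1. **`synthetic`** — a two-domain synthetic image generator (sharp
   nucleus-textured "FFPE-like" scenes with gland-shaped metastatic regions
   and exact masks; an "unfixed-like" degradation adding blur, non-uniform
   background haze and contrast loss), so everything is testable without
   clinical data.
2. **`gan`** — CycleGAN with least-squares adversarial loss, cycle
   consistency and identity terms:
   `l_total = l_adv + α·l_cycle + β·l_identity`, α = 10, β = 1; Adam,
   learning rate 2·10⁻⁴; patches scaled to [−1, 1] by `x/127.5 − 1`.
3. **`classifier`** — CNN with global average pooling and a 2-node head;
   per-patch max normalisation; two-phase SGD training (head first, then all
   weights); the checkpoint with the best validation accuracy is kept and
   the decision threshold maximises validation F1.
4. **`mapping`** — sliding-window whole-image classification: mirror-pad
   128 px, scan a 256-px window in 10-px steps; a 2592 × 2048 image yields a
   259 × 204 binary label map.
5. **`voting`** — majority voting with a k × k kernel, k = ⌈window/step⌉
   (26 at full scale), positive iff the positive fraction ≥ α (70–95%),
   suppressing isolated false positives.
6. **`evaluation`** — the 1-pixel rule (an image is called positive iff any
   voted cell is positive) and the accuracy accounting: per-model
   correct/total per class, pooled class averages, and per-condition model
   averages.

The two trainable stages are scikit-learn style estimators
(`CycleGANTranslator`, `PatchClassifier`) running on a small numpy
backprop engine (`musemap.nn`), so the package has no deep-learning
framework dependency and runs on one CPU.

## Worked example

```python
from musemap import PipelineConfig, run_experiment

result = run_experiment(PipelineConfig(seed=1), log=print)
print(result["accounting_with"].render("With translation"))
print(result["accounting_without"].render("Without translation"))
```

This synthesises the desk-scale study (288 × 224 px images; 64-px windows,
16-px steps, 32-px mirror padding; 4 × 4 voting kernel at 95%), trains the
classifier on FFPE-domain patches only, trains the translator on unpaired
patches from both domains, and diagnoses 20 unfixed-domain test images
(10 positive / 10 negative) both ways. With seed 1 it prints:

```
With translation
model               met(-)    met(+)  accuracy
cnn                  10/10     10/10     100.0
Average (%)          100.0     100.0     100.0

Without translation
model               met(-)    met(+)  accuracy
cnn                   0/10     10/10      50.0
Average (%)            0.0     100.0      50.0
```

Without translation the domain shift makes the classifier call hazy
lymphoid tissue "metastasis" everywhere, so every negative image fails the
1-pixel rule and accuracy sits at the 50% class base rate; after
translation the out-of-focus background is removed and all 20 images are
diagnosed correctly — the same direction of effect as the clinical study
this pipeline models, where translation lifted average accuracy from 66.3%
to 84.6%.

The same run is available from the shell:

```bash
musemap run-all --seed 1 --out results/run1
```

and the individual stages as `musemap synth / train-translate /
train-classify / map / vote / evaluate`.

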