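# grapesense

Hyperspectral classification of pesticide-residue levels on table-grape
clusters. The package implements the full analysis chain used in laboratory
residue studies — flat-field reflectance calibration, berry-ROI segmentation,
mean-spectrum extraction, Savitzky–Golay + SNV preprocessing, PCA score
exploration with confidence ellipses, grid-tuned classical classifiers (SVM,
logistic regression, random forest), bespoke 1-D CNN and ResNet spectral
networks, and gradient-saliency maps of wavelength importance — together
with a synthetic hyperspectral scene generator that reproduces the
statistical structure of such experiments, so every stage is testable
without proprietary instrument data.

It is written for chemometricians and ag-imaging researchers who want a
tested, seedable reference implementation of this pipeline, either as a
library or from the shell.

## The science in brief

Raw sensor counts are converted to reflectance with white/dark references,

    R = (I_raw − I_dark) / (I_white − I_dark),

the berry region of interest is thresholded on one high-contrast band
(804 nm Vis-NIR / 1092 nm NIR, Otsu by default) and each cluster's spectrum
is the ROI mean. Spectra are trimmed to the instrument's clean range
(476–890 nm / 970–1594 nm), smoothed (Savitzky–Golay, polyorder 0, window 3)
and scatter-corrected with the standard normal variate transform
x ↦ (x − mean(x)) / sd(x). Four residue levels (0%, 15%, 30%, 50% of a
standard three-fungicide mixture) are classified from the preprocessed
spectrum by five models under a stratified 3:1:1 train/validation/test
split; accuracy = TP / All. Wavelength importance of a trained network is
the saliency statistic

    w(λ) = | ∂S_c / ∂x(λ) |,

the absolute input-gradient of the true class's pre-softmax score, averaged
over correctly classified test samples and max-normalized.

The synthetic generator plants class signal as small Gaussian absorption
peaks (depths 0.00/0.02/0.04/0.08) at three informative wavelengths under
heavy per-sample multiplicative scatter and additive baseline — exactly the
corruption SNV removes — and encodes scenes as raw digital numbers by the
exact inverse of the calibration formula, giving each stage an oracle.

## Worked example

```python
import grapesense as gs
from grapesense.deep import TrainConfig, build_cnn, train_model

ds = gs.generate_dataset(gs.visnir_config(seed=1))   # 1071 samples, 80 bands
prep = gs.preprocess(ds)                             # SG -> SNV
split = gs.split_dataset(prep, seed=3)               # 644 / 214 / 213

net = build_cnn(prep.n_bands, seed=0)
result = train_model(net, prep, split,
                     TrainConfig(epochs=100, batch_size=32,
                                 learning_rate=1e-3, seed=0))
print(result.accuracies)

prof = gs.saliency_map(net, prep.subset(split.test))
info = gs.visnir_config().informative_band_indices()
print(prof.importance[info].mean() / prof.importance.mean())
```

Output:

```
{'train': 0.9984472049689441, 'val': 0.985981308411215, 'test': 0.9906103286384976}
2.700317153850033
```

The CNN classifies ~99% of held-out clusters correctly, and the three
planted informative wavelengths (nearest grid bands to 530/670/810 nm,
indices 10/37/64) carry well over twice the average saliency — the network
is looking where the signal was planted. The spray-design arithmetic is
also available directly:

```python
>>> gs.mixture_concentrations()
                           Jiatu  Xishuangke  Huiyin
Level 0 (0%)              0.0000      0.0000  0.0000
Level 1 (15%)             0.0375      0.0250  0.0625
Level 2 (30%)             0.0750      0.0500  0.1250
Level 3 (50%)             0.1250      0.0833  0.2083
Standard solution (100%)  0.2500      0.1667  0.4167
```

The same chain runs from the shell:

```bash
grapesense synth-dataset --out spectra.csv
grapesense preprocess --in spectra.csv --out prep.csv
grapesense split --in prep.csv --seed 3 --out split.json
grapesense train-deep --arch cnn --in prep.csv --split split.json \
    --epochs 100 --out cnn.json --saliency-out saliency.csv
grapesense run --instrument visnir --seed 1 --out results/
```

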