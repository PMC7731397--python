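# seedxray

Classification of seed viability from 2D X-ray projection images, for seed
technologists and image-analysis researchers who want a fully tested,
scriptable version of the classical machine-vision route to non-destructive
seed quality inspection.

A radiograph of a seed shows its internal morphology: a viable seed has a
regular, uniformly bright endosperm inside the coat, while deteriorated
seeds accommodate internal air spaces (dark cavities) or an irregular,
partially filled endosperm. `seedxray` turns that contrast into a binary
classifier (*viable* vs. *nonviable/abnormal*) with a pipeline of:

1. **Preprocessing** — crop each seed to 224×224, segment it with Otsu's
   threshold, and derive three enhanced images per seed: `set_A` (max
   normalization), `set_B` (standard-deviation scaling of `set_A`) and
   `set_C` (3×3 median filter of `set_B`).
2. **Texture features** — six families per enhanced image: basic intensity
   (6), uniform local binary patterns at radii 1–4 (234), a 4-frequency ×
   8-orientation Gabor bank (67), basic contrast (5), Haralick
   co-occurrence statistics (28) and local Fourier texture (8) — 348 per
   image, **1044 per seed**.
3. **Feature selection** — features are ranked by the Fisher score
   J = (μ₁−μ₂)² / (σ₁²+σ₂²), and sequential forward selection (SFS) greedily
   grows a subset that maximizes cross-validated classifier accuracy.
4. **Classification** — LDA, QDA and KNN (k=5) behind per-fold feature
   standardization, assessed by 10-fold stratified cross-validation with a
   95% confidence band over fold accuracies.

Because curated seed radiographs are rarely shareable, the package includes
a **synthetic radiograph generator** that renders both morphology classes
with controllable air-space fraction, outline irregularity, blur and noise
— every downstream stage is developed and validated against it. A six-fold
geometric augmentation module (rotation, reflection, x/y translation, x/y
scaling with leakage-safe 70:15:15 splitting) and a small from-scratch
numpy ConvNet baseline (3×3 stride-1 convolutions, ReLU, max-pooling,
FC + softmax) round out the toolkit.

## Worked example

Generate 30 seeds per class where nonviable seeds carry low-contrast air
spaces over 8% of the endosperm, extract features, select with SFS and
cross-validate:

```python
import seedxray as sx
from seedxray.workflow import extract_dataset_features
from seedxray.selection import sfs, summarize_selection
from seedxray.classify import make_cv_evaluator, cross_validate

nonviable = sx.MorphologyParams(air_space_fraction=0.08, n_blobs=3,
                                air_intensity=0.58)
params = {c: {sx.VIABLE: sx.MorphologyParams(), sx.NONVIABLE: nonviable}
          for c in ("a", "b")}
images, manifest = sx.generate_dataset(30, ["a", "b"], params, rng_seed=1)

features = extract_dataset_features(images)
labels = manifest.set_index("seed_id")["label"].loc[features.index].to_numpy()

trace = sfs(features, labels, make_cv_evaluator("lda", 5, 1),
            max_k=8, candidate_pool=25)
print(trace.best_k, [round(a, 1) for a in trace.cv_accuracy_at_step])
for clf in ("lda", "qda", "knn"):
    r = cross_validate(features[trace.best_features], labels, clf, 10, 1)
    print(clf.upper(), round(r.mean, 1), round(r.uci, 1), round(r.lci, 1))
```

prints

```
2 [98.3, 100.0, 100.0, 100.0, 100.0, 100.0, 100.0, 100.0]
LDA 100.0 100.0 100.0
QDA 100.0 100.0 100.0
KNN 100.0 100.0 100.0
```

i.e. one feature already reaches 98.3% CV accuracy and two features
(`i-Haralick IMC2[mean][A]` plus an LBP uniform-pattern share) separate
the classes perfectly; all three classifiers then agree. On this synthetic
task the morphological contrast is strong — the validation suite therefore
also exercises the hard regimes, down to an effect size of zero where
accuracy must fall back to chance.

The same flow is available from the shell:

```bash
seedxray simulate --n-per-class 30 --seed 1 --out data/
seedxray extract --input-dir data/ --out features.csv
seedxray train --seed 1 --out run/
seedxray predict --model run/model.joblib data/*.png
```

`seedxray report --table germination.csv` summarizes a germination-count
table (cultivar, viable, nonviable) into integer germination-rate percent
per cultivar and overall.

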