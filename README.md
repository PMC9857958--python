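# sffnet

Classification of mass-forming intrahepatic cholangiocarcinoma (MF-ICC)
versus hepatocellular carcinoma (HCC) on T2-weighted MRI slices. The two
tumors demand different treatment but overlap radiologically; the most
informative cue is the lesion margin — HCC tends to a sharp, rimmed
("pseudocapsule") boundary, MF-ICC to a blurred, irregular one. This
package implements a complete, reproducible workflow around that cue, for
researchers in medical image analysis who have slice images with aligned
binary lesion masks:

* **Semi-SP preprocessing** — a square region of interest sized by the
  lesion's maximal diameter `side = ceil(s · max(h_bbox, w_bbox))`,
  cropped, rescaled to a fixed patch size and contrast-enhanced with
  CLAHE, plus four controlled comparison strategies (2×/3× ROI, whole
  image, lesion-only).
* **SFFNet** — a ResNet101-style backbone with CBAM attention in the
  stem, pre-activation "stationary" residual blocks (SRB), and
  multilayer feature fusion (MFF) of shallow, middle and deep maps:

      FL  = concat(X0, up2(X3))
      Ffu = concat(FL, up16(X6))

  with X0 ∈ R^{B×64×112×112}, X3 ∈ R^{B×256×56×56}, X6 ∈ R^{B×2048×7×7}
  for 224×224 input, bilinear upsampling `up2`/`up16`, and a global
  average pool + fully connected head over Ffu (B×2368×112×112).
* **Training & evaluation** — lesion-grouped stratified 6:2:2 splits (no
  tumor spans two splits), momentum-SGD with a step learning-rate
  schedule, best-validation checkpointing, and per-class
  precision/recall/F1, accuracy, confusion matrix and threshold-sweep
  ROC-AUC.
* **Synthetic phantom cohort** — a seeded generator of two-phenotype
  lesion phantoms (sharp+rim vs. blurred+irregular) with ground-truth
  masks and multi-slice lesions, so the whole pipeline is testable
  without clinical data.

The network runs on a compact NumPy reverse-mode autodiff layer library
(`sffnet.nn`, im2col + BLAS convolutions), so the package has no
deep-learning-framework dependency.

## Worked example

```python
from sffnet.pipeline import benchmark_run_config, run_pipeline

record = run_pipeline(benchmark_run_config("runs/demo", seed=0))
print(record["stages"]["eval"])
```

This generates a 60-lesion phantom cohort (30 per class, 4 slices each),
splits it by lesion 6:2:2, applies Semi-SP, trains the reduced-depth
SFFNet at 64×64 for 25 epochs, and evaluates on the held-out lesions.
Output (seed 0):

```
{'test_accuracy': 0.9583333333333334, 'test_macro_auc': 0.9999999999999999}
```

and `runs/demo/metrics.json` holds the full report — per-slice confusion
matrix `[[22, 2], [0, 24]]` (rows: truth HCC, MF-ICC), per-class F1
0.957/0.960, lesion-level majority-vote accuracy 1.0: of 48 held-out
slices, two HCC slices are taken for MF-ICC, and every MF-ICC slice is
recognized — the blurred-margin phenotype is the easier one to rule in,
mirroring the clinical intuition that edge sharpness carries the signal.
The directory also contains `history.csv` (per-epoch loss, accuracy,
learning rate), `roc.csv`, `checkpoint.npz` and `run_record.json` (the
resolved config, seeds, versions and stage timings that make the run
repeatable bit-for-bit).

The same stages are scriptable from the shell:

```bash
sffnet synth --out cohort/ --n-per-class 30 --seed 7
sffnet preprocess --manifest cohort/manifest.csv --strategy semi_sp --out patches/
sffnet split --manifest cohort/manifest.csv --out split.csv --seed 7
sffnet train --manifest patches/patches.csv --split split.csv --out run/ --epochs 25 --lr 0.01
sffnet eval --checkpoint run/checkpoint.npz --manifest patches/patches.csv --split split.csv --out metrics.json
```

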