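# dcemcs

Benign/malignant breast-lesion classification on dynamic contrast-enhanced
MRI (DCE-MRI) with a two-channel **multiple classifier system (MCS)**: a
Gaussian naive-Bayes classifier votes voxel by voxel on kinetic
(time-intensity) features, a decision tree classifies lesion-level shape
features, and the two channels are fused by a weighted probability rule.
The package is aimed at researchers in breast-MRI computer-aided diagnosis
who want a fully automatic, reproducible reference pipeline — including a
synthetic phantom generator, so every stage is testable without patient
data.

## Method

A DCE-MRI study is one pre-contrast volume and T post-contrast volumes.
Malignant lesions typically enhance early and wash out; benign lesions
enhance slowly and persist. The pipeline:

1. **Automatic segmentation.** A sum-of-intensity-differences map,
   `SOD = Pre + Σᵢ |Post(i) − Post(i−1)|`, is Otsu-thresholded into a
   breast mask, cleaned by morphological closing, hole filling and erosion.
   A voxel is *suspicious* if its relative enhancement
   `RE(tᵢ) = (SI(tᵢ) − BS)/BS` exceeds 0.3 at some scan **and** its signal
   peaks strictly before the last scan. 26-connected components of
   suspicious voxels become candidate lesions (VOIs).
2. **Features.** Morphological, per lesion: slice-wise area (`nₖ·dx·dy`)
   and perimeter (boundary-voxel count), aggregated as slice medians; 3D
   compactness `S²/V`; eccentricity `√(a² − b²)/a` from the principal
   semi-axes. Dynamic, per voxel: basal signal BS, the least-squares slope
   of RE over the post-contrast scans, and SOD.
3. **Two channels.** The naive-Bayes classifier labels every voxel in the
   VOI; the voxel-vote fractions give the dynamic-channel probabilities
   `D_m = n_m/N`, `D_b = n_b/N`. The (unpruned, confidence factor 0.25)
   decision tree gives morphological probabilities `M_m`, `M_b`.
4. **Fusion.** The lesion is called malignant when
   `α·D_m + β·M_m > α·D_b + β·M_b` with `α + β = 1`. The coefficient α is
   chosen on a 0.05 grid by leave-one-out accuracy on the training split,
   taking the midpoint of the widest maximal-accuracy plateau.
5. **Evaluation.** Sensitivity, specificity, PPV, NPV and accuracy
   (malignant positive), plus a McNemar test for paired classifiers.

Feature-subset selection (correlation-based merit and consistency scoring
under forward/backward/bidirectional/greedy/ranking searches) is included
for reducing larger feature tables.

## Worked example

Simulate an overlapping-class cohort of 22 benign and 26 malignant lesions
(32 train / 16 test) and run the whole pipeline — automatic segmentation,
feature extraction, both classifiers, and fusion:

```python
import dcemcs

cfg = dcemcs.hard_cohort_config()
result = dcemcs.run_phantom_experiment(22, 26, cfg, seed=1)
print(f"alpha* = {result.alpha_star:.2f}")
for channel, acc in result.test_accuracy.items():
    print(f"{channel:14s} test accuracy: {acc:.1f}%")
```

prints

```
alpha* = 0.65
dynamic        test accuracy: 100.0%
morphological  test accuracy: 75.0%
fused          test accuracy: 93.8%
```

The dynamic channel separates the simulated kinetics well on this seed, the
shape channel is noisier, and the fused decision tracks the better channel;
across seeds the fused accuracy matches or beats the best single channel on
average. The same flow is available from the shell via the `dcemcs` CLI
(`simulate`, `segment`, `features`, `select`, `train`, `classify`,
`evaluate`), each subcommand taking `--config`, `--seed` and `--out`.

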