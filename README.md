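# boarscan

Scanning-factor analysis for image-based prediction of boar semen-production
potential.

Commercial studs want to know, from early testicular B-mode ultrasound,
which young boars will go on to produce high-quality semen.  Answering that
with an image classifier raises a second-order question that this package
is built around: **which scanning and processing choices actually move the
classifier's performance?**  Four binary factors are crossed in a 2×2×2×2
grid — image **region** (full view vs. a crop of the central seminiferous-
tubule area), probe **angle** (horizontal vs. vertical), **augmentation**
group (geometry-only vs. geometry plus brightness transforms) and model
**capacity** (medium vs. small) — and every configuration–run evaluation
becomes one observation of a general linear model

    y = μ + R + A + B + M + ε                      (main effects)
    y = μ + R + A + B + M + ΣΣ (X×Y) + ε           (all two-way interactions)

fit by OLS under treatment coding, with ANOVA F-tests, coefficient tables
with 95 % CIs, and Durbin–Watson / condition-number diagnostics.

Because farm data of this kind are proprietary, the package ships a
synthetic-data generator that emulates a realistic stud (107 boars,
2–49 semen collections each at 5–14 day intervals, 9–17 images per boar in
two probe orientations, class-dependent echogenicity) with a *planted*,
brightness-carried class signal.  Every stage is therefore testable end to
end: the two-step labeling rule recovers planted boar classes, cropping
provably costs recall, brightness augmentation provably costs precision,
and the factorial machinery recovers those planted effects with the right
signs.

The pipeline stages:

1. **Labeling** — a collection is *good* if total sperm count ≥ 20×10⁹,
   motility > 70 % and morphology > 70 %; *bad* if it meets ≤ 1 criterion;
   technician-flagged *trash* counts as low-quality.  A boar is
   *underperforming* if it has more than one low-quality collection and
   those are ≥ 10 % of its collections.
2. **Imaging prep** — central cropping, and two augmentation groups that
   keep brightness-altering operators strictly separate from morphological
   ones.
3. **Model harness** — By-ID 5-fold cross-validation (all images of a boar
   stay in one subset) and a pluggable classifier contract with a two-tier
   logistic baseline over intensity features.
4. **Evaluation** — per-boar aggregation: image probabilities are averaged
   and thresholded at 0.3 (high-quality is the positive class); precision,
   recall and F1 = 2PR/(P+R).
5. **Factorial statistics** — the grid runner and the GLM/ANOVA layer.

## Worked example

```python
import boarscan as bs
from boarscan import stats

ds = bs.make_dataset(n_boars=60, seed=1)          # population + records + images
labels = bs.label_dataset(ds.records)             # two-step rule
print(labels["label"].value_counts().to_dict())

results = stats.run_grid(ds, n_runs=4, base_seed=101)   # 16 configs x 4 runs
report = stats.fit_main_effects(results, "recall")
print(report.coefficients[["term", "estimate", "p"]].round(4).to_string(index=False))
```

prints (numbers from this exact invocation):

```
{'high_quality': 42, 'underperforming': 18}
                        term  estimate      p
            Region (Cropped)   -0.0417 0.0002
            Angle (Vertical)    0.0417 0.0002
Augmentation (Comprehensive)    0.1057 0.0000
               Model (Small)    0.0000 1.0000
```

Reading: on this synthetic dataset the rule labels 18 of 60 boars
underperforming; cropping lowers boar-level recall by about 4 points
(p < 0.001), the vertical probe angle raises it, brightness augmentation
raises recall (while lowering precision — fit `"precision"` to see its
negative coefficient), and model capacity does nothing — the qualitative
fingerprint the pipeline is designed to expose.  A command-line interface
mirrors the stages (`boarscan simulate / label / train-eval / anova`).

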