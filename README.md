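# koalawalk

Behaviour classification, energetics and ground-visit detection from koala
collar accelerometry.

Koalas spend almost their entire life in trees; the few minutes a day they
spend walking on the ground account for a disproportionate share of their
mortality (vehicles, dogs). Quantifying *when*, *how often* and *for how
long* koalas come to the ground therefore matters directly for conservation
scheduling — but the behaviour is too brief and too nocturnal to observe
directly, and GPS fixes are too sparse to resolve it. High-frequency collar
accelerometry can: each behaviour leaves a distinctive signature in the
50 Hz tri-axial acceleration signal, and a supervised classifier trained on
video-annotated captive data can score multi-day free-ranging deployments
second by second.

`koalawalk` implements that analysis chain end to end, for anyone working
with 50 Hz collar accelerometer data from arboreal mammals:

- **synthetic data** — a semi-Markov behaviour simulator (gamma dwell
  times, diel occurrence modulation, an inhomogeneous ground-visit process
  concentrated in the pre-dawn hours, behaviour-specific signal signatures,
  optional canopy-sway contamination and collar-tap calibration events), so
  every downstream stage is testable without field data;
- **signal I/O** — delimited-text streams with JSON sidecars, g → m·s⁻²
  conversion, gap flagging, boxcar-mean decimation (100 → 50 Hz), tap-event
  detection for video/collar clock alignment;
- **features** — 1 s windows with 50 % overlap; per-axis statistics,
  spectral descriptors, cross-axis correlations, and dynamic body
  acceleration summaries. VeDBA is the Euclidean norm of the
  gravity-removed acceleration, `VeDBA = √(d_x² + d_y² + d_z²)`, with the
  static component estimated as a centred 2 s running mean per axis;
- **classifier** — chronological 60/20/20 train/validation/test split per
  (behaviour, individual) stratum (no sequence leakage), Random-Forest
  tuning on validation macro-F1 (unweighted class mean), per-second
  prediction, and the full metric set (precision, recall, F1, balanced
  accuracy, prevalence, macro averages);
- **post-processing** — centred 5 s modal filter (ties keep the centre
  label), collapse of runs < 3 s into the surrounding state, regrouping of
  seven model classes into four ecological categories, non-overlapping 20 s
  majority bins with per-bin VeDBA_max/VeDBA_min means;
- **ground visits & budgets** — clusters of Walking bins separated by
  ≤ 60 s form Ground Visits; daily behaviour budgets are rescaled to
  1440 min and summarised within individuals first, then across animals;
- **diel models** — cyclic smooths of activity (VeDBA_max) and of the
  walking proportion over hour-of-day with random intercepts per
  individual (`CyclicActivityModel` → `.fit()` → results with `predict`,
  `hourly_table`, `summary`, `plot`), Kruskal–Wallis + pairwise Wilcoxon
  (Benjamini–Hochberg) comparison of VeDBA across behaviours, and a linear
  mixed model for sex/habitat effects on daily walking time.

## Worked example

Simulate a small deployment, train, score and summarise (also available as
`koalawalk --config demo.yaml all`):

```python
import koalawalk as kw
from koalawalk import classify, postprocess, visits
import pandas as pd

# 1. captive training data: two animals, balanced behaviour repertoire
cfg = kw.captive_config(days_per_individual=0.08, seed=11)
table = pd.concat(
    [kw.extract_feature_table(kw.simulate_stream(cfg, i)) for i in range(2)],
    ignore_index=True)
train, val, test = classify.chronological_split(classify.training_table(table))
model = classify.train_forest(train, classify.ModelConfig(300, 7, 16, 0))
cm = classify.ConfusionMatrix.from_labels(
    test["label"], classify.predict(model, test))
print(classify.classification_metrics(cm).summary().round(3))
```

```
                  precision  recall     f1  balanced_accuracy  prevalence
Bellowing             1.000   1.000  1.000              1.000        89.0
Climbing              1.000   1.000  1.000              1.000       364.0
Feeding               0.592   0.919  0.720              0.921       589.0
Grooming              0.745   0.465  0.573              0.723       602.0
In-tree Movement      0.999   0.932  0.964              0.966      1486.0
Still                 1.000   1.000  1.000              1.000       769.0
Walking               1.000   1.000  1.000              1.000      1619.0
Macro-average         0.905   0.902  0.894              0.944         NaN
```

Walking — the behaviour that matters for ground-risk — is classified
near-perfectly; the residual confusion sits where it does in real
deployments, between feeding, grooming and low-intensity in-tree movement.

Ground-visit recovery on the wild-deployment generator (ground-truth label
path, 9 animals × 8 days):

```python
from koalawalk.pipeline import ground_truth_bins
bins = ground_truth_bins(kw.wild_config(seed=1))
rates = visits.visit_rates(visits.detect_visits(bins), bins)
print(round(rates["visits_per_day"].mean(), 2), "visits/day")
budgets = visits.daily_budget(bins)
walk = budgets[budgets.category == "Walking"]
print(round(walk.groupby("individual_id")["minutes"].mean().mean(), 2),
      "walking min/day")
print(visits.peak_hour(bins, "Walking"), "peak hour")
```

```
2.81 visits/day
2.88 walking min/day
(3, 4) peak hour
```

The configured truth is 2.95 visits/day and ~3 walking minutes/day
concentrated between 02:00 and 05:00; the pipeline recovers all three
through the full smoothing/binning/clustering chain.

## Documentation

`docs/methods.md` describes the models, the generator's assumptions and
calibration, numerical conventions (tie-breaks, degenerate inputs) and
known limitations.
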