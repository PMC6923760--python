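# somnoclust

Unsupervised clustering of insomnia sleep/activity phenotypes from
multi-week daily wearable logs.

People with similar insomnia questionnaire scores can have very
different day-to-day sleep/activity dynamics — long sleepers with poor
efficiency, short efficient sleepers who burn many calories, low-activity
morning types. `somnoclust` finds such groups directly from smart-band
daily aggregates, without labels:

1. **Preprocess** — drop subjects with >2 consecutive non-wear days,
   drop `onbed_min` (collinear) and sleep-stage columns, min-max
   normalize each of the 12 remaining sleep+activity features to [0, 1]
   over the pooled cohort.
2. **Image** — cut each subject's day × feature matrix into 8-day
   sliding windows and discount older rows by γ^(m−1) (γ = 0.75, m = 1
   for the newest day), so each window is an 8 × 12 recency-weighted
   "image". A 42-day record yields 42 − 8 + 1 = 35 windows.
3. **Encode** — compress each image to a 15-dimensional code with a
   one-convolution autoencoder (30 filters of 3 × 12, no pooling,
   Adam 1e-4, L2-regularized MSE), implemented in pure numpy.
4. **Cluster windows** — embed the codes to 2-D with t-SNE (perplexity
   30), repeat over seeded trials, and keep the k-means /
   agglomerative / DBSCAN partition with the highest average silhouette
   (AS; ties by lower SSE; AS ≥ 0.4 counts as significant).
5. **Assign subjects** — each subject's window labels form a Markov
   chain; the cluster with the highest PageRank score (damped stationary
   distribution, d = 0.85) of their own chain is their dominant
   insomnia-activity cluster. Clusters are then profiled with rank-ANOVA
   and Kruskal-Wallis tests on subject-level feature means.

Because cohorts of this kind are rarely shareable, the package ships a
generator of synthetic cohorts with planted behavioural regimes
(per-regime truncated-Gaussian daily features, Markov persistence,
realistic non-wear gaps) so the whole pipeline is testable end to end.

## Worked example

```python
import pandas as pd
from somnoclust import PipelineConfig, CAEConfig, run_pipeline
from somnoclust.synthetic import CohortSpec, default_regimes, generate_cohort

spec = CohortSpec(n_subjects=42, n_days=42,
                  regimes=default_regimes(3, persistence=0.95), seed=7)
logs, truth = generate_cohort(spec)
demo = pd.DataFrame({"subject_id": spec.subject_ids, "BMI": 22.0, "ISI": 18.0})

cfg = PipelineConfig(out_dir="out", seed=7,
                     cae=CAEConfig(epochs=150, early_stopping=False),
                     n_embedding_trials=2, methods=("kmeans",))
res = run_pipeline(cfg, logs=logs, demographics=demo)
print(res.stack.n_images, res.stack.n_pixels)
print(res.trained.loss_history[0], res.trained.final_loss)
print(res.clustering.n_clusters, round(res.clustering.AS, 3))
print(res.assignment_summary)
```

prints (deterministic for this seed):

```
1470 141120
0.12088749345462667 0.009118452619711361
3 0.626
  cluster   n  pct  pagerank  BMI_mean  BMI_sd  ISI_mean  ISI_sd
0       C  14   33  0.624124      22.0     0.0      18.0     0.0
1       B   8   19  0.609865      22.0     0.0      18.0     0.0
2       A  20   48  0.597613      22.0     0.0      18.0     0.0
```

Reading it: 42 subjects × 35 windows give 1470 images of 8 × 12 =
141,120 pixels; 150 training epochs cut the regularized reconstruction
loss from 0.121 to 0.009; the silhouette-maximizing sweep selects k = 3
clusters (AS 0.63, "significant" by the ≥ 0.4 rule); and PageRank over
each subject's label chain distributes the cohort over the three
clusters, here with the per-cluster mean dominant score and the joined
demographics. All artifacts (window labels, loss history, checkpoints,
summary tables, plots, a hash manifest) land in `out/`.

The same pipeline is scriptable from the shell:

```bash
somnoclust simulate --out-dir data --n-subjects 42 --n-days 42 --seed 7
somnoclust run --logs data/daily_logs.csv --out-dir out --seed 7 --trials 2
```

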