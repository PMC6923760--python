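# Methods

## Problem and data model

`somnoclust` clusters people with insomnia by the *joint* trajectory of
their sleep and daytime activity, as recorded by a wrist-worn device over
several weeks. The input is a long table of subject-day rows carrying 13
daily aggregates in two modalities:

- sleep: bed-entry and get-up times, minutes in bed (`onbed_min`),
  minutes asleep (`sleep_min`), sleep efficiency
  (`sleep_min / onbed_min`), minutes and number of awakenings;
- activity: total and active kilocalories, steps, distance, floors
  climbed, and the active ratio (active time over wear time).

Demographics (age, gender, BMI, ISI) never enter the clustering; they
are joined back onto the derived clusters for interpretation only.

## Pipeline

1. **Preprocessing.** Subjects with any run of more than
   `max_consecutive_gap` (default 2) consecutive non-wear days are
   excluded. `onbed_min` is dropped (near-collinear with the other sleep
   durations) and any sleep-stage columns are dropped as unreliable,
   leaving a 12-dimensional daily "multiplex" vector (6 sleep + 6
   activity). Remaining short gaps of retained subjects are linearly
   interpolated inside the subject (edge gaps take the nearest value) so
   each subject has a dense day × feature matrix. Each feature is
   min-max normalized to [0, 1] with bounds pooled over the whole cohort
   — subjects must share one scale for cross-subject clustering — and
   the bounds are stored so raw units can be recovered exactly.
   Additionally, any retained feature whose |Pearson r| with an earlier
   retained feature exceeds `correlation_threshold` (default 0.9) is
   flagged in the screening report but not dropped unless requested.
   Constant features normalize to 0 (the conventional degenerate
   output).

2. **Window imaging.** Each subject's D × 12 matrix is cut into
   overlapping windows of `win_size` = 8 consecutive days (stride 1), so
   a 42-day record yields 35 windows. Inside a window the rows are
   weighted by recency: with closeness rank m (m = 1 for the newest day,
   m = 8 for the oldest), row m is multiplied by γ^(m−1), γ = 0.75 by
   default. Sleep debt accumulates but is dominated by the last one or
   two nights, which is exactly what an exponential discount encodes.
   The newest row carries weight 1 (γ^(m−1), the standard discounted-sum
   convention); the alternative γ^m weighting is available through
   `discount_exponent_offset=0`. The window's timestamp t is the day
   immediately after the window (a window over days 1–8 has t = 9;
   internally 0-based). Discounted images are fed to the autoencoder
   directly, without rescaling back to a common range: the decaying row
   envelope is information the encoder should see.

3. **Convolutional autoencoder.** Each 8 × 12 image is compressed to a
   latent code of 15 numbers. The encoder is a single convolution of 30
   filters of height 3 spanning the full 12-feature width — so the
   kernel slides only along time, with valid padding, stride 1 and no
   pooling (the input is far too small to throw away resolution) —
   followed by ReLU, flatten, and a linear dense layer to the code. The
   decoder mirrors it (dense, ReLU, one transposed convolution) and ends
   in a sigmoid so reconstructions stay inside the [0, 1] data range.
   Training minimizes mean squared reconstruction error plus an L2
   penalty on the weights (coefficient 1e-4) with Adam at learning rate
   1e-4, batch 64, up to 500 epochs with early stopping on a 10%
   validation split (patience 25, best-validation parameters restored).
   The implementation is plain numpy with hand-written backpropagation:
   at ~10k parameters and ~1500 images this trains in seconds on one
   CPU and is bit-reproducible under a fixed seed. A grid search over
   {learning rate, γ, kernel height, filter count, latent size} is
   provided; the γ axis re-runs the imaging stage, and diverging
   combinations are recorded with infinite loss.

   The latent layer is linear rather than ReLU-clipped: a signed,
   unbounded code wastes none of its 15 dimensions on dead units, and
   the bounded-output constraint belongs to the reconstruction side
   only. Reported losses are per-pixel means over the full stack.

4. **Embedding and window clustering.** The N × 15 codes are embedded to
   2-D with Barnes-Hut t-SNE (perplexity 30, euclidean metric, PCA
   initialisation). Because t-SNE is stochastic, the embed+cluster pair
   is repeated over seeded trials (100 by default) and the trial with
   the highest average silhouette (AS) is kept. Candidate partitions per
   trial come from a k-means sweep (k = 2…10, 10 restarts) and
   optionally an agglomerative sweep (ward linkage) and DBSCAN (min_pts
   4, eps from the k-distance elbow; noise points are excluded from
   AS/SSE and counted separately). The winner maximizes AS with ties
   broken by lower SSE; AS ≥ 0.4 is flagged as a significant partition.
   AS and SSE are computed in the 2-D embedding space, where the
   partition is actually formed. Clusters are renamed to letters A, B,
   C, … in decreasing size order.

5. **Subject assignment.** Each subject becomes a time-ordered sequence
   of window letters. Treating consecutive letters as a first-order
   Markov chain, the subject's transition matrix is the row-normalized
   pair-count matrix (optional additive smoothing; letters the subject
   never emitted get uniform outgoing rows, the standard dangling-node
   treatment). PageRank scores are the stationary distribution of
   d·P + (1−d)/K with damping d = 0.85, computed by power iteration to
   1e-10; the letter with the highest score is the subject's dominant
   cluster (ties broken alphabetically with a warning). The per-cluster
   summary reports membership counts and percentages, the mean dominant
   score of members, and mean (SD) BMI/ISI; empty clusters appear with
   count 0. If the winning partition is DBSCAN, noise windows take the
   letter of the nearest centroid so every sequence stays full length.

6. **Profiling.** Group differences across clusters are tested
   nonparametrically: ANOVA on the global mid-ranks of the pooled values
   (df = k−1, N−k) and Kruskal-Wallis with tie correction. Each subject
   contributes one value per feature — their across-day mean, mapped
   back to raw units — so days are never pseudo-replicated within
   subjects. p-values are reported unadjusted with a Holm-adjusted
   column alongside; stars follow † p<.10, * p<.05, ** p<.01, *** p<.001.

## Synthetic cohorts

Real smart-band cohorts of this kind are not public, so the
`synthetic` module generates them. Each subject follows a first-order
Markov chain over a small set of behavioural *regimes* (e.g. "long
sleeper with low efficiency", "short efficient sleeper with high
activity", "morning type with low activity"), staying in the current
regime each day with probability `persistence` (default 0.95, i.e. runs
of ~20 days). Each subject-day draws the 13 features from per-regime
truncated Gaussians (truncated at physical bounds), and derived features
are recomputed from the sampled primaries — efficiency = sleep/onbed,
awake-in-bed = onbed − sleep, get-up time = bed time + 60·onbed — so
every row is internally consistent and carries the correlation structure
the screening step expects (which is why `onbed_min` and several
activity features get flagged, as intended). The six built-in regime
archetypes differ by ≥ 3 within-regime SDs on several of the cardinal
markers (time in bed, sleep minutes, active calories, steps, stairs).
Missing wear is modelled as absent rows, either i.i.d. per day or as
injected contiguous gaps for exercising the compliance filter.

What the generator does **not** emulate: minute-level traces, weekday /
weekend structure, gradual drift within a regime, device measurement
bias, or correlated missingness (people tend to stop wearing the device
when their routine collapses). Passing the planted-structure checks
therefore shows the pipeline recovers block-structured daily regimes
through the full image→code→embedding→chain path; it does not certify
performance on real Fitbit data.

## Subject-level ground truth and an intrinsic limit

With per-day persistence 0.95 over 42 days, the probability a subject
never switches regime is 0.95⁴¹ ≈ 0.12 — most synthetic subjects occupy
two or three regimes during the study. The recovery benchmark therefore
scores assignments against each subject's *modal* planted regime.
This makes subject-level recovery intrinsically noisy: an assignment
method can legitimately disagree with the modal regime for subjects who
split their time. An oracle experiment (perfect window labels fed
straight to the assignment stage, bypassing the autoencoder and the
embedding) puts a ceiling of about ARI ≈ 0.75 on majority-vote
assignment against modal truth at these settings, and per-subject
PageRank sits below that: with raw pair counts the subject's final
regime run has no observed outgoing transitions, becomes an absorbing
state, and attracts the stationary mass — PageRank answers "where does
this chain end up", not "where was it most often". Additive smoothing
softens but does not remove this. The benchmark reports the measured
ARI distribution rather than hiding the gap; on real cohorts, where
label sequences are far noisier and chains are ergodic, the distinction
is much smaller.

## Numerical and design notes

- **Determinism.** Every stochastic stage takes a seed; the pipeline
  fans one global seed into per-stage seeds via CRC32("stage:seed").
  Reruns with the same config and seed produce byte-identical artifact
  hashes (this is a test).
- **Benchmark problem sizes.** Recovery runs use the study-sized 42 × 42
  cohort, 3 embedding trials and a 150-epoch fixed training budget —
  ample at this data size; the paper-sized 100-trial selection remains
  the default for real runs. Calibration uses 1000 label permutations on
  a fixed 42-subject null panel with group sizes 12/9/4/12/5.
- **Degenerate inputs.** γ = 1 makes discounting the identity; constant
  features normalize to 0; constant label sequences dominate as
  themselves for any damping > 0; uniform chains give uniform PageRank;
  single-cluster partitions have no silhouette (AS recorded as NaN and
  never selected over a scored partition).
- **Known limitations.** One conv layer and a shared kernel cap the
  encoder's expressiveness (with the default sigmoid output its held-out
  reconstruction error sits ~25% above an optimal rank-15 linear
  projection; with a linear output it matches it). t-SNE's cluster
  geometry can inflate silhouettes; AS is computed where clustering
  happens, in the embedding, and the ≥ 0.4 rule should be read as a
  heuristic. Latent codes are learned pooled across subjects, so
  subject-specific offsets are not factored out.
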