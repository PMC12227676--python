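# Methods

`smokegeo` quantifies how much *temporal* features (time of day, day of
week, weekend, season) versus *spatial* features (stay-region cluster
labels or displacement) contribute to predicting self-reported smoking
events from smartphone data. Because real cohorts of this kind are
access-restricted, the package pairs the analysis pipeline with a
synthetic cohort generator whose temporal-habit and location structure
is known and tunable, so every inference the pipeline makes can be
checked against the construction that produced the data.

## Event labeling

Self-reports are single timestamps, but a smoking episode spans several
minutes and reported times are noisy. Each report at time *t* is
expanded into a closed **half-time window** `[t − H, t + H]` with
H ∈ {5, 10, 15, 20, 30} minutes. Every GPS fix inside the union of
windows is labeled smoking (1), all others non-smoking (0). A window
containing no fix contributes a **fallback sample**: a smoking-labeled
row at the window centre that copies the coordinates of the fix nearest
in time (ties break toward the earlier fix). Fallback rows carry a
`source_fix_idx` pointer so spatial encodings computed per fix transfer
to them.

Boundary conventions are fixed once: window membership is closed at
both endpoints; day bins are half-open `[start, end)`; a bin counts as
overlapping a window only when the intersection has strictly positive
duration; the pre-quit filter keeps timestamps strictly before the quit
datetime. These choices reproduce the canonical worked example exactly
(a 9:10 a.m. report with H = 15 yields `[8:55, 9:25]` and marks the
8:45–9:00, 9:00–9:15 and 9:15–9:30 quarter-hour bins).

Two readings of the "96 quarter-hour binary features" exist. Used
literally — bin b = 1 iff it overlaps a smoking window — the features
encode the outcome and would leak it into the classifier. The default
classifier encoding is therefore a leak-free **one-hot of each sample's
own quarter-hour bin**; the literal overlap construction is kept as
`interval_overlap_labels` and feeds the association analysis, where the
outcome is location rather than smoking. Day-of-week is one-hot
(7 columns), weekend is one flag, and season follows the meteorological
month rule. All features use the participant's local wall-clock time; a
wall-clock day always yields 96 quarter-hour bins.

## Spatial representations

Three per-participant encodings of a fix's whereabouts, computed on the
raw pre-quit fixes:

* **DBSCAN** over great-circle distances (`eps` 100 m, `min_samples` 5
  by default; both configurable). Noise points form their own
  categorical level rather than being dropped, since every sample must
  reach the classifier. Cluster ids are renumbered in first-appearance
  order for determinism. The defaults are not dictated by the data
  format; 100 m matches the order of the app's movement-trigger
  granularity and produces realistic stay-region counts on calibrated
  synthetic cohorts.
* **K-means** on locally projected (equirectangular) planar
  coordinates, with the cluster count chosen by the mean silhouette
  score over k = 2..10 (ties to the smaller k; fewer than three
  distinct points falls back to a single cluster). The silhouette is
  computed on the same projected coordinates K-means optimises.
* **DFI** — great-circle metres from the participant's first recorded
  fix, a continuous mobility proxy; z-scored using training-fold
  statistics during cross-validation to avoid leakage.

All three commute with the per-participant constant privacy offset
applied to published coordinates (DFI up to the ~0.3 % equirectangular
projection error a genuine latitude shift introduces).

## Ablation modeling grid

Per participant, the full Cartesian grid {DBSCAN, K-means, DFI} ×
{logistic regression, random forest, multilayer perceptron} ×
{H = 5, 10, 15, 20, 30 min} × {all features, location-excluded,
time-excluded} is evaluated with stratified, shuffled 5-fold
cross-validation and scored by **Macro-F1** (unweighted mean of the two
per-class F1 scores; a class absent from both truth and prediction
contributes 0). The participant's score for a configuration is the mean
over folds.

Hyperparameters are conventional and fixed: LR with L2 penalty, C = 1,
up to 1000 iterations; RF with 100 trees, unlimited depth; MLP with
hidden layers (300, 150), ReLU, Adam, learning rate 1e-3, batch size
32, up to 200 epochs with plateau-based early stopping. Models are
trained per participant (individual-level); a pooled-cohort mode
(`pool_participants`), in which one model is cross-validated over all
participants' samples with participant-specific spatial columns in
disjoint blocks, is available behind a flag. All non-smoking samples
are used (no subsampling), and clustering runs on all pre-quit fixes
rather than smoking-labeled fixes only.

Pairing guarantees make the signed-rank comparisons valid: for a fixed
participant and half-time, every ablation and every spatial method is
scored on the same fold partition, and the location-excluded
configuration — which cannot depend on the spatial method — is fitted
once per (participant, family, half-time) and replicated verbatim
across methods, so its rows are identical by construction.

## Statistics

* **Wilcoxon signed-rank** compares per-participant all-features scores
  with each ablated feature set. Zero differences are discarded;
  absolute differences are ranked with midranks; for up to 15 retained
  pairs the two-sided p-value comes from full enumeration of the 2^n
  sign assignments, otherwise from the tie-corrected normal
  approximation. Significance is flagged at α = 0.05 and α = 0.005,
  with no multiplicity correction by default (a Benjamini–Hochberg mode
  is available). Comparisons with fewer than 6 complete pairs are
  flagged underpowered.
* **Welch's t** (unequal variances; a pooled option exists) compares
  participant characteristics between enrollment subgroups. The
  subgroup split assigns enrollment on or before 2023-05-11 (the end of
  the COVID-19 public-health emergency) to the "during" group.
* **Time–location associations**: for each time-of-day bin (quarter- or
  half-hour) a linear mixed model predicts the location outcome from
  the binary bin indicator with a participant random intercept
  (maximum likelihood); a per-participant OLS mode implements the
  N × M reading. Because a linear model on arbitrary integer cluster
  ids is scale-dependent, the default outcome is
  `modal_cluster_binary` — whether the sample lies in the participant's
  most frequent smoking cluster — with `cluster_numeric` kept as a
  literal-replication mode. For each significant association the
  **support value** is reported in the association-rule sense: the
  percentage of stratum samples where the bin indicator and the modal
  cluster co-occur.

## The synthetic cohort generator

Each participant receives: 1–6 anchor locations (≥400 m apart, spread
~5 km around a personal centre); a 96-bin habit profile — a uniform
floor blended with 1–4 wrapped von Mises peaks, blend weight
`1 − exp(−beta_time)` so `beta_time = 0` is exactly uniform; an hourly
visit schedule (home mornings/evenings, other anchors in daytime
blocks); and a study length drawn from a normal (mean 13.65, SD 3.43
days) truncated below at 3 days.

Anchor occupancy per 15-minute waking slot (07:00–23:00) follows the
schedule with probability `rho_redundancy` and otherwise evolves as a
sticky, time-independent random walk — `rho = 1` makes location a
deterministic function of hour of day (fully redundant), `rho = 0`
makes it independent. Smoking events are drawn from an inhomogeneous
Poisson process with slot intensity proportional to
`exp(beta_time · ĥ(bin) + beta_loc · ĝ(anchor))` (ĥ, ĝ standardized),
normalised so `base_rate` is the expected events per waking hour; a
gamma multiplier (shape 1.85) gives realistic between-person
dispersion. Reported times add Gaussian jitter (SD 3 min — smaller than
the smallest half-time so labels stay mostly correct) clipped to the
study window.

GPS fixes follow the movement-trigger rule: candidate positions (a few
per slot at the occupied anchor, sparse samples along transition paths
with lateral route jitter emulating different roads, Gaussian
positional noise) are emitted only when displaced more than 100 ft
(0.3048 m/ft exactly) from the last emitted fix; report-time candidates
are always emitted. A per-participant lognormal activity factor spreads
fix counts widely, as in real cohorts. Finally a constant per-
participant offset is added to all coordinates, emulating the privacy
transformation, and recorded in the ground truth.

Determinism: `SeedSequence([master_seed, participant_index])` spawns
independent substreams for profile, occupancy, events, emission and
offset, so identical configs produce byte-identical cohorts and adding
participants never perturbs earlier ones.

Default parameters are calibrated so a default 38-participant cohort
matches the emulated study's pre-quit data characteristics —
~487 fixes, ~47 reported events, ~13.65 days, ~2.8 DBSCAN stay regions
per participant — with enrollment dates straddling 2023-05-11 in a
29:9 ratio. What the generator does *not* emulate: road-network
mobility, weather or social covariates, device/battery behaviour, and
post-quit behaviour change. Tests passing on these cohorts show the
pipeline recovers structure it was designed to detect; they do not
certify performance numbers on real populations.

## Experiment problem sizes

The packaged experiments (`smokegeo.experiments`) run the full ablation
grid at desk scale: 20 participants × ~5 study days for the
time-dominant regime (`beta_time = 6`, `rho = 1`), and 8 participants ×
~12 days for the location-dominant control (`beta_time = 0`, `rho = 0`,
`beta_loc = 4`, higher event rate so the preferred place is
majority-smoking). The control uses more days deliberately: with few
days each (day-of-week, bin) pair identifies a unique slot of the
study, letting flexible models memorise event windows through purely
temporal features; two weeks of uniform-habit data removes that
artefact. Desk-scale model capacities (50 trees, MLP early stopping at
tolerance 2e-3 with batch 64, epoch cap 100) are sized to the ~100–200
samples per participant these cohorts produce; scores saturate well
before the caps.

## Numerical and degenerate-input choices

Zero-variance DFI encodes as a zero column (guarded division).
Participants whose labels cannot support stratified 5-fold evaluation
(fewer than 10 samples, a single class, or a minority class under 5)
are skipped with a logged reason rather than aborting the grid. A
mixed-model fit with zero residual variance reports p = 0 for a perfect
nonzero slope and p = 1 otherwise. Identical constant groups in the
t-test return (0, 1). All-zero difference vectors are a degenerate
input to the signed-rank test and are reported as p = NA in comparison
tables. MLP scores are reproducible to 1e-6 for a fixed seed on the
same platform only.

## Known limitations

The generator's mobility model is schedule-driven rather than learned
from real trajectories; its corridor fixes are sparser than a
continuously logging phone would produce. The redundancy knob couples
time and place through a single hourly schedule, which is cruder than
real weekly routines. Classification folds are random over samples, so
temporally adjacent samples from one event can appear in both train and
test folds — the memorisation this permits is a property of the
emulated design itself and is why the falsification control uses long
uniform-habit windows. Association models treat bins independently with
no multiplicity correction by default.
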