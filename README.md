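# smokegeo

**How much does *where* you are add to *when* it is, for predicting
smoking events?**

Just-in-time adaptive interventions (JITAIs) for smoking cessation need
to predict moments of vulnerability from data a smartphone can collect
passively. Two obvious candidates are the clock and the GPS. `smokegeo`
is a reusable pipeline for measuring their relative predictive value on
cohorts of per-participant event streams — movement-triggered GPS fixes
plus self-reported smoking events — and, because real datasets of this
kind are access-restricted, it ships a calibrated synthetic cohort
generator with known temporal-habit and location structure so the whole
analysis is testable end to end.

The pipeline, for each participant:

1. **Harmonization** — each report at time *t* becomes a closed window
   `[t − H, t + H]` (half-time H ∈ {5, 10, 15, 20, 30} min); every GPS
   fix in a window is labeled smoking, others non-smoking; windows with
   no fix contribute a fallback sample from the nearest fix. Temporal
   features: one-hot quarter-hour bin (96/day), day of week, weekend
   flag, season.
2. **Spatial features** — one of three per-participant location
   representations: DBSCAN stay-region labels (noise is its own
   category), K-means labels with the cluster count chosen by
   silhouette score, or DFI (great-circle metres from the first fix).
3. **Ablation grid** — {DBSCAN, K-means, DFI} × {logistic regression,
   random forest, MLP(300, 150)} × {5 half-times} × {all features /
   location-excluded / time-excluded}, stratified 5-fold CV, scored by
   Macro-F1 = ½(F1₀ + F1₁).
4. **Statistics** — paired Wilcoxon signed-rank tests of each ablation
   against all-features (exact by sign-pattern enumeration for n ≤ 15),
   Welch t-tests for subgroup characteristics, an enrollment-date
   subgroup split at 2023-05-11, and per-time-bin linear mixed models
   (participant random intercepts) quantifying time–location
   redundancy, with association-rule support values.

On synthetic cohorts built to be *time-dominant and location-redundant*
(strong habit peaks; hour of day determines the occupied place), the
grid reproduces the expected signature: excluding temporal features
costs on the order of 20+ Macro-F1 points (p < 0.005 in every
configuration), while excluding location costs well under one point —
and the location-excluded column is identical across the three spatial
methods by construction. A location-dominant, time-uniform control
cohort reverses the pattern, so the pipeline is not biased toward
temporal features.

## Worked example

```python
from smokegeo.pipeline import run_all

config = {
    "generator": {"n_participants": 4, "days_mean": 5, "days_sd": 1,
                  "min_days": 4, "beta_time": 4.0, "base_rate": 0.4,
                  "n_anchors_range": [2, 3], "event_dispersion": 8.0,
                  "activity_sigma": 0.3, "stationary_samples": 1.5},
    "harmonization": {"half_times": [15], "bin_width_min": 15},
    "modeling": {"families": ["lr"]},
    "seed": 5,
}
out = run_all(config, "demo_run")
```

`demo_run/table_ablation.csv` (Macro-F1 as percent, "mean (SD)" across
participants):

```
spatial_method family  half_time_min          all  no_location      no_time
        dbscan     lr           15.0 97.48 (0.02) 96.85 (0.03) 77.65 (0.20)
           dfi     lr           15.0 96.77 (0.04) 96.85 (0.03) 72.95 (0.21)
        kmeans     lr           15.0 97.52 (0.03) 96.85 (0.03) 68.99 (0.18)
```

Removing the time features costs ~20–29 points; removing location is
nearly free, and the `no_location` column repeats because it cannot
depend on the spatial method. (With only 4 participants the signed-rank
comparisons are flagged underpowered, so no significance stars are
attached.) `demo_run/table_characteristics.csv` summarises the cohort
the generator produced:

```
         variable            all         during          post
    observed_days    4.83 (0.38)    4.93 (0.40)   4.54 (0.00)
          n_fixes 165.50 (27.05) 176.00 (20.88) 134.00 (0.00)
         n_events  35.50 (22.07)  41.00 (23.43)  19.00 (0.00)
        n_samples 165.50 (27.05) 176.00 (20.88) 134.00 (0.00)
n_smoking_samples  45.50 (25.79)  50.67 (28.94)  30.00 (0.00)
       n_clusters    3.25 (0.50)    3.33 (0.58)   3.00 (0.00)
```

and `demo_run/association_summary.json` reports how many time-bin →
location-cluster associations were significant and the range of their
support values.

The same stages are available from the shell:

```sh
smokegeo simulate --config cfg.yaml --out cohort/ --seed 1
smokegeo run-all  --config cfg.yaml --out results/ --seed 1
```

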