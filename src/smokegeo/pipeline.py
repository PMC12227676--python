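"""End-to-end orchestration: simulate -> harmonize -> features -> model ->
stats -> report.

A run is driven by a YAML/dict configuration validated up front (unknown
keys are rejected by name), executes the enabled stages in order into an
output directory, and writes a JSON manifest (config hash + seed +
package version) so every output file is traceable to the run that
produced it. Reruns with the same config and seed reproduce the same
result CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, ParticipantSkipped
from .harmonize import (DEFAULT_HALF_TIMES, EventStream, SampleTable,
                        build_sample_table, parse_event_stream,
                        restrict_to_prequit)
from .modeling import GridConfig, run_grid
from .spatial import (METHODS, SpatialConfig, SpatialRepresentation,
                      compute_representation, dbscan_clusters)
from .stats import association_analysis, compare_ablations, covid_subgroup_split
from .synthetic import GeneratorConfig, generate_cohort

logger = logging.getLogger(__name__)

_ALLOWED_KEYS = {
    "": {"generator", "harmonization", "spatial", "modeling", "stats",
         "stages", "seed", "log_level"},
    "generator": {f.name for f in dataclasses.fields(GeneratorConfig)},
    "harmonization": {"half_times", "bin_width_min", "feature_semantics"},
    "spatial": {"methods", "eps_m", "min_samples", "k_range",
                "distance_model", "seed"},
    "modeling": {"families", "ablations", "min_samples", "model_params",
                 "pool_participants"},
    "stats": {"min_pairs", "bh_correct", "outcome_coding", "pooled",
              "association_bin_widths", "subgroups"},
}
_STAGES = ("simulate", "harmonize", "features", "model", "stats", "report")


def validate_config(config: dict) -> dict:
    """Reject unknown keys by name; return the config unchanged."""
    for key in config:
        if key not in _ALLOWED_KEYS[""]:
            raise ConfigError(f"unknown config key '{key}'")
    for section, allowed in _ALLOWED_KEYS.items():
        if not section or section not in config:
            continue
        for key in config[section]:
            if key not in allowed:
                raise ConfigError(f"unknown config key '{section}.{key}'")
    for stage in config.get("stages", []):
        if stage not in _STAGES:
            raise ConfigError(f"unknown stage '{stage}'")
    return config


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return validate_config(cfg)


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def load_cohort(cohort_dir) -> dict[str, EventStream]:
    """Parse every participant's CSVs under a cohort directory."""
    cohort_dir = Path(cohort_dir)
    meta = pd.read_csv(cohort_dir / "metadata.csv")
    streams: dict[str, EventStream] = {}
    for _, row in meta.iterrows():
        pid = str(row["participant_id"])
        stream = parse_event_stream(cohort_dir / f"{pid}_gps.csv",
                                    cohort_dir / f"{pid}_reports.csv",
                                    row.to_dict())
        if stream.quit_datetime is not None:
            stream = restrict_to_prequit(stream)
        streams[pid] = stream
    return streams


def harmonize_cohort(
    streams: dict[str, EventStream],
    half_times=DEFAULT_HALF_TIMES,
    bin_width_min: int = 15,
    feature_semantics: str = "onehot",
) -> dict[str, dict[float, SampleTable]]:
    return {
        pid: {h: build_sample_table(s, h, bin_width_min, feature_semantics)
              for h in half_times}
        for pid, s in streams.items()
    }


def compute_representations(
    streams: dict[str, EventStream],
    methods=METHODS,
    spatial_cfg: SpatialConfig | None = None,
) -> dict[str, dict[str, SpatialRepresentation]]:
    """Per-fix location representations on each participant's raw fixes."""
    base = spatial_cfg or SpatialConfig()
    reps: dict[str, dict[str, SpatialRepresentation]] = {}
    for pid, s in streams.items():
        lat = s.fixes["lat"].to_numpy()
        lon = s.fixes["lon"].to_numpy()
        reps[pid] = {}
        for m in methods:
            cfg = dataclasses.replace(base, method=m)
            reps[pid][m] = compute_representation(lat, lon, cfg)
    return reps


def summarize_cohort(
    streams: dict[str, EventStream],
    tables: dict[str, dict[float, SampleTable]] | None = None,
    half_time: float = 15.0,
    spatial_cfg: SpatialConfig | None = None,
) -> pd.DataFrame:
    """Per-participant data characteristics (fixes, events, samples,
    smoking-labeled samples, dense clusters, study days, group)."""
    rows = []
    for pid, s in streams.items():
        rep = dbscan_clusters(s.fixes["lat"].to_numpy(),
                              s.fixes["lon"].to_numpy(), spatial_cfg)
        n_clusters = int(rep.values.max() + 1) if len(rep.values) else 0
        row = {
            "participant_id": pid,
            "group": s.group,
            "n_fixes": len(s.fixes),
            "n_events": len(s.reports),
            "n_clusters": n_clusters,
        }
        if s.fixes["timestamp"].notna().any():
            span = (s.fixes["timestamp"].iloc[-1]
                    - s.fixes["timestamp"].iloc[0])
            row["observed_days"] = span.total_seconds() / 86400.0
        if tables is not None and pid in tables and half_time in tables[pid]:
            t = tables[pid][half_time]
            row["n_samples"] = len(t)
            row["n_smoking_samples"] = int(t.data["label"].sum())
        rows.append(row)
    return pd.DataFrame(rows)


def samples_with_clusters(
    tables: dict[str, dict[float, SampleTable]],
    representations: dict[str, dict[str, SpatialRepresentation]],
    half_time: float = 15.0,
    method: str = "dbscan",
) -> pd.DataFrame:
    """Pool sample tables with DBSCAN cluster labels attached, the input
    to the time-location association analysis."""
    frames = []
    for pid, by_half in tables.items():
        t = by_half[half_time]
        rep = representations[pid][method]
        df = t.data.copy()
        df["cluster"] = rep.values[df["source_fix_idx"].to_numpy(dtype=int)]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _stars(p) -> str:
    if p is None or (isinstance(p, float) and np.isnan(p)):
        return ""
    if p < 0.005:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def render_ablation_table(aggregate: pd.DataFrame,
                          comparisons: pd.DataFrame) -> pd.DataFrame:
    """Grid results as percent 'mean (SD)' cells with significance stars.

    One row per (spatial method, family, half-time); columns for the
    all-features, location-excluded and time-excluded feature sets. SDs
    are across participants, printed on both the percent scale and, in
    parentheses, the raw fraction scale used by the cells.
    """
    rows = []
    key_cols = ["spatial_method", "family", "half_time_min"]
    for key, grp in aggregate.groupby(key_cols):
        cells = {}
        for _, r in grp.iterrows():
            star = ""
            if r["ablation"] != "all" and len(comparisons):
                m = comparisons[
                    (comparisons["spatial_method"] == key[0])
                    & (comparisons["family"] == key[1])
                    & (comparisons["half_time_min"] == key[2])
                    & (comparisons["comparison"] == r["ablation"])]
                if len(m):
                    star = _stars(m["p_value"].iloc[0])
            sd = 0.0 if np.isnan(r["sd_score"]) else r["sd_score"]
            cells[r["ablation"]] = (
                f"{100 * r['mean_score']:.2f} ({sd:.2f}){star}")
        rows.append({"spatial_method": key[0], "family": key[1],
                     "half_time_min": key[2], **cells})
    return pd.DataFrame(rows).sort_values(key_cols).reset_index(drop=True)


def render_characteristics_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Cohort data-characteristics table: 'mean (SD)' per variable, for
    all participants and for the during/post emergency subgroups."""
    variables = [c for c in ("observed_days", "n_fixes", "n_events",
                             "n_samples", "n_smoking_samples", "n_clusters")
                 if c in summary.columns]

    def fmt(sub: pd.DataFrame, var: str) -> str:
        if len(sub) == 0:
            return "NA"
        v = sub[var].astype(float)
        sd = v.std() if len(v) > 1 else 0.0
        return f"{v.mean():.2f} ({sd:.2f})"

    rows = []
    groups = {"all": summary,
              "during": summary[summary["group"] == "during"],
              "post": summary[summary["group"] == "post"]}
    for var in variables:
        rows.append({"variable": var,
                     **{g: fmt(df, var) for g, df in groups.items()}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run-all
# ---------------------------------------------------------------------------

def run_all(config: dict | str | Path, out_dir, seed: int | None = None) -> Path:
    """Execute the enabled stages in order; returns the output directory.

    Partial failures leave completed stage outputs intact and mark the
    manifest incomplete.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = int(config.get("seed", 0))
    stages = config.get("stages", list(_STAGES))

    manifest = {"config_hash": config_hash(config), "seed": seed,
                "version": __version__, "status": "incomplete",
                "stages": stages}
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))

    gen_cfg = GeneratorConfig(**{**config.get("generator", {}), "seed": seed})
    harm = config.get("harmonization", {})
    half_times = [float(h) for h in harm.get("half_times", DEFAULT_HALF_TIMES)]
    bin_width = int(harm.get("bin_width_min", 15))
    sp = config.get("spatial", {})
    methods = tuple(sp.get("methods", METHODS))
    spatial_cfg = SpatialConfig(
        eps_m=float(sp.get("eps_m", 100.0)),
        min_samples=int(sp.get("min_samples", 5)),
        k_range=tuple(sp.get("k_range", (2, 10))),
        distance_model=sp.get("distance_model", "haversine"),
        seed=seed,
    )
    mod = config.get("modeling", {})
    grid_cfg = GridConfig(
        spatial_methods=methods,
        families=tuple(mod.get("families", ("lr", "rf", "mlp"))),
        half_times=half_times,
        ablations=tuple(mod.get("ablations",
                                ("all", "no_location", "no_time"))),
        seed=seed,
        min_samples=int(mod.get("min_samples", 10)),
        pool_participants=bool(mod.get("pool_participants", False)),
    )
    st = config.get("stats", {})

    cohort_dir = out / "cohort"
    if "simulate" in stages:
        generate_cohort(gen_cfg, cohort_dir)
        logger.info("simulated cohort of %d participants",
                    gen_cfg.n_participants)

    streams = load_cohort(cohort_dir)
    tables = harmonize_cohort(streams, half_times, bin_width,
                              harm.get("feature_semantics", "onehot"))
    if "harmonize" in stages:
        tdir = out / "samples"
        tdir.mkdir(exist_ok=True)
        for pid, by_half in tables.items():
            for h, t in by_half.items():
                t.data.to_csv(tdir / f"{pid}_H{h:g}.csv", index=False)

    reps = compute_representations(streams, methods, spatial_cfg)
    if "features" in stages:
        fdir = out / "features"
        fdir.mkdir(exist_ok=True)
        for pid, by_m in reps.items():
            pd.DataFrame({m: r.values for m, r in by_m.items()}).to_csv(
                fdir / f"{pid}_spatial.csv", index=False)

    if "model" in stages:
        result = run_grid(tables, reps, grid_cfg)
        result.records.to_csv(out / "grid_records.csv", index=False)
        result.aggregate().to_csv(out / "grid_aggregate.csv", index=False)
        if result.skipped:
            pd.DataFrame(result.skipped,
                         columns=["participant_id", "reason"]).to_csv(
                out / "skipped.csv", index=False)

    if "stats" in stages and (out / "grid_records.csv").exists():
        from .modeling import AblationResult
        records = pd.read_csv(out / "grid_records.csv")
        comparisons = compare_ablations(AblationResult(records),
                                        int(st.get("min_pairs", 6)))
        comparisons.to_csv(out / "comparisons.csv", index=False)
        if st.get("subgroups", True):
            meta = pd.read_csv(cohort_dir / "metadata.csv")
            during, post = covid_subgroup_split(meta)
            for name, pids in (("during", during), ("post", post)):
                sub = records[records["participant_id"].isin(pids)]
                if not len(sub):
                    continue
                sub_res = AblationResult(sub)
                sub_res.aggregate().to_csv(
                    out / f"grid_aggregate_{name}.csv", index=False)
                compare_ablations(sub_res, int(st.get("min_pairs", 6))).to_csv(
                    out / f"comparisons_{name}.csv", index=False)
        ref_half = half_times[min(2, len(half_times) - 1)]
        if "dbscan" in methods:
            samples = samples_with_clusters(tables, reps, ref_half, "dbscan")
            widths = [int(w) for w in
                      st.get("association_bin_widths", (15, 30))]
            frames = [association_analysis(
                samples, bin_width_min=w,
                outcome_coding=st.get("outcome_coding",
                                      "modal_cluster_binary"),
                pooled=bool(st.get("pooled", True))) for w in widths]
            assoc = pd.concat(frames, ignore_index=True)
            assoc.to_csv(out / "associations.csv", index=False)
            summary = {}
            for w, frame in zip(widths, frames):
                sig = frame[frame["significant"]
                            & frame["support_pct"].notna()]
                summary[f"bin_width_{w}"] = {
                    "n_significant": int(frame["significant"].sum()),
                    "support_min_pct": (float(sig["support_pct"].min())
                                        if len(sig) else None),
                    "support_max_pct": (float(sig["support_pct"].max())
                                        if len(sig) else None),
                }
            (out / "association_summary.json").write_text(
                json.dumps(summary, indent=1))

    if "report" in stages:
        summary = summarize_cohort(streams, tables,
                                   half_times[min(2, len(half_times) - 1)],
                                   spatial_cfg)
        summary.to_csv(out / "participant_summary.csv", index=False)
        render_characteristics_table(summary).to_csv(
            out / "table_characteristics.csv", index=False)
        for suffix in ("", "_during", "_post"):
            agg_path = out / f"grid_aggregate{suffix}.csv"
            if not agg_path.exists():
                continue
            aggregate = pd.read_csv(agg_path)
            cmp_path = out / f"comparisons{suffix}.csv"
            comparisons = (pd.read_csv(cmp_path) if cmp_path.exists()
                           else pd.DataFrame())
            render_ablation_table(aggregate, comparisons).to_csv(
                out / f"table_ablation{suffix}.csv", index=False)

    manifest["status"] = "complete"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return out
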