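"""Generator behaviour: determinism, limiting cases, emission rule,
privacy offset, and the redundancy knob."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import mutual_info_score

from smokegeo.errors import ConfigError
from smokegeo.spatial import dbscan_clusters
from smokegeo.synthetic import (GeneratorConfig, ParticipantProfile,
                                apply_privacy_offset, generate_cohort,
                                generate_participant,
                                sample_participant_profile,
                                simulate_mobility, simulate_occupancy,
                                simulate_smoking_events)


@pytest.mark.parametrize("field,value", [
    ("n_participants", 0),
    ("days_mean", -1.0),
    ("rho_redundancy", 1.5),
    ("mobility_factor", 0.0),
    ("base_rate", -0.1),
    ("n_anchors_range", (0, 3)),
])
def test_invalid_config_names_field(field, value):
    with pytest.raises(ConfigError):
        GeneratorConfig(**{field: value})


def test_zero_concentration_gives_uniform_habit_profile():
    cfg = GeneratorConfig(beta_time=0.0, seed=1)
    prof = sample_participant_profile(cfg, 0)
    assert np.allclose(prof.habit_profile, 1.0 / 96)


def test_profile_deterministic_for_same_seed_and_index():
    cfg = GeneratorConfig(seed=9)
    a = sample_participant_profile(cfg, 3)
    b = sample_participant_profile(cfg, 3)
    assert a.anchors == b.anchors
    assert np.array_equal(a.habit_profile, b.habit_profile)
    assert a.study_days == b.study_days
    assert a.enrollment_date == b.enrollment_date


def test_study_days_distribution_matches_configured_mean():
    cfg = GeneratorConfig(n_participants=1000, seed=2)
    days = np.array([sample_participant_profile(cfg, i).study_days
                     for i in range(1000)])
    se = days.std() / np.sqrt(len(days))
    assert abs(days.mean() - 13.65) < 3 * se
    assert days.min() >= cfg.min_days


def test_habit_profile_valid_simplex():
    cfg = GeneratorConfig(seed=4)
    for i in range(5):
        prof = sample_participant_profile(cfg, i)
        assert prof.habit_profile.shape == (96,)
        assert abs(prof.habit_profile.sum() - 1.0) < 1e-9
        assert (prof.habit_profile >= 0).all()


def _stationary_profile(gps_noise=0.0) -> tuple[ParticipantProfile, GeneratorConfig]:
    cfg = GeneratorConfig(n_participants=1, n_anchors_range=(1, 1),
                          gps_noise_sd_m=gps_noise, seed=5, days_mean=3,
                          days_sd=0.0, min_days=3)
    return sample_participant_profile(cfg, 0), cfg


def test_no_movement_emits_fixes_only_at_report_times():
    prof, cfg = _stationary_profile(gps_noise=0.0)
    rng = np.random.default_rng(0)
    reports = [prof.study_start + pd.Timedelta(hours=h) for h in (10, 30, 50)]
    fixes, occ = simulate_mobility(prof, cfg, rng, report_times=reports)
    assert len(fixes) == 3
    assert list(fixes["timestamp"]) == reports
    lat0, lon0 = prof.anchors[0]
    assert np.allclose(fixes["lat"], lat0)
    assert np.allclose(fixes["lon"], lon0)


def test_each_kilometre_transition_emits_a_fix():
    cfg = GeneratorConfig(seed=0, gps_noise_sd_m=0.0, route_jitter_m=0.0)
    sched = np.zeros(24, dtype=int)
    sched[10:14] = 1  # one commute out and back per day
    prof = ParticipantProfile(
        participant_id="T", anchors=[(40.0, -90.0), (40.009, -90.0)],
        habit_profile=np.full(96, 1 / 96), anchor_preference=np.array([.5, .5]),
        enrollment_date=date(2023, 3, 6), timezone="-06:00", study_days=2.0,
        group="during", schedule=sched, activity=1.0)
    rng = np.random.default_rng(1)
    occ = simulate_occupancy(prof, cfg, rng)
    n_transitions = int((np.diff(occ.anchor_idx) != 0).sum())
    assert n_transitions == 4  # 2 days x (out + back)
    fixes, _ = simulate_mobility(prof, cfg, np.random.default_rng(1))
    assert len(fixes) >= n_transitions


def test_zero_base_rate_yields_no_events():
    cfg = GeneratorConfig(base_rate=0.0, seed=3)
    prof = sample_participant_profile(cfg, 0)
    occ = simulate_occupancy(prof, cfg, np.random.default_rng(0))
    reports, gt = simulate_smoking_events(prof, occ, cfg,
                                          np.random.default_rng(0))
    assert len(reports) == 0 and len(gt.true_times) == 0


def test_concentrated_habit_confines_events_to_peak():
    """With a single sharp habit peak, nearly all events land within +-3
    bins of it, and the Monte-Carlo share matches direct summation of
    the slot intensities."""
    cfg = GeneratorConfig(n_participants=1, seed=6, beta_time=8.0,
                          n_habit_peaks_range=(1, 1), base_rate=4.0,
                          days_mean=16, days_sd=0, min_days=3,
                          event_dispersion=0.0, beta_loc=0.0,
                          report_jitter_sd_min=0.0)
    prof = sample_participant_profile(cfg, 0)
    occ = simulate_occupancy(prof, cfg, np.random.default_rng(2))
    _, gt = simulate_smoking_events(prof, occ, cfg, np.random.default_rng(2))
    assert len(gt.true_times) > 800
    peak = int(np.argmax(prof.habit_profile))
    bins = np.array([(t.hour * 60 + t.minute) // 15 for t in gt.true_times])
    circ = np.minimum((bins - peak) % 96, (peak - bins) % 96)
    mc_share = (circ <= 3).mean()
    assert mc_share >= 0.9

    # independent check: summed slot intensity mass in the neighbourhood
    h = prof.habit_profile
    h_std = (h - h.mean()) / h.std()
    w = np.exp(cfg.beta_time * h_std[occ.bin_idx])
    near = np.minimum((occ.bin_idx - peak) % 96, (peak - occ.bin_idx) % 96) <= 3
    expected_share = w[near].sum() / w.sum()
    assert abs(mc_share - expected_share) < 0.05


def test_privacy_offset_preserves_pairwise_distances(rng):
    lat = 40 + rng.normal(0, 0.02, 60)
    lon = -90 + rng.normal(0, 0.02, 60)
    ts = pd.date_range("2023-03-06", periods=60, freq="h", tz="-06:00")
    fixes = pd.DataFrame({"timestamp": ts, "lat": lat, "lon": lon})
    shifted, (dlat, dlon) = apply_privacy_offset(fixes, rng, max_offset_deg=0.9)
    assert (shifted["timestamp"] == fixes["timestamp"]).all()

    coslat = np.cos(np.radians(np.asarray(fixes["lat"]).mean()))

    def pairwise(la, lo):
        # equirectangular distances in the participant's local plane
        la, lo = np.asarray(la), np.asarray(lo)
        dx = (lo[:, None] - lo[None, :]) * coslat
        dy = la[:, None] - la[None, :]
        return np.hypot(dx, dy)

    d0 = pairwise(fixes["lat"], fixes["lon"])
    d1 = pairwise(shifted["lat"], shifted["lon"])
    mask = d0 > 0
    assert np.max(np.abs(d1[mask] - d0[mask]) / d0[mask]) < 1e-6


def test_privacy_offset_is_identity_at_zero(rng):
    fixes = pd.DataFrame({
        "timestamp": pd.date_range("2023-03-06", periods=3, freq="h",
                                   tz="-06:00"),
        "lat": [40.0, 40.001, 40.002], "lon": [-90.0, -90.0, -90.0]})
    shifted, _ = apply_privacy_offset(fixes, rng, max_offset_deg=0.0)
    assert np.allclose(shifted["lat"], fixes["lat"])
    assert np.allclose(shifted["lon"], fixes["lon"])


def test_dbscan_labels_unchanged_by_privacy_offset(rng):
    lat = np.r_[40 + rng.normal(0, 3e-4, 30), 40.05 + rng.normal(0, 3e-4, 30)]
    lon = np.full(60, -90.0) + rng.normal(0, 3e-4, 60)
    ts = pd.date_range("2023-03-06", periods=60, freq="15min", tz="-06:00")
    fixes = pd.DataFrame({"timestamp": ts, "lat": lat, "lon": lon})
    shifted, _ = apply_privacy_offset(fixes, rng, max_offset_deg=0.3)
    a = dbscan_clusters(fixes["lat"], fixes["lon"]).values
    b = dbscan_clusters(shifted["lat"], shifted["lon"]).values
    assert np.array_equal(a, b)


def test_cohort_file_counts_and_byte_determinism(tmp_path):
    cfg = GeneratorConfig(n_participants=2, seed=7, days_mean=4, days_sd=0.5,
                          min_days=3)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    generate_cohort(cfg, d1)
    generate_cohort(cfg, d2)
    gps = sorted(p.name for p in d1.glob("*_gps.csv"))
    rep = sorted(p.name for p in d1.glob("*_reports.csv"))
    assert gps == ["P01_gps.csv", "P02_gps.csv"]
    assert rep == ["P01_reports.csv", "P02_reports.csv"]
    assert (d1 / "metadata.csv").exists()
    for p1 in sorted(d1.rglob("*")):
        if p1.is_file():
            p2 = d2 / p1.relative_to(d1)
            assert p1.read_bytes() == p2.read_bytes(), p1.name


def test_adding_participants_never_perturbs_earlier_ones(tmp_path):
    small = GeneratorConfig(n_participants=2, seed=11, days_mean=4,
                            days_sd=0.5, min_days=3)
    big = GeneratorConfig(n_participants=4, seed=11, days_mean=4,
                          days_sd=0.5, min_days=3)
    d1, d2 = tmp_path / "s", tmp_path / "b"
    generate_cohort(small, d1)
    generate_cohort(big, d2)
    for name in ("P01_gps.csv", "P01_reports.csv", "P02_gps.csv"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


def test_reports_stay_inside_study_window():
    cfg = GeneratorConfig(n_participants=4, seed=13, days_mean=5, days_sd=1,
                          min_days=3)
    for i in range(4):
        prof, fixes, reports, _ = generate_participant(cfg, i)
        if len(reports):
            assert reports["timestamp"].min() >= prof.study_start
            assert reports["timestamp"].max() < prof.study_end


def test_redundancy_knob_controls_time_anchor_coupling():
    """rho=1 makes occupancy a deterministic function of hour of day;
    rho=0 makes it statistically independent of it (permutation test)."""
    base = dict(n_participants=1, seed=17, days_mean=10, days_sd=0,
                min_days=3, n_anchors_range=(3, 3), move_prob=0.3)
    cfg1 = GeneratorConfig(rho_redundancy=1.0, **base)
    prof = sample_participant_profile(cfg1, 0)
    occ = simulate_occupancy(prof, cfg1, np.random.default_rng(0))
    hours = occ.bin_idx // 4
    assert np.array_equal(occ.anchor_idx, prof.schedule[hours])

    cfg0 = GeneratorConfig(rho_redundancy=0.0, **base)
    occ0 = simulate_occupancy(prof, cfg0, np.random.default_rng(0))
    hours0 = occ0.bin_idx // 4
    obs = mutual_info_score(hours0, occ0.anchor_idx)
    # circular-shift permutations: occupancy dwells are autocorrelated,
    # so the null must preserve run structure while breaking the
    # alignment with wall-clock hour
    perm_rng = np.random.default_rng(1)
    shifts = perm_rng.integers(1, len(hours0) - 1, 200)
    perms = np.array([
        mutual_info_score(hours0, np.roll(occ0.anchor_idx, int(k)))
        for k in shifts if k % 64 != 0])
    p = (perms >= obs).mean()
    assert p > 0.05
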