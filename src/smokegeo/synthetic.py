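"""Synthetic cohort generator for geotemporal smoking-event analysis.

Real study data of this kind (movement-triggered GPS streams plus
self-reported smoking events) are access-restricted, so every downstream
stage of the pipeline is exercised against simulated cohorts with *known*
temporal-habit and location structure.

The generative model, per participant:

* a small set of anchor locations (home / work / other places) scattered
  around a personal centre;
* a 96-bin quarter-hour habit profile over the day — a mixture of 1-4
  wrapped (circular) peaks blended with a uniform floor, the blend
  controlled by ``beta_time`` (``beta_time = 0`` gives a uniform profile);
* an hourly visit schedule mapping hour-of-day to a preferred anchor.
  Occupancy of anchors follows the schedule with probability
  ``rho_redundancy`` and otherwise evolves as a sticky, time-independent
  random walk over anchors, so ``rho_redundancy`` dials how redundant
  location is with time of day;
* smoking events drawn from an inhomogeneous Poisson process with
  intensity proportional to ``base_rate * exp(beta_time * h(t) +
  beta_loc * g(anchor(t)))`` where ``h`` is the standardized habit profile
  and ``g`` the standardized anchor preference, restricted to waking hours
  (07:00-23:00) and normalised so ``base_rate`` is the mean number of
  events per waking hour;
* GPS fixes emitted whenever displacement since the last emitted fix
  exceeds a movement threshold (100 ft by default, 1 ft = 0.3048 m) and at
  every smoking-report time, with Gaussian positional noise;
* a per-participant constant privacy offset added to all coordinates,
  preserving relative distances.

Determinism: the master seed and the participant index feed a
``numpy.random.SeedSequence([seed, index])``; independent child streams
drive the profile, occupancy, events, fix emission and privacy offset.
Adding participants to a cohort therefore never perturbs earlier ones.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from datetime import date, datetime, timedelta, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

FT_TO_M = 0.3048
BINS_PER_DAY = 96
SLOT_MIN = 15
WAKING_START_H = 7  # events and mobility modeled 07:00-23:00 local
WAKING_END_H = 23
SLOTS_PER_DAY = (WAKING_END_H - WAKING_START_H) * 60 // SLOT_MIN
M_PER_DEG_LAT = 111_320.0
COVID_EMERGENCY_END = date(2023, 5, 11)

# US fixed-offset timezones with cohort weights mirroring a nationwide
# remote study skewed to Eastern/Central time.
_TZ_OFFSETS_H = (-5, -6, -7, -8)
_TZ_WEIGHTS = (19, 15, 3, 1)


# ---------------------------------------------------------------------------
# configuration and profile types
# ---------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    """Tunable knobs of the cohort generator.

    Defaults are calibrated so that a default cohort reproduces the
    observed pre-quit scale of the study population this generator
    emulates: ~38 participants, ~13.65 (SD 3.43) days of data, ~487 GPS
    fixes and ~47 smoking reports per participant, and ~2.8 dense
    geolocation clusters.
    """

    n_participants: int = 38
    days_mean: float = 13.65
    days_sd: float = 3.43
    min_days: float = 3.0
    n_anchors_range: tuple[int, int] = (1, 6)
    anchor_geometric_ratio: float = 0.62  # P(k anchors) ~ ratio**(k-1)
    anchor_spread_m: float = 5000.0
    visit_schedule: Mapping[int, Sequence[float]] | None = None
    base_rate: float = 0.212  # smoking events per waking hour
    beta_time: float = 2.0  # habit concentration (>=0)
    beta_loc: float = 0.5  # location-preference strength (>=0)
    rho_redundancy: float = 1.0  # P(hour determines anchor), in [0, 1]
    move_prob: float = 0.05  # per-slot transition prob in the rho=0 branch
    path_samples: float = 1.5  # mean en-route GPS samples per transition
    stationary_samples: float = 3.9  # mean position samples per 15-min slot
    route_jitter_m: float = 400.0  # lateral route variability between trips
    activity_sigma: float = 0.9  # lognormal sd of per-participant mobility
    event_dispersion: float = 1.85  # gamma shape of per-participant event rate
    n_habit_peaks_range: tuple[int, int] = (1, 4)
    report_jitter_sd_min: float = 3.0
    fix_threshold_ft: float = 100.0
    gps_noise_sd_m: float = 10.0
    mobility_factor: float = 1.0
    p_post_covid: float = 9 / 38
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n_participants) < 1:
            raise ConfigError("n_participants must be >= 1")
        if self.days_mean <= 0:
            raise ConfigError("days_mean must be > 0")
        if not (0.0 <= self.rho_redundancy <= 1.0):
            raise ConfigError("rho_redundancy must lie in [0, 1]")
        if not (0.0 < self.mobility_factor <= 1.0):
            raise ConfigError("mobility_factor must lie in (0, 1]")
        if not (0.0 <= self.p_post_covid <= 1.0):
            raise ConfigError("p_post_covid must lie in [0, 1]")
        lo, hi = self.n_anchors_range
        if lo < 1 or hi < lo:
            raise ConfigError("n_anchors_range must satisfy 1 <= lo <= hi")
        for name in ("days_sd", "min_days", "anchor_spread_m", "base_rate",
                     "beta_time", "beta_loc", "report_jitter_sd_min",
                     "fix_threshold_ft", "gps_noise_sd_m", "path_samples",
                     "activity_sigma", "event_dispersion", "move_prob",
                     "route_jitter_m", "stationary_samples"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")

    @property
    def fix_threshold_m(self) -> float:
        return self.fix_threshold_ft * FT_TO_M


@dataclass
class ParticipantProfile:
    """Frozen per-participant parameters drawn from the config."""

    participant_id: str
    anchors: list[tuple[float, float]]  # (lat, lon)
    habit_profile: np.ndarray  # 96 nonnegative weights summing to 1
    anchor_preference: np.ndarray  # per-anchor weights summing to 1
    enrollment_date: date
    timezone: str  # fixed offset, e.g. "-06:00"
    study_days: float
    group: str  # "during" or "post" (COVID emergency)
    schedule: np.ndarray = field(repr=False, default=None)  # hour -> anchor idx
    activity: float = 1.0  # lognormal mobility multiplier
    event_rate_mult: float = 1.0  # gamma multiplier on base_rate

    def __post_init__(self) -> None:
        self.habit_profile = np.asarray(self.habit_profile, dtype=float)
        if self.habit_profile.shape != (BINS_PER_DAY,):
            raise ConfigError("habit_profile must have exactly 96 entries")
        if abs(self.habit_profile.sum() - 1.0) > 1e-9:
            raise ConfigError("habit_profile must sum to 1 within 1e-9")
        if len(self.anchors) < 1:
            raise ConfigError("profile must have at least one anchor")

    @property
    def tzinfo(self) -> timezone:
        return parse_utc_offset(self.timezone)

    @property
    def study_start(self) -> pd.Timestamp:
        return pd.Timestamp(
            datetime.combine(self.enrollment_date, datetime.min.time()),
            tz=self.tzinfo,
        )

    @property
    def study_end(self) -> pd.Timestamp:
        return self.study_start + pd.Timedelta(days=self.study_days)


@dataclass
class GroundTruth:
    """Hidden generator state for one participant (for recovery tests)."""

    participant_id: str
    true_times: list[pd.Timestamp]
    event_anchor_idx: list[int]
    habit_profile: list[float]
    anchors: list[tuple[float, float]]  # as emitted (post privacy offset)
    anchor_preference: list[float]
    privacy_offset: tuple[float, float]
    schedule: list[int]

    def to_json(self) -> str:
        d = asdict(self)
        d["true_times"] = [t.isoformat() for t in self.true_times]
        return json.dumps(d, indent=1)


@dataclass
class OccupancyTimeline:
    """Anchor occupied during each 15-minute waking slot of the study."""

    slot_start: pd.DatetimeIndex
    anchor_idx: np.ndarray
    bin_idx: np.ndarray  # local quarter-hour bin 0..95

    def __len__(self) -> int:
        return len(self.anchor_idx)


def parse_utc_offset(tz: str) -> timezone:
    """Parse a fixed UTC offset such as ``-06:00`` or ``UTC-06:00``."""
    s = tz.strip()
    if s.upper().startswith("UTC"):
        s = s[3:]
    sign = -1 if s.startswith("-") else 1
    s = s.lstrip("+-")
    hh, _, mm = s.partition(":")
    return timezone(sign * timedelta(hours=int(hh), minutes=int(mm or 0)))


def _participant_streams(seed: int, index: int) -> list[np.random.Generator]:
    """Five independent streams per participant via a counter scheme."""
    ss = np.random.SeedSequence([int(seed), int(index)])
    return [np.random.default_rng(c) for c in ss.spawn(5)]


# ---------------------------------------------------------------------------
# participant profile
# ---------------------------------------------------------------------------

def _build_schedule(n_anchors: int) -> np.ndarray:
    """Hour-of-day -> preferred anchor.

    Anchor 0 is "home" (mornings, evenings, nights); remaining anchors
    fill weekday-style daytime blocks, so every anchor is visited.
    """
    sched = np.zeros(24, dtype=int)
    if n_anchors == 1:
        return sched
    blocks = [(9, 11), (12, 13), (14, 17), (18, 20)]
    others = list(range(1, n_anchors))
    for i, (h0, h1) in enumerate(blocks):
        sched[h0:h1 + 1] = others[i % len(others)]
    return sched


def _habit_mixture(rng: np.random.Generator, n_peaks: int) -> np.ndarray:
    """Mixture of wrapped von Mises peaks over 96 bins, normalised to sum 1."""
    theta = 2 * np.pi * (np.arange(BINS_PER_DAY) + 0.5) / BINS_PER_DAY
    waking_bins = np.arange(WAKING_START_H * 4, WAKING_END_H * 4)
    dens = np.zeros(BINS_PER_DAY)
    weights = rng.dirichlet(np.ones(n_peaks))
    for w in weights:
        center_bin = rng.choice(waking_bins)
        mu = 2 * np.pi * (center_bin + 0.5) / BINS_PER_DAY
        kappa = rng.uniform(20.0, 60.0)
        dens += w * np.exp(kappa * np.cos(theta - mu))
    return dens / dens.sum()


def sample_participant_profile(
    config: GeneratorConfig, participant_index: int
) -> ParticipantProfile:
    """Draw the frozen parameters for one participant.

    Deterministic given ``(config.seed, participant_index)``. Study length
    comes from a normal truncated below at ``config.min_days``; the habit
    profile is a uniform floor blended with 1-4 circular peaks, the blend
    weight ``1 - exp(-beta_time)`` so ``beta_time = 0`` yields the exactly
    uniform profile.
    """
    if participant_index >= config.n_participants:
        raise ConfigError("participant_index must be < n_participants")
    rng = _participant_streams(config.seed, participant_index)[0]
    pid = f"P{participant_index + 1:02d}"

    # study length: truncated normal (resample below min_days)
    study_days = rng.normal(config.days_mean, config.days_sd)
    while study_days < config.min_days:
        study_days = rng.normal(config.days_mean, config.days_sd)

    # anchor count ~ truncated geometric over the configured range
    lo, hi = config.n_anchors_range
    ks = np.arange(lo, hi + 1)
    w = config.anchor_geometric_ratio ** (ks - lo)
    n_anchors = int(rng.choice(ks, p=w / w.sum()))

    center_lat = rng.uniform(30.0, 47.0)
    center_lon = rng.uniform(-120.0, -75.0)
    spread_lat = config.anchor_spread_m / M_PER_DEG_LAT
    coslat = math.cos(math.radians(center_lat))
    spread_lon = spread_lat / coslat
    min_sep_m = min(400.0, config.anchor_spread_m)  # distinct places
    anchors: list[tuple[float, float]] = []
    while len(anchors) < n_anchors:
        cand = (center_lat + rng.uniform(-spread_lat, spread_lat),
                center_lon + rng.uniform(-spread_lon, spread_lon))
        ok = all(
            math.hypot((cand[0] - a[0]) * M_PER_DEG_LAT,
                       (cand[1] - a[1]) * M_PER_DEG_LAT * coslat) >= min_sep_m
            for a in anchors)
        if ok:
            anchors.append(cand)

    if config.beta_time > 0:
        n_peaks = int(rng.integers(config.n_habit_peaks_range[0],
                                   config.n_habit_peaks_range[1] + 1))
        mix = _habit_mixture(rng, n_peaks)
        wmix = 1.0 - math.exp(-config.beta_time)
        habit = (1.0 - wmix) / BINS_PER_DAY + wmix * mix
    else:
        habit = np.full(BINS_PER_DAY, 1.0 / BINS_PER_DAY)
    habit = habit / habit.sum()

    anchor_pref = rng.dirichlet(np.ones(n_anchors))

    if config.visit_schedule is not None:
        sched = np.zeros(24, dtype=int)
        for h in range(24):
            wts = np.asarray(config.visit_schedule.get(h, [1.0]), dtype=float)
            wts = wts[:n_anchors]
            if wts.sum() <= 0 or wts.size == 0:
                sched[h] = 0
            else:
                sched[h] = int(rng.choice(np.arange(wts.size), p=wts / wts.sum()))
    else:
        sched = _build_schedule(n_anchors)

    activity = float(rng.lognormal(-config.activity_sigma ** 2 / 2,
                                   config.activity_sigma))
    k = config.event_dispersion
    event_mult = float(rng.gamma(k, 1.0 / k)) if k > 0 else 1.0

    # enrollment straddles the 2023-05-11 emergency expiration
    n_post = round(config.n_participants * config.p_post_covid)
    is_post = participant_index >= config.n_participants - n_post
    if is_post:
        enroll = date(2023, 5, 12) + timedelta(days=int(rng.integers(0, 230)))
    else:
        enroll = date(2022, 1, 3) + timedelta(days=int(rng.integers(0, 490)))
    tz_h = int(rng.choice(_TZ_OFFSETS_H,
                          p=np.array(_TZ_WEIGHTS) / sum(_TZ_WEIGHTS)))
    tz_str = f"{tz_h:+03d}:00"

    return ParticipantProfile(
        participant_id=pid,
        anchors=anchors,
        habit_profile=habit,
        anchor_preference=anchor_pref,
        enrollment_date=enroll,
        timezone=tz_str,
        study_days=float(study_days),
        group="post" if is_post else "during",
        schedule=sched,
        activity=activity,
        event_rate_mult=event_mult,
    )


# ---------------------------------------------------------------------------
# mobility
# ---------------------------------------------------------------------------

def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def simulate_occupancy(
    profile: ParticipantProfile,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> OccupancyTimeline:
    """Anchor occupancy over all 15-minute waking slots of the study.

    Per slot, with probability ``rho_redundancy`` occupancy is the
    scheduled anchor for that hour; otherwise it stays put and only with
    probability ``move_prob * mobility_factor`` jumps to an anchor drawn
    from the (time-independent) anchor preference.
    """
    if len(profile.anchors) < 1:
        raise ConfigError("anchors must be non-empty")
    start, end = profile.study_start, profile.study_end
    n_days = int(math.ceil(profile.study_days)) + 1

    starts: list[pd.Timestamp] = []
    for d in range(n_days):
        day0 = start + pd.Timedelta(days=d)
        for s in range(SLOTS_PER_DAY):
            t = day0 + pd.Timedelta(minutes=WAKING_START_H * 60 + s * SLOT_MIN)
            if t >= end:
                break
            starts.append(t)
    idx = pd.DatetimeIndex(starts)

    n_anchors = len(profile.anchors)
    pref = profile.anchor_preference
    p_move = config.move_prob * config.mobility_factor
    occ = np.zeros(len(idx), dtype=int)
    prev = int(profile.schedule[WAKING_START_H])
    for i, t in enumerate(idx):
        if rng.random() < config.rho_redundancy:
            cur = int(profile.schedule[t.hour])
        elif n_anchors > 1 and rng.random() < p_move:
            cur = int(rng.choice(n_anchors, p=pref))
        else:
            cur = prev
        occ[i] = cur
        prev = cur

    bins = (idx.hour * 60 + idx.minute) // SLOT_MIN
    return OccupancyTimeline(slot_start=idx, anchor_idx=occ,
                             bin_idx=np.asarray(bins))


def _emit_fixes(
    profile: ParticipantProfile,
    occupancy: OccupancyTimeline,
    config: GeneratorConfig,
    rng: np.random.Generator,
    report_times: Sequence[pd.Timestamp] = (),
) -> pd.DataFrame:
    """Apply the movement-threshold emission rule to the position trace.

    Candidate positions: one per stationary slot at the occupied anchor,
    several en-route samples per transition slot, plus one unconditional
    candidate at each smoking-report time. A candidate becomes a fix when
    its displacement from the last *emitted* fix exceeds the threshold
    (100 ft by default); report-time candidates are always emitted.
    """
    anchors = np.asarray(profile.anchors)  # (A, 2) lat, lon
    noise_deg_lat = config.gps_noise_sd_m / M_PER_DEG_LAT
    lat0 = float(anchors[:, 0].mean())
    coslat = math.cos(math.radians(lat0))
    noise_deg_lon = noise_deg_lat / coslat

    times: list[pd.Timestamp] = []
    lats: list[float] = []
    lons: list[float] = []
    forced: list[bool] = []

    prev_anchor = None
    for i in range(len(occupancy)):
        t0 = occupancy.slot_start[i]
        a = int(occupancy.anchor_idx[i])
        if prev_anchor is None or a == prev_anchor:
            # within-place position samples; only those drifting past the
            # movement threshold will be emitted
            n_sub = rng.poisson(config.stationary_samples * profile.activity)
            for off in np.sort(rng.uniform(0, SLOT_MIN, n_sub)):
                times.append(t0 + pd.Timedelta(minutes=float(off)))
                lats.append(anchors[a, 0] + rng.normal(0, noise_deg_lat))
                lons.append(anchors[a, 1] + rng.normal(0, noise_deg_lon))
                forced.append(False)
        else:
            # transition: en-route samples then arrival at the new anchor
            n_path = max(1, int(rng.poisson(config.path_samples
                                            * profile.activity)))
            fracs = np.append(np.sort(rng.uniform(0, 1, n_path)), 1.0)
            p0, p1 = anchors[prev_anchor], anchors[a]
            # lateral route variability: each trip takes a slightly
            # different road, so en-route fixes do not densify into
            # spurious stay clusters across repeated traversals
            seg = np.array([p1[0] - p0[0], (p1[1] - p0[1]) * coslat])
            norm = np.hypot(*seg)
            perp = (np.array([-seg[1], seg[0]]) / norm if norm > 0
                    else np.zeros(2))
            jit_deg = config.route_jitter_m / M_PER_DEG_LAT
            bow = rng.normal(0, jit_deg)
            for j, f in enumerate(fracs):
                arc = bow * math.sin(math.pi * f) if f < 1 else 0.0
                times.append(t0 + pd.Timedelta(
                    minutes=SLOT_MIN * (j + 1) / (len(fracs) + 1)))
                lats.append(p0[0] + f * (p1[0] - p0[0]) + arc * perp[0]
                            + rng.normal(0, noise_deg_lat))
                lons.append(p0[1] + f * (p1[1] - p0[1])
                            + arc * perp[1] / coslat
                            + rng.normal(0, noise_deg_lon))
                forced.append(False)
        prev_anchor = a

    # unconditional candidates at report times, at the occupied anchor
    if len(report_times) and len(occupancy):
        slot_pos = np.searchsorted(occupancy.slot_start.asi8,
                                   pd.DatetimeIndex(report_times).asi8,
                                   side="right") - 1
        slot_pos = np.clip(slot_pos, 0, len(occupancy) - 1)
        for t, sp in zip(report_times, slot_pos):
            a = int(occupancy.anchor_idx[sp])
            times.append(pd.Timestamp(t))
            lats.append(anchors[a, 0] + rng.normal(0, noise_deg_lat))
            lons.append(anchors[a, 1] + rng.normal(0, noise_deg_lon))
            forced.append(True)

    if not times:
        return pd.DataFrame(columns=["timestamp", "lat", "lon"])

    order = np.argsort(pd.DatetimeIndex(times).asi8, kind="stable")
    lat_arr = np.asarray(lats)[order]
    lon_arr = np.asarray(lons)[order]
    forced_arr = np.asarray(forced)[order]
    t_idx = pd.DatetimeIndex(times)[order]

    thr = config.fix_threshold_m
    keep = np.zeros(len(t_idx), dtype=bool)
    last = None
    for i in range(len(t_idx)):
        if last is None:
            # first candidate sets the displacement reference; emitted
            # only if it is a report-time fix
            keep[i] = bool(forced_arr[i])
            last = (lat_arr[i], lon_arr[i])
            continue
        dlat_m = (lat_arr[i] - last[0]) * M_PER_DEG_LAT
        dlon_m = (lon_arr[i] - last[1]) * M_PER_DEG_LAT * coslat
        if forced_arr[i] or math.hypot(dlat_m, dlon_m) > thr:
            keep[i] = True
            last = (lat_arr[i], lon_arr[i])

    return pd.DataFrame({
        "timestamp": t_idx[keep],
        "lat": lat_arr[keep],
        "lon": lon_arr[keep],
    }).reset_index(drop=True)


def simulate_mobility(
    profile: ParticipantProfile,
    config: GeneratorConfig,
    rng: np.random.Generator,
    report_times: Sequence[pd.Timestamp] = (),
) -> tuple[pd.DataFrame, OccupancyTimeline]:
    """Simulate anchor occupancy and the emitted movement-triggered fixes."""
    occ_rng, fix_rng = rng.spawn(2)
    occ = simulate_occupancy(profile, config, occ_rng)
    fixes = _emit_fixes(profile, occ, config, fix_rng, report_times)
    return fixes, occ


# ---------------------------------------------------------------------------
# smoking events
# ---------------------------------------------------------------------------

_PLACES = ("home", "work", "car", "bar_restaurant", "outdoors", "other")
_REASONS = ("habit", "stress", "boredom", "social", "break", "craving")


def simulate_smoking_events(
    profile: ParticipantProfile,
    occupancy: OccupancyTimeline,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw smoking events from the habit/location-modulated intensity.

    The intensity over 15-minute slots is proportional to
    ``exp(beta_time * h(bin) + beta_loc * g(anchor))`` with ``h`` and ``g``
    standardized, normalised so the expected event count equals
    ``base_rate * waking_hours * event_rate_mult``. Reported timestamps
    add Gaussian jitter and are clipped to the study window.
    """
    h_std = _standardize(profile.habit_profile)
    g_std = _standardize(profile.anchor_preference.astype(float))

    n_slots = len(occupancy)
    if n_slots == 0 or config.base_rate == 0:
        empty = pd.DataFrame(columns=["timestamp", "place", "reason"])
        gt = GroundTruth(profile.participant_id, [], [],
                         profile.habit_profile.tolist(),
                         list(map(tuple, profile.anchors)),
                         profile.anchor_preference.tolist(),
                         (0.0, 0.0), profile.schedule.tolist())
        return empty, gt

    w = np.exp(config.beta_time * h_std[occupancy.bin_idx]
               + config.beta_loc * g_std[occupancy.anchor_idx])
    waking_hours = n_slots * SLOT_MIN / 60.0
    total = config.base_rate * waking_hours * profile.event_rate_mult
    lam = total * w / w.sum()

    counts = rng.poisson(lam)
    true_times: list[pd.Timestamp] = []
    anchor_at_event: list[int] = []
    for i in np.nonzero(counts)[0]:
        for _ in range(int(counts[i])):
            off = rng.uniform(0, SLOT_MIN)
            true_times.append(occupancy.slot_start[i]
                              + pd.Timedelta(minutes=float(off)))
            anchor_at_event.append(int(occupancy.anchor_idx[i]))
    order = np.argsort(pd.DatetimeIndex(true_times).asi8) if true_times else []
    true_times = [true_times[j] for j in order]
    anchor_at_event = [anchor_at_event[j] for j in order]

    start, end = profile.study_start, profile.study_end
    reported: list[pd.Timestamp] = []
    places: list[str] = []
    reasons: list[str] = []
    for t, a in zip(true_times, anchor_at_event):
        jit = rng.normal(0, config.report_jitter_sd_min)
        rt = t + pd.Timedelta(minutes=float(jit))
        rt = min(max(rt, start), end - pd.Timedelta(seconds=1))
        reported.append(rt)
        places.append(_PLACES[a % len(_PLACES)])
        reasons.append(_REASONS[int(rng.integers(len(_REASONS)))])

    reports = pd.DataFrame({
        "timestamp": pd.DatetimeIndex(reported),
        "place": places,
        "reason": reasons,
    })
    gt = GroundTruth(profile.participant_id, true_times, anchor_at_event,
                     profile.habit_profile.tolist(),
                     list(map(tuple, profile.anchors)),
                     profile.anchor_preference.tolist(),
                     (0.0, 0.0), profile.schedule.tolist())
    return reports, gt


# ---------------------------------------------------------------------------
# privacy offset and cohort assembly
# ---------------------------------------------------------------------------

def apply_privacy_offset(
    fixes: pd.DataFrame,
    rng: np.random.Generator,
    max_offset_deg: float = 0.3,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Add one constant (dlat, dlon) to every fix of a participant.

    Relative (local-plane) distances between fixes are preserved;
    timestamps untouched. Returns the shifted frame and the offset.
    """
    if len(fixes) < 1:
        raise ConfigError("apply_privacy_offset requires at least one fix")
    dlat = float(rng.uniform(-max_offset_deg, max_offset_deg))
    dlon = float(rng.uniform(-max_offset_deg, max_offset_deg))
    out = fixes.copy()
    out["lat"] = out["lat"] + dlat
    out["lon"] = out["lon"] + dlon
    return out, (dlat, dlon)


def generate_participant(
    config: GeneratorConfig, participant_index: int
) -> tuple[ParticipantProfile, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Full simulation of one participant: (profile, fixes, reports, truth)."""
    streams = _participant_streams(config.seed, participant_index)
    _, occ_rng, ev_rng, fix_rng, off_rng = streams
    profile = sample_participant_profile(config, participant_index)
    occ = simulate_occupancy(profile, config, occ_rng)
    reports, gt = simulate_smoking_events(profile, occ, config, ev_rng)
    fixes = _emit_fixes(profile, occ, config, fix_rng,
                        report_times=list(reports["timestamp"]))
    if len(fixes):
        fixes, (dlat, dlon) = apply_privacy_offset(fixes, off_rng)
        gt.privacy_offset = (dlat, dlon)
        gt.anchors = [(la + dlat, lo + dlon) for la, lo in gt.anchors]
    fixes.insert(0, "participant_id", profile.participant_id)
    reports.insert(0, "participant_id", profile.participant_id)
    return profile, fixes, reports, gt


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    if "timestamp" in out.columns:
        out["timestamp"] = [t.floor("s").isoformat() for t in out["timestamp"]]
    for c in ("lat", "lon"):
        if c in out.columns:
            out[c] = out[c].map(lambda v: f"{v:.7f}")
    out.to_csv(path, index=False, lineterminator="\n")


def generate_cohort(
    config: GeneratorConfig, out_dir: str | Path
) -> dict[str, GroundTruth]:
    """Write a full cohort to ``out_dir`` and return the ground truth.

    Layout: ``<pid>_gps.csv``, ``<pid>_reports.csv`` per participant,
    ``metadata.csv`` for the cohort, and ``ground_truth/<pid>.json``.
    Fully reproducible from ``config.seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gt_dir = out / "ground_truth"
    gt_dir.mkdir(exist_ok=True)

    meta_rows = []
    truths: dict[str, GroundTruth] = {}
    for i in range(config.n_participants):
        profile, fixes, reports, gt = generate_participant(config, i)
        pid = profile.participant_id
        _write_csv(fixes, out / f"{pid}_gps.csv")
        _write_csv(reports, out / f"{pid}_reports.csv")
        (gt_dir / f"{pid}.json").write_text(gt.to_json())
        truths[pid] = gt
        meta_rows.append({
            "participant_id": pid,
            "enrollment_date": profile.enrollment_date.isoformat(),
            "timezone": profile.timezone,
            "group": profile.group,
            "quit_datetime": profile.study_end.isoformat(),
        })
    pd.DataFrame(meta_rows).to_csv(out / "metadata.csv", index=False,
                                   lineterminator="\n")
    return truths
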