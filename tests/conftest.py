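import logging
import warnings
from datetime import date

import numpy as np
import pandas as pd
import pytest

from smokegeo.synthetic import GeneratorConfig, generate_cohort

logging.getLogger("smokegeo").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", message=".*batch_size.*")

TZ = "-06:00"


@pytest.fixture(scope="session")
def tiny_cohort_dir(tmp_path_factory):
    """A 3-participant cohort with habitual timing, small enough for
    fast end-to-end tests."""
    out = tmp_path_factory.mktemp("cohort")
    cfg = GeneratorConfig(n_participants=3, seed=7, days_mean=5, days_sd=1,
                          min_days=4, beta_time=4.0, rho_redundancy=1.0,
                          n_anchors_range=(2, 3), base_rate=0.4,
                          event_dispersion=8.0, activity_sigma=0.3,
                          stationary_samples=1.5)
    generate_cohort(cfg, out)
    return out


def make_ts(day: str, hh: int, mm: int, ss: int = 0) -> pd.Timestamp:
    return pd.Timestamp(f"{day} {hh:02d}:{mm:02d}:{ss:02d}{TZ}")


def random_stream(rng: np.random.Generator, n_fixes: int = 80,
                  n_reports: int = 8, days: int = 3):
    """Random tz-aware fixes and reports over a few days (test helper)."""
    base = pd.Timestamp(f"2023-03-06 00:00:00{TZ}")
    span_s = days * 86400
    fix_ts = sorted(base + pd.Timedelta(seconds=float(s))
                    for s in rng.uniform(0, span_s, n_fixes))
    rep_ts = sorted(base + pd.Timedelta(seconds=float(s))
                    for s in rng.uniform(0, span_s, n_reports))
    fixes = pd.DataFrame({
        "timestamp": pd.DatetimeIndex(fix_ts),
        "lat": 40 + rng.normal(0, 0.01, n_fixes),
        "lon": -90 + rng.normal(0, 0.01, n_fixes),
    })
    reports = pd.DataFrame({"timestamp": pd.DatetimeIndex(rep_ts)})
    return fixes, reports


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
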