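"""Statistical layer: paired signed-rank ablation tests, Welch t-tests,
the COVID-era subgroup split, and the mixed-effects time-location
association analysis with support values.

The Wilcoxon signed-rank test here follows the classical recipe: zero
differences are discarded, absolute differences are ranked with midranks
for ties, and the two-sided p-value comes from full enumeration of the
2^n sign assignments for n <= 15 retained pairs (the cohort sizes this
pipeline sees), falling back to the tie-corrected normal approximation
for larger n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .modeling import ABLATION_ALL, ABLATION_NO_LOCATION, ABLATION_NO_TIME, AblationResult

logger = logging.getLogger(__name__)

ALPHA = 0.05
ALPHA_STRICT = 0.005
COVID_EMERGENCY_END = date(2023, 5, 11)

OUTCOME_MODAL_BINARY = "modal_cluster_binary"
OUTCOME_CLUSTER_NUMERIC = "cluster_numeric"

STRATUM_SMOKING = "smoking"
STRATUM_NON_SMOKING = "non_smoking"
STRATUM_ALL = "all"


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _sign_matrix(n: int) -> np.ndarray:
    """All 2^n sign patterns as a (2^n, n) 0/1 matrix."""
    return ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1).astype(float)


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def wilcoxon_signed_rank(differences, exact_max_n: int = 15) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Returns ``(W, p)`` where ``W`` is the sum of ranks of the positive
    differences. Zeros are discarded first; all differences zero is a
    degenerate input and raises.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValidationError("all differences are zero")
    ranks = _midranks(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        signs = _sign_matrix(n)
        dist = signs @ ranks  # T+ for every sign assignment
        m = len(dist)
        p_le = np.count_nonzero(dist <= w_pos + 1e-9) / m
        p_ge = np.count_nonzero(dist >= w_pos - 1e-9) / m
        p = min(1.0, 2 * min(p_le, p_ge))
    else:
        mu = n * (n + 1) / 4
        _, counts = np.unique(ranks, return_counts=True)
        tie_corr = ((counts ** 3 - counts).sum()) / 48
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24 - tie_corr)
        z = (w_pos - mu) / sigma
        p = float(2 * sps.norm.sf(abs(z)))
    return w_pos, float(p)


def welch_t_test(group_a, group_b, pooled: bool = False) -> tuple[float, float]:
    """Two-sided t-test for independent samples (unequal variance by
    default; ``pooled=True`` for the classical equal-variance Student
    form). Two identical constant groups return (0, 1)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs n >= 2")
    if a.std() == 0 and b.std() == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    t, p = sps.ttest_ind(a, b, equal_var=pooled)
    return float(t), float(p)


def summarize_alpha(p_values, bh_correct: bool = False) -> pd.DataFrame:
    """Significance flags at alpha 0.05 and 0.005 (star conventions).

    No multiplicity correction by default; ``bh_correct=True`` applies
    Benjamini-Hochberg before flagging.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    if bh_correct and len(p):
        from statsmodels.stats.multitest import multipletests
        p = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({
        "p_value": p,
        "sig_05": p <= ALPHA,
        "sig_005": p < ALPHA_STRICT,
    })


# ---------------------------------------------------------------------------
# ablation comparisons
# ---------------------------------------------------------------------------

@dataclass
class PairedComparison:
    spatial_method: str
    family: str
    half_time_min: float
    comparison: str  # which ablation is compared against all-features
    n_pairs: int
    w_stat: float | None
    p_value: float | None
    sig_05: bool
    sig_005: bool
    underpowered: bool
    note: str = ""


def compare_ablations(result: AblationResult, min_pairs: int = 6) -> pd.DataFrame:
    """Paired Wilcoxon tests of all-features vs each ablated feature set.

    For every (spatial method, model family, half-time) cell, the
    per-participant all-features scores are paired with the ablated
    scores; comparisons with fewer than ``min_pairs`` complete pairs are
    flagged underpowered, and identical score vectors are reported as
    degenerate with p = NA.
    """
    rec = result.records
    rows: list[PairedComparison] = []
    keys = rec[["spatial_method", "family", "half_time_min"]].drop_duplicates()
    for _, key in keys.iterrows():
        cell = rec[(rec["spatial_method"] == key["spatial_method"])
                   & (rec["family"] == key["family"])
                   & (rec["half_time_min"] == key["half_time_min"])]
        base = cell[cell["ablation"] == ABLATION_ALL].set_index("participant_id")["mean_score"]
        for ablated in (ABLATION_NO_LOCATION, ABLATION_NO_TIME):
            other = cell[cell["ablation"] == ablated].set_index("participant_id")["mean_score"]
            common = base.index.intersection(other.index)
            diffs = (base.loc[common] - other.loc[common]).to_numpy()
            n = len(common)
            under = n < min_pairs
            if n == 0:
                rows.append(PairedComparison(key["spatial_method"], key["family"],
                                             key["half_time_min"], ablated, 0,
                                             None, None, False, False, True,
                                             "no complete pairs"))
                continue
            if np.all(diffs == 0):
                rows.append(PairedComparison(key["spatial_method"], key["family"],
                                             key["half_time_min"], ablated, n,
                                             None, None, False, False, under,
                                             "identical score vectors"))
                continue
            w, p = wilcoxon_signed_rank(diffs)
            rows.append(PairedComparison(key["spatial_method"], key["family"],
                                         key["half_time_min"], ablated, n,
                                         w, p, p <= ALPHA, p < ALPHA_STRICT,
                                         under))
    return pd.DataFrame([r.__dict__ for r in rows])


def covid_subgroup_split(metadata: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Split participants by enrollment against the 2023-05-11 emergency
    expiration (enrollment on the boundary date counts as during)."""
    during, post = [], []
    for _, row in metadata.iterrows():
        d = row.get("enrollment_date")
        if d is None or (isinstance(d, float) and np.isnan(d)):
            logger.warning("participant %s lacks enrollment date; excluded",
                           row.get("participant_id"))
            continue
        d = pd.Timestamp(d).date()
        (during if d <= COVID_EMERGENCY_END else post).append(
            str(row["participant_id"]))
    return during, post


# ---------------------------------------------------------------------------
# time-location associations
# ---------------------------------------------------------------------------

@dataclass
class AssociationModel:
    temporal_feature: int  # bin index
    bin_width_min: int
    outcome_coding: str
    stratum: str
    coefficient: float
    p_value: float
    pooled: bool
    participant_id: str | None = None  # set in per-participant mode
    n_obs: int = 0


def _association_outcome(df: pd.DataFrame, outcome_coding: str) -> np.ndarray:
    if outcome_coding == OUTCOME_CLUSTER_NUMERIC:
        return df["cluster"].to_numpy(dtype=float)
    if outcome_coding == OUTCOME_MODAL_BINARY:
        # in the participant's most frequent smoking cluster vs not
        out = np.zeros(len(df))
        for pid, grp in df.groupby("participant_id"):
            smoking = grp[grp["label"] == 1]
            source = smoking if len(smoking) else grp
            modal = source["cluster"].mode().iloc[0]
            out[df["participant_id"] == pid] = (
                grp["cluster"] == modal).astype(float).to_numpy()
        return out
    raise ValidationError(f"unknown outcome coding '{outcome_coding}'")


def _stratum_filter(df: pd.DataFrame, stratum: str) -> pd.DataFrame:
    if stratum == STRATUM_SMOKING:
        return df[df["label"] == 1]
    if stratum == STRATUM_NON_SMOKING:
        return df[df["label"] == 0]
    if stratum == STRATUM_ALL:
        return df
    raise ValidationError(f"unknown stratum '{stratum}'")


def fit_time_location_association(
    samples: pd.DataFrame,
    temporal_feature: int,
    outcome_coding: str = OUTCOME_MODAL_BINARY,
    stratum: str = STRATUM_SMOKING,
    pooled: bool = True,
    bin_width_min: int = 15,
) -> list[AssociationModel]:
    """Association between one time-of-day bin and location clusters.

    ``samples`` needs columns participant_id, label, time_bin (at
    ``bin_width_min`` resolution) and cluster. Pooled mode fits a linear
    mixed model (maximum likelihood) with the binary bin indicator as
    the fixed effect and a participant random intercept; otherwise one
    OLS per participant. Zero-variance outcomes or features are skipped
    with a logged reason (empty return).
    """
    df = _stratum_filter(samples, stratum).copy()
    if len(df) == 0:
        return []
    feat = (df["time_bin"].to_numpy(dtype=int) == temporal_feature).astype(float)
    outcome = _association_outcome(df, outcome_coding)
    out: list[AssociationModel] = []
    if pooled:
        if feat.std() == 0 or outcome.std() == 0:
            logger.info("bin %d: zero-variance feature/outcome; skipped",
                        temporal_feature)
            return []
        groups = df["participant_id"].to_numpy()
        if len(np.unique(groups)) < 2:
            # degenerate grouping: reduces to OLS
            import statsmodels.api as sm
            res = sm.OLS(outcome, sm.add_constant(feat)).fit()
            out.append(AssociationModel(temporal_feature, bin_width_min,
                                        outcome_coding, stratum,
                                        float(res.params[1]),
                                        float(res.pvalues[1]), True,
                                        n_obs=len(df)))
            return out
        import statsmodels.api as sm
        import warnings as _w
        exog = sm.add_constant(feat)
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            model = sm.MixedLM(outcome, exog, groups=groups)
            res = model.fit(reml=False, method="lbfgs", maxiter=200)
        coef = float(np.asarray(res.fe_params)[1])
        pv = float(np.asarray(res.pvalues)[1])
        if not np.isfinite(pv):
            # residual variance ~0: a perfect fit has p -> 0, any other
            # singular fit is reported as uninformative
            pv = 0.0 if (res.scale < 1e-12 and coef != 0) else 1.0
        out.append(AssociationModel(temporal_feature, bin_width_min,
                                    outcome_coding, stratum, coef, pv, True,
                                    n_obs=len(df)))
        return out
    import statsmodels.api as sm
    for pid, grp in df.groupby("participant_id"):
        f = (grp["time_bin"].to_numpy(dtype=int) == temporal_feature).astype(float)
        o = outcome[(df["participant_id"] == pid).to_numpy()]
        if f.std() == 0 or o.std() == 0:
            continue
        res = sm.OLS(o, sm.add_constant(f)).fit()
        out.append(AssociationModel(temporal_feature, bin_width_min,
                                    outcome_coding, stratum,
                                    float(res.params[1]),
                                    float(res.pvalues[1]), False,
                                    participant_id=str(pid), n_obs=len(grp)))
    return out


def association_support(
    samples: pd.DataFrame,
    temporal_feature: int,
    cluster_id,
    stratum: str = STRATUM_SMOKING,
) -> float:
    """Association-rule support, in percent.

    Share of stratum samples where the time-of-day bin is active *and*
    the sample lies in the given location cluster. Empty stratum -> NaN.
    """
    df = _stratum_filter(samples, stratum)
    if len(df) == 0:
        return float("nan")
    hit = ((df["time_bin"].to_numpy(dtype=int) == temporal_feature)
           & (df["cluster"].to_numpy() == cluster_id))
    return 100.0 * hit.sum() / len(df)


def association_analysis(
    samples: pd.DataFrame,
    bin_width_min: int = 15,
    outcome_coding: str = OUTCOME_MODAL_BINARY,
    strata=(STRATUM_SMOKING, STRATUM_NON_SMOKING),
    pooled: bool = True,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Fit one association model per occupied time bin and stratum, and
    compute support values for the significant ones.

    Support is reported against each participant-pooled modal cluster
    (the cluster named by the outcome coding); the summary min/max over
    significant associations mirrors the study-level reporting.
    """
    rows = []
    factor = bin_width_min // 15
    for stratum in strata:
        df = _stratum_filter(samples, stratum)
        if len(df) == 0:
            continue
        bins = np.unique(df["time_bin"].to_numpy(dtype=int) // factor * factor) \
            if factor > 1 else np.unique(df["time_bin"].to_numpy(dtype=int))
        work = samples.copy()
        if factor > 1:
            work["time_bin"] = work["time_bin"] // factor
            bins = np.unique(_stratum_filter(work, stratum)["time_bin"])
        for b in bins:
            models = fit_time_location_association(
                work if factor > 1 else samples, int(b), outcome_coding,
                stratum, pooled, bin_width_min)
            for m in models:
                sig = m.p_value <= alpha
                support = float("nan")
                if sig:
                    sub = work if factor > 1 else samples
                    sdf = _stratum_filter(sub, stratum)
                    active = sdf[sdf["time_bin"] == int(b)]
                    if len(active):
                        modal = active["cluster"].mode().iloc[0]
                        support = association_support(sub, int(b), modal,
                                                      stratum)
                rows.append({
                    "temporal_feature": int(b),
                    "bin_width_min": bin_width_min,
                    "stratum": stratum,
                    "outcome_coding": outcome_coding,
                    "coefficient": m.coefficient,
                    "p_value": m.p_value,
                    "significant": sig,
                    "support_pct": support,
                })
    return pd.DataFrame(rows)
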