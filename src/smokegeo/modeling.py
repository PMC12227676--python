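"""Feature-ablation modeling grid.

For every participant the full Cartesian grid {location representation} x
{LR, RF, MLP} x {half-time 5/10/15/20/30 min} x {all features /
location-excluded / time-excluded} is evaluated with stratified 5-fold
cross-validation and scored by Macro-F1 (the unweighted mean of the two
per-class F1 scores, robust to the smoking/non-smoking imbalance).

Pairing guarantees, needed by the downstream signed-rank comparisons:

* for a fixed participant and half-time, every ablation and every
  location method is evaluated on the *same* fold partition;
* the location-excluded configuration does not depend on the location
  representation, so it is fitted once per (participant, family,
  half-time) and replicated verbatim across representations.

Models are trained per participant (individual-level); a pooled-cohort
mode is available via ``pool_participants`` in :class:`GridConfig`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .errors import ParticipantSkipped, ValidationError
from .harmonize import SampleTable, bin_onehot
from .spatial import SpatialRepresentation, encode_location_feature

logger = logging.getLogger(__name__)

ABLATION_ALL = "all"
ABLATION_NO_LOCATION = "no_location"
ABLATION_NO_TIME = "no_time"
ABLATIONS = (ABLATION_ALL, ABLATION_NO_LOCATION, ABLATION_NO_TIME)

FAMILY_LR = "lr"
FAMILY_RF = "rf"
FAMILY_MLP = "mlp"
FAMILIES = (FAMILY_LR, FAMILY_RF, FAMILY_MLP)

N_FOLDS = 5
_SEASON_ORDER = ("winter", "spring", "summer", "fall")


@dataclass
class ModelSpec:
    """A model family plus its (conventional, fixed) hyperparameters."""

    family: str
    params: dict = field(default_factory=dict)

    _DEFAULTS = {
        FAMILY_LR: {"penalty": "l2", "C": 1.0, "max_iter": 1000},
        FAMILY_RF: {"n_trees": 100, "max_depth": None},
        FAMILY_MLP: {"hidden": (300, 150), "learning_rate": 1e-3,
                     "max_epochs": 200, "batch_size": 32, "tol": 1e-4},
    }

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"family must be one of {FAMILIES}")
        merged = dict(self._DEFAULTS[self.family])
        merged.update(self.params)
        self.params = merged

    def build(self, seed: int):
        p = self.params
        if self.family == FAMILY_LR:
            # ridge-penalised logistic regression (sklearn's default
            # penalty is L2; the key is kept for config transparency)
            if p["penalty"] != "l2":
                raise ValidationError("only the L2 penalty is supported")
            return LogisticRegression(C=p["C"], max_iter=p["max_iter"],
                                      solver="lbfgs")
        if self.family == FAMILY_RF:
            return RandomForestClassifier(n_estimators=p["n_trees"],
                                          max_depth=p["max_depth"],
                                          random_state=seed, n_jobs=1)
        return MLPClassifier(hidden_layer_sizes=tuple(p["hidden"]),
                             activation="relu", solver="adam",
                             learning_rate_init=p["learning_rate"],
                             max_iter=p["max_epochs"], tol=p["tol"],
                             batch_size=p["batch_size"], random_state=seed)


@dataclass
class CVResult:
    participant_id: str
    spatial_method: str
    family: str
    half_time_min: float
    ablation: str
    fold_scores: list[float]
    mean_score: float


@dataclass
class GridConfig:
    spatial_methods: Sequence[str] = ("dbscan", "kmeans", "dfi")
    families: Sequence[str] = FAMILIES
    half_times: Sequence[float] = (5, 10, 15, 20, 30)
    ablations: Sequence[str] = ABLATIONS
    model_specs: Mapping[str, ModelSpec] | None = None
    seed: int = 0
    min_samples: int = 10
    pool_participants: bool = False

    def spec_for(self, family: str) -> ModelSpec:
        if self.model_specs and family in self.model_specs:
            return self.model_specs[family]
        return ModelSpec(family)


@dataclass
class AblationResult:
    """Per-(participant, config) Macro-F1 records plus skip log."""

    records: pd.DataFrame
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def aggregate(self) -> pd.DataFrame:
        """Mean and SD of participant scores per grid configuration."""
        g = self.records.groupby(
            ["spatial_method", "family", "half_time_min", "ablation"],
            as_index=False,
        ).agg(mean_score=("mean_score", "mean"),
              sd_score=("mean_score", "std"),
              n_participants=("mean_score", "size"))
        return g


# ---------------------------------------------------------------------------
# metric
# ---------------------------------------------------------------------------

def macro_f1(y_true, y_pred) -> float:
    """Macro-averaged F1 over the binary classes {0, 1}.

    A class absent from both truth and prediction contributes F1 = 0
    (zero-division rule), keeping the score comparable across folds with
    missing classes.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValidationError("macro_f1 requires equal-length non-empty inputs")
    return float(f1_score(y_true, y_pred, labels=[0, 1], average="macro",
                          zero_division=0))


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def assemble_design_matrix(
    table: SampleTable,
    representation: SpatialRepresentation | None,
    ablation: str,
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """Build (X, y, column_names, continuous_mask) for one configuration.

    Temporal block: one-hot time-of-day bins (96 at 15-min width), 7
    day-of-week indicators, the weekend flag and 4 season indicators.
    Spatial block: the encoded location representation, with fallback
    rows inheriting their source fix's encoding. ``continuous_mask``
    flags columns that must be standardized with training-fold
    statistics during cross-validation (the DFI column).
    """
    if ablation not in ABLATIONS:
        raise ValidationError(f"unknown ablation '{ablation}'")
    df = table.data
    y = df["label"].to_numpy(dtype=int)
    blocks: list[np.ndarray] = []
    names: list[str] = []
    cont: list[np.ndarray] = []

    if ablation in (ABLATION_ALL, ABLATION_NO_LOCATION):
        if table.feature_semantics == "literal_overlap":
            ov_cols = [c for c in df.columns if c.startswith("ov_")]
            tb = df[ov_cols].to_numpy(dtype=float)
        else:
            tb = bin_onehot(df["time_bin"], table.bin_width_min).astype(float)
        n_bins = tb.shape[1]
        blocks.append(tb)
        names += [f"tb_{i}" for i in range(n_bins)]
        dow = np.zeros((len(df), 7))
        dow[np.arange(len(df)), df["dow"].to_numpy(dtype=int)] = 1.0
        blocks.append(dow)
        names += [f"dow_{i}" for i in range(7)]
        blocks.append(df["is_weekend"].to_numpy(dtype=float).reshape(-1, 1))
        names.append("is_weekend")
        sea = np.zeros((len(df), 4))
        sidx = [_SEASON_ORDER.index(s) for s in df["season"]]
        sea[np.arange(len(df)), sidx] = 1.0
        blocks.append(sea)
        names += [f"season_{s}" for s in _SEASON_ORDER]
        cont.append(np.zeros(sum(b.shape[1] for b in blocks), dtype=bool))

    if ablation in (ABLATION_ALL, ABLATION_NO_TIME):
        if representation is None:
            raise ValidationError("spatial ablation requires a representation")
        sp, sp_names = encode_location_feature(
            representation, row_fix_idx=df["source_fix_idx"])
        blocks.append(np.asarray(sp, dtype=float))
        names += sp_names
        cont.append(np.array([n == "dfi_z" for n in sp_names]))

    if not blocks:
        raise ValidationError("ablation produced zero columns")
    X = np.hstack(blocks)
    cont_mask = np.concatenate(cont)
    return X, y, names, cont_mask


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def make_folds(y: np.ndarray, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified shuffled 5-fold partition, reusable across ablations."""
    skf = StratifiedKFold(n_splits=N_FOLDS, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def _check_modelable(y: np.ndarray, participant_id: str, min_samples: int) -> None:
    if len(y) < min_samples:
        raise ParticipantSkipped(participant_id,
                                 f"only {len(y)} samples (< {min_samples})")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ParticipantSkipped(participant_id, "single-class labels")
    if counts.min() < N_FOLDS:
        raise ParticipantSkipped(
            participant_id,
            f"minority class has {counts.min()} samples (< {N_FOLDS} folds)")


def crossvalidate_participant(
    X: np.ndarray,
    y: np.ndarray,
    model_spec: ModelSpec,
    seed: int = 0,
    folds: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
    continuous_mask: np.ndarray | None = None,
    participant_id: str = "",
    min_samples: int = 10,
) -> tuple[list[float], float]:
    """Fold-wise Macro-F1 for one participant and model.

    Continuous columns are standardized with training-fold statistics
    only. Raises :class:`ParticipantSkipped` when the data cannot
    support stratified 5-fold evaluation.
    """
    y = np.asarray(y, dtype=int)
    _check_modelable(y, participant_id, min_samples)
    if folds is None:
        folds = make_folds(y, seed)
    scores = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        # MLP emits a UserWarning when a fold is smaller than batch_size
        warnings.filterwarnings("ignore", message=".*batch_size.*")
        for train, test in folds:
            Xtr, Xte = X[train].copy(), X[test].copy()
            if continuous_mask is not None and continuous_mask.any():
                mu = Xtr[:, continuous_mask].mean(axis=0)
                sd = Xtr[:, continuous_mask].std(axis=0)
                sd[sd == 0] = 1.0
                Xtr[:, continuous_mask] = (Xtr[:, continuous_mask] - mu) / sd
                Xte[:, continuous_mask] = (Xte[:, continuous_mask] - mu) / sd
            model = model_spec.build(seed)
            model.fit(Xtr, y[train])
            scores.append(macro_f1(y[test], model.predict(Xte)))
    return scores, float(np.mean(scores))


# ---------------------------------------------------------------------------
# the grid
# ---------------------------------------------------------------------------

def run_grid(
    cohort_tables: Mapping[str, Mapping[float, SampleTable]],
    representations: Mapping[str, Mapping[str, SpatialRepresentation]],
    grid_config: GridConfig | None = None,
) -> AblationResult:
    """Evaluate the full ablation grid over a cohort.

    ``cohort_tables[pid][half_time]`` holds the labeled sample table and
    ``representations[pid][method]`` the per-fix location representation
    (computed once on the participant's raw fixes). Participants whose
    labels cannot support stratified folds are skipped with a logged
    reason rather than aborting the grid.
    """
    cfg = grid_config or GridConfig()
    if cfg.pool_participants:
        return _run_grid_pooled(cohort_tables, representations, cfg)
    records: list[CVResult] = []
    skipped: list[tuple[str, str]] = []

    for pid, by_half in cohort_tables.items():
        for half in cfg.half_times:
            table = by_half[half]
            y = table.data["label"].to_numpy(dtype=int)
            try:
                _check_modelable(y, pid, cfg.min_samples)
            except ParticipantSkipped as exc:
                skipped.append((pid, f"H={half}: {exc.reason}"))
                logger.info("skipping %s at H=%s: %s", pid, half, exc.reason)
                continue
            folds = make_folds(y, cfg.seed)

            for family in cfg.families:
                spec = cfg.spec_for(family)
                # location-excluded: representation-independent, fit once
                if ABLATION_NO_LOCATION in cfg.ablations:
                    X, yv, _, cm = assemble_design_matrix(
                        table, None, ABLATION_NO_LOCATION)
                    fs, mean = crossvalidate_participant(
                        X, yv, spec, cfg.seed, folds, cm, pid, cfg.min_samples)
                    for method in cfg.spatial_methods:
                        records.append(CVResult(pid, method, family, half,
                                                ABLATION_NO_LOCATION,
                                                list(fs), mean))
                for method in cfg.spatial_methods:
                    rep = representations[pid][method]
                    for ablation in cfg.ablations:
                        if ablation == ABLATION_NO_LOCATION:
                            continue
                        X, yv, _, cm = assemble_design_matrix(
                            table, rep, ablation)
                        fs, mean = crossvalidate_participant(
                            X, yv, spec, cfg.seed, folds, cm, pid,
                            cfg.min_samples)
                        records.append(CVResult(pid, method, family, half,
                                                ablation, list(fs), mean))

    return AblationResult(_records_frame(records), skipped)


def _records_frame(records: list[CVResult]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"participant_id": r.participant_id,
               "spatial_method": r.spatial_method,
               "family": r.family,
               "half_time_min": r.half_time_min,
               "ablation": r.ablation,
               "mean_score": r.mean_score}
        for i, s in enumerate(r.fold_scores):
            row[f"fold_{i + 1}"] = s
        rows.append(row)
    return pd.DataFrame(rows)


def _pooled_design(tables, representations, half, method, ablation):
    """Stack per-participant design matrices; participant-specific
    spatial columns occupy disjoint blocks (location labels have no
    shared meaning across participants)."""
    parts = []
    for pid in tables:
        X, y, names, cm = assemble_design_matrix(
            tables[pid][half],
            None if ablation == ABLATION_NO_LOCATION
            else representations[pid][method],
            ablation)
        parts.append((pid, X, y, names, cm))
    if ablation == ABLATION_NO_LOCATION:
        X = np.vstack([p[1] for p in parts])
        y = np.concatenate([p[2] for p in parts])
        return X, y, parts[0][4]
    # temporal blocks share columns; spatial blocks are per-participant
    n_temporal = len([n for n in parts[0][3] if not (
        n.startswith("loc") or n == "dfi_z")])
    sp_sizes = [p[1].shape[1] - n_temporal for p in parts]
    total_sp = sum(sp_sizes)
    blocks, ys, cms = [], [], []
    offset = 0
    for (pid, X, y, names, cm), k in zip(parts, sp_sizes):
        row = np.zeros((X.shape[0], n_temporal + total_sp))
        row[:, :n_temporal] = X[:, :n_temporal]
        row[:, n_temporal + offset:n_temporal + offset + k] = X[:, n_temporal:]
        blocks.append(row)
        ys.append(y)
        cms.append(cm[n_temporal:])
        offset += k
    cont = np.concatenate([np.zeros(n_temporal, dtype=bool)] + cms)
    return np.vstack(blocks), np.concatenate(ys), cont


def _run_grid_pooled(cohort_tables, representations, cfg) -> AblationResult:
    """Cohort-level mode: one cross-validated model over all
    participants' samples per configuration."""
    records: list[CVResult] = []
    skipped: list[tuple[str, str]] = []
    for half in cfg.half_times:
        ys = np.concatenate([cohort_tables[p][half].data["label"].to_numpy()
                             for p in cohort_tables])
        folds = make_folds(ys, cfg.seed)
        for family in cfg.families:
            spec = cfg.spec_for(family)
            for method in cfg.spatial_methods:
                for ablation in cfg.ablations:
                    X, y, cm = _pooled_design(cohort_tables, representations,
                                              half, method, ablation)
                    try:
                        fs, mean = crossvalidate_participant(
                            X, y, spec, cfg.seed, folds, cm, "__pooled__",
                            cfg.min_samples)
                    except ParticipantSkipped as exc:
                        skipped.append(("__pooled__", exc.reason))
                        continue
                    records.append(CVResult("__pooled__", method, family,
                                            half, ablation, list(fs), mean))
    return AblationResult(_records_frame(records), skipped)
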