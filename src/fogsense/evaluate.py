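"""Random-forest classification under leave-one-subject-out validation.

Each fold holds out every window of one subject; all per-fold fitting -
min-max normalisation, feature ranking, top-k restriction, SMOTE
balancing and forest training - sees training subjects only, so no
information from the held-out subject leaks into the model. Test rows
are never balanced. Aggregate metrics come from pooled confusion counts
(robust to folds without any freezing window, e.g. non-freezer
subjects); fold-wise means and standard deviations are reported
alongside, skipping folds where a metric is undefined.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .balance import SmoteConfig, smote
from .channels import ChannelSpec
from .errors import ConfigError, DataError
from .features import FeatureTable, apply_minmax, compute_features, fit_minmax
from .preprocess import design_fir, preprocess_recording
from .selection import rank_features, top_k_columns
from .simulate import AnnotationTrack, Recording
from .windows import concat_window_sets, segment

logger = logging.getLogger(__name__)

METRIC_NAMES = ("sensitivity", "specificity", "accuracy", "precision", "f_score")


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class Metrics:
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    f_score: float

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """Window-level metrics; undefined ratios become NaN with a warning."""
    if c.total == 0:
        raise DataError("confusion counts are all zero")

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
            return float("nan")
        return num / den

    sens = ratio(c.tp, c.tp + c.fn, "sensitivity")
    spec = ratio(c.tn, c.tn + c.fp, "specificity")
    acc = (c.tp + c.tn) / c.total
    prec = ratio(c.tp, c.tp + c.fp, "precision")
    if math.isnan(sens) or math.isnan(prec) or sens + prec == 0:
        f = float("nan") if math.isnan(sens) or math.isnan(prec) else 0.0
    else:
        f = 2 * sens * prec / (sens + prec)
    return Metrics(sens, spec, acc, prec, f)


@dataclass
class FoldResult:
    subject_id: str
    counts: ConfusionCounts
    metrics: Metrics
    train_subjects: list[str]  # provenance incl. SMOTE parents


@dataclass
class EvalResult:
    per_fold: list[FoldResult]
    aggregate: Metrics
    pooled_counts: ConfusionCounts
    config: dict = field(default_factory=dict)

    def aggregate_dict(self) -> dict:
        return self.aggregate.as_dict()

    def _fold_values(self, name: str) -> np.ndarray:
        vals = np.array([getattr(f.metrics, name) for f in self.per_fold])
        return vals[~np.isnan(vals)]

    def fold_mean(self) -> dict:
        return {n: float(self._fold_values(n).mean()) for n in METRIC_NAMES}

    def fold_sd(self) -> dict:
        return {n: float(self._fold_values(n).std(ddof=1)) for n in METRIC_NAMES}


def loso_splits(table: FeatureTable) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """One fold per subject: (held-out id, train indices, test indices)."""
    subjects = sorted(set(table.subject_ids))
    if len(subjects) < 2:
        raise DataError("leave-one-subject-out needs >= 2 subjects")
    splits = []
    ids = np.asarray(table.subject_ids)
    for s in subjects:
        test = np.flatnonzero(ids == s)
        train = np.flatnonzero(ids != s)
        splits.append((s, train, test))
    return splits


def train_classifier(
    train: FeatureTable, n_trees: int = 10, seed: int = 0
) -> RandomForestClassifier:
    """Fit the forest: ``n_trees`` fully grown (unpruned) trees,
    bootstrap resampling and sqrt(p) feature subsampling per split."""
    if len(np.unique(train.labels)) < 2:
        raise DataError("training set has a single class")
    model = RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=None,
        max_features="sqrt",
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    model.fit(train.values, train.labels.astype(int))
    return model


@dataclass
class PipelineConfig:
    """Everything one evaluation run needs, seeds included."""

    channels: list[ChannelSpec] | None = None  # None = all channels present
    selection_method: str | None = "anova"  # None disables selection
    top_k: int = 35
    smote: SmoteConfig | None = field(default_factory=SmoteConfig)
    n_trees: int = 10
    seed: int = 0
    window_s: float = 2.0
    step_s: float = 0.5
    filter_order: int = 26
    band: tuple[float, float] = (0.5, 10.0)
    mi_bins: int = 10

    def stage_seed(self, fold: int, stage: int) -> int:
        """Deterministic per-fold, per-stage seed derived from the master."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(fold, stage))
        return int(ss.generate_state(1)[0] % (2**31))


def cohort_feature_table(
    recordings: list[Recording],
    annotations: list[AnnotationTrack],
    config: PipelineConfig,
) -> FeatureTable:
    """Preprocess, window and featurise a cohort for a channel subset."""
    if len(recordings) != len(annotations):
        raise DataError("recordings/annotations length mismatch")
    coeffs = design_fir(recordings[0].sample_rate, config.filter_order, config.band)
    sets = []
    for rec, ann in zip(recordings, annotations):
        if rec.subject_id != ann.subject_id:
            raise DataError(
                f"annotation subject {ann.subject_id} does not match recording {rec.subject_id}"
            )
        sub = rec.select_channels(config.channels) if config.channels else rec
        pre = preprocess_recording(sub, coeffs)
        sets.append(segment(pre, ann, config.window_s, config.step_s))
    return compute_features(concat_window_sets(sets))


def evaluate_feature_table(table: FeatureTable, config: PipelineConfig) -> EvalResult:
    """LOSO evaluation of an already-extracted feature table."""
    if config.selection_method is not None and config.top_k > table.n_features:
        raise ConfigError(
            f"top_k={config.top_k} exceeds the {table.n_features} available features"
        )
    folds = []
    pooled = ConfusionCounts()
    for fold_no, (subject, train_idx, test_idx) in enumerate(loso_splits(table)):
        train = table.select_rows(train_idx)
        test = table.select_rows(test_idx)
        norm = fit_minmax(train)
        train = apply_minmax(norm, train)
        test = apply_minmax(norm, test)
        if config.selection_method is not None:
            scores = rank_features(train, config.selection_method, config.mi_bins)
            cols = top_k_columns(scores, train, config.top_k)
            train = train.select_columns(cols)
            test = test.select_columns(cols)
        if config.smote is not None:
            train = smote(
                train, replace(config.smote, seed=config.stage_seed(fold_no, 1))
            )
        model = train_classifier(train, config.n_trees, config.stage_seed(fold_no, 2))
        pred = model.predict(test.values).astype(int)
        truth = test.labels.astype(int)
        counts = ConfusionCounts(
            tp=int(((pred == 1) & (truth == 1)).sum()),
            tn=int(((pred == 0) & (truth == 0)).sum()),
            fp=int(((pred == 1) & (truth == 0)).sum()),
            fn=int(((pred == 0) & (truth == 1)).sum()),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # non-freezer folds: sens undefined
            metrics = compute_metrics(counts)
        folds.append(
            FoldResult(subject, counts, metrics, sorted(set(train.subject_ids)))
        )
        pooled = pooled + counts
        logger.debug("fold %s: %s", subject, metrics.as_dict())
    snapshot = {
        "channels": [c.name for c in config.channels] if config.channels else "all",
        "selection_method": config.selection_method,
        "top_k": config.top_k if config.selection_method else None,
        "smote": None if config.smote is None else vars(config.smote),
        "n_trees": config.n_trees,
        "seed": config.seed,
    }
    return EvalResult(folds, compute_metrics(pooled), pooled, snapshot)


def run_pipeline(
    recordings: list[Recording],
    annotations: list[AnnotationTrack],
    config: PipelineConfig,
) -> EvalResult:
    """Full chain: preprocess -> window -> features -> per-fold
    normalise/select/balance/train -> pooled metrics."""
    table = cohort_feature_table(recordings, annotations, config)
    return evaluate_feature_table(table, config)


def evaluate_sensor_subsets(
    recordings: list[Recording],
    annotations: list[AnnotationTrack],
    subsets: dict[str, list[ChannelSpec]],
    config: PipelineConfig,
) -> tuple[pd.DataFrame, dict[str, EvalResult]]:
    """Run the pipeline per sensor subset with shared folds and seeds.

    Returns a comparison table (one row per subset, the five metrics as
    columns) plus the full per-subset results.
    """
    if not subsets:
        raise ConfigError("no sensor subsets given")
    rows = []
    results: dict[str, EvalResult] = {}
    for name, chans in subsets.items():
        if not chans:
            raise ConfigError(f"subset {name!r} is empty")
        sub_cfg = replace(config, channels=list(chans))
        res = run_pipeline(recordings, annotations, sub_cfg)
        results[name] = res
        rows.append({"subset": name, **res.aggregate.as_dict()})
    return pd.DataFrame(rows).set_index("subset"), results
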