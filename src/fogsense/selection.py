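"""Filter-based feature ranking: one-way ANOVA F and mutual information.

Both scores are computed per feature column against the binary window
label. ANOVA F is the classical between/within variance ratio; features
whose within-class scatter vanishes while class means differ receive an
infinite sentinel that ranks above every finite score. Mutual
information uses the plug-in estimate I(X;Y) = H(Y) - H(Y|X) after
discretising the feature into quantile bins (10 by default), which makes
the score invariant to strictly monotone rescalings of the feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

from .channels import ChannelSpec
from .errors import DataError
from .features import FeatureTable

METHODS = ("anova", "mi")


@dataclass
class FeatureScore:
    feature_id: tuple[ChannelSpec, str]
    method: str
    score: float
    rank: int


def _class_stats(values: np.ndarray, labels: np.ndarray):
    classes = np.unique(labels)
    if len(classes) < 2:
        raise DataError("ANOVA needs at least two classes")
    return classes


def anova_f(values: np.ndarray, labels: np.ndarray) -> float:
    """One-way ANOVA F statistic of one feature against class labels.

    F = [SS_b/(M-1)] / [SS_w/(N-M)] with SS_b the size-weighted squared
    deviation of class means from the grand mean and SS_w the pooled
    within-class sum of squares. SS_w = 0 with distinct means returns
    +inf; SS_b = 0 returns 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = _class_stats(values, labels)
    grand = values.mean()
    ss_b = ss_w = 0.0
    for c in classes:
        grp = values[labels == c]
        ss_b += len(grp) * (grp.mean() - grand) ** 2
        ss_w += ((grp - grp.mean()) ** 2).sum()
    if ss_b <= 0.0:
        return 0.0
    df_b = len(classes) - 1
    df_w = len(values) - len(classes)
    if df_w <= 0:
        raise DataError("need at least one class with >= 2 samples")
    if ss_w == 0.0:
        return float("inf")
    return (ss_b / df_b) / (ss_w / df_w)


def _anova_f_columns(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorised per-column ANOVA F for a binary/most-general label vector."""
    classes = np.unique(y)
    n, p = x.shape
    grand = x.mean(axis=0)
    ss_b = np.zeros(p)
    ss_w = np.zeros(p)
    for c in classes:
        grp = x[y == c]
        mu = grp.mean(axis=0)
        ss_b += len(grp) * (mu - grand) ** 2
        ss_w += ((grp - mu) ** 2).sum(axis=0)
    df_b = len(classes) - 1
    df_w = n - len(classes)
    out = np.zeros(p)
    zero_w = ss_w <= 0
    pos_b = ss_b > 0
    ok = ~zero_w
    out[ok] = (ss_b[ok] / df_b) / (ss_w[ok] / df_w)
    out[zero_w & pos_b] = np.inf
    out[~pos_b] = 0.0
    return out


def _quantile_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, values, side="right")


def mutual_info(values: np.ndarray, labels: np.ndarray, n_bins: int = 10) -> float:
    """Plug-in mutual information (nats) after quantile discretisation."""
    if n_bins < 2:
        raise DataError("n_bins must be >= 2")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise DataError("labels are degenerate")
    xb = _quantile_bins(values, n_bins)
    _, y = np.unique(labels, return_inverse=True)
    _, x = np.unique(xb, return_inverse=True)
    n = len(values)
    joint = np.zeros((x.max() + 1, y.max() + 1))
    np.add.at(joint, (x, y), 1.0)
    joint /= n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)

    def h(p):
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    i = h(px) + h(py) - h(joint.ravel())
    if i < -1e-12:
        raise DataError(f"mutual information estimate went negative: {i}")
    return max(i, 0.0)


def rank_features(table: FeatureTable, method: str, n_bins: int = 10) -> list[FeatureScore]:
    """Score every column and sort descending; ties keep column order."""
    if method not in METHODS:
        raise DataError(f"method must be one of {METHODS}")
    if table.n_rows == 0 or table.n_features == 0:
        raise DataError("empty feature table")
    if method == "anova":
        scores = _anova_f_columns(table.values, table.labels)
    else:
        scores = np.array(
            [mutual_info(table.values[:, j], table.labels, n_bins) for j in range(table.n_features)]
        )
    # stable sort on -score keeps original column order among ties and
    # ranks +inf sentinels first
    order = np.argsort(-scores, kind="stable")
    return [
        FeatureScore(table.feature_ids[j], method, float(scores[j]), rank + 1)
        for rank, j in enumerate(order)
    ]


def top_k_columns(scores: list[FeatureScore], table: FeatureTable, k: int) -> np.ndarray:
    """Column indices of the k best-ranked features, in original column
    order (so selecting all features is the identity)."""
    if k < 1 or k > table.n_features:
        raise DataError(f"k={k} outside 1..{table.n_features}")
    name_to_col = {f"{c.name}__{n}": j for j, (c, n) in enumerate(table.feature_ids)}
    ranked = sorted(scores, key=lambda s: s.rank)
    cols = [
        name_to_col[f"{s.feature_id[0].name}__{s.feature_id[1]}"] for s in ranked[:k]
    ]
    return np.array(sorted(cols))


@dataclass
class SweepPoint:
    k: int
    aggregate: dict
    fold_mean: dict
    fold_sd: dict


def topk_sweep(
    table: FeatureTable,
    method: str,
    ks: Iterable[int],
    evaluator: Callable[[FeatureTable, str, int], "object"],
) -> list[SweepPoint]:
    """Run the evaluation pipeline restricted to the top-k features per k.

    ``evaluator(table, method, k)`` must rank features inside its own
    training folds and return an evaluation result exposing ``aggregate``
    and fold-wise ``fold_mean``/``fold_sd`` metric dicts.
    """
    points = []
    for k in ks:
        if k > table.n_features:
            raise DataError(f"k={k} exceeds {table.n_features} features")
        try:
            res = evaluator(table, method, k)
        except Exception as exc:
            raise DataError(f"evaluator failed at k={k}: {exc}") from exc
        points.append(SweepPoint(k, res.aggregate_dict(), res.fold_mean(), res.fold_sd()))
    return points
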