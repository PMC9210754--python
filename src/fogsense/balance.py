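"""SMOTE oversampling of the minority class to a 1:1 ratio.

For each minority sample x_i, its k nearest minority neighbours (plain
Euclidean distance - apply after min-max normalisation so no raw-scale
feature dominates) are found and synthetic rows are drawn on the
connecting segments: x_i + u (x_ij - x_i) with u ~ Uniform(0, 1).
Original rows are preserved untouched; synthetic rows inherit the
minority label and the subject id of their base sample x_i, so
subject-wise provenance survives oversampling and leave-one-subject-out
audits can prove no synthetic row descends from a held-out subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .errors import ConfigError, DataError
from .features import FeatureTable


@dataclass
class SmoteConfig:
    k_neighbors: int = 5
    target_ratio: float = 1.0  # minority/majority after balancing
    seed: int = 0

    def validate(self) -> None:
        if self.k_neighbors < 1:
            raise ConfigError("k_neighbors must be >= 1")
        if not 0 < self.target_ratio <= 1:
            raise ConfigError("target_ratio must lie in (0, 1]")


def smote(train: FeatureTable, config: SmoteConfig) -> FeatureTable:
    """Oversample the minority class of a training table.

    Deterministic given ``config.seed``. If the minority class has at
    most ``k_neighbors`` samples the neighbourhood shrinks with a
    warning; an empty minority class is an error.
    """
    config.validate()
    labels = np.asarray(train.labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise DataError("training table has a single class")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == 0:
        raise DataError("minority class is empty")
    needed = int(np.floor(config.target_ratio * n_maj)) - n_min
    if needed <= 0:
        return train.select_rows(np.arange(train.n_rows))

    k = config.k_neighbors
    if n_min <= k:
        k = n_min - 1
        warnings.warn(
            f"minority class has only {n_min} samples; k reduced to {k}", stacklevel=2
        )
    if k < 1:
        raise DataError("minority class too small for SMOTE (needs >= 2 samples)")

    min_idx = np.flatnonzero(labels == minority)
    x_min = train.values[min_idx]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x_min)
    neigh = nn.kneighbors(x_min, return_distance=False)[:, 1:]  # drop self

    rng = np.random.default_rng(config.seed)
    per_base = needed // n_min
    base = np.repeat(np.arange(n_min), per_base)
    remainder = needed - per_base * n_min
    if remainder:
        base = np.concatenate([base, rng.choice(n_min, size=remainder, replace=False)])
    picked = neigh[base, rng.integers(0, k, size=needed)]
    u = rng.random((needed, 1))
    synth = x_min[base] + u * (x_min[picked] - x_min[base])

    values = np.vstack([train.values, synth])
    labels_out = np.concatenate([labels, np.full(needed, minority, dtype=labels.dtype)])
    subjects = np.concatenate([train.subject_ids, train.subject_ids[min_idx[base]]])
    starts = np.concatenate([train.start_times_s, train.start_times_s[min_idx[base]]])
    return FeatureTable(values, list(train.feature_ids), labels_out, subjects, starts)
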