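"""The 13 per-channel window features and min-max normalisation.

Per channel and window: freeze index (FI), spectral energy, sum power,
mean, absolute mean, zero-crossing rate, standard deviation, range, RMS,
maximum, minimum, principal-direction eigenvalue, and Shannon entropy.
The spectral features use the plain DFT of the raw window (no taper, no
detrend); the DC bin belongs to neither zone. The freezing zone is
[3, 8] Hz and the motion (locomotor) zone [0.5, 3) Hz - the 3 Hz bin is
assigned exclusively to the freezing zone so that Sum Power counts every
bin once. FI is the freeze/motion power ratio, guarded by a tiny epsilon
so it stays finite when a window contains no locomotor power.

For a triaxial sensor the principal-direction feature is the three
eigenvalues of the 3x3 within-window covariance matrix, sorted
descending and assigned to the x, y, z columns in that order; a lone
channel (pressure cell, or a partial triad) gets its variance. This
keeps the count at exactly 13 features per channel, 624 for the full
48-channel montage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .channels import ChannelSpec, montage_order
from .errors import DataError, SchemaError
from .windows import WindowSet

FEATURE_NAMES = (
    "fi",
    "energy",
    "sum_power",
    "mean",
    "abs_mean",
    "zcr",
    "std",
    "range",
    "rms",
    "max",
    "min",
    "pde",
    "entropy",
)
FREEZE_BAND = (3.0, 8.0)  # Hz, closed
MOTION_BAND = (0.5, 3.0)  # Hz, right-open
FI_EPS = 1e-12
ENTROPY_BINS = 16


def _band_mask(freqs: np.ndarray, band: tuple[float, float], right_open: bool) -> np.ndarray:
    af = np.abs(freqs)
    upper = af < band[1] if right_open else af <= band[1]
    return (af >= band[0]) & upper


def band_power(
    window: np.ndarray, band: tuple[float, float], f: float, right_open: bool = False
) -> float:
    """Sum of squared DFT magnitudes over bins in ``band``, scaled by 1/N.

    Uses the full two-sided DFT (mirror bins included), so summing the
    motion and freezing zones and the DC term recovers the window's total
    energy/N (Parseval).
    """
    window = np.asarray(window, dtype=float)
    if window.size < 2:
        raise DataError("window must have at least 2 samples")
    if not 0 < band[0] < band[1] <= f / 2:
        raise DataError(f"band {band} outside (0, {f / 2}]")
    spec = np.abs(np.fft.fft(window)) ** 2
    freqs = np.fft.fftfreq(window.size, d=1.0 / f)
    return float(spec[_band_mask(freqs, band, right_open)].sum() / window.size)


@dataclass
class FeatureTable:
    """Windows x features matrix with aligned labels and subject ids."""

    values: np.ndarray  # (n_windows, n_features)
    feature_ids: list[tuple[ChannelSpec, str]]
    labels: np.ndarray
    subject_ids: np.ndarray
    start_times_s: np.ndarray

    def __post_init__(self):
        if self.values.shape[1] != len(self.feature_ids):
            raise SchemaError("values/feature_ids width mismatch")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def column_names(self) -> list[str]:
        return [f"{c.name}__{f}" for c, f in self.feature_ids]

    def select_rows(self, index: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            self.values[index],
            list(self.feature_ids),
            self.labels[index],
            self.subject_ids[index],
            self.start_times_s[index],
        )

    def select_columns(self, cols: np.ndarray | list[int]) -> "FeatureTable":
        cols = np.asarray(cols, dtype=int)
        return FeatureTable(
            self.values[:, cols],
            [self.feature_ids[i] for i in cols],
            self.labels,
            self.subject_ids,
            self.start_times_s,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names)
        df.insert(0, "start_s", self.start_times_s)
        df.insert(0, "label", self.labels)
        df.insert(0, "subject_id", self.subject_ids)
        return df


def _zero_crossings(wins: np.ndarray) -> np.ndarray:
    """Strict sign changes; zero samples inherit the previous nonzero sign."""
    s = np.sign(wins)
    for j in range(1, s.shape[1]):
        z = s[:, j] == 0
        s[z, j] = s[z, j - 1]
    return np.count_nonzero(s[:, 1:] * s[:, :-1] < 0, axis=1).astype(float)


def _entropy(wins: np.ndarray) -> np.ndarray:
    """Shannon entropy (nats) of a 16-bin histogram over each window's range."""
    n, length = wins.shape
    lo = wins.min(axis=1, keepdims=True)
    span = wins.max(axis=1, keepdims=True) - lo
    out = np.zeros(n)
    varying = span[:, 0] > 0
    if varying.any():
        w = wins[varying]
        idx = np.floor((w - lo[varying]) / span[varying] * ENTROPY_BINS)
        idx = np.clip(idx, 0, ENTROPY_BINS - 1).astype(int)
        offset = np.arange(idx.shape[0])[:, None] * ENTROPY_BINS
        counts = np.bincount(
            (idx + offset).ravel(), minlength=idx.shape[0] * ENTROPY_BINS
        ).reshape(idx.shape[0], ENTROPY_BINS)
        p = counts / length
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log(p), 0.0)
        out[varying] = -terms.sum(axis=1)
    return out


def _principal_eigenvalues(
    ws: WindowSet, subset: list[ChannelSpec]
) -> dict[str, np.ndarray]:
    """Per-channel principal-direction eigenvalue columns.

    Channels sharing (location, sensor) form a group; eigenvalues of the
    group's within-window covariance (ddof 0) are sorted descending and
    handed to the group's channels in axis order.
    """
    groups: dict[tuple[str, str], list[ChannelSpec]] = {}
    for c in subset:
        groups.setdefault((c.location, c.sensor), []).append(c)
    chan_pos = {c.name: i for i, c in enumerate(ws.channels)}
    out: dict[str, np.ndarray] = {}
    for members in groups.values():
        members = sorted(members, key=lambda c: "xyzn".index(c.axis[0]))
        idx = [chan_pos[c.name] for c in members]
        x = ws.windows[:, idx, :]  # (n_w, k, L)
        xc = x - x.mean(axis=2, keepdims=True)
        cov = xc @ xc.transpose(0, 2, 1) / x.shape[2]
        eig = np.linalg.eigvalsh(cov)[:, ::-1]  # descending
        for pos, chan in enumerate(members):
            out[chan.name] = eig[:, pos]
    return out


def compute_features(
    ws: WindowSet, channel_subset: list[ChannelSpec] | None = None
) -> FeatureTable:
    """Compute the 13 features for every (window, channel) pair.

    Columns run channels-outer (montage order) and features-inner
    (canonical order), deterministically.
    """
    subset = montage_order(channel_subset if channel_subset else ws.channels)
    if not subset:
        raise DataError("empty channel subset")
    chan_pos = {c.name: i for i, c in enumerate(ws.channels)}
    for c in subset:
        if c.name not in chan_pos:
            raise DataError(f"window set lacks channel {c.name}")
    n_w, _, length = ws.windows.shape
    fs = ws.sample_rate
    freqs = np.fft.fftfreq(length, d=1.0 / fs)
    m_motion = _band_mask(freqs, MOTION_BAND, right_open=True)
    m_freeze = _band_mask(freqs, FREEZE_BAND, right_open=False)
    pde = _principal_eigenvalues(ws, subset)

    values = np.empty((n_w, 13 * len(subset)))
    feature_ids: list[tuple[ChannelSpec, str]] = []
    for ci, chan in enumerate(subset):
        wins = ws.windows[:, chan_pos[chan.name], :]
        spec = np.abs(np.fft.fft(wins, axis=1)) ** 2
        motion = spec[:, m_motion].sum(axis=1) / length
        freeze = spec[:, m_freeze].sum(axis=1) / length
        col = {
            "fi": freeze / (motion + FI_EPS),
            "energy": spec.sum(axis=1),
            "sum_power": freeze + motion,
            "mean": wins.mean(axis=1),
            "abs_mean": np.abs(wins).mean(axis=1),
            "zcr": _zero_crossings(wins),
            "std": wins.std(axis=1),
            "range": wins.max(axis=1) - wins.min(axis=1),
            "rms": np.sqrt((wins**2).mean(axis=1)),
            "max": wins.max(axis=1),
            "min": wins.min(axis=1),
            "pde": pde[chan.name],
            "entropy": _entropy(wins),
        }
        for fi_, name in enumerate(FEATURE_NAMES):
            values[:, ci * 13 + fi_] = col[name]
            feature_ids.append((chan, name))
    return FeatureTable(
        values, feature_ids, ws.labels.copy(), ws.subject_ids.copy(), ws.start_times_s.copy()
    )


@dataclass
class NormalizationModel:
    """Per-feature (min, max) learned from a training table."""

    mins: np.ndarray
    maxs: np.ndarray
    feature_ids: list[tuple[ChannelSpec, str]]


def fit_minmax(train: FeatureTable) -> NormalizationModel:
    if train.n_rows == 0:
        raise DataError("cannot fit normalisation on an empty table")
    return NormalizationModel(
        train.values.min(axis=0), train.values.max(axis=0), list(train.feature_ids)
    )


def apply_minmax(model: NormalizationModel, table: FeatureTable) -> FeatureTable:
    """Map v -> (v - min)/(max - min); constant training features map to 0.

    Values outside the training range land outside [0, 1] and are not
    clipped.
    """
    if [f"{c.name}_{n}" for c, n in model.feature_ids] != [
        f"{c.name}_{n}" for c, n in table.feature_ids
    ]:
        raise SchemaError("normalisation model does not match table features")
    span = model.maxs - model.mins
    safe = np.where(span > 0, span, 1.0)
    values = (table.values - model.mins) / safe
    values[:, span == 0] = 0.0
    return FeatureTable(
        values, list(table.feature_ids), table.labels, table.subject_ids, table.start_times_s
    )
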