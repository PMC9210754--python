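"""Sliding-window segmentation with start-point labelling.

A recording of ``l`` samples at ``f`` Hz cut into windows of ``m``
seconds advanced by ``t`` seconds yields ``(l/f - m)/t + 1`` windows
(floored). Each window is labelled by its *start* time point: label 1
iff the start lies inside an annotated freezing episode, episodes being
half-open ``[start_s, end_s)``. The start-point rule compensates the
annotation lag of observers marking freezes from video.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .channels import ChannelSpec
from .errors import DataError
from .simulate import AnnotationTrack, Recording


@dataclass
class WindowSet:
    """Fixed-length windows, aligned labels/subjects/start times."""

    windows: np.ndarray  # (n_windows, n_channels, window_samples)
    labels: np.ndarray  # uint8, 1 = freezing
    subject_ids: np.ndarray  # str per window
    start_times_s: np.ndarray
    sample_rate: float
    window_length_s: float
    step_s: float
    channels: list[ChannelSpec]

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]


def count_windows(l: int, f: float, m: float, t: float) -> int:
    """Number of windows: floor((l/f - m)/t) + 1, or 0 if nothing fits."""
    if t <= 0 or f <= 0:
        raise DataError("step and sample rate must be positive")
    span = l / f - m
    if span < 0:
        return 0
    # guard float representation of e.g. (10-2)/0.5 before flooring
    return int(math.floor(span / t + 1e-9)) + 1


def window_label(start_s: float, episodes: list[tuple[float, float]]) -> int:
    return int(any(a <= start_s < b for a, b in episodes))


def segment(
    recording: Recording,
    annotations: AnnotationTrack,
    m: float = 2.0,
    t: float = 0.5,
) -> WindowSet:
    """Cut one recording into labelled windows (all channels, same bounds)."""
    if recording.missing.any():
        raise DataError("segment expects a preprocessed (gap-free) recording")
    for a, b in annotations.episodes:
        if b > recording.duration_s + 1e-9:
            raise DataError(
                f"episode ({a}, {b}) extends beyond the {recording.duration_s:.2f}s recording"
            )
    fs = recording.sample_rate
    w_len = int(round(m * fs))
    n_w = count_windows(recording.n_samples, fs, m, t)
    starts_s = np.arange(n_w) * t
    start_idx = np.rint(starts_s * fs).astype(int)
    # (n_samples, n_channels) -> per-window views -> (n_w, n_ch, w_len)
    # sliding_window_view over axis 0 yields (n - w_len + 1, n_channels, w_len)
    view = np.lib.stride_tricks.sliding_window_view(recording.data, w_len, axis=0)
    windows = view[start_idx].copy() if n_w else np.empty(
        (0, len(recording.channels), w_len)
    )
    labels = np.array(
        [window_label(s, annotations.episodes) for s in starts_s], dtype=np.uint8
    )
    subject_ids = np.full(n_w, recording.subject_id, dtype=object)
    return WindowSet(
        windows,
        labels,
        subject_ids,
        starts_s,
        fs,
        m,
        t,
        list(recording.channels),
    )


def concat_window_sets(sets: list[WindowSet]) -> WindowSet:
    """Stack per-subject window sets into one cohort-level set."""
    if not sets:
        raise DataError("no window sets to concatenate")
    first = sets[0]
    for ws in sets[1:]:
        if (
            ws.sample_rate != first.sample_rate
            or ws.window_length_s != first.window_length_s
            or ws.step_s != first.step_s
            or [c.name for c in ws.channels] != [c.name for c in first.channels]
        ):
            raise DataError("window sets have incompatible geometry")
    return WindowSet(
        np.concatenate([ws.windows for ws in sets]),
        np.concatenate([ws.labels for ws in sets]),
        np.concatenate([ws.subject_ids for ws in sets]),
        np.concatenate([ws.start_times_s for ws in sets]),
        first.sample_rate,
        first.window_length_s,
        first.step_s,
        list(first.channels),
    )
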