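"""On-disk formats: recording/annotation/feature CSV dialects, results, config.

Recordings are wide CSV, one file per subject: first column ``t_s``,
then one column per channel named ``<location>_<sensor>_<axis>``;
missing samples are empty cells. Annotations are
``subject_id,start_s,end_s``. Feature tables carry
``subject_id,label,start_s`` followed by ``<channel>__<feature>``
columns. Round-trips are lossless up to float formatting (1e-9).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .balance import SmoteConfig
from .channels import expand_subset, parse_channel_name
from .errors import ConfigError, ParseError
from .evaluate import EvalResult, PipelineConfig
from .features import FeatureTable
from .simulate import AnnotationTrack, GeneratorConfig, Recording

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


def write_recording_csv(recording: Recording, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        recording.data, columns=[c.name for c in recording.channels]
    )
    df[recording.missing] = np.nan
    df.insert(0, "t_s", np.arange(recording.n_samples) / recording.sample_rate)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_recording_csv(
    path: str | Path, subject_id: str | None = None, sample_rate: float | None = None
) -> Recording:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.columns[0] != "t_s":
        raise ParseError(f"{path}: first column must be t_s, got {df.columns[0]!r}")
    try:
        channels = [parse_channel_name(c) for c in df.columns[1:]]
    except ConfigError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    t = df["t_s"].to_numpy()
    if sample_rate is None:
        if len(t) < 2:
            raise ParseError(f"{path}: cannot infer sample rate from <2 samples")
        sample_rate = float(round(1.0 / np.median(np.diff(t)), 6))
    data = df.iloc[:, 1:].to_numpy(dtype=float)
    missing = np.isnan(data)
    return Recording(
        subject_id or path.stem, sample_rate, channels, data, missing
    )


def write_cohort(
    cohort: list[tuple[Recording, AnnotationTrack]], out_dir: str | Path
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec, _ in cohort:
        write_recording_csv(rec, out_dir / f"{rec.subject_id}.csv")
    write_annotations_csv([ann for _, ann in cohort], out_dir / "annotations.csv")


def read_cohort(in_dir: str | Path) -> list[tuple[Recording, AnnotationTrack]]:
    in_dir = Path(in_dir)
    rec_paths = sorted(p for p in in_dir.glob("*.csv") if p.name != "annotations.csv")
    if not rec_paths:
        logger.warning("no recording files found in %s", in_dir)
        return []
    ann_path = in_dir / "annotations.csv"
    tracks = {a.subject_id: a for a in read_annotations_csv(ann_path)} if ann_path.exists() else {}
    cohort = []
    for p in rec_paths:
        rec = read_recording_csv(p)
        ann = tracks.get(rec.subject_id, AnnotationTrack(rec.subject_id, []))
        cohort.append((rec, ann))
    return cohort


def write_annotations_csv(tracks: list[AnnotationTrack], path: str | Path) -> None:
    rows = [
        {"subject_id": t.subject_id, "start_s": a, "end_s": b}
        for t in tracks
        for a, b in t.episodes
    ]
    pd.DataFrame(rows, columns=["subject_id", "start_s", "end_s"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_annotations_csv(path: str | Path) -> list[AnnotationTrack]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    expect = ["subject_id", "start_s", "end_s"]
    if list(df.columns) != expect:
        raise ParseError(f"{path}: expected columns {expect}, got {list(df.columns)}")
    tracks = []
    for sid, grp in df.groupby("subject_id", sort=True):
        eps = sorted(zip(grp["start_s"], grp["end_s"]))
        tracks.append(AnnotationTrack(str(sid), [(float(a), float(b)) for a, b in eps]))
    return tracks


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_feature_table(path: str | Path) -> FeatureTable:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    meta = ["subject_id", "label", "start_s"]
    if list(df.columns[:3]) != meta:
        raise ParseError(f"{path}: expected leading columns {meta}")
    feature_ids = []
    for col in df.columns[3:]:
        try:
            chan_name, feat = col.rsplit("__", 1)
            feature_ids.append((parse_channel_name(chan_name), feat))
        except (ValueError, ConfigError) as exc:
            raise ParseError(f"{path}: bad feature column {col!r}: {exc}") from exc
    return FeatureTable(
        df.iloc[:, 3:].to_numpy(dtype=float),
        feature_ids,
        df["label"].to_numpy(dtype=np.uint8),
        df["subject_id"].astype(str).to_numpy(dtype=object),
        df["start_s"].to_numpy(dtype=float),
    )


def eval_result_to_dict(result: EvalResult) -> dict:
    return {
        "config": result.config,
        "aggregate": result.aggregate.as_dict(),
        "pooled_counts": vars(result.pooled_counts),
        "fold_mean": result.fold_mean(),
        "fold_sd": result.fold_sd(),
        "per_fold": [
            {
                "subject_id": f.subject_id,
                "counts": vars(f.counts),
                "metrics": f.metrics.as_dict(),
                "train_subjects": f.train_subjects,
            }
            for f in result.per_fold
        ],
    }


def write_eval_result(result: EvalResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(eval_result_to_dict(result), indent=2))


@dataclasses.dataclass
class RunConfig:
    """One YAML-serialisable configuration for a full pipeline run."""

    generator: GeneratorConfig = dataclasses.field(default_factory=GeneratorConfig)
    channels: str = "all"
    selection_method: str | None = "anova"
    top_k: int = 35
    mi_bins: int = 10
    smote: SmoteConfig = dataclasses.field(default_factory=SmoteConfig)
    n_trees: int = 10
    seed: int = 0
    window_s: float = 2.0
    step_s: float = 0.5
    filter_order: int = 26
    band: tuple[float, float] = (0.5, 10.0)

    def pipeline_config(self) -> PipelineConfig:
        chans = None if self.channels == "all" else expand_subset(self.channels)
        return PipelineConfig(
            channels=chans,
            selection_method=self.selection_method,
            top_k=self.top_k,
            smote=self.smote,
            n_trees=self.n_trees,
            seed=self.seed,
            window_s=self.window_s,
            step_s=self.step_s,
            filter_order=self.filter_order,
            band=self.band,
            mi_bins=self.mi_bins,
        )


def _as_dict(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _as_dict(v) for k, v in vars(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_as_dict(config), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    gen = raw.pop("generator", {})
    for key in ("step_freq_range", "tremble_freq_range", "episode_duration_lognormal"):
        if key in gen:
            gen[key] = tuple(gen[key])
    if "gap_length_range" in gen:
        gen["gap_length_range"] = tuple(int(v) for v in gen["gap_length_range"])
    smote_cfg = raw.pop("smote", {})
    if "band" in raw:
        raw["band"] = tuple(raw["band"])
    try:
        return RunConfig(
            generator=GeneratorConfig(**gen), smote=SmoteConfig(**smote_cfg), **raw
        )
    except TypeError as exc:
        raise ParseError(f"{path}: {exc}") from exc
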