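"""End-to-end orchestration: simulate → preprocess → FC → EC → statistics.

A :class:`RunConfig` (loadable from YAML) fully determines a run; every
stochastic stage consumes a sub-seed derived from the global seed, so the
same config produces bit-identical output tables.  A :class:`RunManifest`
records the config snapshot, software version, per-output SHA-256 hashes,
seeds and timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coherence import pairwise_wpco
from .coupling import DBIConfig, pairwise_ec
from .io import (ec_edge_rows, fc_edge_rows, read_recording, read_scores,
                 write_edges, write_recording, write_scores)
from .preprocess import FilterConfig, MaraConfig, preprocess_recording
from .recording import Recording
from .stats import connectivity_table, run_full_stats
from .synthetic import CohortSpec, make_synthetic_cohort


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    out_dir: str = "hemoconn_run"
    input_dir: str | None = None  # None: simulate the cohort
    cohort: CohortSpec = field(default_factory=CohortSpec)
    bands: tuple[str, ...] = ("III", "IV")
    mara: MaraConfig = field(default_factory=MaraConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    wavelet_f0: float = 1.0
    n_per_octave: int = 16
    n_surrogates: int = 100
    dbi: DBIConfig = field(default_factory=DBIConfig)
    alpha: float = 0.05
    correction: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_surrogates < 2:
            raise ValueError("n_surrogates must be >= 2")
        unknown = set(self.bands) - {"I", "II", "III", "IV"}
        if unknown:
            raise ValueError(f"unknown band(s) {sorted(unknown)}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "cohort" in kwargs and isinstance(kwargs["cohort"], dict):
            kwargs["cohort"] = CohortSpec(**kwargs["cohort"])
        for key, klass in (("mara", MaraConfig), ("filter", FilterConfig),
                           ("dbi", DBIConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        if "bands" in kwargs:
            kwargs["bands"] = tuple(kwargs["bands"])
        return cls(**kwargs)


@dataclass
class RunManifest:
    config: dict
    version: str
    seeds: dict
    hashes: dict
    timestamps: dict

    def write(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _sub_seed(seed: int, *tags) -> np.random.SeedSequence:
    # stable across processes (no reliance on PYTHONHASHSEED)
    stable = tuple(zlib.crc32(str(t).encode()) for t in tags)
    return np.random.SeedSequence((seed,) + stable)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, subject: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for subject {subject!r}: {cause}")
        self.stage = stage
        self.subject = subject


def simulate_stage(config: RunConfig) -> tuple[list[Recording], pd.DataFrame]:
    spec = dataclasses.replace(config.cohort, seed=config.seed)
    return make_synthetic_cohort(spec)


def load_stage(config: RunConfig) -> tuple[list[Recording], pd.DataFrame | None]:
    """Read an existing cohort directory written by a simulate stage (or user
    data of identical layout)."""
    in_dir = Path(config.input_dir)
    recs = []
    for csv_path in sorted(in_dir.glob("*_rec.csv")):
        meta_path = csv_path.with_name(csv_path.name.replace("_rec.csv", "_meta.yaml"))
        recs.append(read_recording(csv_path, meta_path))
    scores_path = in_dir / "scores.csv"
    scores = read_scores(scores_path) if scores_path.exists() else None
    return recs, scores


def write_cohort(recs: list[Recording], scores: pd.DataFrame | None,
                 out: Path) -> list[Path]:
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in recs:
        stem = f"{rec.subject_id}_{rec.condition}"
        csv_path = out / f"{stem}_rec.csv"
        meta_path = out / f"{stem}_meta.yaml"
        write_recording(rec, csv_path, meta_path)
        paths += [csv_path, meta_path]
    if scores is not None:
        p = out / "scores.csv"
        write_scores(scores, p)
        paths.append(p)
    return paths


_STAGES = ("simulate", "preprocess", "fc", "ec", "stats")


def run_pipeline(config: RunConfig, until: str = "stats") -> RunManifest:
    """Execute the stages up to and including ``until``; deterministic given
    the config.

    Outputs under ``config.out_dir``: the simulated cohort (if simulated),
    preprocessed recordings, FC and EC edge lists, the statistics TSV and
    the manifest.
    """
    if until not in _STAGES:
        raise ValueError(f"unknown stage {until!r}")
    last = _STAGES.index(until)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timestamps = {"start": time.strftime("%Y-%m-%dT%H:%M:%S")}
    seeds = {"global": config.seed}
    written: list[Path] = []

    if config.input_dir is None:
        recs, scores = simulate_stage(config)
        written += write_cohort(recs, scores, out / "cohort")
    else:
        recs, scores = load_stage(config)
    timestamps["simulate"] = time.strftime("%Y-%m-%dT%H:%M:%S")

    def finish() -> RunManifest:
        manifest = RunManifest(
            config=config.to_dict(), version=__version__, seeds=seeds,
            hashes={str(p.relative_to(out)): _hash_file(p) for p in written},
            timestamps=timestamps)
        manifest.write(out / "manifest.yaml")
        return manifest

    if last < 1:
        return finish()

    pre_dir = out / "preprocessed"
    pre_dir.mkdir(exist_ok=True)
    clean: list[Recording] = []
    seg_rows = []
    for rec in recs:
        try:
            cleaned, report = preprocess_recording(rec, config.mara, config.filter)
        except Exception as e:  # pragma: no cover
            raise PipelineError("preprocess", rec.subject_id, e) from e
        clean.append(cleaned)
        for row in report.to_dict("records"):
            seg_rows.append({"subject": rec.subject_id,
                             "condition": rec.condition, **row})
        stem = f"{rec.subject_id}_{rec.condition}"
        write_recording(cleaned, pre_dir / f"{stem}_rec.csv",
                        pre_dir / f"{stem}_meta.yaml")
    seg_path = pre_dir / "artifact_segments.tsv"
    pd.DataFrame(seg_rows, columns=["subject", "condition", "channel",
                                    "start_s", "end_s"]).to_csv(
        seg_path, sep="\t", index=False)
    written.append(seg_path)
    timestamps["preprocess"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    if last < 2:
        return finish()

    fc_rows, fc_table_rows = [], []
    for k, rec in enumerate(clean):
        try:
            res = pairwise_wpco(rec, list(config.bands),
                                n_surrogates=config.n_surrogates,
                                seed=_sub_seed(config.seed, "fc", k),
                                n_per_octave=config.n_per_octave,
                                f0=config.wavelet_f0)
        except Exception as e:  # pragma: no cover
            raise PipelineError("fc", rec.subject_id, e) from e
        fc_rows += fc_edge_rows(rec, res)
        row = {"subject": rec.subject_id, "group": rec.group,
               "condition": rec.condition}
        for band, r in res.items():
            for a, b, v in r.region_pairs():
                row[f"{band}:{a}-{b}"] = v
        fc_table_rows.append(row)
    fc_path = out / "fc_edges.tsv"
    write_edges(fc_rows, fc_path)
    written.append(fc_path)
    timestamps["fc"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    if last < 3:
        return finish()

    ec_rows, ec_table_rows = [], []
    for k, rec in enumerate(clean):
        row = {"subject": rec.subject_id, "group": rec.group,
               "condition": rec.condition}
        results = {}
        for band in config.bands:
            try:
                res = pairwise_ec(rec, band, config.dbi,
                                  n_surrogates=config.n_surrogates,
                                  seed=_sub_seed(config.seed, "ec", k, band))
            except Exception as e:  # pragma: no cover
                raise PipelineError("ec", rec.subject_id, e) from e
            results[band] = res
            for a, b, v in res.directed_pairs():
                row[f"{band}:{a}->{b}"] = v
        ec_rows += ec_edge_rows(rec, results)
        ec_table_rows.append(row)
    ec_path = out / "ec_edges.tsv"
    write_edges(ec_rows, ec_path)
    written.append(ec_path)
    timestamps["ec"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    if last < 4:
        return finish()

    fc_table = connectivity_table(fc_table_rows)
    ec_table = connectivity_table(ec_table_rows)
    stats_df = run_full_stats(fc_table, ec_table, scores,
                              alpha=config.alpha,
                              correction=config.correction)
    stats_path = out / "statistics.tsv"
    stats_df.to_csv(stats_path, sep="\t", index=False, float_format="%.8g")
    written.append(stats_path)
    timestamps["stats"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    return finish()


def demo_config(out_dir: str | Path, seed: int = 0) -> RunConfig:
    """A minutes-scale configuration: three subjects per group, one channel
    per region, 300 s records, a reduced surrogate ensemble."""
    cohort = CohortSpec(n_per_group=(3, 3), duration=300.0,
                        n_channels_per_region=1, seed=seed)
    return RunConfig(out_dir=str(out_dir), cohort=cohort,
                     bands=("III", "IV"), n_surrogates=4, seed=seed)
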