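"""Plain-text interchange: recording CSVs, metadata sidecars, edge lists.

A recording is one CSV (column 1: time in seconds; columns 2..n: channel
values; header ``time,ch01,...``) plus a YAML sidecar with subject, group,
condition, sampling rate and the channel → region map.  Connectivity results
are tab-separated edge lists.  Everything is diff-able text.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .coherence import WPCOResult
from .coupling import ECResult
from .recording import REGIONS, Recording


class RecordingParseError(ValueError):
    pass


def write_recording(rec: Recording, csv_path: str | Path,
                    meta_path: str | Path) -> None:
    df = pd.DataFrame(rec.samples.T, columns=rec.channel_names)
    df.insert(0, "time", rec.times)
    df.to_csv(csv_path, index=False, float_format="%.10g")
    meta = {
        "subject": rec.subject_id,
        "group": rec.group,
        "condition": rec.condition,
        "sampling_rate": float(rec.sampling_rate),
        "channel_regions": {name: region for name, region
                            in zip(rec.channel_names, rec.channel_regions)},
    }
    Path(meta_path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_recording(csv_path: str | Path, meta_path: str | Path) -> Recording:
    """Validated round-trip of :func:`write_recording`."""
    meta = yaml.safe_load(Path(meta_path).read_text())
    df = pd.read_csv(csv_path)
    if "time" not in df.columns:
        raise RecordingParseError(f"{csv_path}: missing 'time' column")
    chan_map = meta.get("channel_regions", {})
    channels = [c for c in df.columns if c != "time"]
    if sorted(channels) != sorted(chan_map):
        raise RecordingParseError(
            f"{csv_path}: CSV has {len(channels)} channels but metadata "
            f"lists {len(chan_map)}")
    for name, region in chan_map.items():
        if region not in REGIONS:
            raise RecordingParseError(
                f"{meta_path}: unknown region label {region!r} "
                f"for channel {name}")
    t = df["time"].to_numpy()
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 2  # header + 1-offset
        raise RecordingParseError(
            f"{csv_path}: non-monotone time column near row {row}")
    return Recording(
        df[channels].to_numpy().T,
        sampling_rate=float(meta["sampling_rate"]),
        channel_regions=tuple(chan_map[c] for c in channels),
        subject_id=str(meta.get("subject", "")),
        group=str(meta.get("group", "")),
        condition=str(meta.get("condition", "")),
    )


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, index=False, float_format="%.6g")


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def fc_edge_rows(rec: Recording, results: dict[str, WPCOResult]) -> list[dict]:
    rows = []
    for band, res in results.items():
        for i in range(len(res.regions)):
            for j in range(i + 1, len(res.regions)):
                rows.append({
                    "subject": rec.subject_id, "group": rec.group,
                    "condition": rec.condition, "band": band,
                    "region_a": res.regions[i], "region_b": res.regions[j],
                    "wpco": res.region_matrix[i, j],
                    "surrogate_threshold": (
                        res.region_threshold[i, j]
                        if res.region_threshold is not None else np.nan),
                    "significant": (
                        int(res.significant[i, j])
                        if res.significant is not None else ""),
                })
    return rows


def ec_edge_rows(rec: Recording, results: dict[str, ECResult]) -> list[dict]:
    rows = []
    for band, res in results.items():
        for i, a in enumerate(res.regions):
            for j, b in enumerate(res.regions):
                if i == j:
                    continue
                rows.append({
                    "subject": rec.subject_id, "group": rec.group,
                    "condition": rec.condition, "band": band,
                    "region_from": a, "region_to": b,
                    "cs": res.region_matrix[i, j],
                    "surrogate_mean": (
                        res.surrogate_mean[i, j]
                        if res.surrogate_mean is not None else np.nan),
                    "surrogate_sd": (
                        res.surrogate_sd[i, j]
                        if res.surrogate_sd is not None else np.nan),
                    "significant": (
                        int(res.significant[i, j])
                        if res.significant is not None else ""),
                })
    return rows


def write_edges(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.8g")
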