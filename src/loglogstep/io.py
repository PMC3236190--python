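"""Readers and writers for ISI series, correlation curves, scores and phase diagrams.

Formats are deliberately plain text: series as one interval per line (with an
optional second CSV column carrying the pattern/noise label), curves as TSV,
scores as JSON with full provenance, phase diagrams as long-form CSV.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .correlation import CorrelationCurve
from .phase import PhaseDiagram
from .simulate import ISISeries

__all__ = [
    "read_isi",
    "write_isi",
    "write_curve",
    "read_curve",
    "write_scores",
    "write_phase",
]

PathLike = Union[str, Path]

_LABELS = ("pattern", "noise")


def read_isi(path: PathLike) -> ISISeries:
    """Read an ISI series: one positive interval per line, optional ``,label`` column.

    Malformed or non-positive entries are rejected with their line number.
    """
    intervals: list[float] = []
    labels: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = [t.strip() for t in text.split(",")]
            try:
                value = float(parts[0])
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: not a number: {parts[0]!r}") from None
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{path}: line {lineno}: interval must be positive, got {value}")
            intervals.append(value)
            if len(parts) > 1:
                if parts[1] not in _LABELS:
                    raise ValueError(
                        f"{path}: line {lineno}: label must be one of {_LABELS}, got {parts[1]!r}"
                    )
                labels.append(parts[1])
    if not intervals:
        raise ValueError(f"{path}: no intervals found")
    if labels and len(labels) != len(intervals):
        raise ValueError(f"{path}: labels present on some lines only")
    return ISISeries(np.asarray(intervals), np.asarray(labels) if labels else None)


def write_isi(series: ISISeries, path: PathLike) -> None:
    """Write a series at full precision; labels, when present, as a second CSV column."""
    with open(path, "w") as fh:
        for i, value in enumerate(series.intervals):
            if series.labels is not None:
                fh.write(f"{float(value)!r},{series.labels[i]}\n")
            else:
                fh.write(f"{float(value)!r}\n")


def write_curve(curve: CorrelationCurve, path: PathLike) -> None:
    """TSV with columns log10_eps, log10_C, m."""
    df = pd.DataFrame(
        {"log10_eps": curve.log_eps, "log10_C": curve.log_C, "m": curve.m}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_curve(path: PathLike) -> CorrelationCurve:
    df = pd.read_csv(path, sep="\t")
    m = int(df["m"].iloc[0])
    return CorrelationCurve(
        log_eps=df["log10_eps"].to_numpy(),
        log_C=df["log10_C"].to_numpy(),
        m=m,
        n_points=0,
    )


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_scores(scores: dict, path: PathLike) -> None:
    """Scores plus full provenance (levels, weights, seeds, grid) as JSON."""
    with open(path, "w") as fh:
        json.dump(_jsonable(scores), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_phase(diagram: PhaseDiagram, path: PathLike) -> None:
    """Long-form CSV (jitter, noise, criterion, scores, region); metadata as a JSON sidecar."""
    diagram.to_frame().to_csv(path, index=False)
    meta_path = Path(path).with_suffix(Path(path).suffix + ".meta.json")
    write_scores(diagram.metadata, meta_path)
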