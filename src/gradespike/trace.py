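"""Uniformly sampled time-series container and plain-text trace I/O.

A :class:`Trace` is the currency of the whole pipeline: fluorescence (raw or
ΔF/F) sampled at imaging rates (30–120 Hz) or cell-attached current (pA)
sampled at ≥10 kHz.  Traces travel on disk as a delimited-text matrix (one
column per channel, header row naming channels) plus a JSON sidecar holding
the sample rate, units, seed and scenario, so recordings exported from any
acquisition system can be dropped into the same format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Trace",
    "write_trace_matrix",
    "read_trace_matrix",
    "write_ground_truth_csv",
    "read_ground_truth_csv",
]


@dataclass
class Trace:
    """A uniformly sampled 1-D signal.

    Parameters
    ----------
    samples
        Signal values (ΔF/F, arbitrary fluorescence units, or pA).
    sample_rate
        Sampling rate in Hz; must be positive.
    start_time
        Time of the first sample in seconds.
    units
        Free-text unit label (e.g. ``"dff"``, ``"pA"``, ``"au"``).
    """

    samples: np.ndarray
    sample_rate: float
    start_time: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("Trace samples must be one-dimensional")
        if self.samples.size < 2:
            raise ValueError("Trace must hold at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Trace samples must be finite")
        if not (self.sample_rate > 0):
            raise ValueError(f"sample_rate must be > 0, got {self.sample_rate}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Length of the recording in seconds (n / fs)."""
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start_time + np.arange(self.n_samples) / self.sample_rate

    def with_samples(self, samples: np.ndarray, units: str | None = None) -> "Trace":
        """Copy of this trace with new samples (and optionally new units)."""
        out = replace(self, samples=np.asarray(samples, dtype=float))
        if units is not None:
            out.units = units
        return out

    def index_of(self, t: float) -> int:
        """Nearest sample index for time ``t`` (clipped to the trace)."""
        i = int(round((t - self.start_time) * self.sample_rate))
        return int(np.clip(i, 0, self.n_samples - 1))


def write_trace_matrix(
    path: str | Path,
    traces: dict[str, Trace],
    *,
    seed: int | None = None,
    scenario: str | None = None,
    extra_meta: dict | None = None,
) -> tuple[Path, Path]:
    """Write named channels as ``<path>.csv`` + ``<path>.json`` sidecar.

    All channels must share a sample rate and length.  Returns the two paths.
    """
    if not traces:
        raise ValueError("no channels to write")
    rates = {name: tr.sample_rate for name, tr in traces.items()}
    if len(set(rates.values())) != 1:
        raise ValueError(f"channels disagree on sample rate: {rates}")
    lengths = {tr.n_samples for tr in traces.values()}
    if len(lengths) != 1:
        raise ValueError("channels disagree on length")

    path = Path(path)
    csv_path = path.with_suffix(".csv")
    json_path = path.with_suffix(".json")
    frame = pd.DataFrame({name: tr.samples for name, tr in traces.items()})
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(csv_path, index=False, float_format="%.9g")
    meta = {
        "sample_rate_hz": next(iter(rates.values())),
        "units": {name: tr.units for name, tr in traces.items()},
        "channels": list(traces),
        "start_time_s": {name: tr.start_time for name, tr in traces.items()},
        "seed": seed,
        "scenario": scenario,
    }
    if extra_meta:
        meta.update(extra_meta)
    json_path.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    return csv_path, json_path


def read_trace_matrix(path: str | Path) -> dict[str, Trace]:
    """Read back the channels written by :func:`write_trace_matrix`."""
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    json_path = path.with_suffix(".json")
    if not json_path.exists():
        raise FileNotFoundError(
            f"sidecar {json_path} not found; traces need a JSON sidecar with sample_rate_hz"
        )
    meta = json.loads(json_path.read_text())
    if "sample_rate_hz" not in meta:
        raise KeyError(f"{json_path} lacks mandatory key 'sample_rate_hz'")
    frame = pd.read_csv(csv_path)
    fs = float(meta["sample_rate_hz"])
    units = meta.get("units", {})
    start = meta.get("start_time_s", {})
    return {
        name: Trace(
            frame[name].to_numpy(),
            fs,
            start_time=float(start.get(name, 0.0)),
            units=str(units.get(name, "")),
        )
        for name in frame.columns
    }


def write_ground_truth_csv(path: str | Path, truth) -> Path:
    """Ground truth as CSV (time_s, label, amplitude, secondary_scale)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "time_s": truth.event_times,
            "label": truth.class_labels,
            "amplitude": truth.true_amplitudes,
            "secondary_scale": truth.true_secondary_scales,
        }
    ).to_csv(path, index=False, float_format="%.9g")
    return path


def read_ground_truth_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
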