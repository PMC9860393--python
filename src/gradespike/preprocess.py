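"""Trace conditioning: ΔF/F normalization and EAP band-pass filtering.

Fluorescence is normalised as ΔF/F = (F − F₀)/F₀ with F₀ the 15th percentile
of the whole raw trace (a single scalar baseline per recording, robust to the
sparse activity of these cells).  Current traces are band-pass filtered
6–1500 Hz with a zero-phase 2nd-order Butterworth so detected event times are
not skewed by filter delay.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .trace import Trace

__all__ = ["dff", "bandpass", "BASELINE_PERCENTILE", "BANDPASS_DEFAULT"]

BASELINE_PERCENTILE = 15.0
BANDPASS_DEFAULT = (6.0, 1500.0)  # Hz


def dff(raw: Trace, percentile: float = BASELINE_PERCENTILE) -> Trace:
    """Normalize a raw fluorescence trace to ΔF/F.

    F₀ is the given percentile (default 15th) of the full trace, computed with
    linear interpolation between order statistics.  A non-positive F₀ signals
    a non-physical baseline and is rejected.
    """
    f0 = float(np.percentile(raw.samples, percentile))
    if f0 <= 0:
        raise ValueError(
            f"baseline F0 = {f0:.6g} (percentile {percentile}) is not positive; "
            "dff requires a positive fluorescence baseline"
        )
    return raw.with_samples((raw.samples - f0) / f0, units="dff")


def bandpass(
    trace: Trace,
    low: float = BANDPASS_DEFAULT[0],
    high: float = BANDPASS_DEFAULT[1],
) -> Trace:
    """Zero-phase band-pass filter (2nd-order Butterworth, forward-backward).

    Removes DC and out-of-band components; defaults match the 6–1500 Hz band
    used for EAP detection.  Edges are handled by reflection padding of one
    settling length.
    """
    nyq = trace.sample_rate / 2.0
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got low={low}, high={high}")
    if high >= nyq:
        raise ValueError(
            f"high cutoff {high} Hz must be below the Nyquist frequency "
            f"{nyq} Hz (sample rate {trace.sample_rate} Hz)"
        )
    sos = signal.butter(2, [low, high], btype="bandpass", fs=trace.sample_rate, output="sos")
    # Reflection padding of ~one settling length of the low corner.
    padlen = min(trace.n_samples - 1, int(3 * trace.sample_rate / low))
    out = signal.sosfiltfilt(sos, trace.samples, padtype="even", padlen=padlen)
    return trace.with_samples(out)
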