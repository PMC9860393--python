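#!/usr/bin/env python
"""Spontaneous Ca2+ activity survey: rates, ISI CV, amplitude multimodality.

Simulates a 127-cell population at the study conditions (per-cell rates
log-normal around 0.148 Hz, bimodal small/large amplitude mixture), runs the
full ΔF/F -> derivative -> detection -> measurement chain on every cell, and
summarises the population.  A Poisson process predicts ISI CV near 1; the
two-mode amplitude mixture should trip the Jarque-Bera multimodality flag in
well-sampled cells.
"""

from pathlib import Path

from gradespike import pipeline

OUT = Path(__file__).resolve().parents[1] / "results" / "spontaneous"

cfg = pipeline.RunConfig(scenario="spontaneous", n_cells=127, duration=300.0,
                         seed=1, out_dir=str(OUT), null_replicates=20_000)
res = pipeline.run_spontaneous(cfg)
s = res["summary"]
print(f"{s['n_cells']} cells, {len(res['events'])} detected spikes")
print(f"rate: median {s['rate_hz']['median']:.3f} +/- {s['rate_hz']['iqr']:.3f} Hz (IQR)")
print(f"ISI CV: median {s['isi_cv']['median']:.2f} +/- {s['isi_cv']['iqr']:.2f} (IQR)"
      " — consistent with a Poisson process")
print(f"multimodal amplitude distributions: {s['n_multimodal']} of {s['n_flagged']} "
      "cells (JB vs Monte-Carlo critical value)")
print(f"tables -> {OUT}")
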