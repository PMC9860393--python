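#!/usr/bin/env python
"""EAP waveform analysis: dual depolarizing peaks and ∫EAP multimodality.

Simulates cell-attached recordings for 16 cells at the electrode-elevated
rate, band-passes (6-1500 Hz), detects EAPs per cell with the automatic
threshold, and quantifies (i) the secondary depolarizing peak of each cell's
mean waveform (maximum after the third inflection of the differential) and
(ii) whether the per-cell ∫EAP amplitude distribution departs from normality
(JB with Monte-Carlo critical values), mirroring the Ca2+-side analysis.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gradespike import eap, preprocess, stats, synth

OUT = Path(__file__).resolve().parents[1] / "results" / "eap"
OUT.mkdir(parents=True, exist_ok=True)

SEED = 1
N_CELLS = 16
DURATION = 240.0
RATE = 0.444  # spontaneous rate is ~3-fold higher with a pipette attached

tpl = synth.EapTemplateParams()
null = stats.NullTable(alpha=0.05, replicates=20_000, seed=SEED)
rows = []
for c in range(N_CELLS):
    rng = synth.spawn_rng(SEED, 40, c)
    times = synth.generate_spike_train(RATE, DURATION, rng)
    scales = synth.draw_secondary_scales(times.size, rng)
    trace = synth.render_eap_train(times, tpl, scales, rng, duration=DURATION)
    bp = preprocess.bandpass(trace)
    det = eap.detect_eaps(bp)
    events = eap.measure_eap_events(bp, det)
    t_rel, mean_wf, _ = eap.mean_waveform(bp, det)
    sec_amp, sec_rel, flagged = eap.secondary_peak(t_rel, mean_wf, bp.sample_rate)
    ipeaks = np.array([e.integral_peak for e in events])
    jb = stats.jarque_bera(ipeaks)
    crit = null.critical(ipeaks.size)
    cv = float(np.std(ipeaks, ddof=1) / np.mean(ipeaks))
    rows.append({
        "cell_id": f"cell{c:04d}", "n_events": det.size,
        "secondary_amp_pa": sec_amp, "secondary_rel": sec_rel,
        "no_secondary": flagged, "integral_cv": cv,
        "jb_stat": jb, "jb_crit": crit, "multimodal": bool(jb > crit),
    })

table = pd.DataFrame(rows)
table.to_csv(OUT / "cells.csv", index=False, float_format="%.9g")
q = np.percentile(table["secondary_rel"], [25, 50, 75])
print(f"{N_CELLS} cells, {int(table['n_events'].sum())} EAPs")
print(f"secondary peak: median {100*q[1]:.0f}% of primary "
      f"(quartiles {100*q[0]:.0f}-{100*q[2]:.0f}%)")
print(f"integral-amplitude CV: median {table['integral_cv'].median():.2f}")
print(f"∫EAP multimodal in {int(table['multimodal'].sum())} of {N_CELLS} cells")
print(f"table -> {OUT/'cells.csv'}")
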