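#!/usr/bin/env python
"""Channel pharmacology: TTx (null), Cd2+ (HVA block), ML218 (T-type block).

Each condition is a cohort of continuous recordings whose second half has the
drug transform applied to the generating process; detection runs with one
per-cell threshold set on the control epoch.  Expectations from the channel
model: Na+-channel block changes nothing (spikes are Ca2+-based); Cd2+
removes the large-amplitude mode and shifts the EAP secondary peak; ML218
collapses spontaneous firing.
"""

from pathlib import Path

from gradespike import pipeline

OUT = Path(__file__).resolve().parents[1] / "results" / "pharmacology"

runs = (("TTx", 37), ("Cd", 65), ("ML218", 27))
for cond, n_cells in runs:
    cfg = pipeline.RunConfig(scenario="pharmacology", condition=cond,
                             n_cells=n_cells, duration=480.0, seed=5,
                             out_dir=str(OUT))
    rep = pipeline.run_pharmacology(cfg)["report"]
    rt = rep["rate_test"]
    line = (f"{cond:6s} n={n_cells}: rate {rt['pre_summary']} -> {rt['post_summary']} Hz, "
            f"signed-rank p={rt['p_value']:.2g}")
    if rep["amplitude_ks"] is not None:
        line += f"; normalized-amplitude KS p={rep['amplitude_ks']['p_value']:.2g}"
    if "secondary_shift_pa" in rep:
        sh = rep["secondary_shift_pa"]
        line += f"; secondary-peak shift {sh['mean_pa']:.1f} +/- {sh['sd_pa']:.1f} pA"
    if cond == "ML218":
        line += f"; rate reduction {100*rep['mean_rate_reduction']:.0f}%"
    print(line)
print(f"reports -> {OUT}")
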