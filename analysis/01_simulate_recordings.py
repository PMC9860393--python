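#!/usr/bin/env python
"""Write a small synthetic dataset (traces + sidecars + ground truth).

Produces a spontaneous-imaging cohort and a paired imaging/EAP cohort under
results/data/ in the pipeline's on-disk format, so every later analysis can
also be rerun from files rather than in memory.
"""

from pathlib import Path

from gradespike import pipeline

OUT = Path(__file__).resolve().parents[1] / "results" / "data"

spont = pipeline.RunConfig(scenario="spontaneous", n_cells=4, duration=120.0, seed=1)
pipeline.simulate_to_dir(spont, OUT / "spontaneous")
print(f"spontaneous: {spont.n_cells} cells x {spont.duration:.0f} s at "
      f"{spont.kernel.frame_rate:.0f} Hz -> {OUT/'spontaneous'}")
print("paired recordings carry a >=10 kHz current channel (tens of MB as "
      "delimited text), so later analyses regenerate them in memory from the "
      "same seeds instead of reading them from disk; see 04_paired_coupling.py")
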