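"""Score the filter, wrapper and combined stages on planted ground truth.

Generates independent synthetic datasets (60 samples, 50 molecules, 10
relevant) and reports how precisely each selection stage recovers the
planted molecules.  Selection precision = fraction of selected molecules
that are truly relevant; selection recall = fraction of relevant
molecules recovered.  The filter is liberal (high recall, moderate
precision); the wrapper is conservative (high precision, lower recall);
their combination improves on both.  A small number of datasets keeps
this demo quick — the full benchmark uses 100.
"""

from panelex import run_benchmark

print("stage            precision  recall   (15 datasets)")
for stage, label in [("filter", "filter only"), ("wrapper", "wrapper only"),
                     ("combined", "filter + wrapper")]:
    res = run_benchmark(15, stage, seed=1)
    print(f"{label:17s} {res.mean_precision:8.2f} {res.mean_recall:7.2f}")
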