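#!/usr/bin/env python
"""Bias-correct every ensemble member's hindcast and projection with each
of the five quantile-mapping methods (season-stratified fits), writing
corrected_{method}_{model}_{hist,proj}.csv under results/data/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from study_config import study_config

from heatqm import pipeline, qmap

if __name__ == "__main__":
    cfg = study_config()
    for method in qmap.METHODS:
        rec = pipeline.stage_biascorrect(cfg, method)
        print(f"{method}: corrected {len(rec['outputs'])} series")
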