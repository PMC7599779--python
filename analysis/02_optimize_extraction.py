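#!/usr/bin/env python
"""Maximize the reduced yield surface: seeded GA vs the analytic optimum.

Runs the real-coded genetic algorithm over the coded cube, cross-checks it
against the closed-form stationary point, decodes the optimum to natural
units and rounds it to practical equipment settings.  The optimization
report lands in results/.
"""

import logging
from pathlib import Path

from uadese.pipeline import PipelineConfig, run_pipeline

OUT = Path(__file__).resolve().parent.parent / "results"

result = run_pipeline(
    PipelineConfig(alpha=0.05, seed=42, out_dir=OUT, verbosity=logging.WARNING)
)
print(result.summary)
print(f"reports written to {OUT}: model.json, anova.json, optimization.json, summary.txt")
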