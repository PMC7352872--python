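"""Run the complete analysis end to end and write a report bundle.

Equivalent to `thermopain run --outdir runs/demo --seed 1` on the shell.
"""

import json
from pathlib import Path

from thermopain import PipelineConfig, run_pipeline

config = PipelineConfig(outdir=Path("runs/demo"), seed=1)
result = run_pipeline(config)

print(json.dumps(result["summary"], indent=2, default=str))

# The bundle under runs/demo contains every intermediate: phenotype CSV and
# VCF of the simulated cohort, U-matrix grid, cluster labels, rule list,
# filter reports, importances, the final variant set and a summary JSON.
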