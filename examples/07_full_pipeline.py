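"""Run the whole pipeline end to end and print the stage summaries.

Writes every intermediate table plus report.json under ./scratch/example_run;
a rerun with the same seed is bit-identical.
"""

import json

from reciprome.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(outdir="scratch/example_run", seed=7))
print(json.dumps(report.stages, indent=2, default=str))
print("\ntables written to scratch/example_run/")
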