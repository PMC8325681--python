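"""The whole inference chain in one call.

Runs synteny -> duplicate classification -> Ks peaks -> rate correction ->
clock dating -> tree topologies -> karyotype accounting on a simulated
WGD history and prints the one-page report.  The same entry point accepts
real gene positions, pair lists and Newick trees via PipelineConfig paths.
"""

from paleowgd import PipelineConfig, run_all
from paleowgd.pipeline import format_report

config = PipelineConfig(seed=1, output_dir="scratch/example_run")
report = run_all(config)
print(format_report(report))
print("full JSON report written to scratch/example_run/report.json")
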