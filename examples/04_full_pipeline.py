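"""Run the whole analysis pipeline on files, at the published group sizes.

Writes synthetic exposure tables for six analysis groups (sized 18, 38,
109, 68, 246 and 314 instruments, with true effects at the published
pooled odds ratios) plus one shared outcome table, runs selection ->
harmonization -> IVW -> sensitivity -> BFDR, and prints the main report.
"""

import tempfile
from pathlib import Path

import pandas as pd

from tsmr import (
    AnalysisConfig,
    ExposureSpec,
    paper_scale_scenario,
    run_pipeline,
    simulate_two_sample,
    write_instrument_table,
    write_outcome_table,
)

workdir = Path(tempfile.mkdtemp(prefix="tsmr_example_"))
specs, outcome = [], {}
for scn in paper_scale_scenario():
    table, out = simulate_two_sample(scn)
    path = workdir / (scn.cancer_type.replace(" ", "_") + ".tsv")
    write_instrument_table(table, path)
    outcome.update(out)
    specs.append(ExposureSpec(str(path), scn.cancer_type, scn.smoking_related))
write_outcome_table(outcome, workdir / "outcome.tsv")

config = AnalysisConfig(
    exposures=specs,
    outcome_path=str(workdir / "outcome.tsv"),
    output_dir=str(workdir / "reports"),
    p_threshold=1.0,          # presets model already-established instruments
    groupings=("per-cancer",),  # the composite presets ARE the pooled groups
)
result = run_pipeline(config)

print(pd.read_csv(workdir / "reports" / "results.tsv", sep="\t").to_string(index=False))
print()
print(pd.read_csv(workdir / "reports" / "sensitivity.tsv", sep="\t").to_string(index=False))
print(f"\nfull reports (selection, leave-one-out, funnel, log) in {workdir}/reports")

# Each odds ratio should land near its generating value (0.91, 0.98,
# 0.94, 0.95, 0.98, 0.98): larger groups give tighter CIs; Egger
# intercepts should hover near 0 since no pleiotropy was simulated.
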