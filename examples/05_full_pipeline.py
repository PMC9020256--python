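"""Run the whole pipeline with one call and inspect the report.

simulate -> map -> call -> genotype-design -> segregation-test, with every
stage's outputs persisted under the output directory (FASTA, FASTQ, SAM,
JSON reports, a checksum manifest). Identical config + seed reproduces a
byte-identical report.json.
"""

import json
from pathlib import Path

from tlamap.pipeline import PipelineConfig, run_pipeline

outdir = Path("scratch/example_pipeline")
config = PipelineConfig(seed=1)
report = run_pipeline(config, outdir)

call = report["call"]
print(f"integration: {call['chromosome']}:{call['left_breakpoint']:,}-"
      f"{call['right_breakpoint']:,} ({call['deletion_kb']}), "
      f"copies {call['copies_estimate']}")
print(f"simulated truth: {call['truth']}")
print("gene impacts:")
for g in call["gene_impacts"]:
    detail = f" ({g['detail']})" if g["detail"] else ""
    print(f"  {g['gene_name']}: {g['impact']}{detail}")
print(f"assay bands: WT {report['genotype_design']['predicted_wt_amplicon_bp']} bp / "
      f"TG {report['genotype_design']['predicted_tg_amplicon_bp']} bp, "
      f"in-silico calls {report['genotype_design']['in_silico_calls']}")
print(f"segregation verdict: {report['segregation']['verdict']}")
print(f"outputs under {outdir}/:")
for p in sorted(outdir.iterdir()):
    print(f"  {p.name}")
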