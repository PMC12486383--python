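"""Run the whole analysis end to end and print the report.

Equivalent to `synopsin run --outdir example_run --seed 1` on the
command line.  Stages: simulate -> classify -> scan -> families ->
paralogon -> scenarios; all stage outputs are plain TSV/FASTA/Newick
files in the run directory, plus a manifest with checksums.
"""

from synopsin.pipeline import RunConfig, make_report, run_pipeline

cfg = RunConfig(outdir="example_run", seed=1)
rundir = run_pipeline(cfg)
print(f"run complete: {rundir}\n")
print(make_report(rundir))
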