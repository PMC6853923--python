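"""Run the whole analysis as one reproducible pipeline and print its summary.

Equivalent to `repclone run` on the command line: synthetic cohort ->
productive filter -> clonotype collapse -> donor inclusion -> diversity,
overlap, clustering, MDS and V-J analyses -> report bundle with checksums.
"""

from repclone.pipeline import RunConfig, run_pipeline, summarize

config = RunConfig(
    outdir="scratch/example_run",
    seed=7,
    synthetic=dict(
        n_donors=3,
        sample_depth=2000,
        pool_size_per_tissue=1000,
        subsets=[["CD4", s] for s in ("naive", "CM", "EM", "TRM")],
    ),
)
bundle = run_pipeline(config)
print(f"{len(bundle.manifest)} artifacts written to {bundle.outdir}\n")
print(summarize(bundle.outdir))
# Rerunning with the same config reproduces every artifact byte for byte;
# manifest.json records a sha256 per output.
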