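"""One-call end-to-end run: synthetic inputs through the survival report.

Equivalent to `pcnsl run-all --seed 1 --out pcnsl_demo`; stage outputs are
cached under the output directory and the final report.json aggregates
them without recomputation.
"""

import json

from pcnslkit.pipeline import RunConfig, run_pipeline

config = RunConfig(seed=1, outdir="pcnsl_demo")
report = run_pipeline(config)

for stage, entry in report["stages"].items():
    print(f"{stage:>8s}: {entry['status']}")

ihc_out = report["stages"]["ihc"]["output"]
print(f"\nIHC recovery error: {ihc_out['mean_abs_error_pct_points']:.2f} points")
print("cluster summary  :", json.dumps(report["stages"]["cluster"]["output"], indent=2))
print("survival summary :", json.dumps(report["stages"]["survive"]["output"], indent=2))
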