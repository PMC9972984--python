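"""One-call end-to-end run: simulate -> prioritize -> landscape -> signatures
-> drivers -> druggability, writing the eight-artifact bundle.

Rerunning with the same config and seed reproduces every file byte for byte.
"""

import json

from somascape import CohortConfig, RunConfig, run_all

summary = run_all(
    RunConfig(
        out_dir="scratch/example_run",
        mode="simulate",
        seed=7,
        cohort=CohortConfig(n_samples=20),
    )
)
print(json.dumps(summary["prioritization"], indent=2))
print(json.dumps(summary["burden"], indent=2))
print(json.dumps(summary["actionability"], indent=2))
# full artifact bundle (survivors, trace, burden, recurrent, signature fit,
# driver tests, actionability, summary.json) is in scratch/example_run/
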