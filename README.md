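# somascape

Somatic-mutation landscape analysis for paired tumour/normal cancer cohorts.

`somascape` is a Python library (plus a thin `somascape` CLI) for the
downstream half of a tumour/normal small-variant study: it takes annotated
variant calls and per-patient metadata and produces the standard
cohort-level readouts — prioritized somatic variants with per-stage filter
accounting, tumour mutational burden and hypermutation status, mutation-rate
statistics stratified by microsatellite instability (MSI), 96-channel
mutational-signature attribution, simplified driver-gene tests, and
rule-based matching of alterations to drug response/resistance predictions.
It is aimed at method developers and analysts who need a transparent,
testable, fully offline implementation of this pipeline; a seeded synthetic
cohort generator reproduces the statistical structure of a real colorectal
cohort so every stage can be validated against known ground truth.

## The model in brief

* **Prioritization.** A call survives iff quality > Q30, its maximum
  population allele frequency over the configured databases (1000 Genomes /
  ExAC / ESP6500-style) is ≤ 5% (absent frequencies pass), it is an
  amino-acid-changing call in an annotated gene within exonic/splicing
  regions, and its genomic change `(chrom, pos, ref, alt)` is absent from
  the matched normal. Survivors are flagged *novel* when absent from both
  dbSNP- and COSMIC-style catalogs with a normal sample of depth ≥ 10 and 0
  variant reads. All four removal stages are per-call predicates, so the
  survivor set is provably order-independent.
* **Burden.** Rate = somatic count / callable megabases; hypermutated ⇔
  rate > 12/Mb (strict). MSI-H vs MSI-L rates are compared with an exact
  two-sided Mann–Whitney test (enumeration for ≤ 8 per side), MSI-H ×
  hypermutation with Fisher's exact test.
* **Signatures.** SNVs map to the 96 pyrimidine-centred trinucleotide
  channels; exposures solve min‖We − c‖₂, e ≥ 0 (NNLS) against a reference
  matrix, or are extracted de novo by seeded multi-restart NMF and matched
  to references by cosine similarity.
* **Drivers.** A uniform-background binomial test per gene
  (p = P[X ≥ k], X ~ Bin(n·L, r)) and a positional-clustering test against
  a uniform-scatter permutation null, both BH-adjusted. These are
  deliberate, documented simplifications of covariate-based SMG tools.
* **Druggability.** A transparent TSV of rules (gene + alteration pattern →
  drug, effect, evidence level) replaces web-service annotation; the bundled
  rules are an illustrative fixture, not clinical guidance.

## Worked example

```python
from somascape import (CohortConfig, FilterConfig, compute_burdens,
                       msi_group_stats, reference_signatures,
                       run_prioritization, simulate_cohort)

sim = simulate_cohort(CohortConfig(n_samples=50, seed=7), reference_signatures())
flagged, trace = run_prioritization(sim.tumour_calls, sim.normal_calls, FilterConfig())
burdens = compute_burdens([c for c, _ in flagged], sim.samples)
stats = msi_group_stats(burdens)
for group, median in stats.medians.items():
    print(f"median rate {group.value}: {median:.2f}/Mb")
print(f"rank-test p: {stats.mannwhitney_p_msih_vs_msil:.4g}")
print(f"Fisher p:    {stats.fisher_p_msih_hypermutation:.4g}")
```

prints

```
median rate MSI-H: 44.30/Mb
median rate MSI-L: 4.17/Mb
median rate MSS: 4.17/Mb
rank-test p: 0.007937
Fisher p:    2.832e-06
```

i.e. in this seeded 50-patient cohort the five MSI-H tumours mutate an
order of magnitude faster than the MSI-L/MSS groups (whose medians sit near
their configured 4.1 and 3.8/Mb), the rank test already attains its exact
5-vs-5 floor of 2/252, and MSI-H status is strongly associated with
hypermutation. The `examples/` directory has one short narrative script per
capability (simulation, prioritization, burden/MSI, signatures, drivers,
druggability, full pipeline); each prints the numbers it computes and says
what they mean.

The `somascape` CLI mirrors the library (`somascape run --config run.yaml`,
plus per-stage subcommands); `somascape run` writes an eight-artifact bundle
(survivors, trace, burden, recurrent variants, signature fit, driver tests,
actionability, JSON summary) that is byte-identical across reruns with the
same config and seed.

## Layout

```
src/somascape/   library (formats, synthetic cohorts, prioritization,
                 landscape, signatures, drivers, druggability, pipeline, CLI)
examples/        one narrative script per capability
tests/           pytest suite incl. enumeration oracles and property tests
docs/methods.md  model assumptions, parameter choices, limitations
```
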