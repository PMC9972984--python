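# Methods

This note documents the models, parameter choices and limitations behind
`somascape`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, and what
passing tests do and do not demonstrate.

## Data model and conventions

Every stage exchanges `VariantCall` records: one annotated tumour/normal
observation with 1-based, fully closed VCF coordinates (there is no 0-based
surface anywhere). Population allele frequencies are a map from database
name to frequency; a variant *absent* from a database stays absent — it is
never coerced to 0, and absence never trips a frequency threshold. The
rationale is that the common-variant filter exists to remove *known-common*
germline polymorphisms; lack of evidence is not evidence of commonness.
Annotation vocabulary (regions exonic/splicing/intronic/UTR/…, effects
missense/nonsense/frameshift/…) follows ANNOVAR-style conventions, and the
default VCF dialect maps the corresponding INFO keys
(`Gene.refGene`, `Func.refGene`, `ExonicFunc.refGene`, AF and catalog-id
keys). Unknown INFO keys are ignored.

Raw records keep whatever strand the caller reported; substitutions are
normalized to the pyrimidine-centred strand only at catalog time. This
keeps file round-trips faithful while making every catalog comparable.

## Prioritization chain

Stages, in canonical order: quality, population AF, functional, germline
subtraction, novelty flag. All numeric thresholds are **strict** (quality
must exceed Q30; an AF must exceed 5% to remove), so boundary values
survive — this follows the usual phrasing of such filters ("above Q30",
"more than 5%"). The AF criterion uses the maximum over the configured
databases; applying "any single database exceeds" is equivalent for a
shared threshold, but the maximum is what the code computes and the
database list is configurable. Indels pass through the same chain as SNVs.
Novelty requires absence from *both* catalog databases (dbSNP- and
COSMIC-style) **and** a normal sample with ≥ 10 reads and ≤ 0 variant
reads; it is a flag, never a removal. Manual alignment review has no
computational counterpart; the normal-coverage criterion is the encoded
replacement.

Because each removal stage is a pure per-call predicate (germline
subtraction is a predicate given the fixed normal set), the survivor *set*
is invariant under stage permutation; the trace records the canonical order
and each removed call's first failing stage, and removals sum exactly to
input minus survivors.

## Synthetic cohorts

The generator emulates a 50-patient colorectal cohort at desk scale:

* **Group structure.** MSI proportions 0.1/0.1/0.8 are apportioned by
  largest remainder, so 50 patients always split 5/5/40.
* **Mutation rates.** Per-sample rates are log-normal around the group
  medians 57.7 / 4.1 / 3.8 mutations/Mb with log-sd `rate_dispersion`
  (default 0.6). Published cohorts report only medians and a wide range;
  the log-normal with σ = 0.6 is a stand-in chosen to reproduce that
  qualitative spread (an order-of-magnitude range within MSS) and is
  labelled as such — no distributional claim is made. One MSS sample is
  planted at exactly 244/Mb by default, mirroring the single hypermutated
  microsatellite-stable tumour such cohorts contain; `mss_outlier_rate=None`
  disables it.
* **Callable genome.** `callable_mb` defaults to 30 Mb. This is a
  deliberate scale-down: it keeps a 50-patient cohort around 2×10⁴ variants
  so every test and the acceptance script run in seconds, while preserving
  all per-Mb rates (57.7/Mb × 30 Mb ≈ 1730 calls per MSI-H sample; the
  244/Mb outlier carries 7320). The denominator is always explicit in
  `SampleMeta.callable_mb`; there is no hidden constant.
* **Trinucleotide structure.** Each somatic SNV's channel is drawn from the
  sample group's mixture of the reference signatures (defaults: MSI-H
  0.70 Sig6 / 0.20 Sig1 / 0.10 Sig10; MSI-L 0.50/0.30/0.20 of
  Sig1/Sig6/Sig10; MSS 0.60/0.15/0.25). Half the calls are emitted on the
  purine strand so catalog building must exercise strand normalization.
* **Planted structure.** Hotspots (defaults: KRAS G12D ×6, ACVR2A K435fs
  ×4, TP53 R175H ×4) are placed in exactly their target carrier counts.
  Germline-common variants (Poisson, mean 20/sample, from a shared 40-site
  pool with AF 0.06–0.5) appear with *identical* evidence in tumour and
  normal calls, so the AF filter and the tumour∩normal subtraction are each
  sufficient to remove them and can be tested independently. 8% of somatic
  variants are novel (no catalog ids, clean covered normal).
* **Threshold clearance.** Somatic variants are generated strictly clear of
  every filter boundary (quality U(35,60), exonic/splicing,
  amino-acid-changing, no population AF), which is what makes exact
  precision = recall = 1 recovery a meaningful end-to-end check of the
  chain rather than a statement about borderline calls.

What the generator does **not** emulate: linkage, copy number, subclonality
and allele-fraction structure, indel length spectra, sequencing artifacts,
mapping ambiguity. Passing recovery tests therefore validates the filter
logic and accounting, not robustness to real-data noise sources.

Identical config + seed gives bit-identical output; a single
`numpy.random.default_rng(seed)` drives every draw in a fixed order.

## Burden and MSI statistics

Rate = somatic count / callable Mb; hypermutation is strictly > 12/Mb
(exactly 12 is not hypermutated), with the threshold exposed. For the
MSI-H vs MSI-L rate comparison no specific published test is assumed; a
two-sided Mann–Whitney is the minimal nonparametric choice. With ≤ 8
observations per side the null is evaluated by exhaustive enumeration of
label assignments, counting assignments whose U statistic deviates from its
null mean at least as much as observed (ties contribute ½ to U and are
thereby handled exactly; for symmetric nulls this equals the classical
two-sided exact p). Larger groups use the normal approximation with tie and
continuity corrections via SciPy. The MSI-H × hypermutation association
uses Fisher's exact test (two-sided, point-probability method). Degenerate
inputs (an empty group) yield an absent p-value with a logged reason, not
an error.

## Signatures

Channel order is fixed once, lexicographic in (substitution class, 5' base,
3' base), stored with the bundled reference so matrices can never silently
misalign; readers canonicalize any row order and renormalize columns within
1e-3 of unit sum (anything further off is rejected as data error).

Refitting (NNLS via `scipy.optimize.nnls`) is the default attribution
pathway; de novo extraction (NMF, multiplicative updates on Frobenius loss,
10 restarts of 2000 iterations at tolerance 1e-6, one seeded stream per
restart, best objective kept) is provided as the alternative, since either
can stand behind a published signature figure. Extracted signatures are
matched one-to-one to reference columns by maximum-cosine assignment.
A caveat the examples demonstrate: NMF identifies sharply only processes
that dominate some samples; with few distinct exposure profiles a weakly
represented signature matches its reference with visibly lower cosine.

The bundled reference is **synthetic**: three peaked distributions labelled
Sig1/Sig6/Sig10 with the qualitative features of their COSMIC namesakes
(deamination-like C>T at NpCpG; MMR-like C>T with 5'-G preference;
POLE-like C>A at TpCpT), pairwise cosines ≈ 0.06–0.31. Real cohort cosines
to true COSMIC signatures are not reproducible without real catalogs; the
recovery tests are property-based stand-ins (parameter recovery from known
generators), not reproductions of published similarity values. A real
COSMIC matrix can be supplied by path wherever a `SignatureMatrix` is
accepted.

## Driver tests

The SMG test is intentionally simple: per gene, p = P(X ≥ k) for
X ~ Binomial(n_samples × gene_length, background_rate), BH-adjusted across
genes. No covariate background (replication timing, expression, chromatin)
is modelled, and the output header says so; published covariate-adjusted
SMG lists are not reproducible from a uniform background, so the package's
contract is the statistical correctness of its own test (exact tail sums,
monotonicity, FDR control under the uniform null) rather than agreement
with any published gene ranking. The hotspot test scores the fraction of a
gene's variants at its modal genomic position and compares the observed
maximum multiplicity to a uniform-scatter null — exhaustively enumerated
when the state space is ≤ 10⁵ placements, else ≥ 2000 seeded Monte Carlo
permutations with add-one smoothing (a Monte Carlo p is never exactly 0).
Genes with fewer than two variants carry no clustering signal and are
excluded. Gene lengths come from the bundled panel (hg19-style genomic
spans); the panel is a fixture, not an annotation source.

## Druggability

Matching is deterministic pattern application: a call matches a rule iff
the gene matches and the pattern holds (`exact_aa` compares normalized
amino-acid labels, accepting multi-transcript comma lists; `truncating` =
nonsense/frameshift; `frameshift`; `any_nonsynonymous` = anything but
synonymous; `position_class` = a genomic position range). Disease matching
is exact-string (default COREAD), not an ontology. Evidence levels are
totally ordered (FDA > NCCN > late trials > early trials > case report >
pre-clinical) and reports sort matches accordingly. The bundled rules
transcribe published colorectal biomarker statements (KRAS → anti-EGFR
resistance, APC-truncating → tankyrase-inhibitor response at pre-clinical
level, RNF43-frameshift → porcupine-inhibitor response, PIK3CA, BRAF
V600E, POLE) and are labelled in the report header as an illustrative
fixture, not clinical guidance. No oncogenicity pre-filter is applied: a
rule engine this transparent matches patterns, nothing more.

## Pipeline and determinism

`run_all` executes the stages in a fixed single-process order and writes
eight artifacts; every numeric in `summary.json` is re-derivable from the
stage tables in the same bundle. Floats are serialized with fixed rounding
(`repr` after rounding to 10 decimals) so identical config + seed yields
byte-identical bundles — verified by checksum in the test suite.

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script each
complete in minutes on a single CPU: 50-patient cohorts over a 30 Mb
callable genome (~2×10⁴ variants), 500-per-group cohorts at 5 Mb for
marginal-recovery checks, 30-catalog × 2000-draw cohorts for NMF recovery,
200-gene null simulations over 20 seeds for FDR control. These sizes are
the package's own study conditions; all of them scale up by config.

## Known limitations

* The synthetic generator's dispersion, depth and allele-fraction models
  are stand-ins; only medians, group structure and planted features are
  calibrated quantities.
* The SMG background is uniform; its gene ranking on real data would be
  confounded by covariates that real SMG tools model.
* The exact Mann–Whitney enumeration is O(C(n₁+n₂, n₁)) and is capped at
  8 per side; beyond that the asymptotic approximation applies.
* VCF float INFO fields round-trip through 32-bit floats (htslib), so AF
  values read from VCF can differ from their decimal representation by
  ~1e-8; the TSV path is exact.
* `expand_carriers` duplicates a record per carrier with identical depths;
  carrier-specific evidence is not modelled for printed-table fixtures.
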