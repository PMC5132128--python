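# Methods

## Coordinate model

All internal intervals are 0-based half-open. BED and bedGraph inputs are
consumed as written (they are already 0-based half-open); catalogue and VCF
positions are 1-based and converted on load. Chromosome names are compared
by exact string equality. No `chr`-prefix aliasing is ever applied: a
mismatch between panel and catalogue naming is surfaced by
`validate_chromosomes` rather than silently reconciled, because silent
aliasing in a clinical assay can mis-map every variant on a chromosome.

The panel footprint is the exact interval union of the amplicons, built by
a sorted merge; each base counts once regardless of amplicon overlap.

## Depth engine

Depth at a base is the number of counted reads whose aligned
reference-consuming segments include it. CIGAR semantics follow SAM:
ALN (M/=/X) counts, INS and CLIP consume no reference, SKIP consumes
reference without counting, and DEL consumes reference and counts only when
`count_deletion_spanned_bases` is enabled (off by default: a deleted base
carries no base-level evidence in that read). Reads failing the QC flag or
below `min_mapq` are excluded; reads on chromosomes absent from the panel
are tallied, not fatal. Duplicates are **counted** by default because in
amplicon libraries PCR duplicates are indistinguishable from independent
coverage; the flag exists for capture panels. Both mates of an overlapping
pair count, matching a naive pileup of the upstream aligner's output —
relevant when cross-checking against depth tools that collapse overlaps.
The result is defined to be independent of read order, which makes the
contract property-testable on shuffled inputs.

## Discoverability

A variant's footprint is `[pos-1, pos-1+len(ref))` for substitutions,
deletions and complex indels. A pure insertion (`len(ref) == 1`, alt
extending ref) alters no reference base; its junction is only observable by
reads spanning both sides, so its footprint is the two flanking bases.
Discoverable ⇔ footprint fully inside the panel footprint and minimum depth
≥ threshold. The threshold is **inclusive** (depth exactly 30 passes) and
configurable; 30x is the default clinical minimum.

Per-gene denominators cover the *assayable* catalogue variants: a variant
whose footprint falls outside every amplicon can never be discovered by the
assay, so by default it is excluded from the gene's denominator and listed
separately as not-assayable (otherwise 100% would be unattainable by
design). The alternative accounting — counting such variants as permanently
non-discoverable — is available via `include_outside_panel=True`. Gene
attribution comes solely from the catalogue's gene column, never positional
overlap, avoiding ambiguity at overlapping loci. Genes without catalogued
variants are omitted from reports rather than rendered as 0/0.

The per-gene flag threshold is 0.90, strict less-than, configurable. The
sample-level fraction is the ratio of totals (Σ discoverable / Σ known),
not the mean of gene fractions. Percentages are rendered to one decimal,
rounded half away from zero, matching clinical reporting convention.

## Filter cascade and tiers

The cascade's thresholds and inequality directions are fixed by the
validated assay configuration: QUAL strictly > 100, caller PASS required,
total depth strictly > 30, VAF ≥ 20% (inclusive — germline heterozygotes
expect ~50%, and 20% is the tail allowing for capture bias), population
frequency strictly < 5%, and a whitelist of protein/splice-altering
consequences. An *unknown* population frequency passes the frequency rule:
novel variants have no population record and must survive. The rules are
conjunctive, so the kept set is order-independent; the rejection ledger
(an artifact addition — first failing rule per call, in the order qual,
pass, depth, vaf, pop_freq, consequence) depends on the order.

Tier 1 requires an exact catalogue match flagged pathogenic *and* a gene
matching the case's working diagnosis; Tier 2 is mechanism-based
(frameshift, stop gained/lost, initiator codon, canonical splice — a splice
consequence with intronic offset ±1/±2 when the offset is annotated,
consequence alone otherwise, since transcript geometry is never recomputed
here); Tier 3 covers known-pathogenic hits in wrong-phenotype genes,
annotated cryptic-splice/regulatory predictions, and missense calls whose
externally supplied deleteriousness score reaches the configurable cut-off
(default 0.9 on a 0–1 damaging scale). Deleteriousness scores are consumed
as input annotations, never computed.

The compound-recessive caveat: a case whose only Tier-1/2 findings are
single heterozygous hits in each of two *different* autosomal-recessive
genes stays unsolved — co-inherited carrier states for two unrelated
recessive anaemias are not evidence of pathogenicity without functional
work. Homozygous or compound-heterozygous hits within one AR gene, or any
Tier-1/2 hit in an AD/XL gene, are diagnosis-eligible.

## Validation statistics

Concordance is set algebra over `(chrom, pos, ref, alt)` keys (truth
negatives are `(chrom, pos)` positions). Sensitivity and specificity carry
binomial confidence intervals by the Wilson score method or the exact
Clopper–Pearson method, both delegated to statsmodels and clipped to
[0, 1], with the boundary identities (x=0 ⇒ lower 0, x=n ⇒ upper 1) pinned
exactly. Tests verify the Wilson endpoints against a root-finding oracle on
the score equation and the exact endpoints against the defining binomial
tail equalities (residuals < 1e-9), plus a seeded simulated-coverage check.
The CI *method* behind historically reported intervals for assays of this
kind is typically unstated, so interval values are never used as exact
expectations — only point estimates are.

Reproducibility across replicate libraries is the pooled fraction of
variant keys present in all replicates of their sample among keys present
in any.

## Synthetic data generator

The generator emulates the study conditions of a clinical amplicon panel:

| parameter | default | rationale |
|---|---|---|
| genes | 33 | the red-cell panel scale; symbols are the causative genes of CDA, DBA, SDS, DKC, sideroblastic anaemia and RBC enzyme deficiencies |
| exons per gene | 6 | typical compact gene (e.g. *GATA1*) |
| amplicon length | 425 bp | the panel's design length |
| amplicon overlap | 50 bp | tiling with boundary coverage |
| read length | 301 bp | 2x301 paired-end chemistry |
| mean amplicon depth | 100 | routine MiSeq multiplexing scale |
| catalogue size | 1207 | the panel's known-mutation count |
| class mix | 87/4/8/1% missense/simple-insertion/deletion/complex-indel | the catalogued class composition |
| dropout probability | 0 (tests plant dropouts explicitly) | keeps defect recovery oracle-exact |
| strand imbalance | 0.5 | symmetric forward/reverse anchoring |

Reads are anchored at amplicon ends: forward reads start at the 5' end,
reverse reads end at the 3' end, so a 425 bp amplicon with 301 bp reads has
a 177 bp centre covered by both strands and 124 bp flanks at single-strand
depth — the masking geometry that defeats whole-amplicon mean coverage.
Per-strand read counts are Poisson by default; `exact_depth=True` fixes
them at the rounded expectation for oracle-exact tests. Catalogue class
allocation is deterministic largest-remainder rounding by default
(`exact_mix`), with multinomial sampling available. Every generator is a
pure function of (config, seed) with one independent RNG stream per
operation, so regenerating one artifact never perturbs another.

What the generator does **not** emulate: sequencing error and base
qualities, GC- or primer-driven efficiency variation (dropout is all-or-
nothing), alignment artefacts, overlapping genes, real population allele
frequencies. Passing tests therefore demonstrate the correctness of the
accounting — pileup arithmetic, footprint logic, filter boundaries,
concordance algebra — on data with known ground truth, not the field
performance of any wet-lab assay.

## Numerical and scale choices

Percent rendering uses explicit half-away-from-zero rounding at one
decimal. Depth arrays are int64 per merged footprint interval. Quantiles in
run summaries use linear interpolation (numpy default), cross-checked
against a sort-based oracle. The acceptance script's simulated run uses 8
samples of the full 33-gene panel (~23k reads each), a size chosen to keep
the whole script in seconds while still exercising the multi-sample
distribution machinery; the deterministic headline quantities are invariant
to this choice.

## Known limitations

No liftover, no HGVS/transcript-aware parsing, no annotation engine, no
variant calling, no realignment/BAQ, no deduplication beyond the FLAG bit,
and no full ACMG-2015 criteria engine — the tier shorthand predates it.
The CLI's `--track-gene` output is pure data; plotting is left to the
caller.
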