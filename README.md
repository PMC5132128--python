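# panelcover

Per-base coverage QC, known-mutation "discoverability" reporting and
clinical variant triage for amplicon-based targeted sequencing panels.

## The problem

A targeted NGS panel used for clinical diagnosis must do more than find
mutations: a *negative* result is only reportable if the assay can show it
had adequate sequencing reads at every position where a causative mutation
has previously been described. Amplicon panels fail silently — a single
dropped PCR product blinds the assay to every known mutation inside it — and
the whole-amplicon *mean* coverage that summary tools report can mask
under-covered bases: with paired reads shorter than the amplicon, forward
and reverse reads pile up in the centre, so a mean of 35x may hide flanks at
25x.

`panelcover` answers the per-sample question directly. A catalogued mutation
is **discoverable** when every base of its reference footprint lies inside
the panel footprint and has depth ≥ *t* (default *t* = 30, inclusive). For a
sample *s* and gene *g* with assayable catalogue variants V(g):

    D_g(s) = |{v ∈ V(g) : min_{b ∈ footprint(v)} depth_s(b) ≥ t}| / |V(g)|

Genes with D_g < 0.90 (strict) are flagged `LOW`, guiding the decision to
repeat sequencing or fall back to Sanger. Variant footprints are the
affected reference bases (`[pos-1, pos-1+len(ref))` for substitutions and
deletions); a pure insertion needs both junction-flanking bases covered.

Around the metric the package provides:

* a depth engine with SAM CIGAR/MAPQ/FLAG semantics and bedGraph I/O,
  strand-resolved, order-independent;
* the clinical filter cascade (QUAL > 100, PASS, depth > 30, VAF ≥ 20%,
  population frequency < 5% with unknown passing, consequence whitelist)
  with a per-rule rejection ledger;
* reporting tiers (1: catalogued pathogenic in a phenotype gene;
  2: frameshift/stop/initiator/canonical GT-AG splice; 3: possibly
  causative) and the co-inherited-recessive "unsolved" caveat;
* validation arithmetic: concordance tables against orthogonal truth sets,
  sensitivity/specificity with Wilson or exact Clopper–Pearson intervals,
  replicate reproducibility;
* a seed-deterministic synthetic workspace generator (panel, catalogue,
  reads, depth tables, call sets, cohorts) so everything is testable with
  no external data.

## Worked example

Ten 425 bp amplicons tile a six-exon gene; the second and seventh amplicons
drop out (the seventh covers an intergenic stretch, the second covers exon 2
with two catalogued variants):

```python
from panelcover import compute_depth, render_report, sample_report, variant_discoverable
from panelcover.simulate import SimulationConfig, make_single_gene_workspace, simulate_reads

manifest, catalogue = make_single_gene_workspace()
cfg = SimulationConfig(seed=1, mean_amplicon_depth=200, exact_depth=True)
reads = simulate_reads(manifest, cfg, dropped={"GATA1_a02", "GATA1_a07"})
profile = compute_depth(reads, manifest, sample_id="demo")
print(render_report(sample_report(profile, manifest, catalogue), "tsv"))
for v in catalogue:
    rec = variant_discoverable(profile, v)
    if not rec.discoverable:
        print(v.variant_id, v.chrom, v.pos, "min depth", rec.min_footprint_depth)
```

prints

```
gene	n_known	n_discoverable	percent_discoverable	flag
GATA1	10	8	80.0	LOW

gv02 chrX 561 min depth 0
gv03 chrX 641 min depth 0
```

Eight of ten known mutations remain discoverable; the two in exon 2 have
zero reads at their positions, so for this sample their absence from the
variant calls means *no data*, not *no mutation* — the gene is flagged
`LOW` and the sample would be repeated or rescued by Sanger.

The same pipeline is available from the shell:

```
panelcover simulate --seed 1 --out ws/
panelcover report --depth ws/depth.bedgraph --amplicons ws/amplicons.bed \
    --genes ws/genes.bed --catalogue ws/catalogue.tsv --out ws/report/
```

`report` exits 0 when clean and 3 when any gene is flagged, so pipelines can
react to QC failures mechanically. Validation statistics render like

```
99.7% (95% CI 98.3-99.9%, wilson, 327/328)   # sensitivity
100.0% (95% CI 98.6-100.0%, wilson, 267/267) # specificity
```

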