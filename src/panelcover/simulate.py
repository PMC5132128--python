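"""Seed-controlled synthetic panels, catalogues, reads, call sets and cohorts.

The generator emulates a 33-gene amplicon resequencing panel: 425 bp
amplicons tiling exons and intron/exon boundaries with overlap, 2x301
paired-end chemistry (forward reads anchored at the amplicon 5' end, reverse
reads at the 3' end, producing a fully covered central overlap flanked by
half-depth shoulders), stochastic whole-amplicon dropout, an HGMD-style
catalogue of known mutations with the characteristic class mix (87% missense,
4% simple insertions, 8% deletions, 1% complex indels), annotated call sets
that straddle every filter boundary, and cohort outcome vectors.

Every generator is a pure function of its configuration and seed: repeated
runs are byte-identical. Class allocation in the catalogue is deterministic
(largest-remainder rounding of the expected counts) by default so exact
composition checks are possible; multinomial sampling is available for
stress tests via ``exact_mix=False``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .calls import VariantCall
from .coverage import OP_ALN, AlignedRead
from .panel import (
    Amplicon,
    GeneModel,
    GenomicInterval,
    KnownVariant,
    KnownVariantCatalogue,
    PanelManifest,
)
from .calls import CohortOutcome

#: Default gene symbols for the simulated panel: the causative genes of the
#: inherited-anaemia conditions a red-cell panel targets.
DEFAULT_GENE_SYMBOLS = (
    "C15ORF41", "CDAN1", "SEC23B", "KIF23", "KLF1",
    "RPL11", "RPL26", "RPL35A", "RPL5", "RPS10", "RPS17", "RPS19",
    "RPS24", "RPS7", "RPL19", "RPL27", "RPL9", "RPS26", "RPS29",
    "RPS27", "GATA1",
    "SBDS",
    "DKC1", "NHP2", "NOP10", "TERT", "TERC", "TINF2",
    "ALAS2", "SLC25A38",
    "G6PD", "PKLR", "NT5C3A",
)

DEFAULT_CLASS_MIX = {
    "missense": 0.87,
    "simple_insertion": 0.04,
    "deletion": 0.08,
    "complex_indel": 0.01,
}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic workspace.

    Geometry defaults mirror the panel being emulated: 425 bp amplicons,
    301 bp reads, six exons per gene, a 1207-variant catalogue over 33 genes.
    ``mean_amplicon_depth`` is the expected total read count per amplicon
    (split between strands by ``strand_imbalance``); with ``exact_depth``
    the per-strand counts are fixed at their rounded expectation instead of
    Poisson-sampled, which makes planted-defect tests oracle-exact.
    """

    seed: int = 0
    # panel geometry
    n_genes: int = 33
    exons_per_gene: int = 6
    exon_length: int = 180
    intron_length: int = 260
    intergene_gap: int = 10_000
    amplicon_length: int = 425
    amplicon_overlap: int = 50
    flank: int = 50
    chrom: str = "chr1"
    # read simulation
    read_length: int = 301
    mean_amplicon_depth: float = 100.0
    dropout_prob: float = 0.0
    strand_imbalance: float = 0.5  # fraction of reads on the forward strand
    exact_depth: bool = False
    # catalogue
    catalogue_size: int = 1207
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )
    splice_site_fraction: float = 0.0
    pathogenic_prob: float = 0.5
    exact_mix: bool = True
    # call sets
    n_decoy_calls: int = 100

    def __post_init__(self) -> None:
        if self.amplicon_overlap >= self.amplicon_length:
            raise ValueError("amplicon overlap must be smaller than amplicon length")
        for name in ("dropout_prob", "strand_imbalance", "splice_site_fraction",
                     "pathogenic_prob"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1, got {total}")


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    # One independent stream per generator so that e.g. regenerating reads
    # does not perturb the catalogue.
    return np.random.default_rng([cfg.seed, stream])


def allocate_counts(total: int, mix: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of ``total`` items to the mix fractions."""
    floors = {k: int(np.floor(total * f)) for k, f in mix.items()}
    remainder = total - sum(floors.values())
    fractional = sorted(
        mix, key=lambda k: (total * mix[k]) - floors[k], reverse=True
    )
    for k in fractional[:remainder]:
        floors[k] += 1
    return floors


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------


def make_panel(cfg: SimulationConfig) -> PanelManifest:
    """Deterministic panel: genes laid head-to-tail, amplicons tiling each
    gene's exon span (plus flanks) with the configured overlap."""
    genes: list[GeneModel] = []
    amplicons: list[Amplicon] = []
    step = cfg.amplicon_length - cfg.amplicon_overlap
    cursor = cfg.intergene_gap
    for gi in range(cfg.n_genes):
        symbol = (
            DEFAULT_GENE_SYMBOLS[gi]
            if gi < len(DEFAULT_GENE_SYMBOLS)
            else f"GENE{gi + 1:03d}"
        )
        exons = []
        pos = cursor
        for _ in range(cfg.exons_per_gene):
            exons.append(GenomicInterval(cfg.chrom, pos, pos + cfg.exon_length))
            pos += cfg.exon_length + cfg.intron_length
        gene = GeneModel(symbol, tuple(exons), strand="+")
        genes.append(gene)

        region_start = max(gene.span.start - cfg.flank, 0)
        region_end = gene.span.end + cfg.flank
        start = region_start
        k = 0
        while True:
            k += 1
            amplicons.append(
                Amplicon(
                    f"{symbol}_a{k:02d}",
                    GenomicInterval(cfg.chrom, start, start + cfg.amplicon_length),
                    gene=symbol,
                )
            )
            if start + cfg.amplicon_length >= region_end:
                break
            start += step
        cursor = region_end + cfg.intergene_gap
    return PanelManifest(name=f"synthetic-{cfg.n_genes}-gene-panel",
                         genes=genes, amplicons=amplicons)


# ---------------------------------------------------------------------------
# Catalogue
# ---------------------------------------------------------------------------

_CLASS_CONSEQUENCE = {
    "missense": "missense",
    "nonsense": "stop_gained",
    "splice": "splice",
    "simple_insertion": "inframe_insertion",
    "deletion": "inframe_deletion",
    "complex_indel": "frameshift",
    "other": "missense",
}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _alleles_for_class(rng: np.random.Generator, vclass: str) -> tuple[str, str]:
    if vclass in ("missense", "nonsense", "splice", "other"):
        ref = _random_seq(rng, 1)
        alt = str(rng.choice(_BASES[_BASES != ref]))
        return ref, alt
    if vclass == "simple_insertion":
        ref = _random_seq(rng, 1)
        return ref, ref + _random_seq(rng, int(rng.integers(1, 7)))
    if vclass == "deletion":
        ref = _random_seq(rng, int(rng.integers(2, 8)))
        return ref, ref[0]
    if vclass == "complex_indel":
        while True:
            ref = _random_seq(rng, int(rng.integers(2, 5)))
            alt = _random_seq(rng, int(rng.integers(2, 5)))
            if ref != alt:
                return ref, alt
    raise ValueError(f"unknown variant class {vclass!r}")


def make_catalogue(
    panel: PanelManifest, cfg: SimulationConfig
) -> KnownVariantCatalogue:
    """Place catalogue variants uniformly over the panel's exonic footprint.

    An optional fraction of variants is placed at intron-side splice
    positions (offset 1-2 from an exon boundary, still within amplicon
    coverage) with class ``splice``.
    """
    if cfg.catalogue_size == 0:
        return KnownVariantCatalogue([])
    rng = _rng(cfg, 2)
    n_splice = int(round(cfg.catalogue_size * cfg.splice_site_fraction))
    n_body = cfg.catalogue_size - n_splice
    if cfg.exact_mix:
        counts = allocate_counts(n_body, cfg.class_mix)
    else:
        classes = list(cfg.class_mix)
        draw = rng.multinomial(n_body, [cfg.class_mix[c] for c in classes])
        counts = dict(zip(classes, (int(x) for x in draw)))
    class_sequence = [c for c in sorted(counts) for _ in range(counts[c])]
    class_sequence += ["splice"] * n_splice
    rng.shuffle(class_sequence)

    exon_index = [
        (g, e) for g in panel.genes for e in g.exons
    ]
    variants = []
    for i, vclass in enumerate(class_sequence):
        gene, exon = exon_index[int(rng.integers(len(exon_index)))]
        ref, alt = _alleles_for_class(rng, vclass)
        if vclass == "splice":
            offset = int(rng.integers(1, 3))
            side = int(rng.integers(2))
            pos0 = exon.start - offset if side == 0 else exon.end - 1 + offset
        else:
            span = len(ref)
            pos0 = int(rng.integers(exon.start, exon.end - span + 1))
        variants.append(
            KnownVariant(
                variant_id=f"var{i + 1:05d}",
                chrom=exon.chrom,
                pos=pos0 + 1,
                ref=ref,
                alt=alt,
                gene=gene.symbol,
                variant_class=vclass,
                pathogenic=bool(rng.random() < cfg.pathogenic_prob),
            )
        )
    return KnownVariantCatalogue(variants)


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


def simulate_reads(
    panel: PanelManifest,
    cfg: SimulationConfig,
    dropped: Iterable[str] = (),
) -> list[AlignedRead]:
    """Amplicon reads with the central-overlap depth geometry.

    Per surviving amplicon, forward reads start at the amplicon 5' end and
    reverse reads end at its 3' end; with a read length below the amplicon
    length the centre is covered by both strands while each flank sees only
    one — the masking geometry whole-amplicon mean coverage hides. Amplicons
    listed in ``dropped`` (or hit by the dropout draw) emit no reads.
    """
    rng = _rng(cfg, 3)
    dropped = set(dropped)
    reads: list[AlignedRead] = []
    for amp in panel.amplicons:
        iv = amp.interval
        read_len = min(cfg.read_length, len(iv))
        is_dropout = amp.amplicon_id in dropped or (
            cfg.dropout_prob > 0 and rng.random() < cfg.dropout_prob
        )
        if is_dropout:
            continue
        mean_fwd = cfg.mean_amplicon_depth * cfg.strand_imbalance
        mean_rev = cfg.mean_amplicon_depth * (1.0 - cfg.strand_imbalance)
        if cfg.exact_depth:
            n_fwd, n_rev = int(round(mean_fwd)), int(round(mean_rev))
        else:
            n_fwd = int(rng.poisson(mean_fwd))
            n_rev = int(rng.poisson(mean_rev))
        cigar = ((OP_ALN, read_len),)
        reads.extend(
            AlignedRead(iv.chrom, iv.start, cigar, strand="+")
            for _ in range(n_fwd)
        )
        reads.extend(
            AlignedRead(iv.chrom, iv.end - read_len, cigar, strand="-")
            for _ in range(n_rev)
        )
    return reads


# ---------------------------------------------------------------------------
# Call sets
# ---------------------------------------------------------------------------

# Decoy attribute grids straddle every filter boundary so a random call set
# exercises both sides of each rule.
_DECOY_QUALS = (50.0, 99.0, 100.0, 100.01, 150.0, 250.0)
_DECOY_FILTERS = ("PASS", "PASS", "PASS", "q30")
_DECOY_DEPTHS = (20, 29, 30, 31, 60, 100)
_DECOY_VAF_TARGETS = (0.1, 0.19, 0.20, 0.21, 0.5, 0.9)
_DECOY_POPFREQ = (None, None, 0.001, 0.049, 0.05, 0.2)
_DECOY_CONSEQUENCES = (
    "missense", "frameshift", "stop_gained", "splice", "inframe_deletion",
    "synonymous", "intron", "upstream", "utr",
)


def make_callset(
    catalogue: KnownVariantCatalogue,
    cfg: SimulationConfig,
    planted: Sequence[str] = (),
) -> list[VariantCall]:
    """Planted variants with passing attributes plus boundary-straddling decoys.

    ``planted`` names catalogue variant ids; each is emitted with attributes
    that pass every filter rule. Decoys reuse catalogue loci (with a
    distinguishing id) and draw attributes from grids around each threshold.
    """
    rng = _rng(cfg, 4)
    by_id = {v.variant_id: v for v in catalogue}
    calls: list[VariantCall] = []
    for vid in planted:
        v = by_id[vid]
        calls.append(
            VariantCall(
                variant_id=vid,
                chrom=v.chrom,
                pos=v.pos,
                ref=v.ref,
                alt=v.alt,
                qual=200.0,
                filter_status="PASS",
                total_depth=100,
                alt_depth=50,
                population_freq=None,
                consequence=_CLASS_CONSEQUENCE[v.variant_class],
                gene=v.gene,
                zygosity="het",
            )
        )
    if cfg.n_decoy_calls and len(catalogue):
        for i in range(cfg.n_decoy_calls):
            v = catalogue.variants[int(rng.integers(len(catalogue)))]
            depth = int(rng.choice(_DECOY_DEPTHS))
            vaf = float(rng.choice(_DECOY_VAF_TARGETS))
            popfreq = _DECOY_POPFREQ[int(rng.integers(len(_DECOY_POPFREQ)))]
            calls.append(
                VariantCall(
                    variant_id=f"decoy{i + 1:05d}",
                    chrom=v.chrom,
                    pos=v.pos,
                    ref=v.ref,
                    alt=v.alt,
                    qual=float(rng.choice(_DECOY_QUALS)),
                    filter_status=str(rng.choice(_DECOY_FILTERS)),
                    total_depth=depth,
                    alt_depth=min(int(round(vaf * depth)), depth),
                    population_freq=popfreq,
                    consequence=str(rng.choice(_DECOY_CONSEQUENCES)),
                    gene=v.gene,
                    zygosity=str(rng.choice(("het", "hom"))),
                )
            )
    return calls


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


def make_cohort(
    outcome_mix: Mapping[str, int],
    working_diagnosis: str | Mapping[str, str] = "Unexplained anaemia",
) -> list[CohortOutcome]:
    """Deterministic cohort outcome vector from absolute outcome counts."""
    outcomes = []
    i = 0
    for outcome in sorted(outcome_mix):
        for _ in range(outcome_mix[outcome]):
            i += 1
            diag = (
                working_diagnosis.get(outcome, "Unexplained anaemia")
                if isinstance(working_diagnosis, Mapping)
                else working_diagnosis
            )
            outcomes.append(CohortOutcome(f"case{i:03d}", diag, outcome))
    return outcomes


# ---------------------------------------------------------------------------
# A hand-built single-gene workspace with a known dropout topology
# ---------------------------------------------------------------------------


def make_single_gene_workspace() -> tuple[PanelManifest, KnownVariantCatalogue]:
    """A six-exon gene tiled by ten overlapping amplicons, with ten
    catalogued variants of which exactly two sit in the region covered only
    by the second amplicon, and no exon under the seventh amplicon's
    exclusive zone (an intergenic stretch).

    Dropping amplicons 2 and 7 therefore blinds the assay to exactly those
    two variants, giving a gene discoverability of 8/10 — the canonical
    failed-amplicon scenario per-base reporting exists to expose.
    """
    chrom = "chrX"
    exon_bounds = [(100, 300), (500, 700), (900, 1100),
                   (1300, 1500), (1600, 1800), (3300, 3500)]
    gene = GeneModel(
        "GATA1",
        tuple(GenomicInterval(chrom, s, e) for s, e in exon_bounds),
        strand="+",
    )
    amplicons = [
        Amplicon(f"GATA1_a{k + 1:02d}",
                 GenomicInterval(chrom, k * 375, k * 375 + 425), gene="GATA1")
        for k in range(10)
    ]
    manifest = PanelManifest("single-gene-demo", genes=[gene], amplicons=amplicons)
    # exon 2 spans [500, 700): inside amplicon 2's exclusive zone [425, 750)
    positions0 = [150, 560, 640, 950, 1350, 1450, 1700, 3350, 3420, 3480]
    bases = "ACGTACGTAC"
    variants = [
        KnownVariant(
            variant_id=f"gv{i + 1:02d}",
            chrom=chrom,
            pos=p + 1,
            ref=bases[i],
            alt="T" if bases[i] != "T" else "A",
            gene="GATA1",
            variant_class="missense",
            pathogenic=i % 2 == 0,
        )
        for i, p in enumerate(positions0)
    ]
    return manifest, KnownVariantCatalogue(variants)
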