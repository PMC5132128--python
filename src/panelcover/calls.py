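"""Variant filter cascade, reporting tiers and cohort diagnostic yield.

The filter reproduces a clinical amplicon-panel triage: quality score
strictly above 100, caller PASS status, total read depth strictly above 30,
variant allele fraction at or above 20%, population frequency strictly below
5% (unknown frequency passes — novel variants have no population record and
must survive), and a consequence whitelist of protein- or splice-altering
classes. The rules are conjunctive, so the kept set is independent of rule
order; the rejection ledger records the *first* failing rule per call in the
fixed order above.

Tiers follow the reporting shorthand used for inherited-anaemia panels:

* Tier 1 — exact match to a catalogued variant validated as pathogenic, in a
  gene known to cause the patient's phenotype.
* Tier 2 — expected pathogenic by mutation mechanism: frameshift, stop gain
  or loss, initiator-codon change, or canonical GT/AG splice-site change.
* Tier 3 — possibly causative: known pathogenic but in a gene for a
  different phenotype, predicted cryptic-splice/regulatory effect, or a
  missense change with a high deleteriousness score (the score is consumed
  as an input annotation, never computed here).
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import percent
from .panel import KnownVariantCatalogue, ParseError

DEFAULT_CONSEQUENCE_WHITELIST = frozenset(
    {
        "missense",
        "frameshift",
        "stop_gained",
        "stop_lost",
        "initiator_codon",
        "inframe_insertion",
        "inframe_deletion",
        "splice",
    }
)

#: Mechanism consequences that qualify for Tier 2 on their own.
TIER2_CONSEQUENCES = frozenset(
    {"frameshift", "stop_gained", "stop_lost", "initiator_codon"}
)

FILTER_RULES = ("qual", "pass", "depth", "vaf", "pop_freq", "consequence")

OUTCOMES = ("confirmed", "new_diagnosis", "changed_diagnosis", "unsolved")


@dataclass(frozen=True)
class VariantCall:
    """One annotated variant call from the upstream caller."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float
    filter_status: str  # "PASS" or a caller-specific failure label
    total_depth: int
    alt_depth: int
    population_freq: float | None  # None = not present in population databases
    consequence: str
    gene: str
    variant_id: str = ""
    zygosity: str | None = None  # "het" / "hom" when known
    deleterious_score: float | None = None  # e.g. a SIFT/PolyPhen-style score
    splice_offset: int | None = None  # intronic offset of a splice call, if known
    regulatory_effect: bool = False  # predicted cryptic splice / transcription effect

    def __post_init__(self) -> None:
        if self.alt_depth > self.total_depth:
            raise ValueError(
                f"{self.chrom}:{self.pos} alt_depth {self.alt_depth} exceeds "
                f"total_depth {self.total_depth}"
            )

    @property
    def vaf(self) -> float:
        if self.total_depth == 0:
            return 0.0
        return self.alt_depth / self.total_depth

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filter cascade; inequality directions are fixed."""

    min_qual: float = 100.0  # strict >
    require_pass: bool = True
    min_total_depth: int = 30  # strict >
    min_vaf: float = 0.20  # inclusive >=
    max_pop_freq: float = 0.05  # strict <; unknown frequency passes
    consequence_whitelist: frozenset[str] = DEFAULT_CONSEQUENCE_WHITELIST

    def __post_init__(self) -> None:
        if min(self.min_qual, self.min_total_depth, self.min_vaf, self.max_pop_freq) < 0:
            raise ValueError("filter thresholds must be non-negative")
        if not self.consequence_whitelist:
            raise ValueError("consequence whitelist must be non-empty")


def _first_failing_rule(call: VariantCall, cfg: FilterConfig) -> str | None:
    if not call.qual > cfg.min_qual:
        return "qual"
    if cfg.require_pass and call.filter_status != "PASS":
        return "pass"
    if not call.total_depth > cfg.min_total_depth:
        return "depth"
    if not call.vaf >= cfg.min_vaf:
        return "vaf"
    if call.population_freq is not None and not call.population_freq < cfg.max_pop_freq:
        return "pop_freq"
    if call.consequence not in cfg.consequence_whitelist:
        return "consequence"
    return None


def filter_calls(
    calls: Iterable[VariantCall], cfg: FilterConfig | None = None
) -> tuple[list[VariantCall], dict[str, int]]:
    """Apply the cascade; return kept calls and a per-rule rejection ledger."""
    cfg = cfg or FilterConfig()
    kept: list[VariantCall] = []
    ledger: dict[str, int] = {rule: 0 for rule in FILTER_RULES}
    for call in calls:
        rule = _first_failing_rule(call, cfg)
        if rule is None:
            kept.append(call)
        else:
            ledger[rule] += 1
    return kept, ledger


# ---------------------------------------------------------------------------
# Tier assignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TierAssignment:
    tier: int | None  # 1, 2, 3 or None
    rationale: str
    unsolved_flag: bool = False


def _is_canonical_splice(call: VariantCall) -> bool:
    # A splice consequence with an intronic offset of +/-1 or +/-2 hits the
    # invariant GT/AG dinucleotides; with no offset annotation the consequence
    # alone decides (transcript geometry is never recomputed here).
    if call.consequence != "splice":
        return False
    if call.splice_offset is None:
        return True
    return abs(call.splice_offset) in (1, 2)


def assign_tier(
    call: VariantCall,
    catalogue: KnownVariantCatalogue,
    phenotype_gene_map: Mapping[str, str],
    condition: str,
    high_score_cutoff: float = 0.9,
) -> TierAssignment:
    """Classify one filtered call against the catalogue and the phenotype.

    ``phenotype_gene_map`` maps gene symbol to the condition it causes;
    ``condition`` is the patient's working diagnosis. The deleteriousness
    cut-off applies to the input annotation score (higher = more damaging).
    """
    known = catalogue.lookup(call.chrom, call.pos, call.ref, call.alt)
    phenotype_match = phenotype_gene_map.get(call.gene) == condition
    if known is not None and known.pathogenic and phenotype_match:
        return TierAssignment(1, "known_pathogenic_phenotype_gene")
    if call.consequence in TIER2_CONSEQUENCES:
        return TierAssignment(2, f"mechanism:{call.consequence}")
    if _is_canonical_splice(call):
        return TierAssignment(2, "mechanism:canonical_splice")
    if known is not None and known.pathogenic:
        return TierAssignment(3, "known_pathogenic_other_phenotype")
    if call.regulatory_effect:
        return TierAssignment(3, "predicted_regulatory_or_cryptic_splice")
    if (
        call.consequence == "missense"
        and call.deleterious_score is not None
        and call.deleterious_score >= high_score_cutoff
    ):
        return TierAssignment(3, "high_score_missense")
    return TierAssignment(None, "no_rule_matched")


# ---------------------------------------------------------------------------
# Compound-recessive caveat
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CaseResolution:
    eligible_genes: tuple[str, ...]  # genes with a diagnosis-eligible genotype
    unsolved: bool
    rationale: str


def compound_recessive_check(
    tiered_calls: Sequence[tuple[VariantCall, TierAssignment]],
    inheritance_map: Mapping[str, str],
) -> CaseResolution:
    """Apply the co-inherited-recessive caveat to one case's tiered calls.

    Diagnosis-eligible genotypes: any Tier-1/2 hit in a dominant (AD) or
    X-linked (XL) gene; a homozygous hit or two or more heterozygous hits
    (compound heterozygosity) in a recessive (AR) gene. A case whose only
    findings are single heterozygous Tier-1/2 hits in each of two *different*
    AR genes is left unsolved: co-inheritance of two unrelated recessive
    carrier states is not evidence of pathogenicity without functional work.
    """
    strong = [
        (call, t)
        for call, t in tiered_calls
        if t.tier in (1, 2)
    ]
    per_gene: dict[str, list[VariantCall]] = {}
    for call, _ in strong:
        per_gene.setdefault(call.gene, []).append(call)

    eligible = []
    single_het_ar_genes = []
    for gene, hits in sorted(per_gene.items()):
        mode = inheritance_map.get(gene, "AD")
        if mode == "AR":
            n_hom = sum(1 for c in hits if c.zygosity == "hom")
            if n_hom >= 1 or len(hits) >= 2:
                eligible.append(gene)
            elif len(hits) == 1 and hits[0].zygosity != "hom":
                single_het_ar_genes.append(gene)
        else:  # AD, XL: one hit suffices
            eligible.append(gene)

    if eligible:
        return CaseResolution(tuple(eligible), False, "eligible_genotype_present")
    if len(single_het_ar_genes) >= 2:
        return CaseResolution(
            (), True, "single_het_hits_in_multiple_recessive_genes"
        )
    return CaseResolution((), True, "no_eligible_genotype")


# ---------------------------------------------------------------------------
# Cohort accounting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortOutcome:
    case_id: str
    working_diagnosis: str
    outcome: str  # one of OUTCOMES

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")


@dataclass
class CohortSummary:
    n_cases: int
    counts: dict[str, int]
    n_diagnosed: int  # confirmed + new + changed
    yield_fraction: float
    yield_percent: float  # one decimal, rounded half away from zero
    by_diagnosis: pd.DataFrame  # stratified counts per working diagnosis


def cohort_summary(outcomes: Sequence[CohortOutcome]) -> CohortSummary:
    """Diagnostic-yield accounting over a cohort of referred cases."""
    if not outcomes:
        raise ValueError("cohort_summary requires >= 1 outcome")
    counts = Counter(o.outcome for o in outcomes)
    n = len(outcomes)
    diagnosed = sum(counts[k] for k in ("confirmed", "new_diagnosis", "changed_diagnosis"))
    strata = (
        pd.DataFrame(
            [(o.working_diagnosis, o.outcome) for o in outcomes],
            columns=["working_diagnosis", "outcome"],
        )
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(OUTCOMES), fill_value=0)
        .sort_index()
    )
    return CohortSummary(
        n_cases=n,
        counts={k: counts.get(k, 0) for k in OUTCOMES},
        n_diagnosed=diagnosed,
        yield_fraction=diagnosed / n,
        yield_percent=percent(diagnosed / n),
        by_diagnosis=strata,
    )


# ---------------------------------------------------------------------------
# Call-set I/O
# ---------------------------------------------------------------------------

CALL_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "qual",
    "filter_status",
    "total_depth",
    "alt_depth",
    "population_freq",
    "consequence",
    "gene",
    "zygosity",
    "deleterious_score",
    "splice_offset",
    "regulatory_effect",
]


def read_calls_tsv(path: str | Path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = [c for c in CALL_COLUMNS[:12] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing mandatory column(s) {missing}")
    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            VariantCall(
                variant_id=str(row.variant_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                qual=float(row.qual),
                filter_status=str(row.filter_status),
                total_depth=int(row.total_depth),
                alt_depth=int(row.alt_depth),
                population_freq=(
                    None if str(row.population_freq) == "" else float(row.population_freq)
                ),
                consequence=str(row.consequence),
                gene=str(row.gene),
                zygosity=(str(row.zygosity) or None) if hasattr(row, "zygosity") else None,
                deleterious_score=(
                    float(row.deleterious_score)
                    if getattr(row, "deleterious_score", "") != ""
                    else None
                ),
                splice_offset=(
                    int(row.splice_offset)
                    if getattr(row, "splice_offset", "") != ""
                    else None
                ),
                regulatory_effect=(
                    str(getattr(row, "regulatory_effect", "false")).lower() == "true"
                ),
            )
        )
    return calls


def write_calls_tsv(calls: Sequence[VariantCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for c in calls:
            fields = [
                c.variant_id,
                c.chrom,
                str(c.pos),
                c.ref,
                c.alt,
                repr(c.qual),
                c.filter_status,
                str(c.total_depth),
                str(c.alt_depth),
                "" if c.population_freq is None else repr(c.population_freq),
                c.consequence,
                c.gene,
                c.zygosity or "",
                "" if c.deleterious_score is None else repr(c.deleterious_score),
                "" if c.splice_offset is None else str(c.splice_offset),
                "true" if c.regulatory_effect else "false",
            ]
            fh.write("\t".join(fields) + "\n")


_VCF_INFO_LINES = [
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
    '##INFO=<ID=AO,Number=1,Type=Integer,Description="Alternate allele read depth">',
    '##INFO=<ID=POPAF,Number=1,Type=Float,Description="Population allele frequency">',
    '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">',
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=ZYG,Number=1,Type=String,Description="Zygosity (het/hom)">',
    '##INFO=<ID=DSCORE,Number=1,Type=Float,Description="Deleteriousness score">',
    '##INFO=<ID=SPLOFF,Number=1,Type=Integer,Description="Splice intronic offset">',
    '##INFO=<ID=REG,Number=0,Type=Flag,Description="Predicted regulatory/cryptic-splice effect">',
]


def write_calls_vcf(
    calls: Sequence[VariantCall],
    path: str | Path,
    chrom_lengths: Mapping[str, int],
) -> None:
    """Write calls as an uncompressed VCF with annotations in INFO."""
    import pysam

    header = pysam.VariantHeader()
    for line in _VCF_INFO_LINES:
        header.add_line(line)
    header.add_line('##FILTER=<ID=q30,Description="Failed caller filters">')
    for chrom, length in chrom_lengths.items():
        header.contigs.add(chrom, length=int(length))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            rec = out.new_record(
                contig=c.chrom,
                start=c.pos - 1,
                stop=c.pos - 1 + len(c.ref),
                alleles=(c.ref, c.alt),
                id=c.variant_id or None,
                qual=c.qual,
            )
            rec.filter.add("PASS" if c.filter_status == "PASS" else "q30")
            rec.info["DP"] = c.total_depth
            rec.info["AO"] = c.alt_depth
            if c.population_freq is not None:
                rec.info["POPAF"] = c.population_freq
            rec.info["CSQ"] = c.consequence
            rec.info["GENE"] = c.gene
            if c.zygosity:
                rec.info["ZYG"] = c.zygosity
            if c.deleterious_score is not None:
                rec.info["DSCORE"] = c.deleterious_score
            if c.splice_offset is not None:
                rec.info["SPLOFF"] = c.splice_offset
            if c.regulatory_effect:
                rec.info["REG"] = True
            out.write(rec)


def read_calls_vcf(path: str | Path) -> list[VariantCall]:
    """Read annotated calls from VCF (INFO keys DP/AD/POPAF/CSQ/GENE/...)."""
    from cyvcf2 import VCF

    calls = []
    for i, rec in enumerate(VCF(str(path))):
        popaf = rec.INFO.get("POPAF")
        calls.append(
            VariantCall(
                variant_id=rec.ID or f"call{i}",
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
                qual=float(rec.QUAL if rec.QUAL is not None else 0.0),
                filter_status="PASS" if rec.FILTER is None else rec.FILTER,
                total_depth=int(rec.INFO.get("DP", 0)),
                alt_depth=int(rec.INFO.get("AO", 0)),
                population_freq=None if popaf is None else float(popaf),
                consequence=rec.INFO.get("CSQ") or "",
                gene=rec.INFO.get("GENE") or "",
                zygosity=rec.INFO.get("ZYG"),
                deleterious_score=(
                    float(rec.INFO["DSCORE"]) if rec.INFO.get("DSCORE") is not None else None
                ),
                splice_offset=(
                    int(rec.INFO["SPLOFF"]) if rec.INFO.get("SPLOFF") is not None else None
                ),
                regulatory_effect=bool(rec.INFO.get("REG", False)),
            )
        )
    return calls
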