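"""Known-mutation discoverability: the central QC metric.

A catalogued mutation is *discoverable* in a sample when every reference base
of its footprint lies inside the panel footprint and carries read depth at or
above the minimum threshold (30x by default, inclusive). The metric separates
"no mutation found" from "no data at the mutation's location", which is what
makes a negative result reportable in a clinical context.

Per-gene fractions below 90% (strict) are flagged so a laboratory can decide
to repeat sequencing or fall back to an orthogonal assay for that gene.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import percent_str
from .coverage import AmpliconStatus, DepthProfile, amplicon_status
from .panel import (
    Amplicon,
    GeneModel,
    KnownVariant,
    KnownVariantCatalogue,
    PanelManifest,
    variant_footprint,
)

DEFAULT_THRESHOLD = 30
DEFAULT_FLAG_BELOW = 0.90


@dataclass(frozen=True)
class DiscoverabilityRecord:
    sample_id: str
    variant_id: str
    min_footprint_depth: int
    discoverable: bool
    outside_panel: bool


@dataclass(frozen=True)
class GeneDiscoverability:
    gene: str
    n_known: int
    n_discoverable: int
    fraction: float
    flagged: bool
    n_outside_panel: int = 0


@dataclass
class SampleReport:
    sample_id: str
    genes: list[GeneDiscoverability]
    n_known: int
    n_discoverable: int
    overall_fraction: float  # total discoverable / total known, not a gene mean
    outside_panel: list[str]  # variant ids never assayable by the panel
    needs_review: bool  # any gene flagged -> repeat/rescue guidance
    threshold: int = DEFAULT_THRESHOLD
    flag_below: float = DEFAULT_FLAG_BELOW


@dataclass
class RunSummary:
    """Distribution of discoverability across the samples of a run."""

    n_samples: int
    per_gene: pd.DataFrame  # index gene; columns min, q1, median, q3, max, n_samples
    per_sample: pd.DataFrame  # index sample_id; column overall_fraction
    overall_range: tuple[float, float]


def variant_discoverable(
    profile: DepthProfile,
    variant: KnownVariant,
    threshold: int = DEFAULT_THRESHOLD,
) -> DiscoverabilityRecord:
    """Assess one variant: minimum depth over its footprint vs the threshold."""
    fp = variant_footprint(variant)
    if not profile.contains(fp):
        return DiscoverabilityRecord(
            sample_id=profile.sample_id,
            variant_id=variant.variant_id,
            min_footprint_depth=0,
            discoverable=False,
            outside_panel=True,
        )
    min_depth = profile.min_depth(fp.chrom, fp.start, fp.end)
    return DiscoverabilityRecord(
        sample_id=profile.sample_id,
        variant_id=variant.variant_id,
        min_footprint_depth=min_depth,
        discoverable=min_depth >= threshold,
        outside_panel=False,
    )


def _gene_summary(
    records: Sequence[DiscoverabilityRecord],
    gene: str,
    flag_below: float,
    include_outside_panel: bool,
) -> GeneDiscoverability | None:
    n_outside = sum(r.outside_panel for r in records)
    if include_outside_panel:
        assayable = list(records)
    else:
        assayable = [r for r in records if not r.outside_panel]
    if not assayable:
        return None
    n_disc = sum(r.discoverable for r in assayable)
    fraction = n_disc / len(assayable)
    return GeneDiscoverability(
        gene=gene,
        n_known=len(assayable),
        n_discoverable=n_disc,
        fraction=fraction,
        flagged=fraction < flag_below,
        n_outside_panel=n_outside,
    )


def gene_discoverability(
    profile: DepthProfile,
    gene: GeneModel | str,
    catalogue: KnownVariantCatalogue,
    threshold: int = DEFAULT_THRESHOLD,
    flag_below: float = DEFAULT_FLAG_BELOW,
    include_outside_panel: bool = False,
) -> GeneDiscoverability | None:
    """Discoverable fraction of the catalogued variants of one gene.

    Returns ``None`` when the catalogue has no (assayable) variant for the
    gene — such genes are omitted from reports rather than shown as 0/0.
    Variants whose footprint falls outside the panel are excluded from the
    denominator by default (they can never be discoverable by design) and
    tallied in ``n_outside_panel``; set ``include_outside_panel`` to count
    them as permanently non-discoverable instead.
    """
    symbol = gene.symbol if isinstance(gene, GeneModel) else gene
    variants = catalogue.by_gene().get(symbol)
    if not variants:
        return None
    records = [variant_discoverable(profile, v, threshold) for v in variants]
    return _gene_summary(records, symbol, flag_below, include_outside_panel)


def sample_report(
    profile: DepthProfile,
    manifest: PanelManifest,
    catalogue: KnownVariantCatalogue,
    threshold: int = DEFAULT_THRESHOLD,
    flag_below: float = DEFAULT_FLAG_BELOW,
    include_outside_panel: bool = False,
) -> SampleReport:
    """Per-gene and overall discoverability for one sample.

    Variants are attributed to genes solely via the catalogue's gene column
    (not positional overlap). The overall fraction is the ratio of totals,
    not the mean of gene fractions.
    """
    if len(catalogue) == 0:
        raise ValueError("sample_report requires a non-empty catalogue")
    genes: list[GeneDiscoverability] = []
    outside: list[str] = []
    total_known = 0
    total_disc = 0
    for symbol, variants in sorted(catalogue.by_gene().items()):
        records = [variant_discoverable(profile, v, threshold) for v in variants]
        outside.extend(r.variant_id for r in records if r.outside_panel)
        summary = _gene_summary(records, symbol, flag_below, include_outside_panel)
        if summary is None:
            continue
        genes.append(summary)
        total_known += summary.n_known
        total_disc += summary.n_discoverable
    overall = total_disc / total_known if total_known else 0.0
    return SampleReport(
        sample_id=profile.sample_id,
        genes=genes,
        n_known=total_known,
        n_discoverable=total_disc,
        overall_fraction=overall,
        outside_panel=sorted(outside),
        needs_review=any(g.flagged for g in genes),
        threshold=threshold,
        flag_below=flag_below,
    )


def run_summary(reports: Sequence[SampleReport]) -> RunSummary:
    """Five-number summaries of per-gene fractions across a run's samples."""
    if not reports:
        raise ValueError("run_summary requires >= 1 sample report")
    per_gene_values: dict[str, list[float]] = {}
    for rep in reports:
        for g in rep.genes:
            per_gene_values.setdefault(g.gene, []).append(g.fraction)
    rows = {}
    for gene, values in sorted(per_gene_values.items()):
        arr = np.asarray(values, dtype=float)
        q = np.quantile(arr, [0.0, 0.25, 0.5, 0.75, 1.0])
        rows[gene] = {
            "min": q[0],
            "q1": q[1],
            "median": q[2],
            "q3": q[3],
            "max": q[4],
            "n_samples": len(values),
        }
    per_gene = pd.DataFrame.from_dict(rows, orient="index")
    per_gene.index.name = "gene"
    per_sample = pd.DataFrame(
        {"overall_fraction": [r.overall_fraction for r in reports]},
        index=pd.Index([r.sample_id for r in reports], name="sample_id"),
    )
    overall = per_sample["overall_fraction"]
    return RunSummary(
        n_samples=len(reports),
        per_gene=per_gene,
        per_sample=per_sample,
        overall_range=(float(overall.min()), float(overall.max())),
    )


# ---------------------------------------------------------------------------
# Plot-ready gene track
# ---------------------------------------------------------------------------


def gene_coverage_track(
    profile: DepthProfile,
    gene: GeneModel,
    amplicons: Sequence[Amplicon],
    catalogue: KnownVariantCatalogue,
    threshold: int = DEFAULT_THRESHOLD,
) -> dict:
    """Pure-data track for a gene coverage plot.

    Contains the per-base depth series over the gene's amplicon span, each
    amplicon with its per-base pass/fail status, the threshold value, exon
    intervals, and one marker per catalogued variant with its discoverability.
    Rendering is left to the caller (or a thin matplotlib adapter).
    """
    if not amplicons:
        raise ValueError(f"gene {gene.symbol} has no amplicons")
    chrom = gene.chrom
    span_start = min(
        [a.interval.start for a in amplicons] + [gene.exons[0].start]
    )
    span_end = max([a.interval.end for a in amplicons] + [gene.exons[-1].end])
    depth = profile.depth_slice(chrom, span_start, span_end, fill=0)
    statuses = [amplicon_status(profile, a, threshold) for a in amplicons]
    markers = []
    for v in catalogue.by_gene().get(gene.symbol, []):
        rec = variant_discoverable(profile, v, threshold)
        markers.append(
            {
                "variant_id": v.variant_id,
                "pos": v.pos - 1,
                "discoverable": rec.discoverable,
                "outside_panel": rec.outside_panel,
            }
        )
    return {
        "gene": gene.symbol,
        "chrom": chrom,
        "span": [span_start, span_end],
        "depth": depth.tolist(),
        "threshold": threshold,
        "exons": [[e.start, e.end] for e in gene.exons],
        "amplicons": [
            {
                "amplicon_id": s.amplicon_id,
                "start": a.interval.start,
                "end": a.interval.end,
                "passed": s.passed,
                "pass_fraction": s.pass_fraction,
            }
            for a, s in zip(amplicons, statuses)
        ],
        "markers": markers,
    }


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

_TSV_HEADER = "gene\tn_known\tn_discoverable\tpercent_discoverable\tflag"


def render_report(report: SampleReport | RunSummary, format: str = "tsv") -> str:
    """Serialize a report as TSV (gene matrix) or JSON (all fields).

    Percentages are rendered to one decimal, rounded half away from zero;
    flagged genes carry the literal flag ``LOW``.
    """
    if format not in ("tsv", "json"):
        raise ValueError(f"unknown report format {format!r}")
    if isinstance(report, SampleReport):
        return _render_sample(report, format)
    if isinstance(report, RunSummary):
        return _render_run(report, format)
    raise TypeError(f"cannot render {type(report).__name__}")


def _render_sample(report: SampleReport, format: str) -> str:
    if format == "tsv":
        lines = [_TSV_HEADER]
        for g in report.genes:
            flag = "LOW" if g.flagged else ""
            lines.append(
                f"{g.gene}\t{g.n_known}\t{g.n_discoverable}"
                f"\t{percent_str(g.fraction)}\t{flag}"
            )
        return "\n".join(lines) + "\n"
    payload = {
        "sample_id": report.sample_id,
        "threshold": report.threshold,
        "flag_below": report.flag_below,
        "n_known": report.n_known,
        "n_discoverable": report.n_discoverable,
        "overall_fraction": report.overall_fraction,
        "overall_percent": percent_str(report.overall_fraction),
        "needs_review": report.needs_review,
        "outside_panel": report.outside_panel,
        "genes": [
            {
                "gene": g.gene,
                "n_known": g.n_known,
                "n_discoverable": g.n_discoverable,
                "fraction": g.fraction,
                "percent": percent_str(g.fraction),
                "flag": "LOW" if g.flagged else "",
                "n_outside_panel": g.n_outside_panel,
            }
            for g in report.genes
        ],
    }
    return json.dumps(payload, indent=2) + "\n"


def _render_run(summary: RunSummary, format: str) -> str:
    if format == "tsv":
        buf = StringIO()
        df = summary.per_gene.copy()
        for col in ("min", "q1", "median", "q3", "max"):
            df[col] = df[col].map(lambda x: percent_str(x))
        df.to_csv(buf, sep="\t")
        return buf.getvalue()
    payload = {
        "n_samples": summary.n_samples,
        "overall_range": list(summary.overall_range),
        "per_gene": summary.per_gene.reset_index().to_dict(orient="records"),
        "per_sample": summary.per_sample.reset_index().to_dict(orient="records"),
    }
    return json.dumps(payload, indent=2) + "\n"


def parse_report_tsv(text: str) -> pd.DataFrame:
    """Parse a sample-report TSV back into a DataFrame with exact fractions
    recomputed from the integer counts."""
    df = pd.read_csv(StringIO(text), sep="\t", keep_default_na=False)
    df["fraction"] = df["n_discoverable"] / df["n_known"]
    return df
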