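"""Domain model for amplicon panels, gene/exon structure and known-variant catalogues.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open ``[start, end)``. BED input is
consumed as-is (BED is already 0-based half-open); catalogue and VCF positions
are 1-based and converted on load. Chromosome names are compared by exact
string equality — no ``chr`` prefix aliasing is ever applied, because silently
reconciling mismatched naming schemes is a clinical-safety hazard. Use
:func:`validate_chromosomes` to surface cross-file naming mismatches instead.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

#: Closed vocabulary of known-variant classes. Classes come from the source
#: catalogue annotation (an HGMD-style extract) and are never re-derived from
#: the ref/alt alleles.
VARIANT_CLASSES = frozenset(
    {
        "missense",
        "nonsense",
        "splice",
        "simple_insertion",
        "deletion",
        "complex_indel",
        "other",
    }
)

CATALOGUE_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "variant_class",
    "pathogenic",
]


class PanelError(ValueError):
    """Invalid panel, gene or catalogue content."""


class ParseError(PanelError):
    """Malformed on-disk input; message names the file and line."""


# ---------------------------------------------------------------------------
# Interval primitives
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise PanelError("interval chromosome name must be non-empty")
        if self.start < 0 or self.end <= self.start:
            raise PanelError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "require end > start >= 0"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of ``(start, end)`` pairs as a sorted list of disjoint intervals.

    Abutting intervals are merged, so the result is the unique maximal
    decomposition; applying the function twice is a no-op.
    """
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            prev_start, prev_end = merged[-1]
            merged[-1] = (prev_start, max(prev_end, end))
        else:
            merged.append((start, end))
    return merged


def union_by_chrom(
    intervals: Iterable[GenomicInterval],
) -> dict[str, list[tuple[int, int]]]:
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {chrom: merge_intervals(ivs) for chrom, ivs in sorted(per_chrom.items())}


# ---------------------------------------------------------------------------
# Panel entities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Amplicon:
    """One PCR product of the panel; ``gene`` is empty for intergenic amplicons."""

    amplicon_id: str
    interval: GenomicInterval
    gene: str = ""


@dataclass(frozen=True)
class GeneModel:
    """A gene as an ordered set of exon intervals on one chromosome."""

    symbol: str
    exons: tuple[GenomicInterval, ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise PanelError(f"{self.symbol}: strand must be '+' or '-'")
        if not self.exons:
            raise PanelError(f"{self.symbol}: gene model requires >=1 exon")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise PanelError(f"{self.symbol}: exons span multiple chromosomes {chroms}")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise PanelError(
                    f"{self.symbol}: exons must be sorted and non-overlapping"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end)


@dataclass(frozen=True)
class KnownVariant:
    """A catalogued mutation with its class and pathogenicity annotation.

    ``pos`` is the 1-based position of the first affected reference base,
    matching the convention of the catalogue/VCF sources it is read from.
    """

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    variant_class: str
    pathogenic: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise PanelError(f"{self.variant_id}: pos must be >= 1")
        if self.ref == self.alt:
            raise PanelError(f"{self.variant_id}: ref and alt must differ")
        if self.variant_class not in VARIANT_CLASSES:
            raise PanelError(
                f"{self.variant_id}: unknown variant_class {self.variant_class!r}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def variant_footprint(v: KnownVariant) -> GenomicInterval:
    """Reference bases that must be covered for the variant to be observable.

    Substitutions and deletions need every affected reference base, i.e.
    ``[pos-1, pos-1+len(ref))`` in 0-based coordinates. A pure insertion
    (``len(ref) == 1`` and the alt extends the ref) alters no reference base,
    but its junction can only be seen by reads spanning both flanks, so its
    footprint is the two flanking reference bases ``[pos-1, pos+1)``.
    """
    start = v.pos - 1
    is_pure_insertion = (
        len(v.ref) == 1 and len(v.alt) > 1 and v.alt.startswith(v.ref)
    )
    if is_pure_insertion:
        return GenomicInterval(v.chrom, start, start + 2)
    return GenomicInterval(v.chrom, start, start + len(v.ref))


class KnownVariantCatalogue:
    """An ordered collection of :class:`KnownVariant` records.

    ``warning_count`` records how many input rows carried an unrecognised
    variant class and were remapped to ``other`` on load.
    """

    def __init__(self, variants: Sequence[KnownVariant], warning_count: int = 0):
        self.variants: list[KnownVariant] = list(variants)
        self.warning_count = int(warning_count)
        ids = Counter(v.variant_id for v in self.variants)
        dupes = [i for i, n in ids.items() if n > 1]
        if dupes:
            raise PanelError(f"duplicate variant_id(s) in catalogue: {dupes[:5]}")
        self._by_key = {v.key: v for v in self.variants}

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[KnownVariant]:
        return iter(self.variants)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnownVariantCatalogue):
            return NotImplemented
        return self.variants == other.variants

    def lookup(self, chrom: str, pos: int, ref: str, alt: str) -> KnownVariant | None:
        return self._by_key.get((chrom, pos, ref, alt))

    def by_gene(self) -> dict[str, list[KnownVariant]]:
        out: dict[str, list[KnownVariant]] = {}
        for v in self.variants:
            out.setdefault(v.gene, []).append(v)
        return out

    @property
    def genes(self) -> list[str]:
        return sorted({v.gene for v in self.variants})


def catalogue_composition(c: KnownVariantCatalogue) -> pd.DataFrame:
    """Absolute counts and fractions per variant class, summing to 1.

    Raises :class:`PanelError` on an empty catalogue (a fraction over zero
    records is undefined).
    """
    if len(c) == 0:
        raise PanelError("composition of an empty catalogue is undefined")
    counts = Counter(v.variant_class for v in c)
    classes = sorted(counts)
    df = pd.DataFrame(
        {
            "count": [counts[k] for k in classes],
            "fraction": [counts[k] / len(c) for k in classes],
        },
        index=pd.Index(classes, name="variant_class"),
    )
    return df


@dataclass
class PanelManifest:
    """The panel definition: genes, amplicons, and the derived footprint.

    The footprint is the exact interval union of the amplicons (each base
    counted once regardless of amplicon overlap).
    """

    name: str
    genes: list[GeneModel] = field(default_factory=list)
    amplicons: list[Amplicon] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = Counter(a.amplicon_id for a in self.amplicons)
        dupes = [i for i, n in ids.items() if n > 1]
        if dupes:
            raise PanelError(f"duplicate amplicon_id(s): {dupes[:5]}")
        self._gene_map = {g.symbol: g for g in self.genes}
        self.footprint: dict[str, list[tuple[int, int]]] = union_by_chrom(
            a.interval for a in self.amplicons
        )

    def gene(self, symbol: str) -> GeneModel | None:
        return self._gene_map.get(symbol)

    def amplicons_for_gene(self, symbol: str) -> list[Amplicon]:
        return [a for a in self.amplicons if a.gene == symbol]

    def footprint_length(self) -> int:
        return sum(e - s for ivs in self.footprint.values() for s, e in ivs)

    def contains(self, interval: GenomicInterval) -> bool:
        """True iff the interval lies fully inside the panel footprint."""
        for s, e in self.footprint.get(interval.chrom, []):
            if s <= interval.start and interval.end <= e:
                return True
        return False

    def chrom_lengths(self, margin: int = 1000) -> dict[str, int]:
        """Nominal chromosome lengths, for writing SAM/VCF headers."""
        return {
            chrom: ivs[-1][1] + margin for chrom, ivs in self.footprint.items() if ivs
        }


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _bed_rows(path: str | Path, min_cols: int):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < min_cols:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {min_cols} columns, got {len(cols)}"
                )
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            yield lineno, cols, start, end


def load_manifest(
    amplicon_bed: str | Path, gene_bed: str | Path, name: str = "panel"
) -> PanelManifest:
    """Build a :class:`PanelManifest` from an amplicon BED and a gene/exon BED.

    The amplicon BED is standard 4+ column BED (chrom, start, end, name[, gene]).
    The gene BED carries one exon per row with name ``SYMBOL|exonN`` and strand
    in column 5. Both files are 0-based half-open.
    """
    amplicons: list[Amplicon] = []
    for lineno, cols, start, end in _bed_rows(amplicon_bed, 4):
        try:
            interval = GenomicInterval(cols[0], start, end)
        except PanelError as exc:
            raise ParseError(f"{amplicon_bed}:{lineno}: {exc}") from exc
        gene = cols[4] if len(cols) > 4 else ""
        amplicons.append(Amplicon(cols[3], interval, gene))

    exon_rows: dict[str, list[tuple[int, GenomicInterval, str]]] = {}
    for lineno, cols, start, end in _bed_rows(gene_bed, 5):
        name_field = cols[3]
        if "|" not in name_field:
            raise ParseError(
                f"{gene_bed}:{lineno}: exon name must be 'SYMBOL|exonN', got {name_field!r}"
            )
        symbol, exon_label = name_field.split("|", 1)
        try:
            exon_index = int(exon_label.removeprefix("exon"))
        except ValueError as exc:
            raise ParseError(f"{gene_bed}:{lineno}: bad exon label {exon_label!r}") from exc
        try:
            interval = GenomicInterval(cols[0], start, end)
        except PanelError as exc:
            raise ParseError(f"{gene_bed}:{lineno}: {exc}") from exc
        exon_rows.setdefault(symbol, []).append((exon_index, interval, cols[4]))

    genes = []
    for symbol, rows in sorted(exon_rows.items()):
        rows.sort(key=lambda r: r[0])
        strand = rows[0][2]
        exons = tuple(sorted((r[1] for r in rows), key=lambda iv: iv.start))
        genes.append(GeneModel(symbol, exons, strand))

    return PanelManifest(name=name, genes=genes, amplicons=amplicons)


def write_manifest_beds(
    manifest: PanelManifest, amplicon_bed: str | Path, gene_bed: str | Path
) -> None:
    with open(amplicon_bed, "w") as fh:
        for a in manifest.amplicons:
            fh.write(
                f"{a.interval.chrom}\t{a.interval.start}\t{a.interval.end}"
                f"\t{a.amplicon_id}\t{a.gene}\n"
            )
    with open(gene_bed, "w") as fh:
        for g in manifest.genes:
            for i, exon in enumerate(g.exons, start=1):
                fh.write(
                    f"{exon.chrom}\t{exon.start}\t{exon.end}"
                    f"\t{g.symbol}|exon{i}\t{g.strand}\n"
                )


_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f"}


def _parse_bool(value, context: str) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ParseError(f"{context}: cannot interpret {value!r} as boolean")


def load_catalogue(path: str | Path) -> KnownVariantCatalogue:
    """Read a known-variant catalogue from TSV (or VCF, by extension).

    Rows with a variant class outside the closed vocabulary are kept but
    remapped to ``other``; the number of such remaps is reported on the
    returned catalogue as ``warning_count``.
    """
    path = Path(path)
    if path.suffix.lower() in (".vcf",):
        return _load_catalogue_vcf(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return KnownVariantCatalogue([])
    missing = [c for c in CATALOGUE_COLUMNS if c not in df.columns and c != "pathogenic"]
    if missing:
        raise ParseError(f"{path}: missing mandatory column(s) {missing}")
    variants = []
    warnings = 0
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        vclass = row.variant_class
        if vclass not in VARIANT_CLASSES:
            vclass = "other"
            warnings += 1
        pathogenic = (
            _parse_bool(row.pathogenic, f"{path}:{idx}")
            if "pathogenic" in df.columns
            else False
        )
        try:
            variants.append(
                KnownVariant(
                    variant_id=row.variant_id,
                    chrom=row.chrom,
                    pos=int(row.pos),
                    ref=row.ref,
                    alt=row.alt,
                    gene=row.gene,
                    variant_class=vclass,
                    pathogenic=pathogenic,
                )
            )
        except (PanelError, ValueError) as exc:
            raise ParseError(f"{path}:{idx}: {exc}") from exc
    return KnownVariantCatalogue(variants, warning_count=warnings)


def _load_catalogue_vcf(path: Path) -> KnownVariantCatalogue:
    from cyvcf2 import VCF

    variants = []
    warnings = 0
    for i, rec in enumerate(VCF(str(path))):
        vclass = rec.INFO.get("CLASS") or "other"
        if vclass not in VARIANT_CLASSES:
            vclass = "other"
            warnings += 1
        variants.append(
            KnownVariant(
                variant_id=rec.ID or f"{path.stem}_{i}",
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
                gene=rec.INFO.get("GENE") or "",
                variant_class=vclass,
                pathogenic=bool(rec.INFO.get("PATHOGENIC", False)),
            )
        )
    return KnownVariantCatalogue(variants, warning_count=warnings)


def write_catalogue(catalogue: KnownVariantCatalogue, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CATALOGUE_COLUMNS) + "\n")
        for v in catalogue:
            fh.write(
                f"{v.variant_id}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}"
                f"\t{v.gene}\t{v.variant_class}\t{'true' if v.pathogenic else 'false'}\n"
            )


def validate_chromosomes(
    manifest: PanelManifest, catalogue: KnownVariantCatalogue
) -> dict[str, set[str]]:
    """Report chromosome names that appear in one input but not the other.

    No aliasing is attempted; a ``chr1`` vs ``1`` mismatch is surfaced here
    rather than silently reconciled.
    """
    panel_chroms = set(manifest.footprint)
    catalogue_chroms = {v.chrom for v in catalogue}
    return {
        "manifest_only": panel_chroms - catalogue_chroms,
        "catalogue_only": catalogue_chroms - panel_chroms,
    }
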