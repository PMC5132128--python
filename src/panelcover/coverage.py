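"""Per-base read-depth computation over a panel footprint.

The engine consumes aligned reads (SAM semantics: CIGAR, MAPQ, FLAG bits) or a
precomputed per-base depth table and produces a strand-resolved
:class:`DepthProfile` restricted to the panel footprint. Depth at a base is
the number of counted reads whose aligned (reference-consuming, non-deleted)
segments include that base; deletion-spanned bases are excluded by default but
can be counted via :class:`CountingOptions`. The result is independent of read
order, so sorted input is not required.
"""
from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .panel import Amplicon, GenomicInterval, PanelManifest, ParseError, merge_intervals

# CIGAR operations, named rather than single-letter to keep call sites readable.
OP_ALN = "ALN"  # alignment match/mismatch (SAM M, =, X)
OP_INS = "INS"  # insertion to the reference (SAM I)
OP_DEL = "DEL"  # deletion from the reference (SAM D)
OP_SKIP = "SKIP"  # skipped reference region (SAM N)
OP_CLIP = "CLIP"  # soft/hard clip (SAM S, H)

_REF_CONSUMING = {OP_ALN, OP_DEL, OP_SKIP}


@dataclass(frozen=True)
class AlignedRead:
    """A minimal aligned read: position, CIGAR, mapping quality and flags."""

    chrom: str
    pos: int  # 0-based leftmost reference position
    cigar: tuple[tuple[str, int], ...]
    mapq: int = 60
    strand: str = "+"
    qc_fail: bool = False
    duplicate: bool = False


def aligned_segments(
    read: AlignedRead, include_deletions: bool = False
) -> list[tuple[int, int]]:
    """Reference intervals covered by the read's counted bases.

    ALN segments always count; DEL segments count only when
    ``include_deletions`` is set; SKIP consumes reference without counting;
    INS and CLIP consume no reference.
    """
    segments: list[tuple[int, int]] = []
    ref = read.pos
    for op, length in read.cigar:
        if op == OP_ALN or (op == OP_DEL and include_deletions):
            if segments and segments[-1][1] == ref:
                segments[-1] = (segments[-1][0], ref + length)
            else:
                segments.append((ref, ref + length))
        if op in _REF_CONSUMING:
            ref += length
    return segments


@dataclass(frozen=True)
class CountingOptions:
    """Read-counting policy.

    Duplicates are counted by default: in amplicon sequencing PCR duplicates
    are indistinguishable from independent coverage, so discarding them would
    understate depth. The flag exists for capture-based panels.
    """

    min_mapq: int = 0
    count_deletion_spanned_bases: bool = False
    count_duplicates: bool = True

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")


class DepthProfile:
    """Per-base depth over a panel footprint for one sample.

    Holds total, forward-strand and reverse-strand depth arrays per merged
    footprint interval; forward + reverse equals total at every base.
    """

    def __init__(
        self,
        sample_id: str,
        footprint: Mapping[str, Sequence[tuple[int, int]]],
        options: CountingOptions | None = None,
    ):
        self.sample_id = sample_id
        self.options = options or CountingOptions()
        self.footprint: dict[str, list[tuple[int, int]]] = {
            chrom: merge_intervals(ivs) for chrom, ivs in footprint.items()
        }
        self._starts = {
            chrom: [s for s, _ in ivs] for chrom, ivs in self.footprint.items()
        }
        self.fwd: dict[str, list[np.ndarray]] = {}
        self.rev: dict[str, list[np.ndarray]] = {}
        for chrom, ivs in self.footprint.items():
            self.fwd[chrom] = [np.zeros(e - s, dtype=np.int64) for s, e in ivs]
            self.rev[chrom] = [np.zeros(e - s, dtype=np.int64) for s, e in ivs]
        self.skipped_reads = 0  # reads on chromosomes absent from the footprint

    # -- construction ------------------------------------------------------

    def _add_segment(self, chrom: str, start: int, end: int, strand: str) -> None:
        ivs = self.footprint.get(chrom)
        if not ivs:
            return
        starts = self._starts[chrom]
        arrays = self.fwd[chrom] if strand == "+" else self.rev[chrom]
        i = max(bisect_right(starts, start) - 1, 0)
        while i < len(ivs) and ivs[i][0] < end:
            iv_s, iv_e = ivs[i]
            lo, hi = max(start, iv_s), min(end, iv_e)
            if lo < hi:
                arrays[i][lo - iv_s : hi - iv_s] += 1
            i += 1

    # -- queries -----------------------------------------------------------

    def contains(self, interval: GenomicInterval) -> bool:
        for s, e in self.footprint.get(interval.chrom, []):
            if s <= interval.start and interval.end <= e:
                return True
        return False

    def _locate(self, chrom: str, start: int, end: int) -> int:
        ivs = self.footprint.get(chrom)
        if ivs:
            i = bisect_right(self._starts[chrom], start) - 1
            if i >= 0 and ivs[i][0] <= start and end <= ivs[i][1]:
                return i
        raise KeyError(
            f"[{start}, {end}) on {chrom} is not contained in the profile footprint"
        )

    def depth_slice(
        self,
        chrom: str,
        start: int,
        end: int,
        strand: str | None = None,
        fill: int | None = None,
    ) -> np.ndarray:
        """Depth array over ``[start, end)``.

        With ``fill=None`` the query must lie inside one footprint interval;
        with a numeric ``fill``, bases outside the footprint take that value
        (used for plot tracks that extend past the panel).
        """
        if fill is None:
            i = self._locate(chrom, start, end)
            iv_s, _ = self.footprint[chrom][i]
            arr = self._strand_arrays(strand)[chrom][i]
            return arr[start - iv_s : end - iv_s].copy()
        out = np.full(end - start, fill, dtype=np.int64)
        arrays = self._strand_arrays(strand)
        for i, (iv_s, iv_e) in enumerate(self.footprint.get(chrom, [])):
            lo, hi = max(start, iv_s), min(end, iv_e)
            if lo < hi:
                out[lo - start : hi - start] = arrays[chrom][i][lo - iv_s : hi - iv_s]
        return out

    def _strand_arrays(self, strand: str | None):
        if strand is None:
            return {
                chrom: [f + r for f, r in zip(self.fwd[chrom], self.rev[chrom])]
                for chrom in self.footprint
            }
        if strand == "+":
            return self.fwd
        if strand == "-":
            return self.rev
        raise ValueError(f"strand must be '+', '-' or None, got {strand!r}")

    def min_depth(self, chrom: str, start: int, end: int) -> int:
        return int(self.depth_slice(chrom, start, end).min())

    def runs(self, strand: str | None = None) -> list[tuple[str, int, int, int]]:
        """Constant-depth runs as ``(chrom, start, end, depth)`` rows.

        Zero-depth runs inside the footprint are included so that writing and
        re-reading a profile preserves the footprint exactly.
        """
        rows: list[tuple[str, int, int, int]] = []
        arrays = self._strand_arrays(strand)
        for chrom, ivs in self.footprint.items():
            for i, (iv_s, _) in enumerate(ivs):
                arr = arrays[chrom][i]
                if arr.size == 0:
                    continue
                change = np.flatnonzero(np.diff(arr)) + 1
                bounds = np.concatenate(([0], change, [arr.size]))
                for lo, hi in zip(bounds[:-1], bounds[1:]):
                    rows.append((chrom, iv_s + int(lo), iv_s + int(hi), int(arr[lo])))
        return rows

    def same_depths(self, other: "DepthProfile") -> bool:
        """True iff footprints and total per-base depths are identical."""
        if self.footprint != other.footprint:
            return False
        return self.runs() == other.runs()


def compute_depth(
    reads: Iterable[AlignedRead],
    manifest: PanelManifest,
    options: CountingOptions | None = None,
    sample_id: str = "sample",
) -> DepthProfile:
    """Pile up reads over the manifest footprint.

    Reads failing QC, below ``min_mapq``, or flagged duplicate (when duplicate
    counting is off) are excluded. Reads on chromosomes absent from the
    manifest are tallied in ``skipped_reads`` rather than raising.
    """
    opts = options or CountingOptions()
    profile = DepthProfile(sample_id, manifest.footprint, opts)
    for read in reads:
        if read.chrom not in profile.footprint:
            profile.skipped_reads += 1
            continue
        if read.qc_fail or read.mapq < opts.min_mapq:
            continue
        if read.duplicate and not opts.count_duplicates:
            continue
        for start, end in aligned_segments(
            read, include_deletions=opts.count_deletion_spanned_bases
        ):
            profile._add_segment(read.chrom, start, end, read.strand)
    return profile


# ---------------------------------------------------------------------------
# Depth-table (bedGraph dialect) I/O
# ---------------------------------------------------------------------------


def load_depth_table(
    path: str | Path,
    manifest: PanelManifest | None = None,
    sample_id: str = "sample",
) -> DepthProfile:
    """Read a 4-column bedGraph-style depth table (0-based half-open rows).

    With a manifest, depths are restricted to its footprint and absent bases
    are zero; without one, the footprint is the union of the table's rows.
    Overlapping rows that disagree on depth raise a validation error
    (strand-resolved sub-profiles are not recoverable from a table, so the
    total is stored on the forward component).
    """
    rows: list[tuple[str, int, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            try:
                rows.append((cols[0], int(cols[1]), int(cols[2]), int(float(cols[3]))))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad numeric field") from exc

    if manifest is not None:
        footprint = manifest.footprint
    else:
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e, _ in rows:
            per_chrom.setdefault(chrom, []).append((s, e))
        footprint = {c: merge_intervals(iv) for c, iv in sorted(per_chrom.items())}

    profile = DepthProfile(sample_id, footprint)
    assigned = {
        chrom: [np.zeros(len(a), dtype=bool) for a in arrays]
        for chrom, arrays in profile.fwd.items()
    }
    for chrom, start, end, depth in rows:
        ivs = profile.footprint.get(chrom, [])
        for i, (iv_s, iv_e) in enumerate(ivs):
            lo, hi = max(start, iv_s), min(end, iv_e)
            if lo >= hi:
                continue
            sl = slice(lo - iv_s, hi - iv_s)
            conflict = assigned[chrom][i][sl] & (profile.fwd[chrom][i][sl] != depth)
            if conflict.any():
                raise ParseError(
                    f"{path}: conflicting depths for overlapping rows at "
                    f"{chrom}:{lo + int(np.flatnonzero(conflict)[0])}"
                )
            profile.fwd[chrom][i][sl] = depth
            assigned[chrom][i][sl] = True
    return profile


def write_depth_table(profile: DepthProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, depth in profile.runs():
            fh.write(f"{chrom}\t{start}\t{end}\t{depth}\n")


# ---------------------------------------------------------------------------
# Per-amplicon summaries
# ---------------------------------------------------------------------------


def amplicon_mean_coverage(profile: DepthProfile, amplicon: Amplicon) -> float:
    """Arithmetic mean depth over the amplicon — the summary whole-amplicon
    reporting relies on, which can mask under-covered flanks."""
    iv = amplicon.interval
    return float(profile.depth_slice(iv.chrom, iv.start, iv.end).mean())


@dataclass(frozen=True)
class AmpliconStatus:
    amplicon_id: str
    passed: bool
    pass_fraction: float  # fraction of bases at or above the threshold
    min_depth: int
    mean_depth: float


def amplicon_status(
    profile: DepthProfile, amplicon: Amplicon, min_depth: int = 30
) -> AmpliconStatus:
    """Per-base pass/fail: the amplicon fails iff any base is below threshold.

    The threshold is inclusive — depth exactly at ``min_depth`` passes.
    """
    iv = amplicon.interval
    depths = profile.depth_slice(iv.chrom, iv.start, iv.end)
    ok = depths >= min_depth
    return AmpliconStatus(
        amplicon_id=amplicon.amplicon_id,
        passed=bool(ok.all()),
        pass_fraction=float(ok.mean()),
        min_depth=int(depths.min()),
        mean_depth=float(depths.mean()),
    )


# ---------------------------------------------------------------------------
# SAM I/O (via pysam)
# ---------------------------------------------------------------------------

_PYSAM_OPS = {0: OP_ALN, 7: OP_ALN, 8: OP_ALN, 1: OP_INS, 2: OP_DEL,
              3: OP_SKIP, 4: OP_CLIP, 5: OP_CLIP}


def reads_from_sam(path: str | Path) -> Iterator[AlignedRead]:
    """Stream mapped reads from a SAM/BAM file as :class:`AlignedRead`."""
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.cigartuples is None:
                continue
            cigar = tuple(
                (_PYSAM_OPS[op], length)
                for op, length in aln.cigartuples
                if op in _PYSAM_OPS
            )
            yield AlignedRead(
                chrom=aln.reference_name,
                pos=aln.reference_start,
                cigar=cigar,
                mapq=aln.mapping_quality,
                strand="-" if aln.is_reverse else "+",
                qc_fail=aln.is_qcfail,
                duplicate=aln.is_duplicate,
            )


_SAM_CODES = {OP_ALN: 0, OP_INS: 1, OP_DEL: 2, OP_SKIP: 3, OP_CLIP: 4}


def write_sam(
    reads: Iterable[AlignedRead],
    path: str | Path,
    chrom_lengths: Mapping[str, int],
) -> None:
    """Write reads as a text SAM file (coordinates and CIGAR only, no sequence)."""
    import pysam

    chroms = list(chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": int(chrom_lengths[c])} for c in chroms],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, read in enumerate(reads):
            aln = pysam.AlignedSegment(out.header)
            aln.query_name = f"read{i:07d}"
            aln.reference_id = chroms.index(read.chrom)
            aln.reference_start = read.pos
            aln.mapping_quality = read.mapq
            aln.cigartuples = [(_SAM_CODES[op], length) for op, length in read.cigar]
            aln.flag = (
                (0x10 if read.strand == "-" else 0)
                | (0x200 if read.qc_fail else 0)
                | (0x400 if read.duplicate else 0)
            )
            out.write(aln)
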