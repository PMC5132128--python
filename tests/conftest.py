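import numpy as np
import pytest

from panelcover.coverage import OP_ALN, AlignedRead, compute_depth
from panelcover.panel import (
    Amplicon,
    GeneModel,
    GenomicInterval,
    KnownVariant,
    KnownVariantCatalogue,
    PanelManifest,
)
from panelcover.simulate import SimulationConfig, make_single_gene_workspace, simulate_reads


@pytest.fixture
def toy_manifest():
    """One gene, one chromosome, two overlapping amplicons covering [0, 300)."""
    gene = GeneModel(
        "TOY",
        (GenomicInterval("chr1", 20, 120), GenomicInterval("chr1", 180, 280)),
    )
    amplicons = [
        Amplicon("toy_a1", GenomicInterval("chr1", 0, 180), gene="TOY"),
        Amplicon("toy_a2", GenomicInterval("chr1", 150, 300), gene="TOY"),
    ]
    return PanelManifest("toy", genes=[gene], amplicons=amplicons)


@pytest.fixture
def uniform_reads():
    """Reads giving uniform depth 40 over [0, 300) on chr1."""
    return [
        AlignedRead("chr1", 0, ((OP_ALN, 300),), strand="+" if i % 2 else "-")
        for i in range(40)
    ]


@pytest.fixture
def demo_workspace():
    """Single-gene, ten-amplicon workspace with amplicons 2 and 7 dropped.

    Exactly two catalogue variants (gv02, gv03, in exon 2) sit in the region
    covered only by the dropped second amplicon.
    """
    manifest, catalogue = make_single_gene_workspace()
    cfg = SimulationConfig(seed=11, mean_amplicon_depth=200, exact_depth=True)
    reads = simulate_reads(manifest, cfg, dropped={"GATA1_a02", "GATA1_a07"})
    profile = compute_depth(reads, manifest, sample_id="demo")
    return manifest, catalogue, profile


def brute_force_depth(reads, chrom, start, end, include_deletions=False,
                      min_mapq=0, count_duplicates=True):
    """Independent per-(read, base) membership count used as the depth oracle.

    Walks each CIGAR directly, without the package's segment machinery.
    """
    depth = np.zeros(end - start, dtype=int)
    for read in reads:
        if read.chrom != chrom or read.qc_fail or read.mapq < min_mapq:
            continue
        if read.duplicate and not count_duplicates:
            continue
        ref = read.pos
        for op, length in read.cigar:
            counted = op == "ALN" or (op == "DEL" and include_deletions)
            if op in ("ALN", "DEL", "SKIP"):
                if counted:
                    for b in range(ref, ref + length):
                        if start <= b < end:
                            depth[b - start] += 1
                ref += length
    return depth
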