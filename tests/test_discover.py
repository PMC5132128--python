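"""Discoverability metric: per-variant, per-gene, per-sample, per-run."""
import json

import numpy as np
import pytest

from panelcover.coverage import OP_ALN, AlignedRead, compute_depth
from panelcover.discover import (
    gene_coverage_track,
    gene_discoverability,
    parse_report_tsv,
    render_report,
    run_summary,
    sample_report,
    variant_discoverable,
)
from panelcover.panel import (
    KnownVariant,
    KnownVariantCatalogue,
    variant_footprint,
)
from panelcover.simulate import SimulationConfig, make_single_gene_workspace, simulate_reads


def _uniform_profile(manifest, depth, span=300, sample_id="s"):
    reads = [AlignedRead("chr1", 0, ((OP_ALN, span),)) for _ in range(depth)]
    return compute_depth(reads, manifest, sample_id=sample_id)


def _variant(i, pos, ref="A", alt="T", gene="TOY", vclass="missense"):
    return KnownVariant(f"v{i:03d}", "chr1", pos, ref, alt, gene, vclass)


class TestVariantDiscoverable:
    def test_zero_depth_not_discoverable(self, toy_manifest):
        profile = _uniform_profile(toy_manifest, 0)
        rec = variant_discoverable(profile, _variant(1, 50))
        assert not rec.discoverable and rec.min_footprint_depth == 0

    def test_depth_exactly_at_threshold_is_discoverable(self, toy_manifest):
        profile = _uniform_profile(toy_manifest, 30)
        rec = variant_discoverable(profile, _variant(1, 50), threshold=30)
        assert rec.discoverable and rec.min_footprint_depth == 30

    def test_deletion_minimum_over_footprint(self, toy_manifest):
        # 4 bp deletion at pos 50: footprint bases 49..52; base 52 at 29x
        reads = [AlignedRead("chr1", 0, ((OP_ALN, 300),)) for _ in range(29)]
        reads += [AlignedRead("chr1", 0, ((OP_ALN, 52),)) for _ in range(71)]
        profile = compute_depth(reads, toy_manifest)
        v = _variant(1, 50, ref="ACGT", alt="A", vclass="deletion")
        fp = variant_footprint(v)
        oracle_min = min(
            int(profile.depth_slice("chr1", b, b + 1)[0])
            for b in range(fp.start, fp.end)
        )
        rec = variant_discoverable(profile, v)
        assert rec.min_footprint_depth == oracle_min == 29
        assert not rec.discoverable

    def test_variant_outside_panel_flagged(self, toy_manifest):
        profile = _uniform_profile(toy_manifest, 100)
        rec = variant_discoverable(profile, _variant(1, 5000))
        assert rec.outside_panel and not rec.discoverable


class TestGeneDiscoverability:
    def _profile_with_low_region(self, manifest, n_low):
        """Uniform 100x except depth 0 over [200, 300)."""
        reads = [AlignedRead("chr1", 0, ((OP_ALN, 200),)) for _ in range(100)]
        reads += [AlignedRead("chr1", 200, ((OP_ALN, 100),)) for _ in range(0)]
        return compute_depth(reads, manifest)

    def test_fraction_at_flag_boundary(self, toy_manifest):
        # 20 variants, 18 covered (pos <= 200), 2 in the uncovered tail
        variants = [_variant(i, 10 + i) for i in range(18)]
        variants += [_variant(90, 250), _variant(91, 260)]
        cat = KnownVariantCatalogue(variants)
        profile = self._profile_with_low_region(toy_manifest, 2)
        g = gene_discoverability(profile, "TOY", cat, threshold=30)
        assert g.fraction == 0.90
        assert not g.flagged  # the flag rule is strict <

    def test_fraction_below_boundary_flagged(self, toy_manifest):
        variants = [_variant(i, 10 + i) for i in range(17)]
        variants += [_variant(90, 250), _variant(91, 260), _variant(92, 270)]
        cat = KnownVariantCatalogue(variants)
        profile = self._profile_with_low_region(toy_manifest, 3)
        g = gene_discoverability(profile, "TOY", cat, threshold=30)
        assert g.fraction == 0.85
        assert g.flagged

    def test_gene_absent_from_catalogue_omitted(self, toy_manifest):
        cat = KnownVariantCatalogue([_variant(1, 50)])
        profile = _uniform_profile(toy_manifest, 100)
        assert gene_discoverability(profile, "NOSUCH", cat) is None

    def test_random_fixture_matches_per_variant_tally(self, toy_manifest):
        rng = np.random.default_rng(17)
        variants = [_variant(i, int(rng.integers(1, 301))) for i in range(60)]
        cat = KnownVariantCatalogue(variants)
        reads = [
            AlignedRead("chr1", int(rng.integers(0, 280)), ((OP_ALN, 40),))
            for _ in range(400)
        ]
        profile = compute_depth(reads, toy_manifest)
        g = gene_discoverability(profile, "TOY", cat, threshold=30)
        oracle = sum(
            variant_discoverable(profile, v, 30).discoverable for v in variants
        )
        assert g.n_discoverable == oracle
        assert g.fraction == oracle / g.n_known


class TestSampleReport:
    def test_uniform_coverage_full_discoverability(self, toy_manifest):
        cat = KnownVariantCatalogue([_variant(i, 20 + i) for i in range(10)])
        profile = _uniform_profile(toy_manifest, 100)
        rep = sample_report(profile, toy_manifest, cat)
        assert rep.overall_fraction == 1.0
        assert not rep.needs_review
        assert rep.outside_panel == []

    def test_dropped_amplicon_flags_only_its_gene(self, demo_workspace):
        manifest, catalogue, profile = demo_workspace
        rep = sample_report(profile, manifest, catalogue)
        (gene,) = rep.genes
        assert gene.gene == "GATA1"
        assert (gene.n_known, gene.n_discoverable) == (10, 8)
        assert gene.flagged and rep.needs_review
        non_disc = {
            v.variant_id
            for v in catalogue
            if not variant_discoverable(profile, v).discoverable
        }
        assert non_disc == {"gv02", "gv03"}  # the two exon-2 variants

    def test_overall_is_ratio_of_totals_not_mean_of_fractions(self, toy_manifest):
        variants = [_variant(i, 20 + i) for i in range(8)]
        variants += [
            _variant(90, 250, gene="TOY2"),
            _variant(91, 260, gene="TOY2"),
        ]
        cat = KnownVariantCatalogue(variants)
        reads = [AlignedRead("chr1", 0, ((OP_ALN, 200),)) for _ in range(100)]
        profile = compute_depth(reads, toy_manifest)
        rep = sample_report(profile, toy_manifest, cat)
        total_known = sum(g.n_known for g in rep.genes)
        total_disc = sum(g.n_discoverable for g in rep.genes)
        assert rep.overall_fraction == total_disc / total_known == 0.8

    def test_threshold_monotonicity(self, demo_workspace):
        manifest, catalogue, profile = demo_workspace
        prev = 1.1
        for threshold in (0, 10, 50, 100, 150, 300):
            rep = sample_report(profile, manifest, catalogue, threshold=threshold)
            assert rep.overall_fraction <= prev
            prev = rep.overall_fraction

    def test_threshold_zero_makes_all_in_panel_discoverable(self, demo_workspace):
        manifest, catalogue, profile = demo_workspace
        rep = sample_report(profile, manifest, catalogue, threshold=0)
        assert rep.overall_fraction == 1.0

    def test_adding_reads_never_decreases_fractions(self, toy_manifest):
        rng = np.random.default_rng(23)
        cat = KnownVariantCatalogue(
            [_variant(i, int(rng.integers(1, 301))) for i in range(40)]
        )
        reads = [
            AlignedRead("chr1", int(rng.integers(0, 280)), ((OP_ALN, 40),))
            for _ in range(600)
        ]
        prev = None
        for n in (100, 200, 400, 600):
            profile = compute_depth(reads[:n], toy_manifest)
            rep = sample_report(profile, toy_manifest, cat)
            if prev is not None:
                assert rep.overall_fraction >= prev
            prev = rep.overall_fraction

    def test_empty_catalogue_rejected(self, toy_manifest):
        profile = _uniform_profile(toy_manifest, 10)
        with pytest.raises(ValueError):
            sample_report(profile, toy_manifest, KnownVariantCatalogue([]))


class TestRunSummary:
    def _report(self, manifest, cat, depth, sample_id):
        profile = _uniform_profile(manifest, depth, sample_id=sample_id)
        return sample_report(profile, manifest, cat)

    def test_identical_reports_collapse_distribution(self, toy_manifest):
        cat = KnownVariantCatalogue([_variant(i, 20 + i) for i in range(10)])
        reports = [self._report(toy_manifest, cat, 100, f"s{i}") for i in range(5)]
        summary = run_summary(reports)
        row = summary.per_gene.loc["TOY"]
        assert row["min"] == row["median"] == row["max"] == 1.0
        assert summary.n_samples == 5

    def test_overall_range_across_samples(self, toy_manifest):
        # two samples at overall 0.84 and 0.92 -> range (0.84, 0.92)
        cat = KnownVariantCatalogue(
            [_variant(i, 20 + i) for i in range(25)]
            + [_variant(100 + i, 210 + i) for i in range(75)]
        )
        reads_a = [AlignedRead("chr1", 0, ((OP_ALN, 268),)) for _ in range(100)]
        reads_b = [AlignedRead("chr1", 0, ((OP_ALN, 276),)) for _ in range(100)]
        rep_a = sample_report(compute_depth(reads_a, toy_manifest, sample_id="a"),
                              toy_manifest, cat)
        rep_b = sample_report(compute_depth(reads_b, toy_manifest, sample_id="b"),
                              toy_manifest, cat)
        assert rep_a.overall_fraction == 0.84
        assert rep_b.overall_fraction == 0.92
        assert run_summary([rep_a, rep_b]).overall_range == (0.84, 0.92)

    def test_quantiles_match_sorted_interpolation_oracle(self, toy_manifest):
        rng = np.random.default_rng(29)
        cat = KnownVariantCatalogue([_variant(i, 20 + i) for i in range(50)])
        reports = []
        for i in range(9):
            reads = [
                AlignedRead("chr1", int(rng.integers(0, 250)), ((OP_ALN, 50),))
                for _ in range(int(rng.integers(50, 500)))
            ]
            profile = compute_depth(reads, toy_manifest, sample_id=f"s{i}")
            reports.append(sample_report(profile, toy_manifest, cat))
        summary = run_summary(reports)
        values = sorted(r.genes[0].fraction for r in reports)

        def interp_quantile(sorted_vals, q):
            h = (len(sorted_vals) - 1) * q
            lo, hi = int(np.floor(h)), int(np.ceil(h))
            return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])

        row = summary.per_gene.loc["TOY"]
        for col, q in (("min", 0), ("q1", 0.25), ("median", 0.5),
                       ("q3", 0.75), ("max", 1.0)):
            assert row[col] == pytest.approx(interp_quantile(values, q))

    def test_empty_report_list_rejected(self):
        with pytest.raises(ValueError):
            run_summary([])


class TestGeneTrack:
    def test_uniform_coverage_track_all_pass(self, toy_manifest):
        cat = KnownVariantCatalogue([_variant(1, 50), _variant(2, 250)])
        profile = _uniform_profile(toy_manifest, 100)
        track = gene_coverage_track(
            profile, toy_manifest.genes[0], toy_manifest.amplicons, cat
        )
        assert all(a["passed"] for a in track["amplicons"])
        assert all(m["discoverable"] for m in track["markers"])
        assert track["threshold"] == 30

    def test_dropped_amplicon_topology(self, demo_workspace):
        manifest, catalogue, profile = demo_workspace
        track = gene_coverage_track(
            profile, manifest.genes[0], manifest.amplicons, catalogue
        )
        failed = [a["amplicon_id"] for a in track["amplicons"] if not a["passed"]]
        assert failed == ["GATA1_a02", "GATA1_a07"]
        non_disc = [m["variant_id"] for m in track["markers"] if not m["discoverable"]]
        assert non_disc == ["gv02", "gv03"]

    def test_depth_series_equals_profile_slice(self, demo_workspace):
        manifest, catalogue, profile = demo_workspace
        track = gene_coverage_track(
            profile, manifest.genes[0], manifest.amplicons, catalogue
        )
        start, end = track["span"]
        np.testing.assert_array_equal(
            np.array(track["depth"]),
            profile.depth_slice("chrX", start, end, fill=0),
        )


class TestRendering:
    def test_empty_gene_list_renders_header_only(self, toy_manifest):
        cat = KnownVariantCatalogue([_variant(1, 5000)])  # outside panel
        profile = _uniform_profile(toy_manifest, 100)
        rep = sample_report(profile, toy_manifest, cat)
        tsv = render_report(rep, "tsv")
        assert tsv.splitlines() == [
            "gene\tn_known\tn_discoverable\tpercent_discoverable\tflag"
        ]

    def test_flagged_gene_renders_percent_and_low(self, demo_workspace):
        manifest, catalogue, profile = demo_workspace
        rep = sample_report(profile, manifest, catalogue)
        rep.genes[0] = rep.genes[0].__class__(
            gene="GATA1", n_known=20, n_discoverable=17, fraction=0.85,
            flagged=True, n_outside_panel=0,
        )
        row = render_report(rep, "tsv").splitlines()[1]
        assert "85.0" in row and row.endswith("LOW")

    def test_json_and_tsv_agree_after_round_trip(self, demo_workspace):
        manifest, catalogue, profile = demo_workspace
        rep = sample_report(profile, manifest, catalogue)
        payload = json.loads(render_report(rep, "json"))
        parsed = parse_report_tsv(render_report(rep, "tsv"))
        for json_gene, (_, row) in zip(payload["genes"], parsed.iterrows()):
            assert json_gene["gene"] == row["gene"]
            assert json_gene["fraction"] == row["fraction"]
        assert payload["overall_fraction"] == rep.overall_fraction

    def test_unknown_format_rejected(self, demo_workspace):
        manifest, catalogue, profile = demo_workspace
        rep = sample_report(profile, manifest, catalogue)
        with pytest.raises(ValueError, match="unknown report format"):
            render_report(rep, "xml")
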