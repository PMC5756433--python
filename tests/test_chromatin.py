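import numpy as np
import pytest

from irchrom.core import GenomicInterval, CoverageTrack
from irchrom.events import (
    IntronEvent, call_intron_events, exclude_first_introns,
    match_ie_by_relative_position,
)
from irchrom.chromatin import (
    dhs_content, dhs_bin_profile, gene_coverage_profile,
    coverage_depth_comparison, methylation_profile, classify_genes_by_ir,
)
from irchrom.simulate import SimulationConfig, simulate_dataset


def _event(label, chrom="chr1", base=0, scale=1, strand="+", gene="g", idx=2):
    """An event whose parts are [base, base+100s), [.,+50s), [.,+100s)."""
    return IntronEvent(
        gene_id=gene, intron_index=idx,
        exon5=GenomicInterval(chrom, base, base + 100 * scale, strand),
        intron=GenomicInterval(chrom, base + 100 * scale, base + 150 * scale, strand),
        exon3=GenomicInterval(chrom, base + 150 * scale, base + 250 * scale, strand),
        label=label, relative_position=0.5, is_first_intron=False, strand=strand,
    )


class TestDhsContent:
    def test_fraction_counts(self):
        events = [_event("IR", base=i * 1000, gene=f"g{i}") for i in range(10)]
        events += [_event("IE", base=(i + 20) * 1000, gene=f"h{i}") for i in range(10)]
        peaks = [GenomicInterval("chr1", i * 1000 + 120, i * 1000 + 130)
                 for i in range(3)]  # hit the first 3 IR events
        t = dhs_content(events, peaks)
        assert t.dhs_content_ir == pytest.approx(0.30)
        assert t.dhs_content_ie == 0.0

    def test_no_peaks_gives_zero_content_p_one(self):
        events = [_event("IR"), _event("IE", base=5000, gene="h")]
        t = dhs_content(events, [])
        assert t.dhs_content_ir == t.dhs_content_ie == 0.0
        assert t.p_value == 1.0

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            dhs_content([_event("IR")], [])

    def test_matches_brute_force_pairwise_overlap(self, small_dataset):
        events = exclude_first_introns(
            call_intron_events(small_dataset.models, small_dataset.rna)
        )
        peaks = small_dataset.dhs_peaks
        t = dhs_content(events, peaks)
        for label, n_hit in (("IR", t.ir_overlap), ("IE", t.ie_overlap)):
            brute = sum(
                any(e.span.overlaps(p) for p in peaks)
                for e in events if e.label == label
            )
            assert n_hit == brute

    def test_planted_dhs_assignment_recovered_exactly(self):
        # one non-first intron per gene: no events share exons, so measured
        # content equals the planted truth exactly
        cfg = SimulationConfig(
            seed=55, n_genes=80, introns_per_gene_range=(2, 2),
            dhs_prob_ir=0.5, dhs_prob_ie=0.05,
        )
        ds = simulate_dataset(cfg)
        events = exclude_first_introns(call_intron_events(ds.models, ds.rna))
        t = dhs_content(events, ds.dhs_peaks)
        truth_ir = np.mean([ds.dhs_truth[e.uid] for e in events if e.label == "IR"])
        truth_ie = np.mean([ds.dhs_truth[e.uid] for e in events if e.label == "IE"])
        assert t.dhs_content_ir == pytest.approx(truth_ir, abs=1e-12)
        assert t.dhs_content_ie == pytest.approx(truth_ie, abs=1e-12)


class TestBinProfile:
    def test_event_inside_peak_gives_all_ones(self):
        events = [_event("IR"), _event("IE", base=5000, gene="h")]
        peaks = [GenomicInterval("chr1", 0, 6000)]
        prof = dhs_bin_profile(events, peaks)
        assert (prof["IR"].values == 1.0).all()
        assert (prof["IE"].values == 1.0).all()

    def test_peak_only_in_exon3(self):
        events = [_event("IR"), _event("IE", base=5000, gene="h")]
        peaks = [GenomicInterval("chr1", 160, 240)]  # inside IR exon3 only
        prof = dhs_bin_profile(events, peaks)
        assert prof["IR"].values[2].sum() > 0
        assert prof["IR"].values[0].sum() == 0
        assert prof["IR"].values[1].sum() == 0
        assert prof["IE"].values.sum() == 0

    def test_length_normalization_invariance(self):
        """Uniformly scaling all part lengths leaves the profile unchanged."""
        e1 = [_event("IR", scale=1), _event("IE", base=5000, gene="h", scale=1)]
        e3 = [_event("IR", scale=3), _event("IE", base=5000, gene="h", scale=3)]
        p1 = [GenomicInterval("chr1", 120, 180)]
        p3 = [GenomicInterval("chr1", 360, 540)]
        prof1 = dhs_bin_profile(e1, p1)
        prof3 = dhs_bin_profile(e3, p3)
        np.testing.assert_array_equal(prof1["IR"].values, prof3["IR"].values)

    def test_degenerate_short_part_contributes_whole_part(self):
        e = IntronEvent(
            gene_id="g", intron_index=2,
            exon5=GenomicInterval("chr1", 0, 100),
            intron=GenomicInterval("chr1", 100, 104),  # shorter than 10 bins
            exon3=GenomicInterval("chr1", 104, 200),
            label="IR", relative_position=0.5, is_first_intron=False, strand="+",
        )
        ie = _event("IE", base=5000, gene="h")
        peaks = [GenomicInterval("chr1", 100, 104)]
        prof = dhs_bin_profile([e, ie], peaks)
        assert (prof["IR"].values[1] == 1.0).all()  # all intron bins hit

    def test_minus_strand_bins_are_transcript_oriented(self):
        plus = _event("IR")
        minus = IntronEvent(
            gene_id="m", intron_index=2,
            exon5=GenomicInterval("chr1", 150, 250, "-"),
            intron=GenomicInterval("chr1", 100, 150, "-"),
            exon3=GenomicInterval("chr1", 0, 100, "-"),
            label="IR", relative_position=0.5, is_first_intron=False, strand="-",
        )
        ie = _event("IE", base=5000, gene="h")
        # peak at the transcript-5' tip of the 5' exon in both cases
        prof_p = dhs_bin_profile([plus, ie], [GenomicInterval("chr1", 0, 10)])
        prof_m = dhs_bin_profile([minus, ie], [GenomicInterval("chr1", 240, 250)])
        np.testing.assert_array_equal(prof_p["IR"].values, prof_m["IR"].values)


class TestGeneCoverageProfile:
    def test_constant_coverage_recovered(self, two_intron_gene):
        dnase = CoverageTrack({"chr1": np.full(6500, 5.0)})
        profs = gene_coverage_profile([two_intron_gene], [], dnase)
        df = profs["no_ir"]
        inside = df[(df.position >= 0) & (df.position < 400)]
        assert (inside.mean_coverage == 5.0).all()
        beyond = df[df.position >= 400]  # past the gene end: no contribution
        assert beyond.n_genes.sum() == 0

    def test_group_priority_first_intron_wins(self, two_intron_gene):
        events = [
            IntronEvent(
                gene_id="gA", intron_index=1,
                exon5=two_intron_gene.exons[0],
                intron=two_intron_gene.introns[0],
                exon3=two_intron_gene.exons[1],
                label="IR", relative_position=0.3,
                is_first_intron=True, strand="+",
            ),
            IntronEvent(
                gene_id="gA", intron_index=2,
                exon5=two_intron_gene.exons[1],
                intron=two_intron_gene.introns[1],
                exon3=two_intron_gene.exons[2],
                label="IR", relative_position=0.7,
                is_first_intron=False, strand="+",
            ),
        ]
        groups = classify_genes_by_ir([two_intron_gene], events)
        assert groups["gA"] == "ir_first_intron"

    def test_promoter_peak_shows_up_near_tss(self, small_dataset):
        profs = gene_coverage_profile(
            small_dataset.models,
            call_intron_events(small_dataset.models, small_dataset.rna),
            small_dataset.dnase,
        )
        pooled = None
        for df in profs.values():
            w = df.mean_coverage.fillna(0) * df.n_genes
            pooled = w if pooled is None else pooled + w
        positions = profs["no_ir"].position.to_numpy()
        peak_pos = positions[int(np.nanargmax(pooled.to_numpy()))]
        assert -200 <= peak_pos <= 200


class TestDepthComparison:
    def test_exact_small_sample(self):
        events_ir = [_event("IR", base=i * 1000, gene=f"g{i}") for i in range(3)]
        events_ie = [_event("IE", base=(i + 10) * 1000, gene=f"h{i}") for i in range(3)]
        cov = np.zeros(20000)
        for i, e in enumerate(events_ir):
            cov[e.span.start:e.span.end] = i + 1  # means 1,2,3
        for i, e in enumerate(events_ie):
            cov[e.span.start:e.span.end] = i + 4  # means 4,5,6
        dnase = CoverageTrack({"chr1": cov})
        ir_m, ie_m, u, p = coverage_depth_comparison(events_ir, events_ie, dnase)
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_empty_class_is_error(self):
        with pytest.raises(ValueError):
            coverage_depth_comparison([], [_event("IE")], None)

    def test_dhs_enriched_ir_has_higher_coverage(self, small_dataset):
        events = exclude_first_introns(
            call_intron_events(small_dataset.models, small_dataset.rna)
        )
        ir = [e for e in events if e.label == "IR"]
        ie = match_ie_by_relative_position(
            ir, [e for e in events if e.label == "IE"]
        )
        ir_m, ie_m, _, p = coverage_depth_comparison(ir, ie, small_dataset.dnase)
        assert ir_m.mean() > ie_m.mean()
        assert p < 0.01


class TestMethylationProfile:
    def test_fully_methylated_gives_all_ones(self):
        events = [_event("IR"), _event("IE", base=5000, gene="h")]
        n = 6000
        track = CoverageTrack(
            {"chr1": np.ones(n)}, assay="methylation",
            counts={"chr1": np.full(n, 5)},
        )
        prof = methylation_profile(events, track)
        assert (prof["IR"].values == 1.0).all()

    def test_empty_bin_is_missing(self):
        events = [_event("IR"), _event("IE", base=5000, gene="h")]
        vals = np.full(6000, np.nan)
        counts = np.zeros(6000, dtype=int)
        vals[:250], counts[:250] = 0.5, 3  # IR event covered, IE not
        track = CoverageTrack({"chr1": vals}, assay="methylation",
                              counts={"chr1": counts})
        prof = methylation_profile(events, track)
        assert not np.isnan(prof["IR"].values).any()
        assert np.isnan(prof["IE"].values).all()

    def test_weighting_by_read_count(self):
        events = [_event("IR"), _event("IE", base=5000, gene="h")]
        vals = np.full(6000, np.nan)
        counts = np.zeros(6000, dtype=int)
        # two cytosines in one intron bin: 0.0 with weight 9, 1.0 with weight 1
        vals[100], counts[100] = 0.0, 9
        vals[101], counts[101] = 1.0, 1
        track = CoverageTrack({"chr1": vals}, assay="methylation",
                              counts={"chr1": counts})
        prof = methylation_profile(events, track)
        assert prof["IR"].values[1, 0] == pytest.approx(0.1)

    def test_ir_exon3_hypomethylation_on_synthetic_data(self, small_dataset):
        events = exclude_first_introns(
            call_intron_events(small_dataset.models, small_dataset.rna)
        )
        prof = methylation_profile(events, small_dataset.methylation)
        ir3 = np.nanmean(prof["IR"].values[2])
        ie3 = np.nanmean(prof["IE"].values[2])
        assert ir3 < ie3  # Beta(2,8) mean 0.2 vs Beta(5,5) mean 0.5
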