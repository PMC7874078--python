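import math

import numpy as np
import pytest

from atackit import annotation as ann
from atackit import intervals as iv
from atackit import peaks as pk
from atackit import profiles as pr
from atackit.alignments import Fragment, GenomeIndex


def feature_set_from(features, genome):
    """Build a FeatureSet directly from {name: {contig: intervals}}."""
    full = {name: {} for name in ann.FEATURE_NAMES}
    for name, per in features.items():
        full[name] = {c: iv.merge(arr) for c, arr in per.items()}
    sizes = {name: sum(iv.total_length(a) for a in full[name].values())
             for name in ann.FEATURE_NAMES}
    return ann.FeatureSet(features=full, sizes=sizes)


class TestFoldEnrichment:
    def test_proportional_overlap_is_zero(self):
        genome = GenomeIndex((("chr1", 1000),))
        peaks = [pk.Peak(contig="chr1", start=0, end=100)]
        fset = feature_set_from({"exon": {"chr1": [(80, 280)]}}, genome)
        res = pr.fold_enrichment(peaks, fset, genome)
        row = res["exon"]
        assert (row.s_p, row.s_gf, row.s_pf) == (100, 200, 20)
        assert row.log2_enrichment == 0.0

    def test_double_overlap_is_one(self):
        genome = GenomeIndex((("chr1", 1000),))
        peaks = [pk.Peak(contig="chr1", start=0, end=100)]
        fset = feature_set_from({"exon": {"chr1": [(60, 260)]}}, genome)
        row = pr.fold_enrichment(peaks, fset, genome)["exon"]
        assert row.s_pf == 40
        assert row.log2_enrichment == pytest.approx(1.0)

    def test_matches_per_base_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(5_000, 100_000))
            genome = GenomeIndex((("chr1", n),))
            def rand_ivs(k, w):
                starts = rng.integers(0, n - w, k)
                return [(int(s), int(s) + int(rng.integers(10, w))) for s in starts]
            peaks = [pk.Peak(contig="chr1", start=s, end=e) for s, e in rand_ivs(8, 500)]
            feat = rand_ivs(6, 800)
            fset = feature_set_from({"exon": {"chr1": feat}}, genome)
            res = pr.fold_enrichment(peaks, fset, genome)["exon"]

            pmask = np.zeros(n, bool)
            for p in peaks:
                pmask[p.start:p.end] = True
            fmask = np.zeros(n, bool)
            for s, e in feat:
                fmask[s:e] = True
            s_p, s_gf = pmask.sum(), fmask.sum()
            s_pf = (pmask & fmask).sum()
            if res.defined:
                expected = math.log2((s_pf / s_p) / (s_gf / n))
                assert res.log2_enrichment == pytest.approx(expected, abs=1e-12)
            assert (res.s_p, res.s_gf, res.s_pf) == (s_p, s_gf, s_pf)

    def test_peak_permutation_invariant(self):
        genome = GenomeIndex((("chr1", 1000),))
        peaks = [pk.Peak(contig="chr1", start=0, end=100),
                 pk.Peak(contig="chr1", start=300, end=360)]
        fset = feature_set_from({"exon": {"chr1": [(50, 320)]}}, genome)
        a = pr.fold_enrichment(peaks, fset, genome)["exon"]
        b = pr.fold_enrichment(peaks[::-1], fset, genome)["exon"]
        assert a == b

    def test_doubling_overlap_adds_one(self):
        # antisymmetry of the log2 ratio in S_Pf
        genome = GenomeIndex((("chr1", 10_000),))
        peaks = [pk.Peak(contig="chr1", start=0, end=400)]
        f1 = feature_set_from({"exon": {"chr1": [(300, 1300)]}}, genome)   # overlap 100
        f2 = feature_set_from({"exon": {"chr1": [(200, 1200)]}}, genome)   # overlap 200
        e1 = pr.fold_enrichment(peaks, f1, genome)["exon"].log2_enrichment
        e2 = pr.fold_enrichment(peaks, f2, genome)["exon"].log2_enrichment
        assert e2 - e1 == pytest.approx(1.0)

    def test_zero_overlap_undefined_not_inf(self):
        genome = GenomeIndex((("chr1", 1000),))
        peaks = [pk.Peak(contig="chr1", start=0, end=100)]
        fset = feature_set_from({"exon": {"chr1": [(500, 600)]}}, genome)
        row = pr.fold_enrichment(peaks, fset, genome)["exon"]
        assert not row.defined and math.isnan(row.log2_enrichment)

    def test_empty_peaks_rejected(self, small_genome):
        fset = feature_set_from({}, small_genome)
        with pytest.raises(ValueError, match="no peaks"):
            pr.fold_enrichment([], fset, small_genome)


def uniform_coverage(genome, depth=1.0, total=1000):
    cov = {c: np.full(l, float(depth)) for c, l in genome.contigs}
    return pk.CoverageTrack(depth=cov, mode="full_fragment", total_units=total,
                            genome=genome)


def gene(gid, contig, start, end, strand="+"):
    return ann.GeneModel(gid, contig, start, end, strand, iv.as_array([(start, end)]),
                         iv.EMPTY.copy(), iv.EMPTY.copy(), iv.EMPTY.copy())


class TestSignalMatrix:
    def test_uniform_depth_flat(self, small_genome):
        cov = uniform_coverage(small_genome)
        genes = [gene("g1", "chr1", 3000, 5000)]
        sm = pr.signal_matrix(cov, genes, "gene_scaled", flank=1000, bin_width=10)
        assert np.allclose(sm.matrix, sm.matrix[0, 0])
        assert np.allclose(sm.metaplot, sm.metaplot[0])

    def test_column_count(self, small_genome):
        cov = uniform_coverage(small_genome)
        sm = pr.signal_matrix(cov, [gene("g1", "chr1", 3000, 5000)],
                              "gene_scaled", 1000, 10, body_bins=100)
        assert sm.matrix.shape == (1, 100 + 100 + 100)

    def test_minus_strand_orientation(self, small_genome):
        cov = uniform_coverage(small_genome)
        # gradient depth: higher downstream in genomic coords
        cov.depth["chr1"] = np.arange(10_000, dtype=float)
        plus = pr.signal_matrix(cov, [gene("g", "chr1", 4000, 6000, "+")],
                                "gene_scaled", 1000, 10)
        minus = pr.signal_matrix(cov, [gene("g", "chr1", 4000, 6000, "-")],
                                 "gene_scaled", 1000, 10)
        assert np.allclose(minus.matrix[0], plus.matrix[0][::-1])

    def test_peak_centered_window(self, small_genome):
        cov = uniform_coverage(small_genome)
        peaks = [pk.Peak(contig="chr1", start=4000, end=4400, summit=4200)]
        sm = pr.signal_matrix(cov, peaks, "peak_centered", flank=500, bin_width=10)
        assert sm.matrix.shape == (1, 100)

    def test_promoter_planted_signal_peaks_upstream(self, small_genome):
        g = gene("g1", "chr1", 4000, 6000, "+")
        cov = uniform_coverage(small_genome, depth=0.0)
        cov.depth["chr1"][3000:4000] = 5.0  # accessibility only in the promoter
        sm = pr.signal_matrix(cov, [g], "gene_scaled", 1000, 10)
        assert int(np.argmax(sm.metaplot)) < sm.flank_bins

    def test_conservation_bin_width_one(self, small_genome, frag_factory):
        frags = frag_factory([(3500, 3700), (4100, 4900), (4500, 5100)])
        cov = pk.make_coverage(frags, small_genome)
        g = gene("g1", "chr1", 4000, 5000)
        sm = pr.signal_matrix(cov, [g], "gene_scaled", flank=1000, bin_width=1,
                              body_bins=1000)
        # undo RPKM normalization: value = raw / (binlen_kb) / (units/1e6)
        raw = sm.matrix[0] * (1 / 1000.0) * (cov.total_units / 1e6)
        window_bp = sum(min(f.end, 6000) - max(f.start, 3000) for f in frags)
        assert raw.sum() == pytest.approx(window_bp)

    def test_heatmap_ranking(self, small_genome):
        cov = uniform_coverage(small_genome, depth=0.0)
        cov.depth["chr1"][4000:5000] = 9.0
        genes = [gene("cold", "chr1", 7000, 8000), gene("hot", "chr1", 4000, 5000)]
        sm = pr.signal_matrix(cov, genes, "gene_scaled", 1000, 10)
        assert sm.sorted_by_mean().anchors[0] == "hot"

    def test_zero_length_body_rejected(self, small_genome):
        cov = uniform_coverage(small_genome)
        bad = gene("g", "chr1", 4000, 4000 + 1)
        bad.end = bad.start  # force zero-length
        with pytest.raises(ValueError):
            pr.signal_matrix(cov, [bad], "gene_scaled", 1000, 10)

    def test_bad_bin_width_rejected(self, small_genome):
        cov = uniform_coverage(small_genome)
        with pytest.raises(ValueError):
            pr.signal_matrix(cov, [gene("g", "chr1", 0, 100)], "gene_scaled",
                             1000, 7)


class TestJunctionTrack:
    @pytest.mark.parametrize("length,cls,color", [
        (149, "nfr", (0, 0, 255)),
        (150, "nucleosomal", (255, 0, 0)),
        (151, "nucleosomal", (255, 0, 0)),
    ])
    def test_length_classes(self, length, cls, color):
        (rec,) = pr.junction_track([Fragment("chr1", 0, length, "+")])
        assert rec.cls == cls and rec.color == color

    def test_single_end_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            pr.junction_track([Fragment("chr1", 0, 100, "+")], paired=False)

    def test_bed12_round_trip(self, tmp_path):
        frags = [Fragment("chr1", 0, 149, "+"), Fragment("chr1", 500, 800, "-"),
                 Fragment("chr2", 10, 160, "+")]
        records = pr.junction_track(frags)
        path = tmp_path / "j.bed12"
        pr.junctions_to_bed12(records, path)
        loaded = pr.parse_bed12_junctions(path)
        for a, b in zip(records, loaded):
            assert (a.contig, a.start, a.end, a.length, a.cls, a.color) == \
                   (b.contig, b.start, b.end, b.length, b.cls, b.color)

    def test_bed12_block_structure(self, tmp_path):
        pr.junctions_to_bed12(pr.junction_track([Fragment("chr1", 100, 400, "+")]),
                              tmp_path / "j.bed")
        fields = (tmp_path / "j.bed").read_text().strip().split("\t")
        assert fields[4] == "300"            # score = min(length, 1000)
        assert fields[8] == "255,0,0"        # itemRgb
        assert fields[9] == "2" and fields[10] == "1,1"
        assert fields[11] == "0,299"

    def test_score_capped(self, tmp_path):
        pr.junctions_to_bed12(pr.junction_track([Fragment("chr1", 0, 1500, "+")]),
                              tmp_path / "j.bed")
        assert (tmp_path / "j.bed").read_text().split("\t")[4] == "1000"
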