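"""QC filtering, substitution classes, genomic-context and coding-effect annotation."""

import itertools

import numpy as np
import pytest

import snpcore as sc
from snpcore.errors import UndefinedValueError, ValidationError
from snpcore.model import AnnotationClass
from snpcore.qc import AnnotationIntervals

from conftest import H1, H2, HT, M, make_matrix


class TestMissingAndMaf:
    def test_missing_rate_counts(self):
        gm = make_matrix([[H1], [M], [M], [M], [H2], [H1], [H1], [H1], [H1], [H1]])
        assert sc.missing_rate(gm, "M001") == pytest.approx(0.3)

    def test_missing_rate_zero(self):
        gm = make_matrix([[H1]] * 10)
        assert sc.missing_rate(gm, "M001") == 0.0

    def test_maf_monomorphic(self):
        gm = make_matrix([[H1]] * 10)
        assert sc.minor_allele_frequency(gm, "M001") == 0.0

    def test_maf_balanced(self):
        gm = make_matrix([[H1]] * 5 + [[H2]] * 5)
        assert sc.minor_allele_frequency(gm, "M001") == 0.5

    def test_maf_with_het_contribution(self):
        """6 HOM1 + 3 HOM2 + 1 HET -> alleles 13:7 -> MAF 0.35."""
        gm = make_matrix([[H1]] * 6 + [[H2]] * 3 + [[HT]])
        assert sc.minor_allele_frequency(gm, "M001") == pytest.approx(0.35)

    def test_maf_all_missing_errors(self):
        gm = make_matrix([[M], [M]])
        with pytest.raises(UndefinedValueError):
            sc.minor_allele_frequency(gm, "M001")

    def test_random_panel_matches_brute_force(self, synth_panel):
        gm, _, _ = synth_panel
        for mid in gm.marker_ids[::97]:
            col = gm.column(mid)
            assert sc.missing_rate(gm, mid) == (col == M).sum() / len(col)
            c1 = 2 * (col == H1).sum() + (col == HT).sum()
            c2 = 2 * (col == H2).sum() + (col == HT).sum()
            assert sc.minor_allele_frequency(gm, mid) == pytest.approx(
                min(c1, c2) / (c1 + c2)
            )


class TestApplyFilters:
    def test_boundary_maf_dropped(self):
        """MAF exactly at the threshold fails the strict > rule."""
        calls = [[H1]] * 19 + [[H2]]  # MAF = 2/40 = 0.05
        gm = make_matrix(calls)
        kept, report = sc.apply_filters(gm, sc.FilterConfig())
        assert kept.n_markers == 0
        assert report.loc[0, "first_fail_rule"] == "maf"

    def test_boundary_missing_dropped(self):
        calls = [[M]] * 3 + [[H1]] * 4 + [[H2]] * 3  # missing = 0.30, MAF fine
        gm = make_matrix(calls)
        kept, report = sc.apply_filters(gm, sc.FilterConfig())
        assert kept.n_markers == 0
        assert report.loc[0, "first_fail_rule"] == "missing"

    def test_depth_rule(self):
        calls = np.array([[H1], [H2], [H1], [H2]], dtype=np.int8)
        depth = np.array([[10], [2], [10], [10]])
        gm = make_matrix(calls, depth=depth)
        kept, report = sc.apply_filters(gm, sc.FilterConfig())
        assert kept.n_markers == 0
        assert report.loc[0, "first_fail_rule"] == "depth"
        relaxed = sc.FilterConfig(min_depth_fraction=0.7)
        kept2, _ = sc.apply_filters(gm, relaxed)
        assert kept2.n_markers == 1

    def test_retained_set_matches_re_evaluation(self, synth_panel):
        gm, _, _ = synth_panel
        cfg = sc.FilterConfig()
        kept, report = sc.apply_filters(gm, cfg)
        expected = [
            mid
            for mid in gm.marker_ids
            if sc.missing_rate(gm, mid) < cfg.max_missing
            and sc.minor_allele_frequency(gm, mid) > cfg.min_maf
        ]
        assert kept.marker_ids == expected
        assert report["kept"].sum() == len(expected)
        assert (report.loc[~report["kept"], "first_fail_rule"] != "").all()

    def test_idempotent(self, synth_panel):
        gm, _, _ = synth_panel
        once, _ = sc.apply_filters(gm)
        twice, report = sc.apply_filters(once)
        assert twice.marker_ids == once.marker_ids
        assert report["kept"].all()


class TestSubstitutionType:
    def test_exhaustive_pair_classes(self):
        """All 6 unordered nucleotide pairs: 2 transitions, 4 transversions."""
        classes = {
            frozenset(p): sc.substitution_type(*p)
            for p in itertools.combinations("ACGT", 2)
        }
        assert classes[frozenset("AG")] == "transition"
        assert classes[frozenset("CT")] == "transition"
        assert sum(v == "transversion" for v in classes.values()) == 4

    def test_symmetric(self):
        for a, b in itertools.permutations("ACGT", 2):
            assert sc.substitution_type(a, b) == sc.substitution_type(b, a)

    def test_identical_alleles_rejected(self):
        with pytest.raises(ValidationError):
            sc.substitution_type("A", "A")

    def test_tstv_ratio(self):
        def mk(n_ts, n_tv):
            markers = [
                sc.MarkerRecord(f"ts{i}", "chr1", i + 1, "A", "G") for i in range(n_ts)
            ] + [
                sc.MarkerRecord(f"tv{i}", "chr1", 1000 + i, "A", "T") for i in range(n_tv)
            ]
            return sc.tstv_ratio(markers)

        assert mk(2, 1) == pytest.approx(2.0)
        assert mk(169, 100) == pytest.approx(1.69)
        with pytest.raises(UndefinedValueError):
            mk(3, 0)


def _toy_annotation():
    """5 genes on chr1 with CDS/UTR/intron structure; 1 kb flanks."""
    ann = AnnotationIntervals(updown_bp=1000)
    # gene: (start, end, strand, cds intervals, utr intervals)
    genes = [
        (10_000, 12_000, "+", [(10_200, 10_800), (11_200, 11_800)], [(10_000, 10_199)]),
        (20_000, 21_000, "-", [(20_100, 20_900)], [(20_901, 21_000)]),
        (30_000, 33_000, "+", [(30_500, 31_000)], []),
        (40_000, 41_000, "+", [(40_000, 41_000)], []),
        (50_000, 50_500, "-", [(50_000, 50_400)], [(50_401, 50_500)]),
    ]
    for start, end, strand, cds, utr in genes:
        ann.add_gene("chr1", start, end, strand)
        for s, e in cds:
            AnnotationIntervals._add(ann.cds, "chr1", s, e, (strand, 0))
        for s, e in utr:
            AnnotationIntervals._add(ann.utr, "chr1", s, e)
    return ann, genes


def _brute_force_class(pos, genes, updown=1000):
    in_cds = any(s <= pos <= e for *_, cds, _u in genes for s, e in cds)
    in_utr = any(s <= pos <= e for *_, utr in genes for s, e in utr)
    in_gene = any(s <= pos <= e for s, e, *_ in genes)
    up = down = False
    for s, e, strand, *_ in genes:
        before = s - updown <= pos <= s - 1
        after = e + 1 <= pos <= e + updown
        if strand == "+":
            up |= before
            down |= after
        else:
            up |= after
            down |= before
    if in_cds:
        return AnnotationClass.CDS
    if in_utr:
        return AnnotationClass.UTR
    if in_gene:
        return AnnotationClass.INTRON
    if up and down:
        return AnnotationClass.UP_DOWNSTREAM
    if up:
        return AnnotationClass.UPSTREAM
    if down:
        return AnnotationClass.DOWNSTREAM
    return AnnotationClass.INTERGENIC


class TestClassifyLocation:
    def test_cds_containment(self):
        ann, _ = _toy_annotation()
        m = sc.MarkerRecord("m", "chr1", 10_500, "A", "G")
        assert sc.classify_location(m, ann) == AnnotationClass.CDS

    def test_no_interval_is_intergenic(self):
        ann, _ = _toy_annotation()
        m = sc.MarkerRecord("m", "chr1", 5_000, "A", "G")
        assert sc.classify_location(m, ann) == AnnotationClass.INTERGENIC

    def test_unknown_chromosome_is_intergenic(self):
        ann, _ = _toy_annotation()
        m = sc.MarkerRecord("m", "chr9", 10_500, "A", "G")
        assert sc.classify_location(m, ann) == AnnotationClass.INTERGENIC

    def test_50_random_positions_match_interval_scan(self):
        ann, genes = _toy_annotation()
        rng = np.random.default_rng(2)
        for pos in rng.integers(1, 60_000, size=50):
            m = sc.MarkerRecord("m", "chr1", int(pos), "A", "G")
            assert sc.classify_location(m, ann) == _brute_force_class(int(pos), genes), pos

    def test_every_marker_gets_exactly_one_class(self, synth_panel):
        gm, _, _ = synth_panel
        ann, _ = _toy_annotation()
        classes = sc.qc.annotate_markers(gm, ann)
        assert len(classes) == gm.n_markers
        assert all(isinstance(c, AnnotationClass) for c in classes)

    def test_gff3_round_trip(self, tmp_path):
        gff = tmp_path / "ann.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t10000\t12000\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\tCDS\t10200\t10800\t.\t+\t0\tParent=g1\n"
            "chr1\tsrc\tfive_prime_UTR\t10000\t10199\t.\t+\t.\tParent=g1\n"
        )
        ann = AnnotationIntervals.from_gff3(gff)
        for pos, expected in [
            (10_500, AnnotationClass.CDS),
            (10_100, AnnotationClass.UTR),
            (11_500, AnnotationClass.INTRON),
            (9_500, AnnotationClass.UPSTREAM),
            (12_500, AnnotationClass.DOWNSTREAM),
        ]:
            m = sc.MarkerRecord("m", "chr1", pos, "A", "G")
            assert sc.classify_location(m, ann) == expected, pos


# standard genetic code, written out independently for the oracle
_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_RC = str.maketrans("ACGT", "TGCA")


class TestCodingEffect:
    def test_synonymous_third_position(self):
        """GGA -> GGG is Gly -> Gly."""
        m = sc.MarkerRecord("m", "chr1", 3, "A", "G")
        assert sc.coding_effect(m, "GGA", cds_start=1) == "synonymous"

    def test_nonsynonymous_third_position(self):
        """ATG -> ATA is Met -> Ile."""
        m = sc.MarkerRecord("m", "chr1", 3, "G", "A")
        assert sc.coding_effect(m, "ATG", cds_start=1) == "nonsynonymous"

    def test_stop_gain_is_nonsynonymous(self):
        """TGG -> TGA (Trp -> stop)."""
        m = sc.MarkerRecord("m", "chr1", 3, "G", "A")
        assert sc.coding_effect(m, "TGG", cds_start=1) == "nonsynonymous"

    def test_minus_strand_uses_reverse_complement(self):
        # genomic forward TCC at 1..3; coding strand (-) reads GGA; the
        # marker T>C at genomic pos 1 is A>G at codon position 3: Gly->Gly
        m = sc.MarkerRecord("m", "chr1", 1, "T", "C")
        assert sc.coding_effect(m, "TCC", cds_start=1, strand="-") == "synonymous"

    def test_outside_cds_rejected(self):
        m = sc.MarkerRecord("m", "chr1", 50, "A", "G")
        with pytest.raises(ValidationError, match="outside"):
            sc.coding_effect(m, "GGA", cds_start=1)

    def test_ambiguous_base_rejected(self):
        m = sc.MarkerRecord("m", "chr1", 1, "A", "G")
        with pytest.raises(ValidationError, match="ambiguous"):
            sc.coding_effect(m, "NGA", cds_start=1)

    def test_random_substitutions_match_translation_oracle(self):
        rng = np.random.default_rng(9)
        nucs = "ACGT"
        for _ in range(100):
            cds = "".join(rng.choice(list(nucs), size=9))
            pos0 = int(rng.integers(0, 9))
            a1 = cds[pos0]
            a2 = rng.choice([n for n in nucs if n != a1])
            strand = rng.choice(["+", "-"])
            if strand == "+":
                m = sc.MarkerRecord("m", "chr1", pos0 + 1, a1, a2)
                coding, off = cds, pos0
                b1, b2 = a1, a2
            else:
                m = sc.MarkerRecord("m", "chr1", pos0 + 1, a1, a2)
                coding = cds[::-1].translate(_RC)
                off = len(cds) - 1 - pos0
                b1, b2 = a1.translate(_RC), a2.translate(_RC)
            ci = (off // 3) * 3
            w = off % 3
            codon = coding[ci : ci + 3]
            aa1 = _CODE[codon[:w] + b1 + codon[w + 1 :]]
            aa2 = _CODE[codon[:w] + b2 + codon[w + 1 :]]
            expected = "synonymous" if aa1 == aa2 else "nonsynonymous"
            assert sc.coding_effect(m, cds, cds_start=1, strand=strand) == expected
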