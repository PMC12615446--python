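import numpy as np
import pytest

from fusionkit import junction_annotation as ja
from fusionkit.io_formats import Annotation, FusionCall, Genome, Transcript, revcomp
from tests.conftest import make_call


class TestLocality:
    def test_different_chromosomes(self):
        assert ja.classify_locality(make_call(chrom5="c1", chrom3="c2")) == "interchromosomal"

    def test_same_chromosome(self):
        assert ja.classify_locality(make_call(chrom5="c1", chrom3="c1")) == "intrachromosomal"

    def test_readthrough_opposite_strands_is_intrachromosomal(self):
        call = make_call(chrom5="c1", strand5="+", chrom3="c1", strand3="-")
        assert ja.classify_locality(call) == "intrachromosomal"


class TestBoundaryClass:
    def test_both(self, toy_annotation):
        # bp5 at gA exon end, bp3 at gB exon start
        call = make_call(bp5=200, bp3=401)
        assert ja.breakpoint_boundary_class(call, toy_annotation) == "both"

    def test_one(self, toy_annotation):
        call = make_call(bp5=150, bp3=401)  # bp5 mid-exon
        assert ja.breakpoint_boundary_class(call, toy_annotation) == "one"

    def test_none(self, toy_annotation):
        call = make_call(bp5=150, bp3=420)
        assert ja.breakpoint_boundary_class(call, toy_annotation) == "none"

    def test_unknown_gene_error(self, toy_annotation):
        with pytest.raises(KeyError, match="gX"):
            ja.breakpoint_boundary_class(make_call(gene5="gX"), toy_annotation)

    def test_minus_strand_edges_enumerated(self, toy_annotation):
        # gC: minus strand, exons (1001,1150) and (1301,1400).
        # Hand enumeration: 5'-side boundaries are the transcriptional exon
        # ends = genomic starts {1001, 1301}; 3'-side boundaries are the
        # transcriptional exon starts = genomic ends {1150, 1400}.
        edges = [1001, 1150, 1301, 1400]
        for bp5 in edges:
            call = make_call(gene5="gC", chrom5="c1", strand5="-", bp5=bp5, bp3=420)
            expected = "one" if bp5 in (1001, 1301) else "none"
            assert ja.breakpoint_boundary_class(call, toy_annotation) == expected
        for bp3 in edges:
            call = make_call(gene3="gC", chrom3="c1", strand3="-", bp3=bp3, bp5=150)
            expected = "one" if bp3 in (1150, 1400) else "none"
            assert ja.breakpoint_boundary_class(call, toy_annotation) == expected


def _genome_with(positions: dict[int, str], chrom="c1", length=200) -> Genome:
    seq = list("A" * length)
    # background alternates to avoid accidental homology
    for i in range(length):
        seq[i] = "ACGT"[i % 4]
    for pos, base in positions.items():
        seq[pos - 1] = base
    return Genome({chrom: "".join(seq)})


class TestMotifs:
    def test_plus_plus_canonical(self):
        # (bp5+1, bp5+2) == ("G","T") and (bp3-2, bp3-1) == ("A","G")
        g1 = _genome_with({51: "G", 52: "T"})
        g = Genome({"c1": g1.sequences["c1"], "c2": _genome_with({98: "A", 99: "G"}).sequences["c1"]})
        call = make_call(chrom5="c1", bp5=50, strand5="+", chrom3="c2", bp3=100, strand3="+")
        donor, acceptor, canonical = ja.extract_junction_motifs(call, g)
        assert (donor, acceptor, canonical) == ("GT", "AG", True)

    def test_minus_strand_donor_reverse_complement(self):
        # genomic (bp5-2, bp5-1) == ("A", "C") -> donor revcomp("AC") == "GT"
        g = _genome_with({48: "A", 49: "C"})
        call = make_call(chrom5="c1", bp5=50, strand5="-", chrom3="c1", bp3=100, strand3="+")
        donor, _, _ = ja.extract_junction_motifs(call, g)
        assert donor == "GT"

    def test_minus_strand_acceptor_reverse_complement(self):
        # genomic (bp3+1, bp3+2) == ("C", "T") -> acceptor revcomp("CT") == "AG"
        g = _genome_with({101: "C", 102: "T"})
        call = make_call(chrom5="c1", bp5=50, strand5="+", chrom3="c1", bp3=100, strand3="-")
        _, acceptor, _ = ja.extract_junction_motifs(call, g)
        assert acceptor == "AG"

    def test_ga_ag_not_canonical(self):
        g = _genome_with({51: "G", 52: "A", 98: "A", 99: "G"})
        call = make_call(chrom5="c1", bp5=50, strand5="+", chrom3="c1", bp3=100, strand3="+")
        donor, acceptor, canonical = ja.extract_junction_motifs(call, g)
        assert (donor, acceptor) == ("GA", "AG")
        assert canonical is False

    def test_contig_edge_error(self):
        g = Genome({"c1": "ACGTACGT"})
        call = make_call(chrom5="c1", bp5=7, strand5="+", chrom3="c1", bp3=5, strand3="+")
        with pytest.raises(ValueError, match="contig edge"):
            ja.extract_junction_motifs(call, g)

    def test_mirror_property(self):
        # minus-strand extraction equals plus-strand extraction on the
        # reverse-complemented chromosome with mirrored coordinates
        rng = np.random.default_rng(11)
        for _ in range(50):
            L = 400
            seq = "".join(rng.choice(list("ACGT"), size=L))
            g = Genome({"c1": seq})
            g_mirror = Genome({"c1": revcomp(seq)})
            bp5 = int(rng.integers(10, L - 10))
            bp3 = int(rng.integers(10, L - 10))
            call = make_call(chrom5="c1", bp5=bp5, strand5="-",
                             chrom3="c1", bp3=bp3, strand3="-")
            mirrored = make_call(chrom5="c1", bp5=L - bp5 + 1, strand5="+",
                                 chrom3="c1", bp3=L - bp3 + 1, strand3="+")
            assert ja.extract_junction_motifs(call, g) == ja.extract_junction_motifs(
                mirrored, g_mirror
            )


def _shs_oracle(call, genome, k, l_min):
    """Exhaustive (b, f) oracle built from plain genomic slicing."""

    def window(chrom, strand, lo, hi):
        s = genome.fetch(chrom, lo, hi)
        return s if strand == "+" else revcomp(s)

    if call.strand5 == "+":
        after5 = window(call.chrom5, "+", call.bp5 + 1, call.bp5 + k)
        last5 = window(call.chrom5, "+", call.bp5 - k + 1, call.bp5)
    else:
        after5 = window(call.chrom5, "-", call.bp5 - k, call.bp5 - 1)
        last5 = window(call.chrom5, "-", call.bp5, call.bp5 + k - 1)
    if call.strand3 == "+":
        first3 = window(call.chrom3, "+", call.bp3, call.bp3 + k - 1)
        before3 = window(call.chrom3, "+", call.bp3 - k, call.bp3 - 1)
    else:
        first3 = window(call.chrom3, "-", call.bp3 - k + 1, call.bp3)
        before3 = window(call.chrom3, "-", call.bp3 + 1, call.bp3 + k)

    def ok(s, t):
        return s == t and "N" not in s

    best = 0
    best_bf = (0, 0)
    for f in range(min(len(after5), len(first3)) + 1):
        if f and not ok(after5[:f], first3[:f]):
            continue
        for b in range(min(len(last5), len(before3)) + 1):
            if b and not ok(last5[len(last5) - b :], before3[len(before3) - b :]):
                continue
            if f + b > best:
                best, best_bf = f + b, (b, f)
    if best < l_min:
        return 0, ""
    b, f = best_bf
    return best, (last5[len(last5) - b :] if b else "") + (first3[:f] if f else "")


class TestDetectShs:
    def test_constructed_b3_f2(self):
        # engineered: suffix homology "GCA" (b=3), prefix homology "CG" (f=2)
        seq1 = list("ACGT" * 50)
        seq2 = list("TGCA" * 50)
        # 5' segment (c1, +) ends at bp5=50 with ...GCA; after bp5: CG then divergent
        for pos, base in {47: "T", 48: "G", 49: "C", 50: "A", 51: "C", 52: "G", 53: "A"}.items():
            seq1[pos - 1] = base
        # 3' gene (c2, +): before bp3=50 ends ...GCA with mismatch one earlier;
        # 3' segment starts CG then divergent
        for pos, base in {46: "C", 47: "G", 48: "C", 49: "A", 50: "C", 51: "G", 52: "T"}.items():
            seq2[pos - 1] = base
        g = Genome({"c1": "".join(seq1), "c2": "".join(seq2)})
        call = make_call(chrom5="c1", bp5=50, strand5="+", chrom3="c2", bp3=50, strand3="+")
        assert _shs_oracle(call, g, 20, 4) == (5, "GCACG")  # oracle sanity
        assert ja.detect_shs(call, g) == (5, "GCACG")

    def test_no_homology(self):
        g = Genome({"c1": "A" * 100, "c2": "C" * 100})
        call = make_call(chrom5="c1", bp5=50, strand5="+", chrom3="c2", bp3=50, strand3="+")
        assert ja.detect_shs(call, g) == (0, "")

    def test_below_threshold(self):
        # b=2, f=1 -> total 3 < L_min=4 -> reported as absent
        seq1 = list("ACGT" * 30)
        seq2 = list("TGCA" * 30)
        for pos, base in {49: "G", 50: "A", 51: "C", 52: "T"}.items():
            seq1[pos - 1] = base
        for pos, base in {47: "T", 48: "G", 49: "A", 50: "C", 51: "A"}.items():
            seq2[pos - 1] = base
        g = Genome({"c1": "".join(seq1), "c2": "".join(seq2)})
        call = make_call(chrom5="c1", bp5=50, strand5="+", chrom3="c2", bp3=50, strand3="+")
        expected = _shs_oracle(call, g, 20, 4)
        assert expected[0] in (0, 4, 5)  # construction sanity
        assert ja.detect_shs(call, g) == expected

    def test_n_never_matches(self):
        g = Genome({"c1": "N" * 100, "c2": "N" * 100})
        call = make_call(chrom5="c1", bp5=50, strand5="+", chrom3="c2", bp3=50, strand3="+")
        assert ja.detect_shs(call, g) == (0, "")

    def test_equals_exhaustive_oracle_on_random_junctions(self):
        rng = np.random.default_rng(7)
        # low-entropy alphabet mix to provoke homology frequently
        for trial in range(300):
            alphabet = list("ACGT") if trial % 2 else list("AC")
            g = Genome(
                {
                    "c1": "".join(rng.choice(alphabet, size=300)),
                    "c2": "".join(rng.choice(alphabet, size=300)),
                }
            )
            call = make_call(
                chrom5="c1", bp5=int(rng.integers(1, 300)),
                strand5=["+", "-"][int(rng.integers(2))],
                chrom3="c2", bp3=int(rng.integers(1, 300)),
                strand3=["+", "-"][int(rng.integers(2))],
            )
            assert ja.detect_shs(call, g) == _shs_oracle(call, g, 20, 4)


class TestJunctionQuery:
    def test_full_length(self, toy_genome):
        call = make_call(chrom5="c1", bp5=500, chrom3="c2", bp3=500)
        assert len(ja.build_junction_query(call, toy_genome)) == 200

    def test_clipped_5prime(self, toy_genome):
        call = make_call(chrom5="c1", bp5=40, chrom3="c2", bp3=500)
        assert len(ja.build_junction_query(call, toy_genome)) == 140

    def test_minus_strand_3prime_is_reverse_complement(self):
        seq = "ACGTACGTACGTACGTACGT"
        g = Genome({"c1": seq})
        call = make_call(chrom5="c1", bp5=10, strand5="+", chrom3="c1", bp3=15, strand3="-")
        q = ja.build_junction_query(call, g, flank=5)
        # hand-derived: transcription from bp3=15 downward reads the
        # complement of positions 15,14,13,12,11 = comp(G,G,C,A,T... ) ->
        # revcomp of genomic 11..15 ("GTACG") = "CGTAC"
        assert q == seq[5:10] + "CGTAC"


class TestFrame:
    def test_in_frame(self, toy_annotation):
        # gA CDS through bp5=600 gives L5=300; gB bases before bp3=200 give O3=99
        call = make_call(bp5=600, bp3=200)
        assert ja.classify_frame(call, toy_annotation) == "in_frame"

    def test_frameshift(self, toy_annotation):
        call = make_call(bp5=600, bp3=201)  # O3=100
        assert ja.classify_frame(call, toy_annotation) == "frameshift"

    def test_utr_not_applicable(self):
        tx = Transcript("t1.1", "g1", "c1", "+", [(101, 200), (301, 400)], [(301, 400)])
        tx2 = Transcript("t2.1", "g2", "c1", "+", [(501, 600)], [(501, 600)])
        ann = Annotation({"g1": ("c1", "+", [tx]), "g2": ("c1", "+", [tx2])})
        call = make_call(gene5="g1", bp5=150, gene3="g2", chrom3="c1", bp3=550)
        assert ja.classify_frame(call, ann) == "not_applicable"

    def test_no_cds_not_applicable(self):
        tx = Transcript("t1.1", "g1", "c1", "+", [(101, 200)])
        tx2 = Transcript("t2.1", "g2", "c1", "+", [(501, 600)], [(501, 600)])
        ann = Annotation({"g1": ("c1", "+", [tx]), "g2": ("c1", "+", [tx2])})
        call = make_call(gene5="g1", bp5=150, gene3="g2", chrom3="c1", bp3=550)
        assert ja.classify_frame(call, ann) == "not_applicable"

    def test_isoform_tiebreak_prefers_matching_boundary(self):
        # two isoforms with different CDS; bp5 is an exon end only for short
        short = Transcript("t.s", "g1", "c1", "+", [(101, 160)], [(101, 160)])
        long = Transcript("t.l", "g1", "c1", "+", [(101, 200), (301, 400)],
                          [(101, 200), (301, 400)])
        tx3 = Transcript("t3", "g2", "c1", "+", [(501, 700)], [(501, 700)])
        ann = Annotation({"g1": ("c1", "+", [long, short]), "g2": ("c1", "+", [tx3])})
        # L5 via short isoform = 60 (0 mod 3); O3 = 0 -> in_frame
        call = make_call(gene5="g1", bp5=160, gene3="g2", chrom3="c1", bp3=501)
        assert ja.classify_frame(call, ann) == "in_frame"


class TestAnnotateAndSummary:
    def test_mechanism_rules(self):
        assert ja._mechanism(True, 0) == "canonical_splice"
        assert ja._mechanism(True, 5) == "both"
        assert ja._mechanism(False, 5) == "shs"
        assert ja._mechanism(False, 0) == "other"

    def test_summary_fractions(self, toy_genome, toy_annotation):
        def af(mech, locality="interchromosomal"):
            call = make_call()
            return ja.AnnotatedFusion(call, locality, "none", "GT", "AG",
                                      mech in ("canonical_splice", "both"),
                                      4 if mech in ("shs", "both") else 0, "",
                                      mech, "not_applicable", "")

        annotated = [af("canonical_splice")] * 3 + [af("other")]
        s = ja.mechanism_summary(annotated)
        assert s.category_proportions["canonical_splice"] == pytest.approx(0.75)
        assert s.locality_proportions == {"interchromosomal": 1.0}
        for props in (s.category_proportions, s.locality_proportions, s.boundary_proportions):
            assert sum(props.values()) == pytest.approx(1.0)

    def test_empty_summary_error(self):
        with pytest.raises(ValueError):
            ja.mechanism_summary([])

    def test_annotate_error_reports_row(self, toy_genome, toy_annotation):
        calls = [make_call(), make_call(gene5="gX")]
        with pytest.raises(KeyError, match="row 1"):
            ja.annotate(calls, toy_genome, toy_annotation)

    def test_annotated_tsv_round_trip(self, tmp_path, toy_genome, toy_annotation):
        annotated = ja.annotate([make_call(), make_call(bp5=150, bp3=420)],
                                toy_genome, toy_annotation)
        p = tmp_path / "ann.tsv"
        ja.write_annotated_fusions(p, annotated)
        assert ja.read_annotated_fusions(p) == annotated
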