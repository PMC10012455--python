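"""Back-splice detector: index, breakpoint recovery, classification,
isoform relations, histograms, round-trips."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circsponge import detect as cd
from circsponge.seq import Annotation, Gene, revcomp


# --- k-mer index ------------------------------------------------------------


def test_index_reports_all_forward_occurrences():
    idx = cd.build_index({"chr1": "ACGTACGT"}, 4)
    hits = idx.query("ACGT")
    assert ("chr1", 1, "+") in hits and ("chr1", 5, "+") in hits


def test_index_query_with_n_returns_nothing():
    idx = cd.build_index({"chr1": "ACGTNACGTA"}, 4)
    assert idx.query("CGTN") == []


def test_index_reverse_complement_hits_minus_strand():
    idx = cd.build_index({"chr1": "AACCGGTTAA"}, 5)
    fwd = idx.query("AACCG")
    assert ("chr1", 1, "+") in fwd
    rev = idx.query(revcomp("AACCG"))
    assert ("chr1", 1, "-") in rev


def test_index_k_exceeding_chromosome_errors():
    with pytest.raises(ValueError, match="shortest chromosome"):
        cd.build_index({"chr1": "ACGT"}, 10)


# --- detection --------------------------------------------------------------


def test_planted_junctions_recovered_exactly(mini_cfg, mini_sim, mini_reads, mini_index):
    genome, _, truth = mini_sim
    calls, _ = cd.detect_backsplice(mini_reads, mini_index, genome)
    truth_set = {(c.chrom, c.start, c.end, c.strand) for c in truth.circs}
    call_set = {(c.chrom, c.start, c.end, c.strand) for c in calls}
    assert call_set == truth_set
    by_key = {(c.chrom, c.start, c.end, c.strand): c for c in calls}
    for key in truth_set:
        assert by_key[key].junction_reads >= mini_cfg.junction_depth - 1


def test_linear_reads_alone_give_no_calls(mini_sim, mini_reads, mini_index):
    genome, _, _ = mini_sim
    linear = [(n, s) for n, s in mini_reads if n.startswith("lin|")]
    calls, _ = cd.detect_backsplice(linear, mini_index, genome)
    assert calls == []


def test_min_junction_reads_filters_single_read_support(mini_sim, mini_reads, mini_index):
    genome, _, truth = mini_sim
    target = truth.circs[0].circ_id
    one_read = [(n, s) for n, s in mini_reads if n.startswith(f"junc|{target}|")][:1]
    params = cd.DetectorParams(min_junction_reads=2)
    calls, _ = cd.detect_backsplice(one_read, mini_index, genome, params)
    assert calls == []
    calls1, _ = cd.detect_backsplice(
        one_read, mini_index, genome, cd.DetectorParams(min_junction_reads=1)
    )
    assert [c.circ_id for c in calls1] == [target]


def test_strand_symmetry_under_genome_reverse_complement(mini_sim, mini_reads):
    """Reverse-complementing every chromosome flips strands and mirrors
    coordinates but yields the same call set."""
    genome, _, truth = mini_sim
    flipped = {c: revcomp(s) for c, s in genome.items()}
    idx = cd.build_index(flipped, 20)
    calls, _ = cd.detect_backsplice(mini_reads, idx, flipped)
    lengths = {c: len(s) for c, s in genome.items()}
    expected = {
        (
            c.chrom,
            lengths[c.chrom] - c.end + 1,
            lengths[c.chrom] - c.start + 1,
            "-" if c.strand == "+" else "+",
        )
        for c in truth.circs
    }
    assert {(c.chrom, c.start, c.end, c.strand) for c in calls} == expected


def test_discard_log_reports_ambiguous_anchors():
    # two identical arms make the anchors multi-mapping
    arm = "ACGTGACCTAGGCATTCGAT"
    genome = {"chr1": ("T" * 30 + arm + "T" * 30) * 2}
    idx = cd.build_index(genome, 20)
    calls, discards = cd.detect_backsplice(
        [("r1", arm + arm)], idx, genome, cd.DetectorParams(min_junction_reads=1)
    )
    assert calls == []
    assert discards.get("anchor_ambiguous", 0) == 1


# --- classification ---------------------------------------------------------


@pytest.fixture(scope="module")
def toy_annotation():
    gene_fwd = Gene("GF", "chr1", 101, 700, "+", exons=[(101, 200), (301, 400), (501, 700)])
    gene_rev = Gene("GR", "chr1", 1001, 1400, "-", exons=[(1001, 1100), (1301, 1400)])
    neighbour = Gene("GN", "chr1", 720, 980, "+", exons=[(720, 800), (901, 980)])
    return Annotation([gene_fwd, gene_rev, neighbour])


def _call(start, end, strand="+"):
    return cd.CircRNACall(chrom="chr1", start=start, end=end, strand=strand,
                          junction_reads=5)


def test_classify_exonic_when_both_breakpoints_in_exons(toy_annotation):
    call = cd.classify(_call(301, 700), toy_annotation)
    assert call.circ_type == "exonic" and call.host_genes == ["GF"]


def test_classify_intronic_inside_single_intron(toy_annotation):
    call = cd.classify(_call(210, 290), toy_annotation)
    assert call.circ_type == "intronic" and call.host_genes == ["GF"]


def test_classify_intergenic_in_gene_desert(toy_annotation):
    call = cd.classify(_call(2000, 2500), toy_annotation)
    assert call.circ_type == "intergenic" and call.host_genes == []


def test_classify_two_gene_exonic_records_both_hosts(toy_annotation):
    call = cd.classify(_call(350, 780), toy_annotation)
    assert call.circ_type == "exonic"
    assert call.host_genes == ["GF", "GN"]


def test_classify_antisense_only_overlap_is_intergenic(toy_annotation):
    call = cd.classify(_call(1050, 1350, strand="+"), toy_annotation)
    assert call.circ_type == "intergenic" and call.host_genes == []


def test_classify_unknown_chromosome_errors(toy_annotation):
    with pytest.raises(ValueError, match="chrX"):
        cd.classify(cd.CircRNACall("chrX", 10, 50, "+", 3), toy_annotation)


def test_call_id_uses_colon_pipe_convention():
    assert _call(1000, 2000).circ_id == "chr1:1000|2000"


# --- isoform relations ------------------------------------------------------


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ((100, 500), (150, 400), "containment"),
        ((100, 500), (100, 700), "shared_splice_site"),
        ((100, 500), (600, 900), "no_association"),
        ((100, 500), (100, 500), "containment"),
        ((100, 500), (300, 700), "no_association"),
        ((100, 500), (450, 500), "shared_splice_site"),
    ],
)
def test_relate_pair_rules(a, b, expected):
    assert cd.relate_pair(_call(*a), _call(*b)) == expected


@given(
    st.tuples(st.integers(1, 50), st.integers(51, 100)),
    st.tuples(st.integers(1, 50), st.integers(51, 100)),
)
@settings(max_examples=100, deadline=None)
def test_relate_pair_is_symmetric(iv_a, iv_b):
    assert cd.relate_pair(_call(*iv_a), _call(*iv_b)) == cd.relate_pair(
        _call(*iv_b), _call(*iv_a)
    )


def test_relate_isoforms_needs_two_calls():
    with pytest.raises(ValueError):
        cd.relate_isoforms([_call(1, 10)])


# --- histogram and round-trips ---------------------------------------------


def test_length_histogram_bins_and_partition():
    calls = [_call(100, 449)]  # span 350
    calls[0].circ_type = "exonic"
    table = cd.length_histogram(calls, (0, 200, 1000, 3000))
    assert table.loc["exonic", "[200,1000)"] == 1
    assert table.to_numpy().sum() == 1


def test_length_histogram_rejects_unsorted_edges():
    with pytest.raises(ValueError):
        cd.length_histogram([_call(1, 10)], (0, 1000, 200))


def test_length_histogram_empty_calls_is_all_zero():
    table = cd.length_histogram([], (0, 200, 1000))
    assert table.to_numpy().sum() == 0


def test_catalog_round_trip_is_lossless(tmp_path, mini_sim, mini_reads, mini_index):
    genome, annotation, _ = mini_sim
    calls, _ = cd.detect_backsplice(mini_reads, mini_index, genome)
    for c in calls:
        cd.classify(c, annotation)
    path = tmp_path / "catalog.tsv"
    cd.write_catalog(calls, path)
    back = cd.read_catalog(path)
    assert [dataclasses.asdict(c) for c in back] == [dataclasses.asdict(c) for c in calls]


def test_bed6_export_is_zero_based_half_open(tmp_path):
    call = _call(1000, 2000)
    path = tmp_path / "c.bed"
    cd.write_bed6([call], path)
    chrom, start, end, name, score, strand = path.read_text().split()
    assert (chrom, start, end, strand) == ("chr1", "999", "2000", "+")
    assert name == "chr1:1000|2000"
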