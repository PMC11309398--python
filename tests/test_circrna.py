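"""Back-splice junction reference, read partitioning/counting, and summaries."""

import numpy as np
import pandas as pd
import pytest

from synloc import (
    AnalysisConfig,
    CountDataset,
    JunctionCounts,
    ReadSimParams,
    build_backsplice_reference,
    combined_circ_de,
    count_junction_reads,
    detect_isoform_switches,
    exon_span_summary,
    partition_reads_by_linear_alignment,
    simulate_reads,
    simulate_transcriptome,
)
from synloc.circrna import junctions_to_fasta, parse_junction_id
from synloc.datasets import load_circ_isoform_examples
from synloc.simulate import circle_sequence
from synloc._align import reverse_complement

from conftest import make_dataset, make_transcript


def brute_force_linear_hit(read, transcripts, max_mismatch):
    """Sliding-window Hamming scan over both orientations."""
    for t in transcripts:
        seq = t.sequence
        for oriented in (read, reverse_complement(read)):
            L = len(oriented)
            for pos in range(len(seq) - L + 1):
                mm = sum(a != b for a, b in zip(seq[pos : pos + L], oriented))
                if mm <= max_mismatch:
                    return True
    return False


class TestBuildReference:
    def test_single_exon_transcript_yields_the_self_circle(self):
        t = make_transcript(["ACGTACGTAA"])
        (j,) = build_backsplice_reference([t], flank_len=4)
        assert (j.donor_idx, j.acceptor_idx) == (1, 1)
        assert j.junction_seq == "GTAA" + "ACGT"
        assert j.breakpoint_offset == 4

    def test_three_exons_give_all_six_donor_acceptor_pairs(self):
        t = make_transcript(["AAAACCCC", "GGGGTTTT", "ACACACAC"])
        juncs = build_backsplice_reference([t], flank_len=3)
        pairs = {(j.donor_idx, j.acceptor_idx) for j in juncs}
        assert pairs == {(1, 1), (2, 1), (2, 2), (3, 1), (3, 2), (3, 3)}

    @pytest.mark.parametrize("n_exons,expected", [(1, 1), (3, 6), (5, 15)])
    def test_junction_count_closed_form(self, rng, n_exons, expected):
        tx, _ = simulate_transcriptome(1, (n_exons, n_exons), (30, 60), rng)
        assert len(build_backsplice_reference(tx, 20)) == expected

    def test_flank_construction_from_adjacent_exons(self, rng):
        from synloc.simulate import _random_seq

        e1 = _random_seq(rng, 200)
        e2 = _random_seq(rng, 300)
        t = make_transcript([e1, e2])
        juncs = {(j.donor_idx, j.acceptor_idx): j
                 for j in build_backsplice_reference([t], flank_len=150)}
        j21 = juncs[(2, 1)]
        assert j21.junction_seq == e2[-150:] + e1[:150]
        assert j21.breakpoint_offset == 150

    def test_short_circle_flanks_clamp_without_wrapping(self):
        t = make_transcript(["ACGTACGTAA"])  # 10 nt circle, flank 150
        (j,) = build_backsplice_reference([t], flank_len=150)
        assert j.donor_flank_len == j.acceptor_flank_len == 10
        assert j.junction_seq == t.exon_sequences[0] * 2

    def test_junction_seq_lies_in_doubled_circle_and_crosses_breakpoint(self, rng):
        tx, _ = simulate_transcriptome(5, (2, 6), (40, 120), rng)
        for j in build_backsplice_reference(tx, 70):
            t = {x.transcript_id: x for x in tx}[j.transcript_id]
            circ = circle_sequence(t, j.donor_idx, j.acceptor_idx)
            assert j.junction_seq in circ + circ
            assert 0 < j.breakpoint_offset < len(j.junction_seq)

    def test_redundant_transcripts_deduplicate_by_genomic_span(self):
        t1 = make_transcript(["AAAACCCC", "GGGGTTTT"], transcript_id="tA",
                             gene_id="g1")
        t2 = make_transcript(["AAAACCCC", "GGGGTTTT"], transcript_id="tB",
                             gene_id="g1")
        juncs = build_backsplice_reference([t1, t2], flank_len=4)
        assert len(juncs) == 3  # not 6
        assert all(j.transcript_id == "tA" for j in juncs)


class TestPartitionReads:
    def test_verbatim_transcript_read_maps(self, rng):
        tx, _ = simulate_transcriptome(3, (2, 4), (100, 200), rng)
        read = tx[0].sequence[10:110]
        mapped, unmapped = partition_reads_by_linear_alignment(
            [("r1", read)], tx, max_mismatch=0
        )
        assert mapped == ["r1"]

    def test_backsplice_read_is_unmapped(self, rng):
        tx, _ = simulate_transcriptome(3, (3, 3), (150, 150), rng)
        circ = circle_sequence(tx[0], 3, 1)
        read = (circ + circ)[len(circ) - 50 : len(circ) + 50]
        mapped, unmapped = partition_reads_by_linear_alignment(
            [("r1", read)], tx, max_mismatch=0
        )
        assert mapped == []
        assert unmapped == [("r1", read)]

    @pytest.mark.parametrize("max_mismatch", [0, 2])
    def test_partition_matches_sliding_window_oracle(self, rng, max_mismatch):
        tx, _ = simulate_transcriptome(4, (2, 4), (80, 150), rng)
        circles = [(tx[0].transcript_id, tx[0].n_exons, 1, 1.0)]
        params = ReadSimParams(
            circle_specs=circles, read_length=60, total_reads=300,
            error_rate=0.02, seed=4,
        )
        reads, _ = simulate_reads(tx, params, rng)
        mapped, unmapped = partition_reads_by_linear_alignment(
            reads, tx, max_mismatch
        )
        mapped_set = set(mapped)
        for rid, seq in reads:
            assert (rid in mapped_set) == brute_force_linear_hit(
                seq, tx, max_mismatch
            )
        # unmapped preserves input order
        ids = [r for r, _ in reads]
        assert [r for r, _ in unmapped] == [
            r for r in ids if r not in mapped_set
        ]

    def test_empty_input_returns_empty_outputs(self, rng):
        tx, _ = simulate_transcriptome(2, (2, 2), (100, 100), rng)
        mapped, unmapped = partition_reads_by_linear_alignment([], tx, 0)
        assert mapped == [] and unmapped == []


class TestCountJunctionReads:
    def _setup(self, rng):
        tx, _ = simulate_transcriptome(6, (3, 5), (100, 250), rng)
        juncs = build_backsplice_reference(tx, 150)
        return tx, juncs

    def test_breakpoint_centered_read_counts_once(self, rng):
        tx, juncs = self._setup(rng)
        j = next(x for x in juncs if x.exon_span == 2)
        bp = j.breakpoint_offset
        read = j.junction_seq[bp - 50 : bp + 50]
        jc = count_junction_reads([("r1", read)], [j], min_anchor=10,
                                  max_mismatch=0)
        assert jc.counts.loc[j.junction_id, "sample1"] == 1

    def test_short_anchor_is_rejected(self, rng):
        tx, juncs = self._setup(rng)
        j = juncs[0]
        bp = j.breakpoint_offset
        read = j.junction_seq[bp - 95 : bp + 5]  # only 5 nt past breakpoint
        jc = count_junction_reads([("r1", read)], [j], min_anchor=10,
                                  max_mismatch=0)
        assert jc.counts["sample1"].sum() == 0

    def test_reverse_complement_read_counts(self, rng):
        tx, juncs = self._setup(rng)
        j = juncs[0]
        bp = j.breakpoint_offset
        read = reverse_complement(j.junction_seq[bp - 40 : bp + 40])
        jc = count_junction_reads([("r1", read)], [j], min_anchor=10,
                                  max_mismatch=0)
        assert jc.counts.loc[j.junction_id, "sample1"] == 1

    def test_ambiguous_read_is_discarded_and_tallied(self):
        # two junctions from different genes sharing the same sequence
        t1 = make_transcript(["A" * 30 + "C" * 30, "G" * 30 + "T" * 30],
                             transcript_id="t1", gene_id="g1")
        t2 = make_transcript(["A" * 30 + "C" * 30, "G" * 30 + "T" * 30],
                             transcript_id="t2", gene_id="g2")
        juncs = build_backsplice_reference([t1, t2], flank_len=30)
        j = next(x for x in juncs if (x.donor_idx, x.acceptor_idx) == (2, 1))
        bp = j.breakpoint_offset
        read = j.junction_seq[bp - 20 : bp + 20]
        jc = count_junction_reads([("r1", read)], juncs, min_anchor=10,
                                  max_mismatch=0)
        assert jc.ambiguous_discarded["sample1"] == 1
        assert jc.counts["sample1"].sum() == 0

    def test_error_free_counts_equal_substring_oracle(self, rng):
        tx, _ = simulate_transcriptome(8, (3, 6), (100, 250), rng)
        circles = [
            (tx[0].transcript_id, 3, 1, 2.0),
            (tx[1].transcript_id, 2, 2, 2.0),
            (tx[2].transcript_id, tx[2].n_exons, tx[2].n_exons - 2, 2.0),
        ]
        params = ReadSimParams(circle_specs=circles, read_length=100,
                               total_reads=8000, error_rate=0.0, seed=6)
        reads, truth = simulate_reads(tx, params, rng)
        juncs = build_backsplice_reference(tx, 150)
        _, unmapped = partition_reads_by_linear_alignment(reads, tx, 0)
        jc = count_junction_reads(unmapped, juncs, min_anchor=10, max_mismatch=0)
        a = 10
        for j in juncs:
            t = {x.transcript_id: x for x in tx}[j.transcript_id]
            circ = circle_sequence(t, j.donor_idx, j.acceptor_idx)
            probe = circ[-a:] + circ[:a]
            oracle = sum(
                1
                for _, s in reads
                if probe in s or probe in reverse_complement(s)
            )
            assert jc.counts.loc[j.junction_id, "sample1"] == oracle
        planted = set(truth.circle_expected_junction_reads)
        for j in juncs:
            if j.junction_id not in planted:
                assert jc.counts.loc[j.junction_id, "sample1"] == 0


class TestCombinedCircDE:
    def _linear(self, rng, n_samples=10):
        counts = rng.integers(50, 500, size=(30, n_samples))
        return make_dataset(
            counts,
            fraction=["synaptosome"] * (n_samples // 2)
            + ["homogenate"] * (n_samples // 2),
            condition=["control"] * n_samples,
        )

    def _jc(self, circ_counts, samples):
        df = pd.DataFrame(
            circ_counts,
            index=[f"gX|tX|{i + 2}|1" for i in range(len(circ_counts))],
            columns=samples,
        )
        return JunctionCounts(
            counts=df, ambiguous_discarded=pd.Series(0, index=samples)
        )

    def test_boundary_filter_retains_four_counts_in_five_samples(self, rng):
        lin = self._linear(rng)
        circ = np.zeros((1, 10), dtype=int)
        circ[0, :5] = 4
        de = combined_circ_de(
            lin, self._jc(circ, lin.sample_ids), AnalysisConfig(),
            lin.fraction, ("synaptosome", "homogenate"),
        )
        assert len(de) == 1

    def test_all_zero_circ_counts_give_empty_table(self, rng):
        lin = self._linear(rng)
        circ = np.zeros((3, 10), dtype=int)
        de = combined_circ_de(
            lin, self._jc(circ, lin.sample_ids), AnalysisConfig(),
            lin.fraction, ("synaptosome", "homogenate"),
        )
        assert de.empty

    def test_sample_mismatch_raises_with_difference(self, rng):
        lin = self._linear(rng)
        circ = np.full((1, 9), 10, dtype=int)
        jc = self._jc(circ, lin.sample_ids[:9])
        with pytest.raises(ValueError, match="s10"):
            combined_circ_de(lin, jc, AnalysisConfig(), lin.fraction,
                             ("synaptosome", "homogenate"))

    def test_adding_circ_rows_never_changes_linear_filter_survivors(self, rng):
        from synloc import filter_features

        lin = self._linear(rng)
        cfg = AnalysisConfig()
        before = filter_features(lin, cfg.min_count, cfg.min_samples)
        circ = rng.integers(0, 50, size=(5, 10))
        combined_circ_de(lin, self._jc(circ, lin.sample_ids), cfg,
                         lin.fraction, ("synaptosome", "homogenate"))
        after = filter_features(lin, cfg.min_count, cfg.min_samples)
        assert list(before.counts.index) == list(after.counts.index)


class TestIsoformSwitches:
    def test_published_examples_recover_the_four_switch_genes(self):
        table = load_circ_isoform_examples()
        switches = detect_isoform_switches(table, p_cutoff=0.05)
        assert set(switches["gene"]) == {"ATF6", "ANKS1B", "GSK3B", "UBA2"}
        gsk = switches[switches["gene"] == "GSK3B"]
        assert len(gsk) == 1
        row = gsk.iloc[0]
        assert (row["up_donor"], row["up_acceptor"]) == (9, 7)
        assert row["up_log2fc"] == pytest.approx(1.58)
        assert (row["down_donor"], row["down_acceptor"]) == (10, 9)
        assert row["down_log2fc"] == pytest.approx(-1.68)

    def test_single_significant_isoform_is_not_a_switch(self):
        df = pd.DataFrame(
            {"gene": ["g1", "g1"], "donor": [3, 5], "acceptor": [1, 2],
             "log2fc": [2.0, -2.0], "p": [0.01, 0.5]}
        )
        assert detect_isoform_switches(df).empty

    def test_same_sign_significant_isoforms_are_not_a_switch(self):
        df = pd.DataFrame(
            {"gene": ["g1", "g1"], "donor": [3, 5], "acceptor": [1, 2],
             "log2fc": [2.0, 1.0], "p": [0.01, 0.01]}
        )
        assert detect_isoform_switches(df).empty

    def test_feature_id_parsing_route(self):
        df = pd.DataFrame(
            {
                "feature_id": ["g1|t1|3|1", "g1|t1|5|2"],
                "log2fc": [2.0, -1.0],
                "p": [0.01, 0.02],
            }
        )
        switches = detect_isoform_switches(df)
        assert list(switches["gene"]) == ["g1"]
        assert parse_junction_id("g1|t1|3|1") == ("g1", "t1", 3, 1)


class TestExonSpanSummary:
    def test_spans_and_histogram_match_brute_force(self, rng):
        tx, _ = simulate_transcriptome(5, (2, 6), (40, 100), rng)
        juncs = build_backsplice_reference(tx, 30)
        samples = ["s1"]
        counts = pd.DataFrame(
            rng.integers(0, 3, size=(len(juncs), 1)),
            index=[j.junction_id for j in juncs],
            columns=samples,
        )
        jc = JunctionCounts(counts=counts,
                            ambiguous_discarded=pd.Series(0, index=samples))
        hist = exon_span_summary(juncs, jc)
        expected = {}
        for j in juncs:
            if counts.loc[j.junction_id, "s1"] > 0:
                span = j.donor_idx - j.acceptor_idx
                expected[span] = expected.get(span, 0) + 1
        assert hist.to_dict() == expected

    def test_single_exon_circle_has_span_zero(self):
        t = make_transcript(["ACGTACGTGG"])
        (j,) = build_backsplice_reference([t], flank_len=5)
        assert j.exon_span == 0
        hist = exon_span_summary([j])
        assert hist.to_dict() == {0: 1}
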