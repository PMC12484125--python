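import numpy as np
import pytest
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from hypothesis import given, settings
from hypothesis import strategies as st

from aadckit.align import (
    AlignmentError,
    MultipleAlignment,
    PercentIdentityMatrix,
    build_msa,
    detect_outliers,
    global_align,
    percent_identity,
    phylum_block_summary,
    pim_from_msa,
    read_external_alignment,
    read_pim,
    summarize_group,
    write_alignment,
    write_pim,
)
from aadckit.simulate import (
    FamilySimSpec,
    point_lengths,
    simulate_family,
)
from brute_force import best_score

seqs4 = st.text(alphabet="ACDE", min_size=1, max_size=6)


class TestGlobalAlign:
    def test_self_alignment_has_no_gaps(self):
        aln = global_align("SGHK", "SGHK")
        assert aln.aligned_a == aln.aligned_b == "SGHK"

    def test_shorter_sequence_gets_one_terminal_gap(self):
        aln = global_align("SGHK", "SGH")
        assert aln.aligned_a == "SGHK"
        assert aln.aligned_b.count("-") == 1
        assert best_score("SGHK", "SGH") == aln.score

    def test_single_residue_pair_is_one_column(self):
        aln = global_align("A", "D")
        assert (aln.aligned_a, aln.aligned_b) == ("A", "D")

    def test_empty_sequence_rejected(self):
        with pytest.raises(AlignmentError):
            global_align("", "SGHK")

    def test_no_gap_gap_columns_and_gaps_recover_inputs(self):
        aln = global_align("SGHKDDL", "SGK")
        assert all(
            not (x == "-" and y == "-") for x, y in zip(aln.aligned_a, aln.aligned_b)
        )
        assert aln.aligned_a.replace("-", "") == "SGHKDDL"
        assert aln.aligned_b.replace("-", "") == "SGK"

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(a=seqs4, b=seqs4)
    def test_score_matches_bruteforce_enumeration(self, a, b):
        """The affine-gap aligner is optimal: its score equals the maximum
        over every explicitly enumerated alignment."""
        assert global_align(a, b).score == pytest.approx(best_score(a, b))


class TestPercentIdentity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("SGHK", "SGHK", 100.0),
            ("SGHK", "SGHA", 75.0),
            ("SG-K", "SGHK", 100.0),  # gapped column excluded from denominator
            ("XXXX", "XXXX", 0.0),  # X matches nothing, not even X
            ("--AA", "AA--", 0.0),  # no shared residue columns
        ],
    )
    def test_examples(self, a, b, expected):
        assert percent_identity(a, b) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            percent_identity("SGHK", "SGH")

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        pairs=st.lists(
            st.tuples(st.sampled_from("ACD-"), st.sampled_from("ACD-")),
            min_size=1,
            max_size=12,
        )
    )
    def test_symmetric_and_100_iff_identical_residue_columns(self, pairs):
        pairs = [p for p in pairs if p != ("-", "-")]
        if not pairs:
            return
        a = "".join(x for x, _ in pairs)
        b = "".join(y for _, y in pairs)
        assert percent_identity(a, b) == percent_identity(b, a)
        resid = [(x, y) for x, y in pairs if x != "-" and y != "-"]
        if resid and all(x == y for x, y in resid):
            assert percent_identity(a, b) == 100.0


class TestMsa:
    def test_identical_sequences_align_gapless(self):
        msa = build_msa([("a", "SGHK"), ("b", "SGHK")])
        assert msa.rows == ["SGHK", "SGHK"]

    def test_three_way_with_deletion(self):
        msa = build_msa([("a", "SGHK"), ("b", "SGHK"), ("c", "SGK")])
        assert msa.n_columns == 4
        assert msa.rows[0] == msa.rows[1] == "SGHK"
        assert msa.rows[2].replace("-", "") == "SGK"
        assert msa.rows[2].count("-") == 1

    def test_single_sequence_rejected(self):
        with pytest.raises(AlignmentError):
            build_msa([("a", "SGHK")])

    def test_planted_motif_lands_in_one_column_block(self):
        spec = FamilySimSpec("GluDC", "SGHK", point_lengths(120), divergence=0.10)
        records, kpos = simulate_family(spec, 10, seed=11)
        msa = build_msa([(r.record_id, r.sequence) for r in records])
        k = kpos[0]
        # the K column must be the same alignment column for every row
        cols = set()
        for row in msa.rows:
            count = 0
            for j, ch in enumerate(row):
                if ch != "-":
                    count += 1
                    if count == k:
                        cols.add(j)
                        break
        assert len(cols) == 1
        assert msa.column(cols.pop()) == "K" * 10

    def test_column_count_at_least_longest_sequence(self):
        msa = build_msa([("a", "SGHKDDLLM"), ("b", "SGK"), ("c", "SGHK")])
        assert msa.n_columns >= 9


class TestExternalAlignment:
    def _toy(self):
        return MultipleSeqAlignment(
            [
                SeqRecord(Seq("SGHK"), id="a"),
                SeqRecord(Seq("SG-K"), id="b"),
                SeqRecord(Seq("SGHK"), id="c"),
            ]
        )

    def test_reads_clustal(self, tmp_path):
        p = tmp_path / "toy.aln"
        AlignIO.write(self._toy(), p, "clustal")
        msa = read_external_alignment(p, "clustal")
        assert msa.ids == ["a", "b", "c"]
        assert msa.rows[1] == "SG-K"

    def test_ragged_fasta_rejected(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">a\nSGHK\n>b\nSG\n")
        with pytest.raises(AlignmentError):
            read_external_alignment(p, "fasta")

    def test_round_trip_gives_identical_matrix(self, tmp_path):
        msa = build_msa([("a", "SGHKDD"), ("b", "SGHKDE"), ("c", "SGKDE")])
        p = tmp_path / "out.fasta"
        write_alignment(msa, p)
        again = read_external_alignment(p, "fasta")
        np.testing.assert_allclose(
            pim_from_msa(again).values, pim_from_msa(msa).values
        )


class TestPim:
    def test_identical_rows(self):
        msa = MultipleAlignment(ids=["a", "b"], rows=["SGHK", "SGHK"])
        np.testing.assert_allclose(pim_from_msa(msa).values, 100.0)

    def test_off_diagonal_value(self):
        msa = MultipleAlignment(ids=["a", "b"], rows=["SGHK", "SGHA"])
        assert pim_from_msa(msa).pair("a", "b") == pytest.approx(75.0)

    def test_strain_replicates_stay_above_90(self):
        spec = FamilySimSpec("GluDC", "SGHK", point_lengths(200), divergence=0.03)
        records, _ = simulate_family(spec, 5, seed=3)
        msa = build_msa([(r.record_id, r.sequence) for r in records])
        assert pim_from_msa(msa).off_diagonal().min() > 90.0

    def test_permutation_equivariant(self):
        msa = build_msa([("a", "SGHKDD"), ("b", "SGHKDE"), ("c", "SGKDE")])
        pim = pim_from_msa(msa)
        rev = MultipleAlignment(ids=msa.ids[::-1], rows=msa.rows[::-1])
        pim_rev = pim_from_msa(rev)
        for i in msa.ids:
            for j in msa.ids:
                assert pim.pair(i, j) == pytest.approx(pim_rev.pair(i, j))

    def test_tsv_round_trip(self, tmp_path):
        pim = pim_from_msa(build_msa([("a", "SGHKDD"), ("b", "SGHKDE"), ("c", "SGKDE")]))
        p = tmp_path / "pim.tsv"
        write_pim(pim, p)
        again = read_pim(p)
        assert again.ids == pim.ids
        np.testing.assert_allclose(again.values, pim.values)


class TestGroupSummary:
    def test_all_identical_group(self):
        pim = PercentIdentityMatrix(ids=["a", "b"], values=np.full((2, 2), 100.0))
        s = summarize_group(pim)
        assert (s.average_identity, s.minimum_identity) == (100.0, 100.0)

    def test_singleton_group_not_applicable(self):
        s = summarize_group(None)
        assert not s.applicable

    def test_two_cluster_average_between_cluster_levels(self):
        values = np.full((4, 4), 20.0)
        np.fill_diagonal(values, 100.0)
        values[0, 1] = values[1, 0] = 80.0
        values[2, 3] = values[3, 2] = 80.0
        s = summarize_group(PercentIdentityMatrix(["a", "b", "c", "d"], values))
        assert 20.0 < s.average_identity < 80.0
        assert s.minimum_identity == 20.0


def _group_pim(outlier_level=15.0, base=70.0, n=5):
    values = np.full((n, n), base)
    np.fill_diagonal(values, 100.0)
    values[0, 1:] = values[1:, 0] = outlier_level
    return PercentIdentityMatrix([f"m{i}" for i in range(n)], values)


class TestOutliers:
    def test_low_identity_member_flagged(self):
        reports = detect_outliers(_group_pim())
        flagged = [r for r in reports if r.flagged]
        assert [r.record_id for r in flagged] == ["m0"]
        assert flagged[0].max_identity_to_group == pytest.approx(15.0)

    def test_homogeneous_group_none_flagged(self):
        reports = detect_outliers(_group_pim(outlier_level=70.0))
        assert not any(r.flagged for r in reports)

    def test_lowest_member_reported_even_when_unflagged(self):
        # a 42-45% member is above the default threshold but still surfaced
        reports = detect_outliers(_group_pim(outlier_level=43.0))
        assert [r.record_id for r in reports if r.lowest_in_group] == ["m0"]
        assert not reports[0].flagged

    def test_flags_grow_with_threshold(self):
        pim = _group_pim(outlier_level=25.0, base=45.0)
        low = {r.record_id for r in detect_outliers(pim, 30.0) if r.flagged}
        high = {r.record_id for r in detect_outliers(pim, 50.0) if r.flagged}
        assert low <= high

    def test_small_group_rejected(self):
        with pytest.raises(AlignmentError):
            detect_outliers(PercentIdentityMatrix(["a", "b"], np.full((2, 2), 100.0)))


class TestPhylumBlocks:
    def test_two_planted_clusters_within_exceeds_between(self):
        values = np.full((6, 6), 45.0)
        np.fill_diagonal(values, 100.0)
        for block in ([0, 1, 2], [3, 4, 5]):
            for i in block:
                for j in block:
                    if i != j:
                        values[i, j] = 72.0
        pim = PercentIdentityMatrix([f"m{i}" for i in range(6)], values)
        labels = {f"m{i}": ("Bacteroidota" if i < 3 else "Bacillota") for i in range(6)}
        out = phylum_block_summary(pim, labels)
        assert out[("Bacillota", "Bacillota")] == pytest.approx(72.0)
        assert out[("Bacteroidota", "Bacteroidota")] == pytest.approx(72.0)
        assert out[("Bacillota", "Bacteroidota")] == pytest.approx(45.0)

    def test_single_member_phylum_within_not_applicable(self):
        values = np.full((3, 3), 50.0)
        np.fill_diagonal(values, 100.0)
        pim = PercentIdentityMatrix(["a", "b", "c"], values)
        labels = {"a": "P1", "b": "P1", "c": "P2"}
        out = phylum_block_summary(pim, labels)
        assert out[("P2", "P2")] is None
        assert out[("P1", "P1")] == pytest.approx(50.0)

    def test_simulated_phylum_divergence_lands_in_expected_band(self):
        """Two phylum clusters derived from one root: members within a
        cluster share ~72% identity (0.85^2 per-site retention at 15%
        divergence) while between-cluster identity drops to ~46-49%
        (0.8*0.85 retention per branch, squared, plus coincidental
        matches), the regime described for glutamate decarboxylases."""
        rng_seed = 5
        spec_a = FamilySimSpec("GluDC", "SGHK", point_lengths(450), divergence=0.15)
        recs = []
        labels = {}
        import numpy as np_

        from aadckit.simulate import _mutate, _render, _simulate_family_draw

        rng = np_.random.default_rng(rng_seed)
        root = _simulate_family_draw(spec_a, 1, rng)
        for phylum in ("Bacteroidota", "Bacillota"):
            sub = _mutate(root.seq_codes[0], 0.20, rng,
                          frozen=slice(root.k_position - 4, root.k_position))
            for i in range(4):
                codes = _mutate(sub, 0.15, rng,
                                frozen=slice(root.k_position - 4, root.k_position))
                rid = f"{phylum[:4]}{i}"
                recs.append((rid, _render(codes, 450, "SGHK", root.k_position)))
                labels[rid] = phylum
        pim = pim_from_msa(build_msa(recs))
        out = phylum_block_summary(pim, labels)
        within = [out[("Bacillota", "Bacillota")], out[("Bacteroidota", "Bacteroidota")]]
        between = out[("Bacillota", "Bacteroidota")]
        assert all(w > between for w in within)
        assert 40.0 < between < 55.0
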