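"""Dataset-construction rules: I/O, filtering, extension, shuffling, splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circrbp.sequence_io import (
    GenomicInterval,
    NEGATIVE,
    POSITIVE,
    SequenceRecord,
    deduplicate,
    dinucleotide_counts,
    dinucleotide_shuffle,
    extend_to_fixed_length,
    filter_by_length,
    make_negatives,
    read_fasta,
    split_dataset,
    write_fasta,
)

rna = st.text(alphabet="ACGU", min_size=2, max_size=200)


def _random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), n))


class TestFasta:
    def test_t_mapped_to_u_and_uppercased(self, tmp_path):
        p = tmp_path / "in.fa"
        p.write_text(">x\nacGT\n")
        (rec,) = read_fasta(p)
        assert rec.seq == "ACGU"

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        assert read_fasta(p) == []

    def test_ambiguous_record_rejected_with_warning(self, tmp_path, caplog):
        p = tmp_path / "n.fa"
        p.write_text(">y\nACGN\n>z\nACGU\n")
        with caplog.at_level("WARNING"):
            records = read_fasta(p)
        assert [r.id for r in records] == ["z"]
        assert any("rejecting" in m for m in caplog.messages)

    def test_malformed_header_raises_with_line(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text("ACGU\n>x\nACGU\n")
        with pytest.raises(ValueError, match="bad.fa:1"):
            read_fasta(p)

    def test_round_trip_preserves_seq_id_label(self, tmp_path):
        records = [
            SequenceRecord(id="a", seq="ACGUACGU", label=POSITIVE),
            SequenceRecord(id="b", seq="UUUU", label=NEGATIVE),
        ]
        out = tmp_path / "out.fa"
        write_fasta(records, out)
        back = read_fasta(out)
        assert [(r.id, r.seq, r.label) for r in back] == [(r.id, r.seq, r.label) for r in records]


class TestFilterByLength:
    def test_strict_bounds_on_toy_lengths(self):
        records = [SequenceRecord(id=str(n), seq="A" * n) for n in (30, 50, 51, 75, 99, 100, 120)]
        kept = filter_by_length(records)
        assert [len(r) for r in kept] == [51, 75, 99]

    def test_empty_input(self):
        assert filter_by_length([]) == []

    def test_idempotent(self):
        records = [SequenceRecord(id=str(n), seq="C" * n) for n in range(40, 120, 7)]
        once = filter_by_length(records)
        assert filter_by_length(once) == once

    def test_inverted_bounds_error(self):
        with pytest.raises(ValueError):
            filter_by_length([], min_len=10, max_len=5)


class TestExtendToFixedLength:
    def _genome(self, rng, n=10_000):
        return {"chr1": "".join(rng.choice(list("ACGT"), n))}

    def test_extends_to_exactly_100(self, rng):
        genome = self._genome(rng)
        iv = GenomicInterval("chr1", 1000 - 36, 1000 + 37)  # length 73 around 1000
        rec = extend_to_fixed_length(iv, genome)
        assert rec is not None and len(rec.seq) == 100
        assert len(rec.interval) == 100
        # window centered on the interval midpoint
        assert rec.interval.start == (iv.start + iv.end) // 2 - 50

    def test_interval_already_target_length_unchanged(self, rng):
        genome = self._genome(rng)
        iv = GenomicInterval("chr1", 200, 300)
        rec = extend_to_fixed_length(iv, genome)
        assert rec.interval.start == 200 and rec.interval.end == 300
        assert rec.seq == genome["chr1"][200:300].replace("T", "U")

    def test_left_underflow_dropped(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 100))}
        iv = GenomicInterval("chr1", 10, 70)  # center 40, window [-10, 90)
        assert extend_to_fixed_length(iv, genome) is None

    def test_minus_strand_reverse_complemented(self):
        genome = {"chr1": "A" * 60 + "ACGT" * 30}
        iv = GenomicInterval("chr1", 100, 160, strand="-")
        plus = extend_to_fixed_length(GenomicInterval("chr1", 100, 160, "+"), genome)
        minus = extend_to_fixed_length(iv, genome)
        from Bio.Seq import Seq

        expect = str(Seq(plus.seq.replace("U", "T")).reverse_complement()).replace("T", "U")
        assert minus.seq == expect

    def test_missing_chrom_raises(self):
        with pytest.raises(KeyError):
            extend_to_fixed_length(GenomicInterval("chrX", 10, 60), {"chr1": "A" * 200})

    @pytest.mark.parametrize("start,end", [(55, 120), (300, 373), (9_900, 9_980)])
    def test_always_exact_length_or_dropped(self, rng, start, end):
        genome = self._genome(rng)
        rec = extend_to_fixed_length(GenomicInterval("chr1", start, end), genome)
        assert rec is None or len(rec.seq) == 100


class TestDeduplicate:
    def test_identical_intervals_collapse(self):
        iv = GenomicInterval("chr1", 0, 10)
        a = SequenceRecord(id="a", seq="ACGUACGUAC", interval=iv)
        b = SequenceRecord(id="b", seq="ACGUACGUAC", interval=iv)
        assert deduplicate([a, b]) == [a]

    def test_identical_sequences_without_intervals_collapse(self):
        a = SequenceRecord(id="a", seq="ACGU")
        b = SequenceRecord(id="b", seq="ACGU")
        c = SequenceRecord(id="c", seq="UGCA")
        assert deduplicate([a, b, c]) == [a, c]

    def test_distinct_records_identity(self):
        records = [SequenceRecord(id=str(i), seq="ACGU" + "A" * i) for i in range(5)]
        assert deduplicate(records) == records


class TestDinucleotideShuffle:
    @settings(max_examples=300, derandomize=True)
    @given(seq=rna, seed=st.integers(0, 2**31 - 1))
    def test_conserves_dinucleotide_counts_exactly(self, seq, seed):
        out = dinucleotide_shuffle(seq, np.random.default_rng(seed))
        assert dinucleotide_counts(out) == dinucleotide_counts(seq)
        assert out[0] == seq[0] and out[-1] == seq[-1]

    def test_unique_arrangement_fixed_point(self, rng):
        assert dinucleotide_shuffle("AAAA", rng) == "AAAA"

    def test_short_input_returned_unchanged(self, rng, caplog):
        with caplog.at_level("WARNING"):
            assert dinucleotide_shuffle("A", rng) == "A"
        assert caplog.messages

    def test_output_in_enumerated_valid_set_for_12mer(self, rng):
        from sympy.utilities.iterables import multiset_permutations

        seq = "ACGUACGUACGU"
        target = dinucleotide_counts(seq)
        valid = {
            seq[0] + "".join(mid) + seq[-1]
            for mid in multiset_permutations(list(seq[1:-1]))
            if dinucleotide_counts(seq[0] + "".join(mid) + seq[-1]) == target
        }
        for _ in range(25):
            assert dinucleotide_shuffle(seq, rng) in valid

    def test_usually_differs_from_input_on_random_100mers(self, rng):
        n_diff = 0
        for _ in range(200):
            seq = _random_rna(rng, 100)
            n_diff += dinucleotide_shuffle(seq, rng) != seq
        assert n_diff >= 0.95 * 200


class TestMakeNegatives:
    def _positives(self, rng, n=10):
        return [
            SequenceRecord(id=f"p{i}", seq=_random_rna(rng, 100), label=POSITIVE) for i in range(n)
        ]

    def test_one_negative_per_positive_with_matched_composition(self, rng):
        pos = self._positives(rng)
        neg = make_negatives(pos, seed=3)
        assert len(neg) == len(pos)
        for p, n in zip(pos, neg):
            assert n.id == p.id + "_shuf" and n.label == NEGATIVE
            assert dinucleotide_counts(n.seq) == dinucleotide_counts(p.seq)

    def test_seeded_determinism(self, rng):
        pos = self._positives(rng)
        assert [r.seq for r in make_negatives(pos, seed=7)] == [
            r.seq for r in make_negatives(pos, seed=7)
        ]

    def test_rejects_unlabeled_input(self, rng):
        pos = [SequenceRecord(id="x", seq=_random_rna(rng, 50))]
        with pytest.raises(ValueError):
            make_negatives(pos, seed=0)


class TestSplitDataset:
    def _paired(self, rng, n_pairs):
        pos = [
            SequenceRecord(id=f"p{i}", seq=_random_rna(rng, 60), label=POSITIVE)
            for i in range(n_pairs)
        ]
        return pos + make_negatives(pos, seed=0)

    def test_pair_level_fractions(self, rng):
        records = self._paired(rng, 1000)
        ds = split_dataset(records, seed=5)
        assert len(ds.test) == 400  # 200 pairs
        assert len(ds.validation) == 160  # 80 pairs
        assert len(ds.train) == 1440

    def test_partners_share_partition_and_partitions_disjoint(self, rng):
        records = self._paired(rng, 50)
        ds = split_dataset(records, seed=2)
        parts = {"train": ds.train, "val": ds.validation, "test": ds.test}
        ids = {name: {r.id for r in recs} for name, recs in parts.items()}
        assert not (ids["train"] & ids["val"]) and not (ids["train"] & ids["test"])
        for name, idset in ids.items():
            for rid in idset:
                partner = rid.removesuffix("_shuf") if rid.endswith("_shuf") else rid + "_shuf"
                assert partner in idset

    def test_labels_balanced_within_one(self, rng):
        records = self._paired(rng, 101)
        ds = split_dataset(records, seed=9)
        for part in (ds.train, ds.validation, ds.test):
            n_pos = sum(r.label == POSITIVE for r in part)
            assert abs(n_pos - (len(part) - n_pos)) <= 1

    def test_reproducible_from_seed(self, rng):
        records = self._paired(rng, 40)
        a = split_dataset(records, seed=4)
        b = split_dataset(records, seed=4)
        assert [r.id for r in a.train] == [r.id for r in b.train]
        assert [r.id for r in a.test] == [r.id for r in b.test]

    def test_too_few_records_error(self, rng):
        with pytest.raises(ValueError):
            split_dataset(self._paired(rng, 3)[:6], seed=0)
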