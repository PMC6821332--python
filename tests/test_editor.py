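"""Editing behaviour against the exact k-mer oracle (zero false positives)."""

import numpy as np
import pytest

from kmerpolish.editor import (
    EditRecord,
    PolishConfig,
    assess_position,
    polish_assembly,
    polish_contig,
    try_indels,
    try_substitutions,
)
from kmerpolish.io_formats import SeqRecord
from kmerpolish.kmer_bloom import ExactKmerIndex
from kmerpolish.synthetic import mutate_genome, random_genome

from conftest import canon, random_seq

K = 25


def oracle(truth_seq: str, k: int = K) -> ExactKmerIndex:
    return ExactKmerIndex.from_sequences([truth_seq], k)


def apply_edits(draft: str, edits: list[EditRecord]) -> str:
    """Independent patcher: replay records (original coordinates) onto the draft."""
    out = []
    cursor = 0
    for e in edits:
        p = e.position - 1
        out.append(draft[cursor:p])
        assert draft[p : p + len(e.ref)] == e.ref
        out.append(e.alt)
        cursor = p + len(e.ref)
    out.append(draft[cursor:])
    return "".join(out)


class TestAssess:
    def test_all_present_no_missing(self, small_genome):
        bf = oracle(small_genome)
        cfg = PolishConfig(k=K)
        assert assess_position(small_genome, 500, bf, cfg) == 0

    def test_single_substitution_all_covering_absent(self, small_genome):
        bf = oracle(small_genome)
        cfg = PolishConfig(k=K)
        i = 600
        bad = small_genome[:i] + ("A" if small_genome[i] != "A" else "C") + small_genome[i + 1:]
        assert assess_position(bad, i, bf, cfg) == K

    def test_contig_start_clipped_denominator(self):
        seq = random_seq(2 * K, seed=21)
        bf = ExactKmerIndex(K)  # empty: everything absent
        cfg = PolishConfig(k=K)
        # base 2 is covered by windows starting 0..2 only
        assert assess_position(seq, 2, bf, cfg) == 3

    def test_k_mismatch_refused(self, small_genome):
        bf = oracle(small_genome, k=K)
        with pytest.raises(ValueError, match="does not match"):
            assess_position(small_genome, 100, bf, PolishConfig(k=31))


class TestSubstitutions:
    def test_truth_base_restored_with_full_support(self, small_genome):
        bf = oracle(small_genome)
        cfg = PolishConfig(k=K)
        i = 700
        truth_base = small_genome[i]
        alt = "A" if truth_base != "A" else "C"
        bad = small_genome[:i] + alt + small_genome[i + 1:]
        got = try_substitutions(bad, i, bf, cfg)
        assert got == (truth_base, K)

    def test_no_alternate_qualifies(self, small_genome):
        cfg = PolishConfig(k=K)
        bf = ExactKmerIndex(K)
        assert try_substitutions(small_genome, 500, bf, cfg) is None

    def test_tie_broken_by_base_order(self):
        # engineer equal support for two alternates at base i
        seq = random_seq(60, seed=33)
        i = 30
        assert seq[i] not in "ACGT"[:0]
        base_alts = [b for b in "ACGT" if b != seq[i]][:2]
        kmers = []
        for alt in base_alts:
            mod = seq[:i] + alt + seq[i + 1:]
            # two covering windows each (ending at i and i+1)
            kmers.append(mod[i - K + 1 : i + 1])
            kmers.append(mod[i - K + 2 : i + 2])
        bf = ExactKmerIndex.from_kmers(kmers, K)
        cfg = PolishConfig(k=K, y=13.0)  # accept threshold ceil(25/13)=2
        got = try_substitutions(seq, i, bf, cfg)
        assert got is not None
        assert got[0] == min(base_alts)


class TestIndels:
    def test_two_base_insertion_recovered(self, small_genome):
        bf = oracle(small_genome)
        cfg = PolishConfig(k=K)
        p = 800
        draft = small_genome[:p] + small_genome[p + 2:]  # missing 2 truth bases
        got = try_indels(draft, p, bf, cfg)
        assert got is not None
        kind, bases, n_sup = got
        assert (kind, bases) == ("insertion", small_genome[p : p + 2])
        fixed = draft[:p] + bases + draft[p:]
        assert fixed == small_genome

    def test_three_base_deletion_recovered(self, small_genome):
        bf = oracle(small_genome)
        cfg = PolishConfig(k=K)
        p = 900
        draft = small_genome[:p] + "GTC" + small_genome[p:]  # 3 extra bases
        # adjust if the inserted triplet accidentally extends a genomic match
        got = try_indels(draft, p, bf, cfg)
        assert got is not None
        kind, bases, _ = got
        assert kind == "deletion"
        fixed = draft[:p] + draft[p + len(bases):]
        assert fixed == small_genome

    def test_no_single_indel_exceeds_bound(self, small_genome):
        bf = oracle(small_genome)
        cfg = PolishConfig(k=K, max_indel=5)
        p = 1000
        draft = small_genome[:p] + small_genome[p + 6:]  # 6-base gap
        _, edits = polish_contig(draft, bf, cfg)
        # a repair may be split across passes, but every single indel stays
        # within the max_indel bound
        assert edits
        assert all(len(e.ref) <= 5 and len(e.alt) <= 5 for e in edits)

    def test_max_indel_one_cannot_bridge_two_base_gap_alone(self, small_genome):
        bf = oracle(small_genome)
        p = 1100
        draft = small_genome[:p] + small_genome[p + 2:]
        got = try_indels(draft, p, bf, PolishConfig(k=K, max_indel=1))
        if got is not None:  # only a 1-base partial repair is reachable
            assert len(got[1]) == 1


class TestPolishContig:
    def test_identity_genome_untouched(self, medium_genome):
        bf = oracle(medium_genome)
        out, edits = polish_contig(medium_genome, bf, PolishConfig(k=K))
        assert out == medium_genome and edits == []

    def test_short_contig_passthrough(self):
        bf = ExactKmerIndex(K)
        out, edits = polish_contig("ACGTACG", bf, PolishConfig(k=K))
        assert out == "ACGTACG" and edits == []

    def test_full_recovery_of_isolated_errors_50kb(self):
        truth = random_genome(50_000, seed=77)
        draft, truthset = mutate_genome(truth, 0.001, 0.001,
                                        min_spacing=2 * K, seed=78)
        bf = oracle(truth.seq)
        out, edits = polish_contig(draft.seq, bf, PolishConfig(k=K))
        assert out == truth.seq
        assert len(edits) == len(truthset)

    def test_records_reproduce_output(self):
        truth = random_genome(20_000, seed=79)
        draft, _ = mutate_genome(truth, 0.001, 0.001, min_spacing=2 * K, seed=80)
        bf = oracle(truth.seq)
        out, edits = polish_contig(draft.seq, bf, PolishConfig(k=K))
        assert apply_edits(draft.seq, edits) == out

    def test_coordinate_soundness(self):
        truth = random_genome(20_000, seed=81)
        draft, _ = mutate_genome(truth, 0.001, 0.001, min_spacing=2 * K, seed=82)
        bf = oracle(truth.seq)
        _, edits = polish_contig(draft.seq, bf, PolishConfig(k=K))
        assert edits
        for e in edits:
            assert draft.seq[e.position - 1 : e.position - 1 + len(e.ref)] == e.ref
        positions = [e.position for e in edits]
        assert positions == sorted(positions) and len(set(positions)) == len(positions)

    def test_quiescence_on_repolish(self):
        truth = random_genome(20_000, seed=83)
        draft, _ = mutate_genome(truth, 0.001, 0.001, min_spacing=2 * K, seed=84)
        bf = oracle(truth.seq)
        once, edits1 = polish_contig(draft.seq, bf, PolishConfig(k=K))
        twice, edits2 = polish_contig(once, bf, PolishConfig(k=K))
        assert twice == once and edits2 == []

    def test_leniency_monotonicity(self):
        truth = random_genome(20_000, seed=85)
        draft, _ = mutate_genome(truth, 0.001, 0.001, min_spacing=2 * K, seed=86)
        bf = oracle(truth.seq)
        # lowering a divisor raises its threshold: never more edits
        base_edits = len(polish_contig(draft.seq, bf, PolishConfig(k=K))[1])
        for cfg in (PolishConfig(k=K, x=2.0), PolishConfig(k=K, y=3.0)):
            assert len(polish_contig(draft.seq, bf, cfg)[1]) <= base_edits

    def test_substitutions_only_mode(self):
        truth = random_genome(20_000, seed=87)
        draft, truthset = mutate_genome(truth, 0.001, 0.001, min_spacing=2 * K, seed=88)
        bf = oracle(truth.seq)
        _, edits = polish_contig(draft.seq, bf, PolishConfig(k=K, mode="substitutions-only"))
        assert all(e.kind == "substitution" for e in edits)

    def test_determinism(self):
        truth = random_genome(10_000, seed=89)
        draft, _ = mutate_genome(truth, 0.001, 0.001, min_spacing=2 * K, seed=90)
        bf = oracle(truth.seq)
        r1 = polish_contig(draft.seq, bf, PolishConfig(k=K))
        r2 = polish_contig(draft.seq, bf, PolishConfig(k=K))
        assert r1 == r2


class TestPolishAssembly:
    def test_two_contigs_only_mutated_one_edited(self):
        a = random_genome(5000, seed=91, name="clean")
        b = random_genome(5000, seed=92, name="dirty")
        draft_b, _ = mutate_genome(b, 0.001, 0.001, min_spacing=2 * K, seed=93)
        bf = ExactKmerIndex.from_sequences([a.seq, b.seq], K)
        recs = [SeqRecord("clean", a.seq), SeqRecord("dirty", draft_b.seq)]
        edited, edits = polish_assembly(recs, bf, PolishConfig(k=K))
        assert [r.id for r in edited] == ["clean", "dirty"]
        assert edited[0].seq == a.seq
        assert edited[1].seq == b.seq
        assert edits and all(e.contig == "dirty" for e in edits)

    def test_empty_assembly(self):
        bf = ExactKmerIndex(K)
        edited, edits = polish_assembly([], bf, PolishConfig(k=K))
        assert edited == [] and edits == []
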