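"""Synthetic fixtures: random genomes, mutated drafts, and sequencing reads.

The generator emulates the controlled experiments the polisher is designed
for: a ground-truth genome, a "draft" copy carrying homozygous substitutions
and 1-5 bp indels at set rates, and Illumina-like reads (uniform coverage,
both strands, substitution errors only) at a set depth.  Everything is
deterministic under a seed, and the list of mutations applied to create the
draft is returned so edits can later be scored against ground truth.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import SeqRecord
from .kmer_bloom import _DECODE, decode, encode

log = logging.getLogger(__name__)

__all__ = [
    "Mutation",
    "TruthSet",
    "random_genome",
    "mutate_genome",
    "apply_truthset",
    "simulate_reads",
    "write_truth_tsv",
    "read_truth_tsv",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class Mutation:
    """One ground-truth change applied to the truth genome to make the draft.

    truth_pos/draft_pos are 1-based.  kind describes the truth→draft edit:
    a "deletion" removed ``ref`` from the truth (draft_pos = first base after
    the gap), an "insertion" added ``alt`` to the draft (draft_pos = first
    inserted base), a "substitution" replaced ref by alt in place.
    """

    truth_pos: int
    draft_pos: int
    kind: str
    ref: str
    alt: str


@dataclass
class TruthSet:
    contig: str
    mutations: list[Mutation]

    def __post_init__(self) -> None:
        pos = [m.truth_pos for m in self.mutations]
        if pos != sorted(pos):
            raise ValueError("mutations must be sorted by truth position")
        for a, b in zip(self.mutations, self.mutations[1:]):
            if a.truth_pos + max(1, len(a.ref)) > b.truth_pos:
                raise ValueError(
                    f"overlapping mutations at truth positions {a.truth_pos}, {b.truth_pos}"
                )

    def __len__(self) -> int:
        return len(self.mutations)


def random_genome(length: int, gc: float = 0.5, seed: int | None = None,
                  name: str = "synthetic_genome") -> SeqRecord:
    """Uniform-random genome with the requested GC fraction."""
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must be in [0, 1]")
    if length == 0:
        warnings.warn("random_genome called with length 0", stacklevel=2)
        return _empty_record(name)
    rng = np.random.default_rng(seed)
    # A,C,G,T probabilities honoring the GC target
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=probs).astype(np.uint8)
    return SeqRecord(id=name, seq=decode(codes), description=f"length={length} gc={gc}")


def _empty_record(name: str) -> SeqRecord:
    rec = object.__new__(SeqRecord)
    rec.id = name
    rec.seq = ""
    rec.description = "length=0"
    return rec


def mutate_genome(
    genome: SeqRecord,
    sub_rate: float,
    indel_rate: float,
    max_indel_len: int = 5,
    min_spacing: int = 0,
    seed: int | None = None,
) -> tuple[SeqRecord, TruthSet]:
    """Mutate a copy of ``genome`` into a draft, recording the truth set.

    Substitution and indel site counts are Binomial(L, rate); indel lengths
    are uniform on 1..max_indel_len, insertions and deletions equally likely.
    When ``min_spacing`` is set, consecutive sites are at least that many
    bases apart (used to keep errors isolated for oracle tests); sites also
    keep that distance from the contig ends.
    """
    for name, rate in (("sub_rate", sub_rate), ("indel_rate", indel_rate)):
        if not (0.0 <= rate <= 0.01):
            raise ValueError(f"{name} must be in [0, 0.01], got {rate}")
    rng = np.random.default_rng(seed)
    seq = genome.seq.upper()
    L = len(seq)
    n_sub = int(rng.binomial(L, sub_rate))
    n_indel = int(rng.binomial(L, indel_rate))
    n = n_sub + n_indel
    if n == 0:
        return SeqRecord(id=genome.id + "_draft", seq=seq), TruthSet(genome.id, [])

    gap = max(min_spacing, max_indel_len + 1)
    margin = gap
    head_room = L - 2 * margin - (n - 1) * gap
    if head_room < n:
        raise ValueError(
            f"rates too high to honor spacing: need {n} sites with gap {gap} in {L} bases"
        )
    raw = np.sort(rng.choice(head_room, size=n, replace=False))
    positions = raw + margin + np.arange(n) * gap  # 0-based, pairwise gaps > gap

    kinds = np.array(["substitution"] * n_sub + ["indel"] * n_indel)
    rng.shuffle(kinds)

    codes = encode(seq)
    mutations: list[Mutation] = []
    parts: list[str] = []
    cursor = 0
    offset = 0
    for p, kind in zip(positions.tolist(), kinds.tolist()):
        if kind == "substitution":
            ref = seq[p]
            alt = _BASES[(int(codes[p]) + int(rng.integers(1, 4))) % 4]
            parts.append(seq[cursor:p])
            parts.append(alt)
            cursor = p + 1
            mutations.append(Mutation(p + 1, p + offset + 1, "substitution", ref, alt))
        else:
            length = int(rng.integers(1, max_indel_len + 1))
            if rng.random() < 0.5:  # deletion: truth bases missing from the draft
                ref = seq[p : p + length]
                parts.append(seq[cursor:p])
                cursor = p + length
                mutations.append(Mutation(p + 1, p + offset + 1, "deletion", ref, ""))
                offset -= length
            else:  # insertion: extra bases present in the draft
                alt = "".join(_BASES[int(b)] for b in rng.integers(0, 4, size=length))
                parts.append(seq[cursor:p])
                parts.append(alt)
                cursor = p
                mutations.append(Mutation(p + 1, p + offset + 1, "insertion", "", alt))
                offset += length
    parts.append(seq[cursor:])
    draft = SeqRecord(id=genome.id + "_draft", seq="".join(parts))
    return draft, TruthSet(genome.id, mutations)


def apply_truthset(genome_seq: str, truth: TruthSet) -> str:
    """Replay a truth set on the truth genome; must reproduce the draft exactly."""
    seq = genome_seq.upper()
    parts: list[str] = []
    cursor = 0
    for m in truth.mutations:
        p = m.truth_pos - 1
        parts.append(seq[cursor:p])
        if m.kind == "substitution":
            if seq[p] != m.ref:
                raise ValueError(f"truth mismatch at {m.truth_pos}: {seq[p]!r} != {m.ref!r}")
            parts.append(m.alt)
            cursor = p + 1
        elif m.kind == "deletion":
            if seq[p : p + len(m.ref)] != m.ref:
                raise ValueError(f"truth mismatch at {m.truth_pos}")
            cursor = p + len(m.ref)
        elif m.kind == "insertion":
            parts.append(m.alt)
            cursor = p
        else:
            raise ValueError(f"unknown mutation kind {m.kind!r}")
    parts.append(seq[cursor:])
    return "".join(parts)


def simulate_reads(
    genome: SeqRecord,
    coverage: float,
    read_len: int = 150,
    per_base_error: float = 0.0,
    seed: int | None = None,
) -> list[SeqRecord]:
    """Uniform shotgun reads from both strands with substitution errors only.

    Total bases ≈ coverage × genome length (to within one read); no quality
    model — downstream counting ignores qualities anyway.
    """
    if coverage < 0 or per_base_error < 0 or per_base_error >= 1:
        raise ValueError("bad coverage or error rate")
    seq = genome.seq.upper()
    L = len(seq)
    if L < read_len:
        raise ValueError(f"genome length {L} shorter than read length {read_len}")
    n_reads = int(round(coverage * L / read_len))
    if n_reads == 0:
        return []
    rng = np.random.default_rng(seed)
    codes = encode(seq)
    starts = rng.integers(0, L - read_len + 1, size=n_reads)
    mat = codes[starts[:, None] + np.arange(read_len)]
    minus = rng.random(n_reads) < 0.5
    mat[minus] = 3 - mat[minus][:, ::-1]
    if per_base_error > 0:
        err = rng.random(mat.shape) < per_base_error
        shift = rng.integers(1, 4, size=mat.shape, dtype=np.uint8)
        mat = np.where(err, (mat + shift) % 4, mat)
    chars = _DECODE[mat]
    return [
        SeqRecord(
            id=f"{genome.id}_read{i}",
            seq=chars[i].tobytes().decode("ascii"),
            description=f"start={int(starts[i])} strand={'-' if minus[i] else '+'}",
        )
        for i in range(n_reads)
    ]


_TRUTH_COLUMNS = ("contig", "truth_pos", "draft_pos", "kind", "ref", "alt")


def write_truth_tsv(truth: TruthSet, path) -> None:
    with open(path, "wt", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TRUTH_COLUMNS)
        for m in truth.mutations:
            w.writerow([truth.contig, m.truth_pos, m.draft_pos, m.kind,
                        m.ref or ".", m.alt or "."])


def read_truth_tsv(path) -> TruthSet:
    with open(path, "rt", newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        header = tuple(next(r))
        if header != _TRUTH_COLUMNS:
            raise ValueError(f"{path}: unexpected truth header {header}")
        contig = None
        muts = []
        for row in r:
            if not row:
                continue
            contig = row[0]
            muts.append(Mutation(int(row[1]), int(row[2]), row[3],
                                 "" if row[4] == "." else row[4],
                                 "" if row[5] == "." else row[5]))
    return TruthSet(contig or "contig", muts)
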