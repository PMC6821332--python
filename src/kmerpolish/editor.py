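"""Draft-assembly polishing by k-mer presence/absence.

Each contig is scanned 5'→3'.  Whenever a window is absent from the k-mer
filter, the 3'-end base of that window is scrutinized: if at least
ceil(d/x) of the d valid windows covering that base are absent (first
leniency threshold), candidate fixes are tried — the three alternate bases
first, then deletions and insertions of up to ``max_indel`` bases.  A
candidate must anchor (the k-mer ending at the changed base, with the change
applied, is itself present in the filter) and is accepted when additionally
at least ceil(d/y) of the windows containing the changed sequence are
present (second leniency threshold).  After an accepted
edit the scan resumes just past the edited site on the edited sequence, so a
position is never revisited.

The filter argument can be a :class:`~kmerpolish.kmer_bloom.KmerBloomFilter`
or an :class:`~kmerpolish.kmer_bloom.ExactKmerIndex` (the zero-false-positive
oracle); only homozygous errors are targeted — there is no allele-aware logic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .kmer_bloom import decode, encode, window_hashes

log = logging.getLogger(__name__)

__all__ = [
    "PolishConfig",
    "EditRecord",
    "assess_position",
    "try_substitutions",
    "try_indels",
    "polish_contig",
    "polish_assembly",
]

_BASES = "ACGT"
_SCAN_CHUNK = 8192  # windows re-hashed per vectorized scan block


@dataclass(frozen=True)
class PolishConfig:
    """Editing thresholds.

    x : missing-leniency divisor — attempt an edit only when >= ceil(d/x) of
        the d valid k-mers covering a base are absent (default 5.0).
    y : present-leniency divisor — accept a candidate only when >= ceil(d/y)
        of the valid k-mers containing the changed sequence are present
        (default 9.0).  Larger divisors mean lower thresholds, i.e. more
        lenient behavior.
    max_indel : largest insertion/deletion attempted, 1..5 bases.
    mode : "subs+indels" or "substitutions-only".
    """

    k: int
    x: float = 5.0
    y: float = 9.0
    max_indel: int = 5
    mode: str = "subs+indels"

    def __post_init__(self) -> None:
        if not (4 <= self.k <= 255):
            raise ValueError(f"k must be in [4, 255], got {self.k}")
        if self.x < 1 or self.y < 1:
            raise ValueError("leniency divisors x and y must be >= 1")
        if not (1 <= self.max_indel <= 5):
            raise ValueError(f"max_indel must be in [1, 5], got {self.max_indel}")
        if self.mode not in ("subs+indels", "substitutions-only"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def attempt_threshold(self, d: int) -> int:
        return math.ceil(d / self.x)

    def accept_threshold(self, d: int) -> int:
        return math.ceil(d / self.y)


@dataclass
class EditRecord:
    """One accepted change, in 1-based coordinates on the ORIGINAL draft.

    For substitutions ref/alt are single bases; insertions have ref == "" and
    position = the base before which ``alt`` was inserted; deletions have
    alt == "" and position = the first removed base.  n_missing is the absent
    k-mer count that triggered the attempt, n_support the present k-mer count
    backing the accepted change.
    """

    contig: str
    position: int
    kind: str  # substitution | insertion | deletion
    ref: str
    alt: str
    n_missing: int
    n_support: int


def _check_filter(bf, cfg: PolishConfig) -> None:
    if bf.k != cfg.k:
        raise ValueError(f"filter k={bf.k} does not match editor k={cfg.k}")


def _presence(codes: np.ndarray, bf) -> tuple[np.ndarray, np.ndarray]:
    h1, h2, valid = window_hashes(codes, bf.k)
    present = np.zeros(len(valid), dtype=bool)
    if valid.any():
        present[valid] = bf.contains_hashes(h1[valid], h2[valid])
    return present, valid


def _assess(codes: np.ndarray, i: int, bf, cfg: PolishConfig) -> tuple[int, int]:
    """(n_missing, n_valid) over the windows covering base i, clipped to the contig."""
    k = cfg.k
    lo = max(0, i - k + 1)
    hi = min(i, len(codes) - k)  # last admissible window start
    if hi < lo:
        return 0, 0
    present, valid = _presence(codes[lo : hi + k], bf)
    return int((valid & ~present).sum()), int(valid.sum())


def _support(local: np.ndarray, bf) -> tuple[int, int]:
    """(n_present, n_valid) over every window of a modified local segment."""
    present, valid = _presence(local, bf)
    return int((present & valid).sum()), int(valid.sum())


def _kmer_present(kmer_codes: np.ndarray, bf) -> bool:
    """Presence of one k-length code window (False when it contains non-ACGT)."""
    present, valid = _presence(kmer_codes, bf)
    return bool(len(present) == 1 and valid[0] and present[0])


def _best_substitution(codes: np.ndarray, i: int, bf, cfg: PolishConfig):
    """Best (alt_code, n_support) among the three alternate bases, or None.

    A candidate base must first anchor: the permuted k-mer ending at the
    changed base has to be present in the filter.  Anchored alternates are
    then scored on present overlapping windows; all qualifying ones are
    compared and ties go to the first in fixed A<C<G<T order.
    """
    k = cfg.k
    lo = max(0, i - k + 1)
    hi = min(i, len(codes) - k)
    segment = codes[lo : hi + k].copy()
    orig = int(codes[i])
    has_anchor = i - k + 1 >= 0
    best = None
    for alt in range(4):
        if alt == orig:
            continue
        segment[i - lo] = alt
        if has_anchor and not _kmer_present(segment[i - k + 1 - lo : i - lo + 1], bf):
            continue
        n_sup, d = _support(segment, bf)
        if d and n_sup >= cfg.accept_threshold(d) and (best is None or n_sup > best[1]):
            best = (alt, n_sup, d)
    return best


def _indel_candidates(codes: np.ndarray, i: int, bf, cfg: PolishConfig):
    """Best (kind, bases_codes, n_support) indel at base i, or None.

    Every candidate must anchor exactly like substitutions: a deletion's
    junction k-mer (ending at the first retained base) or an insertion's
    k-mer ending at its last inserted base must be present in the filter
    before overlapping windows are scored.  Deletions of 1..max_indel
    original bases at i are scored on the windows spanning the new junction;
    insertions of 1..max_indel bases before i on the windows containing
    inserted bases.  Insertion strings are enumerated exhaustively for
    lengths 1-2 and by prefix extension beyond that: only anchored prefixes
    are grown, since a correct partial insertion always makes the window
    ending at its last inserted base a genomic k-mer.  Within a length class
    the first candidate (lexicographic order) to reach the acceptance
    threshold wins; across classes the higher support wins, ties going to
    the shorter edit and then deletion over insertion.
    """
    k = cfg.k
    lo = max(0, i - k + 1)
    left = codes[lo:i]
    winners: list[tuple[int, int, int, str, np.ndarray]] = []
    # entries: (n_sup, length, kind_rank, kind, bases); kind_rank 0=deletion, 1=insertion

    for L in range(1, cfg.max_indel + 1):  # deletions, each length its own class
        if i + L > len(codes):
            break
        right = codes[i + L : i + L + (k - 1)]
        local = np.concatenate([left, right])
        if len(local) < k:
            continue
        junction = len(left)  # local index of the first retained base
        if not _kmer_present(local[junction - k + 1 : junction + 1], bf):
            continue
        n_sup, d = _support(local, bf)
        if d and n_sup >= cfg.accept_threshold(d):
            winners.append((n_sup, d, L, 0, "deletion", codes[i : i + L].copy()))

    right_ins = codes[i : i + (k - 1)]

    def _insertion_local(bases: tuple[int, ...]) -> np.ndarray:
        return np.concatenate([left, np.array(bases, dtype=np.uint8), right_ins])

    prefixes: list[tuple[int, ...]] = [()]
    for L in range(1, cfg.max_indel + 1):
        class_winner = None
        next_prefixes: list[tuple[int, ...]] = []
        for stem in prefixes:
            for b in range(4):
                cand = stem + (b,)
                local = _insertion_local(cand)
                if len(local) < k:
                    continue
                last_ins = len(left) + L - 1  # local index of last inserted base
                anchored = last_ins - k + 1 >= 0 and _kmer_present(
                    local[last_ins - k + 1 : last_ins + 1], bf
                )
                if anchored:
                    if class_winner is None:
                        n_sup, d = _support(local, bf)
                        if d and n_sup >= cfg.accept_threshold(d):
                            class_winner = (n_sup, d, L, 1, "insertion",
                                            np.array(cand, dtype=np.uint8))
                    next_prefixes.append(cand)
                elif L < 2:
                    next_prefixes.append(cand)
        if class_winner is not None:
            winners.append(class_winner)
        prefixes = next_prefixes
        if not prefixes:
            break

    if not winners:
        return None
    # rank by support fraction (window counts differ between classes),
    # ties to deletions, then to the shorter edit
    best = max(winners, key=lambda w: (w[0] / w[1], -w[3], -w[2]))
    return best[4], best[5], best[0], best[1]


# -- public, string-level wrappers (mirror the scanning internals) ----------

def assess_position(seq: str, i: int, bf, cfg: PolishConfig) -> int:
    """Absent k-mers among the valid windows covering base ``i`` (0-based)."""
    _check_filter(bf, cfg)
    n_missing, _ = _assess(encode(seq.upper()), i, bf, cfg)
    return n_missing


def try_substitutions(seq: str, i: int, bf, cfg: PolishConfig):
    """Best qualifying (alt_base, n_support) at base ``i``, or None."""
    _check_filter(bf, cfg)
    best = _best_substitution(encode(seq.upper()), i, bf, cfg)
    if best is None:
        return None
    alt, n_sup, _ = best
    return _BASES[alt], n_sup


def try_indels(seq: str, i: int, bf, cfg: PolishConfig):
    """Best qualifying (kind, bases, n_support) micro-indel at base ``i``, or None."""
    _check_filter(bf, cfg)
    cand = _indel_candidates(encode(seq.upper()), i, bf, cfg)
    if cand is None:
        return None
    kind, bases, n_sup, _ = cand
    return kind, decode(bases), n_sup


# -- contig scan ------------------------------------------------------------

def polish_contig(
    contig: str, bf, cfg: PolishConfig, contig_id: str = "contig"
) -> tuple[str, list[EditRecord]]:
    """Single 5'→3' editing pass over one contig.

    Returns the edited sequence and the accepted edits in original draft
    coordinates.  Contigs shorter than k pass through unedited.
    """
    _check_filter(bf, cfg)
    k = cfg.k
    seq = contig.upper()
    if len(seq) < k:
        log.info("contig %s shorter than k=%d; passed through unedited", contig_id, k)
        return seq, []

    codes = encode(seq)
    records: list[EditRecord] = []
    offset = 0  # current coordinate minus original coordinate
    s = 0
    while s <= len(codes) - k:
        end = min(s + _SCAN_CHUNK, len(codes) - k + 1)
        present, valid = _presence(codes[s : end + k - 1], bf)
        edited = False
        for t in np.flatnonzero(valid & ~present):
            w = s + int(t)
            i = w + k - 1  # scrutinized 3'-end base
            n_missing, d = _assess(codes, i, bf, cfg)
            if d == 0 or n_missing < cfg.attempt_threshold(d):
                continue
            orig_pos = i - offset + 1  # 1-based on the original draft
            # edits are emitted at strictly increasing original coordinates;
            # a base that maps onto an already-edited position is not revisited
            if records and orig_pos <= records[-1].position:
                continue

            sub = _best_substitution(codes, i, bf, cfg)
            indel = None
            # an indel can only win on support fraction, so skip the search
            # when the substitution already has every covering window present
            if cfg.mode == "subs+indels" and (sub is None or sub[1] < sub[2]):
                indel = _indel_candidates(codes, i, bf, cfg)
            if sub is not None and (indel is None or sub[1] / sub[2] >= indel[2] / indel[3]):
                alt, n_sup, _ = sub
                ref_base = _BASES[int(codes[i])]
                codes[i] = alt
                records.append(
                    EditRecord(contig_id, orig_pos, "substitution", ref_base,
                               _BASES[alt], n_missing, n_sup)
                )
                resume_base = i + 1
            elif indel is not None:
                kind, bases, n_sup, _ = indel
                if kind == "deletion":
                    records.append(
                        EditRecord(contig_id, orig_pos, "deletion", decode(bases),
                                   "", n_missing, n_sup)
                    )
                    codes = np.concatenate([codes[:i], codes[i + len(bases):]])
                    offset -= len(bases)
                    resume_base = i
                else:
                    records.append(
                        EditRecord(contig_id, orig_pos, "insertion", "",
                                   decode(bases), n_missing, n_sup)
                    )
                    codes = np.concatenate([codes[:i], bases, codes[i:]])
                    offset += len(bases)
                    resume_base = i + len(bases)
            else:
                continue
            # resume so the next scrutinized base is the one after the edit
            s = max(resume_base - k + 1, w + 1, 0)
            edited = True
            break
        if not edited:
            s = end
    return decode(codes), records


def polish_assembly(
    contigs: Iterable, bf, cfg: PolishConfig
) -> tuple[list, list[EditRecord]]:
    """Polish every contig in turn; order preserved, records grouped per contig.

    ``contigs`` is an iterable of objects with ``id`` and ``seq`` attributes
    (e.g. :class:`~kmerpolish.io_formats.SeqRecord`); edited copies of the
    same type are returned.
    """
    _check_filter(bf, cfg)
    edited_records = []
    all_edits: list[EditRecord] = []
    for rec in contigs:
        new_seq, edits = polish_contig(rec.seq, bf, cfg, contig_id=rec.id)
        edited_records.append(type(rec)(id=rec.id, seq=new_seq,
                                        description=getattr(rec, "description", "")))
        all_edits.extend(edits)
    n_sub = sum(1 for e in all_edits if e.kind == "substitution")
    n_ind = len(all_edits) - n_sub
    log.info("polished %d contig(s): %d edits (%d substitutions, %d indels)",
             len(edited_records), len(all_edits), n_sub, n_ind)
    return edited_records, all_edits
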