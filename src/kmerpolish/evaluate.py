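"""Score an edit set against a ground-truth mutation set.

A polisher edit counts as a true positive only when it both lies near an
unmatched truth mutation of the compatible class (substitution↔substitution,
indel↔indel — note a truth *insertion*, i.e. extra draft bases, is reverted
by an edit *deletion* and vice versa) and, when applied to the draft,
locally restores the truth sequence.  The sequence-restoration criterion is
stricter than coordinate matching and is immune to the left/right-shift
ambiguity of indels inside homopolymers.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import pandas as pd

from .editor import EditRecord, PolishConfig, polish_contig
from .filter_builder import BuildConfig, build_filter
from .synthetic import TruthSet, mutate_genome, random_genome, simulate_reads

log = logging.getLogger(__name__)

__all__ = ["EvalReport", "compare_edits", "run_experiment", "sweep"]

_FLANK = 15  # bases of context checked on each side during restoration


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def fdr(self) -> float:
        return self.fp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0


def _classes_compatible(edit_kind: str, truth_kind: str) -> bool:
    if truth_kind == "substitution":
        return edit_kind == "substitution"
    return edit_kind in ("insertion", "deletion")


def _restores(edit: EditRecord, mut, draft: str, reference: str) -> bool:
    """Does applying ``edit`` to the draft reproduce the truth locally?"""
    dp = mut.draft_pos - 1          # 0-based start of the mutation in the draft
    tp = mut.truth_pos - 1          # 0-based start in the truth genome
    left = min(_FLANK, dp, tp)
    d_end = dp + len(mut.alt)       # draft bases owned by the mutation
    t_end = tp + len(mut.ref)
    right = min(_FLANK, len(draft) - d_end, len(reference) - t_end)
    seg = draft[dp - left : d_end + right]
    expected = reference[tp - left : t_end + right]
    off = (edit.position - 1) - (dp - left)
    if off < 0 or off + len(edit.ref) > len(seg):
        return False
    if seg[off : off + len(edit.ref)] != edit.ref:
        return False
    patched = seg[:off] + edit.alt + seg[off + len(edit.ref):]
    return patched == expected


def compare_edits(
    edits: list[EditRecord],
    truth: TruthSet,
    draft: str,
    reference: str,
    window_sub: int = 0,
    window_indel: int = 5,
) -> EvalReport:
    """Match edits to truth mutations (greedy nearest-first) and tally TP/FP/FN.

    ``draft`` and ``reference`` are the full draft and truth sequences of the
    contig the truth set describes; they back the apply-and-compare check.
    Edits on other contigs count as false positives.
    """
    seen: set[tuple[str, int]] = set()
    for e in edits:
        key = (e.contig, e.position)
        if key in seen:
            raise ValueError(f"duplicate edit position {key}; the editor must not emit these")
        seen.add(key)

    candidates = []
    for ei, e in enumerate(edits):
        for ti, m in enumerate(truth.mutations):
            if not _classes_compatible(e.kind, m.kind):
                continue
            window = window_sub if e.kind == "substitution" else window_indel
            dist = abs(e.position - m.draft_pos)
            if dist > window:
                continue
            if _restores(e, m, draft, reference):
                candidates.append((dist, ei, ti))
    candidates.sort()
    matched_e: set[int] = set()
    matched_t: set[int] = set()
    for dist, ei, ti in candidates:
        if ei in matched_e or ti in matched_t:
            continue
        matched_e.add(ei)
        matched_t.add(ti)

    tp = len(matched_t)
    return EvalReport(tp=tp, fp=len(edits) - tp, fn=len(truth) - tp)


def run_experiment(
    genome_length: int = 1_000_000,
    sub_rate: float = 0.001,
    indel_rate: float = 0.001,
    coverage: float = 20.0,
    read_len: int = 150,
    per_base_error: float = 0.005,
    k: int = 25,
    x: float = 5.0,
    y: float = 9.0,
    max_indel: int = 5,
    p_target: float = 5e-4,
    gc: float = 0.5,
    seed: int = 0,
) -> EvalReport:
    """End-to-end simulated polishing run: genome → draft → reads → filter →
    polish → score.  Mutation sites are spaced more than 2k apart so every
    error is isolated at the scale the editor reasons over.
    """
    genome = random_genome(genome_length, gc=gc, seed=seed)
    draft, truth = mutate_genome(
        genome, sub_rate, indel_rate, max_indel_len=max_indel,
        min_spacing=2 * k, seed=seed + 1,
    )
    reads = simulate_reads(genome, coverage, read_len=read_len,
                           per_base_error=per_base_error, seed=seed + 2)
    bf = build_filter(reads, BuildConfig(k=k, p_target=p_target, threshold_mode="auto"))
    cfg = PolishConfig(k=k, x=x, y=y, max_indel=max_indel)
    _, edits = polish_contig(draft.seq, bf, cfg, contig_id=genome.id)
    return compare_edits(edits, truth, draft.seq, genome.seq)


def sweep(
    coverages=(15.0, 20.0, 30.0),
    ks=(25, 35, 45),
    rates=((0.001, 0.001), (0.0001, 0.0001)),
    seeds=(0,),
    genome_length: int = 1_000_000,
    **kwargs,
) -> pd.DataFrame:
    """Grid of polishing experiments; one tidy row per cell per seed."""
    rows = []
    for cov, k, (sr, ir), seed in itertools.product(coverages, ks, rates, seeds):
        rep = run_experiment(
            genome_length=genome_length, sub_rate=sr, indel_rate=ir,
            coverage=cov, k=k, seed=seed, **kwargs,
        )
        rows.append(
            dict(coverage=cov, k=k, sub_rate=sr, indel_rate=ir, seed=seed,
                 tp=rep.tp, fp=rep.fp, fn=rep.fn, recall=rep.recall, fdr=rep.fdr)
        )
        log.info("sweep cell cov=%g k=%d rates=(%g,%g) seed=%d: recall=%.4f fdr=%.4f",
                 cov, k, sr, ir, seed, rep.recall, rep.fdr)
    return pd.DataFrame(rows)
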