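"""Large-indel scanning of orthologous promoter (or any) sequences.

Each query is globally aligned to the reference with affine gap scores
(match +2, mismatch -3, gap open -5, gap extend -1 by default), which
favours one long gap over scattered short ones — the signature of a single
large promoter deletion such as a species losing a cis-regulatory block.
Maximal gap runs of at least ``min_indel`` bases are reported with their
exact length and reference offset; runs separated by fewer than
``merge_gap`` aligned columns merge into one call.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio import Align

from .exceptions import InputError

_IUPAC = re.compile(r"^[ACGTURYSWKMBDHVN]+$", re.IGNORECASE)

DEFAULT_SCORES = (2, -3, -5, -1)  # match, mismatch, gap open, gap extend
_FLANK = 100  # bp of context used for flanking identity


@dataclass
class IndelCall:
    ref_id: str
    query_id: str
    type: str  # "deletion" (query lacks reference bases) | "insertion"
    length: int
    ref_offset: int  # 0-based start in the reference
    flank_identity: float  # percent identity of +/-100 bp of aligned flanks


def _as_pair(rec):
    if isinstance(rec, (tuple, list)):
        return str(rec[0]), str(rec[1])
    return rec.id, str(rec.seq)  # SeqRecord


def _check(name, seq):
    if not seq:
        raise InputError(f"sequence {name!r} is empty")
    if not _IUPAC.match(seq):
        raise InputError(f"sequence {name!r} contains non-IUPAC characters")


def _aligner(scores):
    match, mismatch, gap_open, gap_extend = scores
    return Align.PairwiseAligner(
        mode="global",
        match_score=match,
        mismatch_score=mismatch,
        open_gap_score=gap_open,
        extend_gap_score=gap_extend,
    )


def _gap_runs(aligned):
    """(type, ref_start, ref_end, length, anchor_ref) for inter-block gaps."""
    (ra, qa) = aligned
    runs = []
    for k in range(len(ra) - 1):
        r_gap = ra[k + 1][0] - ra[k][1]
        q_gap = qa[k + 1][0] - qa[k][1]
        if r_gap > 0:
            runs.append(["deletion", int(ra[k][1]), int(ra[k + 1][0]), int(r_gap)])
        if q_gap > 0:
            runs.append(["insertion", int(ra[k][1]), int(ra[k][1]), int(q_gap)])
    return runs


def _identity_window(ref, query, aligned, lo, hi):
    """Percent identity over aligned columns with reference position in
    [lo, hi)."""
    match = total = 0
    for (r1, r2), (q1, q2) in zip(*aligned):
        a, b = max(r1, lo), min(r2, hi)
        if b <= a:
            continue
        off = a - r1
        for x, y in zip(ref[a:b], query[q1 + off : q1 + off + (b - a)]):
            total += 1
            match += x == y
    return 100.0 * match / total if total else 0.0


def scan_promoter_indels(
    reference,
    queries,
    min_indel: int = 50,
    scores=DEFAULT_SCORES,
    merge_gap: int = 10,
) -> list:
    """Report large indels of each query relative to the reference.

    ``reference`` and each query are ``(id, sequence)`` pairs or Bio
    SeqRecords.  A *deletion* means the query lacks reference bases; an
    *insertion* means the query carries extra sequence at the given
    reference offset.  Deterministic: the first optimal alignment is used.
    """
    if min_indel < 1:
        raise InputError("min_indel must be >= 1")
    ref_id, ref_seq = _as_pair(reference)
    _check(ref_id, ref_seq)
    aligner = _aligner(scores)

    calls = []
    for rec in queries:
        q_id, q_seq = _as_pair(rec)
        _check(q_id, q_seq)
        aln = aligner.align(ref_seq.upper(), q_seq.upper())[0]
        aligned = aln.aligned
        runs = _gap_runs(aligned)
        runs.sort(key=lambda r: (r[1], r[0]))
        merged = []
        for run in runs:
            if (
                merged
                and merged[-1][0] == run[0]
                and run[1] - merged[-1][2] < merge_gap
            ):
                merged[-1][2] = run[2]
                merged[-1][3] += run[3]
            else:
                merged.append(list(run))
        for typ, r1, r2, length in merged:
            if length < min_indel:
                continue
            ident = (
                _identity_window(ref_seq, q_seq, aligned, r1 - _FLANK, r1)
                + _identity_window(ref_seq, q_seq, aligned, r2, r2 + _FLANK)
            ) / 2
            calls.append(IndelCall(ref_id, q_id, typ, length, r1, round(ident, 2)))
    return calls
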