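"""Synthetic whole-genome alignments from planted homology.

The simulator tags every genome segment with its ancestral interval, so the
true homology between any two simulated genomes is known exactly.  This
module intersects those segment maps (through ancestor coordinates) and
emits PAF anchor records equivalent to what a whole-genome aligner would
produce — no external aligner is needed for simulated data.

Two classes of planted event need aligner-realistic post-processing:

* tandem expansions/contractions: an aligner extends flanking alignments a
  few bases into the remaining repeat copy, so the flanking anchors overlap
  slightly on the contracted side.  We emulate that with a fixed overlap of
  ``TANDEM_OVERLAP`` bases (kept below the SV caller's ±10 bp breakpoint
  tolerance).
* repeat expansions/contractions: the flanking anchors of a repeat-borne
  event multi-map to the repeat's source locus; we emit one secondary
  record per event to reproduce that multi-mapping.
"""

from __future__ import annotations

from intervaltree import IntervalTree

from .simulate import SimulationResult
from .sv import PafRecord

TANDEM_OVERLAP = 8
_SPURIOUS_LEN = 300
_MIN_ANCHOR = 30


class _Entry:
    __slots__ = ("anc_chrom", "a1", "a2", "strand", "chrom", "pos", "dup")

    def __init__(self, anc_chrom, a1, a2, strand, chrom, pos, dup):
        self.anc_chrom = anc_chrom
        self.a1 = a1
        self.a2 = a2
        self.strand = strand
        self.chrom = chrom
        self.pos = pos
        self.dup = dup

    def project(self, o1, o2):
        """Genome coordinates of ancestor sub-interval [o1, o2)."""
        if self.strand == 1:
            return self.pos + (o1 - self.a1), self.pos + (o2 - self.a1)
        return self.pos + (self.a2 - o2), self.pos + (self.a2 - o1)


def _entries(genome):
    out = []
    for chrom, segs in genome.chroms.items():
        pos = 0
        for s in segs:
            if s.anc is not None and len(s) > 0:
                c, a1, a2 = s.anc
                out.append(_Entry(c, a1, a2, s.strand, chrom, pos, s.dup_event))
            pos += len(s)
    return out


class _Anchor:
    __slots__ = ("qs", "qe", "ts", "te", "qname", "tname", "strand",
                 "anc_chrom", "o1", "o2")

    def __init__(self, qs, qe, ts, te, qname, tname, strand, anc_chrom, o1, o2):
        self.qs, self.qe, self.ts, self.te = qs, qe, ts, te
        self.qname, self.tname, self.strand = qname, tname, strand
        self.anc_chrom, self.o1, self.o2 = anc_chrom, o1, o2


def synthetic_alignment(sim: SimulationResult, query: str, reference: str = "ancestor"):
    """PAF anchors for one simulated genome against a reference genome.

    ``reference`` may be any leaf name or ``"ancestor"``.  Anchors are exact
    projections of shared ancestral intervals; planted tandem- and
    repeat-class events receive the anchor signatures described in the
    module docstring.
    """
    qg = sim.genome(query)
    rg = sim.genome(reference)
    truth = sim.truth

    q_path = set(truth.branches_to(query))
    r_path = set(truth.branches_to(reference))
    q_only = {e.event_id: e for e in truth.sv_events if e.branch in q_path - r_path}
    r_only = {e.event_id: e for e in truth.sv_events if e.branch in r_path - q_path}

    r_index: dict[str, IntervalTree] = {}
    for ent in _entries(rg):
        r_index.setdefault(ent.anc_chrom, IntervalTree()).addi(ent.a1, ent.a2, ent)

    anchors: list[_Anchor] = []
    for qe in _entries(qg):
        tree = r_index.get(qe.anc_chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(qe.a1, qe.a2)):
            re_ = iv.data
            o1, o2 = max(qe.a1, re_.a1), min(qe.a2, re_.a2)
            if o2 - o1 < _MIN_ANCHOR:
                continue
            # pair duplicate-copy segments only with their counterpart copy
            if qe.dup != re_.dup:
                if qe.dup is not None and re_.dup is None and qe.dup in q_only:
                    pass  # query-only tandem copy vs the reference single copy
                else:
                    continue
            qs, qe2 = qe.project(o1, o2)
            ts, te = re_.project(o1, o2)
            strand = "+" if qe.strand * re_.strand == 1 else "-"
            anchors.append(
                _Anchor(qs, qe2, ts, te, qe.chrom, re_.chrom, strand,
                        qe.anc_chrom, o1, o2)
            )

    by_end: dict[tuple, list[_Anchor]] = {}
    by_start: dict[tuple, list[_Anchor]] = {}
    for a in anchors:
        by_end.setdefault((a.anc_chrom, a.o2), []).append(a)
        by_start.setdefault((a.anc_chrom, a.o1), []).append(a)

    def _pick(cands):
        plus = [a for a in cands if a.strand == "+"]
        if not plus:
            return None
        return max(plus, key=lambda a: a.qe - a.qs)

    spurious: list[PafRecord] = []
    v = TANDEM_OVERLAP

    def _emit_spurious(ev):
        left = _pick(by_end.get((ev.anc_chrom, ev.anc_start), []))
        if left is None:
            return
        w = min(_SPURIOUS_LEN, left.qe - left.qs)
        ts = 0
        tname = left.tname
        src_tree = r_index.get(ev.src_chrom)
        if src_tree is not None:
            hits = sorted(src_tree.overlap(ev.src_start, ev.src_start + 1))
            if hits:
                ent = hits[0].data
                o1 = max(ev.src_start, ent.a1)
                o2 = min(o1 + w, ent.a2)
                ts, _ = ent.project(o1, o2)
                tname = ent.chrom
        spurious.append(
            PafRecord(left.qname, 0, left.qe - w, left.qe, "+",
                      tname, 0, ts, ts + w, w, w, 0)
        )

    for ev in q_only.values():
        if ev.type == "tandem_contraction":
            left = _pick(by_end.get((ev.anc_chrom, ev.anc_start), []))
            if left is not None:
                left.qe += v
                left.te += v
        elif ev.type in ("repeat_expansion", "repeat_contraction"):
            _emit_spurious(ev)
    for ev in r_only.values():
        # the reference carries the event; the query-vs-reference view mirrors it
        if ev.type == "tandem_expansion":
            left = _pick(by_end.get((ev.anc_chrom, ev.anc_end), []))
            if left is not None:
                left.qe += v
                left.te += v
        elif ev.type == "tandem_contraction":
            right = _pick(by_start.get((ev.anc_chrom, ev.anc_end), []))
            if right is not None:
                right.qs -= v
                right.ts -= v
        elif ev.type in ("repeat_expansion", "repeat_contraction"):
            _emit_spurious(ev)

    qlens = qg.chrom_lengths()
    tlens = rg.chrom_lengths()
    records = [
        PafRecord(
            a.qname, qlens[a.qname], a.qs, a.qe, a.strand,
            a.tname, tlens[a.tname], a.ts, a.te,
            a.qe - a.qs, a.qe - a.qs, 60,
        )
        for a in anchors
    ]
    for r in spurious:
        r.qlen = qlens.get(r.qname, 0)
        r.tlen = tlens.get(r.tname, 0)
    records.extend(spurious)
    records.sort(key=lambda r: (r.qname, r.qstart, r.tname, r.tstart))
    return records
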