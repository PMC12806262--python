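"""Structural-variant calling from assembly-vs-reference alignments.

The caller consumes PAF anchor records, filters them to a primary chain per
(query chromosome, reference chromosome, strand), and classifies the gap
between each pair of consecutive anchors by the reference-gap ``dr`` and
query-gap ``dq``:

===========================  =======================================
type                         signature
===========================  =======================================
insertion                    dr >= 0, dq >= 0, dq - dr > 0
deletion                     dr >= 0, dq >= 0, dq - dr < 0
tandem_expansion             min(dr, dq) < 0, dq - dr > 0
tandem_contraction           min(dr, dq) < 0, dq - dr < 0
repeat_expansion             a flanking anchor multi-maps, dq - dr > 0
repeat_contraction           a flanking anchor multi-maps, dq - dr < 0
===========================  =======================================

with event size ``|dq - dr|`` filtered to ``[min_size, max_size]``
(defaults 50 bp and 10 kb).  An anchor is *unique* when no other record
overlaps its query interval by more than 10% of the shorter interval.

Hotspots are windows whose SV-breakpoint count exceeds a per-chromosome
uniform permutation null at a Benjamini–Hochberg FDR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .exceptions import InputError

logger = logging.getLogger("panclade")

SV_TYPES = (
    "insertion",
    "deletion",
    "tandem_expansion",
    "tandem_contraction",
    "repeat_expansion",
    "repeat_contraction",
)

MIRROR_TYPE = {
    "insertion": "deletion",
    "deletion": "insertion",
    "tandem_expansion": "tandem_contraction",
    "tandem_contraction": "tandem_expansion",
    "repeat_expansion": "repeat_contraction",
    "repeat_contraction": "repeat_expansion",
}


# ---------------------------------------------------------------------------
# PAF records


@dataclass
class PafRecord:
    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    nmatch: int = 0
    alen: int = 0
    mapq: int = 60

    def to_line(self) -> str:
        return "\t".join(
            str(x)
            for x in (
                self.qname, self.qlen, self.qstart, self.qend, self.strand,
                self.tname, self.tlen, self.tstart, self.tend,
                self.nmatch, self.alen, self.mapq,
            )
        )


def read_paf(path) -> list[PafRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                PafRecord(
                    f[0], int(f[1]), int(f[2]), int(f[3]), f[4],
                    f[5], int(f[6]), int(f[7]), int(f[8]),
                    int(f[9]), int(f[10]), int(f[11]),
                )
            )
    return out


def write_paf(records, path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(r.to_line() + "\n")


# ---------------------------------------------------------------------------
# SV records


@dataclass
class SVRecord:
    ref_genome: str
    query_genome: str
    ref_chrom: str
    ref_start: int  # 0-based half-open on the reference
    ref_end: int
    type: str
    size: int
    query_chrom: str = ""
    query_start: int = -1
    query_end: int = -1


@dataclass
class HotspotRegion:
    ref_chrom: str
    start: int
    end: int
    sv_count: int
    empirical_p: float
    bh_q: float
    genes: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# calling


def _flag_uniqueness(records):
    """Per-record (left_end_multi, right_end_multi) flags.

    An anchor *end* is flagged when another record's query interval
    overlaps the terminal 10% (at least 50 bp) of the anchor on that side —
    the multi-mapping signature of a repeat-borne event, localised to the
    gap it flanks so that one shared flank does not contaminate the event
    on its other side."""
    flags = [[False, False] for _ in records]
    by_q: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_q.setdefault(r.qname, []).append(i)

    def mark(i, lo, hi):
        r = records[i]
        t = max(50, int(0.1 * (r.qend - r.qstart)))
        if lo < r.qstart + t:
            flags[i][0] = True
        if hi > r.qend - t:
            flags[i][1] = True

    for idxs in by_q.values():
        idxs.sort(key=lambda i: records[i].qstart)
        for a_pos, i in enumerate(idxs):
            ra = records[i]
            for j in idxs[a_pos + 1 :]:
                rb = records[j]
                if rb.qstart >= ra.qend:
                    break
                lo, hi = rb.qstart, min(ra.qend, rb.qend)
                shorter = min(ra.qend - ra.qstart, rb.qend - rb.qstart)
                if shorter > 0 and hi - lo > 0.1 * shorter:
                    mark(i, lo, hi)
                    mark(j, lo, hi)
    return flags


def _primary_chain(records):
    """Greedy selection of chain anchors: confidently mapped (mapq > 0)
    before multi-mappers, longest first; a candidate overlapping a kept
    anchor by more than half its own length on the query is dropped."""
    order = sorted(
        range(len(records)),
        key=lambda i: (records[i].mapq == 0,
                       -(records[i].qend - records[i].qstart), records[i].qname,
                       records[i].qstart, records[i].tname, records[i].tstart),
    )
    kept: dict[str, list[tuple[int, int]]] = {}
    primary = []
    for i in order:
        r = records[i]
        mylen = r.qend - r.qstart
        ov = 0
        for s, e in kept.get(r.qname, ()):
            if s < r.qend and r.qstart < e:
                ov = max(ov, min(r.qend, e) - max(r.qstart, s))
        if mylen == 0 or ov > 0.5 * mylen:
            continue
        kept.setdefault(r.qname, []).append((r.qstart, r.qend))
        primary.append(i)
    return sorted(primary)


def call_svs_from_alignment(
    records,
    min_size: int = 50,
    max_size: int = 10_000,
    ref_genome: str = "",
    query_genome: str = "",
) -> list[SVRecord]:
    """Classify gap events between consecutive primary anchors.

    ``records`` is a list of :class:`PafRecord`.  Returns typed
    :class:`SVRecord` calls with 0-based half-open reference coordinates.
    """
    if not records:
        warnings.warn("no usable alignment anchors; returning no SV calls")
        return []
    if any(
        (records[i].qname, records[i].qstart) > (records[i + 1].qname, records[i + 1].qstart)
        for i in range(len(records) - 1)
    ):
        warnings.warn("unsorted PAF input; sorting by (query, start)")
        records = sorted(records, key=lambda r: (r.qname, r.qstart))

    multi = _flag_uniqueness(records)
    primary = _primary_chain(records)

    chains: dict[tuple, list[int]] = {}
    for i in primary:
        r = records[i]
        chains.setdefault((r.qname, r.tname, r.strand), []).append(i)

    calls = []
    for (qname, tname, strand), idxs in sorted(chains.items()):
        idxs.sort(key=lambda i: records[i].qstart)
        for a_i, b_i in zip(idxs, idxs[1:]):
            a, b = records[a_i], records[b_i]
            dq = b.qstart - a.qend
            dr = (b.tstart - a.tend) if strand == "+" else (a.tstart - b.tend)
            delta = dq - dr
            if delta == 0:
                continue
            size = abs(delta)
            if size < min_size or size > max_size:
                continue
            if multi[a_i][1] or multi[b_i][0]:
                svtype = "repeat_expansion" if delta > 0 else "repeat_contraction"
            elif min(dq, dr) < 0:
                svtype = "tandem_expansion" if delta > 0 else "tandem_contraction"
            elif delta > 0:
                svtype = "insertion"
            else:
                svtype = "deletion"
            if strand == "+":
                lo, hi = sorted((a.tend, b.tstart))
            else:
                lo, hi = sorted((b.tend, a.tstart))
            qlo, qhi = sorted((a.qend, b.qstart))
            calls.append(
                SVRecord(
                    ref_genome, query_genome, tname, lo, hi, svtype, size,
                    qname, qlo, qhi,
                )
            )
    calls.sort(key=lambda c: (c.ref_chrom, c.ref_start, c.type))
    return calls


def multi_reference_catalog(
    references,
    queries,
    paf_provider,
    min_size: int = 50,
    max_size: int = 10_000,
):
    """Call SVs for every (reference, query) pair.

    ``paf_provider(ref, query)`` must return the alignment anchors for one
    pair.  Query-equals-reference pairs are skipped.  Returns
    ``(tables, summary)`` where ``tables[(ref, query)]`` is the call list
    and ``summary`` is a tidy DataFrame of counts per reference, query and
    SV type (zero rows included).
    """
    import pandas as pd

    tables = {}
    rows = []
    for ref in references:
        for query in queries:
            if query == ref:
                logger.info("skipping self comparison %s vs %s", query, ref)
                continue
            calls = call_svs_from_alignment(
                paf_provider(ref, query),
                min_size=min_size,
                max_size=max_size,
                ref_genome=ref,
                query_genome=query,
            )
            tables[(ref, query)] = calls
            counts = {t: 0 for t in SV_TYPES}
            for c in calls:
                counts[c.type] += 1
            for t in SV_TYPES:
                rows.append(
                    {"reference": ref, "query": query, "type": t, "count": counts[t]}
                )
    summary = pd.DataFrame(rows, columns=["reference", "query", "type", "count"])
    return tables, summary


# ---------------------------------------------------------------------------
# hotspots


def _windows(length: int, window_bp: int, step_bp: int):
    if window_bp >= length:
        return [(0, length)]
    starts = range(0, length - window_bp + step_bp, step_bp)
    return [(s, min(s + window_bp, length)) for s in starts]


def detect_hotspots(
    svs,
    ref_lengths: dict,
    window_bp: int = 1_000_000,
    step_bp: int | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[HotspotRegion]:
    """Permutation scan for windows enriched in SV breakpoints.

    One breakpoint per SV (its reference start).  The null permutes start
    positions uniformly per chromosome, preserving per-chromosome counts;
    per-window empirical p-values are BH-corrected across all windows and
    significant windows (q <= alpha) are merged when overlapping or
    book-ended.
    """
    if n_perm < 100:
        raise InputError("n_perm must be >= 100")
    if window_bp <= 0:
        raise InputError("window_bp must be positive")
    step_bp = step_bp or window_bp
    rng = np.random.default_rng(seed)

    pos_by_chrom: dict[str, list[int]] = {c: [] for c in ref_lengths}
    for s in svs:
        if s.ref_chrom in pos_by_chrom:
            pos_by_chrom[s.ref_chrom].append(s.ref_start)

    all_windows, all_p = [], []
    for chrom in sorted(ref_lengths):
        length = int(ref_lengths[chrom])
        if window_bp >= length:
            warnings.warn(
                f"window ({window_bp} bp) exceeds {chrom} length; using one window"
            )
        wins = _windows(length, window_bp, step_bp)
        edges_lo = np.array([w[0] for w in wins])
        edges_hi = np.array([w[1] for w in wins])
        pos = np.sort(np.asarray(pos_by_chrom[chrom], dtype=int))
        obs = np.searchsorted(pos, edges_hi) - np.searchsorted(pos, edges_lo)
        ge = np.zeros(len(wins), dtype=int)
        n_sv = len(pos)
        for _ in range(n_perm):
            perm = np.sort(rng.integers(0, length, n_sv))
            cnt = np.searchsorted(perm, edges_hi) - np.searchsorted(perm, edges_lo)
            ge += cnt >= obs
        p = (1.0 + ge) / (1.0 + n_perm)
        for w, pv, ob in zip(wins, p, obs):
            all_windows.append((chrom, w[0], w[1], int(ob)))
            all_p.append(float(pv))

    if not all_windows:
        return []
    reject, q, _, _ = multipletests(all_p, alpha=alpha, method="fdr_bh")

    sig = [
        (w, p_, q_)
        for w, p_, q_, rej in zip(all_windows, all_p, q, reject)
        if rej and q_ <= alpha
    ]
    sig.sort(key=lambda x: (x[0][0], x[0][1]))
    regions: list[HotspotRegion] = []
    for (chrom, start, end, cnt), p_, q_ in sig:
        if regions and regions[-1].ref_chrom == chrom and start <= regions[-1].end:
            r = regions[-1]
            r.end = max(r.end, end)
            r.empirical_p = min(r.empirical_p, p_)
            r.bh_q = min(r.bh_q, q_)
        else:
            regions.append(HotspotRegion(chrom, start, end, 0, p_, q_))
    for r in regions:
        r.sv_count = sum(
            1 for p in pos_by_chrom.get(r.ref_chrom, []) if r.start <= p < r.end
        )
    return regions


def annotate_regions(regions, genes, ref_chroms=None):
    """Attach overlapping gene ids to hotspot regions.

    ``genes`` is an iterable of objects with ``gene_id``, ``chrom``,
    ``start``, ``end`` (0-based half-open), e.g. :meth:`Genome.genes`, or a
    path to a GFF3 file.  Returns ``(regions, skipped_contigs)`` where
    ``skipped_contigs`` lists annotation contigs absent from the reference.
    """
    if isinstance(genes, (str, bytes)) or hasattr(genes, "__fspath__"):
        genes = list(read_gff3_genes(genes))
    else:
        genes = list(genes)
    known = set(ref_chroms) if ref_chroms is not None else {r.ref_chrom for r in regions}
    skipped = sorted({g.chrom for g in genes if g.chrom not in known})
    by_chrom: dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for r in regions:
        r.genes = sorted(
            g.gene_id
            for g in by_chrom.get(r.ref_chrom, [])
            if g.start < r.end and r.start < g.end
        )
    return regions, skipped


def read_gff3_genes(path):
    """Yield gene features from a GFF3 file (0-based half-open coords)."""
    import gffutils

    from .simulate import GeneInfo

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rank: dict[str, int] = {}
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        r = rank.get(feat.seqid, 0)
        rank[feat.seqid] = r + 1
        yield GeneInfo(
            feat.attributes.get("ID", [feat.id])[0],
            feat.attributes.get("family", [""])[0],
            feat.seqid,
            r,
            feat.start - 1,
            feat.end,
            feat.strand,
        )
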