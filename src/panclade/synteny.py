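"""Collinearity blocks and signed marker encodings.

Anchors are gene families that are single-copy in both genomes of a pair;
they are chained into collinearity blocks by longest strictly-monotone
subsequence extraction in gene-rank space (MCScanX-like defaults:
``min_anchors=5``, ``max_gap=25`` ranks).  A block is *disordered* when it
lies on a chromosome pair other than the dominant pairing of its reference
chromosome.  For ancestral-genome inference, genomes are re-encoded as
signed orders of universal marker blocks: maximal runs of universally
single-copy families whose adjacency and relative orientation are conserved
in every genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .exceptions import ConfigurationError, InputError

logger = logging.getLogger("panclade")


@dataclass
class Anchor:
    family: str
    a_chrom: str
    a_rank: int
    a_strand: str
    b_chrom: str
    b_rank: int
    b_strand: str


@dataclass
class SyntenyBlock:
    block_id: str
    genome_a: str
    genome_b: str
    chrom_a: str
    chrom_b: str
    orientation: str  # "+" | "-"
    anchors: list
    disordered: bool | None = None

    @property
    def a_span(self):
        return (self.anchors[0].a_rank, self.anchors[-1].a_rank)

    @property
    def b_span(self):
        ranks = [a.b_rank for a in self.anchors]
        return (min(ranks), max(ranks))

    def __len__(self):
        return len(self.anchors)


@dataclass
class MarkerGenome:
    genome_id: str
    chroms: dict  # chrom -> ordered list of signed marker ids

    def as_lists(self):
        return [list(v) for v in self.chroms.values()]


# ---------------------------------------------------------------------------


def _positions(order: dict):
    """family -> (chrom, rank, strand) for single-copy families; None for
    multi-copy ones."""
    pos: dict = {}
    for chrom, genes in order.items():
        for rank, (_gid, fam, strand) in enumerate(genes):
            pos[fam] = None if fam in pos else (chrom, rank, strand)
    return {f: p for f, p in pos.items() if p is not None}


def find_anchors(families, orders: dict, pair: tuple) -> list:
    """Single-copy anchor pairs between two genomes.

    ``orders[genome]`` maps chrom -> ordered (gene_id, family, strand)
    triples (see :meth:`Genome.gene_order`).  Returns anchors sorted by
    genome-A (chrom, rank).
    """
    ga, gb = pair
    for g in pair:
        if g not in orders:
            raise InputError(f"genome {g!r} absent from annotations")
    pa = _positions(orders[ga])
    pb = _positions(orders[gb])
    anchors = []
    for fam in sorted(set(pa) & set(pb)):
        ca, ra, sa = pa[fam]
        cb, rb, sb = pb[fam]
        anchors.append(Anchor(fam, ca, ra, sa, cb, rb, sb))
    anchors.sort(key=lambda a: (a.a_chrom, a.a_rank))
    return anchors


def _best_chain(items, sign: int, max_gap: int):
    """Longest chain with strictly monotone b-ranks (direction ``sign``)
    and rank gaps <= max_gap on both genomes.  O(n^2) DP."""
    n = len(items)
    dp = [1] * n
    prev = [-1] * n
    for i in range(n):
        ai, bi = items[i]
        for j in range(i):
            aj, bj = items[j]
            if not (0 < ai - aj <= max_gap):
                continue
            if not (0 < sign * (bi - bj) <= max_gap):
                continue
            if dp[j] + 1 > dp[i]:
                dp[i] = dp[j] + 1
                prev[i] = j
    best = max(range(n), key=lambda i: (dp[i], -items[i][0]))
    chain = []
    i = best
    while i != -1:
        chain.append(i)
        i = prev[i]
    return chain[::-1]


def chain_anchors(anchors, min_anchors: int = 5, max_gap: int = 25) -> list:
    """Chain anchors into collinearity blocks (greedy best-chain-first)."""
    if min_anchors < 2:
        raise ConfigurationError("min_anchors must be >= 2")
    groups: dict = {}
    for a in anchors:
        groups.setdefault((a.a_chrom, a.b_chrom), []).append(a)

    blocks = []
    for (ca, cb), grp in sorted(groups.items()):
        grp = sorted(grp, key=lambda a: a.a_rank)
        remaining = list(range(len(grp)))
        while len(remaining) >= min_anchors:
            # chains must be orientation-consistent: forward chains use
            # same-strand anchors, reverse chains use flipped-strand anchors
            fwd = [i for i in remaining if grp[i].a_strand == grp[i].b_strand]
            rev = [i for i in remaining if grp[i].a_strand != grp[i].b_strand]
            up = (
                _best_chain([(grp[i].a_rank, grp[i].b_rank) for i in fwd], +1, max_gap)
                if fwd else []
            )
            down = (
                _best_chain([(grp[i].a_rank, grp[i].b_rank) for i in rev], -1, max_gap)
                if rev else []
            )
            if len(up) >= len(down):
                chain, orient, pool = up, "+", fwd
            else:
                chain, orient, pool = down, "-", rev
            if len(chain) < min_anchors:
                break
            picked = [pool[i] for i in chain]
            blocks.append((ca, cb, orient, [grp[i] for i in picked]))
            used = set(picked)
            remaining = [i for i in remaining if i not in used]

    blocks.sort(key=lambda b: (b[0], b[3][0].a_rank, b[1]))
    out = []
    for k, (ca, cb, orient, members) in enumerate(blocks, start=1):
        out.append(
            SyntenyBlock(f"B{k:04d}", "", "", ca, cb, orient, members)
        )
    return out


def flag_disordered_blocks(blocks) -> list:
    """Mark blocks off the dominant chromosome pairing as disordered.

    The dominant partner of a genome-A chromosome is the genome-B
    chromosome receiving the most anchors (ties to the lexicographically
    smaller id, logged)."""
    votes: dict = {}
    for b in blocks:
        votes.setdefault(b.chrom_a, {}).setdefault(b.chrom_b, 0)
        votes[b.chrom_a][b.chrom_b] += len(b)
    dominant = {}
    for ca, counts in votes.items():
        best = max(counts.values())
        tied = sorted(cb for cb, v in counts.items() if v == best)
        if len(tied) > 1:
            logger.info("dominant-pairing tie for %s: %s; taking %s", ca, tied, tied[0])
        dominant[ca] = tied[0]
    for b in blocks:
        b.disordered = b.chrom_b != dominant[b.chrom_a]
    return blocks


# ---------------------------------------------------------------------------
# marker genomes


def build_marker_genomes(orders: dict, pivot: str, genomes=None) -> list:
    """Encode genomes as signed orders of universal marker blocks.

    Markers are maximal runs of families that are single-copy in every
    genome and whose adjacency and relative orientation (with respect to
    the pivot genome) are conserved everywhere; each genome then reads as a
    signed permutation of the same marker universe, the input encoding for
    genome-median ancestor inference.
    """
    if genomes is None:
        genomes = list(orders)
    if pivot not in orders:
        raise InputError(f"pivot genome {pivot!r} absent from annotations")
    pos = {g: _positions(orders[g]) for g in genomes}
    universal = set(pos[genomes[0]])
    for g in genomes[1:]:
        universal &= set(pos[g])
    if not universal:
        raise InputError(
            "no universal single-copy families; lower min_anchors or relax "
            "family clustering"
        )

    sign = {  # relative strand of each family vs the pivot
        g: {
            f: 1 if pos[g][f][2] == pos[pivot][f][2] else -1
            for f in universal
        }
        for g in genomes
    }
    # per genome: position of each universal family among universal families
    upos: dict = {}
    for g in genomes:
        upos[g] = {}
        for chrom, genes in orders[g].items():
            idx = 0
            for _gid, fam, _s in genes:
                if fam in universal:
                    upos[g][fam] = (chrom, idx)
                    idx += 1

    def mergeable(f, g_next):
        for g in genomes:
            cf, xf = upos[g][f]
            cn, xn = upos[g][g_next]
            if cf != cn:
                return False
            sf, sn = sign[g][f], sign[g][g_next]
            if sf != sn:
                return False
            if sf == 1 and xn != xf + 1:
                return False
            if sf == -1 and xn != xf - 1:
                return False
        return True

    # pivot order of universal families
    marker_of: dict = {}
    marker_members: list = []
    for chrom, genes in orders[pivot].items():
        run: list = []
        for _gid, fam, _s in genes:
            if fam not in universal:
                continue
            if run and mergeable(run[-1], fam):
                run.append(fam)
            else:
                if run:
                    marker_members.append(run)
                run = [fam]
        if run:
            marker_members.append(run)
    for mid, members in enumerate(marker_members, start=1):
        for off, fam in enumerate(members):
            marker_of[fam] = (mid, off)

    out = []
    for g in genomes:
        chroms: dict = {}
        for chrom, genes in orders[g].items():
            fams = [fam for _gid, fam, _s in genes if fam in universal]
            seq: list = []
            i = 0
            while i < len(fams):
                mid, off = marker_of[fams[i]]
                members = marker_members[mid - 1]
                if len(members) == 1:
                    seq.append(mid * sign[g][fams[i]])
                    i += 1
                    continue
                # orientation from the position of this family within its run
                forward = off == 0
                span = fams[i : i + len(members)]
                expected = members if forward else members[::-1]
                if span != expected:  # should not happen by construction
                    raise InputError(
                        f"marker run broken in {g!r} at family {fams[i]!r}"
                    )
                seq.append(mid if forward else -mid)
                i += len(members)
            if seq:
                chroms[chrom] = seq
        out.append(MarkerGenome(g, chroms))
    return out
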