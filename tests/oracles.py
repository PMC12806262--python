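"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: DCJ distance is
recomputed by breadth-first search over elementary double-cut-and-join
operations on adjacency sets, and the genome median by exhaustive
enumeration of all linear block arrangements.
"""

from __future__ import annotations

import itertools
from collections import deque


def adjacency_state(chroms):
    """Genome (list of signed block lists) -> frozenset of adjacencies.

    Extremities are (block, 'h'|'t'); telomeres are implicit (extremities
    absent from every adjacency)."""
    adjs = []
    for chrom in chroms:
        for a, b in zip(chrom, chrom[1:]):
            left = (abs(a), "h" if a > 0 else "t")
            right = (abs(b), "t" if b > 0 else "h")
            adjs.append(frozenset((left, right)))
    return frozenset(adjs)


def _neighbors(state, extremities):
    """All states one DCJ operation away (circular intermediates allowed)."""
    adjs = sorted(state, key=lambda a: sorted(a))
    in_adj = {e for a in state for e in a}
    telomeres = [e for e in extremities if e not in in_adj]
    out = set()
    # two adjacencies -> two reassortments
    for i in range(len(adjs)):
        for j in range(i + 1, len(adjs)):
            a, b = tuple(adjs[i]), tuple(adjs[j])
            for (p, q), (r, s) in (((a[0], a[1]), (b[0], b[1])),):
                base = state - {adjs[i], adjs[j]}
                out.add(base | {frozenset((p, r)), frozenset((q, s))})
                out.add(base | {frozenset((p, s)), frozenset((q, r))})
    # adjacency + telomere -> swap
    for adj in adjs:
        p, q = tuple(adj)
        for t in telomeres:
            base = state - {adj}
            out.add(base | {frozenset((p, t))})
            out.add(base | {frozenset((q, t))})
    # split an adjacency into two telomeres
    for adj in adjs:
        out.add(state - {adj})
    # join two telomeres
    for t1, t2 in itertools.combinations(telomeres, 2):
        out.add(state | {frozenset((t1, t2))})
    return out


def bfs_dcj_distance(genome_a, genome_b, max_depth: int = 12) -> int:
    """Minimum number of DCJ operations turning genome_a into genome_b."""
    blocks = sorted({abs(x) for c in genome_a for x in c})
    extremities = [(b, s) for b in blocks for s in ("t", "h")]
    start = adjacency_state(genome_a)
    goal = adjacency_state(genome_b)
    if start == goal:
        return 0
    # bidirectional BFS
    front = {start: 0}
    back = {goal: 0}
    fq, bq = deque([start]), deque([goal])
    for _ in range(max_depth):
        side_front = len(fq) <= len(bq)
        frontier, other, queue = (front, back, fq) if side_front else (back, front, bq)
        nxt = deque()
        while queue:
            st = queue.popleft()
            d = frontier[st]
            for nb in _neighbors(st, extremities):
                if nb in other:
                    return d + 1 + other[nb]
                if nb not in frontier:
                    frontier[nb] = d + 1
                    nxt.append(nb)
        if side_front:
            fq = nxt
        else:
            bq = nxt
        if not fq and not bq:
            break
    raise RuntimeError("BFS depth exceeded")


def enumerate_linear_genomes(n_blocks: int):
    """Every linear genome over blocks 1..n (canonical, deduplicated)."""
    blocks = list(range(1, n_blocks + 1))
    seen = set()
    for perm in itertools.permutations(blocks):
        for signs in itertools.product((1, -1), repeat=n_blocks):
            seq = [b * s for b, s in zip(perm, signs)]
            for cuts in itertools.product((0, 1), repeat=n_blocks - 1):
                chroms, cur = [], [seq[0]]
                for x, cut in zip(seq[1:], cuts):
                    if cut:
                        chroms.append(cur)
                        cur = [x]
                    else:
                        cur.append(x)
                chroms.append(cur)
                key = frozenset(
                    min(tuple(c), tuple(-x for x in reversed(c))) for c in chroms
                )
                if key not in seen:
                    seen.add(key)
                    yield chroms


def exhaustive_median_total(genomes, dist_fn):
    """Minimum total distance of any linear genome to the inputs."""
    n = len({abs(x) for c in genomes[0] for x in c})
    best = None
    for cand in enumerate_linear_genomes(n):
        tot = sum(dist_fn(cand, g) for g in genomes)
        if best is None or tot < best:
            best = tot
    return best
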