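"""Ancestral genome reconstruction and DCJ rearrangement accounting.

Genomes are signed orders of shared marker blocks.  Every block contributes
two extremities (tail, head); a chromosome induces adjacencies between the
facing extremities of consecutive blocks.  The ancestor is inferred under
the genome median model: candidate adjacencies are weighted by how many
input genomes exhibit them, a maximum-weight matching picks a consistent
adjacency set, matched paths become CARs (contiguous ancestral regions,
linear — cycles are opened at their lightest adjacency), and a greedy DCJ
hill-climb then polishes the candidate against the total DCJ distance to
the inputs.

The DCJ distance between two genomes over the same block universe is
``N - (C + I/2)`` with N blocks, C cycles and I odd paths in the adjacency
graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .exceptions import InputError

HEAD = "h"
TAIL = "t"


def _chromosomes(genome):
    """Accept a MarkerGenome, a dict chrom->list, or a list of lists."""
    if hasattr(genome, "chroms"):
        return [list(v) for v in genome.chroms.values()]
    if isinstance(genome, dict):
        return [list(v) for v in genome.values()]
    return [list(v) for v in genome]


def _universe(chroms):
    blocks = [abs(b) for chrom in chroms for b in chrom]
    if len(blocks) != len(set(blocks)):
        raise InputError("each block id must appear exactly once per genome")
    return set(blocks)


def genome_adjacencies(genome):
    """Set of internal adjacencies (frozensets of two extremities)."""
    adj = set()
    for chrom in _chromosomes(genome):
        for a, b in zip(chrom, chrom[1:]):
            left = (abs(a), HEAD if a > 0 else TAIL)
            right = (abs(b), TAIL if b > 0 else HEAD)
            adj.add(frozenset((left, right)))
    return adj


def _telomeres(genome):
    tel = []
    for chrom in _chromosomes(genome):
        if not chrom:
            continue
        a, b = chrom[0], chrom[-1]
        tel.append((abs(a), TAIL if a > 0 else HEAD))
        tel.append((abs(b), HEAD if b > 0 else TAIL))
    return tel


@dataclass
class AdjacencyGraph:
    """Candidate adjacencies weighted by observation count."""

    weights: dict  # frozenset{extremity, extremity} -> int
    blocks: set
    n_genomes: int


@dataclass
class AncestorGenome:
    cars: list  # list of signed block-id lists

    @property
    def chroms(self):
        return {f"CAR{i + 1}": car for i, car in enumerate(self.cars)}

    def adjacencies(self):
        return genome_adjacencies(self.cars)


@dataclass
class RearrangementSummary:
    genome: str
    dcj_distance: int
    fissions: int
    fusions: int
    inversions_lower_bound: int


# ---------------------------------------------------------------------------
# adjacency graph and median


def build_adjacency_graph(markers) -> AdjacencyGraph:
    markers = list(markers)
    if not markers:
        raise InputError("no marker genomes supplied")
    chrom_sets = [_chromosomes(m) for m in markers]
    universe = _universe(chrom_sets[0])
    for cs in chrom_sets[1:]:
        if _universe(cs) != universe:
            raise InputError("marker genomes use inconsistent block universes")
    weights: dict = {}
    for cs in chrom_sets:
        for adj in genome_adjacencies(cs):
            weights[adj] = weights.get(adj, 0) + 1
    return AdjacencyGraph(weights, universe, len(markers))


def _adjacency_key(adj):
    return tuple(sorted(adj))


def _cars_from_matching(universe, adjacencies, weights=None):
    """Decompose a matching over extremities into linear CARs.

    Cycles are opened at their minimum-weight adjacency (ties by
    lexicographic extremity pair)."""
    partner = {}
    for adj in adjacencies:
        a, b = tuple(adj)
        partner[a] = b
        partner[b] = a

    def other_end(e):
        b, side = e
        return (b, HEAD if side == TAIL else TAIL)

    seen = set()
    cars = []
    # linear paths start at unmatched extremities
    starts = sorted(
        e
        for b in universe
        for e in ((b, TAIL), (b, HEAD))
        if e not in partner
    )
    for start in starts:
        if start[0] in seen:
            continue
        car = []
        e = start
        while True:
            b, side = e
            seen.add(b)
            car.append(b if side == TAIL else -b)
            out = other_end(e)
            nxt = partner.get(out)
            if nxt is None:
                break
            e = nxt
        cars.append(car)
    # remaining blocks are on cycles: open each at its lightest adjacency
    for b in sorted(universe):
        if b in seen:
            continue
        cycle_adjs = []
        e = (b, TAIL)
        while True:
            out = other_end(e)
            nxt = partner[out]
            cycle_adjs.append(frozenset((out, nxt)))
            e = nxt
            if e == (b, TAIL):
                break
        drop = min(
            cycle_adjs,
            key=lambda a: ((weights or {}).get(a, 0), _adjacency_key(a)),
        )
        x, y = tuple(drop)
        del partner[x]
        del partner[y]
        start = min(x, y)
        car = []
        e = start
        while True:
            bb, side = e
            seen.add(bb)
            car.append(bb if side == TAIL else -bb)
            out = other_end(e)
            nxt = partner.get(out)
            if nxt is None:
                break
            e = nxt
        cars.append(car)
    return [_canonical_chrom(c) for c in sorted(cars, key=lambda c: min(abs(x) for x in c))]


def _canonical_chrom(chrom):
    rev = [-x for x in reversed(chrom)]
    return min(chrom, rev, key=lambda c: (tuple(abs(x) for x in c), tuple(c)))


def infer_median_genome(graph: AdjacencyGraph, refine: bool = True,
                        inputs=None) -> AncestorGenome:
    """Genome-median ancestor from the weighted adjacency graph.

    Maximum-weight matching over extremities (each used at most once)
    selects the ancestral adjacencies; matched components become linear
    CARs.  With ``refine`` and the input genomes given, a greedy DCJ
    hill-climb lowers the total distance when the matching alone is not
    optimal.  Deterministic: ties are broken lexicographically.
    """
    if not graph.weights and not graph.blocks:
        raise InputError("empty adjacency graph")
    g = nx.Graph()
    for b in sorted(graph.blocks):
        g.add_node((b, TAIL))
        g.add_node((b, HEAD))
    edges = sorted(graph.weights.items(), key=lambda kv: _adjacency_key(kv[0]))
    eps = 1.0 / (4 * len(edges) + 4)
    for rank, (adj, w) in enumerate(edges):
        a, b = tuple(adj)
        g.add_edge(a, b, weight=w - eps * rank)
    matching = nx.max_weight_matching(g, maxcardinality=False)
    adjs = {frozenset(pair) for pair in matching}
    cars = _cars_from_matching(graph.blocks, adjs, graph.weights)
    ancestor = AncestorGenome(cars)
    if refine and inputs is not None:
        ancestor = _refine_median(ancestor, list(inputs), graph.blocks)
    return ancestor


def _total_distance(cars, inputs):
    return sum(dcj_distance(cars, m) for m in inputs)


def _refine_median(ancestor, inputs, universe, max_rounds: int = 50):
    """Greedy DCJ hill-climb on total distance, restricted to linear
    genomes, multi-started from the matching result and from every input
    genome (the median is then never worse than any leaf)."""
    starts = [_norm(ancestor.cars)]
    for m in inputs:
        cand = _norm(_chromosomes(m))
        if cand not in starts:
            starts.append(cand)

    def climb(cand):
        d = _total_distance(cand, inputs)
        for _ in range(max_rounds):
            improved = False
            for nb in _linear_dcj_neighbors(cand):
                nd = _total_distance(nb, inputs)
                if nd < d:
                    cand, d = nb, nd
                    improved = True
                    break
            if not improved:
                break
        return cand, d

    best, best_d = None, None
    for start in starts:
        cand, d = climb(start)
        if best is None or d < best_d or (d == best_d and cand < best):
            best, best_d = cand, d
    return AncestorGenome(sorted(best, key=lambda c: min(abs(x) for x in c)))


def _linear_dcj_neighbors(chroms):
    """All linear genomes one DCJ operation away (inversions, fissions,
    fusions, translocations via prefix/suffix exchange)."""
    chroms = [list(c) for c in chroms]
    n = len(chroms)
    # inversions within a chromosome
    for ci, chrom in enumerate(chroms):
        L = len(chrom)
        for i in range(L):
            for j in range(i + 1, L + 1):
                inv = [-x for x in reversed(chrom[i:j])]
                new = chrom[:i] + inv + chrom[j:]
                yield _norm(chroms[:ci] + [new] + chroms[ci + 1 :])
    # fissions
    for ci, chrom in enumerate(chroms):
        for i in range(1, len(chrom)):
            yield _norm(chroms[:ci] + [chrom[:i], chrom[i:]] + chroms[ci + 1 :])
    # fusions / translocations between chromosome pairs
    for i in range(n):
        for j in range(i + 1, n):
            a, b = chroms[i], chroms[j]
            rest = [chroms[k] for k in range(n) if k not in (i, j)]
            for x in range(len(a) + 1):
                for y in range(len(b) + 1):
                    a1, a2 = a[:x], a[x:]
                    b1, b2 = b[:y], b[y:]
                    for p, q in (
                        (a1 + b2, b1 + a2),
                        (a1 + [-z for z in reversed(b1)], [-z for z in reversed(b2)] + a2),
                    ):
                        new = [c for c in (p, q) if c]
                        yield _norm(rest + new)


def _norm(chroms):
    return sorted(
        (_canonical_chrom(c) for c in chroms if c),
        key=lambda c: (tuple(abs(x) for x in c), tuple(c)),
    )


# ---------------------------------------------------------------------------
# DCJ distance


def dcj_distance(a, b) -> int:
    """DCJ distance N - (C + I/2) over a shared block universe."""
    ca, cb = _chromosomes(a), _chromosomes(b)
    ua, ub = _universe(ca), _universe(cb)
    if ua != ub:
        raise InputError("genomes have differing block universes")
    n = len(ua)
    if n == 0:
        return 0

    def elements(chroms):
        """extremity -> element id; elements are adjacencies or telomeres."""
        el = {}
        eid = 0
        adjs = genome_adjacencies(chroms)
        for adj in adjs:
            for e in adj:
                el[e] = eid
            eid += 1
        for t in _telomeres(chroms):
            el[t] = eid
            eid += 1
        return el, eid

    ela, na = elements(ca)
    elb, nb = elements(cb)

    parent = list(range(na + nb))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    extremities = [(blk, s) for blk in ua for s in (TAIL, HEAD)]
    for e in extremities:
        ra, rb = find(ela[e]), find(elb[e] + na)
        if ra != rb:
            parent[ra] = rb

    comp_edges: dict = {}
    comp_vertices: dict = {}
    for e in extremities:
        r = find(ela[e])
        comp_edges[r] = comp_edges.get(r, 0) + 1
    counted = set()
    for el, off in ((ela, 0), (elb, na)):
        for e, idx in el.items():
            key = idx + off
            if key in counted:
                continue
            counted.add(key)
            r = find(key)
            comp_vertices[r] = comp_vertices.get(r, 0) + 1

    cycles = 0
    odd_paths = 0
    for r, edges in comp_edges.items():
        v = comp_vertices[r]
        if edges == v:
            cycles += 1
        elif edges % 2 == 1:
            odd_paths += 1
    return int(n - cycles - odd_paths // 2)


# ---------------------------------------------------------------------------
# event accounting


def count_fission_fusion(ancestor, extant, genome_id: str = "") -> RearrangementSummary:
    """Chromosome-count and sign accounting of one extant genome versus the
    inferred ancestor (a lower-bound event estimator)."""
    anc_chroms = _chromosomes(ancestor)
    ext_chroms = _chromosomes(extant)
    ua, ue = _universe(anc_chroms), _universe(ext_chroms)
    shared = ua & ue
    anc_shared = [
        [x for x in c if abs(x) in shared] for c in anc_chroms
    ]
    ext_shared = [
        [x for x in c if abs(x) in shared] for c in ext_chroms
    ]
    anc_shared = [c for c in anc_shared if c]
    ext_shared = [c for c in ext_shared if c]
    n_anc, n_ext = len(anc_shared), len(ext_shared)
    fissions = max(0, n_ext - n_anc)
    fusions = max(0, n_anc - n_ext)

    anc_sign = {}
    for c in (_canonical_chrom(c) for c in anc_shared):
        for x in c:
            anc_sign[abs(x)] = 1 if x > 0 else -1
    inv = 0
    for c in (_canonical_chrom(c) for c in ext_shared):
        agree = sum(1 for x in c if anc_sign[abs(x)] == (1 if x > 0 else -1))
        inv += min(agree, len(c) - agree)

    d = dcj_distance(anc_shared, ext_shared) if shared else 0
    return RearrangementSummary(genome_id, d, fissions, fusions, inv)
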