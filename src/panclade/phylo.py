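"""Distance phylogeny and divergence-time calibration.

Single-copy families (exactly one member in every genome) provide the
alignment columns; pairwise p-distances are combined length-weighted across
families (equivalent to the concatenated-alignment p) and corrected with
the Jukes–Cantor formula d = -(3/4) ln(1 - (4/3) p).  The tree is built by
neighbor joining with deterministic tie-breaking, rooted on the outgroup
edge, and node ages are assigned by scaling mean root-to-leaf depths to a
single calibration age, which enforces ultrametricity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .exceptions import InputError

JC_CEILING = 5.0  # distance used when p >= 0.75 (correction undefined)


@dataclass
class SingleCopySet:
    families: list  # family ids
    sequences: dict  # family -> {genome -> sequence}
    genomes: list


def select_single_copy(families, genomes, cds=None) -> SingleCopySet:
    """Families with exactly one member in every genome.

    ``cds[genome][gene_id]`` supplies sequences when given.
    """
    genomes = list(genomes)
    chosen = []
    seqs: dict = {}
    for f in families:
        per: dict = {}
        for genome, gid in f.members:
            per.setdefault(genome, []).append(gid)
        if set(per) == set(genomes) and all(len(v) == 1 for v in per.values()):
            chosen.append(f.family_id)
            if cds is not None:
                seqs[f.family_id] = {
                    g: cds[g][per[g][0]] for g in genomes
                }
    if not chosen:
        raise InputError(
            "no single-copy families found; relax family clustering parameters"
        )
    return SingleCopySet(chosen, seqs, genomes)


# ---------------------------------------------------------------------------
# distances


def _pair_p(sa: str, sb: str, aligner=None):
    """(mismatch proportion, compared length) for one sequence pair."""
    if len(sa) == len(sb):
        a = np.frombuffer(sa.encode(), dtype=np.uint8)
        b = np.frombuffer(sb.encode(), dtype=np.uint8)
        return float((a != b).mean()), len(sa)
    if aligner is None:
        from Bio import Align

        aligner = Align.PairwiseAligner(
            mode="global",
            match_score=1,
            mismatch_score=-1,
            open_gap_score=-2,
            extend_gap_score=-2,
        )
    aln = aligner.align(sa, sb)[0]
    mism = 0
    ncol = 0
    for (a1, a2), (b1, b2) in zip(*aln.aligned):
        ncol += a2 - a1
        mism += sum(1 for x, y in zip(sa[a1:a2], sb[b1:b2]) if x != y)
    return (mism / ncol if ncol else 0.0), ncol


def jc_correct(p: float) -> float:
    if p >= 0.75:
        warnings.warn(f"p-distance {p:.3f} >= 0.75; using ceiling {JC_CEILING}")
        return JC_CEILING
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def distance_matrix(scs: SingleCopySet) -> pd.DataFrame:
    """Jukes–Cantor distances on length-weighted mean p across families."""
    genomes = sorted(scs.genomes)
    if len(genomes) < 2:
        raise InputError("need at least 2 genomes")
    n = len(genomes)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            tot_mism, tot_len = 0.0, 0
            for fam in scs.families:
                seqs = scs.sequences[fam]
                p, ln = _pair_p(seqs[genomes[i]], seqs[genomes[j]])
                tot_mism += p * ln
                tot_len += ln
            pbar = tot_mism / tot_len if tot_len else 0.0
            d[i, j] = d[j, i] = jc_correct(pbar)
    return pd.DataFrame(d, index=genomes, columns=genomes)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: pd.DataFrame, outgroup: str) -> dendropy.Tree:
    """Neighbor joining rooted on the outgroup edge.

    Negative branch lengths are clamped to zero; the Q-criterion ties break
    on the lexicographically smallest joined-pair names (deterministic).
    """
    labels = list(dm.index)
    if list(dm.columns) != labels:
        raise InputError("distance matrix index and columns must match")
    m = dm.to_numpy(dtype=float)
    if not np.allclose(m, m.T, atol=1e-9):
        raise InputError("distance matrix must be symmetric")
    if outgroup not in labels:
        raise InputError(f"outgroup {outgroup!r} not among genomes")

    nodes = {i: (lab, f"{lab}") for i, lab in enumerate(labels)}  # (name, newick)
    dist = {(i, j): m[i, j] for i in range(len(labels)) for j in range(len(labels))}
    active = list(range(len(labels)))
    nxt = len(labels)

    def d(i, j):
        return dist[(i, j)] if i <= j else dist[(j, i)]

    while len(active) > 2:
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        nA = len(active)
        best = None
        for ai in range(nA):
            for aj in range(ai + 1, nA):
                i, j = active[ai], active[aj]
                q = (nA - 2) * d(i, j) - r[i] - r[j]
                names = tuple(sorted((nodes[i][0], nodes[j][0])))
                key = (q, names)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = d(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (nA - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        name = min(nodes[i][0], nodes[j][0])
        nwk = f"({nodes[i][1]}:{li:.10g},{nodes[j][1]}:{lj:.10g})"
        nodes[nxt] = (name, nwk)
        for k in active:
            if k in (i, j):
                continue
            dist[(min(k, nxt), max(k, nxt))] = 0.5 * (d(i, k) + d(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1

    i, j = active
    dij = max(d(i, j), 0.0)
    newick = f"({nodes[i][1]}:{dij / 2:.10g},{nodes[j][1]}:{dij / 2:.10g});"
    tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")

    # root at the midpoint of the outgroup edge (in the unrooted sense)
    og = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == outgroup:
            og = leaf
            break
    root_kids = tree.seed_node.child_nodes()
    if og in root_kids and len(root_kids) == 2:
        sib = root_kids[0] if root_kids[1] is og else root_kids[1]
        full = (og.edge.length or 0.0) + (sib.edge.length or 0.0)
        og.edge.length = full / 2
        sib.edge.length = full / 2
    else:
        half = (og.edge.length or 0.0) / 2
        tree.reroot_at_edge(og.edge, length1=half, length2=half,
                            update_bipartitions=False)
        tree.suppress_unifurcations()
    tree.seed_node.label = "root"
    n = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.label = node.taxon.label
        elif node.parent_node is not None and not node.label:
            n += 1
            node.label = f"n{n}"
    return tree


# ---------------------------------------------------------------------------
# calibration


@dataclass
class CalibratedTree:
    tree: dendropy.Tree  # edge lengths in age units (e.g. Mya)
    ages: dict  # node label -> age
    calibration: tuple  # (node label, age)

    def newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


def calibrate_ages(tree: dendropy.Tree, calibration_node, calibration_age: float,
                   ) -> CalibratedTree:
    """Scale node depths so the calibration node has the given age.

    ``calibration_node`` is an internal node label, ``"root"``, or an
    iterable of leaf labels (their MRCA).  A node's raw depth is its mean
    distance to descendant leaves; ages are that depth times a single scale
    factor, with leaves at age 0 — which makes the result exactly
    ultrametric.
    """
    if calibration_age <= 0:
        raise InputError("calibration age must be positive")
    tree = _copy_tree(tree)

    if isinstance(calibration_node, (list, tuple, set)):
        taxa = set(calibration_node)
        target = tree.mrca(taxon_labels=sorted(taxa))
    else:
        target = None
        for node in tree.preorder_node_iter():
            if node.label == calibration_node:
                target = node
                break
    if target is None or target.is_leaf():
        raise InputError("calibration node must be an internal node of the tree")

    raw: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            raw[node] = 0.0
        else:
            kids = node.child_nodes()
            raw[node] = sum(
                raw[c] + (c.edge.length or 0.0) for c in kids
            ) / len(kids)
    if raw[target] <= 0:
        raise InputError("calibration node has zero depth")
    scale = calibration_age / raw[target]

    ages: dict = {}
    for node in tree.preorder_node_iter():
        a = raw[node] * scale
        if node.parent_node is not None:
            a = min(a, ages[node.parent_node.label])
        ages[node.label] = a
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = ages[node.parent_node.label] - ages[node.label]
    return CalibratedTree(tree, ages, (target.label, calibration_age))


def _copy_tree(tree: dendropy.Tree) -> dendropy.Tree:
    clone = dendropy.Tree.get(
        data=tree.as_string(schema="newick"), schema="newick",
        rooting="force-rooted",
    )
    for node in clone.preorder_node_iter():
        if node.is_leaf():
            node.label = node.taxon.label
    return clone


def leaf_sets(tree: dendropy.Tree) -> dict:
    """node label -> frozenset of descendant leaf labels."""
    out = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            out[node.label] = frozenset([node.taxon.label if node.taxon else node.label])
        else:
            s = frozenset().union(*(out[c.label] for c in node.child_nodes()))
            out[node.label] = s
    return out
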