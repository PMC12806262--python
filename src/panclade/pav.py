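"""Pan-genome construction and presence/absence-variation analysis.

Genes are clustered into families by nucleotide k-mer Jaccard similarity
(k = 8, threshold 0.5 by default) with single-linkage merging, giving a
partition of all genes across genomes.  The family × genome binary matrix
(PAV matrix) is then partitioned by occupancy into

* ``core``      — present in every genome,
* ``variable``  — present in more than one but not all,
* ``specific``  — present in exactly one genome,

the three classes summing to the pan-genome total.  The module also
computes pan/core gene accumulation curves over random genome orderings,
clusters genomes by their PAV profiles (average linkage on Jaccard
distance), and runs one-sided hypergeometric term enrichment with
Benjamini–Hochberg correction.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from ._util import BASES
from .exceptions import InputError

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


@dataclass
class GeneFamily:
    family_id: str
    members: list  # (genome_id, gene_id)

    @property
    def occupancy(self) -> int:
        return len({g for g, _ in self.members})

    def genomes(self) -> set:
        return {g for g, _ in self.members}


# ---------------------------------------------------------------------------
# family clustering


def _kmer_indices(seq: str, k: int) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if len(codes) < k or (codes == 255).any():
        codes = codes[codes != 255]
        if len(codes) < k:
            return np.empty(0, dtype=np.int64)
    n = len(codes) - k + 1
    km = np.zeros(n, dtype=np.int64)
    for j in range(k):
        km = (km << 2) | codes[j : j + n]
    return np.unique(km)


class _DSU:
    def __init__(self, n):
        self.p = list(range(n))

    def find(self, x):
        while self.p[x] != x:
            self.p[x] = self.p[self.p[x]]
            x = self.p[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.p[max(ra, rb)] = min(ra, rb)


def cluster_gene_families(gene_sequences: dict, k: int = 8, threshold: float = 0.5):
    """Partition genes into families by k-mer Jaccard single linkage.

    ``gene_sequences`` maps genome id -> {gene id -> CDS} (or an iterable of
    ``(gene_id, seq)`` pairs per genome).  Two genes join the same family
    when connected by a chain of pairs with Jaccard similarity >= threshold
    on their k-mer sets.  Deterministic given input order.
    """
    genes: list[tuple[str, str]] = []
    seqs: list[str] = []
    for genome in gene_sequences:
        items = gene_sequences[genome]
        pairs = items.items() if isinstance(items, dict) else list(items)
        seen = set()
        for gid, seq in pairs:
            if gid in seen:
                raise InputError(f"duplicate gene id {gid!r} in genome {genome!r}")
            seen.add(gid)
            if not seq:
                raise InputError(f"empty sequence for gene {gid!r} in {genome!r}")
            genes.append((genome, gid))
            seqs.append(seq)
    n = len(genes)
    if n == 0:
        return []

    kmer_sets = [_kmer_indices(s, k) for s in seqs]
    sizes = np.array([len(s) for s in kmer_sets], dtype=np.int64)
    dsu = _DSU(n)

    if 4**k <= 1 << 20:
        words = (4**k + 63) // 64
        packed = np.zeros((n, words), dtype=np.uint64)
        for i, km in enumerate(kmer_sets):
            np.bitwise_or.at(
                packed[i], km >> 6, np.uint64(1) << (km & 63).astype(np.uint64)
            )
        for i in range(n - 1):
            inter = np.bitwise_count(packed[i + 1 :] & packed[i]).sum(axis=1)
            union = sizes[i + 1 :] + sizes[i] - inter
            with np.errstate(invalid="ignore", divide="ignore"):
                jac = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
            for j in np.nonzero(jac >= threshold)[0]:
                dsu.union(i, i + 1 + int(j))
    else:  # large k: plain set arithmetic
        sets = [set(km.tolist()) for km in kmer_sets]
        for i in range(n - 1):
            for j in range(i + 1, n):
                inter = len(sets[i] & sets[j])
                union = len(sets[i]) + len(sets[j]) - inter
                if union and inter / union >= threshold:
                    dsu.union(i, j)

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(dsu.find(i), []).append(i)
    ordered = sorted(comps.values(), key=lambda idxs: min(genes[i] for i in idxs))
    return [
        GeneFamily(f"F{fi:06d}", sorted(genes[i] for i in idxs))
        for fi, idxs in enumerate(ordered, start=1)
    ]


# ---------------------------------------------------------------------------
# PAV matrix


@dataclass
class PAVMatrix:
    """Binary family × genome matrix with occupancy-class labels."""

    matrix: pd.DataFrame  # index = family ids, columns = genome ids, values 0/1

    @property
    def genomes(self) -> list:
        return list(self.matrix.columns)

    @property
    def families(self) -> list:
        return list(self.matrix.index)

    def occupancy(self) -> pd.Series:
        return self.matrix.sum(axis=1)

    def classes(self) -> pd.Series:
        occ = self.occupancy()
        n = len(self.matrix.columns)
        lab = np.where(occ == n, "core", np.where(occ == 1, "specific", "variable"))
        return pd.Series(lab, index=self.matrix.index, name="class")


def build_pav_matrix(families, genomes=None) -> PAVMatrix:
    if genomes is None:
        genomes = sorted({g for f in families for g in f.genomes()})
    data = np.zeros((len(families), len(genomes)), dtype=np.int8)
    gi = {g: j for j, g in enumerate(genomes)}
    for i, f in enumerate(families):
        for g in f.genomes():
            data[i, gi[g]] = 1
    return PAVMatrix(
        pd.DataFrame(data, index=[f.family_id for f in families], columns=list(genomes))
    )


def classify_occupancy(pav: PAVMatrix) -> dict:
    """Core / variable / specific counts; always sums to the family total."""
    if pav.matrix.empty:
        raise InputError("PAV matrix is empty")
    occ = pav.occupancy()
    if (occ == 0).any():
        raise InputError("PAV matrix has a zero-occupancy family row")
    cls = pav.classes()
    counts = cls.value_counts()
    return {
        "core": int(counts.get("core", 0)),
        "variable": int(counts.get("variable", 0)),
        "specific": int(counts.get("specific", 0)),
        "total": int(len(pav.matrix)),
    }


def accumulation_curves(pav: PAVMatrix, n_orderings=100, seed: int = 0) -> pd.DataFrame:
    """Pan/core size curves over genome orderings (mean ± sd per k).

    ``n_orderings="all"`` enumerates every permutation (refused above 10,000
    orderings); otherwise orderings are sampled uniformly with the given
    seed.  pan(k) is non-decreasing and core(k) non-increasing along every
    ordering.
    """
    m = pav.matrix.to_numpy(dtype=bool)
    n = m.shape[1]
    if n_orderings == "all":
        if math.factorial(n) > 10_000:
            raise InputError("exhaustive enumeration limited to n! <= 10000")
        perms = list(itertools.permutations(range(n)))
    else:
        if int(n_orderings) < 1:
            raise InputError("n_orderings must be >= 1")
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(int(n_orderings))]
    pan = np.empty((len(perms), n), dtype=np.int64)
    core = np.empty((len(perms), n), dtype=np.int64)
    for i, perm in enumerate(perms):
        cols = m[:, list(perm)]
        pan[i] = np.logical_or.accumulate(cols, axis=1).sum(axis=0)
        core[i] = np.logical_and.accumulate(cols, axis=1).sum(axis=0)
    return pd.DataFrame(
        {
            "k": np.arange(1, n + 1),
            "pan_mean": pan.mean(axis=0),
            "pan_sd": pan.std(axis=0, ddof=0),
            "core_mean": core.mean(axis=0),
            "core_sd": core.std(axis=0, ddof=0),
        }
    )


# ---------------------------------------------------------------------------
# genome clustering


def pav_linkage(pav: PAVMatrix):
    """Average-linkage clustering of genomes on Jaccard distance.

    Genomes are ordered lexicographically before clustering so that ties in
    the distance matrix resolve by genome id.  Returns (linkage, labels).
    """
    if len(pav.genomes) < 2:
        raise InputError("need at least 2 genomes to cluster")
    labels = sorted(pav.genomes)
    m = pav.matrix[labels].to_numpy(dtype=bool).T
    d = pdist(m, metric="jaccard")
    return hierarchy.average(d), labels


def _linkage_to_newick(z, labels) -> str:
    tree = hierarchy.to_tree(z)

    def rec(node, parent_height):
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height / 2:.6g}"
        h = node.dist
        left = rec(node.left, h)
        right = rec(node.right, h)
        bl = (parent_height - h) / 2
        return f"({left},{right}):{bl:.6g}"

    root = rec(tree, tree.dist)
    return root.rsplit(":", 1)[0] + ";"


def cluster_genomes_by_pav(pav: PAVMatrix) -> str:
    """Genome dendrogram (Newick) from PAV-profile Jaccard distances."""
    z, labels = pav_linkage(pav)
    return _linkage_to_newick(z, labels)


# ---------------------------------------------------------------------------
# term enrichment


def enrich_terms(gene_set, annotation, background) -> pd.DataFrame:
    """One-sided hypergeometric enrichment with BH correction.

    ``annotation`` maps gene id -> iterable of terms.  Genes of ``gene_set``
    must all be in ``background``.  Returns a DataFrame sorted by (q, p)
    with columns term, n_term, n_set, overlap, fold, p, q.
    """
    background = set(background)
    gene_set = set(gene_set)
    missing = gene_set - background
    if missing:
        raise InputError(f"gene set members absent from background: {sorted(missing)[:5]}")
    cols = ["term", "n_term", "n_set", "overlap", "fold", "p", "q"]
    if not gene_set:
        warnings.warn("empty gene set; no enrichment computed")
        return pd.DataFrame(columns=cols)

    term_bg: dict[str, set] = {}
    covered = 0
    for gene, terms in (annotation.items() if isinstance(annotation, dict) else annotation):
        if gene in background:
            covered += 1
            for t in terms:
                term_bg.setdefault(t, set()).add(gene)
    if covered == 0:
        raise InputError("annotation covers no background gene")

    M, N = len(background), len(gene_set)
    rows = []
    for term in sorted(term_bg):
        K = len(term_bg[term])
        k_obs = len(term_bg[term] & gene_set)
        if K == 0 and k_obs == 0:
            continue
        p = float(hypergeom.sf(k_obs - 1, M, K, N))
        fold = (k_obs / N) / (K / M) if K else 0.0
        rows.append({"term": term, "n_term": K, "n_set": N, "overlap": k_obs,
                     "fold": fold, "p": p})
    df = pd.DataFrame(rows, columns=cols[:-1])
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["q"] = []
    return df.sort_values(["q", "p", "term"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# truth comparison


def family_rand_index(families, truth_gene_families: dict) -> float:
    """Rand index between inferred families and the simulator's truth."""
    from sklearn.metrics import rand_score

    inferred = {}
    for f in families:
        for genome, gid in f.members:
            inferred[(genome, gid)] = f.family_id
    keys, true_lab, inf_lab = [], [], []
    for genome, mapping in truth_gene_families.items():
        for gid, fam in mapping.items():
            key = (genome, gid)
            if key in inferred:
                keys.append(key)
                true_lab.append(fam)
                inf_lab.append(inferred[key])
    if not keys:
        return float("nan")
    return float(rand_score(true_lab, inf_lab))
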