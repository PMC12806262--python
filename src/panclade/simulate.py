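"""Synthetic clade generator.

Evolves an annotated ancestral genome along a rooted tree and emits one
assembly (FASTA) and one annotation (GFF3) per leaf, together with a
:class:`TruthSet` recording every planted event.  The generator covers the
event classes a diploid pan-genome study observes between related genomes:

* gene-family gain and loss (producing core / variable / specific structure),
* chromosomal inversions, fissions, fusions and translocations,
* six classes of structural variant (insertion, deletion, tandem
  expansion/contraction, repeat expansion/contraction), optionally clustered
  into hotspots,
* species-specific promoter deletions,
* Jukes–Cantor substitutions.

Every genome segment carries its ancestral coordinate interval, so planted
homology is known exactly; :mod:`panclade.alignment` turns that knowledge
into synthetic whole-genome alignments without an external aligner.

Coordinates in truth records are 0-based half-open on the ancestor; GFF3
output is 1-based inclusive.
"""

from __future__ import annotations

import csv
import dataclasses
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np

from ._util import BASES, dump_json, load_json, random_dna, revcomp, sha256_file
from .exceptions import ConfigurationError, GenerationError

SV_TYPES = (
    "insertion",
    "deletion",
    "tandem_expansion",
    "tandem_contraction",
    "repeat_expansion",
    "repeat_contraction",
)

_SV_MARGIN = 100  # bp kept intact on each side of a planted SV
_DIRTY_GUARD = 200  # min distance between planted SVs on the ancestor


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimConfig:
    """Parameters of one simulated clade.

    Rates for gene gain/loss and substitutions are per branch-length unit
    (expected substitutions/site); rearrangement and SV rates are expected
    events per branch (Poisson draws).
    """

    n_genomes: int = 8  # leaves; used only when tree == "random"
    n_chromosomes: int = 4
    genes_per_chromosome: int = 40
    gene_length_bp: int = 600
    intergenic_bp: int = 3000
    tree: str = "random"  # "random" (Yule) or a rooted Newick string
    tree_depth: float = 1.0  # total depth used to scale random trees
    rate_gene_gain: float = 0.0
    rate_gene_loss: float = 0.0
    rate_duplication: float = 0.0
    rate_inversion: float = 0.0
    rate_fission: float = 0.0
    rate_fusion: float = 0.0
    rate_translocation: float = 0.0
    sv_rates: dict = field(default_factory=dict)
    sv_size_range: tuple = (50, 2000)
    hotspot_spec: list = field(default_factory=list)  # (chrom, start, end, mult)
    substitution_rate: float = 0.0
    promoter_deletion_spec: list | None = None  # (genomes, family, length[, offset])
    allow_genic_sv: bool = False
    seed: int = 0

    def validate(self) -> None:
        scalar_rates = [
            self.rate_gene_gain,
            self.rate_gene_loss,
            self.rate_duplication,
            self.rate_inversion,
            self.rate_fission,
            self.rate_fusion,
            self.rate_translocation,
            self.substitution_rate,
        ]
        if any(r < 0 for r in scalar_rates):
            raise ConfigurationError("all rates must be >= 0")
        for t, r in self.sv_rates.items():
            if t not in SV_TYPES:
                raise ConfigurationError(f"unknown SV type {t!r}")
            if r < 0:
                raise ConfigurationError("all SV rates must be >= 0")
        lo, hi = self.sv_size_range
        if lo < 50:
            raise ConfigurationError("sv_size_range minimum must be >= 50 bp")
        if hi < lo:
            raise ConfigurationError("sv_size_range must be (min, max) with min <= max")
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise ConfigurationError("need at least one chromosome and one gene")
        if self.gene_length_bp < 30 or self.intergenic_bp < 2 * _SV_MARGIN:
            raise ConfigurationError("gene/intergenic lengths too small")
        if self.tree == "random" and self.n_genomes < 2:
            raise ConfigurationError("a clade needs at least 2 genomes")
        for spot in self.hotspot_spec:
            _, start, end, mult = spot
            if end <= start or mult <= 0:
                raise ConfigurationError(f"bad hotspot interval {spot!r}")


# ---------------------------------------------------------------------------
# genome model


@dataclass
class Segment:
    """A run of sequence with known ancestral provenance.

    ``anc`` is the (chrom, start, end) interval of the ancestor this segment
    descends from (None for novel sequence); ``strand`` is the orientation of
    this genome's forward strand relative to the ancestral forward strand.
    Genes additionally carry ``coding`` — the ancestral coding orientation —
    so the coding strand in this genome is ``coding * strand``.
    """

    seq: str
    kind: str  # "gene" | "intergenic"
    strand: int = 1
    family: str | None = None
    coding: int = 1
    anc: tuple | None = None
    gene_id: str | None = None
    dup_event: str | None = None  # SV event id for tandem-duplicate copies

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneInfo:
    gene_id: str
    family: str
    chrom: str
    rank: int  # 0-based rank along the chromosome
    start: int  # bp, 0-based half-open
    end: int
    strand: str  # coding strand, "+"/"-"


class Genome:
    """Ordered chromosomes of :class:`Segment` runs."""

    def __init__(self, name: str):
        self.name = name
        self.chroms: dict[str, list[Segment]] = {}

    def copy(self, name: str) -> "Genome":
        g = Genome(name)
        g.chroms = {c: [replace(s) for s in segs] for c, segs in self.chroms.items()}
        return g

    def sequence(self, chrom: str) -> str:
        return "".join(s.seq for s in self.chroms[chrom])

    def chrom_lengths(self) -> dict:
        return {c: sum(len(s) for s in segs) for c, segs in self.chroms.items()}

    def genes(self):
        for chrom, segs in self.chroms.items():
            pos = 0
            rank = 0
            for s in segs:
                if s.kind == "gene":
                    strand = "+" if s.coding * s.strand > 0 else "-"
                    yield GeneInfo(s.gene_id, s.family, chrom, rank, pos, pos + len(s), strand)
                    rank += 1
                pos += len(s)

    def cds_sequences(self) -> dict:
        """gene_id -> CDS in coding orientation."""
        out = {}
        for chrom, segs in self.chroms.items():
            for s in segs:
                if s.kind == "gene":
                    out[s.gene_id] = s.seq if s.coding * s.strand > 0 else revcomp(s.seq)
        return out

    def gene_order(self) -> dict:
        """chrom -> ordered list of (gene_id, family, coding strand)."""
        out = {}
        for g in self.genes():
            out.setdefault(g.chrom, []).append((g.gene_id, g.family, g.strand))
        return out

    def assign_gene_ids(self) -> None:
        i = 0
        for segs in self.chroms.values():
            for s in segs:
                if s.kind == "gene":
                    i += 1
                    s.gene_id = f"{self.name}_g{i:05d}"

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in self.chroms:
                fh.write(f">{chrom}\n")
                seq = self.sequence(chrom)
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    def write_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes():
                attrs = f"ID={g.gene_id};Name={g.gene_id}"
                fh.write(
                    f"{g.chrom}\tpanclade\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# truth records


@dataclass(frozen=True)
class FamilyEvent:
    branch: str
    kind: str  # "gain" | "loss" | "duplication"
    family: str
    anc_chrom: str = ""  # ancestor-coordinate anchor of the gene, when known
    anc_pos: int = -1
    size: int = 0


@dataclass(frozen=True)
class RearrangementEvent:
    branch: str
    kind: str  # inversion | fission | fusion | translocation
    chrom: str
    pos: int = -1  # segment index (kind-dependent)
    pos2: int = -1
    chrom2: str = ""
    n_genes: int = 0


@dataclass(frozen=True)
class SVEvent:
    event_id: str
    branch: str
    type: str
    anc_chrom: str
    anc_start: int
    anc_end: int
    size: int
    src_chrom: str = ""
    src_start: int = -1


@dataclass(frozen=True)
class PromoterIndel:
    genome: str
    gene_id: str
    family: str
    length: int
    offset: int


@dataclass
class TruthSet:
    """Planted events of one simulation; the downstream test oracle."""

    family_events: list = field(default_factory=list)
    rearrangement_events: list = field(default_factory=list)
    sv_events: list = field(default_factory=list)
    hotspot_intervals: list = field(default_factory=list)
    promoter_indels: list = field(default_factory=list)
    true_tree: str = ""
    node_ages: dict = field(default_factory=dict)
    leaf_paths: dict = field(default_factory=dict)
    gene_families: dict = field(default_factory=dict)  # genome -> gene_id -> family

    def branches_to(self, genome: str) -> list:
        if genome == "ancestor":
            return []
        return self.leaf_paths[genome]

    def sv_events_for(self, genome: str) -> list:
        """Planted SVs carried by a genome (inherited along its root path)."""
        path = set(self.branches_to(genome))
        return [e for e in self.sv_events if e.branch in path]

    def events_on_branch(self, branch: str, kind: str | None = None) -> list:
        out = [e for e in self.rearrangement_events if e.branch == branch]
        if kind is not None:
            out = [e for e in out if e.kind == kind]
        return out


# ---------------------------------------------------------------------------
# trees


def _label_tree(tree: dendropy.Tree) -> None:
    n = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            if node.taxon is None or not node.taxon.label:
                raise ConfigurationError("every leaf must be labelled")
            node.label = node.taxon.label
        elif node.parent_node is None:
            node.label = node.label or "root"
        elif not node.label:
            n += 1
            node.label = f"n{n}"


def parse_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise ConfigurationError("tree must have at least 2 leaves")
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            raise ConfigurationError("every non-root edge needs a branch length")
    _label_tree(tree)
    return tree


def yule_tree(n_leaves: int, depth: float, rng) -> dendropy.Tree:
    """Ultrametric pure-birth tree with unit birth rate, scaled to ``depth``."""
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    times = {root: 0.0}  # birth time of each node's subtending edge's child end
    t = 0.0
    active = []
    for _ in range(2):  # root splits at time 0
        child = dendropy.Node()
        root.add_child(child)
        times[child] = 0.0
        active.append(child)
    k = 2
    while k < n_leaves:
        t += rng.exponential(1.0 / k)
        idx = int(rng.integers(0, k))
        node = active.pop(idx)
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            times[child] = t
            active.append(child)
        k += 1
    t_end = t + rng.exponential(1.0 / max(k, 1))
    scale = depth / t_end if t_end > 0 else 1.0
    # edge lengths: child's span from its birth to its own split (or t_end)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        end = times[node.child_nodes()[0]] if node.child_nodes() else t_end
        node.edge.length = max(end - times[node], 0.0) * scale
    i = 0
    for leaf in tree.leaf_node_iter():
        i += 1
        leaf.taxon = tns.new_taxon(label=f"g{i}")
    _label_tree(tree)
    return tree


def node_ages(tree: dendropy.Tree) -> dict:
    """Label -> age, with age = (max root-to-leaf depth) - depth of node."""
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    total = max(depths[l] for l in tree.leaf_node_iter())
    return {node.label: total - d for node, d in depths.items()}


# ---------------------------------------------------------------------------
# ancestor construction


def _build_ancestor(cfg: SimConfig, rng) -> tuple[Genome, list]:
    g = Genome("ancestor")
    fam = 0
    families = []
    for c in range(1, cfg.n_chromosomes + 1):
        chrom = f"chr{c}"
        segs = []
        pos = 0

        def add(seq, **kw):
            nonlocal pos
            segs.append(Segment(seq=seq, anc=(chrom, pos, pos + len(seq)), **kw))
            pos += len(seq)

        add(random_dna(rng, cfg.intergenic_bp), kind="intergenic")
        for _ in range(cfg.genes_per_chromosome):
            fam += 1
            fid = f"fam{fam:05d}"
            families.append(fid)
            coding = 1 if rng.integers(0, 2) == 0 else -1
            add(random_dna(rng, cfg.gene_length_bp), kind="gene", family=fid, coding=coding)
            add(random_dna(rng, cfg.intergenic_bp), kind="intergenic")
        g.chroms[chrom] = segs
    return g, families


# ---------------------------------------------------------------------------
# mutation operators

_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
_BASE_ARR = np.frombuffer(BASES.encode(), dtype=np.uint8)


def mutate_jc(seq: str, mu: float, rng) -> str:
    """Apply Jukes–Cantor substitutions for total branch amount ``mu``."""
    if mu <= 0 or not seq:
        return seq
    p = 0.75 * (1.0 - math.exp(-4.0 * mu / 3.0))
    n = int(rng.binomial(len(seq), p))
    if n == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    idx = rng.choice(len(seq), size=n, replace=False)
    code = _CODE[arr[idx]]
    arr[idx] = _BASE_ARR[(code + rng.integers(1, 4, size=n)) % 4]
    return arr.tobytes().decode()


def _split_segment(seg: Segment, off: int) -> tuple[Segment, Segment]:
    """Split a strand-+1 tagged segment at sequence offset ``off``."""
    c, a1, a2 = seg.anc
    left = replace(seg, seq=seg.seq[:off], anc=(c, a1, a1 + off))
    right = replace(seg, seq=seg.seq[off:], anc=(c, a1 + off, a2))
    return left, right


class _Counters:
    def __init__(self):
        self.gain = 0
        self.sv = 0
        self.fission = 0
        # ancestor-coordinate intervals consumed by any planted SV, shared
        # across the whole clade so events on different branches stay
        # separable in every pairwise comparison
        self.dirty: list[tuple] = []
        # families that must survive in every leaf (promoter-scan targets)
        self.protected: set = set()


def _hotspot_multiplier(cfg: SimConfig, anc: tuple) -> float:
    c, a1, a2 = anc
    for chrom, start, end, mult in cfg.hotspot_spec:
        if chrom == c and a1 < end and start < a2:
            return float(mult)
    return 1.0


def _eligible(genome: Genome, need_len: int, cfg: SimConfig):
    out, weights = [], []
    for chrom, segs in genome.chroms.items():
        for i, s in enumerate(segs):
            if (
                s.kind == "intergenic"
                and s.anc is not None
                and s.strand == 1
                and s.dup_event is None
                and len(s) >= need_len
            ):
                out.append((chrom, i))
                weights.append(len(s) * _hotspot_multiplier(cfg, s.anc))
    return out, np.asarray(weights, dtype=float)


def _is_dirty(dirty: list, chrom: str, a1: int, a2: int) -> bool:
    for c, d1, d2 in dirty:
        if c == chrom and a1 - _DIRTY_GUARD < d2 and d1 < a2 + _DIRTY_GUARD:
            return True
    return False


def _place_sv(genome: Genome, svtype: str, size: int, cfg: SimConfig, rng, branch, eid, counters):
    """Realise one SV in intergenic sequence; returns the SVEvent."""
    consumes = svtype in ("deletion", "tandem_contraction", "repeat_contraction")
    dup = svtype == "tandem_expansion"
    need = size + 2 * _SV_MARGIN if (consumes or dup) else 2 * _SV_MARGIN
    cand, weights = _eligible(genome, need, cfg)
    if not cand:
        raise GenerationError(
            f"branch {branch}: no intergenic segment can host a {svtype} of {size} bp"
        )
    for _ in range(100):
        idx = int(rng.choice(len(cand), p=weights / weights.sum()))
        chrom, i = cand[idx]
        seg = genome.chroms[chrom][i]
        c, a1, _ = seg.anc
        if consumes or dup:
            off = int(rng.integers(_SV_MARGIN, len(seg) - size - _SV_MARGIN + 1))
            ev_start, ev_end = a1 + off, a1 + off + size
        else:
            off = int(rng.integers(_SV_MARGIN, len(seg) - _SV_MARGIN + 1))
            ev_start = ev_end = a1 + off
        if not _is_dirty(counters.dirty, c, ev_start, ev_end):
            break
    else:
        raise GenerationError(
            f"branch {branch}: could not place {svtype} of {size} bp away from prior events"
        )

    segs = genome.chroms[chrom]
    src_chrom, src_start = "", -1
    if svtype == "insertion" or svtype == "repeat_expansion":
        if svtype == "repeat_expansion":
            scand, sw = _eligible(genome, size + 2, cfg)
            scand = [x for x in scand if x != (chrom, i)] or scand
            sc, si = scand[int(rng.integers(0, len(scand)))]
            sseg = genome.chroms[sc][si]
            soff = int(rng.integers(0, len(sseg) - size + 1))
            seq = sseg.seq[soff : soff + size]
            src_chrom, src_start = sseg.anc[0], sseg.anc[1] + soff
        else:
            seq = random_dna(rng, size)
        left, right = _split_segment(seg, off)
        novel = Segment(seq=seq, kind="intergenic", anc=None)
        segs[i : i + 1] = [left, novel, right]
    elif consumes:
        left, mid = _split_segment(seg, off)
        _, right = _split_segment(mid, size)
        segs[i : i + 1] = [left, right]
        if svtype == "repeat_contraction":
            scand, _w = _eligible(genome, 2, cfg)
            scand = [x for x in scand if x != (chrom, i)] or scand
            sc, si = scand[int(rng.integers(0, len(scand)))]
            sseg = genome.chroms[sc][si]
            src_chrom, src_start = sseg.anc[0], sseg.anc[1]
    else:  # tandem_expansion: duplicate the slice [off, off+size) in place
        left, right = _split_segment(seg, off + size)
        copy_seg = Segment(
            seq=seg.seq[off : off + size],
            kind="intergenic",
            anc=(c, a1 + off, a1 + off + size),
            dup_event=eid,
        )
        segs[i : i + 1] = [left, copy_seg, right]

    counters.dirty.append((c, ev_start, ev_end))
    return SVEvent(eid, branch, svtype, c, ev_start, ev_end, size, src_chrom, src_start)


def _pick_gene(genome: Genome, rng, exclude: set = frozenset()):
    genes = [
        (chrom, i)
        for chrom, segs in genome.chroms.items()
        for i, s in enumerate(segs)
        if s.kind == "gene" and s.family not in exclude
    ]
    if not genes:
        return None
    return genes[int(rng.integers(0, len(genes)))]


def _apply_branch(genome, branch, bl, cfg, rng, truth, counters):
    # ---- gene losses
    for _ in range(rng.poisson(cfg.rate_gene_loss * bl)):
        pick = _pick_gene(genome, rng, exclude=counters.protected)
        if pick is None:
            break
        chrom, i = pick
        seg = genome.chroms[chrom].pop(i)
        if seg.anc is not None and seg.strand == 1:
            ev = FamilyEvent(branch, "loss", seg.family, seg.anc[0], seg.anc[1], len(seg))
        else:
            ev = FamilyEvent(branch, "loss", seg.family)
        truth.family_events.append(ev)
    # ---- gene gains (new single-member families)
    for _ in range(rng.poisson(cfg.rate_gene_gain * bl)):
        counters.gain += 1
        fid = f"famG{counters.gain:05d}"
        chroms = list(genome.chroms)
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        segs = genome.chroms[chrom]
        j = int(rng.integers(0, len(segs) + 1))
        coding = 1 if rng.integers(0, 2) == 0 else -1
        anc_chrom, anc_pos = "", -1
        for left in range(j - 1, -1, -1):
            sl = segs[left]
            if sl.anc is not None and sl.strand == 1:
                anc_chrom, anc_pos = sl.anc[0], sl.anc[2]
                break
        segs.insert(
            j,
            Segment(
                seq=random_dna(rng, cfg.gene_length_bp),
                kind="gene",
                family=fid,
                coding=coding,
                anc=None,
            ),
        )
        truth.family_events.append(
            FamilyEvent(branch, "gain", fid, anc_chrom, anc_pos, cfg.gene_length_bp)
        )
    # ---- gene duplications (optional, default rate 0)
    for _ in range(rng.poisson(cfg.rate_duplication * bl)):
        pick = _pick_gene(genome, rng)
        if pick is None:
            break
        chrom, i = pick
        seg = genome.chroms[chrom][i]
        genome.chroms[chrom].insert(i + 1, replace(seg, anc=None))
        truth.family_events.append(FamilyEvent(branch, "duplication", seg.family))
    # ---- inversions
    for _ in range(rng.poisson(cfg.rate_inversion)):
        chroms = [c for c, s in genome.chroms.items() if len(s) >= 3]
        if not chroms:
            break
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        segs = genome.chroms[chrom]
        n = len(segs)
        i = int(rng.integers(0, n - 1))
        j = int(rng.integers(i + 1, n))
        block = segs[i : j + 1][::-1]
        inv = [
            replace(s, seq=revcomp(s.seq), strand=-s.strand)
            for s in block
        ]
        segs[i : j + 1] = inv
        ngenes = sum(1 for s in inv if s.kind == "gene")
        truth.rearrangement_events.append(
            RearrangementEvent(branch, "inversion", chrom, i, j, n_genes=ngenes)
        )
    # ---- fissions (both fragments must keep >= 1 gene to stay visible)
    for _ in range(rng.poisson(cfg.rate_fission)):
        chroms = [
            c for c, s in genome.chroms.items()
            if sum(1 for x in s if x.kind == "gene") >= 2
        ]
        if not chroms:
            break
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        segs = genome.chroms[chrom]
        ngenes = np.cumsum([s.kind == "gene" for s in segs])
        valid = [
            k for k in range(1, len(segs))
            if 0 < ngenes[k - 1] < ngenes[-1]
        ]
        if not valid:
            continue
        k = valid[int(rng.integers(0, len(valid)))]
        counters.fission += 1
        new_name = f"{chrom}_f{counters.fission}"
        genome.chroms[chrom] = segs[:k]
        genome.chroms[new_name] = segs[k:]
        truth.rearrangement_events.append(
            RearrangementEvent(branch, "fission", chrom, k, chrom2=new_name)
        )
    # ---- fusions
    for _ in range(rng.poisson(cfg.rate_fusion)):
        if len(genome.chroms) < 2:
            break
        names = list(genome.chroms)
        a, b = rng.choice(len(names), size=2, replace=False)
        ca, cb = names[int(a)], names[int(b)]
        genome.chroms[ca] = genome.chroms[ca] + genome.chroms[cb]
        del genome.chroms[cb]
        truth.rearrangement_events.append(
            RearrangementEvent(branch, "fusion", ca, chrom2=cb)
        )
    # ---- translocations
    for _ in range(rng.poisson(cfg.rate_translocation)):
        if len(genome.chroms) < 2:
            break
        srcs = [c for c, s in genome.chroms.items() if len(s) >= 3]
        if not srcs:
            break
        src = srcs[int(rng.integers(0, len(srcs)))]
        segs = genome.chroms[src]
        n = len(segs)
        i = int(rng.integers(0, n - 1))
        j = int(rng.integers(i, min(i + max(n // 4, 1), n - 1)))
        moved = segs[i : j + 1]
        if len(moved) >= n:
            continue
        remaining_genes = sum(
            1 for s in segs[:i] + segs[j + 1 :] if s.kind == "gene"
        )
        if remaining_genes == 0:  # keep the source chromosome visible
            continue
        genome.chroms[src] = segs[:i] + segs[j + 1 :]
        dests = [c for c in genome.chroms if c != src]
        dest = dests[int(rng.integers(0, len(dests)))]
        dsegs = genome.chroms[dest]
        k = int(rng.integers(0, len(dsegs) + 1))
        genome.chroms[dest] = dsegs[:k] + moved + dsegs[k:]
        truth.rearrangement_events.append(
            RearrangementEvent(
                branch, "translocation", src, i, k, chrom2=dest,
                n_genes=sum(1 for s in moved if s.kind == "gene"),
            )
        )
    # ---- structural variants
    lo, hi = cfg.sv_size_range
    for svtype in SV_TYPES:
        rate = cfg.sv_rates.get(svtype, 0.0)
        for _ in range(rng.poisson(rate)):
            size = int(rng.integers(lo, hi + 1))
            counters.sv += 1
            eid = f"sv{counters.sv:05d}"
            truth.sv_events.append(
                _place_sv(genome, svtype, size, cfg, rng, branch, eid, counters)
            )
    # ---- substitutions
    mu = cfg.substitution_rate * bl
    if mu > 0:
        for segs in genome.chroms.values():
            for s in segs:
                s.seq = mutate_jc(s.seq, mu, rng)


# ---------------------------------------------------------------------------
# promoter helpers


def _find_gene(genome: Genome, key: str):
    for chrom, segs in genome.chroms.items():
        for i, s in enumerate(segs):
            if s.kind == "gene" and (s.family == key or s.gene_id == key):
                return chrom, i
    return None


def promoter_sequence(genome: Genome, gene: str, length: int) -> str:
    """Upstream sequence of a gene (by gene id or family id), coding orientation."""
    loc = _find_gene(genome, gene)
    if loc is None:
        raise GenerationError(f"gene {gene!r} not found in {genome.name}")
    chrom, i = loc
    segs = genome.chroms[chrom]
    seg = segs[i]
    if seg.coding * seg.strand > 0:
        up = "".join(s.seq for s in segs[:i])
        return up[-length:]
    down = "".join(s.seq for s in segs[i + 1 :])
    return revcomp(down[:length])


def _apply_promoter_deletions(genome: Genome, cfg: SimConfig, truth: TruthSet):
    for spec in cfg.promoter_deletion_spec or []:
        genomes, family, length = spec[0], spec[1], int(spec[2])
        offset = int(spec[3]) if len(spec) > 3 else 1000
        if genome.name not in genomes:
            continue
        loc = _find_gene(genome, family)
        if loc is None:
            raise GenerationError(
                f"promoter deletion target {family!r} absent from {genome.name}"
            )
        chrom, i = loc
        segs = genome.chroms[chrom]
        gene = segs[i]
        plus = gene.coding * gene.strand > 0
        _delete_upstream(genome, chrom, i, plus, offset, length, family)
        truth.promoter_indels.append(
            PromoterIndel(genome.name, "", family, length, offset)
        )


def _delete_upstream(genome, chrom, gene_idx, plus, offset, length, family):
    """Remove ``length`` bp starting ``offset`` bp upstream of a gene's 5'
    end (coding orientation), possibly spanning several intergenic
    segments."""
    segs = genome.chroms[chrom]
    upstream = (
        list(range(gene_idx - 1, -1, -1)) if plus
        else list(range(gene_idx + 1, len(segs)))
    )
    total = sum(len(segs[j]) for j in upstream if segs[j].kind == "intergenic")
    if any(segs[j].kind == "gene" for j in upstream[:1]) or total < offset + length + 20:
        raise GenerationError(
            f"promoter of {family!r} too short for a {length}-bp deletion "
            f"at offset {offset}"
        )
    # distance of each upstream segment's gene-proximal edge from the gene
    pieces = []  # (segment index, cut_start, cut_end) in segment seq coords
    dist = 0
    for j in upstream:
        seg = segs[j]
        if seg.kind == "gene":
            break
        lo = max(offset, dist)
        hi = min(offset + length, dist + len(seg))
        if hi > lo:
            if plus:  # distances run right-to-left within the segment
                pieces.append((j, len(seg) - (hi - dist), len(seg) - (lo - dist)))
            else:
                pieces.append((j, lo - dist, hi - dist))
        dist += len(seg)
        if dist >= offset + length:
            break
    removed = sum(e - s for _, s, e in pieces)
    if removed < length:
        raise GenerationError(
            f"promoter of {family!r} too short for a {length}-bp deletion "
            f"at offset {offset}"
        )
    for j, s, e in sorted(pieces, reverse=True):
        seg = segs[j]
        if seg.anc is not None and seg.strand == 1:
            left, mid = _split_segment(seg, s)
            _, right = _split_segment(mid, e - s)
            segs[j : j + 1] = [p for p in (left, right) if len(p)]
        else:
            segs[j] = replace(seg, seq=seg.seq[:s] + seg.seq[e:], anc=None)


def _reserve_promoters(ancestor: Genome, cfg: SimConfig, counters) -> None:
    """Block random SVs from the upstream regions of promoter-deletion
    targets so the planted promoter indel is the only event there."""
    for spec in cfg.promoter_deletion_spec or []:
        family = spec[1]
        length = int(spec[2])
        offset = int(spec[3]) if len(spec) > 3 else 1000
        loc = _find_gene(ancestor, family)
        if loc is None:
            continue
        chrom, i = loc
        segs = ancestor.chroms[chrom]
        gene = segs[i]
        window = offset + length + 600
        g0 = gene.anc[1]
        g1 = gene.anc[2]
        if gene.coding * gene.strand > 0:
            counters.dirty.append((gene.anc[0], max(0, g0 - window), g1))
        else:
            counters.dirty.append((gene.anc[0], g0, g1 + window))


# ---------------------------------------------------------------------------
# top-level simulation


@dataclass
class SimulationResult:
    config: SimConfig
    tree: dendropy.Tree
    ancestor: Genome
    genomes: dict  # leaf name -> Genome
    truth: TruthSet
    paths: dict = field(default_factory=dict)  # name -> {"fasta": ..., "gff3": ...}

    def cds_sequences(self) -> dict:
        return {name: g.cds_sequences() for name, g in self.genomes.items()}

    def gene_orders(self, include_ancestor: bool = False) -> dict:
        out = {name: g.gene_order() for name, g in self.genomes.items()}
        if include_ancestor:
            out["ancestor"] = self.ancestor.gene_order()
        return out

    def genome(self, name: str) -> Genome:
        return self.ancestor if name == "ancestor" else self.genomes[name]


def simulate_clade(config: SimConfig, out_dir=None) -> SimulationResult:
    """Simulate a clade of annotated genomes with a full planted-event record.

    With ``out_dir`` set, writes one FASTA + GFF3 pair per leaf (plus the
    ancestor) and returns their paths in ``result.paths``.  The same seed
    yields byte-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.tree == "random":
        tree = yule_tree(config.n_genomes, config.tree_depth, rng)
    else:
        tree = parse_tree(config.tree)

    ancestor, _fams = _build_ancestor(config, rng)
    counters = _Counters()
    counters.protected = {spec[1] for spec in config.promoter_deletion_spec or []}
    _reserve_promoters(ancestor, config, counters)
    truth = TruthSet(
        hotspot_intervals=[tuple(h) for h in config.hotspot_spec],
        true_tree=tree.as_string(schema="newick").strip(),
        node_ages=node_ages(tree),
    )

    state = {id(tree.seed_node): ancestor}
    genomes = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent = state[id(node.parent_node)]
        g = parent.copy(node.label)
        _apply_branch(g, node.label, node.edge.length, config, rng, truth, counters)
        state[id(node)] = g
        if node.is_leaf():
            genomes[node.label] = g

    for leaf in tree.leaf_node_iter():
        path, node = [], leaf
        while node.parent_node is not None:
            path.append(node.label)
            node = node.parent_node
        truth.leaf_paths[leaf.label] = path[::-1]

    ancestor.assign_gene_ids()
    for name, g in genomes.items():
        _apply_promoter_deletions(g, config, truth)
        g.assign_gene_ids()
        truth.gene_families[name] = {
            s.gene_id: s.family
            for segs in g.chroms.values()
            for s in segs
            if s.kind == "gene"
        }
    # fill emitted gene ids into promoter truth rows
    truth.promoter_indels = [
        replace(
            p,
            gene_id=next(
                (gid for gid, fam in truth.gene_families[p.genome].items() if fam == p.family),
                "",
            ),
        )
        for p in truth.promoter_indels
    ]

    result = SimulationResult(config, tree, ancestor, genomes, truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, g in [("ancestor", ancestor)] + sorted(genomes.items()):
            fa = out / f"{name}.fa"
            gff = out / f"{name}.gff3"
            g.write_fasta(fa)
            g.write_gff3(gff)
            result.paths[name] = {"fasta": str(fa), "gff3": str(gff)}
    return result


# ---------------------------------------------------------------------------
# slim per-locus sequence simulator (phylogeny calibration experiments)


def simulate_sequences(tree, n_loci: int, locus_len: int, rate: float, seed: int):
    """Evolve ``n_loci`` independent loci along a tree under Jukes–Cantor.

    ``tree`` is a Newick string or a dendropy tree.  Returns
    ``(tree, {leaf: [locus sequences]})``.
    """
    if isinstance(tree, str):
        tree = parse_tree(tree)
    rng = np.random.default_rng(seed)
    root_seqs = [random_dna(rng, locus_len) for _ in range(n_loci)]
    state = {id(tree.seed_node): root_seqs}
    out = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        mu = rate * node.edge.length
        seqs = [mutate_jc(s, mu, rng) for s in state[id(node.parent_node)]]
        state[id(node)] = seqs
        if node.is_leaf():
            out[node.label] = seqs
    return tree, out


# ---------------------------------------------------------------------------
# truth fixtures on disk


_TABLES = {
    "family_events": (FamilyEvent, "family_events.tsv"),
    "rearrangement_events": (RearrangementEvent, "rearrangement_events.tsv"),
    "sv_events": (SVEvent, "sv_events.tsv"),
    "promoter_indels": (PromoterIndel, "promoter_indels.tsv"),
}


def _write_table(rows, cls, path):
    fields = [f.name for f in dataclasses.fields(cls)]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(fields)
        for r in rows:
            w.writerow([getattr(r, f) for f in fields])


def _read_table(cls, path):
    out = []
    with open(path, newline="") as fh:
        rd = csv.reader(fh, delimiter="\t")
        header = next(rd)
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for row in rd:
            kw = {}
            for name, val in zip(header, row):
                t = types[name]
                kw[name] = int(val) if t == "int" else val
            out.append(cls(**kw))
    return out


def emit_fixtures(truth: TruthSet, out_dir) -> dict:
    """Write the truth tables as TSV plus a JSON manifest with checksums."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for attr, (cls, fname) in _TABLES.items():
        _write_table(getattr(truth, attr), cls, out / fname)
        files.append(fname)
    with open(out / "hotspot_intervals.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["chrom", "start", "end", "multiplier"])
        for chrom, start, end, mult in truth.hotspot_intervals:
            w.writerow([chrom, start, end, repr(float(mult))])
    files.append("hotspot_intervals.tsv")
    with open(out / "gene_families.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["genome", "gene_id", "family"])
        for genome in sorted(truth.gene_families):
            for gid, fam in sorted(truth.gene_families[genome].items()):
                w.writerow([genome, gid, fam])
    files.append("gene_families.tsv")
    dump_json(
        {
            "true_tree": truth.true_tree,
            "node_ages": truth.node_ages,
            "leaf_paths": truth.leaf_paths,
        },
        out / "tree.json",
    )
    files.append("tree.json")
    manifest = {
        "files": {f: sha256_file(out / f) for f in sorted(files)},
    }
    dump_json(manifest, out / "manifest.json")
    return manifest


def read_fixtures(in_dir) -> TruthSet:
    """Inverse of :func:`emit_fixtures`."""
    d = Path(in_dir)
    truth = TruthSet()
    for attr, (cls, fname) in _TABLES.items():
        setattr(truth, attr, _read_table(cls, d / fname))
    with open(d / "hotspot_intervals.tsv", newline="") as fh:
        rd = csv.reader(fh, delimiter="\t")
        next(rd)
        truth.hotspot_intervals = [
            (c, int(s), int(e), float(m)) for c, s, e, m in rd
        ]
    with open(d / "gene_families.tsv", newline="") as fh:
        rd = csv.reader(fh, delimiter="\t")
        next(rd)
        for genome, gid, fam in rd:
            truth.gene_families.setdefault(genome, {})[gid] = fam
    meta = load_json(d / "tree.json")
    truth.true_tree = meta["true_tree"]
    truth.node_ages = meta["node_ages"]
    truth.leaf_paths = meta["leaf_paths"]
    return truth
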