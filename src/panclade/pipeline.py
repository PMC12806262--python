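"""End-to-end pipeline: simulate -> families -> PAV -> synteny -> ancestor
-> SV -> hotspots -> tree -> promoter scan.

One JSON-able config drives every stage; outputs land in standard text
formats under the output directory and a machine-readable
:class:`PipelineReport` (validated by a bundled JSON Schema) summarises the
run.  Identical config + seed gives byte-identical reports; a cached report
with a matching config checksum is reused unless ``force`` is set.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from pathlib import Path

from pydantic import BaseModel

from . import alignment, ancestor, metrics, pav, phylo, promoter, simulate, sv, synteny
from ._util import dump_json, sha256_bytes, sha256_file
from .exceptions import ConfigurationError

logger = logging.getLogger("panclade")


# ---------------------------------------------------------------------------
# report model


class StageRecord(BaseModel):
    parameters: dict
    outputs: dict  # relative filename -> sha256


class PipelineReport(BaseModel):
    version: int = 1
    seed: int
    config_checksum: str
    stages: dict  # stage name -> StageRecord
    class_counts: dict
    accumulation: list
    genome_dendrogram: str
    n_blocks: int
    n_disordered: int
    marker_count: int
    car_count: int
    rearrangements: list
    sv_counts: list
    hotspots: list
    tree_newick: str
    node_ages: dict
    indel_calls: list
    truth_metrics: dict


def report_schema() -> dict:
    return PipelineReport.model_json_schema()


# ---------------------------------------------------------------------------
# configuration


def demo_config(seed: int = 1) -> dict:
    """A desk-scale clade with every event class planted, including one
    444-bp promoter deletion restricted to one species."""
    # clock-like 8-leaf tree: two cultivated-like species (a1, a2), a wild
    # five-species clade (d1..d5) and an outgroup, as in a diploid cotton
    # panel
    demo_tree = (
        "(out:0.4,((a1:0.06,a2:0.06):0.14,((d1:0.08,d2:0.08):0.06,"
        "(d3:0.1,(d4:0.05,d5:0.05):0.05):0.04):0.06):0.2);"
    )
    return {
        "seed": seed,
        "simulate": {
            "n_genomes": 8,
            "n_chromosomes": 3,
            "genes_per_chromosome": 30,
            "gene_length_bp": 500,
            "intergenic_bp": 3000,
            "tree": demo_tree,
            "tree_depth": 0.4,
            "rate_gene_gain": 8.0,
            "rate_gene_loss": 5.0,
            "rate_inversion": 0.5,
            "rate_fission": 0.1,
            "rate_fusion": 0.05,
            "rate_translocation": 0.1,
            "sv_rates": {
                "insertion": 1.0,
                "deletion": 1.0,
                "tandem_expansion": 1.0,
                "tandem_contraction": 1.0,
                "repeat_expansion": 1.0,
                "repeat_contraction": 1.0,
            },
            "sv_size_range": [50, 600],
            "hotspot_spec": [["chr1", 10000, 60000, 8.0]],
            "substitution_rate": 0.05,
            "promoter_deletion_spec": [[["d4", "d5"], "fam00010", 444, 800]],
        },
        "pav": {"k": 8, "threshold": 0.5, "n_orderings": 100},
        "synteny": {"min_anchors": 5, "max_gap": 25, "pivot": None},
        "sv": {"references": None, "min_size": 50, "max_size": 10000},
        "hotspots": {
            "reference": "ancestor",
            "window_bp": 20000,
            "step_bp": None,
            "n_perm": 300,
            "alpha": 0.05,
        },
        "phylo": {"outgroup": "out", "calibration_node": "root",
                  "calibration_age": 10.13},
        "promoter": {"min_indel": 50, "window_bp": 2000},
    }


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(config) -> dict:
    if config is None:
        cfg = demo_config()
    elif isinstance(config, dict):
        cfg = _merge(demo_config(), config)
    else:
        cfg = _merge(demo_config(), json.loads(Path(config).read_text()))
    return cfg


def _checksum_config(cfg: dict) -> str:
    return sha256_bytes(json.dumps(cfg, sort_keys=True).encode())


# ---------------------------------------------------------------------------
# stage helpers


def _write_pav_matrix(pm: pav.PAVMatrix, path) -> None:
    pm.matrix.to_csv(path, sep="\t", index_label="family")


def _stage(stages, name, params, files):
    stages[name] = StageRecord(
        parameters=params,
        outputs={f.name: sha256_file(f) for f in files},
    )


def inferred_gene_orders(sim_result, families) -> dict:
    """Gene orders labelled with *inferred* family ids (the honest input
    for downstream synteny)."""
    fam_of = {}
    for f in families:
        for genome, gid in f.members:
            fam_of[(genome, gid)] = f.family_id
    orders = {}
    for name, genome in sim_result.genomes.items():
        orders[name] = {
            chrom: [
                (gid, fam_of.get((name, gid), f"orph:{gid}"), strand)
                for gid, _fam, strand in genes
            ]
            for chrom, genes in genome.gene_order().items()
        }
    return orders


def run_pipeline(config=None, out_dir="panclade_out", force: bool = False) -> PipelineReport:
    """Run every stage from one config; returns the validated report."""
    cfg = load_config(config)
    seed = int(cfg["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksum = _checksum_config(cfg)

    report_path = out / "report.json"
    if report_path.exists() and not force:
        try:
            old = PipelineReport.model_validate_json(report_path.read_text())
            if old.config_checksum == checksum:
                logger.info("reusing cached report in %s", out)
                return old
        except ValueError:
            pass

    stages: dict = {}
    t0 = time.time()

    # ---- simulate ------------------------------------------------------
    sim_cfg = simulate.SimConfig(**cfg["simulate"], seed=seed)
    genome_dir = out / "genomes"
    sim = simulate.simulate_clade(sim_cfg, out_dir=genome_dir)
    simulate.emit_fixtures(sim.truth, out / "truth")
    leaves = sorted(sim.genomes)
    _stage(
        stages, "simulate", cfg["simulate"],
        sorted(genome_dir.glob("*.fa")) + sorted(genome_dir.glob("*.gff3")),
    )
    logger.info("simulate: %d genomes (%.1fs)", len(leaves), time.time() - t0)

    # ---- families + PAV ------------------------------------------------
    pcfg = cfg["pav"]
    families = pav.cluster_gene_families(
        sim.cds_sequences(), k=pcfg["k"], threshold=pcfg["threshold"]
    )
    pm = pav.build_pav_matrix(families, leaves)
    class_counts = pav.classify_occupancy(pm)
    acc = pav.accumulation_curves(pm, n_orderings=pcfg["n_orderings"], seed=seed)
    dendrogram = pav.cluster_genomes_by_pav(pm)
    _write_pav_matrix(pm, out / "pav_matrix.tsv")
    acc.to_csv(out / "accumulation.tsv", sep="\t", index=False)
    (out / "genome_dendrogram.nwk").write_text(dendrogram + "\n")
    _stage(stages, "pav", pcfg,
           [out / "pav_matrix.tsv", out / "accumulation.tsv",
            out / "genome_dendrogram.nwk"])

    # ---- synteny -------------------------------------------------------
    scfg = cfg["synteny"]
    orders = inferred_gene_orders(sim, families)
    outgroup = cfg["phylo"]["outgroup"] or leaves[-1]
    pivot = scfg["pivot"] or next(l for l in leaves if l != outgroup)
    n_blocks = n_disordered = 0
    with open(out / "blocks.tsv", "w") as fh:
        fh.write(
            "pivot\tgenome\tblock_id\tchrom_a\tchrom_b\torientation\t"
            "n_anchors\ta_start\ta_end\tdisordered\n"
        )
        for other in leaves:
            if other == pivot:
                continue
            anchors = synteny.find_anchors(families, orders, (pivot, other))
            blocks = synteny.chain_anchors(
                anchors, min_anchors=scfg["min_anchors"], max_gap=scfg["max_gap"]
            )
            synteny.flag_disordered_blocks(blocks)
            for b in blocks:
                n_blocks += 1
                n_disordered += bool(b.disordered)
                fh.write(
                    f"{pivot}\t{other}\t{b.block_id}\t{b.chrom_a}\t{b.chrom_b}\t"
                    f"{b.orientation}\t{len(b)}\t{b.a_span[0]}\t{b.a_span[1]}\t"
                    f"{int(bool(b.disordered))}\n"
                )
    try:
        markers = synteny.build_marker_genomes(orders, pivot, genomes=leaves)
    except Exception as exc:  # degenerate clades: report and continue
        logger.warning("marker construction failed: %s", exc)
        markers = []
    with open(out / "markers.txt", "w") as fh:
        for m in markers:
            for chrom, seq in m.chroms.items():
                fh.write(f"{m.genome_id}\t{chrom}\t" + " ".join(map(str, seq)) + "\n")
    _stage(stages, "synteny", {**scfg, "pivot": pivot},
           [out / "blocks.tsv", out / "markers.txt"])

    # ---- ancestor ------------------------------------------------------
    rearrangements = []
    cars = []
    if markers:
        graph = ancestor.build_adjacency_graph(markers)
        anc = ancestor.infer_median_genome(graph, inputs=markers)
        cars = anc.cars
        for m in markers:
            s = ancestor.count_fission_fusion(anc, m, genome_id=m.genome_id)
            rearrangements.append(
                {"genome": s.genome, "dcj_distance": s.dcj_distance,
                 "fissions": s.fissions, "fusions": s.fusions,
                 "inversions_lower_bound": s.inversions_lower_bound}
            )
    with open(out / "ancestor_cars.txt", "w") as fh:
        for car in cars:
            fh.write(" ".join(map(str, car)) + "\n")
    _stage(stages, "ancestor", {}, [out / "ancestor_cars.txt"])

    # ---- SV calling ----------------------------------------------------
    vcfg = cfg["sv"]
    references = vcfg["references"] or (["ancestor"] + leaves[:2])
    sv_dir = out / "sv"
    sv_dir.mkdir(exist_ok=True)
    tables, summary = sv.multi_reference_catalog(
        references, leaves,
        lambda r, q: alignment.synthetic_alignment(sim, q, r),
        min_size=vcfg["min_size"], max_size=vcfg["max_size"],
    )
    sv_files = []
    for (ref, query), calls in sorted(tables.items()):
        f = sv_dir / f"{ref}_vs_{query}.tsv"
        with open(f, "w") as fh:
            fh.write("ref_chrom\tref_start\tref_end\ttype\tsize\tquery\t"
                     "query_chrom\tquery_start\tquery_end\n")
            for c in calls:
                fh.write(
                    f"{c.ref_chrom}\t{c.ref_start}\t{c.ref_end}\t{c.type}\t"
                    f"{c.size}\t{query}\t{c.query_chrom}\t{c.query_start}\t"
                    f"{c.query_end}\n"
                )
        sv_files.append(f)
    summary.to_csv(out / "sv_summary.tsv", sep="\t", index=False)
    _stage(stages, "sv", {**vcfg, "references": references},
           sv_files + [out / "sv_summary.tsv"])

    # ---- hotspots ------------------------------------------------------
    hcfg = cfg["hotspots"]
    href = hcfg["reference"]
    pooled = [
        c for (ref, _q), calls in tables.items() if ref == href for c in calls
    ]
    regions = sv.detect_hotspots(
        pooled, sim.genome(href).chrom_lengths(),
        window_bp=hcfg["window_bp"], step_bp=hcfg["step_bp"],
        n_perm=hcfg["n_perm"], alpha=hcfg["alpha"], seed=seed,
    )
    sv.annotate_regions(regions, sim.genome(href).genes())
    with open(out / "hotspots.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tsv_count\tp\tq\tgenes\n")
        for r in regions:
            fh.write(
                f"{r.ref_chrom}\t{r.start}\t{r.end}\t{r.sv_count}\t"
                f"{r.empirical_p:.6g}\t{r.bh_q:.6g}\t{','.join(r.genes)}\n"
            )
    with open(out / "hotspots.bed", "w") as fh:
        for r in regions:
            fh.write(f"{r.ref_chrom}\t{r.start}\t{r.end}\thotspot\n")
    _stage(stages, "hotspots", hcfg, [out / "hotspots.tsv", out / "hotspots.bed"])

    # ---- phylogeny -----------------------------------------------------
    fcfg = cfg["phylo"]
    scs = phylo.select_single_copy(families, leaves, cds=sim.cds_sequences())
    dm = phylo.distance_matrix(scs)
    tree = phylo.nj_tree(dm, outgroup)
    calib = phylo.calibrate_ages(
        tree, fcfg["calibration_node"], fcfg["calibration_age"]
    )
    (out / "tree.nwk").write_text(calib.newick() + "\n")
    with open(out / "ages.tsv", "w") as fh:
        fh.write("node\tage\n")
        for lab in sorted(calib.ages):
            fh.write(f"{lab}\t{calib.ages[lab]:.6g}\n")
    _stage(stages, "phylo", {**fcfg, "outgroup": outgroup,
                             "n_single_copy": len(scs.families)},
           [out / "tree.nwk", out / "ages.tsv"])

    # ---- promoter scan -------------------------------------------------
    mcfg = cfg["promoter"]
    indel_rows = []
    for spec in sim_cfg.promoter_deletion_spec or []:
        fam = spec[1]
        targets = set(spec[0])
        ref_leaf = next((l for l in leaves if l not in targets), leaves[0])
        try:
            ref_prom = simulate.promoter_sequence(
                sim.genomes[ref_leaf], fam, mcfg["window_bp"]
            )
            queries = [
                (l, simulate.promoter_sequence(sim.genomes[l], fam, mcfg["window_bp"]))
                for l in leaves
                if l != ref_leaf
            ]
        except Exception as exc:
            logger.warning("promoter scan skipped for %s: %s", fam, exc)
            continue
        calls = promoter.scan_promoter_indels(
            (f"{ref_leaf}:{fam}", ref_prom),
            [(f"{q}:{fam}", s) for q, s in queries if s],
            min_indel=mcfg["min_indel"],
        )
        for c in calls:
            indel_rows.append(
                {"reference": c.ref_id, "query": c.query_id, "type": c.type,
                 "length": c.length, "ref_offset": c.ref_offset,
                 "flank_identity": c.flank_identity}
            )
    with open(out / "promoter_indels.tsv", "w") as fh:
        fh.write("reference\tquery\ttype\tlength\tref_offset\tflank_identity\n")
        for r in indel_rows:
            fh.write(
                f"{r['reference']}\t{r['query']}\t{r['type']}\t{r['length']}\t"
                f"{r['ref_offset']}\t{r['flank_identity']}\n"
            )
    _stage(stages, "promoter", mcfg, [out / "promoter_indels.tsv"])

    # ---- truth comparison ---------------------------------------------
    tmetrics: dict = {}
    tmetrics["family_rand_index"] = pav.family_rand_index(
        families, sim.truth.gene_families
    )
    truth_markers = _truth_markers(sim)
    if truth_markers is not None:
        leaf_m, anc_m = truth_markers
        graph = ancestor.build_adjacency_graph(leaf_m)
        anc_hat = ancestor.infer_median_genome(graph, inputs=leaf_m)
        tmetrics["ancestor_adjacency_recovery"] = metrics.adjacency_recovery(
            anc_hat, anc_m
        )
    ref0 = references[0]
    pooled_expected, pooled_calls = [], []
    promoter_targets = {
        g for spec in (sim_cfg.promoter_deletion_spec or []) for g in spec[0]
    }
    for q in leaves:
        if q == ref0 or q in promoter_targets:
            continue
        pooled_expected.extend(metrics.expected_sv_calls(sim, ref0, q))
        pooled_calls.extend(tables[(ref0, q)])
    rp = metrics.sv_recall_precision(pooled_expected, pooled_calls)
    tmetrics["sv_recall"] = rp["recall"]
    tmetrics["sv_precision"] = rp["precision"]
    if sim_cfg.hotspot_spec and href == "ancestor":
        jac = metrics.hotspot_recovery(regions, sim.truth.hotspot_intervals)
        tmetrics["hotspot_jaccard"] = max(jac) if jac else 0.0
    # evaluate age recovery on the truth's own time scale; calibrate at the
    # ingroup crown (its raw depth does not depend on where the outgroup
    # edge was cut), falling back to the root when the ingroup is not a
    # clade of the true tree
    true_sets = {
        s: lab
        for lab, s in phylo.leaf_sets(simulate.parse_tree(sim.truth.true_tree)).items()
    }
    ingroup = frozenset(l for l in leaves if l != outgroup)
    if ingroup in true_sets and len(ingroup) > 1:
        calib_eval = phylo.calibrate_ages(
            tree, sorted(ingroup), sim.truth.node_ages[true_sets[ingroup]]
        )
    else:
        calib_eval = phylo.calibrate_ages(tree, "root", sim.truth.node_ages["root"])
    errs = metrics.age_errors(calib_eval, sim.truth.true_tree, sim.truth.node_ages)
    if errs:
        rel = sorted(e[3] for e in errs)
        tmetrics["age_median_rel_error"] = rel[len(rel) // 2]

    report = PipelineReport(
        seed=seed,
        config_checksum=checksum,
        stages={k: v.model_dump() for k, v in stages.items()},
        class_counts=class_counts,
        accumulation=[
            {k: (float(v) if k != "k" else int(v)) for k, v in row.items()}
            for row in acc.to_dict(orient="records")
        ],
        genome_dendrogram=dendrogram,
        n_blocks=n_blocks,
        n_disordered=n_disordered,
        marker_count=(
            len({abs(b) for c in markers[0].as_lists() for b in c}) if markers else 0
        ),
        car_count=len(cars),
        rearrangements=rearrangements,
        sv_counts=[
            {"reference": r["reference"], "query": r["query"],
             "type": r["type"], "count": int(r["count"])}
            for r in summary.to_dict(orient="records")
        ],
        hotspots=[
            {"chrom": r.ref_chrom, "start": r.start, "end": r.end,
             "sv_count": r.sv_count, "p": r.empirical_p, "q": r.bh_q,
             "genes": r.genes}
            for r in regions
        ],
        tree_newick=calib.newick(),
        node_ages={k: float(v) for k, v in sorted(calib.ages.items())},
        indel_calls=indel_rows,
        truth_metrics={k: float(v) for k, v in tmetrics.items()},
    )
    report_path.write_text(report.model_dump_json(indent=2) + "\n")
    dump_json(report_schema(), out / "report.schema.json")
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return report


def _truth_markers(sim):
    """Marker genomes over true families (leaves + ancestor); the ancestor's
    representation is returned separately as the evaluation truth."""
    orders = sim.gene_orders(include_ancestor=True)
    names = sorted(sim.genomes)
    try:
        all_m = synteny.build_marker_genomes(
            orders, names[0], genomes=names + ["ancestor"]
        )
    except Exception:
        return None
    anc_m = next(m for m in all_m if m.genome_id == "ancestor")
    leaf_m = [m for m in all_m if m.genome_id != "ancestor"]
    return leaf_m, anc_m
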