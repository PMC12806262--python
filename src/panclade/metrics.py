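"""Truth-comparison metrics for simulated clades.

Everything here scores an analysis result against the simulator's planted
events: family clustering against true families, SV calls against planted
variants (lifted into the reference coordinate system), inferred ancestral
adjacencies against the true ancestor, detected hotspots against planted
hotspot intervals, and calibrated node ages against the generating tree.
"""

from __future__ import annotations

from bisect import bisect_right

from .ancestor import genome_adjacencies
from .sv import MIRROR_TYPE


# ---------------------------------------------------------------------------
# coordinate lifting


def _ref_entries(sim, reference):
    from .alignment import _entries

    by_chrom: dict = {}
    for ent in _entries(sim.genome(reference)):
        by_chrom.setdefault(ent.anc_chrom, []).append(ent)
    for ents in by_chrom.values():
        ents.sort(key=lambda e: (e.a1, e.a2))
    return by_chrom


def lift_position(entries_by_chrom, anc_chrom: str, pos: int):
    """Ancestor position -> (ref chrom, ref pos).

    Prefers the reference segment *ending* exactly at the position (the
    left flank of a reference-side event), then the segment containing it;
    tandem duplicate copies are used only as a last resort."""
    ents = entries_by_chrom.get(anc_chrom, [])
    starts = [e.a1 for e in ents]
    i = bisect_right(starts, pos)
    ending = containing = fallback = None
    for e in reversed(ents[max(0, i - 8) : i]):
        if e.a2 < pos:
            break
        if e.dup is not None:
            if e.a1 <= pos <= e.a2 and fallback is None:
                fallback = e
            continue
        if e.a2 == pos and ending is None:
            ending = e
        elif e.a1 <= pos < e.a2 and containing is None:
            containing = e
    best = ending or containing or fallback
    if best is None:
        return None
    p1, _ = best.project(pos, pos)
    return best.chrom, p1


def expected_sv_calls(sim, reference: str, query: str):
    """Planted events expressed as the calls a query-vs-reference
    comparison should produce: (type, size, ref_chrom, ref_start)."""
    truth = sim.truth
    q_path = set(truth.branches_to(query))
    r_path = set(truth.branches_to(reference))
    entries = _ref_entries(sim, reference)
    out = []
    for ev in truth.sv_events:
        if ev.branch in q_path - r_path:
            typ, pos = ev.type, ev.anc_start
        elif ev.branch in r_path - q_path:
            typ = MIRROR_TYPE[ev.type]
            pos = ev.anc_end if ev.type == "tandem_expansion" else ev.anc_start
        else:
            continue
        lifted = lift_position(entries, ev.anc_chrom, pos)
        if lifted is None:
            continue
        out.append((typ, ev.size, lifted[0], lifted[1]))
    # gene gains and losses are genuine indels a gap caller sees
    for ev in truth.family_events:
        if ev.anc_pos < 0 or ev.kind not in ("gain", "loss"):
            continue
        if ev.branch in q_path - r_path:
            typ = "insertion" if ev.kind == "gain" else "deletion"
        elif ev.branch in r_path - q_path:
            typ = "deletion" if ev.kind == "gain" else "insertion"
        else:
            continue
        lifted = lift_position(entries, ev.anc_chrom, ev.anc_pos)
        if lifted is None:
            continue
        out.append((typ, ev.size, lifted[0], lifted[1]))
    return out


def sv_recall_precision(expected, calls, tol: int = 10, match_type: bool = True):
    """Greedy one-to-one matching of calls to expected events.

    A call matches an expected event when types agree (if ``match_type``),
    sizes agree exactly and the reference start is within ``tol`` bp.
    """
    remaining = list(range(len(calls)))
    matched = 0
    for typ, size, chrom, start in expected:
        hit = None
        for idx in remaining:
            c = calls[idx]
            if match_type and c.type != typ:
                continue
            if c.ref_chrom != chrom or c.size != size:
                continue
            if abs(c.ref_start - start) <= tol:
                hit = idx
                break
        if hit is not None:
            matched += 1
            remaining.remove(hit)
    n_exp, n_calls = len(expected), len(calls)
    return {
        "recall": matched / n_exp if n_exp else float("nan"),
        "precision": matched / n_calls if n_calls else float("nan"),
        "n_expected": n_exp,
        "n_calls": n_calls,
        "matched": matched,
    }


# ---------------------------------------------------------------------------
# ancestor / hotspot / tree metrics


def adjacency_recovery(inferred, true_ancestor) -> float:
    """Fraction of the true ancestor's block adjacencies present in the
    inferred CARs."""
    truth = genome_adjacencies(true_ancestor)
    if not truth:
        return float("nan")
    got = genome_adjacencies(inferred)
    return len(truth & got) / len(truth)


def interval_jaccard(a: tuple, b: tuple) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union else 0.0


def hotspot_recovery(regions, planted_intervals):
    """Best interval Jaccard per planted hotspot interval."""
    out = []
    for chrom, start, end, _mult in planted_intervals:
        best = 0.0
        for r in regions:
            if r.ref_chrom != chrom:
                continue
            best = max(best, interval_jaccard((start, end), (r.start, r.end)))
        out.append(best)
    return out


def age_errors(calibrated, true_tree, true_ages: dict):
    """Relative age errors for internal clades shared with the true tree.

    Clades are matched by descendant leaf sets; the calibration node itself
    (zero error by construction) is included.  Returns a list of
    (clade leaves, true age, estimated age, relative error)."""
    from .phylo import leaf_sets
    from .simulate import parse_tree

    if isinstance(true_tree, str):
        true_tree = parse_tree(true_tree)
    true_sets = {s: lab for lab, s in leaf_sets(true_tree).items() if len(s) > 1}
    est_sets = leaf_sets(calibrated.tree)
    rows = []
    for lab, s in est_sets.items():
        if len(s) < 2 or s not in true_sets:
            continue
        t_age = true_ages[true_sets[s]]
        e_age = calibrated.ages[lab]
        if t_age <= 0:
            continue
        rows.append((sorted(s), t_age, e_age, abs(e_age - t_age) / t_age))
    return rows
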