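"""Taxonomic assignment of query contigs and tree-topology comparison.

Three assignment routes are implemented side by side, mirroring how bulk
mitogenome contigs are placed when no species-level identification exists:

* similarity top hit — the taxonomy of the best-scoring hit below a strict
  E-value cutoff (fast, but inherits database bias and errors);
* minimum-support LCA — an emulation of MEGAN's minimum-coverage heuristic:
  the deepest taxonomy node containing at least a set fraction of the top
  hits' lineages;
* tree topology — the most conservative route: a query is assigned the
  lowest-rank taxon X such that the query descends from the MRCA of X's
  reference tips and every reference tip under that MRCA belongs to X
  (descent + purity formalises "monophyly of the contig with the
  references"; a singleton family can never admit a query, which is why
  small families push assignments up to superfamily or higher).

Tree comparison uses the Robinson–Foulds symmetric difference over
non-trivial bipartitions, with the theoretical maximum 2(n-3) for two fully
resolved unrooted trees on n shared tips.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

from .records import HitRecord, Taxonomy

#: Rank ladder used for assignment, lowest to highest.
RANK_LADDER = ("species", "genus", "subfamily", "family", "superfamily",
               "infraorder", "suborder", "order")


@dataclass
class AssignmentRecord:
    query_id: str
    method: str                 # "tophit" | "lca" | "tree"
    rank: str | None
    taxon: str | None
    evaluable: bool = True
    correct: bool | None = None


# -------------------------------------------------------- hit-based


def _ranked_hits(hits: list[HitRecord], max_evalue: float) -> list[HitRecord]:
    keep = [h for h in hits if h.evalue <= max_evalue]
    keep.sort(key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
    return keep


def tophit_assign(hits: list[HitRecord], taxonomy: Taxonomy,
                  rank: str = "family",
                  max_evalue: float = 1e-19) -> dict[str, AssignmentRecord]:
    """Best-hit assignment at a fixed rank, one record per query.

    Hits above ``max_evalue`` are discarded; the top hit is chosen by
    bitscore, then lower E-value, then lexicographic subject id. Subjects
    missing from the taxonomy yield evaluable=False records.
    """
    by_query: dict[str, list[HitRecord]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    out: dict[str, AssignmentRecord] = {}
    for q, qhits in by_query.items():
        ranked = _ranked_hits(qhits, max_evalue)
        if not ranked:
            out[q] = AssignmentRecord(q, "tophit", None, None)
            continue
        top = ranked[0]
        if top.subject_id not in taxonomy:
            out[q] = AssignmentRecord(q, "tophit", None, None, evaluable=False)
            continue
        taxon = taxonomy.taxon(top.subject_id, rank)
        out[q] = AssignmentRecord(q, "tophit", rank if taxon else None, taxon)
    return out


def lca_assign(hits: list[HitRecord], taxonomy: Taxonomy, top_n: int = 100,
               min_support: float = 0.5,
               max_evalue: float = 1e-19) -> dict[str, AssignmentRecord]:
    """Minimum-support LCA over the top ``top_n`` hits per query.

    Walks the rank ladder from the lowest rank up and assigns the first
    taxon contained in at least ``min_support`` of the hit lineages — the
    deepest taxonomy node reaching the support threshold.
    """
    by_query: dict[str, list[HitRecord]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    out: dict[str, AssignmentRecord] = {}
    for q, qhits in by_query.items():
        ranked = _ranked_hits(qhits, max_evalue)[:top_n]
        lineages = [taxonomy.lineages[h.subject_id] for h in ranked
                    if h.subject_id in taxonomy]
        if not lineages:
            out[q] = AssignmentRecord(q, "lca", None, None,
                                      evaluable=bool(ranked) is False)
            continue
        n = len(lineages)
        assigned = None
        for rank in RANK_LADDER:
            counts: dict[str, int] = {}
            for lin in lineages:
                t = lin.get(rank)
                if t:
                    counts[t] = counts.get(t, 0) + 1
            if not counts:
                continue
            taxon = min(counts, key=lambda t: (-counts[t], t))
            if counts[taxon] >= min_support * n:
                assigned = (rank, taxon)
                break
        if assigned:
            out[q] = AssignmentRecord(q, "lca", assigned[0], assigned[1])
        else:
            out[q] = AssignmentRecord(q, "lca", None, None)
    return out


# ------------------------------------------------------------- trees


def tip_labels(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


def _leafsets(tree: dendropy.Tree) -> dict:
    """Node -> frozenset of descendant tip labels (postorder, one pass)."""
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            acc: set[str] = set()
            for ch in node.child_nodes():
                acc |= below[ch]
            below[node] = frozenset(acc)
    return below


def splits(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as canonical frozensets of tip labels.

    Each split is represented by the side not containing the overall
    smallest tip label, so rooted and unrooted encodings of the same
    topology produce identical sets.
    """
    below = _leafsets(tree)
    all_tips = frozenset(tip_labels(tree))
    anchor = min(all_tips)
    out: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = below[node]
        if anchor in side:
            side = all_tips - side
        if 2 <= len(side) <= len(all_tips) - 2:
            out.add(side)
    return out


def rf_distance(tree1: dendropy.Tree, tree2: dendropy.Tree) -> tuple[int, int]:
    """(symmetric difference, theoretical maximum 2(n-3)).

    Tip sets must be identical — prune to the shared set first. The maximum
    is reported for fully resolved unrooted trees regardless of resolution:
    unresolved trees simply contribute fewer splits.
    """
    t1, t2 = tip_labels(tree1), tip_labels(tree2)
    if t1 != t2:
        raise ValueError(
            f"tip sets differ ({len(t1 - t2)} only in tree1, "
            f"{len(t2 - t1)} only in tree2): prune to shared tips first")
    n = len(t1)
    if n < 4:
        raise ValueError("tree comparison requires >= 4 shared tips")
    s1, s2 = splits(tree1), splits(tree2)
    return len(s1 ^ s2), 2 * (n - 3)


def prune_to_shared(tree1: dendropy.Tree, tree2: dendropy.Tree
                    ) -> tuple[dendropy.Tree, dendropy.Tree]:
    """Clone both trees pruned to their shared tips (degree-2 suppressed)."""
    shared = tip_labels(tree1) & tip_labels(tree2)
    if len(shared) < 4:
        raise ValueError("fewer than 4 shared tips")
    out = []
    for t in (tree1, tree2):
        c = t.clone(depth=1)
        c.retain_taxa_with_labels(sorted(shared))
        out.append(c)
    return out[0], out[1]


def root_on(tree: dendropy.Tree, outgroup: set[str] | list[str]) -> dendropy.Tree:
    """Root on the edge separating the outgroup tips from the rest.

    The outgroup must form one side of some edge of the unrooted topology;
    otherwise the offending tips are reported.
    """
    og = frozenset(outgroup)
    tips = tip_labels(tree)
    missing = og - tips
    if missing:
        raise ValueError(f"outgroup tips absent from tree: {sorted(missing)}")
    t = tree.clone(depth=1)
    below = _leafsets(t)
    target = None
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            continue
        if below[node] == og or below[node] == frozenset(tips) - og:
            target = node
            break
    if target is None:
        raise ValueError(
            f"outgroup is not monophyletic in the unrooted tree: {sorted(og)}")
    edge = target.edge
    if edge.length:
        t.reroot_at_edge(edge, length1=edge.length / 2, length2=edge.length / 2,
                         update_bipartitions=False)
    else:
        t.reroot_at_edge(edge, update_bipartitions=False)
    t.is_rooted = True
    return t


def tree_assign(tree: dendropy.Tree, taxonomy: Taxonomy, query_tips: list[str],
                ranks: tuple[str, ...] = RANK_LADDER
                ) -> dict[str, AssignmentRecord]:
    """Monophyly-constrained placement of query tips on a rooted tree.

    For each rank from lowest to highest and each taxon X at that rank, a
    query is assignable to X iff it descends from the MRCA of X's reference
    tips and every reference tip under that MRCA belongs to X. The lowest
    assignable rank wins; queries assignable nowhere are unassigned.
    """
    if not tree.is_rooted:
        raise ValueError("tree_assign requires a rooted tree (root_on first)")
    below = _leafsets(tree)
    tips = tip_labels(tree)
    ref_tips = {t for t in tips if t in taxonomy}
    queries = [q for q in query_tips if q in tips]
    node_of = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}

    # MRCA leafset per (rank, taxon)
    mrca_set: dict[tuple[str, str], frozenset] = {}
    for rank in ranks:
        groups: dict[str, set[str]] = {}
        for r in ref_tips:
            taxon = taxonomy.taxon(r, rank)
            if taxon:
                groups.setdefault(taxon, set()).add(r)
        for taxon, members in groups.items():
            node = node_of[next(iter(members))]
            while node is not None and not below[node] >= members:
                node = node.parent_node
            if node is not None:
                mrca_set[(rank, taxon)] = below[node]

    out: dict[str, AssignmentRecord] = {}
    for q in sorted(queries):
        assigned = None
        for rank in ranks:
            for (r, taxon), leafset in sorted(mrca_set.items()):
                if r != rank or q not in leafset:
                    continue
                under = leafset & ref_tips
                if under and all(taxonomy.taxon(t, rank) == taxon for t in under):
                    assigned = (rank, taxon)
                    break
            if assigned:
                break
        if assigned:
            out[q] = AssignmentRecord(q, "tree", assigned[0], assigned[1])
        else:
            out[q] = AssignmentRecord(q, "tree", None, None)
    return out


# --------------------------------------------------------- evaluation


def evaluate_assignments(records: list[AssignmentRecord],
                         truth: Taxonomy) -> dict:
    """Rank-by-method tally and per-method family-level success rate.

    Each query counts at the lowest rank it was assigned; correctness is
    scored at that rank against the truth lineage. Family success is the
    fraction of evaluable queries assigned the correct family, to 1 decimal.
    """
    by_method: dict[str, dict[str, dict[str, int]]] = {}
    family_ok: dict[str, int] = {}
    evaluable: dict[str, int] = {}
    for rec in records:
        m = by_method.setdefault(rec.method, {})
        evaluable[rec.method] = evaluable.get(rec.method, 0) + (1 if rec.evaluable else 0)
        if rec.rank is None:
            m.setdefault("unassigned", {"count": 0, "incorrect": 0})["count"] += 1
            continue
        truth_taxon = truth.taxon(rec.query_id, rec.rank) \
            if rec.query_id in truth else None
        correct = (truth_taxon == rec.taxon) if truth_taxon is not None else None
        rec.correct = correct
        slot = m.setdefault(rec.rank, {"count": 0, "incorrect": 0})
        slot["count"] += 1
        if correct is False:
            slot["incorrect"] += 1
        if rec.rank == "family" and correct:
            family_ok[rec.method] = family_ok.get(rec.method, 0) + 1
    success = {}
    for method, n in evaluable.items():
        success[method] = round(100.0 * family_ok.get(method, 0) / n, 1) if n else 0.0
    return {"by_method": by_method, "family_success_pct": success,
            "evaluable": evaluable}


def family_success_pct(correct_family: int, evaluable: int) -> float:
    """Success rate as printed: correct family assignments / evaluable, 1 dp."""
    return round(100.0 * correct_family / evaluable, 1)
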