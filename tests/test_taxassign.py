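"""Taxonomic assignment routes and Robinson–Foulds comparison."""

import itertools
import random

import dendropy
import pytest

from mitosoup.records import HitRecord, Taxonomy
from mitosoup.seqio import read_newick
from mitosoup.taxassign import (AssignmentRecord, RANK_LADDER,
                                evaluate_assignments, lca_assign,
                                prune_to_shared, rf_distance, root_on, splits,
                                tophit_assign, tree_assign)


def _hit(q, s, bitscore=500.0, evalue=1e-30):
    return HitRecord(q, s, 99.0, 500, 0, 0, 1, 500, 1, 500, evalue, bitscore)


TAX = Taxonomy({
    "r1": {"family": "Chrysomelidae", "superfamily": "Chrysomeloidea"},
    "r2": {"family": "Chrysomelidae", "superfamily": "Chrysomeloidea"},
    "r3": {"family": "Cerambycidae", "superfamily": "Chrysomeloidea"},
    "r4": {"family": "Carabidae", "superfamily": "Caraboidea"},
})


def test_tophit_basic_and_threshold():
    out = tophit_assign([_hit("q1", "r1")], TAX)
    assert (out["q1"].rank, out["q1"].taxon) == ("family", "Chrysomelidae")
    out = tophit_assign([_hit("q2", "r1", evalue=1e-10)], TAX)
    assert out["q2"].taxon is None                # above the E-value cutoff
    out = tophit_assign([_hit("q3", "unknown")], TAX)
    assert out["q3"].evaluable is False


def test_tophit_tie_break_matches_sort_oracle():
    hits = [_hit("q", "r3", bitscore=500.0, evalue=1e-30),
            _hit("q", "r1", bitscore=500.0, evalue=1e-30),
            _hit("q", "r2", bitscore=500.0, evalue=1e-40)]
    out = tophit_assign(hits, TAX)
    oracle = sorted(hits, key=lambda h: (-h.bitscore, h.evalue, h.subject_id))[0]
    assert out["q"].taxon == TAX.taxon(oracle.subject_id, "family")
    assert oracle.subject_id == "r2"              # lower E wins the tie


def test_lca_unanimous_family():
    hits = [_hit("q", "r1"), _hit("q", "r2")]
    out = lca_assign(hits, TAX)
    assert (out["q"].rank, out["q"].taxon) == ("family", "Chrysomelidae")


def test_lca_split_support_escalates_rank():
    hits = [_hit("q", "r1"), _hit("q", "r3")]     # 50/50 two families
    out = lca_assign(hits, TAX, min_support=0.6)
    assert (out["q"].rank, out["q"].taxon) == ("superfamily", "Chrysomeloidea")


def test_lca_matches_exhaustive_node_oracle():
    rng = random.Random(13)
    fams = [("F%d" % i, "S%d" % (i // 2), "I%d" % (i // 4)) for i in range(8)]
    refs = {}
    for i in range(40):
        f, s, o = fams[rng.randrange(8)]
        refs[f"ref{i:02d}"] = {"family": f, "superfamily": s, "infraorder": o}
    tax = Taxonomy(refs)
    for trial in range(60):
        subjects = rng.sample(sorted(refs), rng.randint(1, 12))
        hits = [_hit("q", s, bitscore=400 + i) for i, s in enumerate(subjects)]
        min_support = rng.choice([0.5, 0.6, 0.8])
        got = lca_assign(hits, tax, min_support=min_support)["q"]

        # oracle: evaluate every (rank, taxon) node exhaustively
        lineages = [refs[s] for s in subjects]
        expected = None
        for rank in RANK_LADDER:
            cands = {}
            for lin in lineages:
                t = lin.get(rank)
                if t:
                    cands[t] = cands.get(t, 0) + 1
            ok = sorted([t for t, n in cands.items()
                         if n >= min_support * len(lineages)],
                        key=lambda t: (-cands[t], t))
            if ok:
                expected = (rank, ok[0])
                break
        assert (got.rank, got.taxon) == (expected or (None, None))


def test_root_on_single_tip():
    t = read_newick("(A:1,B:1,(C:1,D:1):1);")
    r = root_on(t, {"A"})
    kids = r.seed_node.child_nodes()
    labels = [k.taxon.label if k.is_leaf() else None for k in kids]
    assert "A" in labels
    with pytest.raises(ValueError, match="not monophyletic"):
        root_on(t, {"A", "C"})
    with pytest.raises(ValueError, match="absent"):
        root_on(t, {"Z"})


def test_prune_to_shared_keeps_split_structure():
    t1 = read_newick("(A,(B,(C,(D,E))));")
    t2 = read_newick("(A,(B,(C,(D,(E,X)))));")
    p1, p2 = prune_to_shared(t1, t2)
    d, mx = rf_distance(p1, p2)
    assert d == 0 and mx == 2 * (5 - 3)
    same1, same2 = prune_to_shared(t1, t1)
    assert rf_distance(same1, same2)[0] == 0


def test_rf_identical_and_max():
    t1 = read_newick("(A,(B,C),(D,E));")
    assert rf_distance(t1, read_newick("((C,B),A,(E,D));"))[0] == 0
    with pytest.raises(ValueError, match="prune"):
        rf_distance(t1, read_newick("(A,(B,C),(D,X));"))


def _five_tip_topologies():
    """All 15 unrooted binary topologies on 5 labels as newick strings."""
    labels = ["A", "B", "C", "D", "E"]
    seen = set()
    out = []
    for pair1 in itertools.combinations(labels, 2):
        rest = [x for x in labels if x not in pair1]
        for pair2 in itertools.combinations(rest, 2):
            mid = [x for x in rest if x not in pair2][0]
            key = frozenset([frozenset(pair1), frozenset(pair2)])
            if key in seen:
                continue
            seen.add(key)
            out.append(f"(({pair1[0]},{pair1[1]}),({pair2[0]},{pair2[1]}),{mid});")
    assert len(out) == 15
    return out


def test_rf_matches_dendropy_on_all_5_tip_pairs():
    topos = _five_tip_topologies()
    tns = dendropy.TaxonNamespace()
    dtrees = [dendropy.Tree.get(data=s, schema="newick", taxon_namespace=tns)
              for s in topos]
    for t in dtrees:
        t.encode_bipartitions()
    from dendropy.calculate import treecompare
    for i in range(15):
        for j in range(15):
            mine, mx = rf_distance(read_newick(topos[i]), read_newick(topos[j]))
            oracle = treecompare.symmetric_difference(dtrees[i], dtrees[j])
            assert mine == oracle
            assert mx == 4
            assert mine % 2 == 0 and mine <= mx


def test_rf_metric_properties_on_random_8_tip_trees():
    rng = random.Random(17)
    labels = [f"t{i}" for i in range(8)]

    def rand_tree():
        tns = dendropy.TaxonNamespace(labels)
        return dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, taxon_namespace=tns,
            num_extant_tips=8, rng=rng)

    trees = [rand_tree() for _ in range(12)]
    from dendropy.calculate import treecompare
    tns = dendropy.TaxonNamespace(labels)
    for a, b in itertools.combinations(range(12), 2):
        d_ab, mx = rf_distance(trees[a], trees[b])
        d_ba, _ = rf_distance(trees[b], trees[a])
        assert d_ab == d_ba                        # symmetry
        assert 0 <= d_ab <= mx == 10
        da = dendropy.Tree.get(data=trees[a].as_string(schema="newick"),
                               schema="newick", taxon_namespace=tns)
        db = dendropy.Tree.get(data=trees[b].as_string(schema="newick"),
                               schema="newick", taxon_namespace=tns)
        for t in (da, db):
            t.is_rooted = False
            t.collapse_basal_bifurcation()
            t.encode_bipartitions()
        assert d_ab == treecompare.symmetric_difference(da, db)
    for a, b, c in itertools.combinations(range(8), 3):
        dab = rf_distance(trees[a], trees[b])[0]
        dbc = rf_distance(trees[b], trees[c])[0]
        dac = rf_distance(trees[a], trees[c])[0]
        assert dac <= dab + dbc                    # triangle inequality


def test_tree_assign_scenarios():
    tax = Taxonomy({
        "f1a": {"family": "F1", "superfamily": "S1"},
        "f1b": {"family": "F1", "superfamily": "S1"},
        "f2a": {"family": "F2", "superfamily": "S1"},
        "og": {"family": "FO", "superfamily": "SO"},
    })
    t = read_newick("(og,(((f1a,qin):1,f1b):1,(f2a,qsis):1):1);")
    rooted = root_on(t, {"og"})
    out = tree_assign(rooted, tax, ["qin", "qsis"])
    # nested inside the F1 clade -> family
    assert (out["qin"].rank, out["qin"].taxon) == ("family", "F1")
    # sister to a singleton family reference: cannot descend from a tip's
    # MRCA -> escalates to superfamily, never the wrong family
    assert (out["qsis"].rank, out["qsis"].taxon) == ("superfamily", "S1")
    with pytest.raises(ValueError, match="rooted"):
        tree_assign(read_newick("(a,b,(c,d));"), tax, ["a"])


def test_tree_assign_never_wrong_family_and_refinement():
    """Grafting queries inside family clades gives that family; adding more
    reference taxa can only keep or lower the assigned rank."""
    tax_small = Taxonomy({
        "f1a": {"family": "F1", "superfamily": "S1"},
        "f2a": {"family": "F2", "superfamily": "S1"},
        "og": {"family": "FO", "superfamily": "SO"},
    })
    tax_big = Taxonomy(dict(tax_small.lineages, **{
        "f1b": {"family": "F1", "superfamily": "S1"}}))
    t = read_newick("(og,((f1a,(q1,f1b)),f2a));")
    rooted = root_on(t, {"og"})
    small = tree_assign(rooted, tax_small, ["q1"])["q1"]
    big = tree_assign(rooted, tax_big, ["q1"])["q1"]
    assert big.taxon == "F1" and big.rank == "family"
    order = {r: i for i, r in enumerate(RANK_LADDER)}
    assert small.rank is None or order[big.rank] <= order[small.rank]


def test_evaluate_published_table_arithmetic():
    records = []
    truth = {}
    # tophit: 77 correct + 18 incorrect at family, 1 elsewhere = 96
    for i in range(77):
        records.append(AssignmentRecord(f"t{i}", "tophit", "family", "GOOD"))
        truth[f"t{i}"] = {"family": "GOOD"}
    for i in range(77, 95):
        records.append(AssignmentRecord(f"t{i}", "tophit", "family", "BAD"))
        truth[f"t{i}"] = {"family": "GOOD"}
    records.append(AssignmentRecord("t95", "tophit", "suborder", "X"))
    truth["t95"] = {"family": "GOOD", "suborder": "X"}
    # tree route: 72 correct at family of 96
    for i in range(72):
        records.append(AssignmentRecord(f"m{i}", "tree", "family", "GOOD"))
        truth[f"m{i}"] = {"family": "GOOD"}
    for i in range(72, 96):
        records.append(AssignmentRecord(f"m{i}", "tree", "superfamily", "S"))
        truth[f"m{i}"] = {"family": "GOOD", "superfamily": "S"}
    # lca route: 53 correct at family of 96
    for i in range(53):
        records.append(AssignmentRecord(f"l{i}", "lca", "family", "GOOD"))
        truth[f"l{i}"] = {"family": "GOOD"}
    for i in range(53, 66):
        records.append(AssignmentRecord(f"l{i}", "lca", "family", "BAD"))
        truth[f"l{i}"] = {"family": "GOOD"}
    for i in range(66, 96):
        records.append(AssignmentRecord(f"l{i}", "lca", "order", "O"))
        truth[f"l{i}"] = {"family": "GOOD", "order": "O"}
    out = evaluate_assignments(records, Taxonomy(truth))
    assert out["family_success_pct"]["tophit"] == 80.2
    assert out["family_success_pct"]["tree"] == 75.0
    assert out["family_success_pct"]["lca"] == 55.2
    assert out["by_method"]["tophit"]["family"] == {"count": 95, "incorrect": 18}


def test_evaluate_all_correct_is_100():
    records = [AssignmentRecord(f"q{i}", "tree", "family", "F") for i in range(5)]
    truth = Taxonomy({f"q{i}": {"family": "F"} for i in range(5)})
    out = evaluate_assignments(records, truth)
    assert out["family_success_pct"]["tree"] == 100.0
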