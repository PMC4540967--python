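"""Contig filtering, circularization, reconciliation and statistics."""

import random

import pytest

from mitosoup.align import align_pair
from mitosoup.contigs import (MergePolicy, assembly_stats, detect_circular,
                              filter_mito_contigs, merge_assemblies)
from mitosoup.records import Contig, HitRecord


def _hit(qid, aln_len, evalue=1e-20):
    return HitRecord(qid, "ref", 99.0, aln_len, 0, 0, 1, aln_len, 1, aln_len,
                     evalue, 500.0)


def test_filter_1kb_boundary():
    contigs = [Contig("a", "A" * 2000), Contig("b", "A" * 2000),
               Contig("c", "A" * 2000)]
    hits = [_hit("a", 1000), _hit("b", 999), _hit("c", 1500, evalue=1e-4)]
    kept = filter_mito_contigs(contigs, hits)
    assert [c.id for c in kept] == ["a"]
    assert filter_mito_contigs(contigs, []) == []


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def test_circularize_exact_terminal_repeat():
    rng = random.Random(0)
    core = _random_seq(rng, 15900)
    out = detect_circular(Contig("c", core + core[:100]))
    assert out.circular
    assert len(out.seq) == 15900
    # rotation-equivalent to the core (doubled-string membership)
    assert out.seq in core + core


def test_short_contig_unchanged_below_15kb():
    rng = random.Random(1)
    core = _random_seq(rng, 11900)
    out = detect_circular(Contig("c", core + core[:100]))
    assert not out.circular
    assert len(out.seq) == 12000


def test_circularize_with_mismatch_in_overlap():
    """Random cut, 80-bp duplicated terminus carrying one mismatch."""
    rng = random.Random(2)
    truth = _random_seq(rng, 15800)
    cut = rng.randrange(len(truth))
    rot = truth[cut:] + truth[:cut]
    dup = list(rot[:80])
    dup[40] = "A" if dup[40] != "A" else "C"
    out = detect_circular(Contig("c", rot + "".join(dup)), min_identity=98.0)
    assert out.circular
    assert len(out.seq) == len(truth)
    assert out.seq in rot + rot                   # rotation-equivalent


def test_circularize_rotation_invariant():
    rng = random.Random(3)
    core = _random_seq(rng, 15500)
    outs = set()
    for k in (0, 1234, 9999):
        rot = core[k:] + core[:k]
        res = detect_circular(Contig("c", rot + rot[:90]))
        assert res.circular
        outs.add(res.seq)
    assert len(outs) == 1                         # canonical rotation


def test_merge_identical_contig_in_both_sets():
    rng = random.Random(4)
    seq = _random_seq(rng, 4000)
    sets = {"A": [Contig("a1", seq, source="A")],
            "B": [Contig("b1", seq, source="B")]}
    merged, rep = merge_assemblies(sets, MergePolicy(source_preference=("B", "A")))
    assert len(merged) == 1
    assert sorted(merged[0].provenance) == ["a1", "b1"]


def test_merge_two_fragments_against_truth():
    rng = random.Random(5)
    truth = _random_seq(rng, 12000)
    frag5 = truth[:7000]
    frag3 = list(truth[6000:])                    # 1 kb overlap
    muts = 0
    for p in rng.sample(range(1000), 5):          # 99.5% overlap identity
        frag3[p] = "A" if frag3[p] != "A" else "G"
        muts += 1
    sets = {"A": [Contig("five", frag5, source="A")],
            "B": [Contig("three", "".join(frag3), source="B")]}
    merged, rep = merge_assemblies(sets, MergePolicy(source_preference=("A", "B")))
    assert len(merged) == 1
    consensus = merged[0].seq
    assert len(consensus) == len(truth)
    diffs = sum(1 for x, y in zip(consensus, truth) if x != y)
    assert diffs == 0                             # preferred source wins SNPs
    assert len(rep.arbitrations) == muts


def test_merge_indel_arbitration_prefers_intact_orf(small_community):
    sp = small_community.species[0]
    genome = sp.genome.seq
    pcg = next(f for f in sp.features if f.gene == "cox1")
    pos = (pcg.start + pcg.end) // 2
    with_ins = genome[:pos] + "A" + genome[pos:]  # 1-bp insertion inside PCG
    sets = {"A": [Contig("broken", with_ins, source="A")],
            "B": [Contig("clean", genome, source="B")]}
    # source preference favours the broken one: ORF arbitration must override
    merged, rep = merge_assemblies(sets, MergePolicy(source_preference=("A", "B")))
    assert len(merged) == 1
    assert merged[0].seq == genome
    assert any("indel" in n for n in rep.arbitrations)


def test_merge_is_fixed_point(small_variants):
    from mitosoup.contigs import detect_circular as dc
    sets = {lab: [dc(c) for c in cs] for lab, cs in small_variants.sets.items()}
    merged, _ = merge_assemblies(sets, MergePolicy(source_preference=("asmB", "asmA")))
    again, _ = merge_assemblies({"nr": merged},
                                MergePolicy(source_preference=("nr",)))
    assert sorted(c.seq for c in again) == sorted(c.seq for c in merged)


def test_merge_provenance_conservation(small_variants):
    from mitosoup.contigs import detect_circular as dc
    sets = {lab: [dc(c) for c in cs] for lab, cs in small_variants.sets.items()}
    merged, rep = merge_assemblies(sets, MergePolicy(source_preference=("asmB", "asmA")))
    n_inputs = sum(len(cs) for cs in sets.values())
    n_dropped = len(rep.dropped_linear)
    n_prov = sum(len(c.provenance) for c in merged)
    assert n_prov == n_inputs - n_dropped


def test_merge_output_aligns_to_members(small_variants):
    from mitosoup.contigs import detect_circular as dc
    sets = {lab: [dc(c) for c in cs] for lab, cs in small_variants.sets.items()}
    by_id = {c.id: c for cs in sets.values() for c in cs}
    merged, _ = merge_assemblies(sets, MergePolicy(source_preference=("asmB", "asmA")))
    for c in merged:
        for member_id in c.provenance:
            m = by_id[member_id]
            target = c.seq + c.seq if c.circular else c.seq
            aln = align_pair(m.seq, target, "semiglobal")
            assert aln.identity >= 98.0
            assert aln.aln_len >= 0.95 * len(m.seq)


def test_assembly_stats_examples():
    s = assembly_stats([Contig("a", "A" * 5000)])
    assert (s["n50"], s["mean"]) == (5000, 5000.0)
    assert s["size_classes"]["5000-10000"] == (1, 0)
    s = assembly_stats([Contig("a", "A" * 2000), Contig("b", "A" * 3000),
                        Contig("c", "A" * 5000)])
    assert s["n50"] == 5000
    empty = assembly_stats([])
    assert empty["count"] == 0 and empty["n50"] == 0


def test_n50_against_brute_force_oracle():
    rng = random.Random(7)
    for _ in range(300):
        lengths = [rng.randint(1, 20000) for _ in range(rng.randint(1, 40))]
        contigs = [Contig(f"c{i}", "A" * L) for i, L in enumerate(lengths)]
        got = assembly_stats(contigs)
        total = sum(lengths)
        # oracle: largest L with sum of lengths >= L reaching half the total
        n50 = max(L for L in lengths
                  if sum(x for x in lengths if x >= L) >= total / 2)
        assert got["n50"] == n50
        assert got["total_length"] == total
        tally = sum(v[0] for v in got["size_classes"].values())
        assert tally == sum(1 for L in lengths if L >= 1000)


def test_size_class_tally_shape():
    contigs = [Contig(f"c{i}", "A" * 16000, circular=(i < 7))
               for i in range(10)]
    s = assembly_stats(contigs)
    assert s["size_classes"]["15000-inf"] == (10, 7)
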