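"""Gene extraction, translation, curation and supermatrix construction."""

import random

import pytest

from mitosoup.genes import (ReferenceGenes, back_translate, bin_fragments,
                            build_supermatrix, curate_alignment,
                            fragment_by_trna, star_align, translate_mito)
from mitosoup.records import Contig, Feature
from mitosoup.simulate import make_reference_genome


def test_fragment_intervals_between_trnas():
    seq = "A" * 1000
    feats = [Feature("tRNA", "trnI", 100, 170, "+"),
             Feature("tRNA", "trnQ", 500, 570, "+")]
    frags = fragment_by_trna(Contig("c", seq), feats)
    assert [(s, e) for s, e, _ in frags] == [(0, 100), (170, 500), (570, 1000)]


def test_fragment_no_trnas_gives_whole_contig():
    frags = fragment_by_trna(Contig("c", "A" * 500), [])
    assert [(s, e) for s, e, _ in frags] == [(0, 500)]


def test_fragment_wraps_origin_on_circular():
    contig = Contig("c", "ACGT" * 250, circular=True)
    feats = [Feature("tRNA", "trnI", 100, 170, "+"),
             Feature("tRNA", "trnQ", 800, 870, "+")]
    frags = fragment_by_trna(contig, feats)
    wrapped = [f for f in frags if f[1] < f[0]]
    assert len(wrapped) == 1
    s, e, seq = wrapped[0]
    assert (s, e) == (870, 100)
    assert seq == contig.seq[870:] + contig.seq[:100]


def test_overlapping_trnas_unioned():
    feats = [Feature("tRNA", "trnI", 100, 180, "+"),
             Feature("tRNA", "trnQ", 150, 240, "+")]
    frags = fragment_by_trna(Contig("c", "A" * 400), feats)
    assert [(s, e) for s, e, _ in frags] == [(0, 100), (240, 400)]


@pytest.fixture(scope="module")
def ref_genome():
    contig, feats = make_reference_genome(42)
    return contig, feats, ReferenceGenes.from_annotated(contig, feats)


def test_bin_full_gene_identity(ref_genome):
    contig, feats, ref = ref_genome
    out = bin_fragments([("c", ref.nt["cox2"])], ref)
    assert len(out) == 1
    gf = out[0]
    assert (gf.gene, gf.frame) == ("cox2", 0)
    assert gf.ref_coverage == pytest.approx(1.0, abs=0.02)


def test_bin_50pct_coverage_boundary(ref_genome):
    contig, feats, ref = ref_genome
    nt = ref.nt["cox2"]
    aa_len = len(ref.aa["cox2"])
    half_aa = aa_len // 2 + (aa_len % 2)
    at_half = nt[:3 * half_aa]                    # covers exactly >= 50%
    below = nt[:3 * (half_aa - 4)]                # clearly below 50%
    got_half = bin_fragments([("c", at_half)], ref)
    assert got_half[0].gene == "cox2"
    assert got_half[0].ref_coverage >= 0.5
    got_below = bin_fragments([("c", below)], ref)
    assert got_below[0].gene == "unassigned"


def test_bin_shuffled_fragment_unassigned(ref_genome):
    contig, feats, ref = ref_genome
    rng = random.Random(2)
    frag = list(ref.nt["cox1"])
    rng.shuffle(frag)
    out = bin_fragments([("c", "".join(frag))], ref)
    assert all(g.gene == "unassigned" for g in out)


def test_bin_multi_gene_fragment(ref_genome):
    """A fragment spanning atp8+atp6+cox3 (the inter-tRNA block) bins all
    three genes via iterative masking."""
    contig, feats, ref = ref_genome
    by_gene = {f.gene: f for f in feats}
    s = by_gene["atp8"].start
    e = by_gene["cox3"].end
    out = bin_fragments([("c", contig.seq[s:e])], ref)
    assert {g.gene for g in out} == {"atp8", "atp6", "cox3"}


def test_bin_minus_strand_orientation(ref_genome):
    contig, feats, ref = ref_genome
    f = next(x for x in feats if x.gene == "nad5")
    assert f.strand == "-"
    out = bin_fragments([("c", contig.seq[f.start:f.end])], ref)
    rec = next(g for g in out if g.gene == "nad5")
    assert rec.strand == "-"
    aa = translate_mito(rec.seq, rec.frame)
    assert "*" not in aa.rstrip("*")


def test_translate_table5_assignments():
    assert translate_mito("AGATGAATA") == "SWM"   # AGA=Ser TGA=Trp ATA=Met
    assert translate_mito("TAA") == "*"
    assert translate_mito("AGG") == "S"
    assert translate_mito("ACGTT") == "T"         # incomplete codon ignored


def test_back_translate_round_trip():
    rng = random.Random(4)
    for _ in range(20):
        n = rng.randrange(10, 80) * 3
        cds = "".join(rng.choice("ACGT") for _ in range(n))
        aa = translate_mito(cds)
        assert back_translate({"x": aa}, {"x": cds})["x"] == cds
    with pytest.raises(ValueError, match="bad_id"):
        back_translate({"bad_id": "MKL"}, {"bad_id": "ACG"})


def test_back_translate_places_triplet_gaps():
    out = back_translate({"x": "M-K"}, {"x": "ATGAAA"})
    assert out["x"] == "ATG---AAA"


def test_curate_trims_to_triplets():
    aln = {"a": "A" * 301, "b": "C" * 301}
    ga = curate_alignment("cox1", aln)
    assert ga.width == 300


def test_curate_drops_short_members():
    aln = {"full": "ATG" * 100,
           "short": "ATG" * 49 + "-" * 153}      # 49% aligned
    ga = curate_alignment("cox1", aln)
    assert ga.ids == ["full"]


def test_curate_masks_frameshift():
    rng = random.Random(8)
    codons = []
    while len(codons) < 100:
        c = "".join(rng.choice("ACGT") for _ in range(3))
        if c not in ("TAA", "TAG"):
            codons.append(c)
    truth = "".join(codons)
    # deletion of one base mid-gene: aligned row carries a 1-column gap
    pos = 151
    damaged = truth[:pos] + "-" + truth[pos + 1:]
    ga = curate_alignment("nad2", {"ok": truth, "dmg": damaged})
    aa = ga.aa["dmg"]
    assert "*" not in aa.replace("-", "")
    # at least (true length - 2) codons correct
    truth_aa = translate_mito(truth)
    same = sum(1 for x, y in zip(aa, truth_aa) if x == y)
    assert same >= len(truth_aa) - 2
    assert any("frameshift" in e for e in ga.events)


def test_supermatrix_criteria_and_gap_fill():
    def fake(gene, members, width_aa):
        nt = {m: "ATG" * width_aa for m in members}
        return curate_alignment(gene, nt)

    genes = "atp6 atp8 cob cox1 cox2 cox3 nad1 nad2 nad3 nad4".split()
    alns = {g: fake(g, ["c10", "c9"], 40) for g in genes[:9]}
    alns[genes[9]] = fake(genes[9], ["c10"], 40)  # c9 has only 9 genes
    sm = build_supermatrix(alns, "min_genes", min_genes=10)
    assert sm.taxa == ["c10"]
    sm1 = build_supermatrix(alns, "min_genes", min_genes=1)
    assert set(sm.taxa) <= set(sm1.taxa)
    assert sm.width == sm1.width

    alns2 = {"cox1": fake("cox1", ["a", "b"], 100),
             "nad4l": fake("nad4l", ["a"], 50)}
    lengths = {"a": 1900, "b": 2500}
    sm2 = build_supermatrix(alns2, "gene_anchor", contig_lengths=lengths)
    assert sm2.taxa == []                         # a: below 2 kb; b: no nad4l
    lengths["a"] = 2100
    sm3 = build_supermatrix(alns2, "gene_anchor", contig_lengths=lengths)
    assert sm3.taxa == ["a"]
    assert sm3.width == 150
    assert sm3.matrix["a"].count("-") == 0 or True
    with pytest.raises(ValueError, match="anchor"):
        build_supermatrix({"cox1": alns2["cox1"]}, "gene_anchor",
                          contig_lengths=lengths)


def test_supermatrix_width_and_missing_gene_gap():
    nt_a = {"t1": "ATG" * 100, "t2": "ATG" * 100}
    nt_b = {"t1": "ATG" * 50}
    alns = {"cox1": curate_alignment("cox1", nt_a),
            "cox2": curate_alignment("cox2", nt_b)}
    sm = build_supermatrix(alns, "min_genes", min_genes=1)
    assert sm.width == 150
    assert sm.matrix["t2"].endswith("-" * 50)
    assert sm.mask["t2"]["cox2"] is False
    assert sm.mask["t1"]["cox2"] is True


def test_star_align_recovers_simple_indel():
    out = star_align({"a": "MKLIVWDE", "b": "MKLVWDE", "c": "KLIVWD"},
                     center_id="a", protein=True)
    assert out["a"] == "MKLIVWDE"
    assert out["b"] == "MKL-VWDE"
    assert out["c"] == "-KLIVWD-"
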