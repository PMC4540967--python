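"""The synthetic community: structure, bounds, reproducibility, truth tables."""

import numpy as np
import pytest

from mitosoup.align import align_pair
from mitosoup.genes import fragment_by_trna, translate_mito
from mitosoup.records import revcomp
from mitosoup.simulate import (make_assembly_variants, make_community,
                               make_reference_genome, shred_reads)


@pytest.mark.parametrize("seed", range(1, 6))
def test_reference_genome_structure(seed):
    contig, feats = make_reference_genome(seed)
    pcgs = [f for f in feats if f.type == "PCG"]
    trnas = [f for f in feats if f.type == "tRNA"]
    assert len(pcgs) == 13
    assert len(trnas) == 22
    assert contig.circular
    strands = {f.strand for f in feats}
    assert strands == {"+", "-"}
    for f in pcgs:
        s = contig.seq[f.start:f.end]
        if f.strand == "-":
            s = revcomp(s)
        aa = translate_mito(s)
        assert s[:2] == "AT"                      # ATN start codon
        assert aa.endswith("*")
        assert "*" not in aa[:-1]


def test_fragment_complement_of_trnas():
    contig, feats = make_reference_genome(4)
    frags = fragment_by_trna(contig, feats)
    L = len(contig.seq)
    covered = set()
    for s, e, seq in frags:
        span = set(range(s, L)) | set(range(0, e)) if e < s else set(range(s, e))
        assert not covered & span                 # disjoint
        covered |= span
    trna = set()
    for f in feats:
        if f.type == "tRNA":
            trna |= set(range(f.start, f.end))
    assert covered == set(range(L)) - trna        # exact interval complement


def test_single_species_community():
    comm = make_community(1, haplotypes_per_species=1, seed=2)
    assert len(comm.species) == 1
    assert comm.species[0].abundance == pytest.approx(1.0)


def test_identity_bounds(small_community):
    sp = small_community.species
    cox1 = next(f for f in sp[0].features if f.gene == "cox1")
    for a, b in [(0, 1), (1, 2), (0, 5)]:
        aln = align_pair(sp[a].genome.seq[cox1.start:cox1.end],
                         sp[b].genome.seq[cox1.start:cox1.end], "global")
        assert aln.identity <= 95.0               # interspecific ceiling
    for s in sp[:3]:
        h = align_pair(s.haplotypes[0][:6000], s.haplotypes[1][:6000], "global")
        assert h.identity >= 99.0                 # intraspecific floor


def test_abundance_cv_matches_lognormal_expectation():
    """Coefficient of variation of normalised abundances vs a Monte-Carlo
    oracle of the same statistic (sample CV of 30 normalised lognormals)."""
    rng = np.random.default_rng(999)
    mc = []
    for _ in range(4000):
        x = rng.lognormal(0.0, 1.0, 30)
        x = x / x.sum()
        mc.append(np.std(x) / np.mean(x))
    mc_mean, mc_sd = np.mean(mc), np.std(mc)

    cvs = []
    for seed in range(12):
        comm = make_community(30, sigma=1.0, haplotypes_per_species=1,
                              n_background=0, seed=seed)
        ab = np.array([s.abundance for s in comm.species])
        assert ab.sum() == pytest.approx(1.0)
        cvs.append(np.std(ab) / np.mean(ab))
    se = mc_sd / np.sqrt(len(cvs))
    assert abs(np.mean(cvs) - mc_mean) < 3 * se * np.sqrt(len(mc) / len(cvs))


def test_shred_exact_substrings_without_errors(small_community):
    res = shred_reads(small_community, 150, error_rate=0.0,
                      nuclear_fraction=0.0, seed=21)
    by_id = {s.species_id: s for s in small_community.species}
    for pair, row in zip(res.pairs, res.truth.itertuples()):
        doubled = by_id[row.species].haplotypes[row.haplotype] * 2
        assert pair.seq1 in doubled or revcomp(pair.seq1) in doubled
        assert pair.seq2 in doubled or revcomp(pair.seq2) in doubled


def test_shred_nuclear_fraction(small_community):
    n = 4000
    res = shred_reads(small_community, n, nuclear_fraction=0.99, seed=5)
    mito = (res.truth.origin == "mito").sum()
    # binomial(4000, 0.01): mean 40, sd ~6.3
    assert 15 <= mito <= 70


def test_shred_depth_matches_expectation(small_community):
    n = 20000
    res = shred_reads(small_community, n, error_rate=0.0,
                      nuclear_fraction=0.0, seed=8)
    w = np.array([s.abundance * len(s.genome.seq)
                  for s in small_community.species])
    w = w / w.sum()
    for i, sp in enumerate(small_community.species):
        expected = n * 2 * 250 * w[i] / len(sp.genome.seq)
        got = (res.truth.species == sp.species_id).sum() * 2 * 250 \
            / len(sp.genome.seq)
        if expected > 20:                          # enough reads to be stable
            assert got == pytest.approx(expected, rel=0.10)


def test_variants_without_fracture_are_exact_copies(small_community):
    av = make_assembly_variants(small_community, fracture=False,
                                p_snp=0.0, p_indel=0.0, seed=7)
    by_id = {s.species_id: s for s in small_community.species}
    for lab, contigs in av.sets.items():
        assert len(contigs) == len(small_community.species)
        for c in contigs:
            sp = by_id[c.id.split("_")[1]]
            assert c.seq in sp.haplotypes


def test_variants_split_terminates_in_control_region(small_community):
    av = make_assembly_variants(small_community, p_snp=0.0, p_indel=0.0,
                                seed=7)
    full = av.truth[av.truth.kind == "full"]
    cts = {c.id: c for lab in av.sets for c in av.sets[lab]}
    for cid in full.contig_id:
        tail = cts[cid].seq[-200:]
        at = (tail.count("A") + tail.count("T")) / len(tail)
        assert at > 0.7                           # AT-rich control region


def test_same_seed_byte_identical(small_community):
    a = shred_reads(small_community, 50, seed=33)
    b = shred_reads(small_community, 50, seed=33)
    assert all(x.seq1 == y.seq1 and x.seq2 == y.seq2
               for x, y in zip(a.pairs, b.pairs))
    assert a.truth.equals(b.truth)
    va = make_assembly_variants(small_community, seed=33)
    vb = make_assembly_variants(small_community, seed=33)
    assert all(x.seq == y.seq for x, y in
               zip(va.sets["asmA"], vb.sets["asmA"]))
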