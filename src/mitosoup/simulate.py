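"""Synthetic beetle-community generator.

Emulates the data a bulk-specimen shotgun sequencing run produces: a pool of
species with circular ~16 kb mitogenomes (13 protein-coding genes and 22
tRNAs in an insect-like order, an AT-rich control region, genes on both
strands), intraspecific haplotypes, log-normally skewed species abundances, a
nuclear background, paired-end reads with an insert-size model, and two
artificially fractured "assemblies" with injected SNP/indel discrepancies.

Everything is reproducible from a single integer seed: each operation draws
from its own RNG stream derived from (seed, operation name), so changing one
stage's parameters never perturbs another stage's randomness.

Truth tables accompany every output so downstream stages can be scored
without re-simulation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import Contig, Feature, revcomp

# Coding lengths in codons (stop codon added separately); proportions follow
# typical beetle mitogenomes so the short-gene/long-gene coverage rules see
# realistic sizes (atp8, nad3, nad4l are the three genes under 400 nt).
PCG_CODONS = {
    "nad2": 341, "cox1": 512, "cox2": 229, "atp8": 52, "atp6": 224,
    "cox3": 262, "nad3": 117, "nad5": 572, "nad4": 446, "nad4l": 97,
    "nad6": 151, "cob": 379, "nad1": 313,
}

#: Insect-like gene order: (name, kind, strand). 22 tRNAs, 13 PCGs, control
#: region appended last so full-length linear contigs end in the AT-rich region.
GENOME_LAYOUT = (
    ("trnI", "tRNA", "+"), ("trnQ", "tRNA", "-"), ("trnM", "tRNA", "+"),
    ("nad2", "PCG", "+"), ("trnW", "tRNA", "+"), ("trnC", "tRNA", "-"),
    ("trnY", "tRNA", "-"), ("cox1", "PCG", "+"), ("trnL2", "tRNA", "+"),
    ("cox2", "PCG", "+"), ("trnK", "tRNA", "+"), ("trnD", "tRNA", "+"),
    ("atp8", "PCG", "+"), ("atp6", "PCG", "+"), ("cox3", "PCG", "+"),
    ("trnG", "tRNA", "+"), ("nad3", "PCG", "+"), ("trnA", "tRNA", "+"),
    ("trnR", "tRNA", "+"), ("trnN", "tRNA", "+"), ("trnS1", "tRNA", "+"),
    ("trnE", "tRNA", "+"), ("trnF", "tRNA", "-"), ("nad5", "PCG", "-"),
    ("trnH", "tRNA", "-"), ("nad4", "PCG", "-"), ("nad4l", "PCG", "-"),
    ("trnT", "tRNA", "+"), ("trnP", "tRNA", "-"), ("nad6", "PCG", "+"),
    ("cob", "PCG", "+"), ("trnS2", "tRNA", "+"), ("nad1", "PCG", "-"),
    ("trnL1", "tRNA", "-"), ("trnV", "tRNA", "-"),
)

STOPS = ("TAA", "TAG")   # invertebrate mitochondrial code: TGA is Trp
START_CODONS = ("ATA", "ATT", "ATG", "ATC")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(seed: int, op: str) -> np.random.Generator:
    """Per-operation RNG stream: seeded from (seed, crc32(op name))."""
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(op.encode())])


def _random_seq(rng: np.random.Generator, length: int,
                p=(0.25, 0.25, 0.25, 0.25)) -> str:
    return _BASES[rng.choice(4, size=length, p=list(p))].tobytes().decode()


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """A valid ORF: ATN start, no internal stop, TAA terminal stop."""
    codons = [START_CODONS[rng.integers(4)]]
    while len(codons) < n_codons:
        c = _random_seq(rng, 3)
        if c in STOPS:
            continue
        codons.append(c)
    codons.append("TAA")
    return "".join(codons)


@dataclass
class SimSpecies:
    species_id: str
    lineage: dict[str, str]
    genome: Contig                    # circular reference haplotype
    features: list[Feature]
    haplotypes: list[str]             # index 0 is the genome sequence itself
    abundance: float = 1.0


@dataclass
class SimCommunity:
    species: list[SimSpecies]
    background: list[str] = field(default_factory=list)
    seed: int = 0

    def feature_table(self) -> dict[str, list[Feature]]:
        return {sp.genome.id: sp.features for sp in self.species}

    def panel(self) -> list[Contig]:
        """Reference genomes, usable as a MitoDB-style filtering panel."""
        return [sp.genome for sp in self.species]


def make_reference_genome(seed: int, mean_length: float = 15700.0,
                          sd_length: float = 800.0,
                          species_id: str = "sim") -> tuple[Contig, list[Feature]]:
    """Build one circular annotated mitogenome.

    The 13 PCGs are valid ORFs under the invertebrate mitochondrial code, the
    22 tRNAs are ~70 bp, and the AT-rich control region absorbs the length
    draw so total length is ~N(mean_length, sd_length), floored so the
    control region never vanishes.
    """
    rng = _rng(seed, "make_reference_genome")
    parts: list[str] = []
    features: list[Feature] = []
    pos = 0
    for name, kind, strand in GENOME_LAYOUT:
        if kind == "tRNA":
            seq = _random_seq(rng, int(rng.integers(64, 73)))
        else:
            orf = _random_orf(rng, PCG_CODONS[name])
            seq = orf if strand == "+" else revcomp(orf)
        features.append(Feature(kind, name, pos, pos + len(seq), strand))
        parts.append(seq)
        pos += len(seq)
    target = int(rng.normal(mean_length, sd_length))
    cr_len = max(200, target - pos)
    parts.append(_random_seq(rng, cr_len, p=(0.425, 0.075, 0.075, 0.425)))
    contig = Contig(species_id, "".join(parts), source="truth", circular=True)
    return contig, features


def _mutate_haplotype(rng: np.random.Generator, seq: str,
                      features: list[Feature], rate: float) -> str:
    """Point-mutate a genome copy without breaking any PCG reading frame."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n_mut = rng.binomial(len(arr), rate)
    pcg_spans = [(f.start, f.end, f.strand) for f in features if f.type == "PCG"]
    positions = rng.choice(len(arr), size=n_mut, replace=False)
    for p in sorted(int(x) for x in positions):
        old = arr[p]
        choices = [b for b in _BASES if b != old]
        for newb in rng.permutation(choices):
            arr[p] = newb
            ok = True
            for s, e, strand in pcg_spans:
                if not (s <= p < e):
                    continue
                if strand == "+":
                    cs = s + ((p - s) // 3) * 3
                    codon = arr[cs:cs + 3].tobytes().decode()
                else:
                    ce = e - ((e - 1 - p) // 3) * 3
                    codon = revcomp(arr[ce - 3:ce].tobytes().decode())
                # never introduce an in-frame stop (terminal stop may mutate freely)
                if codon in STOPS and not (p >= e - 3 if strand == "+" else p < s + 3):
                    ok = False
                break
            if ok:
                break
        else:
            arr[p] = old
    return arr.tobytes().decode()


_SUBORDERS = ("Polyphaga", "Adephaga")


def _lineage_for(i: int, n_families: int) -> dict[str, str]:
    """Strictly nested synthetic lineage: family 0 forms a small outgroup
    suborder, the rest nest two families per superfamily, four per infraorder."""
    fam = i % n_families
    if fam == 0:
        suborder, infra, sup = _SUBORDERS[1], "infraA", "supfamA"
    else:
        suborder = _SUBORDERS[0]
        infra = f"infra{1 + (fam - 1) // 4:02d}"
        sup = f"supfam{1 + (fam - 1) // 2:02d}"
    return {
        "suborder": suborder,
        "infraorder": infra,
        "superfamily": sup,
        "family": f"fam{fam:02d}",
        "genus": f"genus{i:03d}",
        "species": f"sp{i:03d}",
    }


def make_community(n_species: int, sigma: float = 1.0,
                   haplotypes_per_species: int = 1,
                   intra_divergence: float = 0.005,
                   species_divergence: float = 0.10,
                   mean_length: float = 15700.0, sd_length: float = 800.0,
                   n_background: int = 40, background_len: int = 8000,
                   seed: int = 0) -> SimCommunity:
    """Assemble a community: related genomes, haplotypes, abundances.

    Species genomes descend from a common ancestral mitogenome, each mutated
    at ``species_divergence`` per site in the gene-bearing portion (frames
    kept intact, so proteins stay recognisably homologous across the
    community, as real beetle mitogenomes are) while the AT-rich control
    region is redrawn per species, which also spreads total genome length
    ~N(mean_length, sd_length). Pairwise interspecific identity lands around
    1 - 2 x divergence, well under the 95% ceiling the downstream thresholds
    assume; intraspecific haplotypes are point-mutated copies at
    ``intra_divergence`` (default 0.5%, keeping identity above the 99%
    floor). Abundances are log-normal(0, sigma), normalised, emulating the
    skewed per-species DNA input of a bulk extraction.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = _rng(seed, "make_community")
    anc_seed = int(rng.integers(1, 2**31 - 1))
    ancestor, anc_feats = make_reference_genome(anc_seed, mean_length, sd_length)
    genes_end = max(f.end for f in anc_feats)      # control region follows
    core = ancestor.seq[:genes_end]
    species: list[SimSpecies] = []
    n_families = max(2, min(12, n_species // 2 or 1))
    for i in range(n_species):
        mutated = _mutate_haplotype(rng, core, anc_feats, species_divergence)
        target = int(rng.normal(mean_length, sd_length))
        cr_len = max(200, target - len(mutated))
        cr = _random_seq(rng, cr_len, p=(0.425, 0.075, 0.075, 0.425))
        contig = Contig(f"sp{i:03d}", mutated + cr, source="truth",
                        circular=True)
        feats = [Feature(f.type, f.gene, f.start, f.end, f.strand)
                 for f in anc_feats]
        haps = [contig.seq]
        for _ in range(haplotypes_per_species - 1):
            haps.append(_mutate_haplotype(rng, contig.seq, feats, intra_divergence))
        species.append(SimSpecies(f"sp{i:03d}", _lineage_for(i, n_families),
                                  contig, feats, haps))
    ab = rng.lognormal(0.0, sigma, size=n_species)
    ab = ab / ab.sum()
    for sp, a in zip(species, ab):
        sp.abundance = float(a)
    background: list[str] = []
    for j in range(n_background):
        if j % 2 == 0 or not species:
            background.append(_random_seq(rng, background_len,
                                          p=(0.35, 0.15, 0.15, 0.35)))
        else:
            src = species[int(rng.integers(n_species))].genome.seq
            start = int(rng.integers(max(1, len(src) - background_len)))
            chunk = np.frombuffer(src[start:start + background_len].encode(),
                                  np.uint8).copy()
            muts = rng.random(len(chunk)) < 0.25     # ~75% identity <= 80% ceiling
            chunk[muts] = _BASES[rng.integers(0, 4, muts.sum())]
            background.append(chunk.tobytes().decode())
    return SimCommunity(species, background, seed)


# ------------------------------------------------------------- reads


@dataclass
class ShredResult:
    pairs: list            # list[ReadPair]
    truth: pd.DataFrame    # pair_id, origin, species, haplotype, pos, insert


def shred_reads(community: SimCommunity, n_pairs: int, read_len: int = 250,
                insert_mean: float = 480.0, insert_sd: float = 60.0,
                error_rate: float = 0.002, nuclear_fraction: float = 0.99,
                seed: int = 0) -> ShredResult:
    """Shotgun paired-end reads from the community.

    Mitochondrial pairs are drawn per species proportional to
    abundance x genome length, positions uniform on the circle (reads wrap
    the origin); ``nuclear_fraction`` of pairs come from the background pool.
    Substitution errors follow the per-base quality model: base quality from
    the error rate with a 10-point linear 3' decay over the final 50 bases.
    """
    from .records import ReadPair

    if insert_mean < read_len:
        raise ValueError("insert mean must be >= read length")
    rng = _rng(seed, "shred_reads")
    n_sp = len(community.species)
    w = np.array([sp.abundance * len(sp.genome.seq) for sp in community.species])
    w = w / w.sum()
    lo = 2 * read_len - 50
    hi = insert_mean + 4 * insert_sd

    # per-position quality/error profile
    if error_rate > 0:
        q0 = min(40.0, -10.0 * np.log10(error_rate))
    else:
        q0 = 40.0
    posn = np.arange(read_len)
    decay = 10.0 * np.clip(posn - (read_len - 50), 0, None) / 50.0
    quals = np.clip(np.round(q0 - decay), 2, 93).astype(np.uint8)
    perr = 10.0 ** (-quals.astype(float) / 10.0) if error_rate > 0 \
        else np.zeros(read_len)

    is_nuclear = rng.random(n_pairs) < nuclear_fraction
    pairs = []
    rows = []
    for i in range(n_pairs):
        pid = f"pair{i:07d}"
        insert = int(np.clip(rng.normal(insert_mean, insert_sd), lo, hi))
        if is_nuclear[i] and community.background:
            bi = int(rng.integers(len(community.background)))
            src = community.background[bi]
            if len(src) <= insert:
                insert = len(src)
            start = int(rng.integers(0, len(src) - insert + 1))
            frag = src[start:start + insert]
            origin, spid, hap, pos = "nuclear", f"bg{bi:03d}", -1, start
        else:
            si = int(rng.choice(n_sp, p=w))
            sp = community.species[si]
            hap = int(rng.integers(len(sp.haplotypes)))
            g = sp.haplotypes[hap]
            pos = int(rng.integers(len(g)))
            frag = (g + g)[pos:pos + insert]       # wraparound over the origin
            origin, spid = "mito", sp.species_id
        if rng.random() < 0.5:
            frag = revcomp(frag)
        r1 = frag[:read_len]
        r2 = revcomp(frag[-read_len:])
        if error_rate > 0:
            r1 = _apply_errors(rng, r1, perr)
            r2 = _apply_errors(rng, r2, perr)
        pairs.append(ReadPair(pid, r1, quals[:len(r1)].copy(),
                              r2, quals[:len(r2)].copy()))
        rows.append((pid, origin, spid, hap, pos, insert))
    truth = pd.DataFrame(rows, columns=["pair_id", "origin", "species",
                                        "haplotype", "pos", "insert"])
    return ShredResult(pairs, truth)


def _apply_errors(rng: np.random.Generator, seq: str, perr: np.ndarray) -> str:
    arr = np.frombuffer(seq.encode(), np.uint8).copy()
    hit = rng.random(len(arr)) < perr[:len(arr)]
    if hit.any():
        idx = np.nonzero(hit)[0]
        shift = rng.integers(1, 4, len(idx))
        lut = {65: 0, 67: 1, 71: 2, 84: 3}
        for p, s in zip(idx, shift):
            arr[p] = _BASES[(lut.get(int(arr[p]), 0) + int(s)) % 4]
    return arr.tobytes().decode()


# -------------------------------------------------- assembly variants


@dataclass
class AssemblyVariants:
    sets: dict[str, list[Contig]]                   # label -> contigs
    features: dict[str, list[Feature]]              # contig id -> features
    truth: pd.DataFrame   # contig_id, source, species, haplotype, kind,
                          # circular_complete, n_snps, n_indels


def _shift_features(features: list[Feature], edits: list[tuple[int, int]],
                    length: int) -> list[Feature]:
    """Adjust feature coordinates for 1-bp edits [(pos, +1|-1), ...]."""
    out = []
    for f in features:
        ds = sum(d for p, d in edits if p < f.start)
        de = sum(d for p, d in edits if p < f.end)
        s, e = f.start + ds, f.end + de
        if 0 <= s < e <= length:
            out.append(Feature(f.type, f.gene, s, e, f.strand))
    return out


def _inject_discrepancies(rng: np.random.Generator, seq: str,
                          features: list[Feature], p_snp: float,
                          p_indel: float) -> tuple[str, list[Feature], int, int]:
    arr = list(seq)
    n_snp = rng.binomial(len(arr), p_snp)
    for p in sorted(int(x) for x in rng.choice(len(arr), n_snp, replace=False)):
        alt = [b for b in "ACGT" if b != arr[p]]
        arr[p] = alt[int(rng.integers(3))]
    pcg_spans = [(f.start, f.end) for f in features if f.type == "PCG"]
    total_pcg = sum(e - s for s, e in pcg_spans)
    n_indel = rng.binomial(total_pcg, p_indel)
    edits: list[tuple[int, int]] = []
    for _ in range(n_indel):
        s, e = pcg_spans[int(rng.integers(len(pcg_spans)))]
        p = int(rng.integers(s + 10, e - 10))
        p_adj = p + sum(d for q, d in edits if q < p)
        if rng.random() < 0.5:
            arr.insert(p_adj, "ACGT"[int(rng.integers(4))])
            edits.append((p, 1))
        else:
            del arr[p_adj]
            edits.append((p, -1))
    new_seq = "".join(arr)
    new_feats = _shift_features(features, edits, len(new_seq))
    return new_seq, new_feats, int(n_snp), int(n_indel)


def _window_features(features: list[Feature], start: int, end: int) -> list[Feature]:
    """Features fully inside [start, end), re-based to the window."""
    return [Feature(f.type, f.gene, f.start - start, f.end - start, f.strand)
            for f in features if start <= f.start and f.end <= end]


def make_assembly_variants(community: SimCommunity, n_variants: int = 2,
                           fracture: bool = True, p_snp: float = 5e-4,
                           p_indel: float = 1e-4, p_circular: float = 0.5,
                           dup_len: int = 80, min_circular_len: int = 15000,
                           labels: tuple[str, ...] = ("asmA", "asmB"),
                           seed: int = 0) -> AssemblyVariants:
    """Fracture the community into per-assembler contig sets.

    Per species one variant carries either a circular-completable contig
    (full genome plus a duplicated ``dup_len`` terminus, probability
    ``p_circular``) or a full-length linear contig terminating in the AT-rich
    control region; the other variant carries two fragments overlapping by
    1.2–2 kb. SNPs are injected genome-wide at ``p_snp``; rare 1-bp indels at
    ``p_indel`` land inside PCGs so ORF arbitration is exercised. With
    ``fracture=False`` and zero rates both variants are exact genome copies.
    """
    assert n_variants == len(labels)
    rng = _rng(seed, "make_assembly_variants")
    sets: dict[str, list[Contig]] = {lab: [] for lab in labels}
    feat_out: dict[str, list[Feature]] = {}
    rows = []

    for sp in community.species:
        hap_pick = [int(rng.integers(len(sp.haplotypes))) for _ in labels]
        circ_variant = -1
        long_variant = 0
        if fracture:
            if rng.random() < p_circular:
                circ_variant = int(rng.integers(n_variants))
                long_variant = circ_variant
            else:
                long_variant = int(rng.integers(n_variants))
        for v, lab in enumerate(labels):
            base = sp.haplotypes[hap_pick[v]]
            feats = sp.features
            if p_snp > 0 or p_indel > 0:
                base, feats, n_snp, n_indel = _inject_discrepancies(
                    rng, base, feats, p_snp, p_indel)
            else:
                n_snp = n_indel = 0
            L = len(base)
            if not fracture or (fracture and v == long_variant and v != circ_variant):
                cid = f"{lab}_{sp.species_id}_full"
                sets[lab].append(Contig(cid, base, source=lab))
                feat_out[cid] = feats
                rows.append((cid, lab, sp.species_id, hap_pick[v], "full",
                             False, n_snp, n_indel))
            elif v == circ_variant:
                cut = int(rng.integers(L))
                rot = base[cut:] + base[:cut]
                seq = rot + rot[:dup_len]
                cid = f"{lab}_{sp.species_id}_circ"
                sets[lab].append(Contig(cid, seq, source=lab))
                shifted = [Feature(f.type, f.gene, (f.start - cut) % L,
                                   (f.start - cut) % L + (f.end - f.start),
                                   f.strand) for f in feats]
                feat_out[cid] = [f for f in shifted if f.end <= L]
                rows.append((cid, lab, sp.species_id, hap_pick[v], "circ",
                             L >= min_circular_len, n_snp, n_indel))
            else:
                c = int(rng.integers(int(0.35 * L), int(0.6 * L)))
                ov = int(rng.integers(1200, 2000))
                w1 = (0, min(L, c + ov))
                w2 = (c, L)
                for part, (s, e) in enumerate((w1, w2), 1):
                    cid = f"{lab}_{sp.species_id}_f{part}"
                    sets[lab].append(Contig(cid, base[s:e], source=lab))
                    feat_out[cid] = _window_features(feats, s, e)
                    rows.append((cid, lab, sp.species_id, hap_pick[v],
                                 f"frag{part}", False, n_snp, n_indel))
    truth = pd.DataFrame(rows, columns=[
        "contig_id", "source", "species", "haplotype", "kind",
        "circular_complete", "n_snps", "n_indels"])
    return AssemblyVariants(sets, feat_out, truth)
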