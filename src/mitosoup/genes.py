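"""Gene extraction, codon-aware alignment curation and supermatrix assembly.

The extraction route follows the tRNA-anchor trick: the 13 protein-coding
genes are not located directly; instead every maximal contig interval not
covered by a tRNA annotation is excised (including the segments before the
first and after the last tRNA), translated in all six frames, and sorted
into genes by local protein alignment against a reference gene set. Because
insect gene order places several PCGs back to back between two tRNAs
(atp8–atp6–cox3, nad4–nad4l, nad6–cob), binning is iterative: the best
gene region of a fragment is assigned and masked, and the remainder is
re-scanned, so a three-gene fragment yields three gene fragments.

Alignment curation reproduces the published rules: trim to complete
triplets, drop members aligned over less than half the final width, and
repair apparent single-base frameshifts by masking the minimal codon window
(never by editing sequence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .records import Contig, Feature, PCG_ORDER, revcomp

# ------------------------------------------------------------ fragments


def fragment_by_trna(contig: Contig, features: list[Feature]
                     ) -> list[tuple[int, int, str]]:
    """Inter-tRNA intervals of a contig: (start, end, sequence), 0-based.

    The complement of the union of tRNA features, including terminal
    segments (the single-base-sentinel behaviour of the original protocol).
    For circular contigs the interval spanning the origin is emitted as one
    wrapped fragment with end < start.
    """
    L = len(contig.seq)
    trnas = sorted((f.start, f.end) for f in features if f.type == "tRNA")
    merged: list[list[int]] = []
    for s, e in trnas:
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)   # overlapping tRNAs: union
        else:
            merged.append([s, e])
    if not merged:
        return [(0, L, contig.seq)]
    out: list[tuple[int, int, str]] = []
    if contig.circular:
        # wrapped fragment from last tRNA end around to first tRNA start
        first_s = merged[0][0]
        last_e = merged[-1][1]
        if last_e < L or first_s > 0:
            if last_e % L != first_s:
                out.append((last_e % L, first_s,
                            (contig.seq + contig.seq)[last_e:L + first_s]
                            if last_e > first_s else contig.seq[last_e:first_s]))
    else:
        if merged[0][0] > 0:
            out.append((0, merged[0][0], contig.seq[:merged[0][0]]))
    for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
        if e1 < s2:
            out.append((e1, s2, contig.seq[e1:s2]))
    if not contig.circular and merged[-1][1] < L:
        out.append((merged[-1][1], L, contig.seq[merged[-1][1]:]))
    return sorted(out, key=lambda t: t[0])


# --------------------------------------------------------------- binning


@dataclass
class GeneFragment:
    contig_id: str
    gene: str                  # one of the 13 PCG names, or "unassigned"
    seq: str                   # oriented to the coding strand
    frame: int                 # 0|1|2 offset into seq
    ref_coverage: float        # fraction of the reference gene covered
    strand: str = "+"
    score: float = 0.0


@dataclass
class ReferenceGenes:
    """The 13 reference PCGs as nt and aa, e.g. from an annotated genome."""

    nt: dict[str, str]
    aa: dict[str, str]

    @classmethod
    def from_annotated(cls, contig: Contig, features: list[Feature]
                       ) -> "ReferenceGenes":
        nt: dict[str, str] = {}
        aa: dict[str, str] = {}
        for f in features:
            if f.type != "PCG":
                continue
            s = contig.seq[f.start:f.end]
            if f.strand == "-":
                s = revcomp(s)
            nt[f.gene] = s
            aa[f.gene] = translate_mito(s, 0).rstrip("*")
        return cls(nt, aa)


def _protein_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    al.mode = "local"
    return al


def _aa_kmers(s: str, k: int = 5) -> set[str]:
    return {s[i:i + k] for i in range(len(s) - k + 1)}


def _self_score(aa: str) -> float:
    mat = substitution_matrices.load("BLOSUM62")
    return float(sum(mat[c, c] for c in aa if c in mat.alphabet))


def bin_fragments(fragments: list[tuple[str, str]], reference: ReferenceGenes,
                  min_ref_cov: float = 0.5, score_floor: float = 0.4
                  ) -> list[GeneFragment]:
    """Sort (contig_id, fragment_seq) pairs into genes.

    Each fragment is translated in all six frames and locally aligned to the
    reference proteins; the best-scoring gene region is assigned when its
    score reaches ``score_floor`` x the self-score of the covered reference
    span and the covered fraction of the reference gene length is at least
    ``min_ref_cov``. The assigned region is then masked and the fragment
    re-scanned, so fragments spanning several adjacent genes bin each of
    them. Unassignable fragments are reported once as "unassigned".
    """
    aligner = _protein_aligner()
    ref_kmers = {g: _aa_kmers(a) for g, a in reference.aa.items()}
    out: list[GeneFragment] = []
    for contig_id, frag in fragments:
        found: list[GeneFragment] = []
        # aa translations per (strand, frame), recomputed after masking
        work = frag
        for _round in range(16):          # at most all 13 PCGs per fragment
            best = None
            for strand in ("+", "-"):
                oriented = work if strand == "+" else revcomp(work)
                for frame in range(3):
                    aa = translate_mito(oriented, frame, allow_partial=True)
                    if len(aa) < 15:
                        continue
                    km = _aa_kmers(aa.replace("*", "x"))
                    for gene, ref_aa in reference.aa.items():
                        # k-mer prescreen only for long references: a short,
                        # diverged protein (atp8) can share no exact 5-mer yet
                        # align perfectly well
                        if len(ref_aa) >= 120 and len(km & ref_kmers[gene]) < 2:
                            continue
                        try:
                            alns = aligner.align(aa, ref_aa)
                            aln = alns[0]
                        except (IndexError, OverflowError):
                            continue
                        score = float(aln.score)
                        qb, tb = aln.aligned
                        t0, t1 = tb[0][0], tb[-1][1]
                        q0, q1 = qb[0][0], qb[-1][1]
                        cov = (t1 - t0) / len(ref_aa)
                        floor = score_floor * _self_score(ref_aa[t0:t1])
                        if score < floor or cov < min_ref_cov:
                            continue
                        key = (score, gene)
                        if best is None or key > best[0]:
                            best = (key, gene, strand, frame, q0, q1, cov, score)
            if best is None:
                break
            _, gene, strand, frame, q0, q1, cov, score = best
            oriented = work if strand == "+" else revcomp(work)
            nt0 = frame + 3 * q0
            nt1 = frame + 3 * q1
            found.append(GeneFragment(contig_id, gene, oriented[nt0:nt1], 0,
                                      round(cov, 4), strand, score))
            # mask the assigned region (on the working strand) and re-scan
            if strand == "+":
                work = work[:nt0] + "N" * (nt1 - nt0) + work[nt1:]
            else:
                m0 = len(work) - nt1
                m1 = len(work) - nt0
                work = work[:m0] + "N" * (m1 - m0) + work[m1:]
        if found:
            out.extend(found)
        else:
            out.append(GeneFragment(contig_id, "unassigned", frag, 0, 0.0))
    return out


# ----------------------------------------------------------- translation

_GAP_AA = "-"


def translate_mito(nt: str, frame: int = 0, allow_partial: bool = True) -> str:
    """Invertebrate mitochondrial translation (table 5): AGA/AGG=Ser,
    ATA=Met, TGA=Trp. The incomplete terminal codon is ignored."""
    sub = nt[frame:]
    sub = sub[:len(sub) - len(sub) % 3]
    if not sub:
        return ""
    out = []
    for i in range(0, len(sub), 3):
        codon = sub[i:i + 3]
        if codon == "---":
            out.append(_GAP_AA)
        elif "-" in codon or "N" in codon:
            out.append("X")
        else:
            out.append(str(Seq(codon).translate(table=5)))
    return "".join(out)


def back_translate(aa_alignment: dict[str, str], nt_originals: dict[str, str]
                   ) -> dict[str, str]:
    """Insert triplet gaps into original nt wherever the aa alignment has
    gaps; reproduces the original nucleotides everywhere else."""
    out: dict[str, str] = {}
    for sid, aa in aa_alignment.items():
        nt = nt_originals[sid]
        need = 3 * sum(1 for c in aa if c != _GAP_AA)
        if need > len(nt) or len(nt) - need >= 3:
            raise ValueError(f"aa/nt length inconsistency for sequence {sid!r}")
        cols = []
        i = 0
        for c in aa:
            if c == _GAP_AA:
                cols.append("---")
            else:
                cols.append(nt[i:i + 3])
                i += 3
        out[sid] = "".join(cols)
    return out


# ------------------------------------------------------- star alignment


def _pair_coords(aligner: Align.PairwiseAligner, center: str, other: str):
    aln = aligner.align(center, other)[0]
    cb, ob = aln.aligned
    return list(zip([tuple(x) for x in cb], [tuple(x) for x in ob]))


def star_align(seqs: dict[str, str], center_id: str | None = None,
               protein: bool = True) -> dict[str, str]:
    """Center-star multiple alignment.

    Pairwise semiglobal alignments of every member to the center (longest
    sequence unless ``center_id`` names one, e.g. a reference gene added to
    ``seqs``); member residues that fall between center blocks become
    insertion columns shared across the output.
    """
    if not seqs:
        return {}
    if center_id is None:
        center_id = max(seqs, key=lambda s: (len(seqs[s]), s))
    center = seqs[center_id]
    al = Align.PairwiseAligner()
    if protein:
        al.substitution_matrix = substitution_matrices.load("BLOSUM62")
        al.open_gap_score = -11.0
        al.extend_gap_score = -1.0
    else:
        al.match_score = 1.0
        al.mismatch_score = -1.0
        al.open_gap_score = -2.0
        al.extend_gap_score = -1.0
    al.mode = "global"
    al.end_gap_score = 0.0

    n = len(center)
    ins_before = [0] * (n + 1)       # insertion columns before center pos
    rows: dict[str, list[tuple[str, int, int, str]]] = {}
    for sid, s in seqs.items():
        if sid == center_id:
            rows[sid] = [("C", i, 0, c) for i, c in enumerate(center)]
            continue
        placed: list[tuple[str, int, int, str]] = []
        prev_c = prev_o = 0
        blocks = _pair_coords(al, center, s) + [((n, n), (len(s), len(s)))]
        for (c0, c1), (o0, o1) in blocks:
            ins = s[prev_o:o0]
            ins_before[c0] = max(ins_before[c0], len(ins))
            for k, ch in enumerate(ins):
                placed.append(("I", c0, k, ch))
            for ci, oi in zip(range(c0, c1), range(o0, o1)):
                placed.append(("C", ci, 0, s[oi]))
            prev_c, prev_o = c1, o1
        rows[sid] = placed

    col_of_center: dict[int, int] = {}
    ins_col: dict[tuple[int, int], int] = {}
    col = 0
    for pos in range(n + 1):
        for k in range(ins_before[pos]):
            ins_col[(pos, k)] = col
            col += 1
        if pos < n:
            col_of_center[pos] = col
            col += 1
    out: dict[str, str] = {}
    for sid, placed in rows.items():
        row = ["-"] * col
        for kind, pos, k, ch in placed:
            row[col_of_center[pos] if kind == "C" else ins_col[(pos, k)]] = ch
        out[sid] = "".join(row)
    return out


# -------------------------------------------------------------- curation


@dataclass
class GeneAlignment:
    gene: str
    ids: list[str]
    nt: dict[str, str]
    aa: dict[str, str]
    width: int = 0
    events: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.nt:
            self.width = len(next(iter(self.nt.values())))


def curate_alignment(gene: str, nt_alignment: dict[str, str],
                     min_aligned_frac: float = 0.5) -> GeneAlignment:
    """Curate a raw per-gene nt alignment into a codon-clean GeneAlignment.

    Trims terminal columns to complete triplets, masks the minimal codon
    window around apparent single-base frameshifts (gap runs of non-triplet
    length), then drops members whose non-gap length is under
    ``min_aligned_frac`` of the final width. Masking is conservative: the
    sequence is never edited, only gapped.
    """
    if not nt_alignment:
        return GeneAlignment(gene, [], {}, {})
    widths = {len(s) for s in nt_alignment.values()}
    if len(widths) != 1:
        raise ValueError(f"{gene}: inconsistent alignment widths {sorted(widths)}")
    width = widths.pop()
    events: list[str] = []
    excess = width % 3
    if excess:
        nt_alignment = {k: v[:width - excess] for k, v in nt_alignment.items()}
        width -= excess
        events.append(f"trimmed {excess} trailing column(s) to complete triplets")

    repaired: dict[str, str] = {}
    for sid, row in nt_alignment.items():
        chars = list(row)
        i = 0
        while i < width:
            if chars[i] != "-":
                i += 1
                continue
            j = i
            while j < width and chars[j] == "-":
                j += 1
            run = j - i
            if run % 3:
                # mask forward to the next codon boundary: restores frame
                need = 3 - (run % 3)
                k = j
                while need and k < width:
                    if chars[k] != "-":
                        chars[k] = "-"
                        need -= 1
                    k += 1
                events.append(f"frameshift masked in {sid} at column {i}")
                j = k
            i = j
        repaired[sid] = "".join(chars)

    final: dict[str, str] = {}
    for sid, row in repaired.items():
        aligned = sum(1 for c in row if c != "-")
        if aligned < min_aligned_frac * width:
            events.append(f"dropped {sid}: aligned {aligned}/{width}")
            continue
        final[sid] = row
    if not final:
        events.append("no sequence survived curation")
    aa = {sid: translate_mito(row, 0) for sid, row in final.items()}
    ga = GeneAlignment(gene, sorted(final), final, aa)
    ga.events = events
    return ga


# ------------------------------------------------------------ supermatrix


@dataclass
class Supermatrix:
    taxa: list[str]
    matrix: dict[str, str]                 # concatenated aa per taxon
    mask: dict[str, dict[str, bool]]       # taxon -> gene -> present
    spans: dict[str, tuple[int, int]]      # gene -> aa column span
    width: int = 0


def build_supermatrix(gene_alignments: dict[str, GeneAlignment],
                      criterion: str = "min_genes", min_genes: int = 10,
                      anchor_gene: str = "nad4l", min_contig_len: int = 2000,
                      contig_lengths: dict[str, int] | None = None) -> Supermatrix:
    """Concatenate per-gene aa alignments into a supermatrix.

    ``criterion="min_genes"`` keeps contigs carrying at least ``min_genes``
    of the 13 PCGs (the "10+" set by default); ``criterion="gene_anchor"``
    keeps contigs that carry ``anchor_gene`` and are at least
    ``min_contig_len`` long (the nad4l-centred community matrix). Genes are
    concatenated in the canonical order with gap-fill for absent genes.
    """
    per_contig: dict[str, set[str]] = {}
    for gene, ga in gene_alignments.items():
        for sid in ga.ids:
            per_contig.setdefault(sid, set()).add(gene)
    if criterion == "min_genes":
        taxa = sorted(c for c, gs in per_contig.items() if len(gs) >= min_genes)
    elif criterion == "gene_anchor":
        if anchor_gene not in gene_alignments or not gene_alignments[anchor_gene].ids:
            raise ValueError(f"anchor gene {anchor_gene!r} absent from alignments")
        if contig_lengths is None:
            raise ValueError("gene_anchor criterion requires contig_lengths")
        taxa = sorted(c for c, gs in per_contig.items()
                      if anchor_gene in gs
                      and contig_lengths.get(c, 0) >= min_contig_len)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    spans: dict[str, tuple[int, int]] = {}
    pos = 0
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    mask: dict[str, dict[str, bool]] = {t: {} for t in taxa}
    for gene in PCG_ORDER:
        ga = gene_alignments.get(gene)
        if ga is None or not ga.nt:
            continue
        aaw = ga.width // 3
        spans[gene] = (pos, pos + aaw)
        pos += aaw
        for t in taxa:
            if t in ga.aa:
                parts[t].append(ga.aa[t])
                mask[t][gene] = any(c != "-" for c in ga.aa[t])
            else:
                parts[t].append("-" * aaw)
                mask[t][gene] = False
    matrix = {t: "".join(parts[t]) for t in taxa}
    return Supermatrix(taxa, matrix, mask, spans, pos)


# --------------------------------------------- reference-based annotation


def transfer_annotations(contig: Contig, ref: Contig,
                         ref_features: list[Feature]) -> list[Feature]:
    """Project tRNA/PCG features from a reference genome onto a contig.

    Stands in for covariance-model tRNA annotation: each reference feature
    sequence is located on the contig by alignment. Features that cannot be
    placed (missing regions, fractured contigs) are skipped.
    """
    import edlib

    out: list[Feature] = []
    L = len(contig.seq)
    target = contig.seq + (contig.seq[:400] if contig.circular else "")
    for f in ref_features:
        fseq = ref.seq[f.start:f.end]
        best = None
        for flipped, probe in ((False, fseq), (True, revcomp(fseq))):
            res = edlib.align(probe, target, mode="HW", task="locations",
                              k=max(4, int(0.15 * len(probe))))
            if res["editDistance"] < 0:
                continue
            if best is None or res["editDistance"] < best[0]:
                loc = res["locations"][0]
                best = (res["editDistance"], flipped, loc[0] or 0, loc[1] + 1)
        if best is None:
            continue
        _, flipped, s, e = best
        if s >= L:
            continue
        strand = f.strand if not flipped else ("-" if f.strand == "+" else "+")
        out.append(Feature(f.type, f.gene, s, e, strand))
    return sorted(out, key=lambda f: f.start)
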