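"""Barcode-bait linkage of contigs to specimens and morphospecies.

PCR-derived cox1-5' barcodes ("baits", ~648 bp) carry specimen identity;
assembled contigs are linked to a morphospecies when their barcode region
matches a bait at >= 98% identity — loose enough to catch contigs whose
haplotype escaped PCR, tight enough to stay within species. The overlap
summary counts species-level entities recovered by PCR only, by contigs
only, or by both.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import align_pair
from .records import Contig, SeqRecord


@dataclass
class Bait:
    haplotype_id: str
    seq: str
    specimen_ids: tuple[str, ...] = ()
    morphospecies_id: str = ""
    family: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not 400 <= len(self.seq) <= 800:
            raise ValueError(
                f"bait {self.haplotype_id}: length {len(self.seq)} outside [400, 800]")


@dataclass
class BaitLink:
    contig_id: str
    haplotype_id: str
    pct_identity: float
    morphospecies_id: str


def collapse_haplotypes(seqs: list[SeqRecord]) -> tuple[list[SeqRecord], dict[str, int]]:
    """Exact-match haplotype dedup after normalisation.

    Normalisation: uppercase and strip terminal Ns; internal Ns keep
    sequences distinct. The representative is the first-seen id.
    """
    seen: dict[str, SeqRecord] = {}
    mult: dict[str, int] = {}
    for rec in seqs:
        norm = rec.seq.upper().strip("N")
        if norm in seen:
            mult[seen[norm].id] += 1
        else:
            rep = SeqRecord(rec.id, norm, rec.desc)
            seen[norm] = rep
            mult[rec.id] = 1
    return list(seen.values()), mult


def extract_barcode_region(contig: Contig, reference_barcodes: list[SeqRecord],
                           min_aln: int = 200, min_identity: float = 70.0
                           ) -> tuple[str, int, int] | None:
    """Locate the cox1-5' barcode region on a contig.

    Best local alignment against the reference barcode(s); a hit of
    >= ``min_aln`` columns at >= ``min_identity`` yields the oriented
    subsequence and its contig coordinates (0-based half-open), else None.
    """
    from .records import revcomp

    best = None
    for ref in reference_barcodes:
        for strand, probe in (("+", contig.seq), ("-", revcomp(contig.seq))):
            aln = align_pair(ref.seq, probe, "semiglobal")
            if aln.aln_len < min_aln or aln.identity < min_identity:
                continue
            key = (aln.identity, aln.aln_len)
            if best is None or key > best[0]:
                best = (key, strand, aln.b_start, aln.b_end)
    if best is None:
        return None
    _, strand, s, e = best
    L = len(contig.seq)
    if strand == "+":
        return contig.seq[s:e], s, e
    return revcomp(contig.seq)[s:e], L - e, L - s


def bait_contigs(contig_barcodes: dict[str, str], baits: list[Bait],
                 threshold: float = 98.0
                 ) -> tuple[list[BaitLink], list[str], list[str]]:
    """Link contig barcode regions to bait haplotypes at >= ``threshold``.

    Best hit only per contig; equal-best baits from one morphospecies break
    lexicographically, equal-best across different morphospecies flag the
    contig ambiguous (unlinked). Returns (links, contig_only ids,
    pcr_only haplotype ids).
    """
    links: list[BaitLink] = []
    contig_only: list[str] = []
    hit_baits: set[str] = set()
    for cid in sorted(contig_barcodes):
        seq = contig_barcodes[cid]
        scored: list[tuple[float, str, Bait]] = []
        for b in baits:
            aln = align_pair(seq, b.seq, "semiglobal")
            if aln.aln_len >= 0.5 * min(len(seq), len(b.seq)):
                scored.append((round(aln.identity, 2), b.haplotype_id, b))
        scored.sort(key=lambda t: (-t[0], t[1]))
        qualifying = [t for t in scored if t[0] >= threshold]
        if not qualifying:
            contig_only.append(cid)
            continue
        top = qualifying[0][0]
        tied = [t for t in qualifying if t[0] == top]
        morphos = {t[2].morphospecies_id for t in tied}
        if len(morphos) > 1:
            contig_only.append(cid)     # ambiguous equal-best: flagged, unlinked
            continue
        ident, hap, bait = tied[0]
        links.append(BaitLink(cid, hap, ident, bait.morphospecies_id))
        hit_baits.add(hap)
    pcr_only = sorted(b.haplotype_id for b in baits
                      if b.haplotype_id not in hit_baits)
    return links, contig_only, pcr_only


def summarize_linkage(*, shared: int | None = None, pcr_only: int | None = None,
                      contig_only: int | None = None,
                      links: list[BaitLink] | None = None,
                      bait_groups: dict[str, str] | None = None,
                      contig_groups: dict[str, str] | None = None,
                      specimens_total: int | None = None,
                      specimens_barcoded: int | None = None) -> dict:
    """Overlap of PCR-derived and contig-derived species entities.

    Either pass the three counts directly (published-table arithmetic) or
    pass ``bait_groups``/``contig_groups`` mapping haplotype ids to
    species-entity labels (an external species delimitation, or simulator
    truth) to have them counted. Percentages to 1 decimal; optionally a
    specimen barcode success rate.
    """
    if shared is None:
        ents_pcr = set((bait_groups or {}).values())
        ents_contig = set((contig_groups or {}).values())
        shared = len(ents_pcr & ents_contig)
        pcr_only = len(ents_pcr - ents_contig)
        contig_only = len(ents_contig - ents_pcr)
    total = shared + pcr_only + contig_only
    out = {
        "shared": shared, "pcr_only": pcr_only, "contig_only": contig_only,
        "total_entities": total,
        "shared_pct": round(100.0 * shared / total, 1) if total else 0.0,
        "pcr_only_pct": round(100.0 * pcr_only / total, 1) if total else 0.0,
        "contig_only_pct": round(100.0 * contig_only / total, 1) if total else 0.0,
    }
    if specimens_total:
        out["barcode_success_pct"] = round(
            100.0 * (specimens_barcoded or 0) / specimens_total, 1)
    return out
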