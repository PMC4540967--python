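"""Hit-based per-gene coverage and assembly-of-origin tallies.

Mean coverage of a gene alignment is estimated from similarity hits of the
reads against the alignment members: total contributing bases divided by the
total number of aligned nucleotides (the summed non-gap length of the member
sequences, so both the number of members and their lengths are accounted
for). A read contributes through its best hit only. Long genes (reference
length > 400 bp) require hits of >= 200 bp at >= 98% identity; the three
short genes (atp8, nad3, nad4l) require >= 98% identity over >= 50% of the
reference gene length.
"""

from __future__ import annotations

from .genes import GeneAlignment
from .records import HitRecord

SHORT_GENE_MAX_REF = 400
LONG_GENE_MIN_ALN = 200
IDENTITY_THRESHOLD = 98.0


def _qualifies(hit: HitRecord, ref_len: int) -> bool:
    ident = round(hit.pct_identity, 2)
    if ident < IDENTITY_THRESHOLD:
        return False
    if ref_len > SHORT_GENE_MAX_REF:
        return hit.aln_len >= LONG_GENE_MIN_ALN
    return hit.aln_len >= 0.5 * ref_len


def gene_coverage(gene_alignments: dict[str, GeneAlignment],
                  read_hits: list[HitRecord],
                  reference_gene_lengths: dict[str, int]) -> dict[str, dict]:
    """Per-gene coverage report.

    ``read_hits`` are hits of reads against the alignment member sequences;
    each read counts once, through its best-bitscore hit (ties: lower
    E-value, then lexicographic subject id). A gene whose members carry zero
    aligned nucleotides is an error, not a zero.
    """
    member_gene: dict[str, str] = {}
    aligned_nt: dict[str, int] = {}
    for gene, ga in gene_alignments.items():
        if gene not in reference_gene_lengths:
            raise ValueError(f"no reference length for gene {gene!r}")
        aligned_nt[gene] = sum(sum(1 for c in row if c != "-")
                               for row in ga.nt.values())
        for sid in ga.ids:
            member_gene[sid] = gene

    # best hit per read (max_target_seqs 1 semantics on the read side)
    best: dict[str, HitRecord] = {}
    for h in read_hits:
        if h.subject_id not in member_gene:
            continue
        cur = best.get(h.query_id)
        if cur is None or (-h.bitscore, h.evalue, h.subject_id) < \
                (-cur.bitscore, cur.evalue, cur.subject_id):
            best[h.query_id] = h

    contributing: dict[str, int] = {g: 0 for g in gene_alignments}
    for h in best.values():
        gene = member_gene[h.subject_id]
        if _qualifies(h, reference_gene_lengths[gene]):
            contributing[gene] += h.aln_len

    report: dict[str, dict] = {}
    for gene, ga in gene_alignments.items():
        nt = aligned_nt[gene]
        if nt == 0:
            raise ValueError(f"gene {gene!r} has zero aligned nucleotides")
        report[gene] = {
            "n_members": len(ga.ids),
            "aligned_nucleotides": nt,
            "contributing_bases": contributing[gene],
            "mean_coverage": round(contributing[gene] / nt, 1),
        }
    return report


def sequence_source_tally(gene_alignments: dict[str, GeneAlignment],
                          hits_by_set: dict[str, list[HitRecord]],
                          identity: float = 98.0) -> dict[str, dict[str, int]]:
    """Score each alignment member as present in each assembly's fragments.

    ``hits_by_set`` maps assembly label -> hits of alignment members
    (queries) against that assembly's inter-tRNA fragment set. A member is
    present in a set iff its best hit there reaches ``identity``. Returns per
    gene the counts {"<A> only", "<B> only", ..., "both", "neither"}; counts
    sum to the alignment size.
    """
    labels = sorted(hits_by_set)
    best: dict[str, dict[str, float]] = {lab: {} for lab in labels}
    for lab in labels:
        for h in hits_by_set[lab]:
            cur = best[lab].get(h.query_id, -1.0)
            if h.pct_identity > cur:
                best[lab][h.query_id] = h.pct_identity
    out: dict[str, dict[str, int]] = {}
    for gene, ga in gene_alignments.items():
        counts = {f"{lab} only": 0 for lab in labels}
        counts["both"] = 0
        counts["neither"] = 0
        for sid in ga.ids:
            present = [lab for lab in labels
                       if round(best[lab].get(sid, -1.0), 2) >= identity]
            if len(present) == len(labels) and len(labels) > 1:
                counts["both"] += 1
            elif len(present) == 1:
                counts[f"{present[0]} only"] += 1
            elif len(present) == 0:
                counts["neither"] += 1
            else:
                counts["both"] += 1
        out[gene] = counts
    return out
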