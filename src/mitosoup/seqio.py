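"""Readers and writers for all external formats.

FASTA/FASTQ go through Bio.SeqIO; Newick through dendropy. The tab-separated
dialects (12-column BLAST tabular, feature tables, taxonomy tables) are plain
TSV and are parsed directly. Emitted coordinates are 1-based inclusive
throughout; see :mod:`mitosoup.records` for the conversion rules.
"""

from __future__ import annotations

import re
from pathlib import Path

import dendropy
from Bio import SeqIO

from .records import (
    Contig, Feature, HitRecord, PCG_NAMES, RANKS, ReadPair, SeqRecord,
    Taxonomy, to_external, to_internal,
)

# ---------------------------------------------------------------- FASTA


def read_fasta(path) -> list[SeqRecord]:
    """Read FASTA, uppercasing sequences. Duplicate ids are an error."""
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SeqRecord(rec.id, str(rec.seq), rec.description[len(rec.id):].strip()))
    return records


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {rec.desc}" if getattr(rec, "desc", "") else ""
            fh.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def write_contig_fasta(contigs: list[Contig], path) -> None:
    """Contigs as FASTA with ``circular=true|false`` flagged in the header."""
    recs = [SeqRecord(c.id, c.seq, f"circular={'true' if c.circular else 'false'} source={c.source}")
            for c in contigs]
    write_fasta(recs, path)


# ---------------------------------------------------------------- FASTQ

_MATE_TAG = re.compile(r"(/[12]|[._][12])$")


def strip_mate_tag(read_id: str) -> str:
    """Base id of a read: strips /1, /2 and similar trailing mate tags."""
    return _MATE_TAG.sub("", read_id.split()[0])


def read_fastq_pairs(path1, path2) -> list[ReadPair]:
    """Read two mate FASTQ files paired by record order.

    Qualities are decoded from Sanger/Phred+33. A length mismatch between the
    files is reported with the index of the first missing record.
    """
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    pairs: list[ReadPair] = []
    i = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            break
        if r1 is None or r2 is None:
            raise ValueError(
                f"mate files differ in length: record index {i} missing from "
                f"{'mate 1' if r1 is None else 'mate 2'}")
        pairs.append(ReadPair(
            strip_mate_tag(r1.id),
            str(r1.seq).upper(), list(r1.letter_annotations["phred_quality"]),
            str(r2.seq).upper(), list(r2.letter_annotations["phred_quality"]),
        ))
        i += 1
    return pairs


def write_fastq_pairs(pairs: list[ReadPair], path1, path2) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            q1 = "".join(chr(q + 33) for q in p.qual1)
            q2 = "".join(chr(q + 33) for q in p.qual2)
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{q1}\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{q2}\n")


# ------------------------------------------------------- BLAST tabular


def read_blast_tab(path) -> list[HitRecord]:
    """Parse 12-column BLAST tabular (outfmt 6) hits."""
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(parts)}")
            try:
                hits.append(HitRecord(
                    parts[0], parts[1], float(parts[2]), int(parts[3]),
                    int(parts[4]), int(parts[5]), int(parts[6]), int(parts[7]),
                    int(parts[8]), int(parts[9]), float(parts[10]), float(parts[11]),
                ))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable hit line ({exc})") from None
    return hits


def write_blast_tab(hits: list[HitRecord], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join(map(str, (
                h.query_id, h.subject_id, f"{h.pct_identity:.2f}", h.aln_len,
                h.mismatches, h.gap_opens, h.q_start, h.q_end, h.s_start,
                h.s_end, f"{h.evalue:.2g}", f"{h.bitscore:.1f}"))) + "\n")


# ------------------------------------------------------------- Newick


def read_newick(path_or_string) -> dendropy.Tree:
    """Read a Newick tree (file path or literal string)."""
    s = str(path_or_string)
    try:
        if ";" in s or "(" in s:
            return dendropy.Tree.get(data=s, schema="newick",
                                     suppress_internal_node_taxa=True,
                                     preserve_underscores=True)
        return dendropy.Tree.get(path=s, schema="newick",
                                 suppress_internal_node_taxa=True,
                                 preserve_underscores=True)
    except Exception as exc:
        raise ValueError(f"unparseable Newick input: {exc}") from None


def write_newick(tree: dendropy.Tree, path=None) -> str:
    out = tree.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        Path(path).write_text(out)
    return out


# ----------------------------------------------- feature & taxonomy TSV


def read_features(path) -> dict[str, list[Feature]]:
    """Feature TSV (contig_id, type, gene, start, end, strand), 1-based inclusive.

    Returns internal (0-based half-open) features keyed by contig id.
    """
    table: dict[str, list[Feature]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("contig_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns")
            cid, ftype, gene, start, end, strand = parts
            if ftype not in ("tRNA", "PCG"):
                raise ValueError(f"{path}:{lineno}: unknown feature type {ftype!r}")
            if ftype == "PCG" and gene not in PCG_NAMES:
                raise ValueError(f"{path}:{lineno}: unknown PCG name {gene!r}")
            s, e = to_internal(int(start), int(end))
            table.setdefault(cid, []).append(Feature(ftype, gene, s, e, strand))
    return table


def write_features(table: dict[str, list[Feature]], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\ttype\tgene\tstart\tend\tstrand\n")
        for cid, feats in table.items():
            for f in feats:
                s, e = to_external(f.start, f.end)
                fh.write(f"{cid}\t{f.type}\t{f.gene}\t{s}\t{e}\t{f.strand}\n")


def read_taxonomy(path) -> Taxonomy:
    """Taxonomy TSV: header ``id`` + rank names, one lineage per row."""
    tax = Taxonomy()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "id":
            raise ValueError(f"{path}: taxonomy header must start with 'id'")
        for rank in header[1:]:
            if rank not in RANKS:
                raise ValueError(f"{path}: unknown rank {rank!r} in header")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            lineage = {r: v for r, v in zip(header[1:], parts[1:]) if v}
            tax.add(parts[0], lineage)
    return tax


def write_taxonomy(tax: Taxonomy, path) -> None:
    ranks = [r for r in RANKS if any(r in lin for lin in tax.lineages.values())]
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(ranks) + "\n")
        for ref, lin in tax.lineages.items():
            fh.write(ref + "\t" + "\t".join(lin.get(r, "") for r in ranks) + "\n")
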