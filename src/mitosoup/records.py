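"""Domain records shared across the pipeline.

All in-memory coordinates are 0-based half-open; every emitted table and every
parsed external format uses 1-based inclusive coordinates. The two converters
below are exact inverses and are the only place the convention is translated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The 13 mitochondrial protein-coding genes, in the fixed concatenation order
#: used for supermatrices (alphabetical with nad4l last).
PCG_ORDER = (
    "atp6", "atp8", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad5", "nad6", "nad4l",
)
PCG_NAMES = frozenset(PCG_ORDER)

#: Taxonomic rank ladder, lowest to highest. Extra BLAST-only ranks from
#: reference taxonomies (order, subclass, infraclass) are accepted in input.
RANKS = (
    "species", "genus", "subfamily", "family", "superfamily",
    "infraorder", "suborder", "order", "subclass", "infraclass",
)


def to_external(start: int, end: int) -> tuple[int, int]:
    """0-based half-open ``[start, end)`` -> 1-based inclusive ``(start, end)``."""
    return start + 1, end


def to_internal(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open. Inverse of :func:`to_external`."""
    return start - 1, end


@dataclass
class SeqRecord:
    """A named nucleotide (or amino-acid) sequence."""

    id: str
    seq: str
    desc: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record with empty id")
        self.seq = self.seq.upper()

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReadPair:
    """A paired-end read with Sanger (Phred+33) decoded qualities."""

    id: str
    seq1: str
    qual1: list[int]
    seq2: str
    qual2: list[int]

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"read pair {self.id}: sequence/quality length mismatch")


@dataclass
class HitRecord:
    """One pairwise similarity hit, BLAST tabular (outfmt 6) semantics.

    Subject coordinates with ``s_start > s_end`` encode a minus-strand hit,
    exactly as in BLAST tabular output.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    @property
    def minus_strand(self) -> bool:
        return self.s_start > self.s_end


@dataclass
class Feature:
    """A tRNA or protein-coding gene feature, internal coordinates."""

    type: str           # "tRNA" | "PCG"
    gene: str
    start: int          # 0-based half-open on the stored sequence
    end: int
    strand: str         # "+" | "-"


@dataclass
class Contig:
    """An assembled sequence with provenance through merging."""

    id: str
    seq: str
    source: str = ""
    circular: bool = False
    provenance: list[str] = field(default_factory=list)
    notes: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.provenance:
            self.provenance = [self.id]

    def __len__(self) -> int:
        return len(self.seq)


class Taxonomy:
    """Ranked lineages for a set of reference ids.

    Stored as ``{ref_id: {rank: taxon}}`` over the fixed rank ladder; missing
    ranks are simply absent.
    """

    def __init__(self, lineages: dict[str, dict[str, str]] | None = None):
        self.lineages: dict[str, dict[str, str]] = {}
        for ref, lin in (lineages or {}).items():
            self.add(ref, lin)

    def add(self, ref_id: str, lineage: dict[str, str]) -> None:
        clean = {}
        for rank, taxon in lineage.items():
            if rank not in RANKS:
                raise ValueError(f"unknown rank {rank!r} for {ref_id}")
            if taxon:
                clean[rank] = taxon
        self.lineages[ref_id] = clean

    def taxon(self, ref_id: str, rank: str) -> str | None:
        return self.lineages.get(ref_id, {}).get(rank)

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self.lineages

    def __len__(self) -> int:
        return len(self.lineages)

    def ids(self) -> list[str]:
        return list(self.lineages)


COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]
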