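"""Contig filtering, circularization and multi-assembly reconciliation.

The reconciliation procedure mirrors a four-step merge of two assemblers'
contig sets into one non-redundant set: (1) cluster circular contigs across
sets at the top identity tier and keep one representative per cluster;
(2) drop linear contigs that are contained in a circular representative;
(3) single-linkage merge the remaining linear contigs at the top tier,
highest identity first, building extended consensus sequences; (4) repeat at
the second, slightly more permissive tier. Within an overlap, substitution
conflicts take the base from the preferred source; 1-bp indel conflicts are
arbitrated by open-reading-frame plausibility (the variant whose local
translation has fewer internal stop codons wins, ties to the longer contig).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import Alignment, align_pair
from .records import Contig, Feature, HitRecord, revcomp
from Bio.Seq import Seq


@dataclass
class MergePolicy:
    tier_identities: tuple[float, ...] = (99.0, 98.0)
    min_overlap: int = 100
    source_preference: tuple[str, ...] = ()
    orf_arbitration: bool = True

    def __post_init__(self) -> None:
        ids = list(self.tier_identities)
        if ids != sorted(ids, reverse=True) or not all(0 < t <= 100 for t in ids):
            raise ValueError("tier identities must be descending, in (0, 100]")

    def pref_rank(self, source: str) -> int:
        try:
            return self.source_preference.index(source)
        except ValueError:
            return len(self.source_preference)


# ----------------------------------------------------------- filtering


def filter_mito_contigs(contigs: list[Contig], hits: list[HitRecord],
                        min_aln: int = 1000,
                        max_evalue: float = 1e-5) -> list[Contig]:
    """Retain contigs with >=1 panel hit of alignment length >= ``min_aln``.

    One qualifying hit suffices; hits need not tile the contig. The 1 kb
    default deliberately discards short true mitochondrial contigs along with
    the non-mitochondrial ones.
    """
    ok = {h.query_id for h in hits
          if h.aln_len >= min_aln and h.evalue <= max_evalue}
    return [c for c in contigs if c.id in ok]


# ------------------------------------------------------ circularization


def _least_rotation(s: str) -> int:
    """Booth's algorithm: index of the lexicographically minimal rotation."""
    ss = s + s
    f = [-1] * len(ss)
    k = 0
    for j in range(1, len(ss)):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def canonical_rotation(seq: str, features: list[Feature] | None = None) -> tuple[str, int]:
    """Canonical origin: first base of cox1 if annotated, else the
    lexicographically minimal rotation. Returns (rotated seq, cut index)."""
    cut = None
    for f in features or ():
        if f.gene == "cox1":
            cut = f.start
            break
    if cut is None:
        cut = _least_rotation(seq)
    return seq[cut:] + seq[:cut], cut


def detect_circular(contig: Contig, min_len: int = 15000, min_overlap: int = 50,
                    min_identity: float = 99.0, max_overlap: int = 1000,
                    features: list[Feature] | None = None) -> Contig:
    """Circularize a long contig with near-identical overlapping termini.

    Contigs of length >= ``min_len`` whose prefix matches their suffix over
    >= ``min_overlap`` columns at >= ``min_identity`` lose one copy of the
    overlap, are flagged circular and are rotated to the canonical origin.
    The longest qualifying overlap is used. Shorter contigs are returned
    unchanged (manual inspection in the original protocol only covered
    contigs over 15 kb).
    """
    seq = contig.seq
    if contig.circular or len(seq) < min_len:
        return contig
    w = min(len(seq) // 2, max_overlap)
    pre = np.frombuffer(seq[:w].encode(), np.uint8)
    suf = np.frombuffer(seq[-w:].encode(), np.uint8)
    isn_p = pre == ord("N")
    isn_s = suf == ord("N")
    best_d = 0
    for d in range(min_overlap, w + 1):
        a = pre[:d]
        b = suf[w - d:]
        m = int(np.count_nonzero((a == b) & ~isn_p[:d] & ~isn_s[w - d:]))
        if 100.0 * m / d >= min_identity:
            best_d = d
    if best_d == 0:
        # indel-tolerant fallback over the terminal windows
        aln = align_pair(seq[-w:], seq[:w], "semiglobal")
        anchored = (aln.a_end >= w - 2) and (aln.b_start <= 2)
        if not (anchored and aln.aln_len >= min_overlap
                and aln.identity >= min_identity):
            return contig
        trim = w - aln.a_start
    else:
        trim = best_d
    new_seq = seq[:len(seq) - trim]
    rotated, _ = canonical_rotation(new_seq, features)
    return Contig(contig.id, rotated, source=contig.source, circular=True,
                  provenance=list(contig.provenance),
                  notes=(contig.notes + f" circularized(trim={trim})").strip())


# -------------------------------------------------------------- merging


def _circ_identity(query: Contig, rep: Contig) -> Alignment:
    """Rotation-invariant comparison: query against the doubled representative."""
    return align_pair(query.seq, rep.seq + rep.seq, "semiglobal")


def _count_min_stops(window: str) -> int:
    """Minimum internal-stop count over the six reading frames (table 5)."""
    best = 10**9
    for s in (window, revcomp(window)):
        for off in range(3):
            sub = s[off:]
            sub = sub[:len(sub) - len(sub) % 3]
            if not sub:
                continue
            aa = str(Seq(sub).translate(table=5))
            best = min(best, aa.count("*"))
    return best if best < 10**9 else 0


def _arbitrate_indel(a_seq: str, b_seq: str, a_pos: int, b_pos: int,
                     win: int = 600) -> str:
    # the window is deliberately wide: with only two stop codons in the
    # invertebrate code, short frameshifted windows often show a stop-free
    # frame by chance and the comparison degenerates to a tie
    """'A' or 'B': which variant's local sequence looks in-frame."""
    wa = a_seq[max(0, a_pos - win):a_pos + win]
    wb = b_seq[max(0, b_pos - win):b_pos + win]
    sa, sb = _count_min_stops(wa), _count_min_stops(wb)
    if sa < sb:
        return "A"
    if sb < sa:
        return "B"
    return "tie"


def _consensus(a: Contig, b: Contig, aln: Alignment, policy: MergePolicy
               ) -> tuple[str, list[str]]:
    """Build the merged consensus along the overlap alignment.

    Returns (sequence, arbitration notes). Assumes a dovetail or containment
    layout (validated by the caller).
    """
    prefer_a = policy.pref_rank(a.source) <= policy.pref_rank(b.source)
    # tie-break owner for indels: longer contig, then preferred source
    if len(a.seq) != len(b.seq):
        indel_owner_default = "A" if len(a.seq) > len(b.seq) else "B"
    else:
        indel_owner_default = "A" if prefer_a else "B"
    out: list[str] = [a.seq[:aln.a_start] if aln.a_start >= aln.b_start
                      else b.seq[:aln.b_start]]
    notes: list[str] = []
    out_len = len(out[0])
    i, j = aln.a_start, aln.b_start
    ops = aln.ops
    idx = 0
    while idx < len(ops):
        ca, cb = ops[idx]
        if ca != "-" and cb != "-":
            if ca == cb:
                out.append(ca)
            else:
                out.append(ca if prefer_a else cb)
                notes.append(f"snp@{out_len}:{ca}/{cb}")
            out_len += 1
            i += 1
            j += 1
            idx += 1
            continue
        # collect the whole indel run as one event
        run = idx
        while run < len(ops) and ("-" in ops[run]):
            run += 1
        ins_a = "".join(x for x, y in ops[idx:run] if x != "-")
        ins_b = "".join(y for x, y in ops[idx:run] if y != "-")
        owner = "tie"
        if policy.orf_arbitration:
            owner = _arbitrate_indel(a.seq, b.seq, i, j)
        if owner == "tie":
            owner = indel_owner_default
        chosen = ins_a if owner == "A" else ins_b
        out.append(chosen)
        out_len += len(chosen)
        notes.append(f"indel@{i}/{j}:{owner}")
        i += len(ins_a)
        j += len(ins_b)
        idx = run
    out.append(a.seq[aln.a_end:]
               if (len(a.seq) - aln.a_end) >= (len(b.seq) - aln.b_end)
               else b.seq[aln.b_end:])
    return "".join(out), notes


def _layout_ok(a_len: int, b_len: int, aln: Alignment) -> bool:
    """Overlap layout is consistent iff overhangs sit on at most one side of
    each sequence: dovetail (A suffix ~ B prefix or vice versa) or containment."""
    slack = 25
    a_left, a_right = aln.a_start, a_len - aln.a_end
    b_left, b_right = aln.b_start, b_len - aln.b_end
    left_ok = a_left <= slack or b_left <= slack
    right_ok = a_right <= slack or b_right <= slack
    return left_ok and right_ok


@dataclass
class MergeReport:
    circular_clusters: list[list[str]] = field(default_factory=list)
    dropped_linear: list[tuple[str, str]] = field(default_factory=list)
    merges: list[str] = field(default_factory=list)
    conflicts: list[str] = field(default_factory=list)
    arbitrations: list[str] = field(default_factory=list)


def merge_assemblies(contig_sets: dict[str, list[Contig]],
                     policy: MergePolicy | None = None
                     ) -> tuple[list[Contig], MergeReport]:
    """Reconcile labeled contig sets into a non-redundant set.

    See the module docstring for the four-step procedure. Deterministic
    throughout: candidate merges are ordered by identity (descending), then
    combined length, then source preference, then id.
    """
    if not contig_sets or not any(contig_sets.values()):
        raise ValueError("at least one non-empty contig set required")
    policy = policy or MergePolicy()
    if not policy.source_preference:
        policy = MergePolicy(policy.tier_identities, policy.min_overlap,
                             tuple(contig_sets), policy.orf_arbitration)
    report = MergeReport()
    tier1 = policy.tier_identities[0]

    def order_key(c: Contig):
        return (-len(c.seq), policy.pref_rank(c.source), c.id)

    every = [c for lab in contig_sets for c in contig_sets[lab]]
    circular = sorted([c for c in every if c.circular], key=order_key)
    linear = [c for c in every if not c.circular]

    # Candidate screen: shared k-mers on a consistent alignment diagonal.
    # Raw k-mer sharing is not specific enough once the inputs contain
    # related species; a true overlap concentrates its seed matches on one
    # diagonal, chance cross-species matches scatter.
    pos_index_cache: dict[str, dict[str, list[int]]] = {}

    def pos_index(key: str, seq: str) -> dict[str, list[int]]:
        if key not in pos_index_cache:
            ix: dict[str, list[int]] = {}
            for j in range(0, len(seq) - 21 + 1):
                ix.setdefault(seq[j:j + 21], []).append(j)
            pos_index_cache[key] = ix
        return pos_index_cache[key]

    def diag_votes(a: Contig, b: Contig, doubled_b: bool = False
                   ) -> tuple[int, int]:
        """(max votes on one diagonal bin, offset estimate pos_b - pos_a)."""
        bseq = b.seq + b.seq if doubled_b else b.seq
        ix = pos_index(b.id + ("*2" if doubled_b else ""), bseq)
        votes: dict[int, int] = {}
        for i in range(0, max(1, len(a.seq) - 21 + 1), 16):
            for j in ix.get(a.seq[i:i + 21], ())[:4]:
                d = (j - i) // 8
                votes[d] = votes.get(d, 0) + 1
        if not votes:
            return 0, 0
        best = min(votes, key=lambda d: (-votes[d], d))
        return votes[best], best * 8

    def similar_enough(a: Contig, b: Contig, offset: int,
                       doubled_b: bool = False) -> bool:
        """Banded edit-distance screen on the implied overlap: False when the
        pair cannot reach the merge identity tiers (a related species, say)."""
        import edlib as _edlib

        bseq = b.seq + b.seq if doubled_b else b.seq
        if offset >= 0:
            a0, b0 = 0, offset
        else:
            a0, b0 = -offset, 0
        span = min(len(a.seq) - a0, len(bseq) - b0)
        if span < policy.min_overlap:
            return False
        lim = int(0.035 * span) + 60
        res = _edlib.align(a.seq[a0:a0 + span], bseq[b0:b0 + span],
                           mode="NW", task="distance", k=lim)
        return res["editDistance"] >= 0

    # Step 1: cluster circular contigs, rotation-invariant
    reps: list[Contig] = []
    for c in circular:
        placed = False
        for r in reps:
            votes, off = diag_votes(c, r, doubled_b=True)
            if votes < 4 or not similar_enough(c, r, off, doubled_b=True):
                continue
            aln = _circ_identity(c, r)
            if aln.identity >= tier1 and aln.aln_len >= 0.8 * len(c.seq):
                r.provenance = sorted(set(r.provenance) | set(c.provenance))
                placed = True
                break
        if not placed:
            reps.append(Contig(c.id, c.seq, source=c.source, circular=True,
                               provenance=list(c.provenance), notes=c.notes))
    report.circular_clusters = [list(r.provenance) for r in reps]

    # Step 2: drop linear contigs contained in a circular representative
    survivors: list[Contig] = []
    for l in linear:
        dropped = False
        for r in reps:
            votes, off = diag_votes(l, r, doubled_b=True)
            if votes < 4 or not similar_enough(l, r, off, doubled_b=True):
                continue
            aln = _circ_identity(l, r)
            if aln.identity >= tier1 and aln.aln_len >= 0.8 * len(l.seq):
                report.dropped_linear.append((l.id, r.id))
                dropped = True
                break
        if not dropped:
            survivors.append(Contig(l.id, l.seq, source=l.source,
                                    provenance=list(l.provenance), notes=l.notes))

    # Steps 3 & 4: tiered single-linkage merging of linear contigs
    pool = survivors
    counter = 0
    aln_cache: dict[tuple[str, str], Alignment | None] = {}
    conflict_seen: set[tuple[str, str]] = set()
    for tier in policy.tier_identities:
        while True:
            best = None
            for x in range(len(pool)):
                for y in range(x + 1, len(pool)):
                    a, b = pool[x], pool[y]
                    pair = (a.id, b.id)
                    if pair not in aln_cache:
                        votes, off = diag_votes(a, b)
                        if votes < 4 or not similar_enough(a, b, off):
                            aln_cache[pair] = None
                        else:
                            aln_cache[pair] = align_pair(a.seq, b.seq, "semiglobal")
                    aln = aln_cache[pair]
                    if aln is None or aln.aln_len < policy.min_overlap \
                            or aln.identity < tier:
                        continue
                    if not _layout_ok(len(a.seq), len(b.seq), aln):
                        if pair not in conflict_seen:
                            conflict_seen.add(pair)
                            report.conflicts.append(
                                f"inconsistent_layout:{a.id}~{b.id}")
                        continue
                    key = (-aln.identity, -(len(a.seq) + len(b.seq)),
                           min(policy.pref_rank(a.source), policy.pref_rank(b.source)),
                           min(a.id, b.id))
                    if best is None or key < best[0]:
                        best = (key, x, y, aln)
            if best is None:
                break
            _, x, y, aln = best
            a, b = pool[x], pool[y]
            seq, notes = _consensus(a, b, aln, policy)
            counter += 1
            merged = Contig(f"nr{counter:04d}", seq,
                            source=min((a, b), key=lambda c: policy.pref_rank(c.source)).source,
                            provenance=sorted(set(a.provenance) | set(b.provenance)))
            report.merges.append(f"{a.id}+{b.id}->{merged.id}@{aln.identity:.2f}")
            report.arbitrations.extend(f"{merged.id}:{n}" for n in notes)
            pool = [c for k, c in enumerate(pool) if k not in (x, y)] + [merged]
        # next tier continues with the current pool
    out = reps + sorted(pool, key=order_key)
    return out, report


# ---------------------------------------------------------------- stats

SIZE_CLASSES = ((1000, 5000), (5000, 10000), (10000, 15000), (15000, None))


def assembly_stats(contigs: list[Contig]) -> dict:
    """Count/min/max/mean/N50/total plus size-class tallies (circular noted).

    N50 is the largest length L such that contigs of length >= L sum to at
    least half the total length. Size classes are half-open: [1,5), [5,10),
    [10,15) kb and >= 15 kb (with the circular count alongside).
    """
    if not contigs:
        return {"count": 0, "min": 0, "max": 0, "mean": 0.0, "n50": 0,
                "total_length": 0,
                "size_classes": {f"{a}-{b}": (0, 0) for a, b in SIZE_CLASSES}}
    lengths = sorted((len(c.seq) for c in contigs), reverse=True)
    total = sum(lengths)
    acc = 0
    n50 = lengths[-1]
    for L in lengths:
        acc += L
        if acc >= total / 2:
            n50 = L
            break
    classes = {}
    for lo, hi in SIZE_CLASSES:
        members = [c for c in contigs
                   if len(c.seq) >= lo and (hi is None or len(c.seq) < hi)]
        classes[f"{lo}-{hi if hi else 'inf'}"] = (
            len(members), sum(1 for c in members if c.circular))
    return {"count": len(contigs), "min": lengths[-1], "max": lengths[0],
            "mean": round(total / len(lengths), 1), "n50": n50,
            "total_length": total, "size_classes": classes}
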