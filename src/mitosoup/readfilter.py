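"""Read quality control and mitochondrial-like pair filtering.

Quality trimming follows the two stringency regimes used before assembly:
low (minimum length 150 bp, 3' bases below Q20 trimmed, mean quality >= Q25,
no Ns) and high (5' and 3' below Q30 trimmed, mean >= Q30, no Ns). Trimming
is a single maximal suffix (and optional prefix) strip of bases strictly
below the threshold; the mean is computed after trimming.

Pair filtering keeps a pair when one (mode "either") or both (mode "both")
mates hit the reference mitogenome panel at the E-value cutoff. The
conservative mitochondrial-fraction estimate requires both mates to align
over >= 100 bp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import HitRecord, ReadPair
from .seqio import strip_mate_tag


@dataclass
class QCParams:
    min_len: int = 150
    trim3_q: int = 20
    trim5_q: int | None = None
    min_mean_q: float = 25.0
    allow_N: bool = False


#: The two stringency regimes applied before assembly.
QC_LOW = QCParams(min_len=150, trim3_q=20, trim5_q=None, min_mean_q=25.0)
QC_HIGH = QCParams(min_len=150, trim3_q=30, trim5_q=30, min_mean_q=30.0)


def _trim_read(seq: str, qual, params: QCParams) -> tuple[str, np.ndarray]:
    q = np.asarray(qual)
    end = len(q)
    while end > 0 and q[end - 1] < params.trim3_q:
        end -= 1
    start = 0
    if params.trim5_q is not None:
        while start < end and q[start] < params.trim5_q:
            start += 1
    return seq[start:end], q[start:end]


def _read_passes(seq: str, qual: np.ndarray, params: QCParams) -> str | None:
    """None if the trimmed read passes, else the failure reason."""
    if len(seq) < params.min_len:
        return "too_short"
    if len(qual) and float(np.mean(qual)) < params.min_mean_q:
        return "low_mean_q"
    if not params.allow_N and "N" in seq:
        return "contains_N"
    return None


def quality_trim(pairs: list[ReadPair], params: QCParams = QC_LOW,
                 pairing: str = "both_pass") -> tuple[list[ReadPair], dict]:
    """Trim and filter read pairs; returns kept pairs and a reason tally.

    Under ``both_pass`` a pair is kept iff both mates pass individually;
    ``independent`` keeps the pair whenever at least one mate passes (the
    failing mate is retained untrimmed-out, flagged in the report).
    """
    if pairing not in ("both_pass", "independent"):
        raise ValueError(f"unknown pairing rule {pairing!r}")
    kept: list[ReadPair] = []
    report = {"input": len(pairs), "kept": 0, "dropped": 0,
              "too_short": 0, "low_mean_q": 0, "contains_N": 0}
    for p in pairs:
        s1, q1 = _trim_read(p.seq1, p.qual1, params)
        s2, q2 = _trim_read(p.seq2, p.qual2, params)
        r1 = _read_passes(s1, q1, params)
        r2 = _read_passes(s2, q2, params)
        for r in (r1, r2):
            if r:
                report[r] += 1
        ok = (r1 is None and r2 is None) if pairing == "both_pass" \
            else (r1 is None or r2 is None)
        if ok:
            kept.append(ReadPair(p.id, s1, q1, s2, q2))
            report["kept"] += 1
        else:
            report["dropped"] += 1
    return kept, report


def _pair_hit_map(pairs: list[ReadPair], hits: list[HitRecord],
                  max_evalue: float, min_aln_len: int = 0):
    """Map pair id -> set of mates (1/2) with a qualifying hit."""
    base_ids = {p.id for p in pairs}
    got: dict[str, set[int]] = {}
    unknown: list[str] = []
    for h in hits:
        qid = h.query_id
        base = strip_mate_tag(qid)
        if base not in base_ids:
            unknown.append(qid)
            continue
        if h.evalue > max_evalue or h.aln_len < min_aln_len:
            continue
        mate = 2 if qid.rstrip().endswith("2") and base != qid else 1
        got.setdefault(base, set()).add(mate)
    if unknown:
        shown = ", ".join(sorted(set(unknown))[:10])
        raise ValueError(f"hits reference unknown read ids: {shown}")
    return got


def filter_mito_pairs(pairs: list[ReadPair], hits: list[HitRecord],
                      mode: str = "either",
                      max_evalue: float = 1e-5) -> tuple[list[ReadPair], dict]:
    """Keep pairs with a qualifying panel hit from one or both mates."""
    if mode not in ("either", "both"):
        raise ValueError(f"unknown filter mode {mode!r}")
    got = _pair_hit_map(pairs, hits, max_evalue)
    kept = []
    for p in pairs:
        mates = got.get(p.id, set())
        if (mode == "either" and mates) or (mode == "both" and mates == {1, 2}):
            kept.append(p)
    report = {"input": len(pairs), "kept": len(kept),
              "retained_fraction": len(kept) / len(pairs) if pairs else 0.0}
    return kept, report


def estimate_mito_fraction(pairs_total: int, hits: list[HitRecord],
                           pairs: list[ReadPair] | None = None,
                           numerator: int | None = None,
                           min_aln_len: int = 100,
                           max_evalue: float = 1e-5) -> dict:
    """Conservative mitochondrial fraction: both mates, long alignments.

    The numerator counts pairs where BOTH mates have a hit with alignment
    length >= ``min_aln_len`` at E <= ``max_evalue``; the denominator is
    ``pairs_total``. When only the counts are known (published-table
    arithmetic), pass ``numerator`` directly.
    """
    if pairs_total < 1:
        raise ValueError("pairs_total must be >= 1")
    if numerator is None:
        got = _pair_hit_map(pairs or [], hits, max_evalue, min_aln_len)
        numerator = sum(1 for mates in got.values() if mates == {1, 2})
    fraction = round(100.0 * numerator / pairs_total, 2)
    return {"numerator": numerator, "denominator": pairs_total,
            "percent": fraction}


def summarize_retention(stage_counts: dict[str, list[int]]) -> dict:
    """Per-stage retention relative to the first (raw) stage, 2 decimals.

    ``stage_counts`` maps library name -> ordered counts, raw first.
    """
    out: dict[str, list[tuple[int, float]]] = {}
    for lib, counts in stage_counts.items():
        if not counts or counts[0] <= 0:
            raise ValueError(f"library {lib}: missing raw count")
        raw = counts[0]
        out[lib] = [(c, round(100.0 * c / raw, 2)) for c in counts]
    return out
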