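"""Pipeline driver: staged execution from a YAML/dict config.

Stage order: simulate -> readfilter -> contigs -> genes -> coverage ->
linkage -> taxassign. Each enabled stage either reads the files named in its
config section or consumes the in-memory products of an earlier enabled
stage (the usual self-contained route starts from ``simulate``). Inputs are
validated for every enabled stage before any stage runs. Every stage writes
TSV reports into the output directory; the run log records package version,
parameters and seed (no wall-clock content, so identical config + seed gives
byte-identical outputs).
"""

from __future__ import annotations

import zlib
from pathlib import Path

import yaml

from . import __version__
from .align import search_hits
from .contigs import MergePolicy, assembly_stats, detect_circular, \
    filter_mito_contigs, merge_assemblies
from .coverage import gene_coverage
from .genes import GeneAlignment, ReferenceGenes, bin_fragments, \
    build_supermatrix, curate_alignment, fragment_by_trna, star_align, \
    transfer_annotations
from .linkage import Bait, bait_contigs, \
    extract_barcode_region, summarize_linkage
from .readfilter import QC_HIGH, QC_LOW, filter_mito_pairs, quality_trim
from .records import Contig, SeqRecord, Taxonomy
from .seqio import read_blast_tab, read_fasta, read_fastq_pairs, \
    read_features, read_taxonomy, write_blast_tab, write_contig_fasta, \
    write_fasta, write_fastq_pairs, write_features, write_taxonomy
from .simulate import make_assembly_variants, make_community, shred_reads
from .taxassign import evaluate_assignments, root_on, tophit_assign, tree_assign

STAGES = ("simulate", "readfilter", "contigs", "genes", "coverage",
          "linkage", "taxassign")


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return path_or_dict
    with open(path_or_dict) as fh:
        return yaml.safe_load(fh)


def _validate(cfg: dict) -> None:
    stages = cfg.get("stages", [])
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    have_sim = "simulate" in stages
    need = {
        "readfilter": ["fastq1", "fastq2", "panel"],
        "contigs": ["sets"],
        "genes": ["contigs", "features", "reference"],
        "coverage": [],
        "linkage": ["baits"],
        "taxassign": ["taxonomy"],
    }
    for stage in stages:
        if stage == "simulate":
            continue
        section = cfg.get(stage, {}) or {}
        for key in need.get(stage, []):
            if key not in section and not have_sim:
                raise ValueError(
                    f"stage {stage!r} enabled but input {key!r} missing "
                    f"(and no simulate stage to provide it)")


class PipelineState:
    """In-memory products handed between stages."""

    def __init__(self) -> None:
        self.community = None
        self.pairs = None
        self.panel: list[Contig] | None = None
        self.panel_features = None
        self.taxonomy: Taxonomy | None = None
        self.contig_sets: dict[str, list[Contig]] | None = None
        self.nonredundant: list[Contig] | None = None
        self.features: dict | None = None
        self.reference: ReferenceGenes | None = None
        self.gene_alignments: dict[str, GeneAlignment] | None = None
        self.baits: list[Bait] | None = None
        self.links = None


def _tsv(path: Path, header: list[str], rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def run_pipeline(config, outdir=None) -> Path:
    cfg = load_config(config)
    _validate(cfg)
    out = Path(outdir or cfg.get("outdir", "mitosoup_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = cfg.get("stages", [])
    st = PipelineState()
    log: list[str] = [f"mitosoup {__version__}", f"seed {seed}",
                      f"stages {' '.join(stages)}"]

    if "simulate" in stages:
        _stage_simulate(cfg.get("simulate", {}) or {}, seed, st, out, log)
    if "readfilter" in stages:
        _stage_readfilter(cfg.get("readfilter", {}) or {}, st, out, log)
    if "contigs" in stages:
        _stage_contigs(cfg.get("contigs", {}) or {}, st, out, log)
    if "genes" in stages:
        _stage_genes(cfg.get("genes", {}) or {}, st, out, log)
    if "coverage" in stages:
        _stage_coverage(cfg.get("coverage", {}) or {}, st, out, log)
    if "linkage" in stages:
        _stage_linkage(cfg.get("linkage", {}) or {}, st, out, log)
    if "taxassign" in stages:
        _stage_taxassign(cfg.get("taxassign", {}) or {}, st, out, log)

    (out / "run.log").write_text("\n".join(log) + "\n")
    return out


# ------------------------------------------------------------- stages


def _stage_simulate(sc: dict, seed: int, st: PipelineState, out: Path,
                    log: list[str]) -> None:
    n_species = int(sc.get("n_species", 10))
    st.community = make_community(
        n_species,
        sigma=float(sc.get("sigma", 1.0)),
        haplotypes_per_species=int(sc.get("haplotypes_per_species", 2)),
        seed=seed)
    st.panel = st.community.panel()
    st.panel_features = st.community.feature_table()
    st.taxonomy = Taxonomy({sp.species_id: sp.lineage
                            for sp in st.community.species})
    n_pairs = int(sc.get("n_pairs", 2000))
    shred = shred_reads(st.community, n_pairs,
                        error_rate=float(sc.get("error_rate", 0.002)),
                        nuclear_fraction=float(sc.get("nuclear_fraction", 0.99)),
                        seed=seed)
    st.pairs = shred.pairs
    variants = make_assembly_variants(st.community, seed=seed,
                                      p_snp=float(sc.get("p_snp", 5e-4)),
                                      p_indel=float(sc.get("p_indel", 1e-4)))
    st.contig_sets = variants.sets
    st.variant_features = variants.features
    write_fastq_pairs(shred.pairs, out / "reads_1.fastq", out / "reads_2.fastq")
    shred.truth.to_csv(out / "reads_truth.tsv", sep="\t", index=False)
    variants.truth.to_csv(out / "contigs_truth.tsv", sep="\t", index=False)
    write_fasta([SeqRecord(c.id, c.seq) for c in st.panel], out / "panel.fasta")
    write_features(st.panel_features, out / "panel_features.tsv")
    write_taxonomy(st.taxonomy, out / "taxonomy.tsv")
    for lab, contigs in st.contig_sets.items():
        write_contig_fasta(contigs, out / f"assembly_{lab}.fasta")
    log.append(f"simulate n_species={n_species} n_pairs={n_pairs}")


def _stage_readfilter(sc: dict, st: PipelineState, out: Path,
                      log: list[str]) -> None:
    if st.pairs is None:
        st.pairs = read_fastq_pairs(sc["fastq1"], sc["fastq2"])
    if st.panel is None:
        st.panel = [Contig(r.id, r.seq) for r in read_fasta(sc["panel"])]
    params = QC_HIGH if sc.get("qc", "low") == "high" else QC_LOW
    kept, qc_report = quality_trim(st.pairs, params)
    if "hits" in sc:
        hits = read_blast_tab(sc["hits"])
    else:
        reads = [SeqRecord(f"{p.id}/{m}", s) for p in kept
                 for m, s in ((1, p.seq1), (2, p.seq2))]
        panel_recs = [SeqRecord(c.id, c.seq) for c in st.panel]
        hits = search_hits(reads, panel_recs, max_targets=1,
                           max_evalue=float(sc.get("max_evalue", 1e-5)))
        write_blast_tab(hits, out / "read_hits.tsv")
    mito, report = filter_mito_pairs(kept, hits, mode=sc.get("mode", "either"),
                                     max_evalue=float(sc.get("max_evalue", 1e-5)))
    st.pairs = mito
    _tsv(out / "retention.tsv", ["stage", "pairs", "pct_of_raw"], [
        ("raw", qc_report["input"], "100.00"),
        ("quality_controlled", qc_report["kept"],
         f"{100.0 * qc_report['kept'] / max(1, qc_report['input']):.2f}"),
        ("mitochondrial_like", report["kept"],
         f"{100.0 * report['kept'] / max(1, qc_report['input']):.2f}"),
    ])
    log.append(f"readfilter kept={report['kept']}/{qc_report['input']}")


def _stage_contigs(sc: dict, st: PipelineState, out: Path,
                   log: list[str]) -> None:
    if st.contig_sets is None:
        st.contig_sets = {lab: [Contig(r.id, r.seq, source=lab)
                                for r in read_fasta(path)]
                          for lab, path in sc["sets"].items()}
    if st.panel is None and "panel" in sc:
        st.panel = [Contig(r.id, r.seq) for r in read_fasta(sc["panel"])]
    sets = st.contig_sets
    if sc.get("filter", True) and st.panel:
        panel_recs = [SeqRecord(c.id, c.seq) for c in st.panel]
        filtered = {}
        for lab, contigs in sets.items():
            hits = search_hits([SeqRecord(c.id, c.seq) for c in contigs],
                               panel_recs, max_targets=1, max_evalue=1e-5,
                               stride=16)
            filtered[lab] = filter_mito_contigs(contigs, hits)
        sets = filtered
    if sc.get("circularize", True):
        sets = {lab: [detect_circular(c) for c in contigs]
                for lab, contigs in sets.items()}
    policy = MergePolicy(source_preference=tuple(sc.get(
        "source_preference", sorted(sets, reverse=True))))
    st.nonredundant, merge_report = merge_assemblies(sets, policy)
    write_contig_fasta(st.nonredundant, out / "nonredundant.fasta")
    stats = assembly_stats(st.nonredundant)
    rows = [("count", stats["count"]), ("min_bp", stats["min"]),
            ("max_bp", stats["max"]), ("mean_bp", stats["mean"]),
            ("n50_bp", stats["n50"]), ("total_bp", stats["total_length"])]
    rows += [(f"class_{k}", f"{v[0]} ({v[1]})")
             for k, v in stats["size_classes"].items()]
    _tsv(out / "assembly_stats.tsv", ["metric", "value"], rows)
    _tsv(out / "merge_report.tsv", ["event"],
         [(x,) for x in merge_report.merges + merge_report.conflicts])
    log.append(f"contigs nonredundant={len(st.nonredundant)}")


def _annotate_nonredundant(st: PipelineState) -> dict:
    """Features for merged contigs, transferred from the best panel genome."""
    feats = {}
    panel_by_id = {c.id: c for c in (st.panel or [])}
    for contig in st.nonredundant:
        best = None
        ckmers = {contig.seq[i:i + 21] for i in range(0, len(contig.seq) - 21)}
        for pid, p in panel_by_id.items():
            shared = sum(1 for i in range(0, len(p.seq) - 21, 33)
                         if p.seq[i:i + 21] in ckmers)
            if best is None or shared > best[0]:
                best = (shared, pid)
        if best is None or best[0] < 3:
            feats[contig.id] = []
            continue
        ref = panel_by_id[best[1]]
        feats[contig.id] = transfer_annotations(contig, ref,
                                                st.panel_features[best[1]])
    return feats


def _stage_genes(sc: dict, st: PipelineState, out: Path,
                 log: list[str]) -> None:
    if st.nonredundant is None:
        st.nonredundant = [Contig(r.id, r.seq,
                                  circular="circular=true" in r.desc)
                           for r in read_fasta(sc["contigs"])]
    if "features" in sc:
        st.features = read_features(sc["features"])
    elif st.panel is not None and st.panel_features is not None:
        st.features = _annotate_nonredundant(st)
    if "reference" in sc:
        ref_contig = [Contig(r.id, r.seq) for r in read_fasta(sc["reference"])][0]
        ref_feats = read_features(sc["reference_features"])[ref_contig.id]
        st.reference = ReferenceGenes.from_annotated(ref_contig, ref_feats)
    else:
        first = st.panel[0]
        st.reference = ReferenceGenes.from_annotated(
            first, st.panel_features[first.id])
    frags = []
    for contig in st.nonredundant:
        for s, e, seq in fragment_by_trna(contig, st.features.get(contig.id, [])):
            frags.append((contig.id, seq))
    gene_frags = bin_fragments(frags, st.reference)
    st.gene_alignments = {}
    for gene, ref_nt in st.reference.nt.items():
        members = {gf.contig_id: gf.seq for gf in gene_frags if gf.gene == gene}
        if not members:
            continue
        seqs = dict(members)
        seqs["__ref__"] = ref_nt
        aligned = star_align(seqs, center_id="__ref__", protein=False)
        aligned.pop("__ref__")
        st.gene_alignments[gene] = curate_alignment(gene, aligned)
    lengths = {c.id: len(c.seq) for c in st.nonredundant}
    sm10 = build_supermatrix(st.gene_alignments, "min_genes", min_genes=10)
    try:
        sm_anchor = build_supermatrix(st.gene_alignments, "gene_anchor",
                                      contig_lengths=lengths)
    except ValueError:
        sm_anchor = None
    st.supermatrix = sm10
    for gene, ga in st.gene_alignments.items():
        write_fasta([SeqRecord(i, ga.nt[i]) for i in ga.ids],
                    out / f"aln_{gene}_nt.fasta")
        write_fasta([SeqRecord(i, ga.aa[i]) for i in ga.ids],
                    out / f"aln_{gene}_aa.fasta")
    write_fasta([SeqRecord(t, sm10.matrix[t]) for t in sm10.taxa],
                out / "supermatrix_10plus.fasta")
    if sm_anchor:
        write_fasta([SeqRecord(t, sm_anchor.matrix[t]) for t in sm_anchor.taxa],
                    out / "supermatrix_nad4l2kb.fasta")
    _tsv(out / "gene_presence.tsv", ["contig", "n_genes"],
         sorted((c, sum(1 for ga in st.gene_alignments.values()
                        if c in ga.aa)) for c in lengths))
    log.append(f"genes alignments={len(st.gene_alignments)} "
               f"taxa10plus={len(sm10.taxa)}")


def _stage_coverage(sc: dict, st: PipelineState, out: Path,
                    log: list[str]) -> None:
    members = [SeqRecord(f"{g}::{i}", ga.nt[i].replace("-", ""))
               for g, ga in st.gene_alignments.items() for i in ga.ids]
    renamed = {}
    for g, ga in st.gene_alignments.items():
        renamed[g] = GeneAlignment(g, [f"{g}::{i}" for i in ga.ids],
                                   {f"{g}::{i}": ga.nt[i] for i in ga.ids},
                                   {f"{g}::{i}": ga.aa[i] for i in ga.ids})
    if "hits" in sc:
        hits = read_blast_tab(sc["hits"])
    else:
        reads = [SeqRecord(f"{p.id}/{m}", s) for p in (st.pairs or [])
                 for m, s in ((1, p.seq1), (2, p.seq2))]
        hits = search_hits(reads, members, max_targets=1, max_evalue=1e-5)
    ref_lengths = {g: len(nt) for g, nt in st.reference.nt.items()}
    report = gene_coverage(renamed, hits, ref_lengths)
    _tsv(out / "coverage.tsv",
         ["gene", "n_members", "aligned_nt", "contributing_bp", "mean_cov"],
         [(g, r["n_members"], r["aligned_nucleotides"],
           r["contributing_bases"], r["mean_coverage"])
          for g, r in sorted(report.items())])
    log.append(f"coverage genes={len(report)}")


def _make_sim_baits(st: PipelineState) -> list[Bait]:
    """PCR-style baits: cox1-5' (648 bp) of one haplotype per species."""
    baits = []
    for sp in st.community.species:
        cox1 = next(f for f in sp.features if f.gene == "cox1")
        hap = sp.haplotypes[zlib.crc32(sp.species_id.encode()) % len(sp.haplotypes)]
        seq = hap[cox1.start:cox1.start + 648]
        baits.append(Bait(f"bc_{sp.species_id}", seq,
                          morphospecies_id=sp.species_id,
                          family=sp.lineage.get("family", "")))
    return baits


def _stage_linkage(sc: dict, st: PipelineState, out: Path,
                   log: list[str]) -> None:
    if "baits" in sc:
        recs = read_fasta(sc["baits"])
        st.baits = [Bait(r.id, r.seq) for r in recs]
    else:
        st.baits = _make_sim_baits(st)
    refs = [SeqRecord(b.haplotype_id, b.seq) for b in st.baits]
    barcodes = {}
    for contig in st.nonredundant:
        hit = extract_barcode_region(contig, refs)
        if hit:
            barcodes[contig.id] = hit[0]
    links, contig_only, pcr_only = bait_contigs(
        barcodes, st.baits, threshold=float(sc.get("threshold", 98.0)))
    st.links = links
    summary = summarize_linkage(
        bait_groups={b.haplotype_id: b.morphospecies_id for b in st.baits},
        contig_groups={l.contig_id: l.morphospecies_id for l in links})
    _tsv(out / "links.tsv",
         ["contig_id", "haplotype_id", "pct_identity", "morphospecies"],
         [(l.contig_id, l.haplotype_id, l.pct_identity, l.morphospecies_id)
          for l in links])
    _tsv(out / "linkage_summary.tsv", ["quantity", "value"],
         sorted(summary.items()))
    log.append(f"linkage links={len(links)} contig_only={len(contig_only)} "
               f"pcr_only={len(pcr_only)}")


def _truth_tree(st: PipelineState, queries: dict[str, str]):
    """Reference topology from the true lineages, queries grafted at their
    species tips (synthetic stand-in for an inferred phylogeny)."""
    import dendropy

    tax = {sp.species_id: sp.lineage for sp in st.community.species}

    def nest(ids, ranks):
        if not ranks or len(ids) == 1:
            leaves = []
            for i in ids:
                qs = [q for q, s in queries.items() if s == i]
                leaves.append(f"({i},{','.join(qs)})" if qs else i)
            return ",".join(leaves)
        rank = ranks[0]
        groups: dict[str, list[str]] = {}
        for i in ids:
            groups.setdefault(tax[i].get(rank, "?"), []).append(i)
        parts = [f"({nest(g, ranks[1:])})" if len(g) > 1 else nest(g, ranks[1:])
                 for _, g in sorted(groups.items())]
        return ",".join(parts)

    ids = sorted(tax)
    nwk = f"({nest(ids, ['suborder', 'infraorder', 'superfamily', 'family'])});"
    return dendropy.Tree.get(data=nwk, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)


def _stage_taxassign(sc: dict, st: PipelineState, out: Path,
                     log: list[str]) -> None:
    from .seqio import read_newick

    if st.taxonomy is None:
        st.taxonomy = read_taxonomy(sc["taxonomy"])
    queries = {l.contig_id: l.morphospecies_id for l in (st.links or [])}
    records = []
    if "tree" in sc:
        tree = read_newick(sc["tree"])
    elif st.community is not None and queries:
        tree = _truth_tree(st, queries)
    else:
        tree = None
    if tree is not None:
        og = sc.get("outgroup")
        if not og and st.community is not None:
            og_sp = {s.species_id for s in st.community.species
                     if s.lineage.get("suborder") == "Adephaga"}
            og = sorted(og_sp | {q for q, s in queries.items() if s in og_sp})
        rooted = root_on(tree, og) if og else tree
        records.extend(tree_assign(rooted, st.taxonomy,
                                   sorted(queries)).values())
    # similarity route on the contig barcode regions vs the panel
    if st.panel is not None and st.nonredundant is not None:
        panel_recs = [SeqRecord(c.id, c.seq) for c in st.panel]
        contig_recs = [SeqRecord(c.id, c.seq) for c in st.nonredundant
                       if c.id in queries]
        hits = search_hits(contig_recs, panel_recs, max_targets=5,
                           max_evalue=1e-19, stride=16)
        records.extend(tophit_assign(hits, st.taxonomy).values())
    truth = Taxonomy({q: st.taxonomy.lineages[s] for q, s in queries.items()
                      if s in st.taxonomy.lineages}) if queries else st.taxonomy
    summary = evaluate_assignments(records, truth)
    _tsv(out / "assignments.tsv",
         ["query", "method", "rank", "taxon", "correct"],
         [(r.query_id, r.method, r.rank or "", r.taxon or "",
           "" if r.correct is None else r.correct) for r in records])
    _tsv(out / "assignment_summary.tsv", ["method", "family_success_pct"],
         sorted(summary["family_success_pct"].items()))
    log.append(f"taxassign records={len(records)}")
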