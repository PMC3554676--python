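"""End-to-end orchestration: run every stage on input files and emit the
report bundle (summary tables, candidate lists, scatter data, run manifest).

Stages: preprocess both libraries -> collapse to tags -> map to genome ->
classify against annotations and known matures -> two-library comparison and
length distribution -> conserved-family differential table -> novel-miRNA
hairpin discovery (+ star detection) -> target prediction for novel miRNAs ->
term enrichment of abundant-miRNA targets.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml
from Bio import SeqIO

from . import __version__
from .annotate import (
    aggregate_families,
    classify_tags,
    compare_libraries,
    length_distribution,
    load_gff3_features,
    map_to_genome,
)
from .differential import build_family_table, normalize_rpm
from .enrichment import enrich, filter_by_abundance
from .hairpin import HairpinThresholds, detect_star, discover
from .preprocess import (
    TrimConfig,
    collapse,
    fastq_reads,
    preprocess_library,
    round_half_up,
    summarize_preprocessing,
)
from .targets import DuplexRules, predict_targets

log = logging.getLogger("seedmir")


@dataclass
class PipelineConfig:
    """Inputs and thresholds for a full run.

    Threshold defaults are the conventional ones for plant miRNA annotation:
    inserts >= 18 nt are kept, hairpins must reach -20 kcal/mol with <= 6
    mature/star mismatches and <= 6 unpaired duplex nucleotides at 5-240 nt
    mature-star distance and 20-22 nt matures, duplexes allow <= 4 mismatch
    points (G:U = 0.5), families are flagged at P <= 0.01, and enrichment
    considers miRNAs sequenced > 50 times per million.
    """

    fastq_ds: str = "lib_ds.fastq"
    fastq_gs: str = "lib_gs.fastq"
    genome: str = "genome.fa"
    annotations: str = "annotations.gff3"
    known_mirnas: str = "known_mirnas.fa"
    transcripts: str = "transcripts.fa"
    term_map: str = "terms.tsv"
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    min_len: int = 18
    hairpin: HairpinThresholds = field(default_factory=HairpinThresholds)
    duplex: DuplexRules = field(default_factory=DuplexRules)
    flank: int = 250
    alpha: float = 0.01
    min_reads: float = 50.0
    fold_backend: str = "builtin"
    diff_method: str = "fisher"
    seed: int = 1
    outdir: str = "seedmir_out"

    def config_hash(self) -> str:
        """Hash of the analytic configuration (where outputs go does not
        change what is computed)."""
        d = asdict(self)
        d.pop("outdir")
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class ReportBundle:
    stats_ds: object = None
    stats_gs: object = None
    tags: list = field(default_factory=list)
    hits: dict = field(default_factory=dict)
    classes: dict = field(default_factory=dict)
    mapped_tags: list = field(default_factory=list)
    libsizes: tuple = (0, 0)
    comparison: object = None
    lengths: dict = field(default_factory=dict)
    families: list = field(default_factory=list)
    family_table: list = field(default_factory=list)
    candidates: list = field(default_factory=list)
    rejections: list = field(default_factory=list)
    targets: list = field(default_factory=list)
    enrichment: list = field(default_factory=list)
    abundant_novel: set = field(default_factory=set)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_term_map(path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            gene, term, *rest = line.rstrip("\n").split("\t")
            name = rest[0] if rest else ""
            out.setdefault(gene, []).append(f"{term}:{name}" if name else term)
    return out


def _stage(name: str):
    log.info("stage: %s", name)
    return time.time()


def run_all(cfg: PipelineConfig, indir: str | Path = ".") -> ReportBundle:
    """Run the full pipeline and write the report bundle under cfg.outdir."""
    indir = Path(indir)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")
    bundle = ReportBundle()
    t0 = time.time()

    def path(p):  # inputs may be absolute or relative to indir
        p = Path(p)
        return p if p.is_absolute() else indir / p

    try:
        stage = "preprocess"
        _stage(stage)
        trim = TrimConfig(adapter3=cfg.adapter3, adapter5=cfg.adapter5, min_len=cfg.min_len)
        inserts_ds, bundle.stats_ds = preprocess_library(fastq_reads(path(cfg.fastq_ds)), trim)
        inserts_gs, bundle.stats_gs = preprocess_library(fastq_reads(path(cfg.fastq_gs)), trim)

        stage = "collapse"
        _stage(stage)
        bundle.tags = collapse([inserts_ds, inserts_gs])

        stage = "map_to_genome"
        _stage(stage)
        genome = read_fasta(path(cfg.genome))
        bundle.hits = map_to_genome(bundle.tags, genome)
        bundle.mapped_tags = [t for t in bundle.tags if bundle.hits.get(t.sequence)]
        bundle.libsizes = (
            sum(t.counts[0] for t in bundle.mapped_tags),
            sum(t.counts[1] for t in bundle.mapped_tags),
        )

        stage = "classify"
        _stage(stage)
        features = load_gff3_features(path(cfg.annotations))
        known = read_fasta(path(cfg.known_mirnas))
        bundle.classes = classify_tags(bundle.tags, bundle.hits, features, known)

        stage = "compare_libraries"
        _stage(stage)
        bundle.comparison = compare_libraries(bundle.mapped_tags)
        bundle.lengths = length_distribution(bundle.tags)

        stage = "families"
        _stage(stage)
        bundle.families = aggregate_families(bundle.tags, bundle.classes, known)
        bundle.family_table = build_family_table(
            bundle.families, max(bundle.libsizes[0], 1), max(bundle.libsizes[1], 1),
            alpha=cfg.alpha, method=cfg.diff_method,
        )

        stage = "hairpin_discovery"
        _stage(stage)
        candidates, bundle.rejections = discover(
            bundle.mapped_tags, bundle.hits, genome, bundle.classes,
            thresholds=cfg.hairpin, flank=cfg.flank, backend=cfg.fold_backend,
        )
        candidates = _keep_dominant_arm(candidates, bundle.tags)
        bundle.candidates = detect_star(candidates, bundle.tags)
        for cand in bundle.candidates:
            mat_dna = cand.mature_seq.replace("U", "T")
            if mat_dna in bundle.classes:
                bundle.classes[mat_dna] = "novel_miRNA"
            for star in cand.star_tags:
                bundle.classes[star.replace("U", "T")] = "novel_miRNA"

        stage = "target_prediction"
        _stage(stage)
        transcripts = read_fasta(path(cfg.transcripts))
        novel = {
            f"novel-mir-{i + 1}": c.mature_seq
            for i, c in enumerate(
                sorted(bundle.candidates, key=lambda c: (c.locus, c.mature_seq))
            )
        }
        bundle.targets = predict_targets(novel, transcripts, cfg.duplex)

        stage = "enrichment"
        _stage(stage)
        counts = {t.sequence: t.counts for t in bundle.tags}
        libsize_ds, libsize_gs = (max(s, 1) for s in bundle.libsizes)
        rpm = {
            mid: normalize_rpm(sum(counts.get(seq.replace("U", "T"), (0, 0))), libsize_ds + libsize_gs)
            for mid, seq in novel.items()
        }
        bundle.abundant_novel = filter_by_abundance(rpm, cfg.min_reads)
        term_map = read_term_map(path(cfg.term_map))
        background = list(transcripts)
        target_genes = sorted(
            {d.transcript_id for d in bundle.targets if d.mirna_id in bundle.abundant_novel}
        )
        bundle.enrichment = enrich(target_genes, background, term_map) if target_genes else []

        stage = "report"
        _stage(stage)
        write_reports(cfg, bundle, outdir)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return bundle


def _keep_dominant_arm(candidates, tags):
    """Collapse candidates with overlapping precursor loci (either strand —
    the reverse complement of a hairpin is itself a hairpin) to the most
    abundant tag: the dominant arm is the mature, the rest are star/noise."""
    counts = {t.sequence: sum(t.counts) for t in tags}

    def total(c):
        return counts.get(c.mature_seq.replace("U", "T"), 0)

    kept = []
    for cand in sorted(candidates, key=lambda c: (-total(c), c.locus, c.mature_seq)):
        chrom, lo, hi, _strand = cand.locus
        clash = any(
            k.locus[0] == chrom and lo < k.locus[2] and k.locus[1] < hi for k in kept
        )
        if not clash:
            kept.append(cand)
    return kept


# ----------------------------------------------------------------------------
# report writing


def _header(cfg: PipelineConfig) -> str:
    return (
        f"# seedmir {__version__}\n"
        f"# config_hash: {cfg.config_hash()}\n"
        f"# seed: {cfg.seed}\n"
    )


def write_reports(cfg: PipelineConfig, bundle: ReportBundle, outdir: Path) -> None:
    hdr = _header(cfg)

    with open(outdir / "Table1.tsv", "w") as fh:
        fh.write(hdr)
        fh.write("category\tDS_count\tDS_percent\tGS_count\tGS_percent\n")
        rows_ds = summarize_preprocessing(bundle.stats_ds)
        rows_gs = summarize_preprocessing(bundle.stats_gs)
        for cat in rows_ds:
            c1, p1 = rows_ds[cat]
            c2, p2 = rows_gs[cat]
            fh.write(
                f"{cat}\t{c1}\t{'' if p1 is None else p1}\t{c2}\t{'' if p2 is None else p2}\n"
            )

    # Table 2: per-class distinct and total signatures among genome-matched tags
    with open(outdir / "Table2.tsv", "w") as fh:
        fh.write(hdr)
        fh.write(
            "class\tDS_distinct\tDS_distinct_pct\tDS_total\tDS_total_pct"
            "\tGS_distinct\tGS_distinct_pct\tGS_total\tGS_total_pct\n"
        )
        per_class: dict[str, list[int]] = {}
        tot = [0, 0, 0, 0]  # ds_distinct, ds_total, gs_distinct, gs_total
        for t in bundle.mapped_tags:
            cls = bundle.classes.get(t.sequence, "other")
            row = per_class.setdefault(cls, [0, 0, 0, 0])
            if t.counts[0]:
                row[0] += 1
                row[1] += t.counts[0]
                tot[0] += 1
                tot[1] += t.counts[0]
            if t.counts[1]:
                row[2] += 1
                row[3] += t.counts[1]
                tot[2] += 1
                tot[3] += t.counts[1]
        order = [
            "snoRNA", "snRNA", "tRNA", "rRNA", "siRNA", "exon_antisense", "exon_sense",
            "intron_antisense", "intron_sense", "known_miRNA", "novel_miRNA", "other",
        ]
        for cls in order:
            row = per_class.get(cls, [0, 0, 0, 0])
            pcts = [
                round_half_up(100.0 * row[i] / tot[i]) if tot[i] else 0.0 for i in range(4)
            ]
            fh.write(
                f"{cls}\t{row[0]}\t{pcts[0]}\t{row[1]}\t{pcts[1]}"
                f"\t{row[2]}\t{pcts[2]}\t{row[3]}\t{pcts[3]}\n"
            )
        fh.write(f"Total\t{tot[0]}\t\t{tot[1]}\t\t{tot[2]}\t\t{tot[3]}\t\n")

    with open(outdir / "Table3.tsv", "w") as fh:
        fh.write(hdr)
        fh.write("subset\tunique_reads\tunique_pct\ttotal_reads\ttotal_pct\n")
        c = bundle.comparison
        p = c.percentages()
        fh.write(f"total\t{c.unique_total}\t100.00\t{c.reads_total}\t100.00\n")
        fh.write(f"shared\t{c.shared_unique}\t{p['shared_unique']}\t{c.shared_total}\t{p['shared_total']}\n")
        fh.write(f"ds_specific\t{c.ds_specific_unique}\t{p['ds_specific_unique']}\t{c.ds_specific_total}\t{p['ds_specific_total']}\n")
        fh.write(f"gs_specific\t{c.gs_specific_unique}\t{p['gs_specific_unique']}\t{c.gs_specific_total}\t{p['gs_specific_total']}\n")

    with open(outdir / "Table4.tsv", "w") as fh:
        fh.write(hdr)
        fh.write("family\tDS\tGS\tratio_DS_GS\tp_value\tsignificant\tdirection\n")
        for row in bundle.family_table:
            ratio = "" if row.ratio is None else ("inf" if row.ratio == float("inf") else row.ratio)
            fh.write(
                f"{row.family}\t{row.count_ds}\t{row.count_gs}\t{ratio}"
                f"\t{row.p_value:.3g}\t{'**' if row.significant else ''}\t{row.direction}\n"
            )

    with open(outdir / "length_distribution.tsv", "w") as fh:
        fh.write(hdr)
        fh.write("length\tunique_tags\ttotal_reads\n")
        for length, row in bundle.lengths.items():
            fh.write(f"{length}\t{row['unique']}\t{row['total']}\n")

    with open(outdir / "novel_candidates.tsv", "w") as fh:
        fh.write(hdr)
        fh.write(
            "mature\tchrom\tstart\tend\tstrand\tarm\tprecursor_len\tmfe\tamfe\tmfei"
            "\tn_mismatch\tn_unpaired\tdistance\tstar_reads\n"
        )
        for c2 in bundle.candidates:
            chrom, lo, hi, strand = c2.locus
            fh.write(
                f"{c2.mature_seq}\t{chrom}\t{lo}\t{hi}\t{strand}\t{c2.arm}"
                f"\t{len(c2.precursor)}\t{c2.mfe:.1f}\t{c2.amfe:.2f}\t{c2.mfei:.3f}"
                f"\t{c2.n_mismatch}\t{c2.n_unpaired}\t{c2.distance}\t{c2.star_reads}\n"
            )

    with open(outdir / "precursors.fa", "w") as fh:
        for i, c2 in enumerate(bundle.candidates):
            fh.write(f">novel-mir-{i + 1} {c2.locus}\n{c2.precursor}\n{c2.structure.dotbracket}\n")

    with open(outdir / "targets.tsv", "w") as fh:
        fh.write(hdr)
        fh.write("mirna\ttranscript\tstart\tend\tscore\tscore_1_12\tcleavage_site\talignment\n")
        for d in bundle.targets:
            fh.write(
                f"{d.mirna_id}\t{d.transcript_id}\t{d.site[0]}\t{d.site[1]}"
                f"\t{d.score}\t{d.score_1_12}\t{d.cleavage_site}\t{d.alignment()}\n"
            )

    with open(outdir / "enrichment.tsv", "w") as fh:
        fh.write(hdr)
        fh.write("term\tk\tK\tn\tN\tp_value\tp_adjusted\n")
        for r in bundle.enrichment:
            fh.write(f"{r.term}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t{r.p_value:.4g}\t{r.p_adjusted:.4g}\n")

    with open(outdir / "scatter_ds_gs.tsv", "w") as fh:
        fh.write(hdr)
        fh.write("sequence\tcount_ds\tcount_gs\n")
        for t in bundle.tags:
            fh.write(f"{t.sequence}\t{t.counts[0]}\t{t.counts[1]}\n")

    manifest = {
        "seedmir_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "config": asdict(cfg),
        "n_tags": len(bundle.tags),
        "n_mapped_tags": len(bundle.mapped_tags),
        "libsizes": list(bundle.libsizes),
        "n_novel_candidates": len(bundle.candidates),
        "n_targets": len(bundle.targets),
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True, default_flow_style=False)
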