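"""Synthetic-data generator: determinism, conservation, planted-truth
validity, and sampling-error recovery of planted ratios and categories."""

from __future__ import annotations

import math

import pytest

from seedmir.hairpin import HairpinCandidate, evaluate_candidate
from seedmir.preprocess import TrimConfig, collapse, preprocess_library
from seedmir.simulate import (
    GenomeTooShort,
    SimConfig,
    build_genome,
    build_transcriptome,
    simulate_all,
    simulate_libraries,
)


def tiny_cfg(**kw) -> SimConfig:
    base = dict(
        seed=7,
        genome_length=20_000,
        n_planted_hairpins=3,
        n_known_mirnas=6,
        n_known_families=3,
        n_ncrna_loci=5,
        n_genes=2,
        n_other_tags=25,
        n_unmapped_tags=5,
        n_transcripts=8,
        library_depths=(5_000, 5_000),
        error_rate=0.0,
    )
    base.update(kw)
    return SimConfig(**base)


class TestBuildGenome:
    def test_zero_hairpins_empty_truth(self):
        genome, truth = build_genome(tiny_cfg(n_planted_hairpins=0))
        assert truth.planted_mirnas == []
        assert len(genome["chr1"]) == 20_000

    def test_deterministic_given_seed(self, tmp_path):
        t1 = simulate_all(tiny_cfg(), tmp_path / "a")
        t2 = simulate_all(tiny_cfg(), tmp_path / "b")
        for name in ("genome.fa", "lib_ds.fastq", "lib_gs.fastq", "transcripts.fa",
                     "annotations.gff3", "known_mirnas.fa", "terms.tsv", "truth.yaml"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes(), name
        assert t1.planted_ratios == t2.planted_ratios

    def test_planted_precursors_pass_evaluator(self, small_truth):
        """Every planted precursor, refolded from scratch, satisfies all the
        stem-loop criteria under default thresholds."""
        genome, truth = small_truth
        assert truth.precursors
        for p in truth.precursors:
            res = evaluate_candidate(p["precursor"], p["mature"])
            assert isinstance(res, HairpinCandidate), p["mature"]

    def test_precursor_lengths_in_observed_range(self, small_truth):
        _, truth = small_truth
        for p in truth.precursors:
            assert 64 <= len(p["precursor"]) <= 371

    def test_precursors_embedded_at_recorded_locus(self, small_truth):
        genome, truth = small_truth
        for mature, (chrom, lo, hi, strand), arm in truth.planted_mirnas:
            window = genome[chrom][lo:hi].replace("T", "U")
            pre = next(
                p["precursor"] for p in truth.precursors if p["mature"] == mature
            )
            assert window == pre

    def test_genome_too_short_fails_loudly(self):
        with pytest.raises(GenomeTooShort):
            build_genome(tiny_cfg(genome_length=900))


class TestBuildTranscriptome:
    def test_every_transcript_has_a_term(self, small_cfg):
        genome, truth = build_genome(small_cfg)
        transcripts, term_map = build_transcriptome(small_cfg, truth)
        assert set(term_map) == set(transcripts)
        assert all(term_map[t] for t in term_map)

    def test_sites_written_into_transcripts(self, small_cfg):
        genome, truth = build_genome(small_cfg)
        transcripts, _ = build_transcriptome(small_cfg, truth)
        for t in truth.planted_targets:
            s = t["site_start"]
            window = transcripts[t["transcript_id"]][s : s + len(t["mirna"])]
            assert window == t["site_seq"].replace("U", "T")


class TestSimulateLibraries:
    def test_depth_conservation(self):
        cfg = tiny_cfg()
        _, truth = build_genome(cfg)
        ds, gs = simulate_libraries(cfg, truth)
        assert (len(ds), len(gs)) == cfg.library_depths

    def test_zero_depth_empty_library(self):
        cfg = tiny_cfg(library_depths=(0, 100))
        _, truth = build_genome(cfg)
        ds, gs = simulate_libraries(cfg, truth)
        assert ds == [] and len(gs) == 100

    def test_round_trip_collapse_equals_emitted_counts(self):
        """With no sequencing errors, the preprocessing pipeline recovers the
        simulator's per-tag counts exactly."""
        cfg = tiny_cfg(library_depths=(10_000, 10_000), error_rate=0.0)
        _, truth = build_genome(cfg)
        ds, gs = simulate_libraries(cfg, truth)
        trim = TrimConfig(adapter3=cfg.adapter3, adapter5=cfg.adapter5)
        qual = [40] * cfg.read_length
        ins_ds, _ = preprocess_library(((s, qual) for s, _ in ds), trim)
        ins_gs, _ = preprocess_library(((s, qual) for s, _ in gs), trim)
        tags = {t.sequence: t.counts for t in collapse([ins_ds, ins_gs])}
        for tag_id, (eds, egs) in truth.emitted_counts.items():
            t = truth.tags[tag_id]
            if len(t.sequence) < trim.min_len:
                continue  # removed by the length filter, as designed
            assert tags.get(t.sequence, (0, 0)) == (eds, egs), tag_id

    def test_planted_ratio_recovered_within_3sd(self):
        """A planted DS:GS ratio of 7.7 at 1e5 reads/library is recovered:
        the empirical count ratio lands within 3 SD (delta-method binomial
        oracle) of the exact expected ratio, and after library-composition
        normalization the expected ratio is exactly 7.7."""
        probe = tiny_cfg()
        _, truth0 = build_genome(probe)
        known = [t for t in truth0.tags.values() if t.tag_id.startswith("known_")]
        tag_id = max(known, key=lambda t: t.weight).tag_id
        cfg = tiny_cfg(
            library_depths=(100_000, 100_000), fold_change_spec=[(tag_id, 7.7)]
        )
        _, truth = build_genome(cfg)
        simulate_libraries(cfg, truth)
        eds, egs = truth.emitted_counts[tag_id]
        d_ds, d_gs = cfg.library_depths
        mu_ds, mu_gs = d_ds * truth.p_ds[tag_id], d_gs * truth.p_gs[tag_id]
        expected_ratio = mu_ds / mu_gs
        sd = expected_ratio * math.sqrt(1 / mu_ds + 1 / mu_gs)
        assert abs(eds / egs - expected_ratio) <= 3 * sd
        # composition factor: any flat (ratio-1) tag measures the Z_ds/Z_gs shift
        flat = next(
            t for t in truth.tags.values() if t.ratio == 1.0 and t.tag_id != tag_id
        )
        factor = (d_ds * truth.p_ds[flat.tag_id]) / (d_gs * truth.p_gs[flat.tag_id])
        assert expected_ratio / factor == pytest.approx(7.7, rel=1e-9)

    def test_junk_category_proportions_recovered(self):
        """Preprocessing category counts match the configured junk fractions
        within 3 SD (multinomial oracle)."""
        cfg = tiny_cfg(library_depths=(50_000, 50_000))
        _, truth = build_genome(cfg)
        ds, _ = simulate_libraries(cfg, truth)
        trim = TrimConfig(adapter3=cfg.adapter3, adapter5=cfg.adapter5)
        qual = [40] * cfg.read_length
        _, stats = preprocess_library(((s, qual) for s, _ in ds), trim)
        depth = cfg.library_depths[0]
        short_tag_mass = sum(
            truth.p_ds[t.tag_id] for t in truth.tags.values() if len(t.sequence) < 18
        )
        expected = {
            "adaptor3_null": cfg.frac_no_adapter,
            "insert_null": cfg.frac_insert_null,
            "adaptor5_contaminants": cfg.frac_adapter5,
            "small_than_18nt": cfg.frac_short + short_tag_mass,
            "polyA": cfg.frac_polya,
        }
        for cat, frac in expected.items():
            mu = depth * frac
            sd = math.sqrt(depth * frac * (1 - frac))
            assert abs(stats.categories[cat] - mu) <= 3 * sd + 1, cat
        # low-quality reads are excluded before categorization
        mu_lq = depth * cfg.frac_lowq
        sd_lq = math.sqrt(mu_lq * (1 - cfg.frac_lowq))
        assert abs((stats.total_reads - stats.high_quality) - mu_lq) <= 3 * sd_lq + 1

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(frac_lowq=1.2).validate()
        with pytest.raises(ValueError):
            SimConfig(insert_length_distribution={20: 0.0}).validate()
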