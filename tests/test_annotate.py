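"""Genome mapping vs brute-force scan, classification precedence, family
aggregation, and two-library comparison arithmetic."""

from __future__ import annotations

import numpy as np
import pytest

from seedmir.annotate import (
    Feature,
    LibraryComparison,
    aggregate_families,
    classify_tags,
    compare_libraries,
    length_distribution,
    map_to_genome,
    parse_family,
)
from seedmir.hairpin import revcomp
from seedmir.preprocess import SmallRNATag


def brute_force_hits(tag: str, genome: dict[str, str]):
    """Independent exhaustive substring scan over both strands."""
    out = []
    for chrom, seq in genome.items():
        L = len(tag)
        for i in range(len(seq) - L + 1):
            if seq[i : i + L] == tag:
                out.append((chrom, i, i + L, "+"))
            if revcomp(seq[i : i + L]) == tag:
                out.append((chrom, i, i + L, "-"))
    return out


class TestMapToGenome:
    def test_forward_hit(self):
        genome = {"chr1": "A" * 50 + "CCGGTTAACCGGTTAACCGG" + "A" * 50}
        tags = [SmallRNATag("CCGGTTAACCGGTTAACCGG", (1, 0))]
        hits = map_to_genome(tags, genome)
        assert ("chr1", 50, 70, "+") in hits["CCGGTTAACCGGTTAACCGG"]

    def test_minus_strand_hit(self):
        genome = {"chr1": "T" * 40 + "CCGGATAACCGGTTAACCGG" + "T" * 40}
        tag = revcomp("CCGGATAACCGGTTAACCGG")
        hits = map_to_genome([SmallRNATag(tag, (1, 0))], genome)
        assert ("chr1", 40, 60, "-") in hits[tag]

    def test_unmatched_tag_empty(self):
        hits = map_to_genome([SmallRNATag("G" * 20, (1, 0))], {"chr1": "A" * 1000})
        assert hits["G" * 20] == []

    def test_equals_brute_force_on_10kb(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 10_000))}
        tags = []
        for _ in range(30):  # tags drawn from the genome, both strands
            s = int(rng.integers(0, 9_975))
            seq = genome["chr1"][s : s + 21]
            tags.append(SmallRNATag(seq if rng.random() < 0.5 else revcomp(seq), (1, 1)))
        hits = map_to_genome(tags, genome)
        for t in tags:
            assert sorted(hits[t.sequence]) == sorted(brute_force_hits(t.sequence, genome))


class TestClassify:
    GENOME = {"chr1": "".join(np.random.default_rng(5).choice(list("ACGT"), 3000))}

    def _tag_at(self, start, end, strand="+"):
        seq = self.GENOME["chr1"][start:end]
        return SmallRNATag(seq if strand == "+" else revcomp(seq), (1, 0))

    def test_rrna_outranks_known_mirna(self):
        tag = self._tag_at(100, 121)
        feats = [Feature("chr1", 90, 200, "+", "rRNA")]
        known = {"zma-miR1": tag.sequence}
        hits = map_to_genome([tag], self.GENOME)
        assert classify_tags([tag], hits, feats, known)[tag.sequence] == "rRNA"

    def test_known_mirna_exact_match(self):
        tag = self._tag_at(500, 521)
        hits = map_to_genome([tag], self.GENOME)
        cls = classify_tags([tag], hits, [], {"zma-miR9999": tag.sequence})
        assert cls[tag.sequence] == "known_miRNA"

    def test_exon_antisense(self):
        tag = self._tag_at(1000, 1021, strand="-")
        feats = [Feature("chr1", 980, 1100, "+", "exon")]
        hits = map_to_genome([tag], self.GENOME)
        assert classify_tags([tag], hits, feats, {})[tag.sequence] == "exon_antisense"

    def test_intron_sense(self):
        tag = self._tag_at(1500, 1522)
        feats = [Feature("chr1", 1400, 1600, "+", "intron")]
        hits = map_to_genome([tag], self.GENOME)
        assert classify_tags([tag], hits, feats, {})[tag.sequence] == "intron_sense"

    def test_unmapped_tag_is_other(self):
        tag = SmallRNATag("G" * 21, (1, 0))
        assert classify_tags([tag], {tag.sequence: []}, [], {})[tag.sequence] == "other"

    def test_order_independent(self, rng):
        tags = [self._tag_at(i * 40, i * 40 + 21) for i in range(20)]
        feats = [
            Feature("chr1", 0, 200, "+", "tRNA"),
            Feature("chr1", 300, 600, "-", "exon"),
        ]
        hits = map_to_genome(tags, self.GENOME)
        a = classify_tags(tags, hits, feats, {})
        b = classify_tags(list(reversed(tags)), hits, feats, {})
        assert a == b


class TestFamilies:
    def test_parse_family(self):
        assert parse_family("zma-miR156a-5p") == "MIR156"
        assert parse_family("zma-miR156d") == "MIR156"
        assert parse_family("osa-miR1432") == "MIR1432"
        assert parse_family("weird-name") == "UNKNOWN"

    def test_two_members_one_family(self):
        known = {"zma-miR156a": "ACGUACGUACGUACGUACGUA", "zma-miR156d": "CCGUACGUACGUACGUACGUA"}
        tags = [
            SmallRNATag("ACGTACGTACGTACGTACGTA", (5, 2)),
            SmallRNATag("CCGTACGTACGTACGTACGTA", (3, 1)),
        ]
        classes = {t.sequence: "known_miRNA" for t in tags}
        fams = aggregate_families(tags, classes, known)
        assert len(fams) == 1
        assert fams[0].family == "MIR156"
        assert len(fams[0].members) == 2
        assert fams[0].counts == (8, 3)

    def test_empty_input(self):
        assert aggregate_families([], {}, {}) == []

    def test_simulated_families_recovered(self, small_truth):
        _, truth = small_truth
        tags = [
            SmallRNATag(t.sequence, (10, 10))
            for t in truth.tags.values()
            if t.annotation_class == "known_miRNA"
        ]
        classes = {t.sequence: "known_miRNA" for t in tags}
        fams = aggregate_families(tags, classes, truth.known_mature)
        expected = {parse_family(mid) for mid in truth.known_mature}
        assert {f.family for f in fams} == expected


class TestCompareLibraries:
    def test_partition_identity(self, rng):
        seqs = {"".join(rng.choice(list("ACGT"), 20)) for _ in range(200)}
        tags = [
            SmallRNATag(s, (int(rng.integers(0, 5)), int(rng.integers(0, 5))))
            for s in sorted(seqs)
        ]
        tags = [t for t in tags if sum(t.counts)]
        c = compare_libraries(tags)
        assert c.shared_unique + c.ds_specific_unique + c.gs_specific_unique == len(tags)
        assert c.reads_total == sum(sum(t.counts) for t in tags)

    def test_printed_percentages(self):
        c = LibraryComparison(
            shared_unique=495034,
            ds_specific_unique=640849,
            gs_specific_unique=2318749,
            shared_total=16754063,
            ds_specific_total=2370868,
            gs_specific_total=2952077,
        )
        assert c.unique_total == 3454632
        assert c.reads_total == 22077008
        p = c.percentages()
        assert p["shared_unique"] == 14.33
        assert p["shared_total"] == 75.89
        assert p["ds_specific_unique"] == 18.55
        assert p["gs_specific_unique"] == 67.12

    def test_one_sided_library(self):
        tags = [SmallRNATag("ACGTACGTACGTACGTAC", (3, 0))]
        c = compare_libraries(tags)
        assert c.percentages()["shared_unique"] == 0.0


class TestLengthDistribution:
    def test_unique_and_total(self):
        tags = [
            SmallRNATag("A" * 10 + "C" * 11, (1, 0)),
            SmallRNATag("C" * 10 + "G" * 11, (2, 0)),
            SmallRNATag("G" * 10 + "T" * 11, (0, 3)),
        ]
        hist = length_distribution(tags)
        assert hist == {21: {"unique": 3, "total": 6}}

    def test_empty(self):
        assert length_distribution([]) == {}
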