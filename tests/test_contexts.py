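"""Context classification, catalog assembly, and genome-aberration summaries."""

import numpy as np
import pandas as pd
import pytest

from oracles import (
    aberration_oracle,
    all_dbs_events,
    dbs_class_count,
    dbs_equivalent,
    id83_oracle,
    left_align_deletion,
    left_align_insertion,
    sbs96_oracle,
)
from sigkit.contexts import (
    CNSegment,
    ContextMismatchError,
    MutationRecord,
    NormalizationError,
    SchemaMismatchError,
    SVEvent,
    UnclassifiableError,
    build_catalog,
    classify_cn,
    classify_dbs,
    classify_id,
    classify_sbs,
    classify_sv,
    collapse_strand,
    genome_aberration_fraction,
)
from sigkit.genome import GeneInterval, GenomeBoundsError, SequenceGenome
from sigkit.schemas import DBS78, ID83, SBS96, SBS288, default_cn_schema, default_sv_schema


class TestClassifySBS:
    def test_purine_reference_is_reverse_complemented(self):
        g = SequenceGenome({"1": "AGC"})
        assert classify_sbs(MutationRecord("s", "1", 2, "G", "T"), g) == "G[C>A]T"

    def test_intergenic_stranded_prefix(self):
        g = SequenceGenome({"1": "AACAA"})
        rec = MutationRecord("s", "1", 3, "C", "T")
        assert classify_sbs(rec, g, stranded=True) == "N:A[C>T]A"

    def test_reference_mismatch_raises(self):
        g = SequenceGenome({"1": "AAA"})
        with pytest.raises(ContextMismatchError):
            classify_sbs(MutationRecord("s", "1", 2, "C", "T"), g)

    def test_ambiguous_flank_raises(self):
        g = SequenceGenome({"1": "NCA"})
        with pytest.raises(UnclassifiableError):
            classify_sbs(MutationRecord("s", "1", 2, "C", "T"), g)

    def test_out_of_genome_raises(self):
        g = SequenceGenome({"1": "CA"})
        with pytest.raises(GenomeBoundsError):
            classify_sbs(MutationRecord("s", "1", 1, "C", "T"), g)

    def test_agrees_with_enumeration_oracle_on_random_events(self):
        """1,000 random draws vs membership scanning of all 96 labels."""
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        for _ in range(1000):
            tri = "".join(rng.choice(bases, 3))
            ref = tri[1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            g = SequenceGenome({"1": tri})
            rec = MutationRecord("s", "1", 2, ref, alt)
            assert classify_sbs(rec, g) == sbs96_oracle(tri, ref, alt)

    def test_strand_complement_symmetry(self):
        """The same biological event on either strand yields one label."""
        rng = np.random.default_rng(12)
        bases = np.array(list("ACGT"))
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for _ in range(200):
            tri = "".join(rng.choice(bases, 3))
            ref = tri[1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            rc_tri = "".join(comp[b] for b in reversed(tri))
            a = classify_sbs(MutationRecord("s", "1", 2, ref, alt), SequenceGenome({"1": tri}))
            b = classify_sbs(
                MutationRecord("s", "1", 2, comp[ref], comp[alt]),
                SequenceGenome({"1": rc_tri}),
            )
            assert a == b

    def test_stranded_prefixes(self, toy_genome):
        """Pyrimidine on the template strand gives T:, otherwise U:.

        geneA (plus strand, so template is the minus strand) covers
        chr1:11-30 alone: a pyrimidine reference there reads U:, a purine
        reference T:.
        """
        for pos in range(12, 30):
            ref = toy_genome.base("chr1", pos)
            alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref]
            label = classify_sbs(
                MutationRecord("s", "chr1", pos, ref, alt), toy_genome, stranded=True
            )
            expected = "U" if ref in "CT" else "T"
            assert label.split(":")[0] == expected

    def test_both_strand_overlap_resolved_by_longest_gene(self, toy_genome):
        # 31-40 overlaps geneA (len 30) and geneB (len 50): geneB (minus) wins,
        # so its template is the plus strand and pyrimidine references read T:
        for pos in range(32, 40):
            ref = toy_genome.base("chr1", pos)
            alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref]
            label = classify_sbs(
                MutationRecord("s", "chr1", pos, ref, alt), toy_genome, stranded=True
            )
            expected = "T" if ref in "CT" else "U"
            assert label.split(":")[0] == expected


class TestClassifyDBS:
    def test_canonical_passthrough_and_revcomp(self):
        assert classify_dbs(MutationRecord("s", "1", 1, "CC", "TT")) == "CC>TT"
        assert classify_dbs(MutationRecord("s", "1", 1, "GG", "AA")) == "CC>TT"

    def test_all_events_map_to_78_consistent_classes(self):
        """Exhaustive check of all 144 doublet events.

        The classifier must produce exactly 78 distinct labels, each label
        must describe the event it was produced for (directly or via
        reverse complement), and reverse-complement-equivalent events must
        share a label.
        """
        assert dbs_class_count() == 78
        labels = {}
        for ref, alt in all_dbs_events():
            lab = classify_dbs(MutationRecord("s", "1", 1, ref, alt))
            lref, lalt = lab.split(">")
            assert dbs_equivalent((lref, lalt), (ref, alt)) or dbs_equivalent(
                (ref, alt), (lref, lalt)
            )
            labels[(ref, alt)] = lab
        assert len(set(labels.values())) == 78
        for ref, alt in all_dbs_events():
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            rc = lambda s: "".join(comp[b] for b in reversed(s))
            assert labels[(ref, alt)] == labels[(rc(ref), rc(alt))]

    def test_partial_doublet_rejected(self):
        with pytest.raises(UnclassifiableError):
            classify_dbs(MutationRecord("s", "1", 1, "CC", "CT"))


def _random_indel_record(rng, seq):
    """A random left-aligned anchored indel on ``seq`` (or None)."""
    n = len(seq)
    if rng.random() < 0.5:  # deletion
        L = int(rng.integers(1, 7))
        s0 = int(rng.integers(1, n - L))
        s0 = left_align_deletion(seq, s0, L)
        if s0 < 1:
            return None
        pos = s0  # 1-based anchor = s0 (0-based s0-1)
        ref = seq[s0 - 1 : s0 + L]
        alt = seq[s0 - 1]
        return MutationRecord("s", "1", pos, ref, alt)
    L = int(rng.integers(1, 7))
    ins = "".join(rng.choice(list("ACGT"), L))
    a0 = int(rng.integers(0, n - 1))
    a0, ins = left_align_insertion(seq, a0, ins)
    if a0 < 0:
        return None
    return MutationRecord("s", "1", a0 + 1, seq[a0], seq[a0] + ins)


@pytest.fixture(scope="module")
def repeat_rich_genome():
    # biased alphabet plus planted repeats so all 83 branches get traffic
    rng = np.random.default_rng(7)
    parts = []
    for _ in range(400):
        if rng.random() < 0.4:
            unit = "".join(rng.choice(list("ACGT"), rng.integers(1, 5)))
            parts.append(unit * int(rng.integers(1, 7)))
        else:
            parts.append("".join(rng.choice(list("ACGT"), rng.integers(1, 8))))
    return "".join(parts)


class TestClassifyID:
    def test_single_base_deletion_in_homopolymer_run(self):
        # one T deleted from a run of exactly 4 Ts
        g = SequenceGenome({"1": "ACTTTTGA"})
        rec = MutationRecord("s", "1", 2, "CT", "C")
        assert classify_id(rec, g) == "1:Del:T:3"

    def test_single_base_insertion_no_repeat(self):
        g = SequenceGenome({"1": "AAGTA"})
        rec = MutationRecord("s", "1", 1, "A", "AC")
        assert classify_id(rec, g) == "1:Ins:C:0"

    def test_microhomology_deletion(self):
        # deletion of GTACG whose 3-bp prefix GTA recurs immediately downstream
        seq = "TT" + "GTACG" + "GTATT"
        g = SequenceGenome({"1": seq})
        rec = MutationRecord("s", "1", 2, "T" + "GTACG", "T")
        assert classify_id(rec, g) == "5:Del:M:3"

    def test_not_left_aligned_raises(self):
        g = SequenceGenome({"1": "ATTTA"})
        # deleting the *last* T of the run is shift-left-able
        rec = MutationRecord("s", "1", 3, "TT", "T")
        with pytest.raises(NormalizationError):
            classify_id(rec, g)

    def test_agrees_with_string_scanning_oracle(self, repeat_rich_genome):
        """>=1,000 random left-aligned indels vs an independent classifier."""
        seq = repeat_rich_genome
        g = SequenceGenome({"1": seq})
        rng = np.random.default_rng(23)
        checked = 0
        seen = set()
        while checked < 1200:
            rec = _random_indel_record(rng, seq)
            if rec is None:
                continue
            got = classify_id(rec, g)
            expected = id83_oracle(seq, rec.position, rec.ref, rec.alt)
            assert got == expected, f"{rec.position} {rec.ref}>{rec.alt}"
            assert got in ID83.categories
            seen.add(got)
            checked += 1
        assert len(seen) > 40  # the random stream exercises a broad label set


class TestClassifyCNSV:
    def test_diploid_het_segment(self):
        schema = default_cn_schema()
        seg = CNSegment("1", 1, 5_000_000, 2, 1)
        assert classify_cn(seg, schema) == "2:het:3Mb-10Mb"

    def test_sub100kb_homdel_bin_is_distinct(self):
        schema = default_cn_schema()
        short = classify_cn(CNSegment("1", 1, 50_000, 0, 0), schema)
        long = classify_cn(CNSegment("1", 1, 500_000, 0, 0), schema)
        assert short == "0:homdel:10kb-100kb"
        assert short != long

    def test_default_cn_schema_enumerates_68(self):
        schema = default_cn_schema()
        assert len(schema) == 68
        # every category is reachable: state x TCN x length bin arithmetic
        assert sum(1 for c in schema.categories if c.startswith("0:homdel")) == 5
        assert sum(1 for c in schema.categories if ":LOH:" in c) == 5 * 7
        assert sum(1 for c in schema.categories if ":het:" in c) == 4 * 7

    def test_cn_classification_covers_every_category(self):
        schema = default_cn_schema()
        hit = set()
        lengths = [5_000, 50_000, 500_000, 2_000_000, 5_000_000, 20_000_000, 60_000_000]
        for tcn, minor in [(0, 0), (1, 0), (2, 0), (3, 0), (6, 0), (9, 0), (2, 1), (4, 2), (8, 2), (12, 3)]:
            for ln in lengths:
                hit.add(classify_cn(CNSegment("1", 1, ln, tcn, minor), schema))
        assert hit == set(schema.categories)

    def test_sub1kb_sv_bin(self):
        schema = default_sv_schema()
        ev = SVEvent("DEL", "1", 1000, "1", 1500, clustered=False)
        assert classify_sv(ev, schema) == "non-clustered:del:0-1kb"

    def test_translocation_ignores_size(self):
        schema = default_sv_schema()
        ev = SVEvent("TRA", "1", 1000, "2", 99_000_000, clustered=True)
        assert classify_sv(ev, schema) == "clustered:tra"

    def test_default_sv_schema_enumerates_38(self):
        schema = default_sv_schema()
        assert len(schema) == 38
        hit = set()
        for clustered in (False, True):
            for svt in ("DEL", "DUP", "INV"):
                for size in (500, 5_000, 50_000, 500_000, 5_000_000, 50_000_000):
                    hit.add(
                        classify_sv(
                            SVEvent(svt, "1", 1, "1", 1 + size, clustered, size=size), schema
                        )
                    )
            hit.add(classify_sv(SVEvent("TRA", "1", 1, "2", 5, clustered), schema))
        assert hit == set(schema.categories)

    def test_tra_on_same_chromosome_rejected(self):
        with pytest.raises(ValueError):
            SVEvent("TRA", "1", 1, "1", 100)


class TestBuildCatalog:
    def test_identical_events_accumulate(self):
        g = SequenceGenome({"1": "AACAA"})
        recs = [MutationRecord("s1", "1", 3, "C", "T") for _ in range(3)]
        cat = build_catalog(recs, g, SBS96)
        assert cat.counts["s1"].sum() == 3
        assert cat.counts.loc["A[C>T]A", "s1"] == 3
        assert (cat.counts["s1"] > 0).sum() == 1

    def test_empty_input_yields_empty_catalog(self):
        cat = build_catalog([], None, SBS96)
        assert cat.n_samples == 0

    def test_schema_mismatch_raises(self):
        g = SequenceGenome({"1": "AACAA"})
        with pytest.raises(SchemaMismatchError):
            build_catalog([MutationRecord("s", "1", 3, "C", "TT")], g, SBS96)

    def test_column_sums_match_direct_tally(self, toy_genome):
        """200 random events over 5 samples conserve per-sample counts."""
        rng = np.random.default_rng(31)
        recs = []
        tally = {}
        for _ in range(200):
            sample = f"s{rng.integers(5)}"
            pos = int(rng.integers(2, 199))
            ref = toy_genome.base("chr1", pos)
            alt = rng.choice([b for b in "ACGT" if b != ref])
            recs.append(MutationRecord(sample, "chr1", pos, ref, alt))
            tally[sample] = tally.get(sample, 0) + 1
        cat = build_catalog(recs, toy_genome, SBS96)
        for s, n in tally.items():
            assert cat.counts[s].sum() == n
        assert list(cat.sample_ids) == list(dict.fromkeys(r.sample_id for r in recs))

    def test_strand_collapse_reproduces_sbs96_catalog(self, toy_genome):
        rng = np.random.default_rng(37)
        recs = []
        for _ in range(300):
            sample = f"s{rng.integers(3)}"
            pos = int(rng.integers(2, 199))
            ref = toy_genome.base("chr1", pos)
            alt = rng.choice([b for b in "ACGT" if b != ref])
            recs.append(MutationRecord(sample, "chr1", pos, ref, alt))
        c288 = build_catalog(recs, toy_genome, SBS288)
        c96 = build_catalog(recs, toy_genome, SBS96)
        collapsed = collapse_strand(c288)
        pd.testing.assert_frame_equal(collapsed.counts, c96.counts)

    def test_collapse_requires_sbs288(self):
        cat = build_catalog([], None, SBS96)
        with pytest.raises(SchemaMismatchError):
            collapse_strand(cat)


class TestGenomeAberration:
    def test_half_aberrant_single_chromosome(self):
        segs = [CNSegment("1", 1, 50, 2, 1), CNSegment("1", 51, 100, 3, 1)]
        assert genome_aberration_fraction(segs, {"1": 100}) == 0.5

    def test_fully_diploid_genome(self):
        segs = [CNSegment("1", 1, 100, 2, 1)]
        assert genome_aberration_fraction(segs, {"1": 100}) == 0.0

    def test_overlap_raises(self):
        segs = [CNSegment("1", 1, 50, 2, 1), CNSegment("1", 50, 100, 3, 1)]
        with pytest.raises(ValueError):
            genome_aberration_fraction(segs, {"1": 100})

    def test_matches_per_base_oracle_on_random_segmentations(self):
        rng = np.random.default_rng(41)
        lengths = {"1": 6000, "2": 4000}
        for _ in range(25):
            segs = []
            for chrom, L in lengths.items():
                cuts = np.sort(rng.choice(np.arange(2, L), size=8, replace=False))
                bounds = [1, *cuts.tolist(), L]
                for lo, hi in zip(bounds[:-1], bounds[1:]):
                    if rng.random() < 0.3:
                        continue  # leave gaps: uncovered genome is excluded
                    tcn = int(rng.integers(0, 5))
                    minor = int(rng.integers(0, tcn // 2 + 1))
                    segs.append(CNSegment(chrom, lo, hi - 1, tcn, minor))
            if not segs:
                continue
            got = genome_aberration_fraction(segs, lengths)
            assert got == pytest.approx(aberration_oracle(segs, lengths), abs=1e-12)
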