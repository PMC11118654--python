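"""Classification of somatic events into mutational-context categories.

Single base substitutions map to the pyrimidine-centered trinucleotide
(SBS-96) categories, optionally annotated with transcription strand
(SBS-288); doublets to DBS-78; small insertions/deletions to ID-83
(homopolymer / tandem-repeat / microhomology encoding); copy-number
segments and structural variants to configurable CN/SV schemas that
resolve short (<100 kb / <1 kb) events.  ``build_catalog`` tallies
classified events into a categories x samples matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schemas
from .genome import GenomeBoundsError
from .schemas import (
    COMPLEMENT,
    ContextSchema,
    DBS_CANONICAL_REFS,
    PURINES,
    PYRIMIDINES,
    bin_index,
    length_bin_labels,
    revcomp,
)

logger = logging.getLogger(__name__)


class ClassificationError(ValueError):
    """Base class for unclassifiable or inconsistent records."""


class ContextMismatchError(ClassificationError):
    """The reference allele disagrees with the genome at the locus."""


class UnclassifiableError(ClassificationError):
    """Ambiguous bases (N) or other content preventing classification."""


class NormalizationError(ClassificationError):
    """The indel is not left-aligned / trimmed."""


class SchemaMismatchError(ClassificationError):
    """Record class inconsistent with the requested schema."""


# ---------------------------------------------------------------------------
# records


@dataclass(frozen=True)
class MutationRecord:
    """One somatic small variant in VCF-style representation.

    ``variant_class`` is derived: SBS (1->1), DBS (2->2), or ID (indel with
    the shared VCF anchor base, left-aligned and trimmed).
    """

    sample_id: str
    chromosome: str
    position: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self):
        ref, alt = self.ref.upper(), self.alt.upper()
        object.__setattr__(self, "ref", ref)
        object.__setattr__(self, "alt", alt)
        if ref == alt:
            raise ValueError(f"ref == alt ({ref}) at {self.chromosome}:{self.position}")
        if not ref or not alt:
            raise ValueError("empty allele; symbolic alleles are not supported")
        for a in (ref, alt):
            if any(b not in "ACGTN" for b in a):
                raise ValueError(f"non-nucleotide allele {a!r}")

    @property
    def variant_class(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SBS"
        if len(self.ref) == 2 and len(self.alt) == 2:
            return "DBS"
        if len(self.ref) != len(self.alt):
            return "ID"
        raise ValueError(
            f"{len(self.ref)}->{len(self.alt)} substitution is neither SBS, DBS nor ID"
        )


@dataclass(frozen=True)
class CNSegment:
    """An allele-specific copy-number segment, 1-based inclusive."""

    chromosome: str
    start: int
    end: int
    total_cn: int
    minor_cn: int
    sample_id: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("segment start > end")
        if self.total_cn < 0 or self.minor_cn < 0:
            raise ValueError("copy numbers must be >= 0")
        if self.total_cn < self.minor_cn:
            raise ValueError("total_cn < minor_cn")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SVEvent:
    """A structural variant; size is undefined for translocations."""

    sv_type: str  # DEL | DUP | INV | TRA
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    clustered: bool = False
    sample_id: str = ""
    size: int | None = None

    def __post_init__(self):
        svt = self.sv_type.upper()
        object.__setattr__(self, "sv_type", svt)
        if svt not in ("DEL", "DUP", "INV", "TRA"):
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if svt == "TRA":
            if self.chrom1 == self.chrom2:
                raise ValueError("translocation breakpoints on the same chromosome")
        else:
            if self.size is None and self.chrom1 == self.chrom2:
                object.__setattr__(self, "size", abs(self.pos2 - self.pos1))
            if self.size is None or self.size <= 0:
                raise ValueError(f"{svt} requires a positive size")


# ---------------------------------------------------------------------------
# SBS


def classify_sbs(record: MutationRecord, genome, stranded: bool = False) -> str:
    """SBS-96 (or SBS-288 when ``stranded``) category of a substitution.

    Purine-reference mutations are reverse-complemented into the
    pyrimidine representation, with the flanking bases swapped and
    complemented.  The SBS-288 prefix reports whether the pyrimidine lies
    on the transcribed (template) strand (T:), the untranscribed strand
    (U:), or outside annotated genes (N:).
    """
    if record.variant_class != "SBS":
        raise SchemaMismatchError(f"not an SBS record: {record.ref}>{record.alt}")
    actual = genome.base(record.chromosome, record.position)
    if actual != record.ref:
        raise ContextMismatchError(
            f"{record.chromosome}:{record.position} is {actual}, record says {record.ref}"
        )
    tri = genome.flank(record.chromosome, record.position, 1)
    if "N" in tri or record.alt == "N":
        raise UnclassifiableError(f"ambiguous base in context {tri}")

    ref, alt = record.ref, record.alt
    if ref in PURINES:
        tri = revcomp(tri)
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        pyr_on_plus = False
    else:
        pyr_on_plus = True
    label = f"{tri[0]}[{ref}>{alt}]{tri[2]}"
    if not stranded:
        return label

    coding = genome.transcribed_strand(record.chromosome, record.position)
    if coding == "none":
        prefix = "N"
    else:
        # template (transcribed) strand is the opposite of the coding strand
        template_is_plus = coding == "minus"
        prefix = "T" if pyr_on_plus == template_is_plus else "U"
    return f"{prefix}:{label}"


def collapse_strand(catalog: "CatalogMatrix") -> "CatalogMatrix":
    """Sum the T:/U:/N: strata of an SBS-288 catalog down to SBS-96."""
    if catalog.schema.schema_id != "SBS288":
        raise SchemaMismatchError("collapse_strand requires an SBS288 catalog")
    stripped = [c.split(":", 1)[1] for c in catalog.schema.categories]
    collapsed = catalog.counts.groupby(stripped, sort=False).sum()
    collapsed = collapsed.reindex(schemas.SBS96.categories)
    return CatalogMatrix(schemas.SBS96, collapsed)


# ---------------------------------------------------------------------------
# DBS


def classify_dbs(record: MutationRecord, genome=None) -> str:
    """DBS-78 category; non-canonical reference doublets are reverse-complemented."""
    if record.variant_class != "DBS":
        raise SchemaMismatchError(f"not a DBS record: {record.ref}>{record.alt}")
    ref, alt = record.ref, record.alt
    if "N" in ref + alt:
        raise UnclassifiableError(f"ambiguous base in doublet {ref}>{alt}")
    if any(r == a for r, a in zip(ref, alt)):
        raise UnclassifiableError(
            f"{ref}>{alt} does not substitute both bases of the doublet"
        )
    if genome is not None:
        actual = genome.sequence(record.chromosome, record.position, record.position + 1)
        if actual != ref:
            raise ContextMismatchError(
                f"{record.chromosome}:{record.position} is {actual}, record says {ref}"
            )
    if ref not in DBS_CANONICAL_REFS:
        ref, alt = revcomp(ref), revcomp(alt)
    if f"{ref}>{alt}" not in schemas._DBS78_LOOKUP:
        alt = revcomp(alt)  # palindromic refs collapse alt orientations
    label = f"{ref}>{alt}"
    if label not in schemas._DBS78_LOOKUP:
        raise UnclassifiableError(f"doublet {record.ref}>{record.alt} has no category")
    return label


# ---------------------------------------------------------------------------
# ID


def _trim_indel(record: MutationRecord) -> tuple[str, str, int]:
    """Return (kind, changed sequence, locus) from the anchored representation.

    For a deletion the locus is the first deleted reference position; for
    an insertion it is the anchor position (insertion occurs to its right).
    """
    ref, alt = record.ref, record.alt
    # strip the longest common prefix (>=1 by the VCF anchor convention)
    k = 0
    while k < min(len(ref), len(alt)) and ref[k] == alt[k]:
        k += 1
    if k == 0 or (len(ref) > k and len(alt) > k):
        raise NormalizationError(
            f"{ref}>{alt} is not a trimmed, anchored insertion or deletion"
        )
    if len(ref) > len(alt):
        return "Del", ref[k:], record.position + k
    return "Ins", alt[k:], record.position + k - 1


def _run_length_right(genome, chrom: str, start: int, base: str, cap: int) -> int:
    """Number of consecutive ``base`` at start, start+1, ... (capped)."""
    n = 0
    end = genome.chrom_length(chrom)
    while n < cap and start + n <= end and genome.base(chrom, start + n) == base:
        n += 1
    return n


def _tandem_copies_right(genome, chrom: str, start: int, unit: str, cap: int) -> int:
    """Copies of ``unit`` at start, start+len, ... (capped)."""
    L = len(unit)
    n = 0
    end = genome.chrom_length(chrom)
    while n < cap and start + (n + 1) * L - 1 <= end:
        if genome.sequence(chrom, start + n * L, start + (n + 1) * L - 1) != unit:
            break
        n += 1
    return n


def _microhomology(genome, chrom: str, s: int, e: int, deleted: str) -> int:
    """Longest homology between the deletion ends and its flanks.

    Checks the deleted prefix against the downstream flank and the deleted
    suffix against the upstream flank; the maximum is reported, capped at
    len(deleted) - 1.
    """
    L = len(deleted)
    cap = L - 1
    end = genome.chrom_length(chrom)
    pre = 0
    while pre < cap and e + 1 + pre <= end and genome.base(chrom, e + 1 + pre) == deleted[pre]:
        pre += 1
    suf = 0
    while suf < cap and s - 1 - suf >= 1 and genome.base(chrom, s - 1 - suf) == deleted[L - 1 - suf]:
        suf += 1
    return max(pre, suf)


def classify_id(record: MutationRecord, genome) -> str:
    """ID-83 category of a left-aligned, trimmed insertion or deletion."""
    if record.variant_class != "ID":
        raise SchemaMismatchError(f"not an ID record: {record.ref}>{record.alt}")
    if "N" in record.ref + record.alt:
        raise UnclassifiableError("ambiguous base in indel allele")
    kind, seq, locus = _trim_indel(record)
    chrom = record.chromosome
    L = len(seq)

    actual = genome.sequence(chrom, record.position, record.position + len(record.ref) - 1)
    if actual != record.ref:
        raise ContextMismatchError(
            f"{chrom}:{record.position} is {actual}, record says {record.ref}"
        )

    if kind == "Del":
        s, e = locus, locus + L - 1
        # a shift left preserving the allele means the record is not left-aligned
        if s > 1 and genome.base(chrom, s - 1) == seq[-1]:
            raise NormalizationError(f"deletion at {chrom}:{s} is not left-aligned")
        if L == 1:
            run = _run_length_right(genome, chrom, s, seq, cap=7)  # includes deleted base
            base = seq if seq in PYRIMIDINES else COMPLEMENT[seq]
            return f"1:Del:{base}:{min(run - 1, 5)}"
        extra = _tandem_copies_right(genome, chrom, e + 1, seq, cap=6)
        size = min(L, 5)
        if extra > 0:
            return f"{size}:Del:R:{min(extra, 5)}"
        mh = _microhomology(genome, chrom, s, e, seq)
        if mh > 0:
            return f"{size}:Del:M:{min(mh, 5)}"
        return f"{size}:Del:R:0"

    # insertion: ``locus`` anchors the inserted sequence to its right
    if genome.base(chrom, locus) == seq[-1]:
        raise NormalizationError(f"insertion at {chrom}:{locus} is not left-aligned")
    if L == 1:
        run = _run_length_right(genome, chrom, locus + 1, seq, cap=6)
        base = seq if seq in PYRIMIDINES else COMPLEMENT[seq]
        return f"1:Ins:{base}:{min(run, 5)}"
    copies = _tandem_copies_right(genome, chrom, locus + 1, seq, cap=6)
    return f"{min(L, 5)}:Ins:R:{min(copies, 5)}"


# ---------------------------------------------------------------------------
# CN / SV


def classify_cn(segment: CNSegment, schema: ContextSchema) -> str:
    """Allele-state x total-CN x length-bin category of a CN segment."""
    if schema.schema_id != "CN_CONFIG":
        raise SchemaMismatchError("classify_cn requires a CN schema")
    if segment.length <= 0:
        raise ClassificationError("segment length <= 0")
    p = schema.parameters
    if segment.total_cn == 0:
        labels = length_bin_labels(p["homdel_length_edges"])
        return f"0:homdel:{labels[bin_index(segment.length, p['homdel_length_edges'])]}"
    state = "LOH" if segment.minor_cn == 0 else "het"
    tcn_bins = p["loh_tcn_bins"] if state == "LOH" else p["het_tcn_bins"]
    tcn_label = None
    for lab, lo, hi in tcn_bins:
        if segment.total_cn >= lo and (hi is None or segment.total_cn <= hi):
            tcn_label = lab
            break
    if tcn_label is None:
        raise ClassificationError(
            f"total_cn={segment.total_cn} outside configured {state} bins"
        )
    labels = length_bin_labels(p["length_edges"])
    return f"{tcn_label}:{state}:{labels[bin_index(segment.length, p['length_edges'])]}"


def classify_sv(event: SVEvent, schema: ContextSchema) -> str:
    """Clustered-status x type x size-bin category of a structural variant."""
    if schema.schema_id != "SV_CONFIG":
        raise SchemaMismatchError("classify_sv requires an SV schema")
    clust = "clustered" if event.clustered else "non-clustered"
    if event.sv_type == "TRA":
        return f"{clust}:tra"
    if event.size is None or event.size <= 0:
        raise ClassificationError(f"{event.sv_type} without a positive size")
    edges = schema.parameters["size_edges"]
    labels = length_bin_labels(edges)
    return f"{clust}:{event.sv_type.lower()}:{labels[bin_index(event.size, edges)]}"


# ---------------------------------------------------------------------------
# catalogs


@dataclass
class CatalogMatrix:
    """Mutation-context catalog: categories x samples.

    Counts are nonnegative; they are integers for raw catalogs and may be
    real-valued after hypermutator normalization.  ``unclassified`` tallies
    events that could not be classified, per sample.
    """

    schema: ContextSchema
    counts: pd.DataFrame
    unclassified: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if list(self.counts.index) != list(self.schema.categories):
            self.counts = self.counts.reindex(self.schema.categories, fill_value=0)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("catalog counts must be nonnegative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def copy(self) -> "CatalogMatrix":
        return CatalogMatrix(self.schema, self.counts.copy(), dict(self.unclassified))


def _classify_one(rec, genome, schema: ContextSchema) -> str:
    sid = schema.schema_id
    if isinstance(rec, CNSegment):
        if sid != "CN_CONFIG":
            raise SchemaMismatchError("CN segment under a non-CN schema")
        return classify_cn(rec, schema)
    if isinstance(rec, SVEvent):
        if sid != "SV_CONFIG":
            raise SchemaMismatchError("SV event under a non-SV schema")
        return classify_sv(rec, schema)
    vc = rec.variant_class
    if sid in ("SBS96", "SBS288"):
        if vc != "SBS":
            raise SchemaMismatchError(f"{vc} record under {sid}")
        return classify_sbs(rec, genome, stranded=(sid == "SBS288"))
    if sid == "DBS78":
        if vc != "DBS":
            raise SchemaMismatchError(f"{vc} record under DBS78")
        return classify_dbs(rec, genome)
    if sid == "ID83":
        if vc != "ID":
            raise SchemaMismatchError(f"{vc} record under ID83")
        return classify_id(rec, genome)
    raise SchemaMismatchError(f"unknown schema {sid}")


def build_catalog(records, genome, schema: ContextSchema) -> CatalogMatrix:
    """Tally classified events into a catalog.

    Sample columns appear in first-appearance order.  Events that raise
    :class:`UnclassifiableError` are logged and counted in
    ``catalog.unclassified``; structurally inconsistent records
    (schema/class mismatch, context mismatch, bad normalization) propagate
    as errors.
    """
    index = schema.index()
    columns: dict[str, np.ndarray] = {}
    unclassified: dict[str, int] = {}
    for rec in records:
        sample = rec.sample_id
        if sample not in columns:
            columns[sample] = np.zeros(len(schema), dtype=np.int64)
            unclassified[sample] = 0
        try:
            cat = _classify_one(rec, genome, schema)
        except UnclassifiableError as exc:
            logger.warning("unclassifiable event in %s: %s", sample, exc)
            unclassified[sample] += 1
            continue
        columns[sample][index[cat]] += 1
    counts = pd.DataFrame(
        columns, index=list(schema.categories), dtype=np.int64
    )
    return CatalogMatrix(schema, counts, unclassified)


# ---------------------------------------------------------------------------
# genome aberration


def genome_aberration_fraction(segments, genome_length_table: dict[str, int]) -> float:
    """Fraction of the segment-covered genome not in the diploid (2,1) state.

    Segments must be non-overlapping per chromosome; the denominator is
    the genome covered by segments, so uncovered regions do not dilute the
    estimate.
    """
    segs = sorted(segments, key=lambda s: (s.chromosome, s.start))
    covered = 0
    aberrant = 0
    prev_end: dict[str, int] = {}
    for seg in segs:
        chrom_len = genome_length_table.get(seg.chromosome)
        if chrom_len is None:
            raise KeyError(f"chromosome {seg.chromosome!r} not in length table")
        if seg.end > chrom_len:
            raise ValueError(f"segment {seg.chromosome}:{seg.start}-{seg.end} beyond chromosome end")
        if seg.start <= prev_end.get(seg.chromosome, 0):
            raise ValueError(f"overlapping segments on {seg.chromosome} at {seg.start}")
        prev_end[seg.chromosome] = seg.end
        covered += seg.length
        if (seg.total_cn, seg.minor_cn) != (2, 1):
            aberrant += seg.length
    if covered == 0:
        return 0.0
    return aberrant / covered
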