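"""Reference-sequence and gene-annotation context.

Classification needs three queries at a locus: the reference base, a
symmetric flank, and the transcription strand implied by overlapping gene
annotations.  ``SequenceGenome`` answers them from in-memory sequences
(tests, simulations); ``FastaGenome`` from an indexed FASTA via pyfaidx.
Coordinates are 1-based inclusive throughout, matching VCF.
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree


class GenomeBoundsError(KeyError):
    """Raised for queries outside the supplied sequence."""


@dataclass(frozen=True)
class GeneInterval:
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # '+' or '-'
    gene_id: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+'/'-', got {self.strand!r}")
        if self.start > self.end:
            raise ValueError("gene interval start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class _AnnotatedGenome:
    """Shared strand-annotation logic over a per-chromosome interval tree."""

    def __init__(self, genes: list[GeneInterval] | None = None):
        self._trees: dict[str, IntervalTree] = {}
        for g in genes or []:
            # IntervalTree is half-open; store [start, end+1)
            self._trees.setdefault(g.chromosome, IntervalTree()).addi(
                g.start, g.end + 1, g
            )

    def _sequence(self, chrom: str, start: int, end: int) -> str:
        raise NotImplementedError

    def chrom_length(self, chrom: str) -> int:
        raise NotImplementedError

    def sequence(self, chrom: str, start: int, end: int) -> str:
        """Uppercase reference sequence for [start, end], 1-based inclusive."""
        if start < 1 or end > self.chrom_length(chrom) or start > end:
            raise GenomeBoundsError(
                f"{chrom}:{start}-{end} outside supplied sequence"
            )
        return self._sequence(chrom, start, end)

    def base(self, chrom: str, pos: int) -> str:
        return self.sequence(chrom, pos, pos)

    def flank(self, chrom: str, pos: int, k: int) -> str:
        """The (2k+1)-mer centered on ``pos``."""
        return self.sequence(chrom, pos - k, pos + k)

    def transcribed_strand(self, chrom: str, pos: int) -> str:
        """Coding strand of the gene overlapping ``pos``: 'plus', 'minus', or 'none'.

        Loci under genes on both strands are resolved by the longest
        overlapping interval, ties by lexicographic gene id, so the answer
        is deterministic.
        """
        tree = self._trees.get(chrom)
        if tree is None:
            return "none"
        hits = [iv.data for iv in tree.at(pos)]
        if not hits:
            return "none"
        best = max(hits, key=lambda g: (g.length, _revlex(g.gene_id)))
        return "plus" if best.strand == "+" else "minus"


def _revlex(s: str):
    # max() with this key picks the lexicographically *smallest* id on ties
    return tuple(-ord(c) for c in s)


class SequenceGenome(_AnnotatedGenome):
    """Genome backed by a dict of chromosome → sequence strings."""

    def __init__(self, sequences: dict[str, str], genes: list[GeneInterval] | None = None):
        super().__init__(genes)
        self._seqs = {c: s.upper() for c, s in sequences.items()}

    def chrom_length(self, chrom: str) -> int:
        try:
            return len(self._seqs[chrom])
        except KeyError:
            raise GenomeBoundsError(f"unknown chromosome {chrom!r}") from None

    def _sequence(self, chrom: str, start: int, end: int) -> str:
        return self._seqs[chrom][start - 1 : end]


class FastaGenome(_AnnotatedGenome):
    """Genome backed by an indexed FASTA file."""

    def __init__(self, fasta_path: str, genes: list[GeneInterval] | None = None):
        from pyfaidx import Fasta

        super().__init__(genes)
        self._fasta = Fasta(fasta_path, sequence_always_upper=True)

    def chrom_length(self, chrom: str) -> int:
        try:
            return len(self._fasta[chrom])
        except KeyError:
            raise GenomeBoundsError(f"unknown chromosome {chrom!r}") from None

    def _sequence(self, chrom: str, start: int, end: int) -> str:
        return str(self._fasta[chrom][start - 1 : end])


def read_bed_genes(path: str) -> list[GeneInterval]:
    """Gene intervals from a BED file (0-based half-open; strand in col 6)."""
    genes = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"BED line {i + 1}: need 6 columns incl. strand")
            genes.append(
                GeneInterval(f[0], int(f[1]) + 1, int(f[2]), f[5], f[3] or f"gene{i}")
            )
    return genes


def read_gff3_genes(path: str, feature_type: str = "gene") -> list[GeneInterval]:
    """Gene intervals from a GFF3 file (1-based inclusive)."""
    genes = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 8 or f[2] != feature_type:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            ) if len(f) > 8 else {}
            gid = attrs.get("ID", attrs.get("gene_id", f"gene{i}"))
            genes.append(GeneInterval(f[0], int(f[3]), int(f[4]), f[6], gid))
    return genes
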