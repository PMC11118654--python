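"""Mutation-context schemas.

A schema is an ordered set of category labels over which catalogs and
signature profiles are defined.  The point-mutation schemas (SBS-96,
SBS-288, DBS-78, ID-83) are fixed by the COSMIC conventions; the
copy-number and structural-variant schemas carry explicit, overridable
bin boundaries because published CN/SV contexts vary between studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
PYRIMIDINES = ("C", "T")
PURINES = ("A", "G")
BASES = ("A", "C", "G", "T")

#: the six pyrimidine-referenced substitution types, COSMIC order
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: strand annotation prefixes for SBS-288: transcribed / untranscribed /
#: non-transcribed (intergenic)
STRAND_PREFIXES = ("T", "U", "N")


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def sbs96_categories() -> list[str]:
    cats = []
    for sub in SUBSTITUTIONS:
        for five in BASES:
            for three in BASES:
                cats.append(f"{five}[{sub}]{three}")
    return cats


def sbs288_categories() -> list[str]:
    return [f"{p}:{c}" for p in STRAND_PREFIXES for c in sbs96_categories()]


# The 78 canonical doublet-substitution categories.  Ten canonical
# reference doublets; the four palindromic ones (AT, CG, GC, TA) collapse
# reverse-complement-equivalent alternate alleles, leaving 6 categories
# each instead of 9.
_DBS78 = {
    "AC": ("CA", "CG", "CT", "GA", "GG", "GT", "TA", "TG", "TT"),
    "AT": ("CA", "CC", "CG", "GA", "GC", "TA"),
    "CC": ("AA", "AG", "AT", "GA", "GG", "GT", "TA", "TG", "TT"),
    "CG": ("AT", "GC", "GT", "TA", "TC", "TT"),
    "CT": ("AA", "AC", "AG", "GA", "GC", "GG", "TA", "TC", "TG"),
    "GC": ("AA", "AG", "AT", "CA", "CG", "TA"),
    "TA": ("AT", "CG", "CT", "GC", "GG", "GT"),
    "TC": ("AA", "AG", "AT", "CA", "CG", "CT", "GA", "GG", "GT"),
    "TG": ("AA", "AC", "AT", "CA", "CC", "CT", "GA", "GC", "GT"),
    "TT": ("AA", "AC", "AG", "CA", "CC", "CG", "GA", "GC", "GG"),
}

DBS_CANONICAL_REFS = tuple(_DBS78)


def dbs78_categories() -> list[str]:
    return [f"{ref}>{alt}" for ref, alts in _DBS78.items() for alt in alts]


_DBS78_LOOKUP = frozenset(dbs78_categories())


def id83_categories() -> list[str]:
    """COSMIC ID-83 labels, in the conventional plotting order.

    Field syntax ``{size}:{Del|Ins}:{C|T|R|M}:{n}``: 1-bp events are keyed
    by the pyrimidine of the affected base pair and the length of the
    homopolymer run (n = run length - 1 for deletions, n = existing copies
    for insertions, capped at 5); longer events by length bin (2,3,4,5+)
    and tandem-repeat copy number; microhomology deletions by length bin
    and homology length.
    """
    cats = []
    for base in ("C", "T"):
        cats += [f"1:Del:{base}:{n}" for n in range(6)]
    for base in ("C", "T"):
        cats += [f"1:Ins:{base}:{n}" for n in range(6)]
    for size in (2, 3, 4, 5):
        cats += [f"{size}:Del:R:{n}" for n in range(6)]
    for size in (2, 3, 4, 5):
        cats += [f"{size}:Ins:R:{n}" for n in range(6)]
    for size, max_mh in ((2, 1), (3, 2), (4, 3), (5, 5)):
        cats += [f"{size}:Del:M:{m}" for m in range(1, max_mh + 1)]
    return cats


# ---------------------------------------------------------------------------
# CN / SV configurable schemas


def _format_bp(bp: float) -> str:
    if math.isinf(bp):
        return "inf"
    if bp == 0:
        return "0"
    if bp >= 1e6:
        v = bp / 1e6
        unit = "Mb"
    elif bp >= 1e3:
        v = bp / 1e3
        unit = "kb"
    else:
        return f"{int(bp)}bp"
    return f"{v:g}{unit}"


def length_bin_labels(edges: list[float]) -> list[str]:
    """Human-readable labels for the bins cut at ``edges`` (right-open)."""
    bounds = [0.0, *edges, math.inf]
    labels = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if math.isinf(hi):
            labels.append(f">{_format_bp(lo)}")
        else:
            labels.append(f"{_format_bp(lo)}-{_format_bp(hi)}")
    return labels


def bin_index(value: float, edges: list[float]) -> int:
    """Index of the right-open bin of ``value`` among ``edges``."""
    for i, e in enumerate(edges):
        if value < e:
            return i
    return len(edges)


# Default CN schema ("CN-68-like").  Reconstructed to honor the published
# 68-category count and the sub-100 kb refinement: two length bins below
# 100 kb in every allele state.
CN_HOMDEL_LENGTH_EDGES = [10e3, 100e3, 1e6, 10e6]  # 5 bins
CN_LENGTH_EDGES = [10e3, 100e3, 1e6, 3e6, 10e6, 40e6]  # 7 bins
CN_LOH_TCN_BINS = [("1", 1, 1), ("2", 2, 2), ("3-4", 3, 4), ("5-8", 5, 8), ("9+", 9, None)]
CN_HET_TCN_BINS = [("2", 2, 2), ("3-4", 3, 4), ("5-8", 5, 8), ("9+", 9, None)]

# Default SV schema ("SV-38-like"): {clustered, non-clustered} x
# ({DEL, DUP, INV} x 6 size bins incl. a <1 kb bin, + TRA) = 2 x 19 = 38.
SV_SIZE_EDGES = [1e3, 10e3, 100e3, 1e6, 10e6]  # 6 bins
SV_TYPES = ("del", "dup", "inv")
SV_CLUSTER_STATES = ("clustered", "non-clustered")


def cn_categories(
    homdel_edges: list[float] | None = None,
    length_edges: list[float] | None = None,
    loh_tcn_bins=None,
    het_tcn_bins=None,
) -> list[str]:
    homdel_edges = CN_HOMDEL_LENGTH_EDGES if homdel_edges is None else homdel_edges
    length_edges = CN_LENGTH_EDGES if length_edges is None else length_edges
    loh_tcn_bins = CN_LOH_TCN_BINS if loh_tcn_bins is None else loh_tcn_bins
    het_tcn_bins = CN_HET_TCN_BINS if het_tcn_bins is None else het_tcn_bins
    cats = [f"0:homdel:{lab}" for lab in length_bin_labels(homdel_edges)]
    for tcn_label, _, _ in loh_tcn_bins:
        cats += [f"{tcn_label}:LOH:{lab}" for lab in length_bin_labels(length_edges)]
    for tcn_label, _, _ in het_tcn_bins:
        cats += [f"{tcn_label}:het:{lab}" for lab in length_bin_labels(length_edges)]
    return cats


def sv_categories(size_edges: list[float] | None = None) -> list[str]:
    size_edges = SV_SIZE_EDGES if size_edges is None else size_edges
    cats = []
    for clust in SV_CLUSTER_STATES:
        for svtype in SV_TYPES:
            cats += [f"{clust}:{svtype}:{lab}" for lab in length_bin_labels(size_edges)]
        cats.append(f"{clust}:tra")
    return cats


@dataclass(frozen=True)
class ContextSchema:
    """An ordered, uniquely-labelled set of mutation-context categories."""

    schema_id: str
    categories: tuple[str, ...]
    parameters: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if len(set(self.categories)) != len(self.categories):
            raise ValueError("category labels must be unique")
        expected = {"SBS96": 96, "SBS288": 288, "DBS78": 78, "ID83": 83}
        n = expected.get(self.schema_id)
        if n is not None and len(self.categories) != n:
            raise ValueError(
                f"{self.schema_id} requires {n} categories, got {len(self.categories)}"
            )

    def __len__(self) -> int:
        return len(self.categories)

    def index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.categories)}


SBS96 = ContextSchema("SBS96", tuple(sbs96_categories()))
SBS288 = ContextSchema("SBS288", tuple(sbs288_categories()))
DBS78 = ContextSchema("DBS78", tuple(dbs78_categories()))
ID83 = ContextSchema("ID83", tuple(id83_categories()))


def default_cn_schema() -> ContextSchema:
    params = {
        "homdel_length_edges": list(CN_HOMDEL_LENGTH_EDGES),
        "length_edges": list(CN_LENGTH_EDGES),
        "loh_tcn_bins": list(CN_LOH_TCN_BINS),
        "het_tcn_bins": list(CN_HET_TCN_BINS),
    }
    return ContextSchema("CN_CONFIG", tuple(cn_categories()), params)


def default_sv_schema() -> ContextSchema:
    return ContextSchema(
        "SV_CONFIG", tuple(sv_categories()), {"size_edges": list(SV_SIZE_EDGES)}
    )


def get_schema(name: str) -> ContextSchema:
    """Look a schema up by its lowercase CLI name."""
    table = {
        "sbs96": SBS96,
        "sbs288": SBS288,
        "dbs78": DBS78,
        "id83": ID83,
        "cn": default_cn_schema(),
        "sv": default_sv_schema(),
    }
    try:
        return table[name.lower()]
    except KeyError:
        raise KeyError(f"unknown schema {name!r}; expected one of {sorted(table)}") from None
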