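"""Readers and writers for the standard text formats.

Catalogs and signature matrices use the COSMIC matrix dialect: a
``MutationType`` label column followed by one column per sample or
signature.  Mutation input is a minimal VCF (sample taken from a column
or the filename) or a TSV with explicit columns; CN and SV events are
TSVs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .contexts import CatalogMatrix, CNSegment, MutationRecord, SVEvent
from .schemas import ContextSchema

LABEL_COLUMN = "MutationType"


def write_catalog_tsv(catalog: CatalogMatrix, path) -> None:
    df = catalog.counts.copy()
    df.index.name = LABEL_COLUMN
    df.to_csv(path, sep="\t")


def read_catalog_tsv(path, schema: ContextSchema) -> CatalogMatrix:
    df = pd.read_csv(path, sep="\t")
    if LABEL_COLUMN not in df.columns:
        raise ValueError(f"catalog file lacks the {LABEL_COLUMN!r} column")
    df = df.set_index(LABEL_COLUMN)
    missing = set(schema.categories) - set(df.index)
    if missing:
        raise ValueError(f"catalog is missing {len(missing)} categories of {schema.schema_id}")
    df = df.loc[list(schema.categories)]
    df.index.name = None
    return CatalogMatrix(schema, df)


def write_signatures_tsv(profiles: pd.DataFrame, path) -> None:
    out = profiles.copy()
    out.index.name = LABEL_COLUMN
    out.to_csv(path, sep="\t")


def read_signatures_tsv(path, schema: ContextSchema | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t").set_index(LABEL_COLUMN)
    if schema is not None:
        df = df.loc[list(schema.categories)]
    df.index.name = None
    return df


def read_mutations_tsv(path) -> list[MutationRecord]:
    """Mutation records from a TSV with columns sample, chromosome, position, ref, alt."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "ref": str, "alt": str})
    need = {"sample", "chromosome", "position", "ref", "alt"}
    if not need.issubset(df.columns):
        raise ValueError(f"mutation TSV needs columns {sorted(need)}")
    return [
        MutationRecord(r.sample, r.chromosome, int(r.position), r.ref, r.alt)
        for r in df.itertuples(index=False)
    ]


def read_mutations_vcf(path, sample_id: str | None = None) -> list[MutationRecord]:
    """Mutation records from a (possibly multi-allelic) VCF.

    The sample id defaults to the VCF's single sample name, or the file
    stem for sites-only files.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if sample_id is None:
        sample_id = vcf.samples[0] if vcf.samples else Path(path).stem
    records = []
    for var in vcf:
        for alt in var.ALT:
            if alt is None or any(ch not in "ACGTNacgtn" for ch in alt):
                continue
            records.append(
                MutationRecord(sample_id, var.CHROM, var.POS, var.REF, alt)
            )
    return records


def read_cn_tsv(path) -> list[CNSegment]:
    """CN segments from a TSV: sample, chromosome, start, end, total_cn, minor_cn."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return [
        CNSegment(
            r.chromosome, int(r.start), int(r.end), int(r.total_cn), int(r.minor_cn),
            sample_id=getattr(r, "sample", ""),
        )
        for r in df.itertuples(index=False)
    ]


def read_sv_tsv(path) -> list[SVEvent]:
    """SV events from a TSV: sample, sv_type, chrom1, pos1, chrom2, pos2, clustered."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom1": str, "chrom2": str})
    events = []
    for r in df.itertuples(index=False):
        events.append(
            SVEvent(
                r.sv_type, r.chrom1, int(r.pos1), r.chrom2, int(r.pos2),
                clustered=bool(r.clustered), sample_id=getattr(r, "sample", ""),
                size=int(r.size) if "size" in df.columns and not pd.isna(r.size) else None,
            )
        )
    return events


def read_cohort_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    return df


def read_exposure_tsv(path):
    from .associations import ExposureSeries

    return ExposureSeries(pd.read_csv(path, sep="\t"))


def write_activities_tsv(activities: pd.DataFrame, path) -> None:
    """Samples x signatures orientation, as association inputs expect."""
    out = activities.T.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_activities_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t").set_index("sample_id")
    return df.T


def write_probabilities_tsv(table, path) -> None:
    table.to_long().to_csv(path, sep="\t", index=False, float_format="%.6g")
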