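"""Readers and writers for every on-disk artifact of the pipeline.

Formats
-------
expression TSV   probes x samples; first column ``probe_id``, header = sample ids
design CSV       columns patient_id, tumor_sample_id, normal_sample_id
annotation TSV   probe_id, transcript_id, biotype, chromosome, start, end, strand,
                 category_source
gene models      BED12 or GFF3 (one transcript per gene)
gene sets        one identifier per line
Ct CSV           patient_id, condition, gene_id, ct_target, ct_reference

All genomic coordinates are held internally as 0-based half-open intervals
(BED convention); GFF3 input is converted on read.  Writers prepend a comment
line carrying the tool version and, when supplied, a configuration hash, so
that outputs of different runs cannot be silently mixed.  Readers skip ``#``
comment lines.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

from . import __version__
from .exceptions import (
    DuplicateIdError,
    MalformedRecordError,
    MissingSampleError,
    MultiMappingProbeError,
    NonNumericValueError,
    NonPositiveIntensityError,
)

ANNOTATION_COLUMNS = [
    "probe_id", "transcript_id", "biotype", "chromosome",
    "start", "end", "strand", "category_source",
]
CT_COLUMNS = ["patient_id", "condition", "gene_id", "ct_target", "ct_reference"]


def _header_comment(config_hash: str | None) -> str:
    tag = f" config_hash={config_hash}" if config_hash else ""
    return f"# lnchcc {__version__}{tag}\n"


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A coding-gene (or transcript) model on the toy or real genome.

    Coordinates are 0-based half-open.  The TSS is the interval start on the
    plus strand and the interval end on the minus strand.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise MalformedRecordError(
                f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise MalformedRecordError(
                f"{self.gene_id}: start must be < end ({self.start} >= {self.end})")
        if not self.exons:
            self.exons = [(self.start, self.end)]
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        prev_end = None
        for a, b in self.exons:
            if a >= b or a < self.start or b > self.end:
                raise MalformedRecordError(
                    f"{self.gene_id}: exon ({a},{b}) outside span or empty")
            if prev_end is not None and a < prev_end:
                raise MalformedRecordError(
                    f"{self.gene_id}: overlapping exons at {a}")
            prev_end = b

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from BED12 or GFF3, dispatching on the extension."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_gff3(path)
    return _read_bed12(path)


def _read_bed12(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise MalformedRecordError(
                    f"{path}:{lineno}: BED12 requires 12 fields, got {len(parts)}")
            try:
                chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
                strand = parts[5]
                n_blocks = int(parts[9])
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise MalformedRecordError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise MalformedRecordError(
                    f"{path}:{lineno}: blockCount={n_blocks} does not match "
                    f"{len(sizes)} sizes / {len(offsets)} starts")
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            try:
                genes.append(GeneModel(name, chrom, start, end, strand, exons))
            except MalformedRecordError as exc:
                raise MalformedRecordError(f"{path}:{lineno}: {exc}") from exc
    _check_unique([g.gene_id for g in genes], "gene_id")
    return genes


def _read_gff3(path: Path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exons = [
            (e.start - 1, e.end)  # GFF3 1-based closed -> 0-based half-open
            for e in db.children(gene, featuretype="exon")
        ]
        genes.append(
            GeneModel(gene.id, gene.seqid, gene.start - 1, gene.end,
                      gene.strand, exons)
        )
    _check_unique([g.gene_id for g in genes], "gene_id")
    return genes


def write_bed12(genes: list[GeneModel], path, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(config_hash))
        for g in genes:
            sizes = ",".join(str(b - a) for a, b in g.exons)
            offsets = ",".join(str(a - g.start) for a, _ in g.exons)
            fh.write("\t".join(map(str, [
                g.chromosome, g.start, g.end, g.gene_id, 0, g.strand,
                g.start, g.end, "0,0,0", len(g.exons), sizes, offsets,
            ])) + "\n")


def write_gff3(genes: list[GeneModel], path, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(_header_comment(config_hash))
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write("\t".join(map(str, [
                g.chromosome, "lnchcc", "gene", g.start + 1, g.end, ".",
                g.strand, ".", attrs])) + "\n")
            for i, (a, b) in enumerate(g.exons, start=1):
                fh.write("\t".join(map(str, [
                    g.chromosome, "lnchcc", "exon", a + 1, b, ".",
                    g.strand, ".",
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}"])) + "\n")


# ---------------------------------------------------------------------------
# expression matrix + paired design
# ---------------------------------------------------------------------------

def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise DuplicateIdError(f"duplicate {what}: {dups[:5]}")


def validate_design(design: pd.DataFrame, sample_ids) -> pd.DataFrame:
    """Validate a paired design against the matrix columns."""
    required = {"patient_id", "tumor_sample_id", "normal_sample_id"}
    if not required.issubset(design.columns):
        raise MalformedRecordError(
            f"design must have columns {sorted(required)}")
    _check_unique(design["patient_id"], "patient_id")
    referenced = pd.concat(
        [design["tumor_sample_id"], design["normal_sample_id"]])
    _check_unique(referenced, "sample reference")
    missing = set(referenced) - set(sample_ids)
    if missing:
        raise MissingSampleError(
            f"design references samples absent from matrix: {sorted(missing)}")
    return design.reset_index(drop=True)


def validate_expression(matrix: pd.DataFrame, floor: float | None = None) -> pd.DataFrame:
    """Check an intensity matrix: unique labels, numeric, strictly positive.

    ``floor`` optionally clips non-positive intensities up to the given value
    instead of rejecting them.
    """
    _check_unique(matrix.index, "probe_id")
    _check_unique(matrix.columns, "sample_id")
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise NonNumericValueError("expression matrix contains non-numeric cells")
    if not np.all(np.isfinite(values)):
        raise NonNumericValueError("expression matrix contains non-finite cells")
    if np.any(values <= 0):
        if floor is None:
            bad = int((values <= 0).sum())
            raise NonPositiveIntensityError(
                f"{bad} non-positive intensities; pass a floor to clip them")
        matrix = matrix.clip(lower=floor)
    return matrix


def read_expression(path, design_path, floor: float | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read an expression TSV and its paired-design CSV, fully validated."""
    try:
        matrix = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except ValueError as exc:
        raise NonNumericValueError(f"{path}: {exc}") from exc
    for col in matrix.columns:
        if not np.issubdtype(matrix[col].dtype, np.number):
            bad = matrix[col][pd.to_numeric(matrix[col], errors="coerce").isna()]
            raise NonNumericValueError(
                f"{path}: non-numeric cell(s) in sample {col!r}: "
                f"{bad.head(3).to_dict()}")
    matrix = validate_expression(matrix, floor=floor)
    design = pd.read_csv(design_path, comment="#", dtype=str)
    design = validate_design(design, matrix.columns)
    return matrix, design


def write_expression(matrix: pd.DataFrame, path, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(config_hash))
        matrix.to_csv(fh, sep="\t", index_label="probe_id")


def write_design(design: pd.DataFrame, path, config_hash: str | None = None) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_header_comment(config_hash))
        design.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# probe annotation
# ---------------------------------------------------------------------------

def validate_annotation(annot: pd.DataFrame) -> pd.DataFrame:
    missing = set(ANNOTATION_COLUMNS) - set(annot.columns)
    if missing:
        raise MalformedRecordError(f"annotation missing columns {sorted(missing)}")
    if annot["probe_id"].duplicated().any():
        dups = annot.loc[annot["probe_id"].duplicated(), "probe_id"].tolist()
        raise MultiMappingProbeError(
            f"probes mapping to multiple transcripts: {dups[:5]}")
    if not annot["biotype"].isin(["lncRNA", "mRNA"]).all():
        bad = sorted(set(annot["biotype"]) - {"lncRNA", "mRNA"})
        raise MalformedRecordError(f"unknown biotype(s): {bad}")
    if not annot["strand"].isin(["+", "-"]).all():
        raise MalformedRecordError("strand must be '+' or '-'")
    if (annot["start"] >= annot["end"]).any():
        raise MalformedRecordError("annotation intervals must satisfy start < end")
    return annot.reset_index(drop=True)


def read_annotation(path) -> pd.DataFrame:
    annot = pd.read_csv(path, sep="\t", comment="#",
                        dtype={"start": int, "end": int})
    return validate_annotation(annot)


def write_annotation(annot: pd.DataFrame, path, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(config_hash))
        annot.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets, Ct tables, generic result tables
# ---------------------------------------------------------------------------

def read_gene_set(path) -> set[str]:
    """One identifier per line; unknown ids are preserved verbatim."""
    with open(path) as fh:
        return {
            line.strip() for line in fh
            if line.strip() and not line.startswith("#")
        }


def write_gene_set(ids, path, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(config_hash))
        for gid in sorted(ids):
            fh.write(f"{gid}\n")


def read_ct_table(path) -> pd.DataFrame:
    ct = pd.read_csv(path, comment="#")
    missing = set(CT_COLUMNS) - set(ct.columns)
    if missing:
        raise MalformedRecordError(f"Ct table missing columns {sorted(missing)}")
    for col in ("ct_target", "ct_reference"):
        if not np.issubdtype(ct[col].dtype, np.number):
            raise NonNumericValueError(f"Ct table column {col!r} is not numeric")
    if not ct["condition"].isin(["tumor", "normal"]).all():
        raise MalformedRecordError("condition must be 'tumor' or 'normal'")
    return ct


def write_ct_table(ct: pd.DataFrame, path, config_hash: str | None = None) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_header_comment(config_hash))
        ct.to_csv(fh, index=False, quoting=csv.QUOTE_MINIMAL)


def write_table(df: pd.DataFrame, path, config_hash: str | None = None,
                index: bool = False) -> None:
    """Generic TSV writer for result tables (DE results, calls, edges...)."""
    with open(path, "w") as fh:
        fh.write(_header_comment(config_hash))
        df.to_csv(fh, sep="\t", index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
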