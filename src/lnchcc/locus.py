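"""Genomic relationship of lncRNA transcripts to coding-gene models.

Each lncRNA receives exactly one of six categories relative to the coding
genes on its chromosome:

* ``exon sense-overlapping``   — same strand, overlaps at least one exon
* ``intron sense-overlapping`` — same strand, overlaps the gene but no exon
* ``natural antisense``        — opposite strand, overlap touching >= 1 exon
* ``intronic antisense``       — opposite strand, wholly inside one intron
* ``bidirectional``            — no overlap with any gene, but a gene on the
  opposite strand starts within ``bidir_tss_max`` bp (TSS-to-TSS)
* ``intergenic``               — none of the above

When several relations hold (possibly against different genes) the single
label is chosen by precedence: overlap evidence outranks promoter geometry
and sense outranks antisense, i.e. exon sense > intron sense >
natural antisense > intronic antisense > bidirectional > intergenic.

The nearest coding gene is the one minimizing the inter-interval gap
(0 when overlapping); genes at or beyond the ``window`` (default 300 kb,
strict ``<``) are not reported.  Equidistant ties break to the
lexicographically smaller gene id so the classification is deterministic and
independent of input ordering.
"""
from __future__ import annotations

import warnings
from collections import defaultdict

import pandas as pd
from intervaltree import IntervalTree
from sklearn.base import BaseEstimator

from .exceptions import UnknownChromosomeError
from .io import GeneModel

CATEGORIES = (
    "exon sense-overlapping",
    "intron sense-overlapping",
    "natural antisense",
    "intronic antisense",
    "bidirectional",
    "intergenic",
)
_RANK = {c: i for i, c in enumerate(CATEGORIES)}

__all__ = ["CATEGORIES", "PositionalClassifier", "classify",
           "nearest_gene", "subgroup_filter"]


def _overlap(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end


def _gap(a_start, a_end, b_start, b_end) -> int:
    if _overlap(a_start, a_end, b_start, b_end):
        return 0
    return max(b_start - a_end, a_start - b_end)


class PositionalClassifier(BaseEstimator):
    """Classify lncRNA intervals against an indexed set of gene models.

    ``fit`` indexes the gene models (interval tree per chromosome);
    ``predict`` labels a table of lncRNA intervals and reports each one's
    nearest coding gene within the window.
    """

    def __init__(self, window: int = 300_000, bidir_tss_max: int = 1_000):
        self.window = window
        self.bidir_tss_max = bidir_tss_max

    def fit(self, genes: list[GeneModel], y=None):
        self.genes_ = {g.gene_id: g for g in genes}
        self.trees_ = defaultdict(IntervalTree)
        self.by_chrom_ = defaultdict(list)
        for g in genes:
            self.trees_[g.chromosome].addi(g.start, g.end, g.gene_id)
            self.by_chrom_[g.chromosome].append(g)
        return self

    # -- single-interval operations -------------------------------------

    def classify_one(self, chromosome: str, start: int, end: int,
                     strand: str) -> str:
        if chromosome not in self.by_chrom_:
            raise UnknownChromosomeError(
                f"chromosome {chromosome!r} absent from gene models")
        best = "intergenic"
        overlapping = self.trees_[chromosome].overlap(start, end)
        for iv in overlapping:
            gene = self.genes_[iv.data]
            cat = self._overlap_category(start, end, strand, gene)
            if _RANK[cat] < _RANK[best]:
                best = cat
        if not overlapping and best == "intergenic":
            tss = start if strand == "+" else end
            for gene in self.by_chrom_[chromosome]:
                if gene.strand != strand and \
                        abs(tss - gene.tss) <= self.bidir_tss_max:
                    best = "bidirectional"
                    break
        return best

    @staticmethod
    def _overlap_category(start: int, end: int, strand: str,
                          gene: GeneModel) -> str:
        exon_hit = any(_overlap(start, end, a, b) for a, b in gene.exons)
        if strand == gene.strand:
            return "exon sense-overlapping" if exon_hit \
                else "intron sense-overlapping"
        if not exon_hit and any(
                a <= start and end <= b for a, b in gene.introns):
            return "intronic antisense"
        return "natural antisense"

    def nearest_gene(self, chromosome: str, start: int, end: int
                     ) -> tuple[str | None, int | None]:
        """Nearest gene id and gap within the window; (None, None) if empty."""
        best_id, best_gap = None, None
        for gene in self.by_chrom_.get(chromosome, []):
            gap = _gap(start, end, gene.start, gene.end)
            if gap >= self.window:
                continue
            if best_gap is None or gap < best_gap or \
                    (gap == best_gap and gene.gene_id < best_id):
                best_id, best_gap = gene.gene_id, gap
        return best_id, best_gap

    # -- table-level interface ------------------------------------------

    def predict(self, lnc: pd.DataFrame) -> pd.DataFrame:
        """Positional calls for a table of lncRNA intervals.

        ``lnc`` needs columns chromosome, start, end, strand, and an
        identifier column (``probe_id`` and/or ``transcript_id``), which is
        carried through to the output.
        """
        records = []
        for row in lnc.itertuples(index=False):
            category = self.classify_one(
                row.chromosome, row.start, row.end, row.strand)
            gene_id, distance = self.nearest_gene(
                row.chromosome, row.start, row.end)
            rec = {}
            for id_col in ("probe_id", "transcript_id"):
                if hasattr(row, id_col):
                    rec[id_col] = getattr(row, id_col)
            rec.update(category=category, nearby_gene_id=gene_id,
                       distance_bp=distance)
            records.append(rec)
        return pd.DataFrame(records)


def classify(chromosome, start, end, strand, genes: list[GeneModel],
             window: int = 300_000, bidir_tss_max: int = 1_000
             ) -> tuple[str, str | None, int | None]:
    """One-shot classification of a single lncRNA interval."""
    clf = PositionalClassifier(window, bidir_tss_max).fit(genes)
    category = clf.classify_one(chromosome, start, end, strand)
    gene_id, distance = clf.nearest_gene(chromosome, start, end)
    return category, gene_id, distance


def nearest_gene(chromosome, start, end, genes: list[GeneModel],
                 window: int = 300_000) -> tuple[str | None, int | None]:
    return PositionalClassifier(window).fit(genes).nearest_gene(
        chromosome, start, end)


def subgroup_filter(calls: pd.DataFrame, de_ids: set, catalog: set,
                    id_col: str = "probe_id") -> dict:
    """Catalog members that are differentially expressed, and how many of
    those lie near a differentially expressed coding gene.

    ``de_ids`` is the union of DE identifiers for both biotypes (lncRNA ids in
    ``calls[id_col]`` and coding gene ids as they appear in
    ``nearby_gene_id``); the nearest-gene window was already applied by the
    classifier.
    """
    if not catalog:
        warnings.warn("empty subgroup catalog")
    members = calls[calls[id_col].isin(catalog)]
    de_members = members[members[id_col].isin(de_ids)]
    with_de_neighbor = de_members[
        de_members["nearby_gene_id"].notna()
        & de_members["nearby_gene_id"].isin(de_ids)
    ]
    return {
        "n_catalog": len(catalog),
        "n_detected": int(len(members)),
        "n_de": int(len(de_members)),
        "n_de_with_de_neighbor": int(len(with_de_neighbor)),
        "table": de_members.assign(
            neighbor_de=de_members["nearby_gene_id"].isin(de_ids)),
    }
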