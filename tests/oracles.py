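"""Independent brute-force oracles used by the test suite.

These are deliberately naive implementations kept separate from the package:
closed-form t-test p-values via the regularized incomplete beta function, a
literal step-up FDR, and an exhaustive interval-arithmetic positional
classifier that scans every gene without any index.
"""
import math

import numpy as np
from scipy.special import betainc


def paired_t_p(diffs) -> tuple[float, float]:
    """Closed-form two-sided one-sample t-test: p = I_{df/(df+t^2)}(df/2, 1/2)."""
    d = np.asarray(diffs, dtype=float)
    n = d.size
    mean = d.mean()
    se = d.std(ddof=1) / math.sqrt(n)
    t = mean / se
    df = n - 1
    p = betainc(df / 2.0, 0.5, df / (df + t * t))
    return t, float(p)


def bh_stepup(p_values) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up with the running-minimum pass."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        adjusted[idx] = running_min
    return adjusted


def correlation_t_p(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
    df = n - 2
    return float(betainc(df / 2.0, 0.5, df / (df + t * t)))


# ---------------------------------------------------------------------------
# exhaustive positional classification
# ---------------------------------------------------------------------------

def _overlap(a0, a1, b0, b1):
    return a0 < b1 and b0 < a1


def brute_force_classify(lnc, genes, window=300_000, bidir_tss_max=1_000):
    """(category, nearest_gene_id, distance) by exhaustive scan.

    ``lnc`` is (chrom, start, end, strand); ``genes`` is a list of objects
    with gene_id, chromosome, start, end, strand, exons, introns, tss.
    """
    chrom, start, end, strand = lnc
    categories = []
    on_chrom = [g for g in genes if g.chromosome == chrom]
    any_overlap = False
    for g in on_chrom:
        if not _overlap(start, end, g.start, g.end):
            continue
        any_overlap = True
        exon_hit = any(_overlap(start, end, a, b) for a, b in g.exons)
        if strand == g.strand:
            categories.append(
                "exon sense-overlapping" if exon_hit
                else "intron sense-overlapping")
        elif not exon_hit and any(a <= start and end <= b for a, b in g.introns):
            categories.append("intronic antisense")
        else:
            categories.append("natural antisense")
    if not any_overlap:
        tss = start if strand == "+" else end
        for g in on_chrom:
            if g.strand != strand and abs(tss - g.tss) <= bidir_tss_max:
                categories.append("bidirectional")
                break
    precedence = ["exon sense-overlapping", "intron sense-overlapping",
                  "natural antisense", "intronic antisense",
                  "bidirectional", "intergenic"]
    category = next((c for c in precedence if c in categories), "intergenic")

    best_id, best_gap = None, None
    for g in on_chrom:
        gap = 0 if _overlap(start, end, g.start, g.end) \
            else max(g.start - end, start - g.end)
        if gap >= window:
            continue
        if best_gap is None or gap < best_gap \
                or (gap == best_gap and g.gene_id < best_id):
            best_id, best_gap = g.gene_id, gap
    return category, best_id, best_gap


def random_toy_config(rng):
    """A randomized toy chromosome: 1-4 genes and one lncRNA interval."""
    from lnchcc.io import GeneModel

    genes = []
    for gi in range(rng.integers(1, 5)):
        start = int(rng.integers(0, 500_000))
        n_exons = int(rng.integers(1, 4))
        exon_len = int(rng.integers(100, 800))
        intron_len = int(rng.integers(200, 3_000))
        exons = []
        pos = start
        for _ in range(n_exons):
            exons.append((pos, pos + exon_len))
            pos += exon_len + intron_len
        end = exons[-1][1]
        genes.append(GeneModel(f"G{gi}", "chr1", start, end,
                               "+" if rng.random() < 0.5 else "-", exons))
    lnc_start = int(rng.integers(0, 700_000))
    lnc_len = int(rng.integers(100, 5_000))
    lnc_strand = "+" if rng.random() < 0.5 else "-"
    return ("chr1", lnc_start, lnc_start + lnc_len, lnc_strand), genes
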