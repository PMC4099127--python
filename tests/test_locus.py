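import numpy as np
import pandas as pd
import pytest

from lnchcc import CATEGORIES, PositionalClassifier, classify, subgroup_filter
from lnchcc.exceptions import UnknownChromosomeError
from lnchcc.io import GeneModel
from oracles import brute_force_classify, random_toy_config


@pytest.fixture
def toy_gene():
    # + strand gene, exons at both ends and in the middle
    return GeneModel("GENEA", "chr1", 1_000, 6_000, "+",
                     [(1_000, 1_400), (3_000, 3_600), (5_600, 6_000)])


@pytest.mark.parametrize("start,end,strand,expected", [
    (3_100, 3_300, "+", "exon sense-overlapping"),
    (1_500, 2_900, "+", "intron sense-overlapping"),
    (3_100, 3_300, "-", "natural antisense"),
    (1_500, 2_900, "-", "intronic antisense"),
    (200, 500, "-", "bidirectional"),          # TSS-to-TSS gap 500
    (200_000, 201_000, "+", "intergenic"),
    (900, 1_200, "-", "natural antisense"),    # overlaps first exon, antisense
    (5_500, 6_500, "+", "exon sense-overlapping"),
])
def test_six_category_vocabulary(toy_gene, start, end, strand, expected):
    category, _, _ = classify("chr1", start, end, strand, [toy_gene])
    assert category == expected
    assert expected in CATEGORIES


def test_bidirectional_requires_opposite_strand_and_close_tss(toy_gene):
    same_strand, _, _ = classify("chr1", 200, 500, "+", [toy_gene])
    assert same_strand == "intergenic"
    too_far, _, _ = classify("chr1", 7_200, 7_900, "-", [toy_gene])
    assert too_far == "intergenic"


def test_precedence_exon_sense_beats_antisense():
    plus = GeneModel("GP", "chr1", 1_000, 3_000, "+", [(1_000, 3_000)])
    minus = GeneModel("GM", "chr1", 1_500, 2_500, "-", [(1_500, 2_500)])
    category, _, _ = classify("chr1", 1_600, 2_400, "+", [plus, minus])
    assert category == "exon sense-overlapping"


def test_unknown_chromosome_is_named_error(toy_gene):
    clf = PositionalClassifier().fit([toy_gene])
    with pytest.raises(UnknownChromosomeError):
        clf.classify_one("chrZ", 0, 100, "+")


# ---------------------------------------------------------------------------
# nearest gene
# ---------------------------------------------------------------------------

def test_nearest_gene_window_and_tie_break():
    genes = [
        GeneModel("G_NEAR", "chr1", 110_000, 115_000, "+"),
        GeneModel("G_FAR", "chr1", 350_000, 360_000, "+"),
    ]
    clf = PositionalClassifier().fit(genes)
    gene, dist = clf.nearest_gene("chr1", 99_000, 100_000)
    assert gene == "G_NEAR" and dist == 10_000

    # gap exactly 300 kb: strict '<' excludes it
    sole = [GeneModel("G1", "chr1", 400_000, 405_000, "+")]
    clf = PositionalClassifier().fit(sole)
    assert clf.nearest_gene("chr1", 99_000, 100_000) == (None, None)
    assert clf.nearest_gene("chr1", 99_001, 100_001)[0] == "G1"

    # equidistant: lexicographically smaller id wins
    twins = [GeneModel("GB", "chr1", 10_000, 11_000, "+"),
             GeneModel("GA", "chr1", 4_000, 5_000, "+")]
    clf = PositionalClassifier().fit(twins)
    gene, dist = clf.nearest_gene("chr1", 7_000, 8_000)
    assert dist == 2_000 and gene == "GA"


def test_overlapping_gene_has_distance_zero(toy_gene):
    clf = PositionalClassifier().fit([toy_gene])
    assert clf.nearest_gene("chr1", 2_000, 2_100) == ("GENEA", 0)


# ---------------------------------------------------------------------------
# invariance properties
# ---------------------------------------------------------------------------

def _flip(strand):
    return "-" if strand == "+" else "+"


def test_strand_flip_and_shift_preserve_calls(rng):
    overlap_cats = {"exon sense-overlapping", "intron sense-overlapping",
                    "natural antisense", "intronic antisense"}
    for _ in range(200):
        lnc, genes = random_toy_config(rng)
        cat, gid, dist = classify(*lnc, genes)
        # strand flip preserves every overlap-defined category (bidirectional
        # depends on TSS geometry, which an isolated strand flip moves)
        if cat in overlap_cats:
            flipped_genes = [
                GeneModel(g.gene_id, g.chromosome, g.start, g.end,
                          _flip(g.strand), g.exons) for g in genes]
            cat_f, _, _ = classify(lnc[0], lnc[1], lnc[2], _flip(lnc[3]),
                                   flipped_genes)
            assert cat_f == cat
        # full reflection (mirror coordinates + flip strands) preserves all
        origin = 1_000_000
        mirrored_genes = [
            GeneModel(g.gene_id, g.chromosome, origin - g.end,
                      origin - g.start, _flip(g.strand),
                      [(origin - b, origin - a) for a, b in g.exons])
            for g in genes]
        cat_m, gid_m, dist_m = classify(
            lnc[0], origin - lnc[2], origin - lnc[1], _flip(lnc[3]),
            mirrored_genes)
        assert (cat_m, gid_m, dist_m) == (cat, gid, dist)
        shift = 12_345
        shifted_genes = [
            GeneModel(g.gene_id, g.chromosome, g.start + shift, g.end + shift,
                      g.strand, [(a + shift, b + shift) for a, b in g.exons])
            for g in genes]
        cat_s, gid_s, dist_s = classify(
            lnc[0], lnc[1] + shift, lnc[2] + shift, lnc[3], shifted_genes)
        assert (cat_s, gid_s, dist_s) == (cat, gid, dist)


def test_classification_independent_of_gene_order(rng):
    for _ in range(50):
        lnc, genes = random_toy_config(rng)
        forward = classify(*lnc, genes)
        backward = classify(*lnc, list(reversed(genes)))
        assert forward == backward


def test_agreement_with_brute_force_oracle(rng):
    for _ in range(300):
        lnc, genes = random_toy_config(rng)
        cat, gid, dist = classify(*lnc, genes)
        assert (cat, gid, dist) == brute_force_classify(lnc, genes)


# ---------------------------------------------------------------------------
# generator truth and subgroup filter
# ---------------------------------------------------------------------------

def test_generator_planted_categories_recovered_exactly(demo_dataset):
    clf = PositionalClassifier().fit(demo_dataset.genes)
    lnc = demo_dataset.annotation[demo_dataset.annotation.biotype == "lncRNA"]
    pred = clf.predict(lnc)
    truth = demo_dataset.truth.positional
    merged = pred.merge(truth, on="probe_id", suffixes=("_pred", "_true"))
    assert len(merged) == len(truth)
    assert (merged.category_pred == merged.category_true).all()
    same_gene = (merged.nearby_gene_id_pred == merged.nearby_gene_id_true) \
        | (merged.nearby_gene_id_pred.isna() & merged.nearby_gene_id_true.isna())
    assert same_gene.all()
    for cat in CATEGORIES:
        assert (truth.category == cat).any()


def test_far_intergenic_lnc_has_no_nearby_gene(demo_dataset):
    truth = demo_dataset.truth.positional
    far = truth[truth.nearby_gene_id.isna()]
    assert len(far) > 0
    assert (far.category == "intergenic").all()


def test_subgroup_filter_counts_planted_de_neighbors():
    calls = pd.DataFrame({
        "probe_id": [f"L{i}" for i in range(12)],
        "category": ["intergenic"] * 12,
        "nearby_gene_id": [f"G{i}" for i in range(10)] + [None, "G10"],
        "distance_bp": [1_000] * 10 + [None, 5_000],
    })
    catalog = {f"L{i}" for i in range(10)}
    de_ids = {f"L{i}" for i in range(10)} | {"G0", "G1", "G2", "G3"}
    res = subgroup_filter(calls, de_ids, catalog)
    assert res["n_de"] == 10
    assert res["n_de_with_de_neighbor"] == 4

    with pytest.warns(UserWarning):
        empty = subgroup_filter(calls, de_ids, set())
    assert empty["n_de"] == 0

    disjoint = subgroup_filter(calls, de_ids, {"NOPE"})
    assert disjoint["n_de"] == 0

    # catalog equal to all DE lncRNAs: first count equals total DE lncRNAs
    res_all = subgroup_filter(calls, de_ids, {f"L{i}" for i in range(12)})
    assert res_all["n_de"] == 10
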