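import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lnchcc import (
    FcBinSummary,
    PairedDifferentialExpression,
    bh_fdr,
    bin_fold_changes,
    call_de,
    paired_t_test,
    per_pair_log2_ratio,
    quantile_normalize,
)
from lnchcc.exceptions import InsufficientPairsError, NonPositiveIntensityError
from oracles import bh_stepup, paired_t_p


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def test_quantile_normalize_rank_mean_oracle():
    m = pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 4.0]}, index=["p1", "p2"])
    out = quantile_normalize(m)
    expected = pd.DataFrame({"a": [1.5, 3.5], "b": [1.5, 3.5]},
                            index=["p1", "p2"])
    pd.testing.assert_frame_equal(out, expected)


def test_quantile_normalize_fixed_point_on_identical_columns():
    col = [2.0, 7.0, 1.0, 5.0]
    m = pd.DataFrame({"a": col, "b": col, "c": col})
    pd.testing.assert_frame_equal(quantile_normalize(m), m)


def test_quantile_normalize_postcondition_and_idempotence(rng):
    m = pd.DataFrame(2.0 ** rng.normal(10, 3, (200, 6)),
                     columns=[f"s{i}" for i in range(6)])
    out = quantile_normalize(m)
    sorted_cols = np.sort(out.to_numpy(), axis=0)
    spread = sorted_cols.max(axis=1) - sorted_cols.min(axis=1)
    assert spread.max() < 1e-9
    again = quantile_normalize(out)
    np.testing.assert_allclose(again.to_numpy(), out.to_numpy(), atol=1e-9)
    assert out.index.equals(m.index) and out.columns.equals(m.columns)


def test_quantile_normalize_single_sample_warns_and_passes_through():
    m = pd.DataFrame({"only": [1.0, 2.0]})
    with pytest.warns(UserWarning):
        out = quantile_normalize(m)
    pd.testing.assert_frame_equal(out, m)


# ---------------------------------------------------------------------------
# log2 ratios
# ---------------------------------------------------------------------------

def _design(n):
    return pd.DataFrame({
        "patient_id": [f"H{i+1}" for i in range(n)],
        "tumor_sample_id": [f"T{i+1}" for i in range(n)],
        "normal_sample_id": [f"N{i+1}" for i in range(n)],
    })


def test_per_pair_log2_ratio_trivials_and_brute_force(rng):
    m = pd.DataFrame({"T1": [4.0], "N1": [1.0], "T2": [2.0], "N2": [2.0]},
                     index=["p"])
    r = per_pair_log2_ratio(m, _design(2))
    assert r.loc["p", "H1"] == 2.0       # tumor = 4 x normal
    assert r.loc["p", "H2"] == 0.0       # tumor = normal

    vals = rng.uniform(0.5, 100, (5, 6))
    m = pd.DataFrame(vals, columns=["T1", "T2", "T3", "N1", "N2", "N3"])
    r = per_pair_log2_ratio(m, _design(3))
    np.testing.assert_allclose(
        r.to_numpy(), np.log2(vals[:, :3]) - np.log2(vals[:, 3:]))

    m.iloc[0, 0] = -1.0
    with pytest.raises(NonPositiveIntensityError):
        per_pair_log2_ratio(m, _design(3))


# ---------------------------------------------------------------------------
# paired t-test
# ---------------------------------------------------------------------------

def test_paired_t_matches_closed_form_oracle():
    t, p = paired_t_test(np.array([1.0, 1.2, 0.8]))
    t_oracle, p_oracle = paired_t_p([1.0, 1.2, 0.8])
    assert t == pytest.approx(8.660254, abs=1e-6)
    assert p == pytest.approx(0.0131, abs=1e-4)
    assert abs(p - p_oracle) < 1e-10 and abs(t - t_oracle) < 1e-10


def test_paired_t_degenerate_inputs():
    t, p = paired_t_test(np.array([0.0, 0.0, 0.0]))
    assert t == 0.0 and p == 1.0
    t, p = paired_t_test(np.array([1.0, 1.0, 1.0]))  # zero var, nonzero mean
    assert np.isinf(t) and p == 0.0
    with pytest.raises(InsufficientPairsError):
        paired_t_test(np.array([1.0]))


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(-10, 10), min_size=2, max_size=8))
def test_paired_t_agrees_with_oracle_everywhere(diffs):
    d = np.asarray(diffs)
    if d.std(ddof=1) == 0:
        return
    _, p = paired_t_test(d)
    _, p_oracle = paired_t_p(d)
    assert abs(p - p_oracle) < 1e-10


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------

def test_bh_hand_oracle_cases():
    np.testing.assert_allclose(bh_fdr([0.5]), [0.5])
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
def test_bh_matches_stepup_oracle_and_is_monotone(ps):
    q = bh_fdr(ps)
    np.testing.assert_allclose(q, bh_stepup(ps), atol=1e-12)
    assert np.all((q >= 0) & (q <= 1))
    order = np.argsort(ps, kind="stable")
    assert np.all(np.diff(q[order]) >= -1e-12)
    assert np.all(q >= np.asarray(ps) - 1e-12)


# ---------------------------------------------------------------------------
# calling and binning
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("fc,p,q,expected", [
    (2.0, 0.01, 0.04, "up"),        # fold boundary inclusive
    (0.5, 0.01, 0.04, "down"),
    (1.0, 0.001, 0.001, "ns"),      # fold fails
    (0.25, 0.2, 0.01, "ns"),        # p fails
    (4.0, 0.01, 0.06, "ns"),        # FDR fails
])
def test_call_de_triple_criterion(fc, p, q, expected):
    assert call_de([fc], [p], [q])[0] == expected


def test_bin_fold_changes_half_open_edges():
    up_folds = [2.0, 3.99, 4.0, 6.0, 8.5]
    ratios = np.log2(up_folds)
    s = bin_fold_changes(ratios, "H1")
    assert s.up_bins == (2, 1, 2)
    assert s.down_bins == (0, 0, 0)
    assert s.up_total == 5


def test_bin_fold_changes_down_uses_reciprocal_fold():
    ratios = np.log2([1 / 2.0, 1 / 5.0, 1 / 7.0, 3.0])
    s = bin_fold_changes(ratios, "H1")
    assert s.down_bins == (1, 1, 1)
    assert s.up_bins == (1, 0, 0)
    assert s.aberrant == 4


def test_bin_empty_ratio_set_is_all_zero():
    s = bin_fold_changes([], "H9")
    assert s.up_bins == s.down_bins == (0, 0, 0)
    assert s.aberrant == 0


def test_fc_bin_summary_totals_reproduce_reference_row():
    # published per-patient tallies aggregate exactly
    s = FcBinSummary("H1", (1917, 461, 335), (1120, 235, 301))
    assert s.up_total == 2713
    assert s.down_total == 1656
    assert s.aberrant == 4369


# ---------------------------------------------------------------------------
# estimator-level properties
# ---------------------------------------------------------------------------

def test_calls_invariant_under_global_rescaling(demo_dataset, fitted_de):
    scaled = demo_dataset.matrix * 2.7
    biotype = demo_dataset.annotation.set_index("probe_id")["biotype"]
    de2 = PairedDifferentialExpression().fit(
        quantile_normalize(scaled), demo_dataset.design, biotype)
    assert (de2.results_["call"] == fitted_de.results_["call"]).all()


def test_fdr_within_biotype_vs_pooled_flag(demo_dataset, normalized):
    biotype = demo_dataset.annotation.set_index("probe_id")["biotype"]
    pooled = PairedDifferentialExpression(fdr_within_biotype=False).fit(
        normalized, demo_dataset.design, biotype)
    q = pooled.results_["q_value"].to_numpy()
    np.testing.assert_allclose(
        q, bh_stepup(pooled.results_["p_value"].to_numpy()), atol=1e-12)


def test_null_calibration_type_I_error():
    """With no planted effects the p<0.05 fraction stays near 0.05."""
    from lnchcc import generate_expression, null_config

    matrix, design, _ = generate_expression(null_config(7))
    ratios = per_pair_log2_ratio(matrix, design)
    _, p = paired_t_test(ratios.to_numpy())
    frac = (p < 0.05).mean()
    se = np.sqrt(0.05 * 0.95 / p.size)
    assert abs(frac - 0.05) < 3 * se


def test_planted_signal_recovery(demo_dataset, fitted_de):
    """Recall and precision >= 0.9 against the generator's ground truth."""
    calls = fitted_de.results_["call"]
    called = set(fitted_de.results_.index[calls != "ns"])
    truth = demo_dataset.truth.probes.set_index("probe_id")["de_status"]
    planted = set(truth.index[truth != "null"])
    tp = len(called & planted)
    assert tp / len(planted) >= 0.9
    assert tp / len(called) >= 0.9
    # directions agree with the planted signs
    res = fitted_de.results_
    up_called = res.loc[sorted(called & planted), "call"] == "up"
    planted_up = truth[sorted(called & planted)] == "up"
    assert (up_called == planted_up).all()
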