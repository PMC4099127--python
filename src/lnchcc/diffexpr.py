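"""Paired tumor/normal differential expression on microarray intensities.

The calling rule is the triple criterion used throughout this pipeline: linear
fold change >= 2.0 (up) or <= 0.5 (down), two-sided paired t-test p < 0.05 and
Benjamini-Hochberg FDR < 0.05.  Fold change is the geometric mean of the
per-patient tumor/normal ratios, i.e. 2 to the mean per-pair log2 ratio.
FDR is computed within biotype (lncRNA and mRNA probes adjusted separately) by
default, matching the separate tallies such profiling studies report; a flag
pools them.

Per-patient summaries count up- and down-regulated probes into half-open
linear fold bins [2,4), [4,6), [6,inf) — down-regulated probes are binned by
the reciprocal fold N/T so the up/down tables are symmetric.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from ._stats import bh_fdr, paired_t_test
from .exceptions import NonPositiveIntensityError

__all__ = [
    "QuantileNormalizer",
    "quantile_normalize",
    "per_pair_log2_ratio",
    "call_de",
    "PairedDifferentialExpression",
    "FcBinSummary",
    "bin_fold_changes",
    "summarize_fold_bins",
]


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Force all arrays (columns) to share one intensity distribution.

    ``fit`` learns the reference distribution — the across-array means of the
    column-sorted intensities; ``transform`` replaces each array's values by
    the reference quantile of their within-array rank (ties receive the mean
    of the tied reference values).  Fitting and transforming the same matrix
    is the classical quantile normalization and is idempotent.
    """

    def fit(self, X: pd.DataFrame, y=None):
        X = self._validate(X)
        sorted_cols = np.sort(X.to_numpy(dtype=float), axis=0)
        self.reference_ = sorted_cols.mean(axis=1)
        self.n_probes_ = X.shape[0]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = self._validate(X)
        if X.shape[0] != self.n_probes_:
            raise ValueError(
                f"matrix has {X.shape[0]} probes, normalizer fitted on "
                f"{self.n_probes_}")
        if X.shape[1] < 2:
            warnings.warn("single-sample matrix passed through unchanged")
            return X.copy()
        values = X.to_numpy(dtype=float)
        out = np.empty_like(values)
        for j in range(values.shape[1]):
            ranks = stats.rankdata(values[:, j], method="average")
            # average rank -> interpolated reference value handles ties
            out[:, j] = np.interp(
                ranks, np.arange(1, self.n_probes_ + 1), self.reference_)
        return pd.DataFrame(out, index=X.index, columns=X.columns)

    @staticmethod
    def _validate(X: pd.DataFrame) -> pd.DataFrame:
        if np.any(X.to_numpy() <= 0):
            raise NonPositiveIntensityError(
                "quantile normalization expects strictly positive intensities")
        return X


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize the columns of ``matrix`` (thin estimator wrapper)."""
    if matrix.shape[1] < 2:
        warnings.warn("single-sample matrix passed through unchanged")
        return matrix.copy()
    return QuantileNormalizer().fit(matrix).transform(matrix)


def per_pair_log2_ratio(matrix: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """log2(tumor) - log2(normal) per probe and patient.

    Returns a probes x patients DataFrame indexed like ``matrix`` with the
    design's ``patient_id`` values as columns.
    """
    values = matrix.to_numpy(dtype=float)
    if np.any(values <= 0):
        raise NonPositiveIntensityError(
            "log2 ratios require strictly positive intensities")
    tumor = matrix[design["tumor_sample_id"].to_numpy()].to_numpy(dtype=float)
    normal = matrix[design["normal_sample_id"].to_numpy()].to_numpy(dtype=float)
    ratios = np.log2(tumor) - np.log2(normal)
    return pd.DataFrame(ratios, index=matrix.index,
                        columns=design["patient_id"].to_numpy())


def call_de(mean_fc, p, q, fc_threshold: float = 2.0,
            p_threshold: float = 0.05, fdr_threshold: float = 0.05) -> np.ndarray:
    """Vectorized triple-criterion call: 'up', 'down' or 'ns'.

    Boundaries are inclusive for the fold criterion (fold >= 2.0 / <= 0.5) and
    strict for p and FDR.
    """
    mean_fc = np.asarray(mean_fc, dtype=float)
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    sig = (p < p_threshold) & (q < fdr_threshold)
    call = np.full(mean_fc.shape, "ns", dtype=object)
    call[sig & (mean_fc >= fc_threshold)] = "up"
    call[sig & (mean_fc <= 1.0 / fc_threshold)] = "down"
    return call


class PairedDifferentialExpression(BaseEstimator):
    """Call differentially expressed probes from a paired tumor/normal design.

    Parameters
    ----------
    fc_threshold : linear fold-change cutoff (up: >= fc, down: <= 1/fc).
    p_threshold, fdr_threshold : paired t-test and BH FDR cutoffs.
    fdr_within_biotype : adjust lncRNA and mRNA probes separately (default);
        set False to pool all probes into one BH adjustment.
    require_per_pair_fc : additionally require the fold criterion in every
        individual patient, not only on the geometric-mean fold.

    Attributes (after ``fit``)
    --------------------------
    ratios_ : probes x patients log2(T/N) DataFrame.
    results_ : one row per probe with per-pair ratios, ``mean_log2_fc``,
        ``fold_change``, ``p_value``, ``q_value``, ``call``,
        ``consistent_direction`` and ``zero_variance``.
    """

    def __init__(self, fc_threshold: float = 2.0, p_threshold: float = 0.05,
                 fdr_threshold: float = 0.05, fdr_within_biotype: bool = True,
                 require_per_pair_fc: bool = False):
        self.fc_threshold = fc_threshold
        self.p_threshold = p_threshold
        self.fdr_threshold = fdr_threshold
        self.fdr_within_biotype = fdr_within_biotype
        self.require_per_pair_fc = require_per_pair_fc

    def fit(self, X: pd.DataFrame, design: pd.DataFrame,
            biotype: pd.Series | None = None):
        ratios = per_pair_log2_ratio(X, design)
        t, p = paired_t_test(ratios.to_numpy())
        if biotype is None:
            biotype = pd.Series("lncRNA", index=X.index, name="biotype")
        else:
            biotype = biotype.reindex(X.index)
        if self.fdr_within_biotype:
            q = np.empty_like(p)
            for bt in biotype.unique():
                mask = (biotype == bt).to_numpy()
                q[mask] = bh_fdr(p[mask])
        else:
            q = bh_fdr(p)
        mean_log2 = ratios.to_numpy().mean(axis=1)
        fold = 2.0 ** mean_log2
        call = call_de(fold, p, q, self.fc_threshold,
                       self.p_threshold, self.fdr_threshold)
        if self.require_per_pair_fc:
            per_pair_fold = 2.0 ** ratios.to_numpy()
            all_up = (per_pair_fold >= self.fc_threshold).all(axis=1)
            all_down = (per_pair_fold <= 1 / self.fc_threshold).all(axis=1)
            call = np.where(
                (call == "up") & ~all_up, "ns",
                np.where((call == "down") & ~all_down, "ns", call))
        signs = np.sign(ratios.to_numpy())
        consistent = (np.abs(signs.sum(axis=1)) == ratios.shape[1])
        zero_var = ratios.to_numpy().std(axis=1, ddof=1) == 0

        self.ratios_ = ratios
        results = ratios.copy()
        results.columns = [f"log2_ratio_{c}" for c in ratios.columns]
        results.insert(0, "biotype", biotype.to_numpy())
        results["mean_log2_fc"] = mean_log2
        results["fold_change"] = fold
        results["t_statistic"] = t
        results["p_value"] = p
        results["q_value"] = q
        results["call"] = call
        results["consistent_direction"] = consistent
        results["zero_variance"] = zero_var
        results.index.name = "probe_id"
        self.results_ = results
        return self

    def predict(self, X=None) -> pd.Series:
        """Per-probe call ('up' | 'down' | 'ns') from the fitted results."""
        return self.results_["call"]


# ---------------------------------------------------------------------------
# fold-change bin summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FcBinSummary:
    """Per-patient counts of regulated probes in linear fold bins.

    ``up_bins``/``down_bins`` hold counts in the half-open fold bins
    [2,4), [4,6), [6,inf) (down-regulated probes binned by reciprocal fold);
    ``aberrant`` is the up + down total for the patient.
    """

    patient_id: str
    up_bins: tuple[int, int, int]
    down_bins: tuple[int, int, int]

    @property
    def up_total(self) -> int:
        return int(sum(self.up_bins))

    @property
    def down_total(self) -> int:
        return int(sum(self.down_bins))

    @property
    def aberrant(self) -> int:
        return self.up_total + self.down_total

    def as_rows(self) -> pd.DataFrame:
        return pd.DataFrame({
            "patient_id": [self.patient_id] * 2,
            "direction": ["up", "down"],
            "fold_2_4": [self.up_bins[0], self.down_bins[0]],
            "fold_4_6": [self.up_bins[1], self.down_bins[1]],
            "fold_gt6": [self.up_bins[2], self.down_bins[2]],
            "total": [self.up_total, self.down_total],
            "aberrant": [self.aberrant, self.aberrant],
        })


def bin_fold_changes(log2_ratios, patient_id: str = "",
                     edges: tuple[float, float, float] = (2.0, 4.0, 6.0)
                     ) -> FcBinSummary:
    """Bin one patient's per-probe log2 T/N ratios into fold bins.

    A probe counts as up if its linear fold 2**ratio >= edges[0] and as down
    if the fold <= 1/edges[0]; it is then binned by its fold (up) or
    reciprocal fold (down) into [e0,e1), [e1,e2), [e2,inf).
    """
    r = np.asarray(log2_ratios, dtype=float)
    e0, e1, e2 = edges
    # snap away the log2/exp2 round-trip error so boundary folds bin exactly
    fold = np.round(2.0 ** r, 9)
    up = fold[fold >= e0]
    down = np.round(1.0 / fold[fold <= np.round(1.0 / e0, 9)], 9)

    def _bins(f: np.ndarray) -> tuple[int, int, int]:
        return (
            int(((f >= e0) & (f < e1)).sum()),
            int(((f >= e1) & (f < e2)).sum()),
            int((f >= e2).sum()),
        )

    return FcBinSummary(patient_id, _bins(up), _bins(down))


def summarize_fold_bins(ratios: pd.DataFrame,
                        edges: tuple[float, float, float] = (2.0, 4.0, 6.0)
                        ) -> pd.DataFrame:
    """Table of fold-bin counts per patient (two rows per patient: up, down)."""
    rows = [
        bin_fold_changes(ratios[patient], str(patient), edges).as_rows()
        for patient in ratios.columns
    ]
    return pd.concat(rows, ignore_index=True)
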