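"""Relative quantification by 2^-ddCt and concordance scoring.

The Ct table holds one row per (patient, condition, gene) with the target and
reference-gene (e.g. GAPDH) cycle thresholds; technical replicates, if any,
are expected to be averaged on the Ct scale beforehand.  With amplification
efficiency fixed at exact doubling,

    dCt   = ct_target - ct_reference        (per condition)
    ddCt  = dCt(tumor) - dCt(normal)        (per patient and gene)
    fold  = 2 ** -ddCt,   log2 ratio (T/N) = -ddCt

Concordance of qPCR with microarray calls compares the per-patient log2
ratios from both platforms.  Under the default ``majority`` rule a gene is
concordant when the signs agree in more than half of the patients with
nonzero values on both platforms; the stricter ``all-signs`` rule requires
agreement in every such patient.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._stats import paired_t_test
from .exceptions import InsufficientPairsError, MissingCtError
from .coexpression import pearson_r

__all__ = [
    "DeltaDeltaCt",
    "ddct_fold",
    "paired_delta_ct_test",
    "concordance",
    "nearby_gene_concordance",
]


class DeltaDeltaCt(TransformerMixin, BaseEstimator):
    """Transform a long-format Ct table into per-(patient, gene) fold changes.

    ``transform`` returns one row per patient and gene with ``delta_ct_tumor``,
    ``delta_ct_normal``, ``delta_delta_ct``, ``fold`` and ``log2_ratio``.
    """

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        records = []
        for (patient, gene), grp in X.groupby(["patient_id", "gene_id"],
                                              sort=True):
            ddct, fold = _ddct_from_group(grp, patient, gene)
            records.append({
                "patient_id": patient,
                "gene_id": gene,
                "delta_ct_tumor": _delta_ct(grp, "tumor", patient, gene),
                "delta_ct_normal": _delta_ct(grp, "normal", patient, gene),
                "delta_delta_ct": ddct,
                "fold": fold,
                "log2_ratio": -ddct,
            })
        return pd.DataFrame(records)


def _delta_ct(grp: pd.DataFrame, condition: str, patient, gene) -> float:
    rows = grp[grp["condition"] == condition]
    if rows.empty:
        raise MissingCtError(
            f"no {condition} Ct for patient {patient!r}, gene {gene!r}")
    row = rows.iloc[0]
    for col in ("ct_target", "ct_reference"):
        if pd.isna(row[col]):
            raise MissingCtError(
                f"missing {col} for patient {patient!r}, gene {gene!r}, "
                f"{condition}")
    return float(row["ct_target"] - row["ct_reference"])


def _ddct_from_group(grp, patient, gene) -> tuple[float, float]:
    ddct = _delta_ct(grp, "tumor", patient, gene) \
        - _delta_ct(grp, "normal", patient, gene)
    return ddct, 2.0 ** -ddct


def ddct_fold(ct: pd.DataFrame, patient_id, gene_id) -> tuple[float, float]:
    """(delta_delta_ct, fold) for one patient and gene from a Ct table."""
    grp = ct[(ct["patient_id"] == patient_id) & (ct["gene_id"] == gene_id)]
    if grp.empty:
        raise MissingCtError(
            f"no Ct rows for patient {patient_id!r}, gene {gene_id!r}")
    return _ddct_from_group(grp, patient_id, gene_id)


def paired_delta_ct_test(ct: pd.DataFrame, gene_id) -> float:
    """Two-sided paired t-test on dCt (tumor vs normal) across patients."""
    grp = ct[ct["gene_id"] == gene_id]
    diffs = []
    for patient, sub in grp.groupby("patient_id"):
        diffs.append(_delta_ct(sub, "tumor", patient, gene_id)
                     - _delta_ct(sub, "normal", patient, gene_id))
    if len(diffs) < 2:
        raise InsufficientPairsError(
            f"paired dCt test for {gene_id!r} needs >= 2 patients, "
            f"got {len(diffs)}")
    _, p = paired_t_test(np.asarray(diffs))
    return float(p)


def concordance(microarray_log2, qpcr_log2, rule: str = "majority") -> bool:
    """Do qPCR log2 ratios confirm the microarray direction for one gene?

    Patients with a zero value on either platform are excluded (logged).
    ``majority``: sign agreement in > half the informative patients;
    ``all-signs``: agreement in every informative patient.
    """
    if rule not in ("majority", "all-signs"):
        raise ValueError(f"unknown concordance rule {rule!r}")
    m = np.asarray(microarray_log2, dtype=float)
    q = np.asarray(qpcr_log2, dtype=float)
    if m.shape != q.shape:
        raise ValueError("patient sets differ between platforms")
    informative = (m != 0) & (q != 0)
    if not informative.any():
        warnings.warn("all-zero ratio vector; concordance undefined")
        return False
    agree = np.sign(m[informative]) == np.sign(q[informative])
    if rule == "all-signs":
        return bool(agree.all())
    return bool(agree.sum() > informative.sum() / 2)


def nearby_gene_concordance(lnc_log2: pd.DataFrame, gene_log2: pd.DataFrame,
                            pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Sign agreement and correlation of lncRNAs with their nearby genes.

    ``lnc_log2`` and ``gene_log2`` are id x patient tables of log2 T/N
    ratios (same patient columns); ``pairs`` lists (lnc_id, gene_id).
    Returns one row per pair with the fraction of patients whose signs match
    and the Pearson r of the two ratio vectors across patients.
    """
    if not lnc_log2.columns.equals(gene_log2.columns):
        raise ValueError("patient columns differ between tables")
    records = []
    for lnc_id, gene_id in pairs:
        x = lnc_log2.loc[lnc_id].to_numpy(dtype=float)
        y = gene_log2.loc[gene_id].to_numpy(dtype=float)
        agreement = float((np.sign(x) == np.sign(y)).mean())
        records.append({
            "lnc_id": lnc_id,
            "gene_id": gene_id,
            "sign_agreement": agreement,
            "pearson_r": pearson_r(x, y) if x.size >= 3 else np.nan,
        })
    return pd.DataFrame(records)
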