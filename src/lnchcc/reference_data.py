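"""Bundled reference tallies from a published 3-pair HCC/NT microarray profile.

These small tables are inputs for validation arithmetic, not outputs of this
package: per-patient fold-bin counts of aberrantly expressed lncRNAs and
mRNAs, the composition counts of the reported lncRNA-mRNA co-expression
network, and the 40-transcript qRT-PCR confirmation table of per-patient
log2(T/N) ratios on both platforms.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_lnc_fold_bins",
    "load_mrna_fold_bins",
    "load_network_counts",
    "load_qpcr_validation",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("lnchcc.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_lnc_fold_bins() -> pd.DataFrame:
    """Per-patient up/down lncRNA counts in fold bins [2,4), [4,6), [6,inf)."""
    return _read("reference_lnc_fold_bins.tsv")


def load_mrna_fold_bins() -> pd.DataFrame:
    """Per-patient up/down mRNA counts in the same fold bins."""
    return _read("reference_mrna_fold_bins.tsv")


def load_network_counts() -> dict:
    """Reported co-expression network composition (edges, nodes, DE totals)."""
    df = _read("reference_network_counts.tsv")
    return dict(zip(df["key"], df["value"].astype(int)))


def load_qpcr_validation() -> pd.DataFrame:
    """40 transcripts with microarray and qRT-PCR log2(T/N) per patient."""
    return _read("reference_qpcr_validation.tsv")
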