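"""Bipartite lncRNA-mRNA co-expression network from DE probes.

Pearson correlations are computed between every differentially expressed
lncRNA and every differentially expressed mRNA across all arrays of the
experiment (tumor and normal pooled — six columns for the canonical
three-pair design).  An edge is kept when |r| >= ``r_min`` (default 0.99)
and the two-sided p-value of r, from the t-transform with n - 2 degrees of
freedom, is < ``p_max`` (default 0.001).  With six arrays the r threshold is
the binding one: |r| = 0.99 already gives p ~ 1.1e-4.  No multiple-testing
correction is applied to edge p-values by default (a flag adds BH).
"""
from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._stats import bh_fdr, correlation_p

__all__ = ["pearson_r", "CoexpressionNetwork", "build_network"]


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length sample vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        raise ValueError("constant vector: correlation undefined")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


class CoexpressionNetwork(BaseEstimator):
    """All-pairs thresholded Pearson network between two probe sets.

    Parameters
    ----------
    r_min : minimum |r| for an edge (inclusive).
    p_max : maximum two-sided p-value (strict).
    adjust_p : apply BH across all candidate pairs before thresholding.

    Attributes (after ``fit``)
    --------------------------
    edges_ : DataFrame (lnc_probe_id, mrna_probe_id, r, p_value, sign).
    summary_ : dict with node/edge counts, rounded percentage of each DE set
        present in the network, positive-edge count and per-node degrees.
    extremes_ : most positive and most negative retained pair (or None).
    """

    def __init__(self, r_min: float = 0.99, p_max: float = 0.001,
                 adjust_p: bool = False):
        self.r_min = r_min
        self.p_max = p_max
        self.adjust_p = adjust_p

    def fit(self, X: pd.DataFrame, lnc_ids, mrna_ids):
        """Correlate DE lncRNA rows against DE mRNA rows of ``X``.

        ``X`` is the normalized probes x arrays matrix holding every probe in
        ``lnc_ids`` and ``mrna_ids``; constant probes are excluded with a
        warning (their correlation is undefined).
        """
        lnc_ids = [i for i in lnc_ids]
        mrna_ids = [i for i in mrna_ids]
        if not lnc_ids or not mrna_ids:
            warnings.warn("no DE probes on one side; network is empty")
        n = X.shape[1]
        lnc_mat = X.loc[lnc_ids].to_numpy(dtype=float)
        mrna_mat = X.loc[mrna_ids].to_numpy(dtype=float)

        def _standardize(mat, ids):
            sd = mat.std(axis=1)
            keep = sd > 0
            dropped = [i for i, k in zip(ids, keep) if not k]
            if dropped:
                warnings.warn(
                    f"excluded {len(dropped)} constant probe(s): {dropped[:5]}")
            mat = mat[keep]
            z = (mat - mat.mean(axis=1, keepdims=True)) \
                / mat.std(axis=1, keepdims=True)
            return z, [i for i, k in zip(ids, keep) if k]

        z_lnc, lnc_kept = _standardize(lnc_mat, lnc_ids)
        z_mrna, mrna_kept = _standardize(mrna_mat, mrna_ids)
        r = np.clip(z_lnc @ z_mrna.T / n, -1.0, 1.0)
        p = correlation_p(r.ravel(), n).reshape(r.shape)
        if self.adjust_p:
            p = bh_fdr(p.ravel()).reshape(p.shape)
        keep = (np.abs(r) >= self.r_min) & (p < self.p_max)
        ii, jj = np.nonzero(keep)
        edges = pd.DataFrame({
            "lnc_probe_id": [lnc_kept[i] for i in ii],
            "mrna_probe_id": [mrna_kept[j] for j in jj],
            "r": r[ii, jj],
            "p_value": p[ii, jj],
        })
        edges["sign"] = np.where(edges["r"] >= 0, "positive", "negative")
        edges = edges.sort_values(
            ["lnc_probe_id", "mrna_probe_id"]).reset_index(drop=True)

        self.n_arrays_ = n
        self.n_candidate_pairs_ = len(lnc_kept) * len(mrna_kept)
        self.edges_ = edges
        self.summary_ = self._summarize(edges, len(lnc_ids), len(mrna_ids))
        self.extremes_ = self._extremes(edges)
        return self

    @staticmethod
    def _summarize(edges: pd.DataFrame, n_de_lnc: int, n_de_mrna: int) -> dict:
        lnc_deg = edges["lnc_probe_id"].value_counts().to_dict()
        mrna_deg = edges["mrna_probe_id"].value_counts().to_dict()
        return {
            "n_edges": int(len(edges)),
            "n_lnc_nodes": len(lnc_deg),
            "n_mrna_nodes": len(mrna_deg),
            "n_positive_edges": int((edges["sign"] == "positive").sum()),
            "pct_lnc_of_de": network_percentage(len(lnc_deg), n_de_lnc),
            "pct_mrna_of_de": network_percentage(len(mrna_deg), n_de_mrna),
            "lnc_degree": lnc_deg,
            "mrna_degree": mrna_deg,
        }

    @staticmethod
    def _extremes(edges: pd.DataFrame) -> dict:
        out = {"max_positive": None, "max_negative": None}
        pos = edges[edges["r"] > 0]
        neg = edges[edges["r"] < 0]
        if len(pos):
            row = pos.loc[pos["r"].idxmax()]
            out["max_positive"] = (row["lnc_probe_id"], row["mrna_probe_id"],
                                   float(row["r"]))
        if len(neg):
            row = neg.loc[neg["r"].idxmin()]
            out["max_negative"] = (row["lnc_probe_id"], row["mrna_probe_id"],
                                   float(row["r"]))
        return out

    def to_graph(self) -> nx.Graph:
        """Bipartite networkx graph of the fitted edge set."""
        g = nx.Graph()
        for lnc in self.edges_["lnc_probe_id"].unique():
            g.add_node(lnc, bipartite="lncRNA")
        for mrna in self.edges_["mrna_probe_id"].unique():
            g.add_node(mrna, bipartite="mRNA")
        for row in self.edges_.itertuples(index=False):
            g.add_edge(row.lnc_probe_id, row.mrna_probe_id,
                       r=float(row.r), p_value=float(row.p_value),
                       sign=row.sign)
        return g

    def write(self, out_dir, config_hash: str | None = None) -> None:
        """Edge table TSV, node-degree TSV, GraphML and plain edge list."""
        from pathlib import Path

        from .io import write_table
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_table(self.edges_, out_dir / "edges.tsv", config_hash)
        nodes = pd.DataFrame(
            [{"node_id": k, "biotype": "lncRNA", "degree": v}
             for k, v in self.summary_["lnc_degree"].items()]
            + [{"node_id": k, "biotype": "mRNA", "degree": v}
               for k, v in self.summary_["mrna_degree"].items()])
        write_table(nodes, out_dir / "nodes.tsv", config_hash)
        nx.write_graphml(self.to_graph(), out_dir / "network.graphml")
        with open(out_dir / "edges.txt", "w") as fh:
            for row in self.edges_.itertuples(index=False):
                fh.write(f"{row.lnc_probe_id}\t{row.mrna_probe_id}"
                         f"\t{row.r:.6f}\n")


def network_percentage(n_nodes: int, n_de: int) -> int:
    """Share of the DE set present in the network, to the nearest integer."""
    if n_de == 0:
        return 0
    return int(np.floor(100.0 * n_nodes / n_de + 0.5))


def build_network(X: pd.DataFrame, lnc_ids, mrna_ids, r_min: float = 0.99,
                  p_max: float = 0.001) -> tuple[pd.DataFrame, dict]:
    """Thin wrapper: fitted edge table and composition summary."""
    net = CoexpressionNetwork(r_min=r_min, p_max=p_max).fit(X, lnc_ids, mrna_ids)
    return net.edges_, net.summary_
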