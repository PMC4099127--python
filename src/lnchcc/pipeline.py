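"""End-to-end orchestration: normalize -> DE -> classify -> network -> qPCR.

A :class:`PipelineConfig` collects every input path and threshold; the
pipeline writes all result tables into the output directory, stamps each file
with a hash of the configuration so outputs of different runs cannot be
mixed, and records a run manifest (tool version, config hash, seed, stage
record counts).
"""
from __future__ import annotations

import hashlib
import json
import logging

import numpy as np
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__, io
from .coexpression import CoexpressionNetwork
from .diffexpr import PairedDifferentialExpression, QuantileNormalizer, summarize_fold_bins
from .exceptions import LncHccError
from .locus import PositionalClassifier, subgroup_filter
from .qpcr import DeltaDeltaCt, paired_delta_ct_test

logger = logging.getLogger("lnchcc")

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline", "write_demo_inputs"]


class PipelineStageError(LncHccError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, error: Exception):
        self.stage = stage
        self.code = f"E_{stage.upper()}"
        super().__init__(f"[{self.code}] stage {stage!r} failed: {error}")


@dataclass
class PipelineConfig:
    expression: str
    design: str
    annotation: str
    gene_models: str
    out_dir: str
    ct_table: str | None = None
    gene_sets: dict = field(default_factory=dict)
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    fdr_threshold: float = 0.05
    r_min: float = 0.99
    p_max: float = 0.001
    window: int = 300_000
    bidir_tss_max: int = 1_000
    fold_bin_edges: tuple = (2.0, 4.0, 6.0)
    concordance_rule: str = "majority"
    seed: int = 101

    def __post_init__(self):
        for name in ("fc_threshold", "p_threshold", "fdr_threshold",
                     "r_min", "p_max", "window", "bidir_tss_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.fold_bin_edges = tuple(float(e) for e in self.fold_bin_edges)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    @property
    def config_hash(self) -> str:
        canonical = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash
    counts: dict[str, dict] = {}

    def stage(name):
        logger.info("stage %s starting", name)

    try:
        stage("read")
        matrix, design = io.read_expression(config.expression, config.design)
        annot = io.read_annotation(config.annotation)
        genes = io.read_gene_models(config.gene_models)
        counts["read"] = {"n_probes": int(matrix.shape[0]),
                          "n_samples": int(matrix.shape[1]),
                          "n_pairs": int(len(design)),
                          "n_genes": len(genes)}
    except LncHccError as exc:
        raise PipelineStageError("read", exc) from exc

    try:
        stage("normalize")
        norm = QuantileNormalizer().fit(matrix).transform(matrix)
        io.write_expression(norm, out / "normalized.tsv", h)
        counts["normalize"] = {"n_probes": int(norm.shape[0])}
    except Exception as exc:
        raise PipelineStageError("normalize", exc) from exc

    try:
        stage("diffexpr")
        biotype = annot.set_index("probe_id")["biotype"]
        de = PairedDifferentialExpression(
            fc_threshold=config.fc_threshold,
            p_threshold=config.p_threshold,
            fdr_threshold=config.fdr_threshold,
        ).fit(norm, design, biotype)
        io.write_table(de.results_, out / "de_results.tsv", h, index=True)
        summary = summarize_fold_bins(de.ratios_, config.fold_bin_edges)
        io.write_table(summary, out / "fold_bin_summary.tsv", h)
        calls = de.results_["call"]
        counts["diffexpr"] = {
            "n_up": int((calls == "up").sum()),
            "n_down": int((calls == "down").sum()),
        }
    except Exception as exc:
        raise PipelineStageError("diffexpr", exc) from exc

    try:
        stage("locus")
        clf = PositionalClassifier(
            window=config.window, bidir_tss_max=config.bidir_tss_max).fit(genes)
        lnc_annot = annot[annot["biotype"] == "lncRNA"]
        positional = clf.predict(lnc_annot)
        io.write_table(positional, out / "positional_calls.tsv", h)
        counts["locus"] = positional["category"].value_counts().to_dict()

        de_probe_ids = set(de.results_.index[calls != "ns"])
        gene_by_probe = annot.set_index("probe_id")["transcript_id"]
        de_gene_ids = {gene_by_probe.get(p, p) for p in de_probe_ids}
        for name, path in config.gene_sets.items():
            catalog = io.read_gene_set(path)
            res = subgroup_filter(positional, de_probe_ids | de_gene_ids,
                                  catalog)
            io.write_table(res["table"], out / f"subgroup_{name}.tsv", h)
            counts[f"subgroup_{name}"] = {
                "n_de": res["n_de"],
                "n_de_with_de_neighbor": res["n_de_with_de_neighbor"]}
    except Exception as exc:
        raise PipelineStageError("locus", exc) from exc

    try:
        stage("coexnet")
        bt = de.results_["biotype"]
        de_lnc = de.results_.index[(calls != "ns") & (bt == "lncRNA")]
        de_mrna = de.results_.index[(calls != "ns") & (bt == "mRNA")]
        log_norm = np.log2(norm)
        net = CoexpressionNetwork(
            r_min=config.r_min, p_max=config.p_max).fit(log_norm, de_lnc, de_mrna)
        net.write(out / "network", h)
        counts["coexnet"] = {k: v for k, v in net.summary_.items()
                             if not k.endswith("degree")}
    except Exception as exc:
        raise PipelineStageError("coexnet", exc) from exc

    if config.ct_table:
        try:
            stage("qpcr")
            ct = io.read_ct_table(config.ct_table)
            folds = DeltaDeltaCt().fit(ct).transform(ct)
            pvals = {g: paired_delta_ct_test(ct, g)
                     for g in sorted(ct["gene_id"].unique())
                     if ct[ct["gene_id"] == g]["patient_id"].nunique() >= 2}
            folds["p_value"] = folds["gene_id"].map(pvals)
            io.write_table(folds, out / "qpcr_results.tsv", h)
            counts["qpcr"] = {"n_genes": int(ct["gene_id"].nunique())}
        except Exception as exc:
            raise PipelineStageError("qpcr", exc) from exc

    manifest = {
        "tool": "lnchcc",
        "version": __version__,
        "config_hash": h,
        "seed": config.seed,
        "stages": counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    for name, c in counts.items():
        logger.info("stage %s done: %s", name, c)
    return manifest


def write_demo_inputs(out_dir, seed: int = 101) -> PipelineConfig:
    """Generate the bundled synthetic study on disk and a matching config."""
    from .simulate import demo_config, generate_dataset, generate_qpcr

    out = Path(out_dir)
    inputs = out / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    cfg = demo_config(seed)
    ds = generate_dataset(cfg)
    io.write_expression(ds.matrix, inputs / "expression.tsv")
    io.write_design(ds.design, inputs / "design.csv")
    io.write_annotation(ds.annotation, inputs / "annotation.tsv")
    io.write_bed12(ds.genes, inputs / "genes.bed")
    ct = generate_qpcr(ds.truth, cfg)
    io.write_ct_table(ct, inputs / "ct.csv")
    cfg.to_yaml(inputs / "synth_config.yaml")
    io.write_table(ds.truth.probes, inputs / "truth_probes.tsv")
    io.write_table(ds.truth.couples, inputs / "truth_couples.tsv")
    io.write_table(ds.truth.positional, inputs / "truth_positional.tsv")
    return PipelineConfig(
        expression=str(inputs / "expression.tsv"),
        design=str(inputs / "design.csv"),
        annotation=str(inputs / "annotation.tsv"),
        gene_models=str(inputs / "genes.bed"),
        ct_table=str(inputs / "ct.csv"),
        out_dir=str(out / "results"),
        seed=seed,
    )
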