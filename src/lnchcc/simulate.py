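"""Synthetic paired tumor/normal expression datasets with recorded ground truth.

The generator emulates the design of a 3-pair HCC / adjacent non-tumor
two-color-style microarray experiment: log-normal probe intensities, a
planted fraction of up-/down-regulated probes whose |log2 effects| span the
2-4 / 4-6 / >6 linear fold bins, near-perfectly correlated lncRNA-mRNA
couples driven by a shared per-sample latent factor, a toy single-chromosome
genome placing lncRNAs in all six positional categories relative to coding
genes, and Ct tables following the exact-doubling model
``Ct = offset - log2(expression) + noise``.

Intensities are built on the log2 scale and exponentiated, which guarantees
positivity.  A planted differential probe has expected tumor - normal log2
difference equal to its planted effect; per-patient biological heterogeneity
of the effect (``patient_effect_sd``) and per-cell residual noise
(``noise_sd``) are added on top.  Couple members share their entire
per-sample deviation (tumor contrast plus latent factor) up to a small
independent noise (``couple_noise_sd``), which directly controls the
attainable correlation.  All randomness flows from ``config.seed``;
regeneration with the same config is bit-identical.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError
from .io import GeneModel
from .locus import CATEGORIES

__all__ = [
    "SynthConfig", "GroundTruth", "SyntheticDataset",
    "generate_expression", "generate_annotation", "generate_qpcr",
    "generate_dataset",
    "demo_config", "network_validation_config", "null_config",
]

_CHROM = "chrT"


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults mirror the canonical design this package targets: three
    tumor/normal pairs, a few hundred probes per biotype with 30% planted
    differential probes split evenly between up and down (a symmetric split
    keeps the array-wide intensity distributions comparable, the assumption
    quantile normalization rests on), planted |log2 effects| spanning all
    three fold bins, a wide baseline dynamic range typical of fluorescence
    arrays, and ten near-perfectly correlated lncRNA-mRNA couples.
    """

    n_patients: int = 3
    n_lnc_probes: int = 400
    n_mrna_probes: int = 400
    frac_up: float = 0.15
    frac_down: float = 0.15
    effect_log2_range: tuple[float, float] = (1.0, 3.5)
    noise_sd: float = 0.2
    patient_effect_sd: float = 0.10
    n_coexpr_pairs: int = 10
    couple_noise_sd: float = 0.01
    couple_latent_sd: float = 0.15
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 3.0
    genome_length: int = 100_000_000
    qpcr_reference_ct: float = 16.0
    seed: int = 101

    def __post_init__(self):
        if min(self.n_patients, self.n_lnc_probes, self.n_mrna_probes) <= 0:
            raise ConfigError("all counts must be positive")
        if self.frac_up < 0 or self.frac_down < 0 \
                or self.frac_up + self.frac_down > 1:
            raise ConfigError("need frac_up, frac_down >= 0 and sum <= 1")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.effect_log2_range[0] > self.effect_log2_range[1] \
                or self.effect_log2_range[0] < 0:
            raise ConfigError("effect_log2_range must be 0 <= lo <= hi")
        if self.n_coexpr_pairs < 0:
            raise ConfigError("n_coexpr_pairs must be >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "effect_log2_range" in raw:
            raw["effect_log2_range"] = tuple(raw["effect_log2_range"])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Recorded truth of one synthetic dataset.

    probes      : probe_id, biotype, de_status (up|down|null), log2_effect
    couples     : lnc_probe_id, mrna_probe_id, sign (positive|negative)
    positional  : probe_id, category, nearby_gene_id, distance_bp
                  (filled by :func:`generate_annotation`)
    """

    probes: pd.DataFrame
    couples: pd.DataFrame
    positional: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["probe_id", "category", "nearby_gene_id", "distance_bp"]))

    def de_ids(self, biotype: str | None = None) -> set[str]:
        t = self.probes
        mask = t["de_status"] != "null"
        if biotype is not None:
            mask &= t["biotype"] == biotype
        return set(t.loc[mask, "probe_id"])


@dataclass
class SyntheticDataset:
    config: SynthConfig
    matrix: pd.DataFrame
    design: pd.DataFrame
    annotation: pd.DataFrame
    genes: list[GeneModel]
    truth: GroundTruth


def _probe_ids(config: SynthConfig) -> tuple[list[str], list[str]]:
    lnc = [f"LNC{i:05d}" for i in range(config.n_lnc_probes)]
    mrna = [f"MRNA{i:05d}" for i in range(config.n_mrna_probes)]
    return lnc, mrna


def _plant_de(n: int, config: SynthConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """(de_status, log2_effect) vectors for one biotype block."""
    n_up = int(round(config.frac_up * n))
    n_down = int(round(config.frac_down * n))
    status = np.array(["up"] * n_up + ["down"] * n_down
                      + ["null"] * (n - n_up - n_down), dtype=object)
    lo, hi = config.effect_log2_range
    magnitude = rng.uniform(lo, hi, size=n)
    effect = np.where(status == "up", magnitude,
                      np.where(status == "down", -magnitude, 0.0))
    return status, effect


def generate_expression(config: SynthConfig
                        ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Intensity matrix (probes x 2*n_patients), paired design and truth."""
    rng = np.random.default_rng([config.seed, 1])
    lnc_ids, mrna_ids = _probe_ids(config)
    probe_ids = lnc_ids + mrna_ids
    biotype = np.array(["lncRNA"] * len(lnc_ids) + ["mRNA"] * len(mrna_ids),
                       dtype=object)

    lnc_status, lnc_eff = _plant_de(len(lnc_ids), config, rng)
    mrna_status, mrna_eff = _plant_de(len(mrna_ids), config, rng)
    status = np.concatenate([lnc_status, mrna_status])
    effect = np.concatenate([lnc_eff, mrna_eff])

    n_pat = config.n_patients
    tumor_cols = [f"T{p + 1}" for p in range(n_pat)]
    normal_cols = [f"N{p + 1}" for p in range(n_pat)]
    samples = tumor_cols + normal_cols
    n_probes = len(probe_ids)

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                          n_probes)
    # per-probe, per-patient realized effect (biological heterogeneity)
    jitter = rng.normal(0.0, config.patient_effect_sd, (n_probes, n_pat))
    realized = (effect[:, None] + jitter) * (effect[:, None] != 0)
    log2x = np.tile(baseline[:, None], (1, 2 * n_pat))
    log2x[:, :n_pat] += realized
    log2x += rng.normal(0.0, config.noise_sd, log2x.shape)

    couples = _plant_couples(config, lnc_ids, mrna_ids, status, effect,
                             log2x, baseline, rng)

    matrix = pd.DataFrame(2.0 ** log2x, index=pd.Index(probe_ids, name="probe_id"),
                          columns=samples)
    design = pd.DataFrame({
        "patient_id": [f"H{p + 1}" for p in range(n_pat)],
        "tumor_sample_id": tumor_cols,
        "normal_sample_id": normal_cols,
    })
    probes = pd.DataFrame({
        "probe_id": probe_ids,
        "biotype": biotype,
        "de_status": status,
        "log2_effect": effect,
    })
    return matrix, design, GroundTruth(probes=probes, couples=couples)


def _plant_couples(config, lnc_ids, mrna_ids, status, effect, log2x,
                   baseline, rng) -> pd.DataFrame:
    """Overwrite couple members with a shared per-sample profile.

    Couple members are taken from the planted up/down blocks when there are
    any (so they survive the DE filter), otherwise from null probes.  The
    pair's sign alternates positive/negative; a negative couple links an
    up-regulated lncRNA with a down-regulated mRNA through a negated copy of
    the shared profile.
    """
    k = config.n_coexpr_pairs
    if k == 0:
        return pd.DataFrame(
            columns=["lnc_probe_id", "mrna_probe_id", "sign"])
    n_lnc = len(lnc_ids)
    n_pat = config.n_patients
    lnc_up = [i for i in range(n_lnc) if status[i] == "up"]
    lnc_null = [i for i in range(n_lnc) if status[i] == "null"]
    m_up = [i for i in range(len(mrna_ids)) if status[n_lnc + i] == "up"]
    m_down = [i for i in range(len(mrna_ids)) if status[n_lnc + i] == "down"]
    m_null = [i for i in range(len(mrna_ids)) if status[n_lnc + i] == "null"]

    lnc_pool = lnc_up if len(lnc_up) >= k else lnc_null
    if len(lnc_pool) < k:
        raise ConfigError("not enough lncRNA probes to plant couples")
    rows = []
    used_up, used_down, used_null = 0, 0, 0
    for c in range(k):
        li = lnc_pool[c]
        sign = "positive" if c % 2 == 0 else "negative"
        if lnc_pool is lnc_null:
            mi = m_null[used_null]; used_null += 1
        elif sign == "positive":
            if used_up < len(m_up):
                mi = m_up[used_up]; used_up += 1
            else:
                raise ConfigError("not enough up-regulated mRNA probes")
        else:
            if used_down < len(m_down):
                mi = m_down[used_down]; used_down += 1
            else:
                raise ConfigError("not enough down-regulated mRNA probes")
        mg = n_lnc + mi
        eff = effect[li]
        s = 1.0 if sign == "positive" else -1.0
        # shared profile: planted contrast with one per-patient jitter draw,
        # plus a per-sample latent factor
        pat_eff = (eff + rng.normal(0, config.patient_effect_sd, n_pat)) \
            * (eff != 0)
        shared = np.concatenate([pat_eff, np.zeros(n_pat)])
        shared = shared + rng.normal(0, config.couple_latent_sd, 2 * n_pat)
        log2x[li] = baseline[li] + shared \
            + rng.normal(0, config.couple_noise_sd, 2 * n_pat)
        log2x[mg] = baseline[mg] + s * shared \
            + rng.normal(0, config.couple_noise_sd, 2 * n_pat)
        effect[mg] = s * eff
        if eff != 0:
            status[mg] = "up" if s * eff > 0 else "down"
        rows.append({"lnc_probe_id": lnc_ids[li],
                     "mrna_probe_id": mrna_ids[mi], "sign": sign})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# toy genome / annotation
# ---------------------------------------------------------------------------

_GENE_SPAN = 5_000
_GENE_PITCH = 40_000
_EXONS_REL = [(0, 400), (2_000, 2_600), (4_600, 5_000)]
_MARGIN = 50_000
_FAR_ZONE_GAP = 400_000
_FAR_PITCH = 700_000


def generate_annotation(config: SynthConfig
                        ) -> tuple[pd.DataFrame, list[GeneModel], pd.DataFrame]:
    """Probe annotation, coding-gene models and planted positional truth.

    One coding gene per mRNA probe, laid out on a single toy chromosome;
    lncRNAs cycle through the six positional categories relative to their
    host gene (lncRNA i hosts at gene i mod n_genes).  Every fourth
    intergenic lncRNA is placed in a far zone, > 300 kb from every gene, so
    the nearest-gene lookup has genuinely empty neighborhoods to report.
    """
    lnc_ids, mrna_ids = _probe_ids(config)
    genes: list[GeneModel] = []
    for i, pid in enumerate(mrna_ids):
        start = _MARGIN + i * _GENE_PITCH
        strand = "+" if i % 2 == 0 else "-"
        exons = [(start + a, start + b) for a, b in _EXONS_REL]
        genes.append(GeneModel(f"GENE{i:05d}", _CHROM, start,
                               start + _GENE_SPAN, strand, exons))

    far_zone_start = _MARGIN + len(genes) * _GENE_PITCH + _FAR_ZONE_GAP
    rows, truth_rows = [], []
    n_far = 0
    n_intergenic = 0
    for i, pid in enumerate(lnc_ids):
        host = genes[i % len(genes)]
        category = CATEGORIES[i % 6]
        strand = host.strand
        anti = "-" if host.strand == "+" else "+"
        g0 = host.start
        if category == "exon sense-overlapping":
            start, end = g0 + 2_200, g0 + 3_200
        elif category == "intron sense-overlapping":
            start, end = g0 + 600, g0 + 1_800
        elif category == "natural antisense":
            start, end, strand = g0 + 2_200, g0 + 3_200, anti
        elif category == "intronic antisense":
            start, end, strand = g0 + 600, g0 + 1_800, anti
        elif category == "bidirectional":
            strand = anti
            if host.strand == "+":
                start, end = host.tss - 1_100, host.tss - 300
            else:
                start, end = host.tss + 300, host.tss + 1_100
        else:  # intergenic
            if n_intergenic % 4 == 3:
                start = far_zone_start + n_far * _FAR_PITCH
                end = start + 1_000
                n_far += 1
                strand = "+"
            else:
                start, end = host.end + 15_000, host.end + 16_000
                strand = "+"
            n_intergenic += 1
        nearby, dist = _expected_neighbor(category, host, start, end)
        rows.append((pid, f"LNCT{i:05d}", "lncRNA", _CHROM, start, end,
                     strand, "synthetic"))
        truth_rows.append((pid, category, nearby, dist))

    needed = far_zone_start + n_far * _FAR_PITCH + _MARGIN
    if needed > config.genome_length:
        raise ConfigError(
            f"genome_length {config.genome_length} too short; need {needed}")

    for i, pid in enumerate(mrna_ids):
        g = genes[i]
        rows.append((pid, g.gene_id, "mRNA", _CHROM, g.start, g.end,
                     g.strand, "synthetic"))
    annot = pd.DataFrame(rows, columns=[
        "probe_id", "transcript_id", "biotype", "chromosome",
        "start", "end", "strand", "category_source"])
    positional = pd.DataFrame(truth_rows, columns=[
        "probe_id", "category", "nearby_gene_id", "distance_bp"])
    return annot, genes, positional


def _expected_neighbor(category, host, start, end):
    if category in ("exon sense-overlapping", "intron sense-overlapping",
                    "natural antisense", "intronic antisense"):
        return host.gene_id, 0
    if category == "bidirectional":
        return host.gene_id, 300
    if start > host.end + 300_000 - 1_000:  # far intergenic
        return None, None
    return host.gene_id, start - host.end


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def generate_qpcr(truth: GroundTruth, config: SynthConfig,
                  gene_ids=None, n_patients: int | None = None,
                  noise_sd: float | None = None) -> pd.DataFrame:
    """Long-format Ct table for the planted probes.

    Ct follows the exact-doubling model: one cycle fewer per planted doubling
    of target expression, a condition-independent reference gene, and
    Gaussian cycle noise (default ``config.noise_sd``).  ``gene_ids``
    defaults to every planted differential probe.
    """
    rng = np.random.default_rng([config.seed, 2])
    if gene_ids is None:
        gene_ids = sorted(truth.de_ids())
    n_pat = n_patients if n_patients is not None else config.n_patients
    sd = config.noise_sd if noise_sd is None else noise_sd
    eff = truth.probes.set_index("probe_id")["log2_effect"]
    offset = {g: 24.0 + rng.uniform(-4, 4) for g in gene_ids}
    rows = []
    for g in gene_ids:
        for p in range(n_pat):
            pid = f"H{p + 1}"
            for cond in ("tumor", "normal"):
                shift = eff[g] if cond == "tumor" else 0.0
                rows.append({
                    "patient_id": pid,
                    "condition": cond,
                    "gene_id": g,
                    "ct_target": offset[g] - shift + rng.normal(0, sd),
                    "ct_reference": config.qpcr_reference_ct
                    + rng.normal(0, sd),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------

def generate_dataset(config: SynthConfig) -> SyntheticDataset:
    """Expression + annotation + truth in one seeded bundle."""
    matrix, design, truth = generate_expression(config)
    annot, genes, positional = generate_annotation(config)
    truth.positional = positional
    return SyntheticDataset(config=config, matrix=matrix, design=design,
                            annotation=annot, genes=genes, truth=truth)


def demo_config(seed: int = 101) -> SynthConfig:
    """The bundled demonstration study: 3 pairs, planted |log2 effect| 3,
    residual noise 0.2, 120 planted DE probes per biotype, ten couples."""
    return SynthConfig(effect_log2_range=(3.0, 3.0), seed=seed)


def network_validation_config(seed: int = 101) -> SynthConfig:
    """Planted couples over an independent-noise background: no planted DE,
    ten couples, >= 10^4 candidate background pairs."""
    return SynthConfig(n_lnc_probes=110, n_mrna_probes=110,
                       frac_up=0.0, frac_down=0.0, n_coexpr_pairs=10,
                       couple_latent_sd=1.0, seed=seed)


def null_config(seed: int = 101) -> SynthConfig:
    """No planted signal at all; used for type-I-error calibration."""
    return SynthConfig(n_lnc_probes=1_000, n_mrna_probes=1_000,
                       frac_up=0.0, frac_down=0.0, n_coexpr_pairs=0,
                       seed=seed)
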