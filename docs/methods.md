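# Methods

## Scope and model

The package implements the canonical analysis chain for a small paired
tumor/normal lncRNA+mRNA microarray study: quantile normalization,
paired-ratio differential expression with a triple threshold
(fold ≥ 2 or ≤ 0.5, paired-t p < 0.05, BH FDR < 0.05), per-patient
fold-change binning, positional classification of lncRNAs against
coding-gene models, an all-pairs thresholded Pearson co-expression network
(|r| ≥ 0.99, p < 0.001), and 2^−ΔΔCt relative quantification with
cross-platform concordance scoring. All stages are deterministic; all
simulation randomness flows from a single integer seed.

## Statistical choices

**Paired test.** The per-probe test is a one-sample t on the per-pair log2
T/N ratios against zero, two-sided, with n_pairs − 1 degrees of freedom.
With three pairs (df = 2) the attainable p-values are heavy-tailed
(p ≈ 1/t² for large t), which makes the FDR step the binding constraint of
the whole calling rule — a property the synthetic experiments reproduce.
Zero-variance ratio vectors are resolved explicitly: zero mean gives
t = 0, p = 1; nonzero mean is reported as the p → 0 limit and flagged.

**FDR.** Benjamini–Hochberg step-up (via statsmodels). The adjustment is
computed within biotype by default, mirroring the separate lncRNA/mRNA
tallies such studies report; a flag pools the biotypes. Step-up adjusted
values are monotone in p and bounded in [0, 1].

**Fold change.** Geometric mean of the per-pair ratios,
FC = 2^mean(log2 ratios). A mean-of-linear-ratios alternative would weight
patients unevenly on the linear scale. An optional stricter rule
(`require_per_pair_fc`) additionally demands the fold criterion in every
individual patient.

**Fold bins.** "2–4 / 4–6 / >6" is implemented as half-open bins
[2,4), [4,6), [6,∞); down-regulated probes are binned by the reciprocal
fold so the up/down tables are symmetric. Folds are rounded to nine
decimals before binning so that log2/exp2 round-trip error cannot move a
boundary fold (e.g. 4.0 arriving as 3.999999999999999…) into the wrong bin.

**Correlation p-values.** Two-sided via the t-transform
t = r√(n−2)/√(1−r²) with n − 2 df; |r| = 1 maps to p = 0. With six arrays
a permutation null could not resolve p < 0.001 at all (min two-sided
permutation p = 2/6! ≈ 0.0028), which is why an analytic test is the only
sensible default. At n = 6, |r| = 0.99 gives p ≈ 1.5 × 10⁻⁴, so the
r-threshold is the binding one — asserted as a test property.

**Network composition percentages** are reported to the nearest integer
(floor(x + 0.5)), matching how such compositions are printed.

## Positional classification

Six mutually exclusive categories; when several relations hold the label is
chosen by precedence: exon sense-overlapping > intron sense-overlapping >
natural antisense > intronic antisense > bidirectional > intergenic
(overlap evidence outranks promoter geometry; sense outranks antisense).
Definitions: natural antisense = opposite-strand overlap touching at least
one exon; intronic antisense = opposite-strand containment wholly within
one intron; bidirectional = no overlap with any gene and an opposite-strand
gene whose TSS lies within 1 kb (configurable) of the lncRNA TSS.
Coordinates are 0-based half-open (BED convention; GFF3 converted on read);
the TSS is the interval start on + and the interval end on −.

Nearest gene = minimal inter-interval gap (0 when overlapping), strict
< 300 kb window, ties broken to the lexicographically smaller gene id so
classification is independent of file order. Note one geometric subtlety:
flipping the strands of both lncRNA and gene preserves every
overlap-defined category, but not necessarily `bidirectional`, because an
isolated strand flip moves both TSSs without mirroring the coordinates;
the exact invariant (tested) is reflection symmetry — mirrored coordinates
plus flipped strands.

## Synthetic data

The generator emulates a 3-pair tumor/normal design with log-normal
intensities: per-probe baseline log2 intensity ~ N(10, 3²) (a wide dynamic
range typical of fluorescence arrays), planted differential probes with
|log2 effect| drawn from a configurable range (default 1–3.5, spanning all
three fold bins; the bundled demo fixes it at 3), per-patient biological
heterogeneity of the effect (sd 0.10) and i.i.d. per-cell residual noise
(sd 0.2). Intensities are built on the log2 scale and exponentiated, which
guarantees positivity. The planted up/down split is symmetric
(15% + 15% of probes per biotype) — a deliberate choice: quantile
normalization assumes comparable array-wide distributions, and at desk
scale (hundreds of probes rather than tens of thousands) a large
one-sided planted fraction visibly distorts the null probes. Real arrays,
where well under 1% of probes are differential, do not face this; the
symmetric split restores the regime the method assumes.

Co-expressed couples share their entire per-sample deviation (the planted
contrast with a single per-patient draw, plus a per-sample latent factor)
up to independent noise of sd 0.01, which pins the pair correlation near
0.9999 — high enough that the *empirical* r over six arrays stays above
0.99 essentially always (at pair ρ = 0.9975 the six-array sample r would
drop below 0.99 about 11% of the time; the near-degenerate coupling is
what makes exact recovery testable). Negative couples negate the shared
profile, linking an up-regulated lncRNA to a down-regulated mRNA.

The toy genome is a single chromosome: one three-exon coding gene per mRNA
probe on alternating strands at 40 kb pitch, with lncRNAs cycling through
the six positional categories relative to their host gene; every fourth
intergenic lncRNA is placed in a far zone > 300 kb from every gene so
empty neighborhoods occur. The construction rules are the classification
rules, so the classifier must recover the planted categories exactly.

Ct tables follow the exact-doubling model
Ct = offset − log2(expression) + noise with a condition-independent
reference gene, so 2^−ΔΔCt recovers the planted fold exactly at zero
noise.

**What the generator does not model:** probe-level hybridization
artifacts, dye bias, batch effects, background, heteroscedastic
intensity-dependent noise, multi-mapping probes, etiology differences
between patients. Passing tests therefore demonstrate correctness of the
computations and calibration of the statistics under a clean log-normal
model, not robustness to array artifacts.

## Validation configurations and problem sizes

Three bundled configurations (each fully determined by a seed):

* **demo** — 400 + 400 probes, 120 planted DE per biotype at |log2 FC| = 3,
  ten couples. Planted recall and precision against recorded truth are
  ≥ 0.9 (typically ≈ 0.95–0.98); over 90% of residual misses are BH
  q-failures, the inherent cost of df = 2.
* **network validation** — 110 + 110 probes, no planted DE, ten couples
  over an independent-noise background (≈ 12,000 background pairs). All
  ten couples are recovered. Under independence P(|r| ≥ 0.99) at n = 6 is
  exactly 1.5 × 10⁻⁴, so ≈ 1.8 background pairs are *expected* to clear
  the threshold by chance; the test bounds false edges by the Poisson
  mean + 3σ of that expectation rather than asserting zero, which no
  threshold rule at n = 6 could honestly deliver.
* **null** — 1,000 + 1,000 probes, no signal. The fraction of probes with
  p < 0.05 must lie within three binomial standard errors of 0.05 (the
  paired t is exact under the generator's normal log-noise).

Problem sizes were chosen so the full suite and the acceptance script run
in seconds while every check retains statistical meaning (e.g. ≥ 10⁴
background pairs for the false-edge rate, 2,000 probes for calibration,
1,000 randomized genomes for the classifier oracle).

## Numerical and degenerate-input conventions

Non-positive intensities are rejected on import (optional flooring flag)
because log2 is taken downstream. Constant probes are excluded from
correlation with a warning (r undefined). Quantile normalization resolves
ties by interpolating the reference distribution at average ranks and is
idempotent; a single-sample matrix passes through unchanged with a
warning. Probe-to-transcript mapping is 1:1; multi-mapping probes raise a
named error. Result files carry a header comment with the tool version and
a SHA-256-derived configuration hash so outputs of different runs cannot
be silently mixed.

## Known limitations

Three pairs give df = 2: power is poor for |log2 FC| below ~2 at the
default noise, and the FDR step dominates the calling rule. The
co-expression network over differential probes at n = 6 arrays is dense
whenever effects are strong and co-directional (the shared tumor/normal
contrast alone produces |r| near 1); interpreting such edges as regulatory
relationships requires external evidence. The positional classifier
assumes single-isoform gene models; multi-isoform collapsing, replicate
probes per transcript, and enrichment analyses are out of scope.
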