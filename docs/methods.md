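# Methods

## Scope and model

`radskin` analyzes probe × sample log2 expression matrices from a dose × time
irradiation design: doses {0, 1, 3, 6, 20} Gy, time points {2h, d4, d7, d21,
d28}, five replicates per group, with the 20 Gy (lethal) arm truncated after
d7 because those animals do not survive the first post-exposure week. The
0 Gy group at each time point is the control for every contrast at that time
point, which absorbs any serial-biopsy (bystander) effect shared by all arms;
contrasts are always (dose, TP) vs (0 Gy, same TP).

## Differential expression

Per contrast, each gene's pooled two-sample variance s²_g (d_g = n₁+n₂−2 df)
is shrunk toward an inverse-chi-square prior (d₀, s₀²) estimated from the
whole gene list by method of moments on z_g = log s²_g: with
e_g = z_g − ψ(d_g/2) + log(d_g/2), the excess of var(e) over ψ′(d_g/2)
identifies d₀ through the inverse trigamma (Newton iteration), and mean(e)
identifies s₀². When the log-variances show no excess dispersion the prior
degenerates to d₀ = ∞ and s₀² is the arithmetic mean of the sample
variances (the same convention as the reference empirical-Bayes
implementation, against which the whole path is cross-checked in the test
suite to ~1e-6 via Rscript). The moderated statistic

    t_g = log2FC_g / (s̃_g · sqrt(1/n₁ + 1/n₂)),
    s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g)

is referred to a t distribution on d₀ + d_g df, with the total df capped at
the family's summed residual df (a prior cannot be more informative than
pooling every gene). Zero variances are floored at 1e-8. BH adjustment is
applied within one contrast's full gene list — contrasts are analyzed
independently, never pooled. SDTG = p_adj < 0.05 and |signed FC| ≥ 2 (both
thresholds configurable; a raw-p mode exists for sensitivity analyses).
Fold change is defined on group means of log2 expression; the signed linear
FC maps log2FC = 0 to +1 by convention.

## Set dynamics

SDTG sets are compared by exact set algebra. "Unique" is the Venn singleton
block (present in exactly one label's set); "common" is the intersection of
all labels' sets; intermediate blocks are retained in the full decomposition
and conserve the union exactly (checked against a brute-force membership-
bitmask oracle). Partitions are identity-based: a common gene may flip
direction between time points, so a separate direction-consistency
annotation is attached. The stationarity index is common/union; the
unique/common ratio uses the first time point's unique count and is flagged
+inf when the common block is empty (0/0 is undefined, not 0). Both
orientations of the common-vs-unique ratio are reported because the source
study states them both ways and its printed values cannot be reconstructed
from any printed table. Percentages are kept exact (rational) internally;
a round-half-up helper formats them to 2 decimals for report tables. The
published tables themselves round inconsistently (some cells half-up, some
truncated), so consistency checks against printed cells allow one unit in
the last printed digit.

Empty sets propagate as missing (`None`) percent-up values, never as 0 —
a time point with no SDTGs carries no directional evidence. Upregulation
peaks break ties toward the earlier time point.

## Dose classification

The decision rules operationalize two qualitative signatures: lethal =
down-dominated early time points plus stationary identity (high common
fraction); sublethal = up-dominated early time points plus dynamic,
TP-specific identity. Numeric cutoffs (defaults: down fraction ≥ 0.60 at
every early TP and stationarity ≥ 0.40 for lethal; up fraction ≥ 0.55 with
sub-cutoff stationarity for sublethal) sit midway between the reported
lethal (~90% down, ~59% common) and sublethal (~70% up, ≤11% common)
signatures, leaving a margin on both sides; all are configurable. A call of
`lethal` requires *both* lethal rules to fire. Conflicting or insufficient
evidence (fewer than two early time points with any SDTGs) yields
`indeterminate` — a first-class outcome. Within the sublethal range the
dose class is ordinal, read from the upregulation peak (2h/d4 → "low",
d7 → "mid", later → "high"); SDTG *counts* are deliberately not used as a
dose scale because they are non-monotone in dose in the low range. The
late-time-point "lethal-like inversion" sometimes seen at the top of the
sublethal range is not used to down-weight confidence (no operational rule
exists for it); the early-TP window is fixed at 2h–d7.

The marker-panel score calls a gene consistent iff FC ≥ 2 at every sublethal
cell and FC ≤ −2 at every lethal cell; genes with missing cells are
unevaluable and excluded from the count. The sublethal-unique screen is the
exact intersection of the up-sets over all sublethal (dose, TP ≤ d7) cells
minus every gene that responds to the lethal dose in any direction at any
time point. Being an exact 9-cell intersection, the screen is brittle to a
single dropped cell; on renormalized data a near-threshold gene can
occasionally fall out (see Limitations).

## Ordination and clustering

Sammon mapping minimizes E = (1/Σ_{i<j} d_ij) Σ_{i<j} (d_ij − D_ij)²/d_ij by
the diagonal pseudo-Newton update (step factor 0.35) with step halving, so
accepted iterations never increase the stress; convergence is a relative
stress change < 1e-9 or 500 iterations. Initialization is deterministic
classical MDS (sign-fixed principal coordinates); a seed only drives a tiny
jitter if the start is degenerate. Zero off-diagonal distances are perturbed
by 1e-12 with a warning (the 1/d weights are undefined there). The default
input distance for expression ordination is Euclidean on the 500
most-variable genes — the source protocol does not state its metric or gene
filter, so this is a package choice, configurable and not claimed faithful.
Clustering uses the uncentered Pearson distance 1 − Σxy/(‖x‖‖y‖) ∈ [0, 2]
with average linkage (scipy), exported as Newick.

## Normalization

Preprocessing order is fixed as within-sample lowess detrend (residuals of a
lowess fit on mean probe intensity; span 0.3 default; the `delta` shortcut
set to 1% of the covariate range) → between-sample quantile normalization →
PCA outlier filtering. Quantile normalization maps each sample onto the mean
of order statistics; tie runs receive the mean of their ranks' reference
values, and untied values take the reference entry directly, which makes a
second application exactly a no-op on tie-free data (under ties the tie rule
itself perturbs the next pass's reference, so idempotence is only
approximate — a property of the tie convention, not of the code). Outliers
are judged within (dose, TP) groups — dose itself separates samples, so a
global criterion would flag biology — as |PC1 or PC2 deviation from the
group median| > k·1.4826·MAD (k = 4 default). The filter refuses to act
(and says so in the report) rather than remove more than 20% of samples,
and errors if every sample would go. For generated data the lowess stage is
off by default in the pipeline config: the simulator emits already
ratio-like log2 values with no intensity trend.

## Synthetic data generator

The generator is first-class, tested code that defines the study conditions:
20,000 probes, 5 replicates per group, the truncated lethal arm, and a
planted DE architecture per dose — a common-to-all-time-points block plus
TP-unique blocks, with the common block size solved in closed form from the
configured common fraction (C = f·Σn_t / (1 + f(k−1))). The default preset
reproduces the published per-dose distinct-gene unions (619, 411, 765, 1038
for 1, 3, 6, 20 Gy) and common fractions (0.16%, 0%, 0.52%, 58.7%); per-TP
totals are set so upregulated counts peak at d4 for 1 and 3 Gy and d7 for
6 Gy, with up fractions 0.60–0.75 at sublethal early TPs, 0.40–0.45 late
(the late down-drift), and 0.10 throughout the lethal arm. Five marker genes
are forced up in every sublethal and down in every lethal early-TP group,
and three further genes up only in sublethal groups — both panels confined
to TPs ≤ d7, matching the published panel grid. Planted |log2FC| is uniform
on [1.5, log2 20]: the cap mirrors the largest reported fold changes
(~20-fold) and the floor keeps planted effects meaningfully above the
2-fold reporting cutoff (an effect at exactly 2-fold sits on the ≥
threshold, where detection is a coin flip under symmetric noise).

Gene variances follow a scaled inverse chi-square prior (d₀ = 4,
s₀ = 0.25) — exactly the hierarchical model the moderated t assumes — with
Gaussian noise on the log2 scale and baselines uniform on [6, 12]. Noise is
drawn gene-major from a single stream in a fixed layout, so enlarging
n_genes appends genes without reshuffling earlier ones; variances, baselines
and effect sizes come from separately keyed streams. Identical seeds give
bit-identical matrices.

What the generator does **not** emulate: two-color dye structure, spatial
artifacts, intensity-dependent trends, probe-level replication of one gene,
correlated gene modules, or replicate attrition (full n = 5 throughout —
the source protocol removed low-quality RNA samples but does not report
per-group attrition). Passing tests therefore demonstrate correctness of
the statistics and decision logic under the planted architecture, not
robustness to those real-data artifacts.

## Problem sizes used in checks

The acceptance script and test suite run the generator at the full study
scale (20,000 probes) for calibration, recovery and the 50-cohorts-per-dose
classification study (cohort = one dose arm plus matched controls), and at
6,000–12,000 probes for shared unit-test fixtures. The whole suite completes
in well under a minute of compute apart from the cohort study (~20 s).

## Known limitations

- Quantile normalization assumes most genes unchanged; with a strongly
  down-skewed arm (the lethal dose) it attenuates large fold changes, which
  can pull a near-threshold marker below the 2-fold cutoff after the full
  pipeline. The set-level statistics and the dose call are insensitive to
  this; single-gene screens are not.
- The sublethal-unique screen requires presence in *all* nine sublethal
  early cells; a relaxed k-of-n variant would be more robust on noisy data
  but is not what the published screen does.
- Dose-class estimation is ordinal (peak-shift based), not a Gy regression;
  absolute absorbed-dose estimation is out of scope.
- The Sammon input distance and gene filter for expression ordination are
  package defaults, not reconstructions of the original figure.
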