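# Methods

## Data model

A `CqTable` holds quantification-cycle values for genes × samples with
per-sample metadata: a timepoint with an explicit unit (hours or days — a
short-hours series and a long-days series are distinct tables and are never
merged or converted silently), an optional group label, and a biological
replicate index. Samples at timepoint 0 are the untreated controls. Cq is
validated against a configurable plausibility band (default 5–40 cycles);
missing values are explicit (NaN) and counted.

Replicate handling is a mode, not an assumption: by default the three
biological replicates are collapsed to one synthetic sample per timepoint
(mean Cq, skipping missing; median available) before stability analysis,
because stability measures answer "is this gene stable across conditions",
not "across pipetting". The `individual` mode treats each replicate as its
own sample; both are exposed because field practice varies and neither is
universally "the" convention.

geNorm and NormFinder need complete cases; samples with any missing gene
are dropped with a logged count rather than imputed — imputation would leak
the very between-gene structure these methods measure.

## From Cq to relative quantity

geNorm and NormFinder operate on relative quantities
Q(g, s) = F_g^(m_g − Cq(g, s)), with F_g the gene's amplification factor
and m_g its minimum observed Cq, so the best sample has Q = 1 and all
quantities lie in (0, 1]. Anchoring to the per-gene mean instead of the
minimum is offered; it multiplies each gene's quantities by a constant,
which is a pure shift on the log scale and cannot move any stability value
or rank (asserted in the tests). Amplification factors default to 2.0
(perfect doubling) unless supplied or fitted.

## geNorm

For genes j, k the pairwise variation is
V_jk = sd_{n−1}( log2 Q_j(s) − log2 Q_k(s) ) over samples; the stability
measure is M_j = mean_{k≠j} V_jk. Ranking is by iterative exclusion: the
gene with the largest M in the current set is removed and assigned rank =
current set size, until two genes remain; the pair is tied at rank 1.5 and
shares its mutual V as final M (their ratio cannot tell them apart). Ties
on the argmax are broken by removing the lexicographically last gene name —
deterministic and documented; with real noisy data exact ties essentially
never occur.

The sample standard deviation uses the n−1 denominator throughout.

The pairwise-variation series is computed along the exclusion ranking (not
re-ranked per n): NF_n(s) is the geometric mean of the n most stable genes'
quantities and V(n/n+1) = sd_{n−1}( log2 NF_n/NF_{n+1} ). The
reference-gene count is the smallest n ≥ 2 with V(n/n+1) below the
conventional 0.15 cut-off; if the rule is never satisfied the full panel is
returned with a warning rather than an arbitrary truncation.

Key invariances, all tested exactly: multiplying all genes in one sample by
a constant (loading) and multiplying one gene everywhere (fold-change)
leave every V, M and the V series unchanged.

## NormFinder

Log2 quantities are modelled as y_ij = α_i + β_j + ε_ij with
ε_ij ~ N(0, σ_i²). Because the sample effects β_j are estimated from the
candidate panel itself, each gene's naive residual variance is contaminated
by the other genes. With l genes and n samples, the double-centred
residuals r_ij satisfy

    E[ Σ_j r_ij² / (n−1) ] = (1 − 2/l) σ_i² + S/l²,   S = Σ_i σ_i².

Summing over genes gives Ŝ = l/(l−1) · Σ_i m_i, and the per-gene estimate
is σ̂_i² = l (m_i − Ŝ/l²)/(l − 2), clamped at zero with a logged count
(negative solutions occur for genuinely quiet genes at small n). The
stability value is σ̂_i; log base 2 is used throughout (base changes scale,
never ranks). At least 3 genes are required — with 2 the sample mean is
half the gene itself and the correction is singular.

The estimator's contract is behavioural and tested: it is unbiased under
the generating model (Monte-Carlo over 500 datasets at l=8, n=50,
tolerance 0.02 on the σ scale — Monte-Carlo error plus the small
square-root-scale Jensen bias), and it agrees on average with an
independent numerical REML fit of the same heteroscedastic two-way model
(the REML oracle maximises the error-contrast likelihood directly with
L-BFGS; agreement is checked on a 60-dataset subset, a size chosen to keep
the suite fast, since agreement is a per-dataset property).

Grouped mode (groups = e.g. timepoints) estimates per-(gene, group)
intragroup variances σ̂²_ig with the same bias correction applied within
each group, and intergroup differences d_ig as the gene × group interaction
(the deviation of the gene's group mean from what gene level plus group
level predict). d is shrunk toward zero by γ̂²/(γ̂² + σ̂²_ig/n_g), where γ̂²
is the method-of-moments between-group variance of d — so a d that is pure
sampling noise contributes nothing. The gene's stability value is the mean
over groups of |d̃_ig| + posterior SD of d, which grows with both
systematic regulation and scatter. Published descriptions of the grouped
estimator differ in their exact shrinkage constants; this package's choice
is the one documented here, and the tests pin its behaviour (a
between-group-shifted gene is flagged; invariances hold), not constants.
The ungrouped mode is the default: a plain time course has no natural
grouping that the stability question requires.

## BestKeeper

Works on raw Cq, replicate-collapsed by default. Dispersion is, by default,
the mean absolute deviation from the arithmetic mean — the original tool's
"SD" — with the n−1 standard deviation as an option; results are labelled
with the mode used. CV = dispersion / mean Cq × 100. The stability rule is
strict: dispersion < 1 cycle passes, exactly 1 fails. The BestKeeper index
is the per-sample geometric mean Cq over the genes that pass the rule; if
none pass, the index falls back to all genes with a prominent warning.
Every gene — including ones excluded from the index — gets a two-sided
Pearson correlation with the index (no multiplicity adjustment, matching
the original tool); a constant-Cq gene's correlation is undefined and
reported as missing. The mean-absolute-deviation dispersion never exceeds
the standard deviation on the same data (tested).

## Consensus ranking

The cross-method consensus is the arithmetic mean of each gene's method
ranks (geNorm's fractional 1.5 included as-is), re-ranked competition
style: tied means share the minimum rank of their block and the next
distinct mean skips by the block size. Average-style tie ranks are *not*
used — they contradict the bundled published tables, whose 24 consensus
cells this rule reproduces exactly from the printed geNorm and NormFinder
rank orders (the package's one bit-exact contact with the published
numbers; the underlying raw Cq were never deposited, so the stability
values themselves are not recomputable). The aggregator accepts any number
of methods (BestKeeper CV ranks can be added); the reproduction pathway
uses exactly geNorm + NormFinder. A geometric-mean aggregation is provided
as a clearly labelled extra.

## Relative quantification

Fold-changes are computed per biological replicate — treated and control
samples are paired by replicate index — then summarised as mean ± n−1 SD
across replicates; the control timepoint is 1 by construction.

* livak: ratio = 2^(−ΔΔCq), ΔΔCq = (Cq_t − Cq_ref)_treated −
  (Cq_t − Cq_ref)_control; the reference Cq is the single gene's Cq or the
  arithmetic mean over the reference panel (the averaged-Cq rule, the
  default multi-reference mode).
* pfaffl: ratio = F_t^(ΔCq_t) / F_r^(ΔCq_ref) with ΔCq = control − treated.
  For the averaged-Cq rule F_r is the geometric mean of the panel's
  factors; the `multi_rg_geomean` mode instead geometric-means the
  single-reference ratios. The two multi-reference modes coincide whenever
  all efficiencies are equal, and pfaffl reduces to livak exactly when
  every factor is 2 (both tested).

A per-sample loading shift (the same Cq offset on every gene) cancels
exactly in livak and in pfaffl with equal factors; with unequal factors the
offset enters numerator and denominator with different bases, so exact
cancellation holds only at matched efficiencies — the generator's
self-validating fold-change test therefore runs loading-free.

The algebra forces the headline bias property: a target that does not
change, normalized against a reference whose Cq rises by δ under treatment,
shows an apparent fold-change of 2^δ > 1. `compare_strategies` reports each
strategy's profile, its ratio to the multi-reference baseline per
timepoint, and whether its peak timepoint moved. Peak detection is the
argmax of the mean fold-change over non-control timepoints, ties broken to
the earliest with a tie flag.

## Synthetic data

The generator draws
Cq(g, s(τ, r)) = μ_g + drift_g(τ) − log_{F_g}(fold_g(τ)) + loading(τ, r) + ε
with loading ~ N(0, λ) shared by all genes of a sample and ε ~ N(0, σ_g)
independent. Defaults mirror the emulated study design and are fixed once:

* 12 candidate reference genes; short series {0, 0.5, 1, 2, 4, 8} h or long
  series {0, 1, 2, 4, 8} d; 3 biological replicates.
* stable genes: σ = 0.15 cycles (typical qPCR technical + biological
  scatter for a stable transcript); loading λ = 0.3 cycles (plausible
  input-normalization spread between samples).
* one drifting gene (+0.4 cycles per timepoint step — a ~24% expression
  drop per step, large enough to matter and small enough to be
  non-trivial); its baseline is drawn low enough that the accumulated
  drift stays inside the emulated 16.6–29.0 Cq envelope.
* baselines: Uniform(17.0, 26.5), inside the envelope with headroom for
  noise; ≥ 99% of generated values fall inside it (tested).
* optional targets: a log-normal-shaped induction peaking mid-series
  (amplitude ~6×) and a null gene (fold 1 everywhere) for bias
  demonstrations.

Noise is Gaussian on the Cq scale — the standard qPCR error model;
heavier-tailed alternatives are out of scope. Fold-changes enter through
the gene's own efficiency factor so that efficiency-corrected
quantification recovers the designed curve exactly in the noise-free
limit. Every written experiment carries a ground-truth JSON sidecar (gene
roles and parameters).

What the generator does *not* emulate: amplification-curve shape,
technical-replicate hierarchies below the biological level, inter-plate
calibration, correlated gene regulation, or non-Gaussian outliers (failed
wells). Passing recovery tests therefore show the estimators work under
the additive Gaussian model they assume — they do not certify behaviour
under plate artefacts or co-regulated candidate panels.

## Pipeline and numerical choices

`run_pipeline` chains collapse → quantity transform → geNorm → NormFinder →
BestKeeper → consensus → V-rule, with defaults at the conventional
thresholds (M acceptability 1.5, V cut-off 0.15, BestKeeper dispersion
rule 1.0 cycle, efficiency band 90–110% with an r² ≥ 0.98 soft warning).
Any stage failure aborts with the stage name. Outputs embed a hash of the
configuration and the seed; identical config + seed reproduces
byte-identical CSVs (tested).

Standard curves regress Cq on log10(amount) — not the reverse — and a
non-negative slope is rejected as a non-amplifying series. Efficiency
percent and factor satisfy slope = −1/log10(factor) exactly (round-trip
tested).

Simulation sizes in the test and acceptance suites (200-seed recovery
runs, 500-dataset bias Monte Carlo, 1000 random oracle instances) are
chosen so the whole suite runs in well under a minute of compute while
leaving Monte-Carlo error far below the asserted margins.

## Known limitations

* The published stability values bundled in `refstab.datasets` cannot be
  recomputed from raw data (none were deposited); only the consensus
  column and the reference-gene-count decisions are reproduced bit-exactly
  from printed inputs.
* The grouped NormFinder estimator's shrinkage constants are a documented
  package choice among published variants; ranks are robust to the choice,
  absolute grouped values may differ from other implementations.
* BestKeeper's regression diagnostics (slope/intercept vs the index,
  x-fold columns) are not implemented.
* No statistical testing between timepoints in expression profiles
  (mean ± SD only).
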