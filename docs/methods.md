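# Methods

`concord` implements the statistics used to compare differential-expression
signatures of rapid-acting antidepressants across conditions and across
modalities: signature calling from per-analyte differential tables,
overlap-enrichment tests, directional-concordance tests, rank correlations of
fold-change profiles, the transcriptome-vs-CSF-proteome temporal concordance
procedure, and MAD-based per-cell QC filtering. It does not fit
differential-expression models; tables arrive pre-computed (or synthetic).

## Signature calling

A *differential table* holds, per analyte, a signed log2 fold change (log2FC)
and a p-value (optionally a multiplicity-adjusted one). An analyte is a
signature member iff

    p < p_cutoff   and   |log2FC| > lfc_cutoff,

both inequalities strict, with direction sign(log2FC); zero fold changes are
never members. The bulk default is `p_cutoff = 0.01`, `lfc_cutoff = 1.5` on
the raw p-value. The fold-change threshold is interpreted on the *magnitude of
the log2 fold change* (|log2FC| > 1.5, i.e. >2.8-fold), not on the linear
ratio: signed log2FC is the quantity every downstream correlation uses, and a
ratio reading would make the threshold asymmetric in direction. The
interpretation is a config option, not hard-wired. Records with missing
numerics are excluded and tallied, never silently dropped. Identifier matching
is exact and case-sensitive (an uppercase normalization hook exists in the
readers' column mapping).

The low-expression filter keeps analytes with counts-per-million strictly
above a floor (default 0.1) in at least `min_samples` (default 5) samples.

## Overlap enrichment

For signatures A and B inside a background universe of N analytes the 2x2
contingency table (a = |A∩B|, b, c, d) yields:

* **Exact tail** — P(X ≥ a) for X hypergeometric(N, |B|, |A|), the chance a
  uniformly placed A overlaps B at least as much as observed
  (`scipy.stats.hypergeom`, log-space stable).
* **Permutation tail** — `n_perm` uniform redraws of a set of size |A| from
  the universe holding B fixed; p = (1 + #{overlap ≥ a}) / (n_perm + 1). The
  add-one estimator avoids zero p-values; resampling only the smaller set is
  distributionally identical to resampling both under the same null and is the
  default (resampling both is available). Every stochastic result carries its
  (n_perm, seed).
* **Odds ratio** (a·d)/(b·c), with the Haldane–Anscombe +0.5 applied to all
  four cells when any cell is zero, and the **Jaccard index** a/(a+b+c).
* Tails are one-sided (enrichment) by default; depletion by flag.
* Percentage overlap is reported under both denominators (smaller set and
  union), since either convention appears in practice.

## Directional concordance

Among overlapping analytes, the number whose fold-change signs agree is tested
against Binomial(n, p0), upper tail, with the null agreement probability

    p0 = uA·uB + (1 − uA)(1 − uB),

where uX is the proportion of *background* (universe) analytes with positive
log2FC in dataset X, zero fold changes excluded. Using the full tested
background rather than the significant subset is the default because the null
should reflect the direction balance of everything that could have been
called; the significant-only variant is a config switch. The exact binomial
tail is used as printed probabilities of this construction are sensitive to
the tail convention (strict vs non-strict) and to how p0 is rounded, the
implementation records p0 to full precision and uses P(X ≥ k).

## Rank correlations and FDR

Spearman correlations use midranks for ties; two-sided p-values come from the
t approximation with df = n − 2, except for n ≤ 8 tie-free vectors where the
exact permutation enumeration is used. The method is recorded in every result
so approximation differences stay diagnosable. Constant vectors produce an
explicitly flagged undefined result. Benjamini–Hochberg adjustment is the
standard step-up procedure (statsmodels), validated to (0, 1].

The cross-condition correlation matrix restricts to the union of analytes
passing a selection threshold in *any* condition (default: BH-adjusted
p < 0.05, no fold-change cutoff), then correlates each pair of conditions over
the analytes both report. Pairs sharing fewer than 3 analytes are flagged
undefined.

## Cross-modal universe and temporal concordance

Gene and protein signatures are comparable only over analytes measured in
both modalities. The universe is therefore the set of genes that (i) were
tested for differential expression and (ii) map to a protein present on the
panel. Many-to-many gene-protein mappings collapse to one record per gene;
the default keeps the protein with the smallest p-value (preserving the
strongest evidence), with first-pair and mean-fold-change alternatives.

`temporal_concordance` compares one fixed neuronal gene signature with serial
proteomic differential tables. Thresholds are asymmetric by design: the
protein side is FDR-corrected (BH < 0.05, computed within the
universe-restricted table when the input lacks adjusted p-values) while the
gene side uses raw p < 0.05 — the panel covers ~1.4k proteins against ~20k
genes, so the multiplicity burdens are not comparable. Signatures are called
within the restricted universe by default; calling globally and intersecting
afterwards is available as a flag, since either order is defensible. Per
timepoint the profile reports overlap count, exact and permutation
enrichment tails, Spearman rho over the overlapping analytes (undefined below
3 shared analytes, without aborting the series), and BH q-values across the
series' correlation p-values. Per-timepoint permutation seeds derive from one
master seed via `SeedSequence`, so profiles are reproducible end to end.
Pharmacokinetic concentration curves can be attached to profile plots as
annotation only; no statistic is computed against them.

## MAD-based QC filtering

Per-cell metrics are filtered on median absolute deviations computed once
over all input cells: mitochondrial percentage has an upper threshold only
(median + 3 MADs), detected genes and UMIs are filtered on both sides.
The MAD is scaled by 1.4826 (normal consistency) by default; the unscaled
variant is selectable. Rules act simultaneously on the original statistics —
no iterative re-computation — so removing a cell flagged by no rule never
changes another cell's fate. A metric with zero MAD makes its rule a logged
no-op. Thresholds are global by default with per-sample grouping available;
targeted removals that depend on clustering (low-complexity clusters,
whole-sample exclusions) are out of scope here because clustering itself is.

## Synthetic data

The generator produces data with the structure the analyses assume, plus
ground truth, so calibration and power are measurable.

**Condition tables.** True effects for a fraction of genes (default 0.15)
are multivariate Gaussian across the 4-agent x 2-timepoint grid
(effect SD 1.0 on the log2 scale); observed log2FC adds N(0, 0.3²) noise, and
p-values are two-sided normal tails of the observed effect against the noise
scale, making null p-values exactly uniform. Correlation targets (default
+0.8 between agents within a timepoint, −0.3 across timepoints — high
same-time agreement with between-time reversal) are stated for the *observed*
Spearman: the latent Pearson is set to 2·sin(π·ρ/6)·(1 + (noise/effect)²),
undoing the Gaussian rank mapping and the noise attenuation. Infeasible
(non-PSD) targets are rejected before sampling.

**Cross-modal pair.** Identifiers are synthetic (G000001…, P000001…) with an
injective base map (1235 mappable of 20k genes / 1461 proteins, matching the
structure of a transcriptome vs a fixed proteomic panel) plus configurable
many-to-many noise pairs confined to already-mapped genes, so the universe
size stays exact. Membership is planted first — a gene set A (expected 72)
and per-timepoint protein sets B_t (expected 364) whose inclusion probability
for A-members is scaled by the enrichment ramp — so the expected overlap is
`enrichment × |A||B|/N` by construction. Statistics are then generated to be
consistent with the calling thresholds: members receive unambiguous
p-values, non-members draw p ~ U(cutoff, 1), which is super-uniform
(conservative) rather than uniform — a deliberate choice that makes called
sets equal planted sets, at the cost of not emulating near-threshold
borderline calls. Fold-change correlation between mapped members ramps from
0.2 to 0.9 at the peak timepoint (default index 5 of 6) and half-decays
after it; at enrichment 1 the series is a pure null with independent
directions. Six draw times (1, 2, 4, 8, 12, 24 h) span a day.

**QC tables.** Inlier library sizes are log-normal (median 10k UMIs, tight
dispersion so the 3-MAD rules are near no-ops on clean data), gene counts a
noisy power of UMIs, mitochondrial percentage Beta-distributed around 5%.
Planted outliers emulate damaged cells: mitochondrial fraction around 33%
with ~4.5-fold reduced library size. The outlier fraction must stay below
0.5 so the median remains anchored to inliers.

What the generator does **not** emulate: count-level noise and
mean-variance relationships of sequencing data, proteomic assay (NPX)
distributions, real pharmacokinetics, correlated multi-gene modules, or
batch structure. Passing tests therefore demonstrate correctness and
calibration of the *statistics*, not robustness to every pathology of real
data.

## Operating characteristics measured by the acceptance suite

* The permutation estimator agrees with the exact hypergeometric tail over
  every contingency configuration with N ≤ 20 at 100k draws, judged by exact
  binomial comparisons at a 3σ family-wise level (tens of thousands of
  simultaneous Monte-Carlo comparisons make a per-comparison 3-SE band
  unattainable for a correct implementation).
* On the 1235-analyte universe with |A| = 72, |B| = 364, a = 28, the exact
  tail is 0.0496 and a 10,000-draw permutation run scatters around it with
  SE ≈ 0.002.
* 500 null cross-modal replicates give permutation p-values consistent with
  uniformity and a directional-concordance false-positive rate within
  binomial error of α = 0.05.
* At 2x planted enrichment the median permutation p over 100 seeds is < 0.05,
  and the temporal-profile rho argmax recovers the planted peak in ≥ 90/100
  seeds.
* Null-calibration and recovery replicates run the generator at
  n_genes = 2000 (the universe stays at its full 1235) so hundreds of
  replicates remain cheap; gene count outside the universe only dilutes the
  neuronal table and does not enter the cross-modal statistics.

## Not reproduced at this scale

Quantities that depend on the original study's raw sequencing/proteomic
data, supplementary tables or external databases are documented but not
reproduced by the synthetic suite: per-drug DEG counts, the
psilocybin–LSD overlap percentage and its odds ratio, the observed
cross-modal Spearman values and their FDRs, and all pathway (hallmark/KEGG/
GO/STRING) enrichment results. The property-based suites above cover the
corresponding machinery instead.

## Known limitations

* The permutation and binomial nulls assume exchangeability of analytes
  within the universe; correlated analytes (co-regulated genes, cross-reactive
  panel proteins) would make the nulls anti-conservative. This mirrors the
  standard practice the statistics come from but is worth remembering when
  interpreting borderline p-values.
* The exact Spearman path is enumerative and limited to n ≤ 8; for 9 ≤ n ≤ 25
  the t approximation is used even though it is only asymptotically exact.
* `background_agreement_prob` treats the two datasets' direction proportions
  as independent; shared analytes induce slight dependence that the binomial
  null ignores.
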