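# concord

Statistics for comparing differential-expression signatures of rapid-acting
antidepressants — across drugs, across time, and across modalities
(iPSC-derived neuronal transcriptome vs CSF proteome after ketamine
infusion). For computational biologists who already have per-condition
differential tables (from limma/voom, Dream, Olink workflows, …) and need
the comparison layer: signature calling, overlap enrichment, directional
concordance, fold-change correlation structure, temporal cross-modal
alignment, and MAD-based single-cell QC filtering.

## What it computes

Given signatures A and B inside a background universe of N analytes with
overlap a = |A ∩ B|:

* exact hypergeometric tail P(X ≥ a), X ~ Hypergeom(N, |B|, |A|);
* permutation tail p = (1 + #{overlap ≥ a}) / (n_perm + 1) from uniform
  redraws of A (seeded, reproducible);
* odds ratio (a·d)/(b·c) (Haldane–Anscombe corrected) and Jaccard a/(a+b+c);
* directional concordance: k sign-agreements among the a overlapping
  analytes tested against Binomial(a, p0), upper tail, with
  p0 = u_A·u_B + (1 − u_A)(1 − u_B) from the background up-regulation
  proportions;
* Spearman ρ (midranks; t approximation, exact enumeration for n ≤ 8)
  with Benjamini–Hochberg FDR across a series;
* `temporal_concordance`: one neuronal signature against serial CSF
  proteomic draws over a gene↔protein-mapped universe, with asymmetric
  thresholds (genes raw p < 0.05, proteins FDR < 0.05) — per-timepoint
  overlap, enrichment tails, ρ and q.

A seeded synthetic-data module generates all inputs with planted ground
truth (correlated drug/timepoint effects, planted cross-modal enrichment
peaking at a chosen timepoint, QC outlier subpopulations), so calibration
and power of every statistic are measurable. See `docs/methods.md` for the
models and design choices.

## Worked example

Simulate a cross-modal dataset (20k genes, 1461-protein panel, 1235-analyte
universe, enrichment 2x peaking at the last of six CSF draws), then run the
full analysis:

```sh
concord simulate -o sim --seed 11
cat > run.yaml <<EOF
neuronal_table: sim/neuronal.tsv
csf_manifest: sim/csf_manifest.tsv
mapping: sim/mapping.tsv
outdir: out
n_perm: 10000
seed: 11
EOF
concord run -c run.yaml
```

prints

```
concord 0.1.0 | seed=11 n_perm=10000
crossmodal arm: universe=1235, peak rho at 24h (rho=0.959, q=1.73e-25);
directional agreement 42/47 (p0=0.500, p=1.26e-08) [1.4s]
```

and writes `out/temporal_profile.tsv`, whose first rows are

```
hours  n_gene_sig  n_protein_sig  overlap_count  expected_overlap  overlap_p_hyper  overlap_p_perm  rho     p        q
1.0    74          351            24             21.03             0.253            0.257           0.137   0.522    0.522
2.0    74          362            30             21.69             0.0219           0.0221          0.584   7.1e-04  1.1e-03
```

Reading: the 74-gene neuronal signature overlaps the 1-hour CSF protein
signature no more than chance (24 observed vs 21.0 expected, permutation
p = 0.26) and fold changes are uncorrelated; by the 24-hour draw the planted
concordance dominates (ρ = 0.96) and 42 of the 47 overlapping analytes agree
in direction against a 0.50 null agreement probability (binomial
p = 1.3e-08). `out/` also contains the per-timepoint JSON, the directional
concordance report, and a provenance block (config hash, seed, n_perm,
version).

Library use mirrors the CLI:

```python
from concord import overlap_counts, hypergeometric_p, permutation_overlap_p

U = [f"x{i}" for i in range(1235)]
B = set(U[:364]); A = set(U[:28]) | set(U[364:408])   # |A∩B| = 28
t = overlap_counts(A, B, U)
hypergeometric_p(t)                       # 0.0496
permutation_overlap_p(A, B, U, n_perm=10_000, seed=1)  # ~0.049
```

Other subcommands: `concord overlap A.tsv B.tsv --universe U.txt`,
`concord qc-mad metrics.tsv`, `concord simulate-qc`.

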