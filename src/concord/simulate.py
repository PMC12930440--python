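"""Synthetic differential-expression data with known ground truth.

Every analysis stage in this package consumes differential-statistics
tables; this module generates such tables with the statistical structure
the analyses assume, so the whole pipeline is testable end to end and its
operating characteristics (null calibration, power, parameter recovery)
can be measured against planted truth.

Three generators:

* :func:`gen_condition_tables` — gene-level tables for a grid of agents x
  timepoints whose *observed* log2 fold changes realize target Spearman
  correlations: high positive between agents at the same timepoint,
  negative between timepoints.  True effects are Gaussian on the log2
  scale; observed = truth + noise and p-values are two-sided normal tails
  of the noisy effect against the noise scale, so null p-values are
  uniform.  The target Spearman rho is converted to the latent Gaussian
  Pearson correlation via r = 2 sin(pi * rho / 6) and inflated by the
  noise attenuation factor 1 + (noise_sd/effect_sd)^2, so the realized
  rank correlation of the observed tables matches the requested target.

* :func:`gen_crossmodal_pair` — one neuronal gene table plus a series of
  protein-panel tables over a partially mappable identifier space.
  Membership is planted first (so expected signature overlap equals
  ``crossmodal_enrichment * |A||B|/N`` by construction) and statistics are
  generated consistently with the calling thresholds afterwards; null
  analytes receive super-uniform p-values.  Fold-change agreement between
  mapped analytes ramps up to ``concordance_peak_timepoint`` and decays
  after it.  With ``crossmodal_enrichment = 1`` the series is a pure null:
  no planted overlap, independent directions.

* :func:`gen_qc_table` — per-cell QC metrics with a planted low-quality
  subpopulation (high mitochondrial fraction, reduced library size).

All generators are deterministic given their seed and return ground truth
alongside the data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .correlation import bh_fdr
from .crossmodal import CrossModalMap
from .signatures import Condition, DifferentialTable, write_differential_table

__all__ = [
    "SyntheticSpec",
    "CrossModalSim",
    "gen_condition_tables",
    "gen_crossmodal_pair",
    "gen_qc_table",
    "write_crossmodal_sim",
]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    Defaults mirror the data structure the analyses expect: ~20k genes,
    a 1461-protein panel with 1235 analytes mappable to tested genes,
    4 agents x 2 timepoints of gene tables, six serial proteomic draws
    over 24 h, and cross-modal signature sizes near 72 (genes) and 364
    (proteins) within the 1235-analyte universe.
    """

    n_genes: int = 20_000
    n_proteins: int = 1461
    n_mappable: int = 1235
    agents: Sequence[str] = ("HNK", "psilocybin", "LSD", "DOI")
    timepoints: Sequence[float] = (6.0, 24.0)
    signal_fraction: float = 0.15
    effect_sd: float = 1.0
    noise_sd: float = 0.3
    within_time_corr: float = 0.8
    across_time_corr: float = -0.3
    crossmodal_enrichment: float = 2.0
    concordance_peak_timepoint: int = 5
    csf_hours: Sequence[float] = (1.0, 2.0, 4.0, 8.0, 12.0, 24.0)
    target_gene_sig: int = 72
    target_protein_sig: int = 364
    gene_p_cutoff: float = 0.05
    peak_corr: float = 0.9
    base_corr: float = 0.2
    n_extra_pairs: int = 50
    seed: int = 0

    def __post_init__(self):
        self.agents = tuple(self.agents)
        self.timepoints = tuple(float(t) for t in self.timepoints)
        self.csf_hours = tuple(float(h) for h in self.csf_hours)
        if not 0 <= self.signal_fraction <= 1:
            raise ValueError("signal_fraction must lie in [0, 1]")
        for name in ("within_time_corr", "across_time_corr"):
            if not -1 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [-1, 1]")
        if self.n_mappable > min(self.n_genes, self.n_proteins):
            raise ValueError("n_mappable must be <= min(n_genes, n_proteins)")
        if not 0 <= self.concordance_peak_timepoint < len(self.csf_hours):
            raise ValueError("concordance_peak_timepoint out of range")
        if (np.diff(np.asarray(self.csf_hours)) <= 0).any():
            raise ValueError("csf_hours must be strictly increasing")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("agents", "timepoints", "csf_hours"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        return cls(**d)


def _gene_ids(n: int) -> np.ndarray:
    return np.array([f"G{i:06d}" for i in range(1, n + 1)])


def _protein_ids(n: int) -> np.ndarray:
    return np.array([f"P{i:06d}" for i in range(1, n + 1)])


def _spearman_to_pearson(rho_s: float) -> float:
    """Bivariate-normal rank-to-linear correlation map."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def _latent_correlation(spec: SyntheticSpec) -> np.ndarray:
    """Correlation of true effects across the condition grid.

    Targets are stated for the *observed* log2FC Spearman; the latent
    Pearson is inflated by the measurement-noise attenuation so the
    observed tables realize the targets.
    """
    attenuation = 1.0 + (spec.noise_sd / spec.effect_sd) ** 2
    w = np.clip(_spearman_to_pearson(spec.within_time_corr) * attenuation, -1, 1)
    x = np.clip(_spearman_to_pearson(spec.across_time_corr) * attenuation, -1, 1)
    conditions = [(a, t) for t in spec.timepoints for a in spec.agents]
    k = len(conditions)
    C = np.empty((k, k))
    for i, (_, ti) in enumerate(conditions):
        for j, (_, tj) in enumerate(conditions):
            C[i, j] = 1.0 if i == j else (w if ti == tj else x)
    if np.linalg.eigvalsh(C).min() < -1e-10:
        raise ValueError("infeasible correlation targets: matrix not positive semi-definite")
    return C


def _pvalues_from_noisy_effects(obs: np.ndarray, noise_sd: float) -> np.ndarray:
    """Two-sided normal tail of the observed effect against its noise scale."""
    z = np.abs(obs) / noise_sd
    return np.clip(2.0 * stats.norm.sf(z), np.finfo(float).tiny, 1.0)


def gen_condition_tables(spec: SyntheticSpec) -> tuple[list[DifferentialTable], dict]:
    """Gene tables for every agent x timepoint with planted correlation structure.

    Returns the tables plus ground truth: signal gene ids, per-condition
    true effects and the latent correlation matrix actually used.
    """
    rng = np.random.default_rng(spec.seed)
    C = _latent_correlation(spec)
    conditions = [(a, t) for t in spec.timepoints for a in spec.agents]
    k = len(conditions)
    ids = _gene_ids(spec.n_genes)
    n_sig = int(round(spec.signal_fraction * spec.n_genes))
    signal_idx = np.sort(rng.choice(spec.n_genes, size=n_sig, replace=False))

    L = np.linalg.cholesky(C + 1e-12 * np.eye(k))
    truth = np.zeros((spec.n_genes, k))
    truth[signal_idx] = rng.standard_normal((n_sig, k)) @ L.T * spec.effect_sd
    obs = truth + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, k))
    pvals = _pvalues_from_noisy_effects(obs, spec.noise_sd)

    tables = []
    for j, (agent, tp) in enumerate(conditions):
        df = pd.DataFrame(
            {
                "analyte_id": ids,
                "log2fc": obs[:, j],
                "p_value": pvals[:, j],
                "adj_p": bh_fdr(pvals[:, j]),
            }
        )
        tables.append(DifferentialTable(Condition(agent, tp, "gene"), df))
    ground_truth = {
        "signal_ids": ids[signal_idx].tolist(),
        "conditions": [(a, t) for a, t in conditions],
        "latent_correlation": C,
        "true_effects": truth,
        "targets": {
            "within_time_corr": spec.within_time_corr,
            "across_time_corr": spec.across_time_corr,
        },
    }
    return tables, ground_truth


def _ramp_fraction(t_idx: int, peak: int, n: int) -> float:
    """0..1 concordance ramp peaking at ``peak``, half-decayed afterwards."""
    if t_idx <= peak:
        return t_idx / peak if peak > 0 else 1.0
    return 1.0 - 0.5 * (t_idx - peak) / max(1, n - 1 - peak)


@dataclass
class CrossModalSim:
    neuronal: DifferentialTable
    csf_series: list  # [(hours, DifferentialTable)]
    cmap: CrossModalMap
    truth: dict


def gen_crossmodal_pair(spec: SyntheticSpec) -> CrossModalSim:
    """Neuronal gene table + serial proteomic tables with planted concordance.

    Signature membership is planted first: a gene set A (expected size
    ``target_gene_sig``) inside the mappable universe, and per timepoint a
    protein-derived set B_t whose inclusion probability for members of A
    is multiplied by the enrichment ramp, so E|A ∩ B_t| =
    e_t * |A| * E|B_t| / N exactly.  Statistics are then generated so the
    default calling thresholds (gene raw p < ``gene_p_cutoff``; protein
    BH FDR < 0.05) recover exactly the planted sets: members get
    unambiguous p-values, non-members super-uniform ones.  Fold-change
    correlation between mapped members ramps to ``peak_corr`` at the peak
    timepoint; with ``crossmodal_enrichment <= 1`` no correlation or
    direction agreement is planted (pure null).
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)
    prots = _protein_ids(spec.n_proteins)
    n_map, N = spec.n_mappable, spec.n_mappable
    base_pairs = pd.DataFrame({"gene_id": genes[:n_map], "protein_id": prots[:n_map]})

    universe = genes[:n_map]
    pA = spec.target_gene_sig / N
    pB = spec.target_protein_sig / N
    in_A = rng.random(N) < pA
    A = set(universe[in_A])
    nA = int(in_A.sum())

    # neuronal gene table
    lfc = rng.normal(0.0, 0.15, size=spec.n_genes)
    p = rng.uniform(spec.gene_p_cutoff, 1.0, size=spec.n_genes)
    a_mask = np.isin(genes, list(A))
    lfc_A = rng.standard_normal(a_mask.sum())
    lfc_A[lfc_A == 0] = 1e-6
    lfc[a_mask] = lfc_A
    p[a_mask] = rng.uniform(1e-8, 0.9 * spec.gene_p_cutoff, size=a_mask.sum())
    neuronal = DifferentialTable(
        Condition("HNK", 24.0, "gene"),
        pd.DataFrame({"analyte_id": genes, "log2fc": lfc, "p_value": p, "adj_p": bh_fdr(p)}),
    )
    gene_lfc = dict(zip(genes, lfc))

    T = len(spec.csf_hours)
    peak = spec.concordance_peak_timepoint
    e = max(spec.crossmodal_enrichment, 0.0)
    series = []
    B_sets, corr_ts, e_ts = [], [], []
    base_gene_for = dict(zip(prots[:n_map], universe))
    for t_idx, hours in enumerate(spec.csf_hours):
        frac = _ramp_fraction(t_idx, peak, T)
        e_t = 1.0 + (e - 1.0) * frac
        corr_t = (spec.base_corr + (spec.peak_corr - spec.base_corr) * frac) if e > 1 else 0.0
        q_in = min(1.0, e_t * pB)
        denom = N - nA
        q_out = np.clip((spec.target_protein_sig - q_in * nA) / denom, 0.0, 1.0) if denom else 0.0
        in_B = np.where(in_A, rng.random(N) < q_in, rng.random(N) < q_out)
        B = set(universe[in_B])

        p_prot = rng.uniform(0.05, 1.0, size=spec.n_proteins)
        lfc_prot = rng.normal(0.0, 0.15, size=spec.n_proteins)
        for i in range(n_map):
            g = universe[i]
            if g in B:
                p_prot[i] = rng.uniform(1e-12, 1e-6)
                if g in A and corr_t != 0.0:
                    lfc_prot[i] = corr_t * gene_lfc[g] + np.sqrt(1 - corr_t**2) * rng.standard_normal()
                else:
                    lfc_prot[i] = rng.standard_normal()
        lfc_prot[lfc_prot == 0] = 1e-6
        table = DifferentialTable(
            Condition("ketamine", float(hours), "protein"),
            pd.DataFrame(
                {
                    "analyte_id": prots,
                    "log2fc": lfc_prot,
                    "p_value": p_prot,
                    "adj_p": bh_fdr(p_prot),
                }
            ),
        )
        series.append((float(hours), table))
        B_sets.append(B)
        corr_ts.append(corr_t)
        e_ts.append(e_t)

    # many-to-many noise pairs among universe genes and never-significant proteins,
    # so collapsing cannot change planted membership
    sig_prots = {prots[i] for i in range(n_map) if any(universe[i] in B for B in B_sets)}
    null_prots = [q for q in prots if q not in sig_prots]
    extra = min(spec.n_extra_pairs, len(null_prots))
    pairs = base_pairs
    if extra:
        extra_df = pd.DataFrame(
            {
                "gene_id": rng.choice(universe, size=extra, replace=True),
                "protein_id": rng.choice(null_prots, size=extra, replace=False),
            }
        )
        pairs = pd.concat([base_pairs, extra_df], ignore_index=True)
    cmap = CrossModalMap(pairs, collapse_policy="best_p")

    truth = {
        "universe": set(universe),
        "A": A,
        "B_per_timepoint": B_sets,
        "corr_per_timepoint": corr_ts,
        "enrichment_per_timepoint": e_ts,
        "expected_overlap_per_timepoint": [e_t * nA * pB for e_t in e_ts],
        "peak_index": peak,
        "n_A": nA,
    }
    return CrossModalSim(neuronal=neuronal, csf_series=series, cmap=cmap, truth=truth)


def gen_qc_table(
    n_cells: int = 2000, outlier_fraction: float = 0.05, seed: int = 0
) -> tuple[pd.DataFrame, set[str]]:
    """Per-cell QC metrics with a planted low-quality subpopulation.

    Inliers: log-normal library sizes (median 10k UMIs), gene counts a
    noisy power of UMIs, mitochondrial percentage Beta-distributed around
    5%.  Outliers emulate damaged cells: mitochondrial fraction around
    33% with reduced library size.  Returns the table and the planted
    outlier cell ids.
    """
    if n_cells < 10:
        raise ValueError("n_cells must be >= 10")
    if not 0 <= outlier_fraction < 0.5:
        raise ValueError("outlier_fraction must lie in [0, 0.5) — the median must stay anchored to inliers")
    rng = np.random.default_rng(seed)
    n_out = int(round(outlier_fraction * n_cells))
    out_idx = rng.choice(n_cells, size=n_out, replace=False)
    is_out = np.zeros(n_cells, dtype=bool)
    is_out[out_idx] = True

    # inlier dispersion is kept tight so the default 3-MAD rules are a
    # near no-op on clean data (the planted outliers carry the signal)
    log_umi = rng.normal(np.log(10_000), 0.15, size=n_cells)
    log_umi[is_out] += rng.normal(-1.5, 0.3, size=n_out)
    n_umi = np.maximum(1, np.round(np.exp(log_umi))).astype(int)
    n_genes = np.maximum(
        1, np.round(np.exp(0.85 * np.log(n_umi) + rng.normal(0, 0.06, size=n_cells)))
    ).astype(int)
    pct = 100 * rng.beta(8, 152, size=n_cells)
    pct[is_out] = 100 * rng.beta(12, 24, size=n_out)
    df = pd.DataFrame(
        {
            "cell_id": [f"CELL{i:05d}" for i in range(n_cells)],
            "n_genes": n_genes,
            "n_umi": n_umi,
            "pct_mito": np.clip(pct, 0, 100),
        }
    )
    outliers = set(df.loc[is_out, "cell_id"])
    return df, outliers


def write_crossmodal_sim(sim: CrossModalSim, outdir: str | Path) -> dict:
    """Write a cross-modal simulation in the TSV dialects the pipeline reads.

    Emits the neuronal table, one protein table per timepoint, a manifest
    (hours, path), the gene-protein mapping and a JSON ground-truth file.
    Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"neuronal": outdir / "neuronal.tsv", "mapping": outdir / "mapping.tsv"}
    write_differential_table(sim.neuronal, paths["neuronal"])
    sim.cmap.pairs.to_csv(paths["mapping"], sep="\t", index=False)
    rows = []
    for hours, table in sim.csf_series:
        p = outdir / f"csf_{hours:g}h.tsv"
        write_differential_table(table, p)
        rows.append({"hours": hours, "path": p.name})
    manifest = outdir / "csf_manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    paths["manifest"] = manifest
    truth_json = {
        "A": sorted(sim.truth["A"]),
        "B_per_timepoint": [sorted(b) for b in sim.truth["B_per_timepoint"]],
        "corr_per_timepoint": sim.truth["corr_per_timepoint"],
        "enrichment_per_timepoint": sim.truth["enrichment_per_timepoint"],
        "expected_overlap_per_timepoint": sim.truth["expected_overlap_per_timepoint"],
        "peak_index": sim.truth["peak_index"],
    }
    (outdir / "truth.json").write_text(json.dumps(truth_json, indent=2))
    paths["truth"] = outdir / "truth.json"
    return paths
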