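"""Cross-modal (transcriptome vs proteome) background and temporal concordance.

A gene-level differential signature can only be compared with a
protein-panel signature over analytes measurable in *both* modalities, so
the background universe is the intersection: genes that were tested for
differential expression AND map to a protein present on the panel.  All
enrichment and concordance statistics are then computed within that
universe; using the full gene universe instead would overstate
enrichment.

:func:`temporal_concordance` runs the comparison of one fixed neuronal
signature against a series of proteomic differential tables (serial CSF
draws), producing per-timepoint overlap counts, permutation enrichment
p-values, Spearman correlations of fold changes over the overlapping
analytes, and BH-adjusted q-values across the series.  Thresholds are
asymmetric by default: the protein side is FDR-corrected, the gene side
uses raw p-values (the protein panel covers far fewer analytes, so the
gene-side multiplicity burden is not comparable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .correlation import bh_fdr, spearman_rho_p
from .overlap import hypergeometric_p, overlap_counts, permutation_overlap_p
from .signatures import (
    Condition,
    DifferentialTable,
    SignatureThresholds,
    call_signature,
    with_bh_adjusted,
)

__all__ = [
    "CrossModalMap",
    "Universe",
    "PKCurve",
    "TemporalProfile",
    "read_mapping",
    "build_universe",
    "project_protein_table",
    "temporal_concordance",
    "GENE_THRESHOLDS",
    "PROTEIN_THRESHOLDS",
]

#: default asymmetric thresholds: genes raw p < 0.05, proteins FDR < 0.05
GENE_THRESHOLDS = SignatureThresholds(p_cutoff=0.05, lfc_cutoff=0.0, use_adjusted=False)
PROTEIN_THRESHOLDS = SignatureThresholds(p_cutoff=0.05, lfc_cutoff=0.0, use_adjusted=True)


@dataclass
class CrossModalMap:
    """Gene <-> protein identifier pairs with a many-to-many collapse policy.

    ``collapse_policy`` governs how several proteins mapping to one gene are
    reduced to one record: ``best_p`` keeps the most significant protein,
    ``first`` the first pair encountered, ``mean_lfc`` averages fold
    changes and keeps the smallest p.
    """

    pairs: pd.DataFrame  # columns: gene_id, protein_id
    collapse_policy: str = "best_p"

    def __post_init__(self):
        if self.collapse_policy not in ("first", "best_p", "mean_lfc"):
            raise ValueError(f"unknown collapse policy {self.collapse_policy!r}")
        df = self.pairs[["gene_id", "protein_id"]].astype(str)
        if df.duplicated().any():
            df = df.drop_duplicates()
        self.pairs = df.reset_index(drop=True)

    def genes_for(self, protein_ids: Iterable[str]) -> set[str]:
        keep = self.pairs["protein_id"].isin(set(protein_ids))
        return set(self.pairs.loc[keep, "gene_id"])


@dataclass(frozen=True)
class Universe:
    """Background analyte set for enrichment statistics."""

    analyte_ids: frozenset
    provenance: str = "single-modality"
    source_sizes: tuple[int, int] | None = None  # (n_genes, n_proteins)
    n_unmapped_genes: int = 0
    n_unmapped_proteins: int = 0

    def __post_init__(self):
        if not self.analyte_ids:
            raise ValueError("universe must be nonempty")

    def __len__(self) -> int:
        return len(self.analyte_ids)

    def __iter__(self):
        return iter(self.analyte_ids)


@dataclass
class PKCurve:
    """Scaled concentration-time curve carried through for plot annotation only."""

    timepoints: Sequence[float]
    concentrations: Sequence[float]
    analyte_label: str

    def __post_init__(self):
        t = np.asarray(self.timepoints, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if len(t) != len(c):
            raise ValueError("timepoints and concentrations must have equal length")
        if (np.diff(t) <= 0).any():
            raise ValueError("timepoints must be strictly increasing")
        if (c < 0).any():
            raise ValueError("concentrations must be nonnegative")


@dataclass
class TemporalProfile:
    """Per-CSF-timepoint concordance of a fixed neuronal signature."""

    table: pd.DataFrame  # hours, n_gene_sig, n_protein_sig, overlap_count, ...
    universe_size: int
    n_perm: int
    seed: int

    def argmax_rho(self) -> int:
        """Index of the timepoint with the largest defined correlation."""
        rho = self.table["rho"].to_numpy(dtype=float)
        if np.isnan(rho).all():
            raise ValueError("no defined correlations in the profile")
        return int(np.nanargmax(rho))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def read_mapping(path: str | Path, collapse_policy: str = "best_p") -> CrossModalMap:
    """Read a two-column TSV (gene_id, protein_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "protein_id"} <= set(df.columns):
        raise ValueError("mapping file needs columns gene_id and protein_id")
    return CrossModalMap(df, collapse_policy=collapse_policy)


def build_universe(
    gene_ids: Iterable[str], protein_ids: Iterable[str], cmap: CrossModalMap
) -> Universe:
    """Genes tested in the transcriptome that map to a measured protein.

    Many-to-many pairs collapse to one universe entry per gene.  Unmapped
    counts on both sides are carried on the result for reporting.
    """
    genes = frozenset(map(str, gene_ids))
    prots = frozenset(map(str, protein_ids))
    pairs = cmap.pairs
    live = pairs[pairs["gene_id"].isin(genes) & pairs["protein_id"].isin(prots)]
    members = frozenset(live["gene_id"])
    if not members:
        raise ValueError("cross-modal universe is empty: no tested gene maps to a measured protein")
    return Universe(
        analyte_ids=members,
        provenance="cross-modal",
        source_sizes=(len(genes), len(prots)),
        n_unmapped_genes=len(genes - set(pairs["gene_id"])),
        n_unmapped_proteins=len(prots - set(pairs["protein_id"])),
    )


def project_protein_table(
    table: DifferentialTable, cmap: CrossModalMap, universe: Universe | None = None
) -> DifferentialTable:
    """Re-index a protein-level table onto gene identifiers.

    Proteins without a mapped gene are dropped; several proteins mapping to
    one gene are collapsed per the map's policy.
    """
    merged = table.data.merge(
        cmap.pairs, left_on="analyte_id", right_on="protein_id", how="inner"
    )
    if universe is not None:
        merged = merged[merged["gene_id"].isin(universe.analyte_ids)]
    if merged.empty:
        raise ValueError("no protein maps into the requested gene space")
    policy = cmap.collapse_policy
    if policy == "first":
        collapsed = merged.groupby("gene_id", sort=True).first()
    elif policy == "best_p":
        collapsed = merged.sort_values("p_value").groupby("gene_id", sort=True).first()
    else:  # mean_lfc
        collapsed = merged.groupby("gene_id", sort=True).agg(
            log2fc=("log2fc", "mean"), p_value=("p_value", "min"), adj_p=("adj_p", "min")
        )
    out = collapsed.reset_index()[["gene_id", "log2fc", "p_value", "adj_p"]].rename(
        columns={"gene_id": "analyte_id"}
    )
    return DifferentialTable(table.condition, out)


def temporal_concordance(
    neuronal: DifferentialTable,
    csf_series: Sequence[tuple[float, DifferentialTable]],
    cmap: CrossModalMap,
    gene_thresholds: SignatureThresholds = GENE_THRESHOLDS,
    protein_thresholds: SignatureThresholds = PROTEIN_THRESHOLDS,
    n_perm: int = 10_000,
    seed: int = 0,
    restrict_to_universe: bool = True,
    min_overlap_for_rho: int = 3,
) -> TemporalProfile:
    """Concordance profile of one neuronal signature against serial CSF draws.

    Per timepoint: the gene signature is called with ``gene_thresholds``
    (raw p by default) and the protein signature with
    ``protein_thresholds`` (FDR by default, computed within the restricted
    table when the input lacks adjusted p-values); overlap enrichment is
    assessed by exact and permutation tails on the cross-modal universe,
    and fold-change Spearman correlation is computed over the overlapping
    analytes.  q is BH across the series' correlation p-values.  Timepoints
    with overlap below ``min_overlap_for_rho`` get NaN correlations and the
    profile continues.
    """
    hours = [h for h, _ in csf_series]
    if (np.diff(hours) <= 0).any():
        raise ValueError("CSF series timepoints must be strictly increasing")
    protein_ids: set[str] = set()
    for _, tab in csf_series:
        protein_ids |= set(tab.analyte_ids)
    universe = build_universe(neuronal.analyte_ids, protein_ids, cmap)

    neuro_u = neuronal.restrict(universe) if restrict_to_universe else neuronal
    gene_sig = call_signature(neuro_u, gene_thresholds, universe_ref="cross-modal")
    gene_members = gene_sig.members & universe.analyte_ids
    gene_sig_u = type(gene_sig)(
        condition=gene_sig.condition,
        members=frozenset(gene_members),
        directions={m: gene_sig.directions[m] for m in gene_members},
        universe_ref="cross-modal",
        thresholds=gene_thresholds,
    )
    neuro_lfc = neuro_u.indexed()["log2fc"]

    seeds = np.random.SeedSequence(seed).generate_state(len(csf_series)) % (2**31)
    rows = []
    for (h, prot_tab), sub_seed in zip(csf_series, seeds):
        projected = project_protein_table(prot_tab, cmap, universe if restrict_to_universe else None)
        if protein_thresholds.use_adjusted and projected.data["adj_p"].isna().any():
            projected = with_bh_adjusted(projected)
        prot_sig = call_signature(projected, protein_thresholds, universe_ref="cross-modal")
        members = prot_sig.members & universe.analyte_ids
        prot_sig = type(prot_sig)(
            condition=prot_sig.condition,
            members=frozenset(members),
            directions={m: prot_sig.directions[m] for m in members},
            universe_ref="cross-modal",
            thresholds=protein_thresholds,
        )
        t = overlap_counts(gene_sig_u, prot_sig, universe)
        p_hyper = hypergeometric_p(t)
        p_perm = permutation_overlap_p(
            gene_sig_u, prot_sig, universe, n_perm=n_perm, seed=int(sub_seed)
        )
        shared = sorted(gene_sig_u.members & prot_sig.members)
        if len(shared) >= min_overlap_for_rho:
            x = neuro_lfc.loc[shared].to_numpy(dtype=float)
            y = projected.indexed().loc[shared, "log2fc"].to_numpy(dtype=float)
            res = spearman_rho_p(x, y, method="t")
            rho, p_rho = res.rho, res.p
        else:
            rho, p_rho = np.nan, np.nan
        rows.append(
            {
                "hours": h,
                "n_gene_sig": len(gene_sig_u),
                "n_protein_sig": len(prot_sig),
                "overlap_count": t.a,
                "expected_overlap": t.expected_overlap,
                "overlap_p_hyper": p_hyper,
                "overlap_p_perm": p_perm,
                "rho": rho,
                "p": p_rho,
            }
        )
    df = pd.DataFrame(rows)
    q = np.full(len(df), np.nan)
    ok = df["p"].notna().to_numpy()
    if ok.any():
        q[ok] = bh_fdr(df.loc[ok, "p"].to_numpy(dtype=float))
    df["q"] = q
    return TemporalProfile(table=df, universe_size=len(universe), n_perm=n_perm, seed=seed)


def plot_profile(profile: TemporalProfile, pk_curves: Sequence[PKCurve] = (), path=None):
    """Plot overlap counts and rho over time, with optional PK overlays."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = profile.table
    fig, ax1 = plt.subplots(figsize=(7, 4))
    ax1.bar(range(len(df)), df["overlap_count"], color="#888", label="overlap count")
    ax1.set_xticks(range(len(df)), [f"{h:g}h" for h in df["hours"]])
    ax1.set_ylabel("overlapping analytes")
    ax2 = ax1.twinx()
    ax2.plot(range(len(df)), df["rho"], "o-", color="C3", label="Spearman rho")
    ax2.set_ylabel("rho")
    for curve in pk_curves:
        scale = np.nanmax(df["rho"]) if np.isfinite(df["rho"]).any() else 1.0
        conc = np.asarray(curve.concentrations, dtype=float)
        conc = conc / conc.max() * scale if conc.max() > 0 else conc
        ax2.plot(
            np.interp(curve.timepoints, df["hours"], range(len(df))),
            conc,
            "--",
            alpha=0.6,
            label=curve.analyte_label,
        )
    ax2.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
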