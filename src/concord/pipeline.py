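"""End-to-end orchestration: config in, report bundle out.

The pipeline is a thin composition of the public operations — every
intermediate (signatures, overlap results, correlation matrices, temporal
profiles) is also writable/readable standalone, so any stage can be rerun
in isolation on the emitted TSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlation import signature_correlation_matrix
from .crossmodal import (
    GENE_THRESHOLDS,
    PROTEIN_THRESHOLDS,
    TemporalProfile,
    read_mapping,
    temporal_concordance,
)
from .overlap import background_agreement_prob, compare_signatures, directional_concordance
from .signatures import (
    Condition,
    SignatureThresholds,
    call_signature,
    read_differential_table,
)

log = logging.getLogger("concord")

__all__ = ["RunConfig", "ReportBundle", "StageError", "run_concordance"]


class StageError(RuntimeError):
    """Failure wrapped with the pipeline stage and offending input path."""

    def __init__(self, stage: str, path, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {path}: {cause}")
        self.stage = stage
        self.path = path
        self.cause = cause


def _thresholds(d: dict | None, default: SignatureThresholds) -> SignatureThresholds:
    if not d:
        return default
    return SignatureThresholds(
        p_cutoff=float(d.get("p_cutoff", default.p_cutoff)),
        lfc_cutoff=float(d.get("lfc_cutoff", default.lfc_cutoff)),
        use_adjusted=bool(d.get("use_adjusted", default.use_adjusted)),
    )


@dataclass
class RunConfig:
    """Validated run configuration (usually loaded from YAML).

    ``neuronal_table``/``csf_manifest``/``mapping`` drive the cross-modal
    arm; an optional ``condition_tables`` list (path, agent, timepoint)
    additionally produces the cross-condition correlation matrix and
    pairwise overlap statistics.
    """

    outdir: Path
    neuronal_table: Path | None = None
    neuronal_condition: Condition = field(default_factory=lambda: Condition("HNK", 24.0, "gene"))
    csf_manifest: Path | None = None
    mapping: Path | None = None
    condition_tables: list = field(default_factory=list)  # [(path, Condition)]
    gene_thresholds: SignatureThresholds = GENE_THRESHOLDS
    protein_thresholds: SignatureThresholds = PROTEIN_THRESHOLDS
    signature_thresholds: SignatureThresholds = field(default_factory=SignatureThresholds)
    selection_thresholds: SignatureThresholds = SignatureThresholds(0.05, 0.0, True)
    n_perm: int = 10_000
    seed: int = 0
    columns: dict = field(default_factory=dict)
    collapse_policy: str = "best_p"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        base = path.parent

        def _p(key):
            return (base / raw[key]).resolve() if raw.get(key) else None

        cond_tables = []
        for entry in raw.get("condition_tables", []):
            cond = Condition(
                str(entry["agent"]), float(entry["timepoint"]), str(entry.get("modality", "gene"))
            )
            cond_tables.append(((base / entry["path"]).resolve(), cond))
        nc = raw.get("neuronal_condition", {})
        cfg = cls(
            outdir=(base / raw.get("outdir", "concord_out")).resolve(),
            neuronal_table=_p("neuronal_table"),
            neuronal_condition=Condition(
                str(nc.get("agent", "HNK")),
                float(nc.get("timepoint", 24.0)),
                str(nc.get("modality", "gene")),
            ),
            csf_manifest=_p("csf_manifest"),
            mapping=_p("mapping"),
            condition_tables=cond_tables,
            gene_thresholds=_thresholds(raw.get("gene_thresholds"), GENE_THRESHOLDS),
            protein_thresholds=_thresholds(raw.get("protein_thresholds"), PROTEIN_THRESHOLDS),
            signature_thresholds=_thresholds(raw.get("signature_thresholds"), SignatureThresholds()),
            selection_thresholds=_thresholds(
                raw.get("selection_thresholds"), SignatureThresholds(0.05, 0.0, True)
            ),
            n_perm=int(raw.get("n_perm", 10_000)),
            seed=int(raw.get("seed", 0)),
            columns=dict(raw.get("columns", {})),
            collapse_policy=str(raw.get("collapse_policy", "best_p")),
        )
        for p in [cfg.neuronal_table, cfg.csf_manifest, cfg.mapping] + [
            t[0] for t in cfg.condition_tables
        ]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        return cfg


@dataclass
class ReportBundle:
    profile: TemporalProfile | None
    overlap_results: list
    concordance: object | None
    correlation_matrix: object | None
    provenance: dict
    outdir: Path


def _provenance(config: RunConfig) -> dict:
    blob = json.dumps(
        {k: str(v) for k, v in dataclasses.asdict(config).items()}, sort_keys=True
    ).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
        "n_perm": config.n_perm,
        "version": __version__,
    }


def run_concordance(config: RunConfig) -> ReportBundle:
    """Execute the configured stages and write TSV/JSON reports.

    Stage errors propagate as :class:`StageError` carrying the stage name
    and the offending input path.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    profile = None
    corr_matrix = None
    overlap_results: list = []
    concordance = None
    summary_lines = [f"concord {__version__} | seed={config.seed} n_perm={config.n_perm}"]

    if config.condition_tables:
        t0 = time.perf_counter()
        tables = []
        for path, cond in config.condition_tables:
            try:
                tables.append(read_differential_table(path, cond, columns=config.columns))
            except Exception as exc:
                raise StageError("signatures", path, exc) from exc
        try:
            corr_matrix = signature_correlation_matrix(tables, config.selection_thresholds)
        except Exception as exc:
            raise StageError("correlation", config.condition_tables[0][0], exc) from exc
        corr_matrix.rho.to_csv(outdir / "correlation_matrix.tsv", sep="\t")
        corr_matrix.n_shared.to_csv(outdir / "correlation_n_shared.tsv", sep="\t")
        # pairwise signature overlap within the shared identifier space
        universe = set()
        for t in tables:
            universe |= set(t.analyte_ids)
        sigs = [call_signature(t, config.signature_thresholds) for t in tables]
        recs = []
        for i in range(len(sigs)):
            for j in range(i + 1, len(sigs)):
                try:
                    res = compare_signatures(
                        sigs[i], sigs[j], universe, n_perm=config.n_perm, seed=config.seed
                    )
                except Exception as exc:
                    raise StageError("overlap_stats", config.condition_tables[i][0], exc) from exc
                recs.append(
                    {
                        "A": sigs[i].condition.label,
                        "B": sigs[j].condition.label,
                        "a": res.contingency.a,
                        "n_A": res.contingency.n_A,
                        "n_B": res.contingency.n_B,
                        "N": res.contingency.N,
                        "expected": res.expected_overlap,
                        "p_hyper": res.p_hyper,
                        "p_perm": res.p_perm,
                        "odds_ratio": res.odds_ratio,
                        "jaccard": res.jaccard,
                        "n_perm": res.n_perm,
                        "seed": res.seed,
                    }
                )
                overlap_results.append(res)
        pd.DataFrame(recs).to_csv(outdir / "pairwise_overlap.tsv", sep="\t", index=False)
        (outdir / "pairwise_overlap.json").write_text(json.dumps(recs, indent=2))
        summary_lines.append(
            f"condition arm: {len(tables)} tables, correlation matrix + "
            f"{len(recs)} pairwise overlaps [{time.perf_counter() - t0:.1f}s]"
        )
        log.info(summary_lines[-1])

    if config.neuronal_table is not None:
        t0 = time.perf_counter()
        if config.csf_manifest is None or config.mapping is None:
            raise StageError(
                "crossmodal", config.neuronal_table, ValueError("csf_manifest and mapping required")
            )
        try:
            neuronal = read_differential_table(
                config.neuronal_table, config.neuronal_condition, columns=config.columns
            )
        except Exception as exc:
            raise StageError("signatures", config.neuronal_table, exc) from exc
        try:
            cmap = read_mapping(config.mapping, collapse_policy=config.collapse_policy)
            manifest = pd.read_csv(config.csf_manifest, sep="\t")
            series = []
            for _, row in manifest.sort_values("hours").iterrows():
                p = Path(config.csf_manifest).parent / row["path"]
                cond = Condition("ketamine", float(row["hours"]), "protein")
                series.append((float(row["hours"]), read_differential_table(p, cond, columns=config.columns)))
            profile = temporal_concordance(
                neuronal,
                series,
                cmap,
                gene_thresholds=config.gene_thresholds,
                protein_thresholds=config.protein_thresholds,
                n_perm=config.n_perm,
                seed=config.seed,
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError("crossmodal", config.csf_manifest, exc) from exc
        profile.to_tsv(outdir / "temporal_profile.tsv")
        (outdir / "temporal_profile.json").write_text(
            json.dumps(
                {
                    "universe_size": profile.universe_size,
                    "n_perm": profile.n_perm,
                    "seed": profile.seed,
                    "rows": profile.table.to_dict(orient="records"),
                },
                indent=2,
            )
        )
        # directional concordance at the best-aligned timepoint
        try:
            best = profile.argmax_rho()
        except ValueError:
            best = None
        if best is not None:
            from .crossmodal import project_protein_table, build_universe
            from .signatures import call_signature as _call, with_bh_adjusted

            hours, prot_tab = series[best]
            prot_ids = set()
            for _, tab in series:
                prot_ids |= set(tab.analyte_ids)
            uni = build_universe(neuronal.analyte_ids, prot_ids, cmap)
            neuro_u = neuronal.restrict(uni)
            proj = project_protein_table(prot_tab, cmap, uni)
            if config.protein_thresholds.use_adjusted and proj.data["adj_p"].isna().any():
                proj = with_bh_adjusted(proj)
            gene_sig = _call(neuro_u, config.gene_thresholds)
            prot_sig = _call(proj, config.protein_thresholds)
            p0 = background_agreement_prob(neuro_u, proj, uni)
            concordance = directional_concordance(gene_sig, prot_sig, p0)
            (outdir / "directional_concordance.json").write_text(
                json.dumps(
                    {
                        "timepoint_hours": hours,
                        "n_overlap": concordance.n_overlap,
                        "k_agree": concordance.k_agree,
                        "p0": concordance.p0,
                        "p_binom": concordance.p_binom,
                        "seed": config.seed,
                    },
                    indent=2,
                )
            )
            summary_lines.append(
                f"crossmodal arm: universe={profile.universe_size}, peak rho at "
                f"{profile.table.loc[best, 'hours']:g}h "
                f"(rho={profile.table.loc[best, 'rho']:.3f}, q={profile.table.loc[best, 'q']:.3g}); "
                f"directional agreement {concordance.k_agree}/{concordance.n_overlap} "
                f"(p0={concordance.p0:.3f}, p={concordance.p_binom:.3g}) "
                f"[{time.perf_counter() - t0:.1f}s]"
            )
            log.info(summary_lines[-1])

    (outdir / "provenance.json").write_text(json.dumps(prov, indent=2))
    (outdir / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    return ReportBundle(
        profile=profile,
        overlap_results=overlap_results,
        concordance=concordance,
        correlation_matrix=corr_matrix,
        provenance=prov,
        outdir=outdir,
    )
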