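"""MAD-based outlier filtering of per-cell QC metrics.

Cells are filtered on robust z-scores: a cell is removed when a metric
lies more than ``n_mads`` median absolute deviations from the median of
all input cells.  Mitochondrial percentage uses an upper threshold only
(high mito = damaged cell); library-size metrics (detected genes, UMIs)
are filtered on both sides.  Thresholds are computed once on the original
statistics — rules never see each other's removals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MADFilterSpec",
    "FilterReport",
    "default_specs",
    "mad_outlier_filter",
    "read_qc_table",
    "write_report",
]

#: normal-consistency scaling of the MAD
NORMAL_MAD_SCALE = 1.4826

QC_COLUMNS = ("cell_id", "n_genes", "n_umi", "pct_mito")


@dataclass(frozen=True)
class MADFilterSpec:
    """One filtering rule: metric, number of MADs, which tail(s), MAD scaling."""

    metric: str
    n_mads: float = 3.0
    sides: str = "both"  # "upper" | "lower" | "both"
    scale_constant: float = NORMAL_MAD_SCALE

    def __post_init__(self):
        if self.n_mads <= 0:
            raise ValueError("n_mads must be > 0")
        if self.sides not in ("upper", "lower", "both"):
            raise ValueError("sides must be 'upper', 'lower' or 'both'")
        if self.scale_constant <= 0:
            raise ValueError("scale_constant must be > 0")


def default_specs() -> list[MADFilterSpec]:
    """Upper-only 3 MADs on pct_mito; both-sided 3 MADs on genes and UMIs."""
    return [
        MADFilterSpec("pct_mito", 3.0, "upper"),
        MADFilterSpec("n_genes", 3.0, "both"),
        MADFilterSpec("n_umi", 3.0, "both"),
    ]


@dataclass
class FilterReport:
    kept: list[str]
    removed: dict[str, list[str]]  # cell_id -> failed rule names
    thresholds: dict[str, tuple[float | None, float | None]]  # rule -> (lower, upper)
    degenerate_rules: list[str] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def _rule_name(spec: MADFilterSpec) -> str:
    return f"{spec.metric}:{spec.sides}:{spec.n_mads:g}mad"


def mad_outlier_filter(table: pd.DataFrame, specs: list[MADFilterSpec] | None = None) -> FilterReport:
    """Apply MAD rules simultaneously and report per-cell removal reasons.

    ``table`` must carry a ``cell_id`` column (unique) plus each spec's
    metric.  A rule whose metric has zero MAD is a no-op and is listed in
    ``degenerate_rules``.
    """
    if specs is None:
        specs = default_specs()
    if table.empty:
        raise ValueError("QC table is empty")
    if "cell_id" not in table.columns:
        raise ValueError("QC table needs a cell_id column")
    cells = table["cell_id"].astype(str)
    if cells.duplicated().any():
        raise ValueError("cell_id values must be unique")
    if "pct_mito" in table.columns:
        pm = table["pct_mito"].to_numpy(dtype=float)
        if ((pm < 0) | (pm > 100)).any():
            raise ValueError("pct_mito must lie in [0, 100]")

    removed: dict[str, list[str]] = {}
    thresholds: dict[str, tuple[float | None, float | None]] = {}
    degenerate: list[str] = []
    for spec in specs:
        if spec.metric not in table.columns:
            raise ValueError(f"metric {spec.metric!r} not in table")
        x = table[spec.metric].to_numpy(dtype=float)
        med = float(np.median(x))
        mad = float(np.median(np.abs(x - med))) * spec.scale_constant
        name = _rule_name(spec)
        if mad == 0:
            degenerate.append(name)
            thresholds[name] = (None, None)
            continue
        lo = med - spec.n_mads * mad if spec.sides in ("lower", "both") else None
        hi = med + spec.n_mads * mad if spec.sides in ("upper", "both") else None
        thresholds[name] = (lo, hi)
        bad = np.zeros(len(x), dtype=bool)
        if lo is not None:
            bad |= x < lo
        if hi is not None:
            bad |= x > hi
        for cid in cells[bad]:
            removed.setdefault(cid, []).append(name)
    kept = [c for c in cells if c not in removed]
    return FilterReport(kept=kept, removed=removed, thresholds=thresholds, degenerate_rules=degenerate)


def read_qc_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(QC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"QC table missing columns: {sorted(missing)}")
    return df


def write_report(report: FilterReport, outdir: str | Path, prefix: str = "qc") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.Series(report.kept, name="cell_id").to_csv(outdir / f"{prefix}_kept.tsv", sep="\t", index=False)
    payload = {
        "n_kept": len(report.kept),
        "n_removed": report.n_removed,
        "thresholds": {k: list(v) for k, v in report.thresholds.items()},
        "degenerate_rules": report.degenerate_rules,
        "removed": report.removed,
    }
    (outdir / f"{prefix}_report.json").write_text(json.dumps(payload, indent=2))
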