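"""Differential-statistics tables and signature calling.

A *differential table* holds one row per analyte (gene or protein) with a
signed log2 fold change and a p-value for one experimental condition
(agent x timepoint x modality).  A *signature* is the set of analytes that
pass a p-value and |log2FC| threshold, each annotated with the sign of its
fold change.  These are the primitives every downstream overlap,
concordance and correlation statistic consumes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "DifferentialTable",
    "SignatureThresholds",
    "SignatureSet",
    "FormatError",
    "read_differential_table",
    "write_differential_table",
    "filter_low_expression",
    "call_signature",
    "with_bh_adjusted",
    "write_signature",
    "read_signature",
    "DEFAULT_COLUMNS",
]

#: default column-name mapping for delimited differential tables
DEFAULT_COLUMNS: dict[str, str] = {
    "analyte": "analyte",
    "log2fc": "log2fc",
    "pvalue": "pvalue",
    "padj": "padj",
}


class FormatError(ValueError):
    """Raised when an input table violates the expected layout."""


@dataclass(frozen=True)
class Condition:
    """Label of one differential contrast: agent, timepoint (hours), modality."""

    agent: str
    timepoint: float
    modality: str = "gene"  # "gene" | "protein"

    @property
    def label(self) -> str:
        return f"{self.agent}_{self.timepoint:g}h_{self.modality}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


class DifferentialTable:
    """Per-analyte differential statistics for one condition.

    Parameters
    ----------
    condition
        The contrast the statistics belong to.
    data
        DataFrame with columns ``analyte_id`` (str), ``log2fc`` (float),
        ``p_value`` (float in (0, 1]) and optionally ``adj_p``.  Missing
        ``adj_p`` is stored as NaN.  Analyte ids must be unique.
    """

    REQUIRED = ("analyte_id", "log2fc", "p_value")

    def __init__(self, condition: Condition, data: pd.DataFrame):
        data = data.copy()
        for col in self.REQUIRED:
            if col not in data.columns:
                raise FormatError(f"missing required column {col!r}")
        if "adj_p" not in data.columns:
            data["adj_p"] = np.nan
        data["analyte_id"] = data["analyte_id"].astype(str)
        if (data["analyte_id"] == "").any():
            raise FormatError("empty analyte_id")
        dup = data["analyte_id"][data["analyte_id"].duplicated()].unique()
        if dup.size:
            raise FormatError(f"duplicate analyte ids: {', '.join(dup[:10])}")
        for col in ("p_value", "adj_p"):
            vals = data[col].to_numpy(dtype=float)
            finite = np.isfinite(vals)
            if ((vals[finite] <= 0) | (vals[finite] > 1)).any():
                raise FormatError(f"{col} values must lie in (0, 1]")
        self.condition = condition
        self.data = data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def analyte_ids(self) -> pd.Series:
        return self.data["analyte_id"]

    def restrict(self, universe: Iterable[str]) -> "DifferentialTable":
        """Subset the table to analytes in ``universe`` (order preserved)."""
        keep = self.data["analyte_id"].isin(set(universe))
        return DifferentialTable(self.condition, self.data.loc[keep])

    def indexed(self) -> pd.DataFrame:
        return self.data.set_index("analyte_id")


@dataclass(frozen=True)
class SignatureThresholds:
    """Significance cutoffs for signature calling.

    Both inequalities are strict: an analyte is a member iff its chosen
    p-value is strictly below ``p_cutoff`` and |log2FC| strictly above
    ``lfc_cutoff``.  ``use_adjusted`` switches between the raw and the
    multiplicity-adjusted p-value column.
    """

    p_cutoff: float = 0.01
    lfc_cutoff: float = 1.5
    use_adjusted: bool = False

    def __post_init__(self):
        if not 0 < self.p_cutoff < 1:
            raise ValueError("p_cutoff must lie in (0, 1)")
        if self.lfc_cutoff < 0:
            raise ValueError("lfc_cutoff must be >= 0")


@dataclass
class SignatureSet:
    """Called differential analytes with per-analyte direction (+1/-1)."""

    condition: Condition
    members: frozenset
    directions: dict
    universe_ref: str | None = None
    n_dropped: int = 0
    thresholds: SignatureThresholds | None = None

    def __post_init__(self):
        if set(self.directions) != set(self.members):
            raise ValueError("directions must be defined for exactly the members")
        bad = [a for a, d in self.directions.items() if d not in (-1, 1)]
        if bad:
            raise ValueError(f"directions must be +1/-1; offenders: {bad[:5]}")

    def __len__(self) -> int:
        return len(self.members)


def read_differential_table(
    path: str | Path,
    condition: Condition,
    columns: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> DifferentialTable:
    """Read a delimited differential-statistics table.

    ``columns`` maps the logical names (``analyte``, ``log2fc``, ``pvalue``,
    optional ``padj``) to the file's header names; defaults to
    :data:`DEFAULT_COLUMNS`.  Rows with unparseable numerics are dropped
    with a warning reporting their row indices.
    """
    path = Path(path)
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, dtype=str)
    for logical in ("analyte", "log2fc", "pvalue"):
        if colmap[logical] not in raw.columns:
            raise FormatError(
                f"missing required column {colmap[logical]!r} (for {logical!r}) in {path}"
            )
    out = pd.DataFrame({"analyte_id": raw[colmap["analyte"]].astype(str)})
    out["log2fc"] = pd.to_numeric(raw[colmap["log2fc"]], errors="coerce")
    out["p_value"] = pd.to_numeric(raw[colmap["pvalue"]], errors="coerce")
    if colmap.get("padj") in raw.columns:
        out["adj_p"] = pd.to_numeric(raw[colmap["padj"]], errors="coerce")
    else:
        out["adj_p"] = np.nan
    # reject rows whose mandatory numerics failed to parse, reporting indices
    had_text = raw[colmap["log2fc"]].notna() & raw[colmap["pvalue"]].notna()
    bad = (out["log2fc"].isna() | out["p_value"].isna()) & had_text
    if bad.any():
        idx = list(out.index[bad])
        warnings.warn(f"{path.name}: dropped rows with unparseable numerics at indices {idx}")
        out = out.loc[~bad]
    return DifferentialTable(condition, out)


def write_differential_table(table: DifferentialTable, path: str | Path, sep: str = "\t") -> None:
    """Write a table in the dialect :func:`read_differential_table` reads back."""
    df = table.data.rename(
        columns={"analyte_id": "analyte", "log2fc": "log2fc", "p_value": "pvalue", "adj_p": "padj"}
    )
    df.to_csv(path, sep=sep, index=False)


def filter_low_expression(
    counts: pd.DataFrame, cpm_min: float = 0.1, min_samples: int = 5
) -> set[str]:
    """Ids of analytes exceeding ``cpm_min`` in at least ``min_samples`` samples.

    ``counts`` is analytes x samples in counts-per-million; the comparison
    against ``cpm_min`` is strict (> cpm_min).
    """
    if cpm_min < 0:
        raise ValueError("cpm_min must be >= 0")
    if counts.shape[1] and not 1 <= min_samples <= counts.shape[1]:
        raise ValueError("min_samples out of range")
    if counts.empty:
        return set()
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    keep = (counts > cpm_min).sum(axis=1) >= min_samples
    return set(counts.index[keep].astype(str))


def call_signature(
    table: DifferentialTable,
    thresholds: SignatureThresholds = SignatureThresholds(),
    universe_ref: str | None = None,
) -> SignatureSet:
    """Apply significance cutoffs and annotate directions.

    Membership: chosen p < ``p_cutoff`` AND |log2fc| > ``lfc_cutoff`` (both
    strict); direction is the sign of log2fc, so zero-fold-change analytes
    are never members.  Records with missing p or log2fc are excluded and
    counted in ``n_dropped``.
    """
    if not len(table):
        raise ValueError("table is empty")
    df = table.data
    pcol = "adj_p" if thresholds.use_adjusted else "p_value"
    if thresholds.use_adjusted:
        missing = df.loc[df["adj_p"].isna(), "analyte_id"]
        if len(missing):
            raise ValueError(
                "use_adjusted requires adj_p for every record; missing for: "
                + ", ".join(missing.head(10))
            )
    p = df[pcol].to_numpy(dtype=float)
    lfc = df["log2fc"].to_numpy(dtype=float)
    usable = np.isfinite(p) & np.isfinite(lfc)
    member = usable & (p < thresholds.p_cutoff) & (np.abs(lfc) > thresholds.lfc_cutoff)
    ids = df["analyte_id"].to_numpy()
    directions = {
        a: (1 if f > 0 else -1) for a, f in zip(ids[member], lfc[member])
    }
    return SignatureSet(
        condition=table.condition,
        members=frozenset(ids[member]),
        directions=directions,
        universe_ref=universe_ref,
        n_dropped=int((~usable).sum()),
        thresholds=thresholds,
    )


def with_bh_adjusted(table: DifferentialTable) -> DifferentialTable:
    """Return a copy whose ``adj_p`` column is BH step-up of ``p_value``."""
    from .correlation import bh_fdr

    df = table.data.copy()
    df["adj_p"] = bh_fdr(df["p_value"].to_numpy(dtype=float))
    return DifferentialTable(table.condition, df)


def write_signature(sig: SignatureSet, path: str | Path) -> None:
    """Write a signature as two-column TSV plus a JSON sidecar."""
    path = Path(path)
    members = sorted(sig.members)
    pd.DataFrame(
        {"analyte_id": members, "direction": [sig.directions[m] for m in members]}
    ).to_csv(path, sep="\t", index=False)
    sidecar = {
        "condition": {
            "agent": sig.condition.agent,
            "timepoint": sig.condition.timepoint,
            "modality": sig.condition.modality,
        },
        "n_members": len(sig),
        "n_dropped": sig.n_dropped,
        "universe_ref": sig.universe_ref,
        "thresholds": None
        if sig.thresholds is None
        else {
            "p_cutoff": sig.thresholds.p_cutoff,
            "lfc_cutoff": sig.thresholds.lfc_cutoff,
            "use_adjusted": sig.thresholds.use_adjusted,
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_signature(path: str | Path, condition: Condition | None = None) -> SignatureSet:
    """Read a two-column signature TSV written by :func:`write_signature`."""
    df = pd.read_csv(path, sep="\t", dtype={"analyte_id": str, "direction": int})
    if condition is None:
        condition = Condition("unknown", 0.0, "gene")
    return SignatureSet(
        condition=condition,
        members=frozenset(df["analyte_id"]),
        directions=dict(zip(df["analyte_id"], df["direction"])),
    )
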