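"""Rank correlations of signed log2 fold changes and BH FDR control.

Spearman correlations use midranks for ties with a two-sided p from the
t approximation (df = n - 2); for n <= 8 tie-free vectors an exact
permutation-enumeration p is used instead and the method is recorded in
the result so the two paths stay diagnosable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .signatures import DifferentialTable, SignatureThresholds, call_signature

__all__ = [
    "CorrelationResult",
    "CorrelationMatrix",
    "spearman_rho_p",
    "bh_fdr",
    "signature_correlation_matrix",
]


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int
    method: str  # "t-approximation" | "exact-enumeration" | "undefined"

    @property
    def defined(self) -> bool:
        return self.method != "undefined"


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman rho between condition log2FC vectors."""

    condition_labels: list[str]
    rho: pd.DataFrame
    p: pd.DataFrame
    n_shared: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.rho.to_csv(path, sep="\t")


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by enumerating all rank permutations (n <= 8, no ties)."""
    n = len(x)
    ranks = np.arange(1, n + 1, dtype=float)
    denom = n * (n * n - 1) / 6.0
    ry = stats.rankdata(y)
    # rho for every permutation of x-ranks against the fixed y-ranks
    hits = 0
    total = 0
    target = abs(rho_obs) - 1e-12
    for perm in permutations(ranks):
        d = np.asarray(perm) - ry
        rho = 1 - (d @ d) / denom
        if abs(rho) >= target:
            hits += 1
        total += 1
    return hits / total


def spearman_rho_p(x, y, method: str = "auto", alternative: str = "two-sided") -> CorrelationResult:
    """Spearman rank correlation with its p-value.

    Midranks are used for ties.  ``method`` is "auto" (exact enumeration
    for n <= 8 without ties, t approximation otherwise), "t" or "exact".
    Constant input yields an explicitly flagged undefined result rather
    than a silent NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(np.nan, np.nan, n, "undefined")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    if method == "exact" or (method == "auto" and n <= 8 and not ties):
        p = _exact_spearman_p(x, y, rho)
        used = "exact-enumeration"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1 - rho * rho))
            p = 2 * float(stats.t.sf(abs(t), n - 2))
        used = "t-approximation"
    if alternative != "two-sided":
        onesided = p / 2 if (rho > 0) == (alternative == "greater") else 1 - p / 2
        p = onesided
    return CorrelationResult(rho, min(max(p, np.nextafter(0, 1)), 1.0), n, used)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-d vector")
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def signature_correlation_matrix(
    tables,
    selection: SignatureThresholds = SignatureThresholds(p_cutoff=0.05, lfc_cutoff=0.0, use_adjusted=True),
    min_shared: int = 3,
) -> CorrelationMatrix:
    """Cross-condition Spearman matrix of log2FC over jointly significant analytes.

    Restricts to the union of analytes passing ``selection`` in ANY
    condition, then correlates each pair of conditions over the analytes
    both report within that union.  Pairs with fewer than ``min_shared``
    shared analytes get NaN entries (flagged undefined).
    """
    tables = list(tables)
    if len(tables) < 2:
        raise ValueError("need at least two tables")
    labels = [t.condition.label for t in tables]
    if len(set(labels)) != len(labels):
        raise ValueError("condition labels must be unique")
    union: set[str] = set()
    for t in tables:
        union |= call_signature(t, selection).members
    frames = {
        lab: t.indexed().loc[lambda df: df.index.isin(union), "log2fc"]
        for lab, t in zip(labels, tables)
    }
    k = len(labels)
    rho = np.eye(k)
    pmat = np.full((k, k), np.nan)
    nmat = np.zeros((k, k), dtype=int)
    np.fill_diagonal(nmat, [len(frames[l]) for l in labels])
    for i in range(k):
        for j in range(i + 1, k):
            a, b = frames[labels[i]].align(frames[labels[j]], join="inner")
            ok = np.isfinite(a.to_numpy()) & np.isfinite(b.to_numpy())
            nmat[i, j] = nmat[j, i] = int(ok.sum())
            if ok.sum() < min_shared:
                rho[i, j] = rho[j, i] = np.nan
                continue
            res = spearman_rho_p(a.to_numpy()[ok], b.to_numpy()[ok], method="t")
            rho[i, j] = rho[j, i] = res.rho
            pmat[i, j] = pmat[j, i] = res.p
    idx = pd.Index(labels)
    return CorrelationMatrix(
        condition_labels=labels,
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p=pd.DataFrame(pmat, index=idx, columns=idx),
        n_shared=pd.DataFrame(nmat, index=idx, columns=idx),
    )
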