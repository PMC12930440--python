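"""Overlap-enrichment and directional-concordance statistics.

Given two signatures A and B over a shared background universe of N
analytes, the chance that a random placement of A produces at least the
observed overlap a = |A ∩ B| follows the hypergeometric upper tail.  The
module computes that tail exactly, estimates it by permutation (uniform
redraws of A holding B fixed — the same null, useful when the printed
analysis is a permutation test), and summarises the 2x2 association with
an odds ratio (Haldane–Anscombe corrected when a cell is empty) and the
Jaccard index.

Directional concordance asks a second question: among overlapping
analytes, do the fold-change *signs* agree more often than chance?  The
null agreement probability p0 = uA*uB + (1-uA)(1-uB) is built from the
proportions of up-regulated analytes in each full background table, and
the observed number of agreements is tested against Binomial(n, p0),
upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats

from .signatures import DifferentialTable, SignatureSet

__all__ = [
    "ContingencyTable",
    "OverlapResult",
    "ConcordanceResult",
    "overlap_counts",
    "hypergeometric_p",
    "permutation_overlap_p",
    "sample_null_overlaps",
    "sample_uniform_subsets",
    "odds_ratio_and_jaccard",
    "background_agreement_prob",
    "directional_concordance",
    "compare_signatures",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 overlap counts: a = |A∩B|, b = |A\\B|, c = |B\\A|, d = rest."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v!r}")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_A(self) -> int:
        return self.a + self.b

    @property
    def n_B(self) -> int:
        return self.a + self.c

    @property
    def expected_overlap(self) -> float:
        return self.n_A * self.n_B / self.N if self.N else 0.0


@dataclass
class OverlapResult:
    contingency: ContingencyTable
    p_hyper: float
    odds_ratio: float
    jaccard: float
    p_perm: float | None = None
    n_perm: int = 0
    seed: int | None = None

    @property
    def expected_overlap(self) -> float:
        return self.contingency.expected_overlap

    def percent_overlap(self) -> dict[str, float]:
        """Overlap as a percentage under both common denominators."""
        t = self.contingency
        smaller = min(t.n_A, t.n_B)
        union = t.a + t.b + t.c
        return {
            "of_smaller_set": 100.0 * t.a / smaller if smaller else 0.0,
            "of_union": 100.0 * t.a / union if union else 0.0,
        }


@dataclass
class ConcordanceResult:
    n_overlap: int
    k_agree: int
    p0: float
    p_binom: float
    p_perm: float | None = None

    def __post_init__(self):
        if not 0 <= self.k_agree <= self.n_overlap:
            raise ValueError("k_agree must lie in [0, n_overlap]")
        if not 0 <= self.p0 <= 1:
            raise ValueError("p0 must lie in [0, 1]")


def _as_set(x) -> frozenset:
    return x.members if isinstance(x, SignatureSet) else frozenset(x)


def overlap_counts(A, B, universe: Iterable[str]) -> ContingencyTable:
    """Build the 2x2 table of two signatures within a universe.

    Raises if either signature contains analytes outside the universe.
    """
    U = frozenset(universe)
    sA, sB = _as_set(A), _as_set(B)
    for name, s in (("A", sA), ("B", sB)):
        stray = s - U
        if stray:
            raise ValueError(
                f"signature {name} has members outside the universe: {sorted(stray)[:10]}"
            )
    a = len(sA & sB)
    b = len(sA) - a
    c = len(sB) - a
    return ContingencyTable(a, b, c, len(U) - a - b - c)


def hypergeometric_p(t: ContingencyTable, alternative: str = "greater") -> float:
    """Exact hypergeometric tail P(X >= a) (or <= a for depletion).

    X counts the overlap when a set of size |A| is drawn uniformly from the
    N analytes, |B| of which are 'successes'.
    """
    if alternative == "greater":
        return float(stats.hypergeom.sf(t.a - 1, t.N, t.n_B, t.n_A))
    if alternative == "less":
        return float(stats.hypergeom.cdf(t.a, t.N, t.n_B, t.n_A))
    raise ValueError("alternative must be 'greater' or 'less'")


def sample_uniform_subsets(
    N: int, k: int, m: int, rng: np.random.Generator
) -> np.ndarray:
    """``m`` uniform k-subsets of range(N), as an (m, k) index array.

    This is the null sampler behind :func:`permutation_overlap_p`, exposed
    so the identical draws can be checked against the exact tail.
    """
    if k == 0:
        return np.empty((m, 0), dtype=np.int64)
    r = rng.random((m, N))
    return np.argpartition(r, k - 1, axis=1)[:, :k]


def sample_null_overlaps(
    N: int, k_A: int, b_mask: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Overlap sizes of ``n_perm`` uniform k_A-subsets of range(N) with B.

    ``b_mask`` is a boolean vector of length N marking B's positions.
    """
    out = np.empty(n_perm, dtype=np.int64)
    chunk = max(1, min(n_perm, int(4e6 // max(N, 1)) or 1))
    pos = 0
    while pos < n_perm:
        m = min(chunk, n_perm - pos)
        idx = sample_uniform_subsets(N, k_A, m, rng)
        out[pos : pos + m] = b_mask[idx].sum(axis=1)
        pos += m
    return out


def permutation_overlap_p(
    A,
    B,
    universe: Iterable[str],
    n_perm: int = 10_000,
    seed: int = 0,
    alternative: str = "greater",
    resample: str = "A",
) -> float:
    """Permutation p-value for the overlap of A and B in the universe.

    Redraws a set the size of A uniformly from the universe ``n_perm``
    times holding B fixed (``resample="both"`` redraws both sets), and
    applies the add-one estimator p = (1 + #{overlap >= a}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    U = sorted(frozenset(universe))
    N = len(U)
    t = overlap_counts(A, B, U)
    pos = {u: i for i, u in enumerate(U)}
    rng = np.random.default_rng(seed)
    if resample == "A":
        b_mask = np.zeros(N, dtype=bool)
        b_mask[[pos[x] for x in _as_set(B)]] = True
        ov = sample_null_overlaps(N, t.n_A, b_mask, n_perm, rng)
    elif resample == "both":
        # equivalent null; redraw both sets independently each round
        ov = np.empty(n_perm, dtype=np.int64)
        for i in range(n_perm):
            a_idx = rng.choice(N, size=t.n_A, replace=False)
            mask = np.zeros(N, dtype=bool)
            mask[rng.choice(N, size=t.n_B, replace=False)] = True
            ov[i] = mask[a_idx].sum()
    else:
        raise ValueError("resample must be 'A' or 'both'")
    if alternative == "greater":
        hits = int((ov >= t.a).sum())
    elif alternative == "less":
        hits = int((ov <= t.a).sum())
    else:
        raise ValueError("alternative must be 'greater' or 'less'")
    return (1 + hits) / (n_perm + 1)


def odds_ratio_and_jaccard(t: ContingencyTable) -> tuple[float, float]:
    """Odds ratio (Haldane–Anscombe +0.5 when any cell is zero) and Jaccard."""
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    odds = (a * d) / (b * c)
    union = t.a + t.b + t.c
    jaccard = t.a / union if union else 0.0
    return float(odds), float(jaccard)


def background_agreement_prob(
    tableA: DifferentialTable, tableB: DifferentialTable, universe: Iterable[str]
) -> float:
    """Null probability that two analytes' fold-change signs agree.

    p0 = uA*uB + (1-uA)(1-uB) with uX the proportion of universe analytes
    with log2fc > 0 in table X; zero or missing fold changes are excluded
    from numerator and denominator.  Analytes of the universe absent from a
    table are simply not counted for that table.
    """
    U = frozenset(universe)
    if not U:
        raise ValueError("universe is empty")
    props = []
    for table in (tableA, tableB):
        df = table.data
        in_u = df["analyte_id"].isin(U)
        lfc = df.loc[in_u, "log2fc"].to_numpy(dtype=float)
        lfc = lfc[np.isfinite(lfc) & (lfc != 0)]
        if lfc.size == 0:
            raise ValueError(
                f"no nonzero fold changes within the universe for condition "
                f"{table.condition.label}"
            )
        props.append(float((lfc > 0).mean()))
    uA, uB = props
    return uA * uB + (1 - uA) * (1 - uB)


def directional_concordance(A: SignatureSet, B: SignatureSet, p0: float) -> ConcordanceResult:
    """Exact binomial upper-tail test of sign agreement on A ∩ B.

    k_agree counts overlapping analytes whose directions match;
    p_binom = P(X >= k_agree) for X ~ Binomial(|A∩B|, p0).  Empty overlap
    yields p_binom = 1.
    """
    if not 0 <= p0 <= 1:
        raise ValueError("p0 must lie in [0, 1]")
    shared = A.members & B.members
    n = len(shared)
    k = sum(1 for x in shared if A.directions[x] == B.directions[x])
    if n == 0:
        return ConcordanceResult(0, 0, p0, 1.0)
    p = float(stats.binom.sf(k - 1, n, p0))
    return ConcordanceResult(n, k, p0, p)


def compare_signatures(
    A: SignatureSet,
    B: SignatureSet,
    universe: Iterable[str],
    n_perm: int = 10_000,
    seed: int = 0,
    alternative: str = "greater",
) -> OverlapResult:
    """Full overlap summary: 2x2 counts, exact tail, permutation tail, OR, Jaccard."""
    U = sorted(frozenset(universe))
    t = overlap_counts(A, B, U)
    odds, jac = odds_ratio_and_jaccard(t)
    p_perm = permutation_overlap_p(A, B, U, n_perm=n_perm, seed=seed, alternative=alternative)
    return OverlapResult(
        contingency=t,
        p_hyper=hypergeometric_p(t, alternative=alternative),
        odds_ratio=odds,
        jaccard=jac,
        p_perm=p_perm,
        n_perm=n_perm,
        seed=seed,
    )
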