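"""Exact overlap testing between two gene sets.

The question: given a universe of N genes, a set A of K genes (e.g. predicted
miR targets) and a set B of n genes (e.g. curated disease genes), is an
observed overlap of k genes larger than chance?  The upper-tail hypergeometric
probability P(X >= k) answers it exactly; the one-sided Fisher exact test on
the corresponding 2x2 table is the identical quantity.

The universe size is never knowable from the sets themselves; the default of
19,000 approximates the annotated human protein-coding gene count and every
report prints the universe actually used.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .io import GeneSet

logger = logging.getLogger(__name__)

DEFAULT_UNIVERSE = 19_000


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    X counts the overlap when n genes are drawn without replacement from a
    universe of N containing K marked genes.
    """
    if N < 1:
        raise ValueError("universe size N must be >= 1")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N; got N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fisher_exact_2x2(a: int, b: int, c: int, d: int,
                     alternative: str = "two-sided") -> tuple:
    """Conditional odds ratio and exact p for the 2x2 table ((a,b),(c,d)).

    The two-sided p sums all tables with the observed margins whose
    probability is <= that of the observed table; ``alternative="greater"``
    gives the upper tail, which on an overlap-layout table equals the
    hypergeometric tail test.  With a zero margin the odds ratio follows the
    0/inf convention while p stays finite.
    """
    counts = (a, b, c, d)
    if any((not float(x).is_integer()) or x < 0 for x in counts):
        raise ValueError("contingency counts must be non-negative integers")
    a, b, c, d = (int(x) for x in counts)
    table = [[a, b], [c, d]]
    p = float(stats.fisher_exact(table, alternative=alternative)[1])
    if b * c == 0 and a * d > 0:
        oratio = math.inf
    elif a * d == 0 and b * c > 0:
        oratio = 0.0
    elif a * d == 0 and b * c == 0:
        oratio = math.nan
    else:
        oratio = float(_odds_ratio(table, kind="conditional").statistic)
    return oratio, p


@dataclass(frozen=True)
class OverlapTestResult:
    """Hypergeometric overlap test between two gene sets in a universe."""

    N: int
    K: int
    n: int
    k: int
    p_upper: float
    expected: float
    fold_enrichment: float
    overlap_genes: tuple

    def to_dict(self) -> dict:
        return {
            "universe_size": self.N,
            "set_a_size": self.K,
            "set_b_size": self.n,
            "overlap": self.k,
            "p_upper": self.p_upper,
            "expected_overlap": self.expected,
            "fold_enrichment": self.fold_enrichment,
            "overlap_genes": list(self.overlap_genes),
        }


def overlap_summary(set_a: GeneSet, set_b: GeneSet, universe=DEFAULT_UNIVERSE) -> OverlapTestResult:
    """Hypergeometric overlap test of two gene sets.

    ``universe`` is either an integer size or a :class:`GeneSet`; in the
    latter case members of A or B outside the universe are dropped with a
    warning (heterogeneous source lists routinely stray outside any fixed
    annotation).
    """
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("both gene sets must be non-empty")
    genes_a, genes_b = set_a.genes, set_b.genes
    if isinstance(universe, GeneSet):
        N = len(universe)
        stray = sorted((genes_a | genes_b) - universe.genes)
        if stray:
            logger.warning("%d genes outside the universe dropped: %s", len(stray), stray[:10])
            genes_a = genes_a & universe.genes
            genes_b = genes_b & universe.genes
        if not genes_a or not genes_b:
            raise ValueError("a gene set is empty after restricting to the universe")
    else:
        N = int(universe)
    K, n = len(genes_a), len(genes_b)
    if K > N or n > N:
        raise ValueError(f"set sizes ({K}, {n}) exceed the universe ({N})")
    overlap = sorted(genes_a & genes_b)
    k = len(overlap)
    expected = K * n / N
    return OverlapTestResult(
        N=N, K=K, n=n, k=k,
        p_upper=hypergeometric_tail(N, K, n, k),
        expected=expected,
        fold_enrichment=(k / expected) if expected > 0 else math.nan,
        overlap_genes=tuple(overlap),
    )
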