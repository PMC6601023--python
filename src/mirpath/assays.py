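"""Statistics for functional assay readouts.

Covers comparative-Ct (delta-delta-Ct) relative quantification of qPCR data,
scratch-wound closure percentages, collagen-gel contraction ratios, and the
small-sample comparison tests such readouts call for: exact Mann-Whitney U and
Wilcoxon signed-rank by full enumeration at small n, and Student/Welch t-tests
(including a summary-statistic mode working from printed means, SEMs and n).

The delta-delta-Ct method assumes amplification efficiency exactly 2, so one
cycle of Ct difference corresponds to a two-fold expression difference and
relative expression = 2^(-ddCt).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import CtTable

EXACT_MW_MAX_TOTAL = 12   # exact enumeration of C(nx+ny, nx) assignments up to here
EXACT_WILCOXON_MAX_N = 15  # exact enumeration of 2^n sign patterns up to here


# ---------------------------------------------------------------------------
# Relative quantification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RelativeQuantResult:
    """Comparative-Ct quantification of case vs control expression."""

    delta_ct_case: float
    delta_ct_control: float
    delta_delta_ct: float
    rel_expression: float

    def to_dict(self) -> dict:
        return {
            "delta_ct_case": self.delta_ct_case,
            "delta_ct_control": self.delta_ct_control,
            "delta_delta_ct": self.delta_delta_ct,
            "rel_expression": self.rel_expression,
        }


def delta_delta_ct(table: CtTable) -> RelativeQuantResult:
    """Relative expression of case vs control by the comparative-Ct method.

    Replicates are averaged per sample first; dCt = mean over samples of
    (target Ct - reference Ct) per group; ddCt = dCt(case) - dCt(control);
    relative expression = 2^(-ddCt).  A positive ddCt therefore means lower
    expression in cases.
    """
    df = table.data
    if df["reference_ct"].isna().any():
        raise ValueError("missing reference Ct values")
    groups = set(df["group"])
    if groups != {"case", "control"}:
        raise ValueError(f"both case and control groups are required; got {sorted(groups)}")
    per_sample = df.groupby(["group", "sample_id"], sort=True).agg(
        target=("target_ct", "mean"), reference=("reference_ct", "mean"))
    dct = (per_sample["target"] - per_sample["reference"]).groupby(level="group").mean()
    ddct = float(dct["case"] - dct["control"])
    return RelativeQuantResult(
        delta_ct_case=float(dct["case"]),
        delta_ct_control=float(dct["control"]),
        delta_delta_ct=ddct,
        rel_expression=2.0 ** (-ddct),
    )


# ---------------------------------------------------------------------------
# Geometry-based readouts
# ---------------------------------------------------------------------------


def wound_closure_percent(initial_breadth: float, remaining_breadth: float) -> float:
    """Percent of a scratch wound closed: (initial - remaining)/initial * 100.

    Unit-free (mm and pixels give the same percentage).  A remaining breadth
    larger than the initial one is rejected: the closure metric cannot
    describe a growing wound, report the raw breadths instead.
    """
    if initial_breadth <= 0:
        raise ValueError("initial breadth must be > 0")
    if remaining_breadth < 0:
        raise ValueError("remaining breadth must be >= 0")
    if remaining_breadth > initial_breadth:
        raise ValueError("remaining breadth exceeds initial breadth")
    return (initial_breadth - remaining_breadth) / initial_breadth * 100.0


def gel_contraction_ratio(diameter_treated: float, diameter_control: float) -> float:
    """Relative collagen-gel diameter, treated over control.

    A ratio above 1 means the treated gel contracted less than the control.
    """
    if diameter_treated <= 0 or diameter_control <= 0:
        raise ValueError("gel diameters must be > 0")
    return diameter_treated / diameter_control


# ---------------------------------------------------------------------------
# Exact rank tests
# ---------------------------------------------------------------------------


def _two_sided_from_distribution(values: np.ndarray, observed: float, mu: float) -> float:
    """P(|V - mu| >= |observed - mu|) over an enumerated null distribution."""
    return float(np.mean(np.abs(values - mu) >= abs(observed - mu) - 1e-12))


def mann_whitney_exact(group_x, group_y) -> tuple:
    """Mann-Whitney U with an exact two-sided p at small n.

    Midranks handle ties.  When nx + ny <= 12 the p-value enumerates all
    C(nx+ny, nx) group assignments and counts those with |U - nx*ny/2| at
    least as extreme as observed; larger samples fall back to the
    tie-corrected normal approximation.  Returns (U of group_x, p).
    """
    x = np.asarray(group_x, dtype=float)
    y = np.asarray(group_y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 observations")
    nx, ny = x.size, y.size
    ranks = stats.rankdata(np.concatenate([x, y]), method="average")
    u_obs = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    if nx + ny <= EXACT_MW_MAX_TOTAL:
        mu = nx * ny / 2.0
        u_all = np.array([
            ranks[list(idx)].sum() - nx * (nx + 1) / 2.0
            for idx in itertools.combinations(range(nx + ny), nx)
        ])
        p = _two_sided_from_distribution(u_all, u_obs, mu)
    else:
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)
    return u_obs, p


def wilcoxon_signed_exact(paired_differences) -> tuple:
    """Wilcoxon signed-rank W+ with an exact two-sided p at small n.

    Zero differences are dropped (standard convention).  For n <= 15 nonzero
    differences the p-value enumerates all 2^n sign assignments of the
    midranked |d|; larger n uses the normal approximation.  Returns (W+, p).
    """
    d = np.asarray(paired_differences, dtype=float)
    if d.size and np.all(d == 0):
        raise ValueError("all differences are zero; the test is undefined")
    d = d[d != 0]
    n = d.size
    if n < 3:
        raise ValueError("need >= 3 nonzero differences")
    ranks = stats.rankdata(np.abs(d), method="average")
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        mu = n * (n + 1) / 4.0
        totals = np.zeros(1)
        for r in ranks:  # convolve sign choices one rank at a time: 2^n totals
            totals = np.concatenate([totals, totals + r])
        p = _two_sided_from_distribution(totals, w_plus, mu)
    else:
        p = float(stats.wilcoxon(d, alternative="two-sided", method="approx").pvalue)
    return w_plus, p


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------


def two_sample_t(group_x, group_y, welch: bool = False) -> tuple:
    """Student (pooled) or Welch two-sample t-test: (t, df, p_two_sided).

    Two zero-variance groups with equal means give (0, df, 1) by convention;
    zero variance with unequal means is degenerate and raises.
    """
    x = np.asarray(group_x, dtype=float)
    y = np.asarray(group_y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            df = x.size + y.size - 2
            return 0.0, float(df), 1.0
        raise ValueError("degenerate variance: zero spread in both groups with unequal means")
    res = stats.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)


def two_sample_t_from_summary(mean_x: float, sem_x: float, n_x: int,
                              mean_y: float, sem_y: float, n_y: int,
                              welch: bool = True) -> tuple:
    """t-test from printed summaries (mean, SEM, n per group): (t, df, p).

    Lets published group summaries be checked without raw measurements.
    Welch: se^2 = sem_x^2 + sem_y^2 with Welch-Satterthwaite df; pooled mode
    reconstructs the pooled variance from the SEMs.
    """
    if n_x < 2 or n_y < 2:
        raise ValueError("each group needs n >= 2")
    if sem_x < 0 or sem_y < 0:
        raise ValueError("SEMs must be >= 0")
    if welch:
        se2 = sem_x**2 + sem_y**2
        if se2 == 0:
            raise ValueError("degenerate variance: both SEMs are zero")
        t = (mean_x - mean_y) / math.sqrt(se2)
        df = se2**2 / (sem_x**4 / (n_x - 1) + sem_y**4 / (n_y - 1))
    else:
        var_x, var_y = sem_x**2 * n_x, sem_y**2 * n_y
        pooled = ((n_x - 1) * var_x + (n_y - 1) * var_y) / (n_x + n_y - 2)
        if pooled == 0:
            raise ValueError("degenerate variance: both SEMs are zero")
        t = (mean_x - mean_y) / math.sqrt(pooled * (1 / n_x + 1 / n_y))
        df = n_x + n_y - 2
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), float(df), p


# ---------------------------------------------------------------------------
# Group comparison wrapper
# ---------------------------------------------------------------------------


TESTS = ("student_t", "welch_t", "mann_whitney_exact", "wilcoxon_signed_exact")


@dataclass(frozen=True)
class AssayComparison:
    """A two-group (or paired) comparison with its summary statistics."""

    mean_x: float
    sem_x: float
    n_x: int
    mean_y: float
    sem_y: float
    n_y: int
    test: str
    statistic: float
    p_two_sided: float

    def to_dict(self) -> dict:
        return {
            "group_x": {"mean": self.mean_x, "sem": self.sem_x, "n": self.n_x},
            "group_y": {"mean": self.mean_y, "sem": self.sem_y, "n": self.n_y},
            "test": self.test,
            "statistic": self.statistic,
            "p_two_sided": self.p_two_sided,
        }


def compare_groups(group_x, group_y, test: str = "mann_whitney_exact") -> AssayComparison:
    """Compare two measurement vectors with the named test.

    ``wilcoxon_signed_exact`` treats the groups as paired (element-wise
    differences) and requires equal lengths.
    """
    x = np.asarray(group_x, dtype=float)
    y = np.asarray(group_y, dtype=float)
    if test == "student_t":
        t, _, p = two_sample_t(x, y, welch=False)
        statistic = t
    elif test == "welch_t":
        t, _, p = two_sample_t(x, y, welch=True)
        statistic = t
    elif test == "mann_whitney_exact":
        statistic, p = mann_whitney_exact(x, y)
    elif test == "wilcoxon_signed_exact":
        if x.size != y.size:
            raise ValueError("paired test needs equal-length groups")
        statistic, p = wilcoxon_signed_exact(x - y)
    else:
        raise ValueError(f"unknown test {test!r}; choose from {TESTS}")

    def sem(a):
        return float(a.std(ddof=1) / math.sqrt(a.size)) if a.size > 1 else 0.0

    return AssayComparison(
        mean_x=float(x.mean()), sem_x=sem(x), n_x=int(x.size),
        mean_y=float(y.mean()), sem_y=sem(y), n_y=int(y.size),
        test=test, statistic=float(statistic), p_two_sided=float(p),
    )
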