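"""Paired differential-expression screen.

Fold changes are computed on the linear intensity scale as the geometric mean
of per-pair case/control ratios and reported as a magnitude >= 1 plus a
direction, the convention of miR microarray reports (a miR suppressed to 0.21x
is printed as magnitude 4.79, direction down).  Significance comes from a
paired t-test on per-pair log2 differences, with Benjamini-Hochberg FDR
adjustment across features.  Hierarchical clustering of selected features uses
complete linkage with Euclidean distance.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .io import PairedExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DifferentialExpressionResult:
    """One feature's screen row: magnitude-with-direction FC and paired-t p."""

    feature_id: str
    fc_magnitude: float
    direction: str
    fc_sd: float
    p_raw: float
    q_bh: float = float("nan")


def _log2_pair_diffs(matrix: PairedExpressionMatrix, feature: str) -> np.ndarray:
    """Per-subject log2(case/control) for one feature."""
    if feature not in matrix.values.index:
        raise KeyError(f"feature {feature!r} not in matrix")
    case = matrix.case_matrix().loc[feature].to_numpy(dtype=float)
    ctrl = matrix.control_matrix().loc[feature].to_numpy(dtype=float)
    if matrix.log2_scale:
        return case - ctrl
    if (case <= 0).any() or (ctrl <= 0).any():
        raise ValueError(f"non-positive linear intensity for feature {feature!r}")
    return np.log2(case) - np.log2(ctrl)


def paired_fold_change(matrix: PairedExpressionMatrix, feature: str) -> tuple:
    """(fc_magnitude, direction, fc_sd) for one feature.

    The mean ratio is the geometric mean of per-pair case/control ratios;
    magnitude is max(r, 1/r); ``fc_sd`` is the sample standard deviation of
    per-pair magnitudes oriented by the overall direction.
    """
    d = _log2_pair_diffs(matrix, feature)
    if d.size < 2:
        raise ValueError("insufficient pairs: need >= 2 subject pairs")
    mean_log2 = float(d.mean())
    r_geo = 2.0 ** mean_log2
    direction = "up" if r_geo > 1.0 else "down"
    magnitude = max(r_geo, 1.0 / r_geo)
    oriented = 2.0 ** (d if direction == "up" else -d)
    fc_sd = float(oriented.std(ddof=1))
    return magnitude, direction, fc_sd


def paired_t_test(matrix: PairedExpressionMatrix, feature: str) -> tuple:
    """Paired t-test on per-pair log2 differences: (t, df, p_two_sided).

    All-zero differences give (0, df, 1).  Identical nonzero differences have
    zero variance, so t and p are undefined; NaN is returned with a warning
    rather than a silent 0.
    """
    d = _log2_pair_diffs(matrix, feature)
    if d.size < 2:
        raise ValueError("insufficient pairs: need >= 2 subject pairs")
    df = d.size - 1
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.allclose(d, 0.0):
            return 0.0, df, 1.0
        warnings.warn(
            f"feature {feature!r}: zero variance of nonzero differences; p undefined",
            RuntimeWarning,
        )
        return float("nan"), df, float("nan")
    t = float(d.mean() / (sd / math.sqrt(d.size)))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, df, p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order, capped at 1.
    NaN entries propagate and are excluded from m.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m:
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
        q = np.empty(m)
        q[order] = q_sorted
        out[ok] = q
    return out


def differential_expression(matrix: PairedExpressionMatrix) -> pd.DataFrame:
    """Full screen table: feature_id, fc, fc_sd, direction, t, p_raw, q_bh.

    Vectorized over features; row semantics match :func:`paired_fold_change`
    and :func:`paired_t_test`.
    """
    case = matrix.case_matrix().to_numpy(dtype=float)
    ctrl = matrix.control_matrix().to_numpy(dtype=float)
    if not matrix.log2_scale:
        if (case <= 0).any() or (ctrl <= 0).any():
            raise ValueError("non-positive linear intensities")
        case, ctrl = np.log2(case), np.log2(ctrl)
    d = case - ctrl
    n = d.shape[1]
    if n < 2:
        raise ValueError("insufficient pairs: need >= 2 subject pairs")
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    r_geo = 2.0 ** mean
    up = r_geo > 1.0
    magnitude = np.where(up, r_geo, 1.0 / r_geo)
    oriented = np.where(up[:, None], d, -d)
    fc_sd = (2.0 ** oriented).std(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    zero_sd = sd == 0.0
    null_rows = zero_sd & np.isclose(mean, 0.0)
    t = np.where(null_rows, 0.0, t)
    p = np.where(null_rows, 1.0, p)
    degenerate = zero_sd & ~null_rows
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} features with zero-variance nonzero differences; p set to NaN",
            RuntimeWarning,
        )
        t = np.where(degenerate, np.nan, t)
        p = np.where(degenerate, np.nan, p)

    return pd.DataFrame({
        "feature_id": matrix.feature_ids,
        "fc": magnitude,
        "fc_sd": fc_sd,
        "direction": np.where(up, "up", "down"),
        "t": t,
        "p_raw": p,
        "q_bh": bh_adjust(p),
    })


def filter_by_fc(results: pd.DataFrame, cutoff: float, alpha: float | None = None) -> tuple:
    """Keep features with fc >= cutoff (inclusive) and, if given, p_raw < alpha.

    Returns (filtered table, count).  The raw-FC mode mirrors a first-pass
    screen; adding ``alpha`` mirrors a significance-filtered report.
    """
    if cutoff <= 1:
        raise ValueError("cutoff must be > 1")
    keep = results["fc"] >= cutoff
    if alpha is not None:
        keep &= results["p_raw"] < alpha
    filtered = results.loc[keep].reset_index(drop=True)
    return filtered, int(keep.sum())


def cluster_features(matrix: PairedExpressionMatrix, features) -> tuple:
    """Complete-linkage Euclidean clustering of feature sample-vectors.

    Features are processed in lexicographic id order so ties break
    deterministically.  Returns (linkage matrix in scipy format, leaf order as
    feature ids).
    """
    features = sorted(dict.fromkeys(features))
    if len(features) < 2:
        raise ValueError("need >= 2 features to cluster")
    missing = [f for f in features if f not in matrix.values.index]
    if missing:
        raise KeyError(f"features not in matrix: {missing}")
    X = matrix.values.loc[features].to_numpy(dtype=float)
    Z = hierarchy.linkage(X, method="complete", metric="euclidean")
    leaves = [features[i] for i in hierarchy.leaves_list(Z)]
    return Z, leaves
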