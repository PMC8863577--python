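"""Nonparametric testing and effect sizes.

Every downstream stage of the pipeline quantifies a two-group contrast
with the same pair of statistics: a two-sided Mann-Whitney U test for
significance and Cliff's delta for a directional standardized effect
size, with Benjamini-Hochberg adjustment across the feature family of
each comparison.  Ordinal/continuous associations use tie-aware Spearman
correlation.

Sign convention: delta > 0 means the feature tends *larger in the second
named group* — comparisons are always written control:case, so positive
deltas mean enrichment in the later disease stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import CohortMatrix, SubjectMetadata, ValidationError

__all__ = [
    "PairwiseResult",
    "cliffs_delta",
    "mwu_test",
    "bh_adjust",
    "spearman_assoc",
    "compare_groups",
]

#: product |x|*|y| at or below which the exact MWU null is enumerated
EXACT_LIMIT = 400


@dataclass
class PairwiseResult:
    feature_id: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    cliffs_delta: float
    p_mwu: float
    q_bh: float
    significant: bool
    skipped: bool = False


def _as_1d(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float).ravel()
    if arr.size == 0:
        raise ValidationError(f"{name}: empty sample")
    return arr[~np.isnan(arr)] if np.isnan(arr).any() else arr


def cliffs_delta(x, y) -> float:
    """Cliff's delta of ``y`` relative to ``x``.

    Returns ``(#{y_j > x_i} - #{y_j < x_i}) / (|x| |y|)`` in [-1, 1];
    positive values mean the second sample tends larger.  Computed from
    midranks in O((n+m) log(n+m)); equals ``2*AUC - 1`` where AUC is the
    two-sample concordance probability with half credit for ties.
    """
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if x.size == 0 or y.size == 0:
        raise ValidationError("cliffs_delta: empty sample after NaN removal")
    n, m = x.size, y.size
    ranks = sps.rankdata(np.concatenate([x, y]))
    # rank-sum of y minus its minimum gives #{y>x} pairs with tie half-credit
    u_y = ranks[n:].sum() - m * (m + 1) / 2.0
    return float(2.0 * u_y / (n * m) - 1.0)


def mwu_test(x, y) -> float:
    """Two-sided Mann-Whitney U p-value.

    Uses exact null enumeration when ``|x|*|y| <= 400`` and there are no
    cross-sample ties, otherwise the tie-corrected normal approximation
    with continuity correction.  Degenerate all-tied input returns 1.
    """
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if x.size < 2 or y.size < 2:
        raise ValidationError("mwu_test: need at least 2 observations per sample")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if x.size * y.size <= EXACT_LIMIT and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if np.isnan(p):  # zero variance under heavy ties
        return 1.0
    return min(p, 1.0)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValidationError("bh_adjust: p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def spearman_assoc(x, y) -> tuple[float, float]:
    """Tie-aware Spearman rho and two-sided p.

    A constant input vector leaves rho undefined; it is returned as NaN
    with p = 1 so the association is treated as non-significant.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValidationError("spearman_assoc: need equal-length samples, n >= 3")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), 1.0
    rho, p = sps.spearmanr(x, y)
    if np.isnan(rho):
        return float("nan"), 1.0
    return float(rho), float(p)


def _vectorized_mwu(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """MWU p and Cliff's delta for every column of subjects-by-features
    blocks ``a`` (group A) and ``b`` (group B); no NaN allowed."""
    n, m = a.shape[0], b.shape[0]
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", axis=0)
    u1 = np.asarray(res.statistic, dtype=float)  # counts a>b (+ tie half-credit)
    delta = 1.0 - 2.0 * u1 / (n * m)
    p = np.asarray(res.pvalue, dtype=float)
    # all-tied columns have zero variance; define p = 1 there
    pooled = np.vstack([a, b])
    degenerate = (pooled == pooled[0]).all(axis=0)
    p = np.where(degenerate, 1.0, p)
    return np.minimum(np.nan_to_num(p, nan=1.0), 1.0), delta


def compare_groups(
    matrix: CohortMatrix,
    metadata: SubjectMetadata,
    group_a: str,
    group_b: str,
    fdr_threshold: float = 0.1,
    min_fraction: float = 0.5,
    pooled_family: bool = False,
) -> pd.DataFrame:
    """Per-feature MWU + Cliff's delta for one group comparison.

    BH adjustment is applied within this comparison, separately inside
    each feature-kind family (taxa, modules, serum metabolites, urine
    metabolites) by default; set ``pooled_family=True`` to pool all
    features into one family.  Features with fewer than ``min_fraction``
    non-missing subjects in either group are skipped and flagged.

    Returns a DataFrame indexed by feature ID with columns
    ``group_a, group_b, n_a, n_b, delta, p, q, significant, skipped``.
    """
    ids_a = metadata.subjects_in(group_a).intersection(matrix.subjects)
    ids_b = metadata.subjects_in(group_b).intersection(matrix.subjects)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValidationError(
            f"comparison {group_a}:{group_b} needs >= 2 subjects per group"
        )
    sub_a = matrix.values.loc[ids_a]
    sub_b = matrix.values.loc[ids_b]
    feats = matrix.features
    n_feat = len(feats)

    delta = np.full(n_feat, np.nan)
    p = np.full(n_feat, np.nan)
    skipped = np.zeros(n_feat, dtype=bool)

    a_arr = sub_a.to_numpy(dtype=float)
    b_arr = sub_b.to_numpy(dtype=float)
    frac_a = 1.0 - np.isnan(a_arr).mean(axis=0)
    frac_b = 1.0 - np.isnan(b_arr).mean(axis=0)
    skipped = (frac_a < min_fraction) | (frac_b < min_fraction)

    clean = ~(np.isnan(a_arr).any(axis=0) | np.isnan(b_arr).any(axis=0))
    use_vec = clean & ~skipped
    small = a_arr.shape[0] * b_arr.shape[0] <= EXACT_LIMIT
    if use_vec.any() and not small:
        p[use_vec], delta[use_vec] = _vectorized_mwu(
            a_arr[:, use_vec], b_arr[:, use_vec]
        )
    elif use_vec.any():
        for j in np.flatnonzero(use_vec):
            delta[j] = cliffs_delta(a_arr[:, j], b_arr[:, j])
            p[j] = mwu_test(a_arr[:, j], b_arr[:, j])
    # columns with scattered NaN: pairwise-complete per feature
    rest = ~clean & ~skipped
    for j in np.flatnonzero(rest):
        xa = a_arr[:, j][~np.isnan(a_arr[:, j])]
        xb = b_arr[:, j][~np.isnan(b_arr[:, j])]
        delta[j] = cliffs_delta(xa, xb)
        p[j] = mwu_test(xa, xb)

    q = np.full(n_feat, np.nan)
    if pooled_family:
        families = pd.Series("all", index=feats)
    else:
        families = matrix.kinds
    for _, members in families.groupby(families):
        idx = feats.get_indexer(members.index)
        idx = idx[~skipped[idx]]
        if len(idx):
            q[idx] = bh_adjust(p[idx])

    out = pd.DataFrame(
        {
            "group_a": group_a,
            "group_b": group_b,
            "n_a": len(ids_a),
            "n_b": len(ids_b),
            "delta": delta,
            "p": p,
            "q": q,
            "significant": (q <= fdr_threshold) & ~skipped,
            "skipped": skipped,
        },
        index=feats,
    )
    out.index.name = "feature_id"
    return out
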