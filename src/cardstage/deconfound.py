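"""Post hoc covariate deconfounding of feature-disease associations.

For every feature significantly associated with disease status in a
two-group comparison, this module asks whether the association can be
reduced to a treatment or host covariate (drug indicators or dosages,
age, BMI, smoking).  The procedure has two steps:

1. *Naive associations.*  Each feature is tested nonparametrically
   against disease status and against every covariate (Mann-Whitney for
   binary variables, Spearman otherwise), BH-adjusted per variable
   across features.

2. *Nested-model likelihood-ratio tests.*  For each covariate B that is
   itself associated with the feature X, an OLS fit of (rank-transformed)
   X on {A, B} is compared against {B} alone — the *forward* test: does
   disease status A add explanatory power beyond B?  If the forward test
   passes (LRT p < 0.05) for every such covariate, the disease signal is
   confidently deconfounded (CD).  Where it fails, the *reverse* test
   ({A, B} vs {A}) asks whether B adds power beyond A: if it does, the
   feature is confounded by B; if neither direction is reducible, the
   two are entangled and the verdict is laxly deconfounded (LD).

Features with no significantly associated covariate are trivially not
confounded (NC); features not associated with status are skipped
(NOT_SIGNIFICANT).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import CohortMatrix, SubjectMetadata, ValidationError
from .stats import bh_adjust, cliffs_delta, mwu_test, spearman_assoc

__all__ = [
    "STATUSES",
    "ConfoundingVerdict",
    "naive_associations",
    "lrt_nested",
    "confounding_status",
    "run_deconfounding",
]

STATUSES = ("NC", "CD", "LD", "CONFOUNDED", "NOT_SIGNIFICANT")

#: verdicts that keep a feature eligible for stage categorization
DECONFOUNDED = ("NC", "CD")

MIN_OBSERVATIONS = 10


@dataclass
class ConfoundingVerdict:
    feature_id: str
    comparison: str
    status: str
    confounders: list[str] = field(default_factory=list)
    naive_q: float = float("nan")
    evidence: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValidationError(f"unknown confounding status {self.status!r}")
        if self.status == "CONFOUNDED" and not self.confounders:
            raise ValidationError("CONFOUNDED verdict must name >= 1 covariate")

    @property
    def worst_forward_p(self) -> float:
        ps = [e["forward_p"] for e in self.evidence.values() if "forward_p" in e]
        return max(ps) if ps else float("nan")

    @property
    def best_reverse_p(self) -> float:
        ps = [e["reverse_p"] for e in self.evidence.values() if "reverse_p" in e]
        return min(ps) if ps else float("nan")


def _split_comparison(comparison: str) -> tuple[str, str]:
    try:
        a, b = comparison.split(":")
    except ValueError as exc:
        raise ValidationError(f"comparison must be 'A:B', got {comparison!r}") from exc
    return a, b


def _spearman_block(m: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Tie-aware Spearman rho and two-sided p of every column of ``m``
    against ``y`` (no NaN)."""
    n = m.shape[0]
    rx = sps.rankdata(m, axis=0)
    ry = sps.rankdata(y)
    rx = rx - rx.mean(axis=0)
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum(axis=0) * (ry**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rx.T @ ry) / denom
        rho = np.clip(rho, -1.0, 1.0)
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(rho), 1.0, np.minimum(p, 1.0))
    return rho, p


def _mwu_block(m: np.ndarray, indicator: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cliff's delta (positive = larger where indicator == 1) and MWU p
    of every column of ``m`` against a binary indicator."""
    a = m[indicator == 0]
    b = m[indicator == 1]
    n, k = a.shape[0], b.shape[0]
    if n < 2 or k < 2:
        return np.full(m.shape[1], np.nan), np.ones(m.shape[1])
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", axis=0)
    u1 = np.asarray(res.statistic, dtype=float)
    delta = 1.0 - 2.0 * u1 / (n * k)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (m == m[0]).all(axis=0)
    p = np.where(degenerate | np.isnan(p), 1.0, np.minimum(p, 1.0))
    return delta, p


def naive_associations(
    matrix: CohortMatrix,
    metadata: SubjectMetadata,
    comparison: str,
    covariates: list[str] | None = None,
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Feature x independent-variable association table for one comparison.

    Variables are the binary disease status (``status``, 1 = second-named
    group) plus every covariate; binary covariates are tested by MWU,
    continuous/ordinal/dosage ones by Spearman.  BH adjustment is applied
    per variable across features.  Covariates constant within the
    comparison are dropped with a warning.

    Returns a long DataFrame with columns ``feature_id, variable, effect,
    p, q, significant``.
    """
    group_a, group_b = _split_comparison(comparison)
    ids_a = metadata.subjects_in(group_a).intersection(matrix.subjects)
    ids_b = metadata.subjects_in(group_b).intersection(matrix.subjects)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValidationError(f"comparison {comparison}: need >= 2 subjects per group")
    ids = ids_a.append(ids_b)
    status = np.r_[np.zeros(len(ids_a)), np.ones(len(ids_b))]
    sub = matrix.values.loc[ids]
    feats = list(sub.columns)
    m = sub.to_numpy(dtype=float)

    if covariates is None:
        covariates = metadata.covariates
    cov_types = metadata.covariate_types

    records = []

    def run_variable(name: str, vec: np.ndarray, binary: bool) -> None:
        keep = ~np.isnan(vec)
        mm, vv = m[keep], vec[keep]
        col_ok = ~np.isnan(mm).any(axis=0)
        eff = np.full(len(feats), np.nan)
        p = np.ones(len(feats))
        if binary:
            if np.unique(vv).size < 2:
                return
            eff[col_ok], p[col_ok] = _mwu_block(mm[:, col_ok], vv)
        else:
            eff[col_ok], p[col_ok] = _spearman_block(mm[:, col_ok], vv)
        # columns with missing values: pairwise-complete fallback
        for j in np.flatnonzero(~col_ok):
            x = mm[:, j]
            ok = ~np.isnan(x)
            if ok.sum() < MIN_OBSERVATIONS or np.unique(vv[ok]).size < 2:
                continue
            if binary:
                eff[j] = cliffs_delta(x[ok][vv[ok] == 0], x[ok][vv[ok] == 1])
                p[j] = mwu_test(x[ok][vv[ok] == 0], x[ok][vv[ok] == 1])
            else:
                eff[j], p[j] = spearman_assoc(x[ok], vv[ok])
        q = bh_adjust(p)
        for j, f in enumerate(feats):
            records.append(
                {
                    "feature_id": f,
                    "variable": name,
                    "effect": eff[j],
                    "p": p[j],
                    "q": q[j],
                    "significant": bool(q[j] <= fdr),
                }
            )

    run_variable("status", status, binary=True)
    for cov in covariates:
        vec = metadata.table.loc[ids, cov].to_numpy(dtype=float)
        vals = vec[~np.isnan(vec)]
        if np.unique(vals).size < 2:
            warnings.warn(
                f"covariate {cov!r} constant in comparison {comparison}; dropped",
                stacklevel=2,
            )
            continue
        binary = cov_types.get(cov) == "binary" or np.isin(vals, [0, 1]).all()
        run_variable(cov, vec, binary=binary)
    return pd.DataFrame.from_records(records)


def _ols_rss(y: np.ndarray, cols: list[np.ndarray]) -> tuple[float, int]:
    """Residual sum of squares and design rank of an intercept OLS fit."""
    x = np.column_stack([np.ones(y.size)] + cols)
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid), int(rank)


def lrt_nested(
    feature_values,
    primary_var,
    nuisance_var,
    rank_transform: bool = True,
) -> float:
    """Likelihood-ratio p for whether ``primary_var`` adds explanatory
    power for the feature beyond ``nuisance_var``.

    Compares OLS fits of the (rank-transformed by default) feature on
    {primary + nuisance} versus {nuisance} alone; the LR statistic
    ``n log(RSS0/RSS1)`` is referred to chi-squared with df = number of
    added independent columns.  A primary variable perfectly collinear
    with the nuisance adds nothing and yields p = 1.
    """
    y = np.asarray(feature_values, dtype=float).ravel()
    a = np.asarray(primary_var, dtype=float).ravel()
    b = np.asarray(nuisance_var, dtype=float).ravel()
    if not (y.size == a.size == b.size):
        raise ValidationError("lrt_nested: input length mismatch")
    keep = ~(np.isnan(y) | np.isnan(a) | np.isnan(b))
    y, a, b = y[keep], a[keep], b[keep]
    if y.size < MIN_OBSERVATIONS:
        raise ValidationError(
            f"lrt_nested: need >= {MIN_OBSERVATIONS} complete observations"
        )
    if rank_transform:
        y = sps.rankdata(y)
    rss_full, rank_full = _ols_rss(y, [a, b])
    rss_red, rank_red = _ols_rss(y, [b])
    df = rank_full - rank_red
    if df <= 0:
        return 1.0  # collinear: primary adds no independent information
    if rss_red <= 0:
        return 1.0  # reduced model already fits perfectly
    rss_full = max(rss_full, np.finfo(float).tiny)
    lr = y.size * np.log(rss_red / rss_full)
    return float(sps.chi2.sf(lr, df))


def confounding_status(
    feature_values,
    status,
    covariate_values: dict[str, np.ndarray],
    status_q: float,
    covariate_q: dict[str, float],
    feature_id: str = "",
    comparison: str = "",
    fdr: float = 0.1,
    lrt_alpha: float = 0.05,
    rank_transform: bool = True,
) -> ConfoundingVerdict:
    """Apply the deconfounding decision tree to one feature-comparison pair.

    ``status_q`` and ``covariate_q`` are the BH-adjusted naive
    association q-values from :func:`naive_associations`.
    """
    evidence: dict[str, dict[str, float]] = {
        c: {"naive_q": float(q)} for c, q in covariate_q.items()
    }
    if not (status_q <= fdr):
        return ConfoundingVerdict(
            feature_id, comparison, "NOT_SIGNIFICANT", naive_q=status_q, evidence=evidence
        )
    sig_covs = [c for c, q in covariate_q.items() if q <= fdr]
    if not sig_covs:
        return ConfoundingVerdict(
            feature_id, comparison, "NC", naive_q=status_q, evidence=evidence
        )
    failing = []
    for cov in sig_covs:
        p_fwd = lrt_nested(
            feature_values, status, covariate_values[cov], rank_transform=rank_transform
        )
        evidence[cov]["forward_p"] = p_fwd
        if not (p_fwd < lrt_alpha):
            failing.append(cov)
    if not failing:
        return ConfoundingVerdict(
            feature_id, comparison, "CD", naive_q=status_q, evidence=evidence
        )
    confounders = []
    for cov in failing:
        p_rev = lrt_nested(
            feature_values, covariate_values[cov], status, rank_transform=rank_transform
        )
        evidence[cov]["reverse_p"] = p_rev
        if p_rev < lrt_alpha:
            confounders.append(cov)
    if confounders:
        return ConfoundingVerdict(
            feature_id,
            comparison,
            "CONFOUNDED",
            confounders=confounders,
            naive_q=status_q,
            evidence=evidence,
        )
    return ConfoundingVerdict(
        feature_id, comparison, "LD", naive_q=status_q, evidence=evidence
    )


def run_deconfounding(
    matrix: CohortMatrix,
    metadata: SubjectMetadata,
    comparisons,
    covariates: list[str] | None = None,
    fdr: float = 0.1,
    lrt_alpha: float = 0.05,
    rank_transform: bool = True,
) -> pd.DataFrame:
    """Deconfounding verdicts for every feature x comparison pair.

    Returns a DataFrame with columns ``feature_id, comparison, status,
    confounders`` (semicolon-joined), ``naive_q, worst_forward_p,
    best_reverse_p``.  Deterministic given its inputs.
    """
    if covariates is None:
        covariates = metadata.covariates
    rows = []
    for comparison in comparisons:
        group_a, group_b = _split_comparison(comparison)
        ids_a = metadata.subjects_in(group_a).intersection(matrix.subjects)
        ids_b = metadata.subjects_in(group_b).intersection(matrix.subjects)
        ids = ids_a.append(ids_b)
        status = np.r_[np.zeros(len(ids_a)), np.ones(len(ids_b))]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assoc = naive_associations(matrix, metadata, comparison, covariates, fdr)
        qtab = assoc.pivot(index="feature_id", columns="variable", values="q")
        present_covs = [c for c in covariates if c in qtab.columns]
        cov_vals = {
            c: metadata.table.loc[ids, c].to_numpy(dtype=float) for c in present_covs
        }
        sub = matrix.values.loc[ids]
        for fid in matrix.features:
            status_q = float(qtab.loc[fid, "status"]) if "status" in qtab else 1.0
            if np.isnan(status_q):
                status_q = 1.0
            cov_q = {
                c: (
                    float(qtab.loc[fid, c])
                    if not np.isnan(qtab.loc[fid, c])
                    else 1.0
                )
                for c in present_covs
            }
            verdict = confounding_status(
                sub[fid].to_numpy(dtype=float),
                status,
                cov_vals,
                status_q,
                cov_q,
                feature_id=fid,
                comparison=comparison,
                fdr=fdr,
                lrt_alpha=lrt_alpha,
                rank_transform=rank_transform,
            )
            rows.append(
                {
                    "feature_id": fid,
                    "comparison": comparison,
                    "status": verdict.status,
                    "confounders": ";".join(verdict.confounders),
                    "naive_q": verdict.naive_q,
                    "worst_forward_p": verdict.worst_forward_p,
                    "best_reverse_p": verdict.best_reverse_p,
                }
            )
    return pd.DataFrame.from_records(rows)
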