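"""Disease-spectrum categorization of deconfounded features.

The natural trajectory toward ischemic heart disease is modeled in two
stages: dysmetabolism (HC vs MMC / HC vs UMMC) and overt disease
(MMC vs IHD / UMMC vs IHD).  Each feature's pattern of significant,
non-confounded, direction-aligned shifts across the five group
comparisons assigns it one category:

* **ESCF** — significant at both stages, same direction (escalates with
  disease progression);
* **DSCF** — significant at both stages, opposite direction (reverses in
  treated disease, i.e. stabilization);
* **IHDF** — significant only at the disease stage (IHD-specific);
* **DMF**  — significant only at the dysmetabolism stage (or only versus
  HC, including the HC:IHD span without disease-stage support);
* **UNCLASSIFIED** otherwise.

Escalation/de-escalation take precedence over the single-stage
categories because their defining two-stage pattern also satisfies the
single-stage routes.  A comparison contributes only when its BH q passes
the FDR threshold *and* its deconfounding verdict is in the eligible set
(NC and CD by default; the laxly deconfounded may be admitted by flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    COMPARISONS,
    STAGE1_COMPARISONS,
    STAGE2_COMPARISONS,
    CohortMatrix,
    SubjectMetadata,
    ValidationError,
)

__all__ = [
    "CATEGORIES",
    "FeatureProfile",
    "StageCategory",
    "build_profiles",
    "categorize_feature",
    "categorize_all",
    "subtype_categorize",
]

CATEGORIES = ("DMF", "IHDF", "ESCF", "DSCF", "UNCLASSIFIED")

ELIGIBLE_STATUSES = ("NC", "CD")


@dataclass
class FeatureProfile:
    """Per-feature evidence across the five canonical comparisons.

    ``per_comparison`` maps a comparison to a dict with keys ``delta``,
    ``q``, ``significant`` (q passes FDR), ``status`` (deconfounding
    verdict) and ``fires`` (significant AND status eligible).  Deltas are
    oriented positive = higher in the later disease stage.
    """

    feature_id: str
    per_comparison: dict[str, dict]

    def fires(self, comparison: str) -> bool:
        return bool(self.per_comparison[comparison]["fires"])


@dataclass
class StageCategory:
    feature_id: str
    category: str
    route: list[str] = field(default_factory=list)
    stage1_delta: float = float("nan")
    stage2_delta: float = float("nan")

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")


def build_profiles(
    results: dict[str, pd.DataFrame],
    verdicts: pd.DataFrame | None,
    eligible_statuses=ELIGIBLE_STATUSES,
    fdr_threshold: float = 0.1,
) -> list[FeatureProfile]:
    """Assemble per-feature comparison profiles.

    ``results`` maps each of the five canonical comparisons to the
    output of :func:`cardstage.stats.compare_groups`; ``verdicts`` is the
    table from :func:`cardstage.deconfound.run_deconfounding` (pass
    ``None`` to treat every pair as NC, e.g. for covariate-free runs).
    A comparison *fires* for a feature when its q passes the threshold
    and its deconfounding status is eligible.
    """
    missing = [c for c in COMPARISONS if c not in results]
    if missing:
        raise ValidationError(f"missing comparisons: {missing}")
    feats = results[COMPARISONS[0]].index
    for comp in COMPARISONS:
        extra = feats.symmetric_difference(results[comp].index)
        if len(extra):
            raise ValidationError(
                f"comparison {comp}: feature set mismatch ({list(extra[:5])})"
            )
    if verdicts is not None:
        vmap = verdicts.set_index(["feature_id", "comparison"])["status"]
        vmissing = [
            (f, c)
            for c in COMPARISONS
            for f in feats
            if (f, c) not in vmap.index
        ]
        if vmissing:
            raise ValidationError(
                f"verdicts missing for {len(vmissing)} feature/comparison "
                f"pairs, e.g. {vmissing[:3]}"
            )
    profiles = []
    for fid in feats:
        per_comp = {}
        for comp in COMPARISONS:
            row = results[comp].loc[fid]
            status = "NC" if verdicts is None else str(vmap.loc[(fid, comp)])
            significant = bool(row["q"] <= fdr_threshold) if pd.notna(row["q"]) else False
            per_comp[comp] = {
                "delta": float(row["delta"]),
                "q": float(row["q"]) if pd.notna(row["q"]) else float("nan"),
                "significant": significant,
                "status": status,
                "fires": significant and status in eligible_statuses,
            }
        profiles.append(FeatureProfile(feature_id=fid, per_comparison=per_comp))
    return profiles


def _stage_direction(
    profile: FeatureProfile, stage_comparisons
) -> tuple[bool, float, list[str]]:
    """Whether a stage fired, its defining delta, and the firing comparisons.

    When both comparisons of a stage fire, the one with the smaller q
    defines the stage direction; q ties break toward the larger |delta|.
    """
    fired = [c for c in stage_comparisons if profile.fires(c)]
    if not fired:
        return False, float("nan"), []
    best = min(
        fired,
        key=lambda c: (
            profile.per_comparison[c]["q"],
            -abs(profile.per_comparison[c]["delta"]),
        ),
    )
    return True, profile.per_comparison[best]["delta"], fired


def categorize_feature(profile: FeatureProfile) -> StageCategory:
    """Assign one feature its disease-spectrum category (see module docs)."""
    s1, d1, fired1 = _stage_direction(profile, STAGE1_COMPARISONS)
    s2, d2, fired2 = _stage_direction(profile, STAGE2_COMPARISONS)
    span_fires = profile.fires("HC:IHD")
    route = fired1 + fired2 + (["HC:IHD"] if span_fires else [])

    if s1 and s2:
        sign1, sign2 = np.sign(d1), np.sign(d2)
        if sign1 != 0 and sign1 == sign2:
            return StageCategory(profile.feature_id, "ESCF", route, d1, d2)
        if sign1 != 0 and sign2 != 0 and sign1 == -sign2:
            return StageCategory(profile.feature_id, "DSCF", route, d1, d2)
        return StageCategory(profile.feature_id, "UNCLASSIFIED", route, d1, d2)
    if s2 and not s1:
        return StageCategory(profile.feature_id, "IHDF", route, d1, d2)
    if s1 and not s2:
        return StageCategory(profile.feature_id, "DMF", route, d1, d2)
    if span_fires:
        # shifted only relative to HCs across the whole span: a
        # dysmetabolism-onset signal without disease-stage support
        return StageCategory(
            profile.feature_id,
            "DMF",
            route,
            profile.per_comparison["HC:IHD"]["delta"],
            float("nan"),
        )
    return StageCategory(profile.feature_id, "UNCLASSIFIED", route, d1, d2)


def categorize_all(
    profiles: list[FeatureProfile],
) -> tuple[pd.DataFrame, dict]:
    """Categorize every profile; returns (table, summary).

    The table has one row per feature (columns ``category, route,
    stage1_delta, stage2_delta``); the summary counts features per
    category and per firing route.
    """
    rows = []
    for prof in profiles:
        cat = categorize_feature(prof)
        rows.append(
            {
                "feature_id": cat.feature_id,
                "category": cat.category,
                "route": "+".join(cat.route),
                "stage1_delta": cat.stage1_delta,
                "stage2_delta": cat.stage2_delta,
            }
        )
    table = pd.DataFrame.from_records(rows).set_index("feature_id")
    counts = table["category"].value_counts().to_dict()
    summary = {
        "n_features": int(len(table)),
        "counts": {c: int(counts.get(c, 0)) for c in CATEGORIES},
        "routes": {
            str(k): int(v) for k, v in table["route"].value_counts().items() if k
        },
    }
    return table, summary


def subtype_categorize(
    matrix: CohortMatrix,
    metadata: SubjectMetadata,
    subtype: str,
    covariates: list[str] | None = None,
    fdr_threshold: float = 0.1,
    lrt_alpha: float = 0.05,
    eligible_statuses=ELIGIBLE_STATUSES,
    deconfound: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Stage categorization with an IHD subtype (or the whole IHD group)
    as the disease-stage case group.

    Runs the two-group tests (and optionally the deconfounding screen)
    with ``subtype`` substituted for IHD in the HC:IHD, MMC:IHD and
    UMMC:IHD comparisons, then applies the identical categorization
    logic.  Control groups are reused globally (not subtype-rematched).
    """
    from .deconfound import run_deconfounding
    from .stats import compare_groups

    if not len(metadata.subjects_in(subtype)):
        raise ValidationError(f"no subjects with subtype/group {subtype!r}")
    case_of = {
        "HC:MMC": ("HC", "MMC"),
        "HC:UMMC": ("HC", "UMMC"),
        "HC:IHD": ("HC", subtype),
        "MMC:IHD": ("MMC", subtype),
        "UMMC:IHD": ("UMMC", subtype),
    }
    results = {
        comp: compare_groups(matrix, metadata, a, b, fdr_threshold=fdr_threshold)
        for comp, (a, b) in case_of.items()
    }
    verdicts = None
    if deconfound and (covariates or metadata.covariates):
        parts = []
        for comp, (a, b) in case_of.items():
            v = run_deconfounding(
                matrix,
                metadata,
                [f"{a}:{b}"],
                covariates=covariates,
                fdr=fdr_threshold,
                lrt_alpha=lrt_alpha,
            )
            v["comparison"] = comp  # canonical slot name
            parts.append(v)
        verdicts = pd.concat(parts, ignore_index=True)
    profiles = build_profiles(
        results, verdicts, eligible_statuses=eligible_statuses, fdr_threshold=fdr_threshold
    )
    return categorize_all(profiles)
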