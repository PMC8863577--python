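"""Stage categorization: the DMF/IHDF/ESCF/DSCF decision rules and their
recovery of planted archetypes."""

import numpy as np
import pandas as pd
import pytest

from cardstage import (
    SyntheticSpec,
    build_profiles,
    categorize_all,
    categorize_feature,
    compare_groups,
    generate_cohort,
    run_deconfounding,
    subtype_categorize,
)
from cardstage.categorize import FeatureProfile
from cardstage.containers import COMPARISONS, ValidationError


def make_profile(fid="f", **spec):
    """Build a FeatureProfile from comparison -> (delta, q, status)."""
    per_comp = {}
    for comp in COMPARISONS:
        delta, q, status = spec.get(comp.replace(":", "_"), (0.0, 1.0, "NC"))
        per_comp[comp] = {
            "delta": delta,
            "q": q,
            "significant": q <= 0.1,
            "status": status,
            "fires": q <= 0.1 and status in ("NC", "CD"),
        }
    return FeatureProfile(feature_id=fid, per_comparison=per_comp)


class TestCategorizeFeature:
    def test_same_direction_both_stages_is_escalation(self):
        prof = make_profile(HC_MMC=(0.3, 0.02, "NC"), MMC_IHD=(0.2, 0.04, "NC"))
        cat = categorize_feature(prof)
        assert cat.category == "ESCF"
        assert np.sign(cat.stage1_delta) == np.sign(cat.stage2_delta)

    def test_reversed_direction_is_deescalation(self):
        prof = make_profile(HC_MMC=(-0.3, 0.02, "NC"), MMC_IHD=(0.2, 0.04, "NC"))
        cat = categorize_feature(prof)
        assert cat.category == "DSCF"
        assert np.sign(cat.stage1_delta) == -np.sign(cat.stage2_delta)

    def test_stage_one_only_is_dysmetabolic(self):
        prof = make_profile(HC_MMC=(0.3, 0.02, "NC"), HC_IHD=(0.25, 0.05, "NC"))
        assert categorize_feature(prof).category == "DMF"

    def test_hc_ihd_alone_routes_to_dmf(self):
        prof = make_profile(HC_IHD=(0.3, 0.02, "NC"))
        assert categorize_feature(prof).category == "DMF"

    def test_stage_two_only_is_disease_specific(self):
        prof = make_profile(UMMC_IHD=(0.3, 0.02, "NC"), HC_IHD=(0.2, 0.03, "NC"))
        assert categorize_feature(prof).category == "IHDF"

    def test_nothing_significant_unclassified(self):
        assert categorize_feature(make_profile()).category == "UNCLASSIFIED"

    def test_confounded_comparisons_do_not_fire(self):
        prof = make_profile(
            HC_MMC=(0.3, 0.02, "CONFOUNDED"), MMC_IHD=(0.2, 0.04, "CONFOUNDED")
        )
        assert categorize_feature(prof).category == "UNCLASSIFIED"

    def test_lax_deconfounding_excluded_by_default(self):
        prof = make_profile(HC_MMC=(0.3, 0.02, "LD"))
        assert categorize_feature(prof).category == "UNCLASSIFIED"

    def test_small_effects_still_categorized(self):
        """The |delta| > 0.1 display filter plays no role in assignment."""
        prof = make_profile(HC_MMC=(0.04, 0.02, "NC"), MMC_IHD=(0.03, 0.04, "NC"))
        assert categorize_feature(prof).category == "ESCF"

    def test_stage_direction_tie_break_by_q(self):
        prof = make_profile(
            HC_MMC=(0.3, 0.05, "NC"),
            HC_UMMC=(-0.4, 0.01, "NC"),  # smaller q defines stage direction
            MMC_IHD=(-0.2, 0.04, "NC"),
        )
        cat = categorize_feature(prof)
        assert cat.stage1_delta == -0.4
        assert cat.category == "ESCF"


class TestBuildProfiles:
    def test_missing_comparison_rejected(self, small_cohort):
        matrix, metadata, _ = small_cohort
        results = {
            c: compare_groups(matrix, metadata, *c.split(":"))
            for c in COMPARISONS[:3]
        }
        with pytest.raises(ValidationError, match="missing comparisons"):
            build_profiles(results, None)

    def test_mismatched_features_rejected(self, small_cohort):
        matrix, metadata, _ = small_cohort
        results = {
            c: compare_groups(matrix, metadata, *c.split(":")) for c in COMPARISONS
        }
        results["HC:MMC"] = results["HC:MMC"].iloc[:-2]
        with pytest.raises(ValidationError, match="feature set mismatch"):
            build_profiles(results, None)

    def test_verdict_eligibility_controls_firing(self, small_cohort):
        matrix, metadata, _ = small_cohort
        results = {
            c: compare_groups(matrix, metadata, *c.split(":")) for c in COMPARISONS
        }
        rows = [
            {"feature_id": f, "comparison": c, "status": "CONFOUNDED"}
            for f in matrix.features
            for c in COMPARISONS
        ]
        verdicts = pd.DataFrame(rows)
        profiles = build_profiles(results, verdicts)
        table, summary = categorize_all(profiles)
        assert summary["counts"]["UNCLASSIFIED"] == len(matrix.features)


@pytest.fixture(scope="module")
def benchmark():
    spec = SyntheticSpec(
        group_sizes={"HC": 300, "UMMC": 300, "MMC": 300, "IHD": 300},
        n_features={"taxon": 60, "metabolite": 60},
        archetype_mix={
            "null": 0.2,
            "dmf": 0.2,
            "ihdf": 0.2,
            "escf": 0.2,
            "dscf": 0.2,
        },
        effect_size=0.4,
        drug_model={},
        subtypes=False,
        seed=55,
    )
    matrix, metadata, truth = generate_cohort(spec)
    results = {
        c: compare_groups(matrix, metadata, *c.split(":")) for c in COMPARISONS
    }
    profiles = build_profiles(results, None)
    table, summary = categorize_all(profiles)
    return truth, table, summary


class TestRecovery:

    def test_planted_archetypes_recovered(self, benchmark):
        truth, table, _ = benchmark
        mapping = {
            "dmf": "DMF",
            "ihdf": "IHDF",
            "escf": "ESCF",
            "dscf": "DSCF",
            "null": "UNCLASSIFIED",
        }
        for arch, cat in mapping.items():
            planted = truth.features_with(arch)
            acc = (table.loc[planted, "category"] == cat).mean()
            assert acc >= 0.7, f"{arch}: accuracy {acc:.2f}"

    def test_category_counts_sum_to_features(self, benchmark):
        _, table, summary = benchmark
        assert sum(summary["counts"].values()) == len(table)
        assert summary["n_features"] == len(table)

    def test_every_feature_exactly_one_category(self, benchmark):
        _, table, _ = benchmark
        assert table["category"].isin(
            ["DMF", "IHDF", "ESCF", "DSCF", "UNCLASSIFIED"]
        ).all()

    def test_permuted_labels_mostly_unclassified(self, benchmark, rng):
        spec = SyntheticSpec(
            group_sizes={"HC": 150, "UMMC": 150, "MMC": 150, "IHD": 150},
            n_features={"metabolite": 100},
            archetype_mix={"dmf": 0.5, "ihdf": 0.5},
            effect_size=0.4,
            drug_model={},
            subtypes=False,
            seed=56,
        )
        matrix, metadata, _ = generate_cohort(spec)
        from cardstage import SubjectMetadata

        perm = metadata.table.copy()
        perm["group"] = rng.permutation(perm["group"].to_numpy())
        md_perm = SubjectMetadata(table=perm, covariate_types=metadata.covariate_types)
        results = {
            c: compare_groups(matrix, md_perm, *c.split(":")) for c in COMPARISONS
        }
        table, summary = categorize_all(build_profiles(results, None))
        assert summary["counts"]["UNCLASSIFIED"] >= 0.95 * len(table)


@pytest.fixture(scope="module")
def subtype_cohort():
    spec = SyntheticSpec(
        group_sizes={"HC": 150, "UMMC": 120, "MMC": 150, "IHD": 180},
        n_features={"metabolite": 60},
        archetype_mix={"null": 0.4, "ihdf": 0.3, "ihdf_ACS": 0.3},
        effect_size=0.5,
        drug_model={},
        subtypes=True,
        seed=60,
    )
    return generate_cohort(spec)


class TestSubtypes:
    def test_whole_ihd_group_matches_categorize_all(self, subtype_cohort):
        matrix, metadata, _ = subtype_cohort
        results = {
            c: compare_groups(matrix, metadata, *c.split(":")) for c in COMPARISONS
        }
        table_all, _ = categorize_all(build_profiles(results, None))
        table_sub, _ = subtype_categorize(
            matrix, metadata, "IHD", deconfound=False
        )
        assert (table_all["category"] == table_sub["category"]).all()

    def test_subtype_specific_feature_found_for_its_subtype(self, subtype_cohort):
        matrix, metadata, truth = subtype_cohort
        table_acs, _ = subtype_categorize(matrix, metadata, "ACS", deconfound=False)
        planted = truth.features_with("ihdf_ACS")
        assert (table_acs.loc[planted, "category"] == "IHDF").mean() >= 0.7

    def test_subtype_feature_diluted_in_other_subtypes(self, subtype_cohort):
        matrix, metadata, truth = subtype_cohort
        table_hf, _ = subtype_categorize(matrix, metadata, "HF", deconfound=False)
        planted = truth.features_with("ihdf_ACS")
        # an ACS-only shift should rarely look IHD-specific for HF cases
        assert (table_hf.loc[planted, "category"] == "IHDF").mean() <= 0.3

    def test_absent_subtype_rejected(self, subtype_cohort):
        matrix, metadata, _ = subtype_cohort
        md = metadata.table.copy()
        md["subtype"] = ""
        from cardstage import SubjectMetadata

        md2 = SubjectMetadata(table=md, covariate_types=metadata.covariate_types)
        with pytest.raises(ValidationError):
            subtype_categorize(matrix, md2, "ACS", deconfound=False)
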