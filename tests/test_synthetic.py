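"""Synthetic cohort generator: determinism, planted effect calibration,
archetype structure, and fixture serialization."""

import numpy as np
import pytest
from scipy import stats as sps

from cardstage import SyntheticSpec, cliffs_delta, compare_groups, generate_cohort
from cardstage.containers import ValidationError
from cardstage.synthetic import (
    emit_fixture,
    fixture_checksum,
    shift_for_lognormal,
    shift_for_zinb,
    zinb_delta,
)


def _group_values(matrix, metadata, feature, group):
    return matrix.values.loc[metadata.subjects_in(group), feature].to_numpy()


class TestSpecValidation:
    def test_bad_mix_sum_names_field(self):
        spec = SyntheticSpec(archetype_mix={"null": 0.5, "dmf": 0.2})
        with pytest.raises(ValidationError, match="archetype_mix"):
            spec.validate()

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"group_sizes": {"HC": 1, "IHD": 10}}, "group_sizes"),
            ({"effect_size": 1.2}, "effect_size"),
            ({"n_features": {"protein": 5}}, "n_features"),
            ({"drug_model": {"statin": {"HC": 1.4}}}, "drug_model"),
        ],
    )
    def test_invalid_fields_named(self, kwargs, field):
        with pytest.raises(ValidationError, match=field):
            SyntheticSpec(**kwargs).validate()


class TestDeterminism:
    def test_same_seed_identical_matrices(self):
        spec = SyntheticSpec(
            group_sizes={"HC": 20, "MMC": 20},
            n_features={"taxon": 8, "metabolite": 8},
            seed=7,
        )
        m1, md1, t1 = generate_cohort(spec)
        m2, md2, t2 = generate_cohort(spec)
        assert m1.values.equals(m2.values)
        assert md1.table.equals(md2.table)
        assert t1.table.equals(t2.table)

    def test_fixture_checksum_stable(self, tmp_path):
        spec = SyntheticSpec(
            group_sizes={"HC": 15, "IHD": 15},
            n_features={"taxon": 5, "metabolite": 5},
            seed=3,
        )
        c1 = fixture_checksum(emit_fixture(spec, tmp_path / "a"))
        c2 = fixture_checksum(emit_fixture(spec, tmp_path / "b"))
        assert c1 == c2

    def test_truth_row_count(self, small_cohort):
        matrix, _, truth = small_cohort
        assert len(truth.table) == len(matrix.features)


class TestShiftCalibration:
    def test_lognormal_closed_form(self):
        # delta = 2 Phi(d/(s sqrt 2)) - 1 inverts exactly
        for target in (0.2, 0.4, -0.6):
            d = shift_for_lognormal(target, sigma=1.3)
            back = 2 * sps.norm.cdf(d / (1.3 * np.sqrt(2))) - 1
            assert back == pytest.approx(target, abs=1e-12)

    def test_zinb_exact_delta_matches_monte_carlo(self, rng):
        mu, r, pi = 80.0, 1.0, 0.25
        d = shift_for_zinb(0.4, mu, r, pi)
        n = 60000

        def draw(m):
            c = rng.negative_binomial(r, r / (r + m), n)
            return np.where(rng.random(n) < pi, 0, c)

        mc = cliffs_delta(draw(mu), draw(mu * np.exp(d)))
        assert mc == pytest.approx(0.4, abs=0.02)

    def test_planted_delta_near_target(self):
        """Median empirical |delta| over planted features within 0.1 of
        the requested 0.4 at n=300/group, for both feature classes."""
        spec = SyntheticSpec(
            group_sizes={"HC": 300, "MMC": 300},
            n_features={"taxon": 50, "metabolite": 50},
            archetype_mix={"dmf": 1.0},
            effect_size=0.4,
            drug_model={},
            subtypes=False,
            seed=21,
        )
        matrix, metadata, truth = generate_cohort(spec)
        deltas = np.array(
            [
                cliffs_delta(
                    _group_values(matrix, metadata, f, "HC"),
                    _group_values(matrix, metadata, f, "MMC"),
                )
                for f in matrix.features
            ]
        )
        assert abs(np.median(np.abs(deltas)) - 0.4) < 0.1


class TestArchetypeStructure:
    def test_escalation_keeps_direction_across_stages(self):
        """escf at effect 0.5, n=200/group: HC:MMC and MMC:IHD deltas share
        a sign for >= 95% of 100 features."""
        spec = SyntheticSpec(
            group_sizes={"HC": 200, "MMC": 200, "IHD": 200},
            n_features={"taxon": 50, "metabolite": 50},
            archetype_mix={"escf": 1.0},
            effect_size=0.5,
            drug_model={},
            subtypes=False,
            seed=5,
        )
        matrix, metadata, _ = generate_cohort(spec)
        agree = 0
        for f in matrix.features:
            d1 = cliffs_delta(
                _group_values(matrix, metadata, f, "HC"),
                _group_values(matrix, metadata, f, "MMC"),
            )
            d2 = cliffs_delta(
                _group_values(matrix, metadata, f, "MMC"),
                _group_values(matrix, metadata, f, "IHD"),
            )
            agree += np.sign(d1) == np.sign(d2)
        assert agree >= 95

    def test_deescalation_reverses_direction(self):
        spec = SyntheticSpec(
            group_sizes={"HC": 200, "MMC": 200, "IHD": 200},
            n_features={"metabolite": 60},
            archetype_mix={"dscf": 1.0},
            effect_size=0.5,
            drug_model={},
            subtypes=False,
            seed=6,
        )
        matrix, metadata, _ = generate_cohort(spec)
        opposite = 0
        for f in matrix.features:
            d1 = cliffs_delta(
                _group_values(matrix, metadata, f, "HC"),
                _group_values(matrix, metadata, f, "MMC"),
            )
            d2 = cliffs_delta(
                _group_values(matrix, metadata, f, "MMC"),
                _group_values(matrix, metadata, f, "IHD"),
            )
            opposite += np.sign(d1) == -np.sign(d2)
        assert opposite >= 0.95 * 60

    def test_disease_specific_features_silent_at_stage_one(self):
        spec = SyntheticSpec(
            group_sizes={"HC": 200, "MMC": 200, "IHD": 200},
            n_features={"metabolite": 60},
            archetype_mix={"ihdf": 1.0},
            effect_size=0.5,
            drug_model={},
            subtypes=False,
            seed=8,
        )
        matrix, metadata, _ = generate_cohort(spec)
        res1 = compare_groups(matrix, metadata, "HC", "MMC")
        res2 = compare_groups(matrix, metadata, "MMC", "IHD")
        assert res1["significant"].mean() <= 0.1  # null at stage 1
        assert res2["significant"].mean() >= 0.9

    def test_drug_driven_features_follow_indicator_not_group(self):
        spec = SyntheticSpec(
            group_sizes={"HC": 150, "IHD": 150},
            n_features={"metabolite": 40},
            archetype_mix={"drug_driven": 1.0},
            effect_size=0.5,
            drug_model={"statin": {"HC": 0.5, "IHD": 0.5}},  # independent of group
            subtypes=False,
            seed=9,
        )
        matrix, metadata, truth = generate_cohort(spec)
        assert (truth.table["confounder"] == "statin").all()
        on = metadata.table.index[metadata.table["statin"] == 1]
        off = metadata.table.index[metadata.table["statin"] == 0]
        drug_deltas = []
        group_deltas = []
        for f in matrix.features:
            drug_deltas.append(
                abs(cliffs_delta(matrix.values.loc[off, f], matrix.values.loc[on, f]))
            )
            group_deltas.append(
                abs(
                    cliffs_delta(
                        _group_values(matrix, metadata, f, "HC"),
                        _group_values(matrix, metadata, f, "IHD"),
                    )
                )
            )
        assert np.median(drug_deltas) > 0.35
        assert np.median(group_deltas) < 0.15

    def test_global_null_controls_significance(self):
        spec = SyntheticSpec(
            group_sizes={"HC": 100, "UMMC": 80, "MMC": 100, "IHD": 100},
            n_features={"taxon": 60, "metabolite": 60},
            archetype_mix={"null": 1.0},
            effect_size=0.0,
            seed=13,
        )
        matrix, metadata, _ = generate_cohort(spec)
        for comp in ("HC:MMC", "HC:IHD", "MMC:IHD"):
            res = compare_groups(matrix, metadata, *comp.split(":"))
            assert res["significant"].mean() <= 0.1

    def test_zero_inflation_cap_is_respected(self):
        # requesting more separation than structural zeros allow falls
        # back to the boundary shift instead of diverging
        d = shift_for_zinb(0.95, mu=50.0, r=1.0, pi=0.3)
        assert d == 8.0
        assert zinb_delta(50.0, 50.0 * np.exp(d), 1.0, 0.3) < 0.95


class TestFixture:
    def test_roundtrip_through_readers(self, tmp_path):
        from cardstage import read_matrix, read_metadata

        spec = SyntheticSpec(
            group_sizes={"HC": 20, "MMC": 20, "IHD": 20},
            n_features={"taxon": 6, "metabolite": 6},
            seed=11,
        )
        paths = emit_fixture(spec, tmp_path)
        matrix, metadata, truth = generate_cohort(spec)
        m2 = read_matrix(paths["abundance"])
        md2 = read_metadata(paths["metadata"])
        assert list(m2.features) == list(matrix.features)
        assert (m2.kinds == matrix.kinds).all()
        np.testing.assert_allclose(
            m2.values.to_numpy(), matrix.values.to_numpy(), rtol=1e-11
        )
        assert md2.covariate_types == metadata.covariate_types
        assert (md2.table["group"] == metadata.table["group"]).all()
        # truth file covers every feature
        truth_lines = (tmp_path / "truth.tsv").read_text().strip().splitlines()
        assert len(truth_lines) - 1 == len(matrix.features)
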