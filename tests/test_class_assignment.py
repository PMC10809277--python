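"""Class assignment: delta-CCS arbitration, m/z constraints, scoring."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twimcal import (
    BiomolecularClass,
    Feature,
    InstrumentConfig,
    TrendlineModel,
    apply_calibration,
    assign_feature,
    class_eligible,
    default_curves,
    default_trendlines,
    generate_synthetic_features,
    invert_calibration,
    score_assignment,
    SyntheticSpec,
)
from twimcal.errors import (
    MissingCurveError,
    UnassignableFeatureError,
    UnsupportedChargeError,
)

LIPID = BiomolecularClass.LIPID
SM = BiomolecularClass.SMALL_MOLECULE
PEP = BiomolecularClass.PEPTIDE


def constant_trendline(cls, value, domain=(100.0, 1200.0)):
    """Flat trendline predicting `value` everywhere: makes deltas exact."""
    return TrendlineModel(cls, "linear", (value, 0.0), domain, 5)


class TestEligibility:
    def test_small_molecule_above_cap_ineligible(self, config):
        assert not class_eligible(SM, 692.517, config)

    def test_lipid_below_floor_ineligible(self, config):
        assert not class_eligible(LIPID, 250.0, config)

    @pytest.mark.parametrize("mz", [100.0, 300.0, 550.0, 2000.0])
    def test_peptide_always_eligible(self, config, mz):
        assert class_eligible(PEP, mz, config)

    def test_boundaries_are_strict(self, config):
        # "less than 550", "greater than 300": the boundary itself fails
        assert not class_eligible(SM, 550.0, config)
        assert class_eligible(SM, 549.999, config)
        assert not class_eligible(LIPID, 300.0, config)
        assert class_eligible(LIPID, 300.001, config)


class TestScoring:
    @pytest.mark.parametrize("next_best,expected", [
        (213.0, 4),   # 6.5% apart: calibration choice very consequential
        (209.0, 3),   # 4.5%
        (204.0, 2),   # 2.0%
        (201.0, 1),   # 0.5%: all calibrations nearly agree
    ])
    def test_buckets(self, next_best, expected):
        assert score_assignment(200.0, next_best, 1) == expected

    @pytest.mark.parametrize("d_pct,expected", [
        (6.0, 4), (5.999, 3), (3.0, 3), (2.999, 2), (1.0, 2), (0.999, 1),
    ])
    def test_boundaries_belong_to_higher_score(self, d_pct, expected):
        assert score_assignment(200.0, 200.0 * (1 + d_pct / 100), 1) == expected

    def test_multiply_charged_scores_zero(self):
        assert score_assignment(480.0, None, 2) == 0
        assert score_assignment(480.0, 470.0, 3) == 0

    def test_single_attempted_class_has_no_score(self):
        assert score_assignment(200.0, None, 1) is None

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        assigned=st.floats(min_value=50.0, max_value=1000.0),
        rel=st.floats(min_value=-0.2, max_value=0.2),
    )
    def test_exhaustive_and_deterministic(self, assigned, rel):
        s = score_assignment(assigned, assigned * (1 + rel), 1)
        assert s in (1, 2, 3, 4)
        assert s == score_assignment(assigned, assigned * (1 + rel), 1)


class TestAssignFeature:
    def test_minimum_delta_class_wins(self, config, curves):
        # deltas engineered via flat trendlines to match the worked example:
        # lipid 0.8, small molecule 38.7, peptide 25.3 at m/z 692.517
        feature = Feature("lip1", 692.517, 1, 8.0)
        ccs = {
            k: apply_calibration(8.0, 692.517, 1, curves[k], config)
            for k in ("lipid", "small_molecule", "peptide")
        }
        trendlines = {
            "lipid": constant_trendline(LIPID, ccs["lipid"] - 0.8),
            "small_molecule": constant_trendline(SM, ccs["small_molecule"] - 38.7),
            "peptide": constant_trendline(PEP, ccs["peptide"] + 25.3),
        }
        a = assign_feature(feature, curves, trendlines, config)
        assert a.assigned_class == "lipid"
        assert a.per_class_delta["lipid"] == pytest.approx(0.8, abs=1e-9)
        assert a.per_class_delta["small_molecule"] == pytest.approx(38.7, abs=1e-9)
        assert a.per_class_delta["peptide"] == pytest.approx(25.3, abs=1e-9)
        assert a.final_ccs == pytest.approx(ccs["lipid"])
        assert not a.constraint_fallback

    def test_structurally_matched_synthetic_feature_has_zero_delta(
        self, config, curves, trendlines
    ):
        spec = SyntheticSpec(n_features=30, trendline_scatter_pct=0.0, seed=2)
        for feature, true_class in generate_synthetic_features(
            spec, trendlines, curves, config
        ):
            a = assign_feature(feature, curves, trendlines, config)
            assert a.assigned_class == true_class.value
            assert a.per_class_delta[true_class.value] == pytest.approx(0.0, abs=1e-8)

    def test_mz_constraint_fallback(self, config, curves):
        # m/z 250: lipid has the smallest delta but is ineligible below 300,
        # so the next closest (small molecule) wins with the flag set
        feature = Feature("sm_low", 250.0, 1, 5.0)
        ccs = {
            k: apply_calibration(5.0, 250.0, 1, curves[k], config)
            for k in ("lipid", "small_molecule", "peptide")
        }
        trendlines = {
            "lipid": constant_trendline(LIPID, ccs["lipid"] - 0.1),
            "small_molecule": constant_trendline(SM, ccs["small_molecule"] - 0.5),
            "peptide": constant_trendline(PEP, ccs["peptide"] - 5.0),
        }
        a = assign_feature(feature, curves, trendlines, config)
        assert a.assigned_class == "small_molecule"
        assert a.constraint_fallback

    def test_no_eligible_class_is_unassignable_with_deltas(self, config, curves):
        feature = Feature("orphan", 600.0, 1, 7.0)
        only_sm = {"small_molecule": curves["small_molecule"]}
        trendlines = {"small_molecule": constant_trendline(SM, 180.0)}
        with pytest.raises(UnassignableFeatureError) as err:
            assign_feature(feature, only_sm, trendlines, config)
        assert "small_molecule" in err.value.per_class_delta

    def test_multiply_charged_routes_to_peptide_curve_only(self, config, curves, trendlines):
        feature = Feature("pep2", 450.0, 2, 6.0)
        a = assign_feature(feature, curves, trendlines, config)
        assert a.assigned_class == "peptide_z2"
        assert list(a.per_class_ccs) == ["peptide_z2"]
        assert a.per_class_delta == {}
        assert a.score == 0
        assert a.final_ccs == pytest.approx(
            apply_calibration(6.0, 450.0, 2, curves["peptide_z2"], config)
        )

    def test_charge_four_unsupported(self, config, curves, trendlines):
        with pytest.raises(UnsupportedChargeError):
            assign_feature(Feature("big", 500.0, 4, 6.0), curves, trendlines, config)

    def test_missing_peptide_z3_curve_reported(self, config, curves, trendlines):
        curves = {k: v for k, v in curves.items() if k != "peptide_z3"}
        with pytest.raises(MissingCurveError):
            assign_feature(Feature("p3", 400.0, 3, 6.0), curves, trendlines, config)

    def test_assignment_invariant_to_class_evaluation_order(self, config, curves, trendlines):
        feature = Feature("f", 480.0, 1, 7.5)
        results = []
        for order in itertools.permutations(["lipid", "small_molecule", "peptide"]):
            c = {k: curves[k] for k in order}
            c.update({k: v for k, v in curves.items() if k not in c})
            t = {k: trendlines[k] for k in order}
            a = assign_feature(feature, c, t, config)
            results.append((a.assigned_class, a.final_ccs, a.score))
        assert len(set(results)) == 1

    def test_removing_unrelated_class_preserves_ranking(self, config, curves, trendlines):
        feature = Feature("f", 480.0, 1, 7.5)
        full = assign_feature(feature, curves, trendlines, config)
        ranked = sorted(full.per_class_delta, key=full.per_class_delta.get)
        dropped = ranked[-1]
        sub_curves = {k: v for k, v in curves.items() if k != dropped}
        sub_tl = {k: v for k, v in trendlines.items() if k != dropped}
        sub = assign_feature(feature, sub_curves, sub_tl, config)
        sub_ranked = sorted(sub.per_class_delta, key=sub.per_class_delta.get)
        assert sub_ranked == [k for k in ranked if k != dropped]
        assert sub.assigned_class == full.assigned_class

    def test_exact_tie_broken_by_fixed_priority(self, config, curves):
        feature = Feature("tie", 500.0, 1, 7.0)
        ccs = {
            k: apply_calibration(7.0, 500.0, 1, curves[k], config)
            for k in ("lipid", "small_molecule", "peptide")
        }
        trendlines = {k: constant_trendline(BiomolecularClass(k if k != "small_molecule" else "small_molecule"), v - 1.0) for k, v in ccs.items()}
        a = assign_feature(feature, curves, trendlines, config)
        assert a.assigned_class == "lipid"  # lipid > small_molecule > peptide

    def test_score_attached_from_next_ranked_class(self, config, curves, trendlines):
        feature = Feature("f", 700.0, 1, 9.0)
        a = assign_feature(feature, curves, trendlines, config)
        ranked = sorted(a.per_class_delta, key=a.per_class_delta.get)
        nxt = next(k for k in ranked if k != a.assigned_class)
        expected = score_assignment(
            a.per_class_ccs[a.assigned_class], a.per_class_ccs[nxt], 1,
            config.score_thresholds,
        )
        assert a.score == expected
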