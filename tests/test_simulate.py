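"""Synthetic study generator: reproducibility, noise fidelity, truth labels."""

import numpy as np
import pytest

from thermoniche.briere import niche_summary, optimal_temperature
from thermoniche.data import ConditionLabel
from thermoniche.simulate import (
    DEFAULT_DRUG_EFFECTS,
    STUDY_TEMPERATURES_C,
    apply_drug_effect,
    control_curve,
    curve_with_niche,
    generate_combo_study,
    generate_condition,
    generate_driver_table_null,
    pair_curve_for_category,
)


class TestCurveConstruction:
    def test_control_curve_matches_study_truth(self):
        ns = niche_summary(control_curve())
        assert ns.t_opt == pytest.approx(37.7, abs=1e-6)
        assert ns.breadth == pytest.approx(15.0, abs=1e-5)
        assert ns.g_max == pytest.approx(0.5)

    @pytest.mark.parametrize("t_opt,breadth", [(30.0, 10.0), (37.7, 15.0), (40.0, 20.0)])
    def test_curve_with_niche_hits_targets(self, t_opt, breadth):
        ns = niche_summary(curve_with_niche(t_opt, breadth, 0.4))
        assert ns.t_opt == pytest.approx(t_opt, abs=1e-6)
        assert ns.breadth == pytest.approx(breadth, abs=1e-5)

    def test_infeasible_niche_rejected(self):
        with pytest.raises(ValueError):
            curve_with_niche(t_opt=5.0, breadth=10.0, g_max=0.5)  # below t_min

    def test_drug_effect_shifts_and_narrows(self):
        base = control_curve()
        eff = DEFAULT_DRUG_EFFECTS["GEN"]
        ns0, ns1 = niche_summary(base), niche_summary(apply_drug_effect(base, eff))
        assert ns1.t_opt == pytest.approx(ns0.t_opt + eff.d_topt, abs=1e-5)
        assert ns1.breadth == pytest.approx(ns0.breadth * eff.breadth_factor, rel=1e-4)
        assert ns1.g_max == pytest.approx(ns0.g_max * eff.g_max_factor)


class TestPairCurves:
    @pytest.mark.parametrize("category", ["min", "max", "mean", "attenuated", "elevated"])
    def test_requested_category_realized_exactly(self, category):
        base = control_curve()
        px = apply_drug_effect(base, DEFAULT_DRUG_EFFECTS["GEN"])  # t_opt 32.7
        py = apply_drug_effect(base, DEFAULT_DRUG_EFFECTS["CPR"])  # t_opt 38.7
        pxy = pair_curve_for_category(px, py, category)
        tx, ty = optimal_temperature(px), optimal_temperature(py)
        target = {
            "min": min(tx, ty), "max": max(tx, ty), "mean": 0.5 * (tx + ty),
            "attenuated": min(tx, ty) - 3.0, "elevated": max(tx, ty) + 3.0,
        }[category]
        assert optimal_temperature(pxy) == pytest.approx(target, abs=1e-6)

    def test_unsatisfiable_request_rejected(self):
        base = control_curve()
        px = curve_with_niche(45.0, 3.0, 0.3, t_min=10, t_max=47)
        with pytest.raises(ValueError, match="elevated"):
            pair_curve_for_category(px, base, "elevated")  # 48 degC > t_max


class TestConditionGenerator:
    def test_seeded_reproducibility(self, control_params):
        a = generate_condition(control_params, seed=5)
        b = generate_condition(control_params, seed=5)
        assert a.equals(b)
        c = generate_condition(control_params, seed=6)
        assert not a.equals(c)

    def test_sampling_mean_matches_curve(self, control_params):
        from thermoniche.briere import canonical_evaluate

        df = generate_condition(
            control_params, temperatures=(30.0,), n_replicates=10**4, seed=1
        )
        assert df["od600_24h"].mean() == pytest.approx(
            canonical_evaluate(30.0, control_params), rel=0.01
        )

    def test_boundary_temperature_draws_near_floor(self):
        p = curve_with_niche(37.7, 15.0, 0.5, t_min=10.0, t_max=44.5)
        df = generate_condition(p, seed=2)  # 46 degC is outside the support
        at46 = df[df["temperature_c"] == 46.0]["od600_24h"]
        assert np.all(at46 >= 0)
        assert np.all(at46 < 1e-3)

    def test_design_shape(self, control_params):
        df = generate_condition(control_params, seed=0)
        assert len(df) == len(STUDY_TEMPERATURES_C) * 4
        assert sorted(df["temperature_c"].unique()) == list(STUDY_TEMPERATURES_C)


class TestComboStudy:
    def test_truth_covers_every_observed_condition(self):
        study = generate_combo_study(n_drugs=5, n_pairs=4, seed=3)
        for label in study.observations.conditions:
            assert label in study.truth_params
        assert len(study.truth_categories) == 4
        # 1 control + 5 singles + 4 pairs
        assert len(study.truth_params) == 10

    def test_pair_truth_optima_realize_categories(self):
        study = generate_combo_study(n_drugs=6, n_pairs=6, seed=9)
        for label, category in study.truth_categories.items():
            x, y = label.drugs
            tx = optimal_temperature(study.truth_params[ConditionLabel((x,))])
            ty = optimal_temperature(study.truth_params[ConditionLabel((y,))])
            txy = optimal_temperature(study.truth_params[label])
            if category == "min":
                assert txy == pytest.approx(min(tx, ty), abs=1e-6)
            elif category == "attenuated":
                assert txy == pytest.approx(min(tx, ty) - 3.0, abs=1e-6)
            elif category == "elevated":
                assert txy == pytest.approx(max(tx, ty) + 3.0, abs=1e-6)

    def test_driver_is_member_of_pair(self):
        study = generate_combo_study(n_drugs=8, n_pairs=10, seed=4)
        for label, driver in study.truth_drivers.items():
            if driver is not None:
                assert driver in label.drugs

    def test_reproducible_under_seed(self):
        a = generate_combo_study(n_drugs=4, n_pairs=3, seed=11)
        b = generate_combo_study(n_drugs=4, n_pairs=3, seed=11)
        assert a.observations.table.equals(b.observations.table)


class TestNullDriverTable:
    def test_driver_always_in_pair_and_reproducible(self):
        pairs = [("A", "B"), ("B", "C"), ("A", "C")]
        t1 = generate_driver_table_null(pairs, seed=2)
        t2 = generate_driver_table_null(pairs, seed=2)
        assert t1.entries == t2.entries
        for pair, driver in t1.entries:
            assert driver in pair

    def test_driver_counts_approach_half(self):
        # law of large numbers: drug A drives ~half of its many pairs
        pairs = [("A", f"P{i}") for i in range(2000)]
        table = generate_driver_table_null(pairs, seed=8)
        from thermoniche.permutation import m_statistic

        assert m_statistic(table, "A") / 2000 == pytest.approx(0.5, abs=0.03)
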