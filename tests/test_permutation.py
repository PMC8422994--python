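"""Driver-dominance permutation tests: statistics, calibration, power."""

import itertools

import numpy as np
import pytest

from thermoniche.permutation import (
    DriverTable,
    benjamini_hochberg,
    bonferroni,
    d_statistic,
    m_statistic,
    permutation_test_global,
    permutation_test_per_drug,
)
from thermoniche.simulate import generate_driver_table_null


def balanced_table():
    # every drug drives exactly half of its pairs
    return DriverTable(
        [
            (("A", "B"), "A"),
            (("A", "C"), "C"),
            (("B", "C"), "B"),
            (("B", "D"), "D"),
            (("A", "D"), "A"),
            (("C", "D"), "C"),
            (("A", "E"), "E"),
            (("B", "E"), "B"),
            (("C", "E"), "E"),
            (("D", "E"), "D"),
        ]
    )


class TestStatistics:
    def test_balanced_table_has_zero_d(self):
        assert d_statistic(balanced_table()) == pytest.approx(0.0)

    def test_hand_enumerated_d(self):
        # 4 pairs all containing A, all driven by A:
        # A contributes (4 - 2)^2 = 4; each partner (0 - 0.5)^2 = 0.25
        table = DriverTable([(("A", x), "A") for x in "BCDE"])
        assert d_statistic(table) == pytest.approx(5.0)

    def test_d_invariant_to_entry_order(self):
        entries = list(balanced_table().entries)
        shuffled = DriverTable(entries[::-1])
        assert d_statistic(shuffled) == d_statistic(balanced_table())

    def test_m_counts(self):
        table = DriverTable([(("A", x), "A") for x in "BCD"])
        assert m_statistic(table, "A") == 3
        assert m_statistic(table, "B") == 0
        with pytest.raises(ValueError):
            m_statistic(table, "Z")

    def test_pair_driver_counts_sum_to_one_per_entry(self):
        table = balanced_table()
        total = sum(m_statistic(table, d) for d in table.drugs)
        assert total == len(table)

    def test_duplicate_pair_rejected(self):
        with pytest.raises(ValueError):
            DriverTable([(("A", "B"), "A"), (("B", "A"), "B")])

    def test_foreign_driver_rejected(self):
        with pytest.raises(ValueError):
            DriverTable([(("A", "B"), "C")])


class TestGlobalTest:
    def test_add_one_p_never_zero_and_deterministic(self):
        table = DriverTable([(("A", x), "A") for x in "BCDE"])
        r1 = permutation_test_global(table, n_perm=200, seed=3)
        r2 = permutation_test_global(table, n_perm=200, seed=3)
        assert r1.p_value > 0
        assert r1.p_value == r2.p_value

    def test_matches_exhaustive_enumeration(self):
        table = DriverTable(
            [(("A", "B"), "A"), (("A", "C"), "A"), (("A", "D"), "A"),
             (("B", "C"), "B"), (("B", "D"), "B"), (("C", "D"), "C")]
        )
        drugs = table.drugs
        observed = d_statistic(table)
        # enumerate all 2^6 driver assignments exactly
        count = 0
        pairs = [pair for pair, _ in table.entries]
        for assignment in itertools.product((0, 1), repeat=len(pairs)):
            entries = [(p, p[k]) for p, k in zip(pairs, assignment)]
            if d_statistic(DriverTable(entries)) >= observed - 1e-12:
                count += 1
        p_exact = count / 2 ** len(pairs)
        res = permutation_test_global(table, n_perm=20_000, seed=1)
        assert res.p_value == pytest.approx(p_exact, abs=0.01)

    def test_power_against_single_dominant_drug(self):
        drugs = [f"D{i}" for i in range(13)]
        dom_pairs = [("D0", d) for d in drugs[1:13]]  # 12 pairs containing D0
        others = [(a, b) for a, b in itertools.combinations(drugs[1:], 2)][:28]
        table = DriverTable(
            [(p, "D0") for p in dom_pairs] + [(p, p[0]) for p in others]
        )
        assert len(table) == 40
        res = permutation_test_global(table, n_perm=5000, seed=2)
        assert res.p_value < 0.01

    def test_calibrated_under_null(self):
        drugs = [f"D{i}" for i in range(12)]
        rng = np.random.default_rng(0)
        all_pairs = list(itertools.combinations(drugs, 2))
        pairs = [all_pairs[i] for i in rng.choice(len(all_pairs), 40, replace=False)]
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            table = generate_driver_table_null(pairs, seed=50_000 + rep)
            res = permutation_test_global(table, n_perm=400, seed=rep)
            rejections += res.p_value <= 0.05
        rate = rejections / n_rep
        # 95% binomial band around 0.05 at n=200
        band = 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
        assert 0.05 - band <= rate <= 0.05 + band


class TestPerDrugTest:
    def test_adjusted_at_least_raw(self):
        table = balanced_table()
        res = permutation_test_per_drug(table, n_perm=500, seed=7)
        for d, entry in res.per_drug.items():
            assert entry["p_adjusted"] >= entry["p_raw"]

    def test_balanced_table_nothing_significant(self):
        res = permutation_test_per_drug(balanced_table(), n_perm=1000, seed=11)
        assert all(e["p_adjusted"] > 0.05 for e in res.per_drug.values())

    def test_dominant_drug_has_smallest_adjusted_p(self):
        drugs = [f"D{i}" for i in range(13)]
        dom_pairs = [("D0", d) for d in drugs[1:13]]
        others = [(a, b) for a, b in itertools.combinations(drugs[1:], 2)][:28]
        table = DriverTable(
            [(p, "D0") for p in dom_pairs] + [(p, p[0]) for p in others]
        )
        res = permutation_test_per_drug(table, n_perm=5000, seed=13)
        best = min(res.per_drug, key=lambda d: res.per_drug[d]["p_adjusted"])
        assert best == "D0"

    def test_bonferroni_option(self):
        res = permutation_test_per_drug(
            balanced_table(), n_perm=200, seed=1, adjust="bonferroni"
        )
        for e in res.per_drug.values():
            assert e["p_adjusted"] == pytest.approx(min(1.0, e["p_raw"] * 5))


class TestAdjustments:
    def test_bh_monotone_and_bounded(self):
        p = np.array([0.001, 0.01, 0.02, 0.5, 0.9])
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_bonferroni_formula(self):
        np.testing.assert_allclose(
            bonferroni([0.01, 0.4]), [0.02, 0.8]
        )
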