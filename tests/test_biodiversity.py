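"""IAP, campaign comparison, dissimilarity/ordination, and trait models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from lichenmonitor import biodiversity as bd
from lichenmonitor.datamodel import SpeciesObservation, ValidationError


def _obs(tree, year, species, f, station="S1"):
    return SpeciesObservation(station, tree, year, species, f)


class TestIAP:
    def test_tree_sum(self):
        obs = [
            _obs("T1", 1997, "A a", 3),
            _obs("T1", 1997, "B b", 7),
            _obs("T1", 1997, "C c", 10),
        ]
        assert bd.iap_tree(obs) == 20.0

    def test_empty_tree_is_zero(self):
        assert bd.iap_tree([]) == 0.0

    def test_single_species(self):
        assert bd.iap_tree([_obs("T1", 1997, "A a", 10)]) == 10.0

    def test_mixed_trees_rejected(self):
        with pytest.raises(ValidationError):
            bd.iap_tree([_obs("T1", 1997, "A a", 3), _obs("T2", 1997, "A a", 3)])

    def test_station_mean(self):
        res = bd.iap_station({"T1": 10.0, "T2": 20.0}, "S1", 1997)
        assert res.station_value == 15.0 and res.n_trees == 2
        res1 = bd.iap_station({"T1": 7.0})
        assert res1.station_value == 7.0 and res1.n_trees == 1

    def test_station_requires_trees(self):
        with pytest.raises(ValidationError):
            bd.iap_station({})

    def test_station_idempotent_on_identical_trees(self):
        res = bd.iap_station({f"T{i}": 13.0 for i in range(5)})
        assert res.station_value == 13.0

    def test_station_iap_matches_binomial_expectation(self, small_survey):
        # station IAP ~ n_species * 10p summed over the pool; compare against
        # the direct per-tree means of the same draw
        results = bd.iap_by_station(small_survey)
        for r in results:
            assert r.station_value == pytest.approx(
                np.mean(list(r.per_tree.values()))
            )

    def test_recovers_configured_occupancy(self):
        from lichenmonitor import synthetic
        from lichenmonitor.datamodel import TraitRecord

        p = 0.4
        pool = tuple(
            synthetic.SpeciesSpec(
                f"G s{i}", TraitRecord(f"G s{i}", 3, 3, "foliose_broad", "soredia"), p
            )
            for i in range(5)
        )
        cfg = synthetic.CommunitySimConfig(
            species_pool=pool, n_stations=1, trees_per_station=60, seed=21
        )
        survey = [o for o in synthetic.generate_survey(cfg) if o.year == 1997]
        res = bd.iap_by_station(survey)[0]
        expected = 5 * 10 * p
        se = np.sqrt(5 * 10 * p * (1 - p) / 60)
        assert abs(res.station_value - expected) < 3 * se


class TestCompareYears:
    def test_identical_samples(self):
        t, df, p = bd.compare_years([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_worked_example(self):
        t, df, p = bd.compare_years([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=5e-4)
        assert df == 4
        assert p == pytest.approx(2 * stats.t.sf(3.674, 4), abs=1e-4)

    def test_antisymmetry(self):
        t1, _, p1 = bd.compare_years([1, 2, 3], [4, 5, 7])
        t2, _, p2 = bd.compare_years([4, 5, 7], [1, 2, 3])
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_small_samples_rejected(self):
        with pytest.raises(ValidationError):
            bd.compare_years([1.0], [2.0, 3.0])

    def test_zero_variance_equal_means(self):
        t, df, p = bd.compare_years([2, 2, 2], [2, 2])
        assert (t, p) == (0.0, 1.0)

    @settings(max_examples=50, deadline=None)
    @given(
        x=st.lists(st.floats(-50, 50), min_size=2, max_size=12),
        y=st.lists(st.floats(-50, 50), min_size=2, max_size=12),
    )
    def test_matches_textbook_formula(self, x, y):
        xa, ya = np.array(x), np.array(y)
        n1, n2 = xa.size, ya.size
        sp2 = ((n1 - 1) * xa.var(ddof=1) + (n2 - 1) * ya.var(ddof=1)) / (n1 + n2 - 2)
        if sp2 <= 1e-12:
            return
        t_ref = (xa.mean() - ya.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        t, df, p = bd.compare_years(xa, ya)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_ref), n1 + n2 - 2), abs=1e-10)

    def test_welch_flag(self):
        t, df, p = bd.compare_years([1, 2, 3, 4], [10, 20, 30], welch=True)
        res = stats.ttest_ind([1, 2, 3, 4], [10, 20, 30], equal_var=False)
        assert t == pytest.approx(float(res.statistic))


class TestFrequencyChange:
    def test_mean_difference(self):
        obs = (
            [_obs(f"T{i}", 1997, "A a", 8) for i in range(3)]
            + [_obs(f"T{i}", 2022, "A a", 2) for i in range(3)]
        )
        mat = bd.frequency_change(obs, 1997, 2022)
        assert mat.loc["A a", "S1"] == pytest.approx(-6.0)

    def test_absent_species_is_nan(self):
        obs = [
            _obs("T1", 1997, "A a", 5),
            _obs("T1", 2022, "A a", 5),
            _obs("T1", 1997, "B b", 2, station="S2"),
            _obs("T1", 2022, "B b", 2, station="S2"),
        ]
        mat = bd.frequency_change(obs, 1997, 2022)
        assert np.isnan(mat.loc["B b", "S1"])
        assert mat.loc["B b", "S2"] == pytest.approx(0.0)

    def test_unknown_year_rejected(self, small_survey):
        with pytest.raises(ValidationError):
            bd.frequency_change(small_survey, 1997, 1887)

    def test_imposed_sign_recovered(self):
        from lichenmonitor import synthetic

        pool = synthetic.default_species_pool(20, eutrophication_effect=-0.8, seed=3)
        cfg = synthetic.CommunitySimConfig(
            species_pool=pool, n_stations=1, trees_per_station=20, seed=3
        )
        mat = bd.frequency_change(synthetic.generate_survey(cfg), 1997, 2022)
        affected = [s for s in pool if abs(s.year_effect) > 0.4]
        hits = 0
        for s in affected:
            if s.species in mat.index and not np.isnan(mat.iloc[:, 0][s.species]):
                cell = mat.loc[s.species].iloc[0]
                hits += (cell * s.year_effect) > 0
        assert hits / len(affected) >= 0.9


class TestBrayCurtis:
    def test_identity(self):
        assert bd.bray_curtis([2, 1, 0], [2, 1, 0]) == 0.0

    def test_disjoint_supports(self):
        assert bd.bray_curtis([1, 0], [0, 3]) == 1.0

    def test_worked_example(self):
        assert bd.bray_curtis([2, 1, 0], [1, 1, 1]) == pytest.approx(1 / 3)

    def test_both_zero_rejected(self):
        with pytest.raises(ValidationError):
            bd.bray_curtis([0, 0], [0, 0])

    @settings(max_examples=100, deadline=None)
    @given(
        a=st.lists(st.integers(0, 10), min_size=2, max_size=8),
        b=st.lists(st.integers(0, 10), min_size=2, max_size=8),
    )
    def test_symmetric_and_bounded(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        if sum(a) == 0 and sum(b) == 0:
            return
        d1 = bd.bray_curtis(a, b)
        d2 = bd.bray_curtis(b, a)
        assert d1 == pytest.approx(d2)
        assert 0.0 <= d1 <= 1.0


class TestNMDS:
    def test_embeddable_configuration_has_low_stress(self, rng):
        pts = rng.uniform(size=(15, 2))
        D = squareform(pdist(pts))
        res = bd.nmds(D, k=2, n_restarts=8, seed=0)
        assert res.stress < 0.01

    def test_two_objects_zero_stress(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        res = bd.nmds(D, k=2, n_restarts=1, seed=0)
        assert res.stress == pytest.approx(0.0, abs=1e-8)

    def test_monotone_invariance_under_doubling(self, rng):
        pts = rng.uniform(size=(12, 2))
        D = squareform(pdist(pts))
        s1 = bd.nmds(D, k=2, n_restarts=5, seed=1).stress
        s2 = bd.nmds(2 * D, k=2, n_restarts=5, seed=1).stress
        assert s1 == pytest.approx(s2, abs=1e-6)

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValidationError):
            bd.nmds(D)


class TestTraitModels:
    def test_exactly_linear(self):
        x = np.arange(10, dtype=float)
        res = bd.trait_effect(2 * x + 1, x)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.p_value < 1e-10

    def test_zero_trait_variance_rejected(self):
        with pytest.raises(ValidationError):
            bd.trait_effect([1, 2, 3], [5, 5, 5])

    def test_anova_worked_example(self):
        f, df1, df2, p = bd.trait_anova([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
        assert f == pytest.approx(13.5)
        assert (df1, df2) == (1, 4)
        assert p == pytest.approx(stats.f.sf(13.5, 1, 4))

    def test_anova_all_equal(self):
        f, _, _, p = bd.trait_anova([2, 2, 2, 2], ["a", "a", "b", "b"])
        assert f == 0.0 and p == 1.0

    def test_anova_small_group_rejected(self):
        with pytest.raises(ValidationError):
            bd.trait_anova([1, 2, 3], ["a", "a", "b"])

    def test_regression_type_one_rate_under_permutation(self, rng):
        # permuting the trait against a fixed change vector rejects at ~5%
        change = rng.normal(size=30)
        trait = rng.normal(size=30)
        n_rep, rej = 2000, 0
        for _ in range(n_rep):
            res = bd.trait_effect(change, rng.permutation(trait))
            rej += res.p_value < 0.05
        assert abs(rej / n_rep - 0.05) <= 0.02

    def test_anova_type_one_rate_under_permutation(self, rng):
        change = rng.normal(size=24)
        groups = np.array(["a"] * 8 + ["b"] * 8 + ["c"] * 8)
        n_rep, rej = 2000, 0
        for _ in range(n_rep):
            _, _, _, p = bd.trait_anova(change, rng.permutation(groups))
            rej += p < 0.05
        assert abs(rej / n_rep - 0.05) <= 0.02
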