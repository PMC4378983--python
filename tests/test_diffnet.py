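import numpy as np
import pandas as pd
import pytest

import midna
from midna.connectivity import ConnectivityMatrix
from midna.diffnet import PipelineSettings
from midna.modules import ModuleSet


def _module_set(modules, universe, m=3, eps=0.4):
    return ModuleSet(modules=[frozenset(x) for x in modules], m=m, epsilon=eps,
                     universe=list(universe))


UNIVERSE = ["j1", "j2", "j3", "j4", "j5"]


class TestModularDifference:
    def test_worked_overlap_example(self):
        """A lipid in module {j1,j2,j3} on one side and {j1,j2,j4,j5} on the
        other contributes intersection 2 over union 5; with the shared lipids
        being j1 and j2 the statistic is 1 - 2/5 = 0.6."""
        ms1 = _module_set([{"j1", "j2", "j3"}], UNIVERSE)
        ms2 = _module_set([{"j1", "j2", "j4", "j5"}], UNIVERSE)
        terms = midna.module_overlap_terms(ms1, ms2)
        assert terms == {"j1": (2, 5), "j2": (2, 5)}
        assert midna.modular_difference_statistic(ms1, ms2) == pytest.approx(0.6)

    def test_identical_module_sets_give_zero(self):
        ms = _module_set([{"j1", "j2", "j3"}], UNIVERSE)
        assert midna.modular_difference_statistic(ms, ms) == 0.0

    def test_modules_on_one_side_only_gives_one(self):
        ms1 = _module_set([{"j1", "j2", "j3"}], UNIVERSE)
        empty = _module_set([], UNIVERSE)
        assert midna.modular_difference_statistic(ms1, empty) == 1.0
        assert midna.modular_difference_statistic(empty, ms1) == 1.0

    def test_no_modules_anywhere_gives_zero(self):
        empty = _module_set([], UNIVERSE)
        assert midna.modular_difference_statistic(empty, empty) == 0.0

    def test_disjoint_modules_give_one(self):
        ms1 = _module_set([{"j1", "j2", "j3"}], UNIVERSE)
        ms2 = _module_set([{"j4", "j5", "j3"}], UNIVERSE)
        # shared analyte j3: modules intersect only in j3 -> Jaccard 1/5
        assert midna.modular_difference_statistic(ms1, ms2) == pytest.approx(0.8)

    def test_mismatched_universes_rejected(self):
        ms1 = _module_set([], UNIVERSE)
        ms2 = _module_set([], ["x", "y", "z"])
        with pytest.raises(ValueError, match="universe"):
            midna.module_overlap_terms(ms1, ms2)


class TestConnectivityDifference:
    def _cm(self, s):
        return ConnectivityMatrix(np.asarray(s, float), ["L1", "L2", "L3"], v=1,
                                  rescaled=True)

    def test_identical_matrices_give_zero(self):
        s = np.array([[0, 0.5, 0.1], [0.5, 0, 1.0], [0.1, 1.0, 0]])
        d = midna.connectivity_difference(self._cm(s), self._cm(s))
        np.testing.assert_array_equal(d, np.zeros(3))

    def test_hand_evaluated_example(self):
        s1 = np.array([[0, 0.5, 0.1], [0.5, 0, 1.0], [0.1, 1.0, 0]])
        s2 = np.array([[0, 0.1, 0.3], [0.1, 0, 1.0], [0.3, 1.0, 0]])
        d = midna.connectivity_difference(self._cm(s1), self._cm(s2))
        assert d[0] == pytest.approx((0.4 + 0.2) / 2)

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(3, 3)), rng.normal(size=(3, 3))
        a, b = 0.5 * (a + a.T), 0.5 * (b + b.T)
        np.fill_diagonal(a, 0), np.fill_diagonal(b, 0)
        d12 = midna.connectivity_difference(self._cm(a), self._cm(b))
        d21 = midna.connectivity_difference(self._cm(b), self._cm(a))
        np.testing.assert_array_equal(d12, d21)


class TestPermutationTest:
    def _null_ds(self, seed=50):
        truth = midna.make_truth(6, block_size=3, hub=False, rho=0.5,
                                 censor_quantile=0.15, mcar_rate=0.02)
        ds, _ = midna.simulate_study(12, 12, 6, truth, seed)
        return ds

    def test_observed_zero_statistic_has_pvalue_one(self):
        # m larger than p: no modules can ever form, so N = 0 always
        ds = self._null_ds()
        rep = midna.permutation_imputation_test(
            ds, PipelineSettings(M=1, n_cycles=1, m=10), P=5, seed=1
        )
        assert rep.N_observed == 0.0 and rep.N_pvalue == 1.0

    def test_same_seed_reproduces_report(self):
        ds = self._null_ds()
        st = PipelineSettings(M=2, n_cycles=2)
        a = midna.permutation_imputation_test(ds, st, P=5, seed=3)
        b = midna.permutation_imputation_test(ds, st, P=5, seed=3)
        assert a.N_observed == b.N_observed and a.N_pvalue == b.N_pvalue
        pd.testing.assert_series_equal(a.d_pvalues, b.d_pvalues)
        np.testing.assert_array_equal(a.perm_d, b.perm_d)

    def test_parallel_matches_serial(self):
        ds = self._null_ds()
        st = PipelineSettings(M=1, n_cycles=1)
        serial = midna.permutation_imputation_test(ds, st, P=6, seed=4, n_jobs=1)
        parallel = midna.permutation_imputation_test(ds, st, P=6, seed=4, n_jobs=2)
        np.testing.assert_array_equal(serial.perm_N, parallel.perm_N)
        np.testing.assert_array_equal(serial.perm_d, parallel.perm_d)

    def test_pvalues_are_valid_fractions(self):
        ds = self._null_ds(seed=51)
        rep = midna.permutation_imputation_test(
            ds, PipelineSettings(M=1, n_cycles=1), P=9, seed=5
        )
        assert 0.0 <= rep.N_pvalue <= 1.0
        assert ((rep.d_pvalues >= 0) & (rep.d_pvalues <= 1)).all()
        # without the +1 correction every p-value is a multiple of 1/P
        np.testing.assert_allclose(np.round(rep.d_pvalues * 9, 12) % 1, 0.0)

    def test_add_one_estimator_is_strictly_positive(self):
        ds = self._null_ds(seed=52)
        rep = midna.permutation_imputation_test(
            ds, PipelineSettings(M=1, n_cycles=1, add_one=True), P=9, seed=6
        )
        assert rep.N_pvalue >= 1 / 10
        assert (rep.d_pvalues >= 1 / 10).all()

    def test_hub_attains_smaller_p_than_non_hubs(self):
        """The planted bridge hub should be more significant by p(d) than the
        typical non-hub analyte (median over replicates)."""
        hub_p, other_p = [], []
        for r in range(12):
            truth = midna.make_truth(11, block_size=5, rho=0.7, hub=True)
            ds, truth = midna.simulate_study(100, 100, 11, truth, seed=[60_000 + r])
            rep = midna.permutation_imputation_test(
                ds, PipelineSettings(M=2, n_cycles=3), P=49, seed=60_000 + r
            )
            hub_p.append(rep.d_pvalues.iloc[truth.hub_analytes[0]])
            other_p.append(np.median(rep.d_pvalues.iloc[1:]))
        assert np.median(hub_p) < np.median(other_p)

    def test_epsilon_sweep_has_one_row_per_threshold(self):
        ds = self._null_ds(seed=53)
        grid = [0.3, 0.5, 0.7]
        table = midna.epsilon_sweep(ds, grid, PipelineSettings(M=1, n_cycles=1),
                                    P=4, seed=7)
        assert list(table["epsilon"]) == grid
        assert ((table["N"] >= 0) & (table["N"] <= 1)).all()
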