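import numpy as np
import pandas as pd
import pytest

from islecomm.cca_partition import (cca, isolation_partition,
                                    permutation_test, variance_partition)
from islecomm.core_io import OccurrenceMatrix

from _oracles import brute_force_cca_inertia


def _rand_community(rng, n_sites=8, n_species=10, fill=0.4):
    while True:
        y = (rng.random((n_sites, n_species)) < fill).astype(float)
        if y.sum(0).all() and y.sum(1).all():
            return y


class TestCCA:
    def test_proportional_rows_have_zero_inertia(self):
        # identical relative composition on every island: chi-square
        # residuals vanish
        base = np.array([2.0, 1.0, 3.0])
        y = np.vstack([base, 2 * base, 5 * base, 0.5 * base])
        res = cca(y, np.arange(4.0))
        assert res.total_inertia == pytest.approx(0.0, abs=1e-12)
        assert res.constrained_inertia == pytest.approx(0.0, abs=1e-12)

    def test_constant_constraint_explains_nothing(self, rng):
        y = _rand_community(rng)
        res = cca(y, np.ones(8))
        assert res.constrained_inertia == pytest.approx(0.0, abs=1e-10)
        assert res.df_constraints == 0

    def test_toy_matches_brute_force_oracle(self):
        # 3 species x 4 islands, one binary constraint
        y = np.array([[1.0, 0.0, 1.0],
                      [1.0, 1.0, 0.0],
                      [0.0, 1.0, 1.0],
                      [1.0, 1.0, 1.0]])  # islands x species
        x = np.array([0.0, 0.0, 1.0, 1.0])
        res = cca(y, x)
        total, _, constrained, eig = brute_force_cca_inertia(y, x)
        assert res.total_inertia == pytest.approx(total, abs=1e-10)
        assert res.constrained_inertia == pytest.approx(constrained, abs=1e-10)
        np.testing.assert_allclose(res.eigenvalues, eig, atol=1e-10)

    @pytest.mark.parametrize("with_covars", [False, True])
    def test_oracle_equivalence_on_random_instances(self, rng, with_covars):
        for _ in range(25):
            n_sites = int(rng.integers(4, 7))
            n_species = int(rng.integers(4, 9))
            y = _rand_community(rng, n_sites, n_species)
            x = rng.standard_normal((n_sites, 2))
            z = rng.standard_normal((n_sites, 1)) if with_covars else None
            res = cca(y, x, covariables=z)
            total, cond, constrained, _ = brute_force_cca_inertia(y, x, z)
            assert res.total_inertia == pytest.approx(total, abs=1e-10)
            assert res.conditioned_inertia == pytest.approx(cond, abs=1e-10)
            assert res.constrained_inertia == pytest.approx(constrained,
                                                            abs=1e-10)

    def test_empty_covariables_equal_none(self, rng):
        y = _rand_community(rng)
        x = rng.standard_normal((8, 2))
        r1 = cca(y, x)
        r2 = cca(y, x, covariables=np.empty((8, 0)))
        assert r1.constrained_inertia == pytest.approx(
            r2.constrained_inertia, abs=1e-12)
        assert r1.total_inertia == pytest.approx(r2.total_inertia, abs=1e-12)

    def test_eigenvalues_sum_to_constrained_inertia(self, rng):
        y = _rand_community(rng)
        x = rng.standard_normal((8, 3))
        res = cca(y, x)
        assert res.eigenvalues.sum() == pytest.approx(
            res.constrained_inertia, abs=1e-8)

    def test_constrained_inertia_monotone_in_columns(self, rng):
        y = _rand_community(rng, n_sites=10)
        x = rng.standard_normal((10, 4))
        vals = [cca(y, x[:, :k]).constrained_inertia for k in range(1, 5)]
        assert np.all(np.diff(vals) >= -1e-10)

    def test_collinear_constraints_reduce_rank(self, rng):
        y = _rand_community(rng)
        x = rng.standard_normal((8, 1))
        xx = np.hstack([x, 2 * x, x + 3.0])
        res = cca(y, xx)
        assert res.df_constraints == 1
        assert res.constrained_inertia == pytest.approx(
            cca(y, x).constrained_inertia, abs=1e-10)

    def test_occurrence_matrix_input_drops_empty_islands(self, toy_matrix):
        with pytest.warns(UserWarning, match="empty island"):
            res = cca(toy_matrix, np.arange(4.0))
        assert res.n_sites == 3

    def test_zero_presence_community_errors(self):
        with pytest.raises(ValueError, match="no presences"):
            cca(np.zeros((4, 3)), np.arange(4.0))


class TestPermutationTest:
    def test_type_i_rejection_rate_nominal(self, rng):
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            y = _rand_community(rng, n_sites=10, n_species=8)
            x = rng.standard_normal((10, 2))
            _, p = permutation_test(y, x, n_perm=99, rng=rng)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_perfect_dependence_gives_minimal_p(self, rng):
        # nested staircase community perfectly ordered along the gradient;
        # every site has a distinct assemblage so no permutation ties
        y = np.tril(np.ones((8, 8)))
        x = np.arange(8, dtype=float)
        f, p = permutation_test(y, x, n_perm=99, rng=rng)
        assert p == pytest.approx(1 / 100)
        assert f > 5

    def test_zero_permutations_error(self, rng):
        y = _rand_community(rng)
        with pytest.raises(ValueError):
            permutation_test(y, rng.standard_normal(8), n_perm=0, rng=rng)


class TestVariancePartition:
    def test_duplicated_sets_fully_confounded(self, rng):
        y = _rand_community(rng, n_sites=10)
        x = rng.standard_normal((10, 2))
        part = variance_partition(y, x, x.copy(), n_perm=0, rng=rng)
        assert part.fraction_a == pytest.approx(0.0, abs=1e-8)
        assert part.fraction_c == pytest.approx(0.0, abs=1e-8)
        assert part.fraction_b == pytest.approx(part.total_explained,
                                                abs=1e-8)

    def test_orthogonal_sets_have_no_shared_fraction(self, rng):
        # community built from two independent blocks of structure, each
        # aligned with one orthogonal design column
        n = 12
        x1 = np.repeat([0.0, 1.0], n // 2)
        x2 = np.tile([0.0, 1.0], n // 2)  # orthogonal to x1
        y = np.zeros((n, 4))
        y[x1 == 1, 0] = 1
        y[x1 == 0, 1] = 1
        y[x2 == 1, 2] = 1
        y[x2 == 0, 3] = 1
        part = variance_partition(y, x1, x2, n_perm=0, rng=rng)
        assert part.fraction_b == pytest.approx(0.0, abs=1e-6)
        assert part.fraction_a + part.fraction_c == pytest.approx(
            part.total_explained, abs=1e-6)

    def test_accounting_identity_on_random_instances(self, rng):
        for _ in range(20):
            y = _rand_community(rng, n_sites=9, n_species=7)
            s1 = rng.standard_normal((9, 2))
            s2 = rng.standard_normal((9, 2))
            part = variance_partition(y, s1, s2, n_perm=0, rng=rng)
            # PartitionResult asserts a + b + c == total internally;
            # also check fractions are percentages of total inertia
            assert part.total_explained <= 100 + 1e-9

    def test_fractions_invariant_to_reparameterization(self, rng):
        y = _rand_community(rng, n_sites=10)
        s1 = rng.standard_normal((10, 2))
        s2 = rng.standard_normal((10, 2))
        t = np.array([[2.0, 1.0], [0.0, -3.0]])  # invertible
        p1 = variance_partition(y, s1, s2, n_perm=0, rng=rng)
        p2 = variance_partition(y, s1 @ t, s2 * 7.0 + 1.0, n_perm=0, rng=rng)
        assert p1.fraction_a == pytest.approx(p2.fraction_a, abs=1e-8)
        assert p1.fraction_c == pytest.approx(p2.fraction_c, abs=1e-8)
        assert p1.fraction_b == pytest.approx(p2.fraction_b, abs=1e-8)


class TestIsolationPartition:
    def _islands(self, rng, n=12, isw=None):
        return pd.DataFrame({
            "area_m2": np.exp(rng.uniform(8, 13, n)),
            "elevation_m": rng.uniform(10, 200, n),
            "sha": 1 + rng.random(n),
            "veg_coverage": rng.uniform(0.2, 0.9, n),
            "habitat_richness": rng.integers(1, 6, n).astype(float),
            "isw": rng.uniform(0, 1, n) if isw is None else isw,
            "isd_m": rng.uniform(50, 2000, n),
        }, index=[f"i{j}" for j in range(n)])

    def test_df_fields_match_variable_counts(self, rng):
        y = _rand_community(rng, n_sites=12, n_species=10)
        part = isolation_partition(y, self._islands(rng), n_perm=0, rng=rng)
        assert part.df_set1 == 2
        assert part.df_union == 7

    def test_constant_isolation_explains_nothing(self, rng):
        y = _rand_community(rng, n_sites=12, n_species=10)
        islands = self._islands(rng, isw=np.full(12, 0.5))
        islands["isd_m"] = 300.0
        part = isolation_partition(y, islands, n_perm=0, rng=rng)
        assert part.fraction_a == pytest.approx(0.0, abs=1e-8)

    def test_isw_driven_community_attributes_to_isolation(self, rng):
        n = 14
        islands = self._islands(rng, n=n)
        # community determined by isw alone: species occupy islands above
        # per-species isw cuts
        cuts = np.quantile(islands["isw"], np.linspace(0.2, 0.8, 10))
        y = (islands["isw"].to_numpy()[:, None] > cuts[None, :]).astype(float)
        y[:, 0] = 1.0
        part = isolation_partition(y, islands, n_perm=0, rng=rng)
        assert part.fraction_a > 0.5 * part.total_explained
        assert abs(part.fraction_b) < 0.5 * part.fraction_a
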