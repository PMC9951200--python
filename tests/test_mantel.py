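import numpy as np
import pandas as pd
import pytest

from islecomm.beta_null import DistanceMatrix, pairwise_beta
from islecomm.core_io import OccurrenceMatrix
from islecomm.mantel import (environmental_distance, geographic_distance,
                             mantel, null_expected_partial_mantel,
                             partial_mantel, project_coordinates)

from _oracles import partial_correlation_by_residuals


def _dist(vec6):
    """Embed a 6-vector as the upper triangle of a 4x4 distance matrix."""
    m = np.zeros((4, 4))
    m[np.triu_indices(4, 1)] = vec6
    m = m + m.T
    return DistanceMatrix(("a", "b", "c", "d"), m)


def _orthonormal_triple():
    """Three zero-mean, orthonormal 6-vectors (Helmert contrasts)."""
    h = np.array([
        [1, -1, 0, 0, 0, 0],
        [1, 1, -2, 0, 0, 0],
        [1, 1, 1, -3, 0, 0],
    ], float)
    return [row / np.linalg.norm(row) for row in h]


class TestProjection:
    def test_reference_point_maps_to_origin(self):
        pc = project_coordinates(["x"], [119.0], [29.5], reference=(119.0, 29.5))
        assert pc.x[0] == 0.0 and pc.y[0] == 0.0

    def test_one_degree_longitude_on_equator(self):
        pc = project_coordinates(["a", "b"], [0.0, 1.0], [0.0, 0.0],
                                 reference=(0.0, 0.0))
        d = np.hypot(pc.x[1] - pc.x[0], pc.y[1] - pc.y[0])
        assert d == pytest.approx(6_371_000 * np.pi / 180, rel=1e-9)

    def test_agrees_with_haversine_at_archipelago_scale(self, rng):
        lon = 119.0 + rng.uniform(-0.15, 0.15, 30)
        lat = 29.5 + rng.uniform(-0.12, 0.12, 30)
        pc = project_coordinates(range(30), lon, lat)
        planar = geographic_distance(pc).values
        # haversine oracle
        la = np.deg2rad(lat)
        lo = np.deg2rad(lon)
        dlat = la[:, None] - la[None, :]
        dlon = lo[:, None] - lo[None, :]
        h = (np.sin(dlat / 2) ** 2
             + np.cos(la)[:, None] * np.cos(la)[None, :]
             * np.sin(dlon / 2) ** 2)
        great_circle = 2 * 6_371_000 * np.arcsin(np.sqrt(h))
        iu = np.triu_indices(30, 1)
        rel = np.abs(planar[iu] - great_circle[iu]) / great_circle[iu]
        assert rel.mean() < 1e-3
        assert rel.max() < 3e-3
        # distance ordering is preserved
        from scipy.stats import spearmanr
        assert spearmanr(planar[iu], great_circle[iu]).statistic > 0.9999

    def test_pole_rejected(self):
        with pytest.raises(ValueError):
            project_coordinates(["p"], [0.0], [90.0])


class TestEnvironmentalDistance:
    def test_identical_rows_give_zero(self):
        islands = pd.DataFrame({"a": [1.0, 1.0, 2.0], "b": [3.0, 3.0, 4.0]},
                               index=["i1", "i2", "i3"])
        d = environmental_distance(islands, ("a", "b"))
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_two_island_standardization(self):
        islands = pd.DataFrame({"v": [0.0, 1.0]}, index=["i1", "i2"])
        d = environmental_distance(islands, ("v",))
        assert d.values[0, 1] == pytest.approx(np.sqrt(2), rel=1e-12)

    def test_constant_column_dropped_with_warning(self):
        islands = pd.DataFrame({"v": [0.0, 1.0, 2.0], "const": [5.0] * 3},
                               index=["i1", "i2", "i3"])
        with pytest.warns(UserWarning, match="zero-variance"):
            d2 = environmental_distance(islands, ("v", "const"))
        d1 = environmental_distance(islands, ("v",))
        np.testing.assert_allclose(d1.values, d2.values)

    def test_missing_values_name_islands(self):
        islands = pd.DataFrame({"v": [0.0, np.nan, 2.0]},
                               index=["i1", "i2", "i3"])
        with pytest.raises(ValueError, match="i2"):
            environmental_distance(islands, ("v",))


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        v = rng.random(6)
        res = mantel(_dist(v), _dist(v), n_perm=99, rng=rng)
        assert res.r == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        v = rng.random(6)
        res = mantel(_dist(v), _dist(2.0 + 3.0 * v), n_perm=99, rng=rng)
        assert res.r == pytest.approx(1.0)

    def test_agrees_with_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import mantel as sk_mantel
        n = 12
        a = np.abs(rng.standard_normal((n, n)))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = np.abs(rng.standard_normal((n, n)))
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        ids = tuple(f"i{k}" for k in range(n))
        ours = mantel(DistanceMatrix(ids, a), DistanceMatrix(ids, b),
                      n_perm=99, rng=rng)
        sk_r, _, _ = sk_mantel(SkDM(a, ids), SkDM(b, ids),
                               permutations=0)
        assert ours.r == pytest.approx(sk_r, abs=1e-12)

    def test_too_few_islands_error(self, rng):
        d = DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="at least 3"):
            mantel(d, d, rng=rng)

    def test_p_values_uniform_under_null(self, rng):
        # independent random distance matrices: permutation p ~ uniform
        from scipy.stats import kstest
        n = 15
        ps = []
        for _ in range(200):
            def rand_d():
                m = np.abs(rng.standard_normal((n, n)))
                m = (m + m.T) / 2
                np.fill_diagonal(m, 0)
                return DistanceMatrix(tuple(f"i{k}" for k in range(n)), m)
            ps.append(mantel(rand_d(), rand_d(), n_perm=99, rng=rng).p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_p_never_zero(self, rng):
        v = rng.random(6)
        res = mantel(_dist(v), _dist(v), n_perm=99, rng=rng)
        assert res.p >= 1 / 100


class TestPartialMantel:
    def test_hand_arithmetic_case(self, rng):
        # constructed so r_AB=0.8, r_AC=0.5, r_BC=0.5
        u1, u2, u3 = _orthonormal_triple()
        a = u1
        b = 0.8 * u1 + 0.6 * u2
        s = 1 / 6
        c = 0.5 * u1 + s * u2 + np.sqrt(1 - 0.25 - s ** 2) * u3
        base = np.full(6, 2.0)  # offset keeps entries positive
        A, B, C = _dist(base + a), _dist(base + b), _dist(base + c)
        res = partial_mantel(A, B, C, n_perm=9, rng=rng)
        assert res.r == pytest.approx((0.8 - 0.25) / 0.75, abs=1e-10)
        # independent regression-residual oracle
        oracle = partial_correlation_by_residuals(base + a, base + b, base + c)
        assert res.r == pytest.approx(oracle, abs=1e-10)

    def test_constant_covariable_reduces_to_simple(self, rng):
        v1, v2 = rng.random(6), rng.random(6)
        const = _dist(np.full(6, 0.7))
        simple = mantel(_dist(v1), _dist(v2), n_perm=99,
                        rng=np.random.default_rng(3))
        part = partial_mantel(_dist(v1), _dist(v2), const, n_perm=99,
                              rng=np.random.default_rng(3))
        assert part.r == pytest.approx(simple.r, abs=1e-12)
        assert part.p == simple.p

    def test_identical_control_is_degenerate(self, rng):
        v1, v2 = rng.random(6), rng.random(6)
        with pytest.raises(ValueError, match="degenerate"):
            partial_mantel(_dist(v1), _dist(v2), _dist(v1), n_perm=9, rng=rng)

    def test_symmetric_in_first_two_arguments(self, rng):
        v1, v2, v3 = rng.random(6), rng.random(6), rng.random(6)
        r1 = partial_mantel(_dist(v1), _dist(v2), _dist(v3), n_perm=9,
                            rng=rng).r
        r2 = partial_mantel(_dist(v2), _dist(v1), _dist(v3), n_perm=9,
                            rng=rng).r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_invariant_under_consistent_relabeling(self, rng):
        v1, v2, v3 = rng.random(6), rng.random(6), rng.random(6)
        A, B, C = _dist(v1), _dist(v2), _dist(v3)
        perm = rng.permutation(4)
        ids = tuple(np.array(A.island_ids)[perm])
        Ap = DistanceMatrix(ids, A.values[np.ix_(perm, perm)])
        Bp = DistanceMatrix(ids, B.values[np.ix_(perm, perm)])
        Cp = DistanceMatrix(ids, C.values[np.ix_(perm, perm)])
        r1 = partial_mantel(A, B, C, n_perm=9, rng=np.random.default_rng(0)).r
        r2 = partial_mantel(Ap, Bp, Cp, n_perm=9,
                            rng=np.random.default_rng(0)).r
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestNullExpectedPartialMantel:
    def _setup(self, rng):
        from islecomm.synthetic_data import (ArchipelagoConfig,
                                             CommunityConfig,
                                             generate_archipelago,
                                             generate_community,
                                             island_coordinates)
        arch = generate_archipelago(ArchipelagoConfig(n_islands=25), rng)
        comm = generate_community(
            arch, CommunityConfig(n_species=80, dispersal_scale_m=3000,
                                  baseline_occupancy=0.8), rng)
        geo = geographic_distance(island_coordinates(arch))
        env = environmental_distance(arch)
        return comm, geo, env

    def test_identity_randomizer_gives_ses_zero(self, rng):
        comm, geo, env = self._setup(rng)
        values, cmp_res = null_expected_partial_mantel(
            comm, lambda m, _rng: m, 10, geo, env, rng)
        assert cmp_res.degenerate
        assert np.allclose(values, values[0])
        assert cmp_res.p == 1.0

    def test_ee_null_centred_near_zero_observed_positive(self, rng):
        comm, geo, env = self._setup(rng)
        beta = pairwise_beta(comm)
        obs = partial_mantel(beta, geo, env, n_perm=99, rng=rng)
        values, cmp_res = null_expected_partial_mantel(
            comm, "EE", 60, geo, env, rng, observed_r=obs.r)
        assert abs(cmp_res.expected_mean) < 0.1
        assert obs.r > cmp_res.expected_mean + 3 * cmp_res.expected_sd
        assert cmp_res.p < 0.01

    def test_fixed_seed_reproducible(self, rng):
        comm, geo, env = self._setup(rng)
        v1, _ = null_expected_partial_mantel(
            comm, "PF", 20, geo, env, np.random.default_rng(5))
        v2, _ = null_expected_partial_mantel(
            comm, "PF", 20, geo, env, np.random.default_rng(5))
        np.testing.assert_array_equal(v1, v2)
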