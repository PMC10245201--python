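import numpy as np
import pytest

from warnsig.distances import GlobalMatrix
from warnsig.errors import (DegenerateDenominatorError, InsufficientMembersError,
                            InsufficientPointsError, MembershipError,
                            ValidationError)
from warnsig.mimicry import (centroid_distance, classify_mimicry,
                             mimetic_distance, mimicry_table,
                             population_members, var_ms_correlation,
                             within_population_var)
from warnsig.synth import generate_phenotypes, head_rasters_from_table
from warnsig.distances import global_from_table

from conftest import euclidean_global


def gm3(d01, d02, d12):
    return GlobalMatrix(["a", "b", "c"], np.array([[0, d01, d02],
                                                   [d01, 0, d12],
                                                   [d02, d12, 0]], dtype=float))


class TestVar:
    def test_two_members(self):
        gm = gm3(0.6, 1.0, 1.0)
        assert within_population_var(gm, ["a", "b"]).var == 0.6

    def test_three_members_mean_of_pairs(self):
        gm = gm3(1.0, 2.0, 3.0)
        assert within_population_var(gm, ["a", "b", "c"]).var == pytest.approx(2.0)

    def test_clones_zero(self):
        gm = gm3(0.0, 0.0, 0.0)
        assert within_population_var(gm, ["a", "b", "c"]).var == 0.0

    def test_singleton_rejected(self):
        with pytest.raises(InsufficientMembersError):
            within_population_var(gm3(1, 1, 1), ["a"])

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(8, 3))
        gm = euclidean_global(coords)
        v1 = within_population_var(gm, ["i1", "i3", "i5"]).var
        v2 = within_population_var(gm, ["i5", "i1", "i3"]).var
        assert v1 == v2


class TestCentroidDistance:
    def test_identical_groups_zero(self):
        gm = euclidean_global(np.random.default_rng(0).normal(size=(6, 2)))
        ids = ["i0", "i1", "i2"]
        assert centroid_distance(gm, ids, ids) == pytest.approx(0.0, abs=1e-9)

    def test_coordinate_space_oracle_5d(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(50, 5))
        gm = euclidean_global(coords)
        a = [f"i{k}" for k in range(20)]
        b = [f"i{k}" for k in range(20, 50)]
        direct = np.linalg.norm(coords[:20].mean(axis=0)
                                - coords[20:].mean(axis=0))
        for method in ("gram", "embedding"):
            assert centroid_distance(gm, a, b, method) == pytest.approx(
                direct, abs=1e-8)

    def test_singleton_groups_give_matrix_entry(self):
        gm = gm3(1.25, 2.0, 0.5)
        assert centroid_distance(gm, ["a"], ["b"]) == 1.25

    def test_unknown_id_rejected(self):
        with pytest.raises(MembershipError):
            centroid_distance(gm3(1, 1, 1), ["a"], ["zzz"])


class TestMimeticDistance:
    def members(self):
        return {("S1", "X"): ["a"], ("S2", "X"): ["b"], ("S1", "Y"): ["c"]}

    def test_neutral_point_exact(self):
        gm = gm3(1.0, 1.0, 1.7)
        res = mimetic_distance(gm, self.members(), ("S1", "X"), [("S2", "X")])
        assert res.im[("S2", "X")] == 1.0
        assert res.ms == 1.0

    def test_perfect_mimic_limit(self):
        gm = gm3(0.0, 1.0, 1.0)
        res = mimetic_distance(gm, self.members(), ("S1", "X"), [("S2", "X")])
        assert res.im[("S2", "X")] == 0.0
        assert res.ms == np.inf

    def test_zero_allopatric_denominator(self):
        gm = gm3(1.0, 0.0, 1.0)
        with pytest.raises(DegenerateDenominatorError):
            mimetic_distance(gm, self.members(), ("S1", "X"), [("S2", "X")])

    def test_sum_vs_mean_single_partner_equal(self):
        gm = gm3(0.5, 1.0, 1.7)
        r_sum = mimetic_distance(gm, self.members(), ("S1", "X"),
                                 [("S2", "X")], aggregate="sum")
        r_mean = mimetic_distance(gm, self.members(), ("S1", "X"),
                                  [("S2", "X")], aggregate="mean")
        assert r_sum.ms == r_mean.ms == pytest.approx(2.0)

    def test_ms_scale_invariance(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(12, 3))
        ids = [f"i{k}" for k in range(12)]
        members = {("S1", "X"): ids[:4], ("S2", "X"): ids[4:8],
                   ("S1", "Y"): ids[8:]}
        gm1 = euclidean_global(coords)
        gm5 = GlobalMatrix(gm1.labels, 5.0 * gm1.values)
        r1 = mimetic_distance(gm1, members, ("S1", "X"), [("S2", "X")])
        r5 = mimetic_distance(gm5, members, ("S1", "X"), [("S2", "X")])
        assert r1.ms == pytest.approx(r5.ms, rel=1e-12)


class TestClassify:
    @pytest.mark.parametrize("ms,expected", [
        (0.77, "non_mimetic"),      # published example of a non-mimetic value
        (1.0, "mimetic"),           # boundary inclusive: only 'below 1' is not
        (1.56, "mimetic"),          # published example of a mimetic value
        (2.06, "mimetic"),
    ])
    def test_rule(self, ms, expected):
        assert classify_mimicry(ms) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            classify_mimicry(-0.1)


class TestCorrelation:
    def test_df_convention_15_points(self):
        rng = np.random.default_rng(3)
        res = var_ms_correlation(rng.normal(size=15), rng.normal(size=15))
        assert res.df == 13

    def test_exact_decreasing_line(self):
        x = np.arange(10.0)
        res = var_ms_correlation(x, 5.0 - 2.0 * x)
        assert res.r == pytest.approx(-1.0)
        assert res.p < 1e-12

    def test_bivariate_normal_within_fisher_ci(self):
        # oracle: exact 95% CI of rho = -0.7 at n = 20 via the Fisher z-transform
        rho, n = -0.7, 20
        rng = np.random.default_rng(7)
        cov = [[1.0, rho], [rho, 1.0]]
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        res = var_ms_correlation(xy[:, 0], xy[:, 1])
        z = np.arctanh(rho)
        half = 1.96 / np.sqrt(n - 3)
        lo, hi = np.tanh(z - half), np.tanh(z + half)
        assert lo <= res.r <= hi

    def test_too_few_points(self):
        with pytest.raises(InsufficientPointsError):
            var_ms_correlation([1.0, 2.0], [2.0, 1.0])

    def test_shapiro_reported_both_margins(self):
        rng = np.random.default_rng(5)
        res = var_ms_correlation(rng.normal(size=12), rng.normal(size=12))
        assert set(res.shapiro) == {"var", "ms"}
        for w, p in res.shapiro.values():
            assert 0.0 <= w <= 1.0 and 0.0 <= p <= 1.0

    def test_one_sided_half_of_two_sided_when_negative(self):
        x = np.arange(12.0)
        rng = np.random.default_rng(6)
        y = -x + rng.normal(scale=2.0, size=12)
        res = var_ms_correlation(x, y)
        assert res.r < 0
        assert res.p_one_sided == pytest.approx(res.p / 2.0)


class TestMimicryTable:
    def test_var_added_individual_at_mean_distance(self):
        # adding an individual whose distances all equal the current mean
        # leaves Var unchanged
        gm = GlobalMatrix(["a", "b", "c", "d"], np.array([
            [0, 1, 3, 2], [1, 0, 2, 2], [3, 2, 0, 2], [2, 2, 2, 0]],
            dtype=float))
        v3 = within_population_var(gm, ["a", "b", "c"]).var
        v4 = within_population_var(gm, ["a", "b", "c", "d"]).var
        assert v3 == v4 == pytest.approx(2.0)

    def test_full_study_produces_expected_rows(self, two_locality_study):
        table = generate_phenotypes(two_locality_study)
        gm = global_from_table(table, head_rasters_from_table(table))
        mt = mimicry_table(gm, table, two_locality_study.sympatry)
        assert len(mt) == 4          # 2 species x 2 localities, 1 partner each
        assert set(mt["classification"]) <= {"mimetic", "non_mimetic"}
        assert (mt["n"] == 5).all()

    def test_population_without_partner_skipped(self, two_locality_study):
        table = generate_phenotypes(two_locality_study)
        gm = global_from_table(table, head_rasters_from_table(table))
        # remove A@Y from the data so B@Y has no sympatric partner present
        table = table[~((table.species == "A") & (table.locality == "Y"))]
        with pytest.warns(UserWarning, match="skipped"):
            mt = mimicry_table(gm, table, two_locality_study.sympatry)
        assert ("B", "Y") not in set(zip(mt["species"], mt["locality"]))


def test_parameter_recovery_smoke():
    """Negative Var-ms correlation on a handful of gradient replicates."""
    import warnings as _w
    from warnsig.synth import predation_gradient_study
    hits = 0
    for seed in range(5):
        spec = predation_gradient_study(seed=seed)
        t = generate_phenotypes(spec)
        gm = global_from_table(t, head_rasters_from_table(t))
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            mt = mimicry_table(gm, t, spec.sympatry)
        pts = mt.drop_duplicates(["species", "locality"])
        res = var_ms_correlation(pts["var"], pts["ms"])
        hits += res.r < 0
    assert hits >= 4
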