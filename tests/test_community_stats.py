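import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cutovir.community_stats import (
    DissimilarityMatrix,
    bray_curtis,
    bray_curtis_matrix,
    dispersion_test,
    enrich_features,
    indirect_effect,
    pcoa,
    pearson,
    permanova,
    pielou_evenness,
    plspm_fit,
    rarefy,
    shannon,
    wilcoxon_bh,
)


class TestDiversity:
    def test_shannon_uniform_closed_form(self):
        assert shannon([1, 1, 1, 1]) == pytest.approx(np.log(4))

    def test_shannon_single_taxon_zero(self):
        assert shannon([5, 0, 0]) == 0.0

    def test_shannon_matches_formula(self, rng):
        for _ in range(20):
            c = rng.integers(0, 50, size=12).astype(float)
            if c.sum() == 0:
                continue
            p = c[c > 0] / c.sum()
            assert shannon(c) == pytest.approx(-(p * np.log(p)).sum())

    def test_shannon_all_zero_errors(self):
        with pytest.raises(ValueError):
            shannon([0, 0])

    def test_pielou_uniform_is_one(self):
        assert pielou_evenness([3] * 10) == pytest.approx(1.0)

    def test_pielou_skewed_below_one(self):
        j = pielou_evenness([100, 1])
        assert j == pytest.approx(shannon([100, 1]) / np.log(2))
        assert j < 1.0

    def test_pielou_single_taxon_errors(self):
        with pytest.raises(ValueError):
            pielou_evenness([5, 0])


class TestRarefy:
    def test_full_depth_identity(self):
        c = np.array([5, 3, 2])
        assert list(rarefy(c, 10, seed=1)) == [5, 3, 2]

    def test_depth_one_unit_vector(self):
        out = rarefy([5, 3, 2], 1, seed=2)
        assert out.sum() == 1 and (out >= 0).all()

    def test_depth_exceeds_total_errors(self):
        with pytest.raises(ValueError):
            rarefy([1, 1], 3, seed=0)

    def test_proportions_preserved_in_expectation(self):
        c = np.array([400, 300, 200, 100])
        draws = np.array([rarefy(c, 100, seed=s) for s in range(1000)])
        expected = 100 * c / c.sum()
        se = np.sqrt(expected * (1 - c / c.sum()))  # binomial-scale bound
        assert np.all(np.abs(draws.mean(axis=0) - expected) < 3 * se / np.sqrt(1000))


class TestBrayCurtis:
    def test_identity_zero(self, rng):
        x = rng.random(10)
        assert bray_curtis(x, x) == 0.0

    def test_disjoint_supports_one(self):
        assert bray_curtis([1, 2, 0, 0], [0, 0, 3, 1]) == pytest.approx(1.0)

    def test_matches_formula(self, rng):
        for _ in range(20):
            x, y = rng.random(8), rng.random(8)
            want = np.abs(x - y).sum() / (x + y).sum()
            assert bray_curtis(x, y) == pytest.approx(want)

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(0, 100), min_size=3, max_size=10),
        st.lists(st.floats(0, 100), min_size=3, max_size=10),
    )
    def test_bounds_and_symmetry(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        if sum(x) + sum(y) == 0:
            return
        d = bray_curtis(x, y)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(bray_curtis(y, x))

    def test_both_zero_errors(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])


class TestPcoa:
    def test_two_points_recover_distance(self):
        dm = DissimilarityMatrix(["a", "b"], np.array([[0.0, 3.0], [3.0, 0.0]]))
        coords, eigvals = pcoa(dm)
        assert abs(coords.iloc[0, 0] - coords.iloc[1, 0]) == pytest.approx(3.0)

    def test_euclidean_configuration_recovered(self, rng):
        pts = rng.normal(size=(10, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        dm = DissimilarityMatrix([f"s{i}" for i in range(10)], d)
        coords, eigvals = pcoa(dm)
        # pairwise distances of the embedding reproduce the input
        d2 = np.linalg.norm(
            coords.values[:, None] - coords.values[None, :], axis=2
        )
        assert np.allclose(d2, d, atol=1e-9)

    def test_gower_eigenvalue_identity(self, rng):
        pts = rng.normal(size=(8, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        dm = DissimilarityMatrix([f"s{i}" for i in range(8)], d)
        _, eigvals = pcoa(dm)
        assert eigvals.sum() == pytest.approx((d**2).sum() / (2 * 8))

    def test_matrix_validation(self):
        with pytest.raises(ValueError):
            DissimilarityMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestPermanova:
    def test_separated_clouds_minimum_p(self, rng):
        a = rng.normal(0, 1, size=(10, 3))
        b = rng.normal(10, 1, size=(10, 3))
        pts = np.vstack([a, b])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        dm = DissimilarityMatrix([f"s{i}" for i in range(20)], d)
        f, r2, p = permanova(dm, ["a"] * 10 + ["b"] * 10, n_perm=199, seed=3)
        assert p == pytest.approx(1 / 200)
        assert 0.0 <= r2 <= 1.0

    def test_agrees_with_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        pts = rng.normal(size=(14, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ids = [f"s{i}" for i in range(14)]
        groups = ["a"] * 7 + ["b"] * 7
        f, _, _ = permanova(DissimilarityMatrix(ids, d), groups, n_perm=9, seed=0)
        sk = sk_permanova(skbio.DistanceMatrix(d, ids), grouping=groups, permutations=9)
        assert f == pytest.approx(sk["test statistic"], rel=1e-9)

    def test_degenerate_grouping_errors(self, rng):
        d = np.zeros((4, 4))
        dm = DissimilarityMatrix(list("abcd"), d)
        with pytest.raises(ValueError):
            permanova(dm, ["x", "x", "x", "y"], seed=0)


class TestDispersion:
    def test_scaled_group_detected(self, rng):
        a = rng.normal(0, 1, size=(30, 3))
        b = rng.normal(0, 3, size=(30, 3))
        pts = np.vstack([a, b])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        dm = DissimilarityMatrix([f"s{i}" for i in range(60)], d)
        f, p = dispersion_test(dm, ["a"] * 30 + ["b"] * 30, n_perm=199, seed=5)
        assert f >= 0
        assert p <= 0.01


class TestWilcoxonBh:
    def test_identical_groups_nothing_significant(self, rng):
        x = pd.DataFrame(rng.normal(size=(20, 10)))
        out = wilcoxon_bh(x, ["a"] * 10 + ["b"] * 10)
        assert (out["q"] >= 0.05).all()

    def test_large_shift_detected(self, rng):
        x = pd.DataFrame(rng.normal(size=(40, 5)))
        x.iloc[20:, 0] += 5.0
        out = wilcoxon_bh(x, ["a"] * 20 + ["b"] * 20)
        assert out["q"].iloc[0] < 0.05

    def test_constant_feature_flagged(self, rng):
        x = pd.DataFrame({"c": np.ones(8), "v": rng.normal(size=8)})
        out = wilcoxon_bh(x, ["a"] * 4 + ["b"] * 4)
        assert out.loc["c", "constant"] and out.loc["c", "p"] == 1.0

    def test_bh_stepup_property(self, rng):
        x = pd.DataFrame(rng.normal(size=(16, 12)))
        x.iloc[8:, :3] += 2.0
        out = wilcoxon_bh(x, ["a"] * 8 + ["b"] * 8).sort_values("p")
        assert (out["q"] >= out["p"] - 1e-12).all()
        # q is monotone along sorted p
        assert (np.diff(out["q"]) >= -1e-12).all()


class TestEnrich:
    def test_planted_tenfold_enrichment(self, rng):
        n = 30
        base = np.exp(rng.normal(0, 0.3, size=(2 * n, 6)))
        base[n:, 0] *= 10.0
        values = pd.DataFrame(base, columns=[f"f{i}" for i in range(6)])
        out = enrich_features(values, ["g1"] * n + ["g2"] * n)
        assert out.loc["f0", "enriched_group"] == "g2"

    def test_coefficient_sign_flips_with_labels(self, rng):
        values = pd.DataFrame(np.exp(rng.normal(size=(12, 4))))
        a = enrich_features(values, ["x"] * 6 + ["y"] * 6)
        b = enrich_features(values, ["y"] * 6 + ["x"] * 6)
        assert np.allclose(a["coefficient"], -b["coefficient"])


class TestPearson:
    def test_exact_cases(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson(x, x)[0] == pytest.approx(1.0)
        # constructed orthogonal contrast
        y = [1.0, -1.0, -1.0, 1.0]
        assert pearson(x, y)[0] == pytest.approx(0.0, abs=1e-12)

    def test_recovers_population_correlation(self):
        rng = np.random.default_rng(8)
        cov = [[1, 0.5], [0.5, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=10_000)
        r, _ = pearson(xy[:, 0], xy[:, 1])
        assert r == pytest.approx(0.5, abs=0.03)


class TestPlspm:
    def _blocks(self, rng, n=120, b1=0.5, b2=0.6, noise=0.5):
        xi_p = rng.normal(size=n)
        xi_b = b1 * xi_p + np.sqrt(1 - b1**2) * rng.normal(size=n)
        xi_v = b2 * xi_b + np.sqrt(1 - b2**2) * rng.normal(size=n)

        def block(xi, name):
            return pd.DataFrame(
                {f"{name}{i}": xi + noise * rng.normal(size=n) for i in range(3)}
            )

        return block(xi_p, "p"), block(xi_b, "b"), block(xi_v, "v")

    def test_identities_hold_exactly(self, rng):
        pm = plspm_fit(*self._blocks(rng), n_boot=0, seed=0)
        d = pm.direct
        assert pm.indirect[("PAH", "virus")] == pytest.approx(
            d[("PAH", "bacteria")] * d[("bacteria", "virus")], abs=1e-15
        )
        assert pm.total[("PAH", "virus")] == pytest.approx(
            d[("PAH", "virus")] + pm.indirect[("PAH", "virus")], abs=1e-15
        )

    def test_indirect_effect_worked_example(self):
        # printed direct coefficients multiply to the printed indirect one
        assert round(indirect_effect(0.24, 0.849), 2) == 0.20

    def test_null_paths_near_zero(self, rng):
        n = 150
        blocks = [
            pd.DataFrame(rng.normal(size=(n, 3)), columns=[f"{c}{i}" for i in range(3)])
            for c in "pbv"
        ]
        pm = plspm_fit(*blocks, n_boot=199, seed=4)
        for edge, (lo, hi) in pm.boot_ci.items():
            assert lo < 0.25 and hi > -0.25  # CIs straddle small effects

    def test_bootstrap_flags_real_paths(self, rng):
        pm = plspm_fit(*self._blocks(rng, n=200), n_boot=199, seed=2)
        assert pm.boot_p[("PAH", "bacteria")] < 0.05
        assert pm.boot_p[("bacteria", "virus")] < 0.05

    def test_index_mismatch_errors(self, rng):
        p, b, v = self._blocks(rng)
        v.index = [f"x{i}" for i in range(len(v))]
        with pytest.raises(ValueError):
            plspm_fit(p, b, v)


def test_end_to_end_qualitative_structure():
    """The default synthetic cohort reproduces the planted community
    structure: virome separation by cutotype (PERMANOVA p < 0.05),
    higher host Shannon diversity in the diverse group, and a positive
    PAH -> virus total effect mediated by the bacterial community."""
    from cutovir.abundance import build_abundance_matrix, normalize_depth
    from cutovir.synthetic_community import generate_cohort

    cohort = generate_cohort(15, 15, seed=606)
    matrix = normalize_depth(
        build_abundance_matrix(cohort.profiles, cohort.read_counts)
    )
    rel = matrix.values.div(matrix.values.sum(axis=1), axis=0)
    groups = [cohort.truth.cutotype_of_sample[s] for s in rel.index]
    host_ids = [h.id for h in cohort.hosts]
    virus_ids = [v.id for v in cohort.viruses]

    dm = bray_curtis_matrix(rel[virus_ids])
    _, _, p = permanova(dm, groups, n_perm=199, seed=1)
    assert p < 0.05

    sh = np.array([shannon(rel.loc[s, host_ids]) for s in rel.index])
    mask = np.array(groups) == 1
    assert sh[~mask].mean() > sh[mask].mean()

    bact_coords, _ = pcoa(bray_curtis_matrix(rel[host_ids]), n_axes=3)
    virus_coords, _ = pcoa(dm, n_axes=3)
    pm = plspm_fit(cohort.truth.pah_matrix, bact_coords, virus_coords,
                   n_boot=0, seed=2)
    assert pm.total[("PAH", "virus")] > 0
    assert pm.indirect[("PAH", "virus")] > 0


def test_bray_curtis_matrix_roundtrip(rng):
    table = pd.DataFrame(rng.random((5, 7)), index=[f"s{i}" for i in range(5)])
    dm = bray_curtis_matrix(table)
    assert dm.d[2, 3] == pytest.approx(bray_curtis(table.iloc[2], table.iloc[3]))
    assert np.allclose(dm.d, dm.d.T)
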