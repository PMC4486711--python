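"""Trait similarity, quasi-binomial fits, niche PCA and polyhedron overlap."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from sympatry.inference import back_transform
from sympatry.traits import (
    DegenerateNicheError,
    TraitProfile,
    climate_regression,
    inverse_logit,
    niche_polyhedron,
    overlap_multiple_regression,
    pca_correlation,
    polyhedron_overlap,
    quasibinomial_regression,
    trait_similarity,
)

CUBE = np.array(
    [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
     [1, 1, 0], [1, 0, 1], [0, 1, 1], [1, 1, 1]],
    dtype=float,
)


class TestTraitSimilarity:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"a", "b", "c"}, {"b", "c", "d", "e"}, 2 / 3),
            ({"a", "b"}, {"a", "b", "c", "d"}, 1.0),  # subset scores 1
            ({"a"}, {"b"}, 0.0),
        ],
    )
    def test_shared_over_smaller(self, a, b, expected):
        assert trait_similarity(a, b) == pytest.approx(expected)

    def test_symmetric(self):
        a, b = {"x", "y", "z"}, {"y", "q"}
        assert trait_similarity(a, b) == trait_similarity(b, a)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            trait_similarity(set(), {"a"})

    def test_profile_normalises_labels(self):
        p = TraitProfile("sp", mimicry_rings=frozenset({" Tiger ", "tiger"}))
        assert p.mimicry_rings == frozenset({"tiger"})


class TestInverseLogit:
    @pytest.mark.parametrize(
        "b, expected", [(-0.57, 0.36), (-0.01, 0.5), (0.0, 0.5)]
    )
    def test_printed_proportions(self, b, expected):
        assert round(inverse_logit(b), 2) == expected

    def test_inverse_of_logit(self):
        p = np.linspace(0.01, 0.99, 50)
        assert np.allclose(
            [inverse_logit(np.log(q / (1 - q))) for q in p], p, atol=1e-12
        )


class TestQuasiBinomial:
    def test_all_shared_flags_separation(self):
        y = np.full(10, 5)
        fit = quasibinomial_regression(y, y, np.linspace(1, 10, 10))
        assert fit.flag == "separation"
        assert np.isnan(fit.intercept)

    def test_recovers_known_coefficients(self, rng):
        n, denom = 500, 10
        t = rng.uniform(0.1, 10, n)
        p = 1 / (1 + np.exp(-(-0.5 + 0.05 * t)))
        x = rng.binomial(denom, p)
        # guard against the (vanishingly unlikely) degenerate draw
        fit = quasibinomial_regression(x, np.full(n, denom), t)
        assert fit.flag is None
        assert abs(fit.intercept - (-0.5)) < 3 * fit.intercept_se
        assert abs(fit.slope - 0.05) < 3 * fit.slope_se

    def test_quasi_correction_scales_only_ses(self, rng):
        """Overdispersed counts inflate SEs by sqrt(phi) but leave the
        coefficient point estimates at their binomial-GLM values."""
        n, denom = 300, 20
        t = rng.uniform(0.1, 10, n)
        base = -0.3 + 0.04 * t + rng.normal(0, 0.8, n)  # latent heterogeneity
        x = rng.binomial(denom, 1 / (1 + np.exp(-base)))
        fit = quasibinomial_regression(x, np.full(n, denom), t)
        assert fit.flag is None
        assert fit.dispersion > 1
        assert fit.intercept_se == pytest.approx(
            fit.intercept_se_naive * np.sqrt(fit.dispersion)
        )
        assert fit.slope_se == pytest.approx(
            fit.slope_se_naive * np.sqrt(fit.dispersion)
        )

    def test_back_transform_matches_inverse_logit(self, rng):
        t = rng.uniform(0.1, 10, 100)
        x = rng.binomial(8, 0.4, 100)
        fit = quasibinomial_regression(x, np.full(100, 8), t)
        assert fit.intercept_backtransformed == pytest.approx(
            inverse_logit(fit.intercept)
        )

    def test_shared_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            quasibinomial_regression([5, 5, 5], [4, 6, 6], [1, 2, 3])


class TestClimateRegression:
    def test_constant_overlaps_pin_intercept(self):
        overlaps = np.full(8, np.sin(1.0) ** 2)
        fit = climate_regression(overlaps, np.linspace(1, 8, 8))
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)
        assert fit.slope == pytest.approx(0.0, abs=1e-9)

    def test_recovers_slope_on_synthetic_angular_data(self, rng):
        t = rng.uniform(0.1, 10, 200)
        theta = np.clip(0.8 + 0.04 * t + rng.normal(0, 0.1, 200), 0, np.pi / 2)
        fit = climate_regression(np.sin(theta) ** 2, t)
        assert abs(fit.slope - 0.04) < 3 * fit.slope_se

    def test_full_overlap_at_domain_edge(self):
        fit = climate_regression([1.0, 0.9, 1.0, 0.8], [1, 2, 3, 4])
        assert np.isfinite(fit.intercept)


class TestMultipleRegression:
    def test_recovers_climate_coefficient(self, rng):
        n = 150
        bl = rng.uniform(0.1, 10, n)
        mim = rng.uniform(0, 1, n)
        host = rng.uniform(0, 1, n)
        clim = rng.uniform(0, 1, n)
        theta = np.clip(0.1 + 0.8 * clim + rng.normal(0, 0.1, n), 0, np.pi / 2)
        table = overlap_multiple_regression(np.sin(theta) ** 2, bl, mim, host, clim)
        row = table.loc["climatic_niche_overlap"]
        assert abs(row["coefficient"] - 0.8) < 3 * row["se"]
        assert list(table.index) == [
            "intercept", "branch_length", "mimicry_overlap",
            "host_plant_overlap", "climatic_niche_overlap",
        ]

    def test_no_residual_df_rejected(self, rng):
        with pytest.raises(ValueError):
            overlap_multiple_regression(
                [0.5] * 5, [1, 2, 3, 4, 5], [0.1] * 5, [0.2] * 5, [0.3] * 5
            )

    def test_collinear_predictors_warn(self, rng):
        n = 30
        bl = rng.uniform(0.1, 10, n)
        mim = rng.uniform(0, 1, n)
        y = rng.uniform(0.1, 0.9, n)
        with pytest.warns(UserWarning, match="rank deficient"):
            overlap_multiple_regression(y, bl, mim, mim, rng.uniform(0, 1, n))


class TestPCACorrelation:
    def test_perfectly_correlated_layers_load_on_pc1(self, rng):
        base = rng.standard_normal(500)
        layers = np.vstack([base, 2 * base + 7, -3 * base])
        res = pca_correlation(layers, n_components=3)
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_independent_layers_share_variance(self, rng):
        layers = rng.standard_normal((19, 20_000))
        res = pca_correlation(layers)
        assert np.all(np.abs(res.variance_explained - 1 / 19) < 0.02)

    def test_matches_covariance_of_standardised_data_oracle(self, rng):
        """Eigenvalues of the correlation matrix equal the variances of
        projections of the standardised data (independent SVD path)."""
        layers = rng.standard_normal((6, 300)) * np.arange(1, 7)[:, None]
        res = pca_correlation(layers, n_components=None)
        zs = (layers - layers.mean(axis=1, keepdims=True)) / layers.std(
            axis=1, ddof=1, keepdims=True
        )
        sv = np.linalg.svd(zs.T / np.sqrt(299), compute_uv=False)
        assert np.allclose(np.sort(sv**2), np.sort(res.eigenvalues), atol=1e-8)
        # full-rank reconstruction of the standardised data
        recon = res.scores @ res.loadings.T
        assert np.allclose(recon, zs.T, atol=1e-8)

    def test_constant_layer_named_in_error(self, rng):
        layers = rng.standard_normal((4, 100))
        layers[2] = 3.0
        with pytest.raises(ValueError, match=r"\[2\]"):
            pca_correlation(layers)


class TestNichePolyhedron:
    def test_unit_cube_volume(self):
        assert niche_polyhedron(CUBE).volume == pytest.approx(1.0)

    def test_interior_points_do_not_change_hull(self, rng):
        pts = np.vstack([CUBE, rng.uniform(0.1, 0.9, size=(50, 3))])
        assert niche_polyhedron(pts).volume == pytest.approx(1.0)

    def test_degenerate_sets_rejected(self):
        with pytest.raises(DegenerateNicheError):
            niche_polyhedron(CUBE[:3])
        coplanar = np.column_stack([np.random.rand(10, 2), np.zeros(10)])
        with pytest.raises(DegenerateNicheError):
            niche_polyhedron(coplanar)

    def test_hull_volume_matches_monte_carlo(self, rng):
        """Convex-hull volume agrees with rejection sampling within 2 %."""
        pts = rng.standard_normal((40, 3))
        poly = niche_polyhedron(pts)
        hull = ConvexHull(pts)
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        samples = rng.uniform(lo, hi, size=(200_000, 3))
        A, b = hull.equations[:, :-1], hull.equations[:, -1]
        inside = np.all(samples @ A.T + b <= 1e-12, axis=1)
        mc = inside.mean() * np.prod(hi - lo)
        assert poly.volume == pytest.approx(mc, rel=0.02)


class TestPolyhedronOverlap:
    def test_identical_cubes(self):
        p = niche_polyhedron(CUBE)
        assert polyhedron_overlap(p, p) == pytest.approx(1.0)

    def test_nested_cube(self):
        outer = niche_polyhedron(CUBE)
        inner = niche_polyhedron(0.25 + 0.5 * CUBE)
        assert polyhedron_overlap(outer, inner) == pytest.approx(1.0)

    def test_half_offset_cubes(self):
        a = niche_polyhedron(CUBE)
        b = niche_polyhedron(CUBE + np.array([0.5, 0, 0]))
        assert polyhedron_overlap(a, b) == pytest.approx(0.5)

    def test_disjoint_cubes(self):
        a = niche_polyhedron(CUBE)
        b = niche_polyhedron(CUBE + 5.0)
        assert polyhedron_overlap(a, b) == 0.0

    def test_touching_cubes_score_zero(self):
        a = niche_polyhedron(CUBE)
        b = niche_polyhedron(CUBE + np.array([1.0, 0, 0]))
        assert polyhedron_overlap(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_random_bodies_match_monte_carlo(self, rng):
        """Halfspace-intersection volume agrees with rejection sampling
        within 2 % on random convex bodies."""
        for _ in range(3):
            a = niche_polyhedron(rng.standard_normal((30, 3)))
            b = niche_polyhedron(rng.standard_normal((30, 3)) * 1.2 + 0.3)
            got = polyhedron_overlap(a, b)
            lo = np.minimum(a.vertices.min(0), b.vertices.min(0))
            hi = np.maximum(a.vertices.max(0), b.vertices.max(0))
            samples = rng.uniform(lo, hi, size=(400_000, 3))
            ha, hb = ConvexHull(a.vertices), ConvexHull(b.vertices)
            in_a = np.all(samples @ ha.equations[:, :-1].T + ha.equations[:, -1] <= 0, axis=1)
            in_b = np.all(samples @ hb.equations[:, :-1].T + hb.equations[:, -1] <= 0, axis=1)
            mc_vol = np.mean(in_a & in_b) * np.prod(hi - lo)
            expected = mc_vol / min(a.volume, b.volume)
            assert got == pytest.approx(expected, abs=max(0.02 * expected, 0.005))
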