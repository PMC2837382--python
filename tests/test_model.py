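"""Core model: marginal moments, likelihood, mixing-polygon diagnostic."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import linprog
from scipy.stats import norm

import isomix as im


def mc_moments(p, sources, tefs, conc, sigma, n=200_000, seed=0):
    """Monte-Carlo oracle: draw source and TEF values, form the mixture."""
    rng = np.random.default_rng(seed)
    K, J = sources.means.shape
    s = rng.normal(sources.means, sources.sds, size=(n, K, J))
    c = rng.normal(tefs.means, tefs.sds, size=(n, K, J))
    w = p.p[:, None] * conc.values
    mix = np.einsum("kj,nkj->nj", w, s + c) / w.sum(axis=0)
    return mix.mean(axis=0), mix.var(axis=0) + sigma.sigma ** 2


class TestMixtureMoments:
    def test_single_source_degenerate(self):
        """All diet from one source: mean/variance are that source's plus noise."""
        sources = im.SourceTable(("a", "b"), [[5.0], [99.0]], [[0.5], [3.0]])
        tefs = im.TEFTable([[1.0], [0.0]], [[0.2], [0.0]])
        p = im.ProportionVector([1.0, 0.0])
        mean, var = im.mixture_moments(
            p, sources, tefs, im.ConcentrationTable.ones(2, 1),
            im.ResidualScale([0.1]),
        )
        assert mean[0] == pytest.approx(6.0)
        assert var[0] == pytest.approx(0.25 + 0.04 + 0.01)

    def test_noise_free_midpoint(self):
        sources = im.SourceTable(("a", "b"), [[0.0], [10.0]], [[0.0], [0.0]])
        p = im.ProportionVector([0.5, 0.5])
        mean, var = im.mixture_moments(p, sources)
        assert mean[0] == pytest.approx(5.0)
        assert var[0] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("unequal_conc", [False, True])
    def test_against_monte_carlo(self, random_instance, seed, unequal_conc):
        """Analytic moments match direct simulation of the mixture."""
        p, sources, tefs, conc, sigma = random_instance(
            seed, unequal_conc=unequal_conc
        )
        mean, var = im.mixture_moments(p, sources, tefs, conc, sigma)
        mc_mean, mc_var = mc_moments(p, sources, tefs, conc, sigma, seed=seed)
        mix_sd = np.sqrt(np.maximum(var - sigma.sigma ** 2, 1e-30))
        n = 200_000
        assert np.all(np.abs(mean - mc_mean) <= 4 * mix_sd / np.sqrt(n) + 1e-12)
        assert np.allclose(var, mc_var, rtol=0.02)

    def test_variance_never_below_residual(self, random_instance):
        p, sources, tefs, conc, sigma = random_instance(7, unequal_conc=True)
        _, var = im.mixture_moments(p, sources, tefs, conc, sigma)
        assert np.all(var >= sigma.sigma ** 2)

    def test_dimension_mismatch_rejected(self, random_instance):
        p, sources, tefs, conc, sigma = random_instance(0)
        bad_p = im.ProportionVector([0.5, 0.5])
        with pytest.raises(ValueError, match="sources"):
            im.mixture_moments(bad_p, sources, tefs, conc, sigma)


class TestLogLikelihood:
    def _simple(self):
        sources = im.SourceTable(("a", "b"), [[0.0], [10.0]], [[1.0], [1.0]])
        p = im.ProportionVector([0.4, 0.6])
        sigma = im.ResidualScale([0.5])
        return sources, p, sigma

    def test_density_at_the_mean(self):
        sources, p, sigma = self._simple()
        mean, var = im.mixture_moments(p, sources, sigma=sigma)
        data = im.MixtureObservations([[mean[0]]])
        ll = im.log_likelihood(data, p, sigma, sources)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi * var[0]))

    def test_additive_over_consumers(self):
        sources, p, sigma = self._simple()
        one = im.MixtureObservations([[4.2]])
        two = im.MixtureObservations([[4.2], [4.2]])
        assert im.log_likelihood(two, p, sigma, sources) == pytest.approx(
            2 * im.log_likelihood(one, p, sigma, sources)
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_against_normal_pdf_oracle(self, random_instance, seed):
        """Likelihood equals summed normal log-pdfs at the analytic moments."""
        p, sources, tefs, conc, sigma = random_instance(seed, K=4, J=3,
                                                        unequal_conc=True)
        rng = np.random.default_rng(100 + seed)
        data = im.MixtureObservations(rng.normal(0, 5, size=(6, 3)))
        mean, var = im.mixture_moments(p, sources, tefs, conc, sigma)
        expected = norm.logpdf(data.values, loc=mean, scale=np.sqrt(var)).sum()
        got = im.log_likelihood(data, p, sigma, sources, tefs, conc)
        assert got == pytest.approx(expected)

    def test_zero_variance_off_mean_is_degenerate(self):
        sources = im.SourceTable(("a", "b"), [[0.0], [10.0]], [[0.0], [0.0]])
        p = im.ProportionVector([0.5, 0.5])
        data = im.MixtureObservations([[6.0]])
        with pytest.raises(im.DegenerateLikelihoodError):
            im.log_likelihood(data, p, im.ResidualScale([0.0]), sources)

    def test_source_relabeling_invariance(self, random_instance):
        """Permuting sources together with p leaves the likelihood unchanged."""
        p, sources, tefs, conc, sigma = random_instance(3, K=4, J=2,
                                                        unequal_conc=True)
        rng = np.random.default_rng(33)
        data = im.MixtureObservations(rng.normal(0, 5, size=(5, 2)))
        perm = np.array([2, 0, 3, 1])
        p2 = im.ProportionVector(p.p[perm])
        s2 = im.SourceTable(tuple(sources.source_names[i] for i in perm),
                            sources.means[perm], sources.sds[perm])
        t2 = im.TEFTable(tefs.means[perm], tefs.sds[perm])
        c2 = im.ConcentrationTable(conc.values[perm])
        assert im.log_likelihood(data, p, sigma, sources, tefs, conc) == \
            pytest.approx(im.log_likelihood(data, p2, sigma, s2, t2, c2))

    def test_zero_tefs_equal_omitted_tefs(self, random_instance):
        """Zero-mean, zero-SD TEFs have no bearing on the likelihood."""
        p, sources, _tefs, conc, sigma = random_instance(5)
        rng = np.random.default_rng(55)
        data = im.MixtureObservations(rng.normal(0, 5, size=(5, 2)))
        with_zeros = im.log_likelihood(
            data, p, sigma, sources, im.TEFTable.zeros(3, 2), conc
        )
        without = im.log_likelihood(data, p, sigma, sources, None, conc)
        assert with_zeros == without

    @given(st.floats(-5, 5), st.integers(0, 10))
    def test_tef_offset_shifts_mean(self, shift, seed):
        """A constant TEF offset on one isotope translates that isotope's mean."""
        rng = np.random.default_rng(seed)
        K, J = 3, 2
        p = im.ProportionVector(rng.dirichlet(np.ones(K)))
        sources = im.SourceTable(
            ("a", "b", "c"), rng.normal(0, 10, (K, J)),
            np.abs(rng.normal(0, 2, (K, J))),
        )
        base = im.TEFTable(rng.normal(0, 1, (K, J)), np.zeros((K, J)))
        shifted = im.TEFTable(base.means + np.array([shift, 0.0]), base.sds)
        m0, v0 = im.mixture_moments(p, sources, base)
        m1, v1 = im.mixture_moments(p, sources, shifted)
        np.testing.assert_allclose(m1 - m0, [shift, 0.0], atol=1e-9)
        np.testing.assert_allclose(v1, v0)

    @given(st.floats(0.01, 100), st.integers(0, 10))
    def test_concentration_column_scaling_invariance(self, factor, seed):
        """Rescaling one isotope's concentrations leaves the moments unchanged."""
        rng = np.random.default_rng(seed)
        K, J = 3, 2
        p = im.ProportionVector(rng.dirichlet(np.ones(K)))
        sources = im.SourceTable(
            ("a", "b", "c"), rng.normal(0, 10, (K, J)),
            np.abs(rng.normal(0, 2, (K, J))),
        )
        conc = im.ConcentrationTable(rng.uniform(0.1, 1.0, (K, J)))
        scaled = conc.values.copy()
        scaled[:, 1] *= factor
        m0, v0 = im.mixture_moments(p, sources, conc=conc)
        m1, v1 = im.mixture_moments(p, sources,
                                    conc=im.ConcentrationTable(scaled))
        np.testing.assert_allclose(m1, m0, rtol=1e-12)
        np.testing.assert_allclose(v1, v0, rtol=1e-12)


def lp_inside(point, vertices):
    """Independent feasibility oracle: convex weights reproducing the point."""
    K = vertices.shape[0]
    res = linprog(
        np.zeros(K),
        A_eq=np.vstack([vertices.T, np.ones(K)]),
        b_eq=np.append(point, 1.0),
        bounds=[(0, 1)] * K,
        method="highs",
    )
    return res.status == 0


class TestMixingPolygon:
    def _triangle(self):
        return im.SourceTable(
            ("a", "b", "c"),
            np.array([[-5.0, -5.0], [5.0, -5.0], [0.0, 5.0]]),
            np.full((3, 2), 0.5),
        )

    def test_centroid_inside(self):
        sources = self._triangle()
        centroid = sources.means.mean(axis=0)
        data = im.MixtureObservations(centroid[None, :])
        assert im.mixing_polygon_check(data, sources).all()

    def test_point_beyond_all_sources_outside(self):
        sources = self._triangle()
        data = im.MixtureObservations([[50.0, 0.0]])
        assert not im.mixing_polygon_check(data, sources).any()

    def test_tef_correction_moves_polygon(self):
        sources = self._triangle()
        tefs = im.TEFTable(np.full((3, 2), 100.0), np.zeros((3, 2)))
        data = im.MixtureObservations([[0.0, 0.0]])
        assert im.mixing_polygon_check(data, sources).all()
        assert not im.mixing_polygon_check(data, sources, tefs).any()

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_lp_feasibility_oracle(self, seed):
        rng = np.random.default_rng(seed)
        K = rng.integers(3, 7)
        sources = im.SourceTable(
            tuple(f"s{k}" for k in range(K)),
            rng.normal(0, 5, size=(K, 2)), np.ones((K, 2)),
        )
        pts = rng.normal(0, 5, size=(12, 2))
        data = im.MixtureObservations(pts)
        got = im.mixing_polygon_check(data, sources)
        want = [lp_inside(x, sources.means) for x in pts]
        assert list(got) == want

    def test_collinear_sources_fall_back_with_warning(self):
        sources = im.SourceTable(
            ("a", "b", "c"),
            np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]),
            np.ones((3, 2)),
        )
        data = im.MixtureObservations([[1.0, 1.0], [1.0, 0.0]])
        with pytest.warns(UserWarning, match="degenerate"):
            got = im.mixing_polygon_check(data, sources)
        assert list(got) == [True, False]

    def test_one_isotope_interval(self):
        sources = im.SourceTable(("a", "b"), [[0.0], [10.0]], [[1.0], [1.0]])
        data = im.MixtureObservations([[5.0], [-1.0], [10.0]])
        got = im.mixing_polygon_check(data, sources)
        assert list(got) == [True, False, True]


class TestDomainTypes:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            im.ProportionVector([0.5, 0.4])

    def test_negative_source_sd_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            im.SourceTable(("a", "b"), [[0.0], [1.0]], [[-0.1], [1.0]])

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            im.ConcentrationTable([[0.5], [0.0]])

    def test_label_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="isotope_names"):
            im.MixtureObservations([[1.0, 2.0]], isotope_names=("x",))
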