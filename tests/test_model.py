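"""Model assembly, Gibbs sampler correctness, posterior summaries.

The sampler is checked against independent oracles: a direct dense
mixed-model-equation solve (BLUP) with covariances frozen, and a
grid-search REML on an order-0 half-sib design.
"""

import numpy as np
import pandas as pd
import pytest

from reactnorm.basis import GradientScale
from reactnorm.model import (
    InsufficientSampleError,
    MCMCConfig,
    ModelSpec,
    FitResult,
    assemble,
    credible_interval,
    fit_mcmc,
    map_estimate,
    predict_additive,
    r_squared,
)
from reactnorm.pedigree import Pedigree, build_A
from reactnorm.simulate import EffectRanges, simulate_dataset


# ---------------------------------------------------------------------------
# posterior summaries


class TestMapEstimate:
    def test_constant_draws(self):
        assert map_estimate(np.full(200, 3.25)) == 3.25

    def test_standard_normal_mode(self, rng):
        draws = rng.standard_normal(20_000)
        assert abs(map_estimate(draws)) < 0.1

    def test_bimodal_prefers_heavy_branch(self, rng):
        draws = np.concatenate(
            [rng.normal(-1, 0.1, 900), rng.normal(1, 0.1, 100)]
        )
        assert map_estimate(draws) == pytest.approx(-1.0, abs=0.2)

    def test_too_few_draws(self):
        with pytest.raises(InsufficientSampleError):
            map_estimate(np.arange(10))


class TestCredibleInterval:
    def test_constant_draws_zero_width(self):
        lo, hi = credible_interval(np.full(150, 2.0))
        assert lo == hi == 2.0

    def test_standard_normal_quantiles(self, rng):
        lo, hi = credible_interval(rng.standard_normal(100_000))
        assert lo == pytest.approx(-1.96, abs=0.1)
        assert hi == pytest.approx(1.96, abs=0.1)

    def test_half_level_uniform(self, rng):
        lo, hi = credible_interval(rng.uniform(0, 1, 100_000), level=0.5)
        assert lo == pytest.approx(0.25, abs=0.02)
        assert hi == pytest.approx(0.75, abs=0.02)

    def test_too_few_draws(self):
        with pytest.raises(InsufficientSampleError):
            credible_interval(np.arange(50))


# ---------------------------------------------------------------------------
# assembly


def _toy_data(ped, n_per=2, order_x=(-1.0, 1.0), seed=0, trait="y"):
    rng = np.random.default_rng(seed)
    ids = [i for i in ped.ids if i.startswith(("P", "H", "o", "h"))]
    rows = []
    for i in ids:
        for _ in range(n_per):
            rows.append(
                {
                    "tree_id": i,
                    "site": "S1",
                    "covariate": rng.uniform(*order_x),
                    trait: rng.normal(),
                }
            )
    return pd.DataFrame(rows)


class TestAssemble:
    def test_order_zero_single_site_fixed_design(self):
        ds = simulate_dataset(target_h2=0.5, family_size=2, n_loci=4, seed=0)
        m = assemble(ds.phenotypes(), ds.pedigree(), ModelSpec(order=0, traits=("y",)))
        assert m.W.shape[1] == 1
        np.testing.assert_allclose(m.W[:, 0], 1.0)

    def test_pure_mode_dimensions(self):
        ds = simulate_dataset(target_h2=0.5, family_size=2, n_loci=4, seed=0)
        spec = ModelSpec(order=1, traits=("y",))
        m = assemble(ds.phenotypes(), ds.pedigree(), spec)
        assert spec.k == 2
        assert m.parent_idx.size == 10          # the diallel founders
        assert m.term_idx.size == ds.n_progeny

    def test_hybrid_mode_contribution_dimensions(self):
        recs = [(f"e{i}", None, None, "EL") for i in range(9)]
        recs += [(f"j{i}", None, None, "JL") for i in range(9)]
        k = 0
        rows = []
        rng = np.random.default_rng(1)
        for i in range(9):
            for j in range(9):
                recs.append((f"h{k}", f"e{i}", f"j{j}", "HL"))
                rows.append(
                    {
                        "tree_id": f"h{k}",
                        "site": "S1",
                        "covariate": rng.uniform(-1, 1),
                        "y": rng.normal(),
                    }
                )
                k += 1
        ped = Pedigree.from_records(recs)
        spec = ModelSpec(order=1, traits=("y",), taxon_mode="hybrid")
        m = assemble(pd.DataFrame(rows), ped, spec)
        # 9 parents x 2 coefficients per parental side
        assert len(m.inc.e_parents) * spec.k == 18
        assert len(m.inc.j_parents) * spec.k == 18

    def test_unknown_individual_rejected(self):
        ds = simulate_dataset(target_h2=0.5, family_size=2, n_loci=4, seed=0)
        data = ds.phenotypes()
        data.loc[0, "tree_id"] = "nobody"
        with pytest.raises(Exception, match="nobody"):
            assemble(data, ds.pedigree(), ModelSpec(order=0, traits=("y",)))

    def test_hybrid_records_in_pure_mode_rejected(self, diallel_pedigree):
        data = _toy_data(diallel_pedigree, n_per=1)
        with pytest.raises(ValueError, match="hybrid"):
            assemble(data, diallel_pedigree, ModelSpec(order=0, traits=("y",)))

    def test_repeated_records_need_permanent_term(self):
        ds = simulate_dataset(
            target_h2=0.5, family_size=2, n_loci=4,
            records_per_individual=2, seed=0,
        )
        with pytest.raises(ValueError, match="permanent"):
            assemble(ds.phenotypes(), ds.pedigree(), ModelSpec(order=0, traits=("y",)))


# ---------------------------------------------------------------------------
# sampler vs oracles


def _blup_oracle(data, ped, spec, scale, Sigma_A, sigma2):
    """Direct dense mixed-model-equations solve (independent of the sampler)."""
    A = build_A(ped).matrix
    q = ped.n
    k = spec.k
    x = data["covariate"].to_numpy()
    xs = 2 * (x - scale.min_x) / (scale.max_x - scale.min_x) - 1
    Z_rows = np.column_stack([np.ones_like(xs), xs])[:, : k]
    n = len(data)
    W = Z_rows.copy()  # single site, fixed curve
    Z = np.zeros((n, q * k))
    for r, tid in enumerate(data["tree_id"]):
        i = ped.index(tid)
        Z[r, i * k : (i + 1) * k] = Z_rows[r]
    X = np.hstack([W, Z])
    C = X.T @ X / sigma2
    prior = np.kron(np.linalg.inv(A), np.linalg.inv(Sigma_A))
    C[k:, k:] += prior
    rhs = X.T @ data["y"].to_numpy() / sigma2
    sol = np.linalg.solve(C, rhs)
    return sol[:k], sol[k:].reshape(q, k)


class TestSamplerOracles:
    def test_location_gibbs_matches_blup(self):
        # covariances frozen to truth: posterior mean of effects must equal
        # the direct mixed-model-equation solution
        ds = simulate_dataset(target_h2=0.6, family_size=4, n_founders=4,
                              n_loci=20, seed=3)
        data, ped = ds.phenotypes(), ds.pedigree()
        spec = ModelSpec(order=1, traits=("y",))
        m = assemble(data, ped, spec)
        Sigma_A = np.array([[40.0, 5.0], [5.0, 15.0]])
        sigma2 = 30.0
        fit = fit_mcmc(
            m,
            MCMCConfig(20500, 500, 1, seed=5),
            fix_Sigma_A=Sigma_A,
            fix_sigma2=[sigma2],
            store_effects="all",
        )
        beta_blup, u_blup = _blup_oracle(data, ped, spec, m.scale, Sigma_A, sigma2)

        def batch_se(draws):  # batch means absorb the chain autocorrelation
            B = 20
            bm = draws.reshape(B, -1, *draws.shape[1:]).mean(axis=1)
            return bm.std(axis=0) / np.sqrt(B)

        beta_mean = fit.draws["beta"].mean(axis=0)
        np.testing.assert_array_less(
            np.abs(beta_mean - beta_blup),
            2 * batch_se(fit.draws["beta"]) + 1e-9,
        )
        u_mean = fit.draws["u"].mean(axis=0)
        assert np.all(
            np.abs(u_mean - u_blup) < 2.5 * batch_se(fit.draws["u"]) + 1e-9
        )

    def test_order0_variance_components_match_grid_reml(self):
        # balanced half-sib design, flat norms; REML by eigendecomposition
        rng = np.random.default_rng(12)
        n_sires, n_prog = 50, 20
        s2a_true, s2e_true = 30.0, 70.0
        recs = [(f"s{i}", None, None, "") for i in range(n_sires)]
        rows = []
        sire_bv = rng.normal(0, np.sqrt(s2a_true), n_sires)
        kidx = 0
        for i in range(n_sires):
            for _ in range(n_prog):
                bv = 0.5 * sire_bv[i] + rng.normal(0, np.sqrt(0.75 * s2a_true))
                recs.append((f"p{kidx}", f"s{i}", None, ""))
                rows.append(
                    {
                        "tree_id": f"p{kidx}",
                        "site": "S1",
                        "covariate": rng.uniform(-1, 1),
                        "y": 10.0 + bv + rng.normal(0, np.sqrt(s2e_true)),
                    }
                )
                kidx += 1
        data, ped = pd.DataFrame(rows), Pedigree.from_records(recs)
        m = assemble(data, ped, ModelSpec(order=0, traits=("y",)))
        fit = fit_mcmc(m, MCMCConfig(6000, 1500, 5, seed=7))
        s2a_mcmc = map_estimate(fit.draws["Sigma_A"][:, 0, 0])

        # independent REML: V = s2a * Z A Z' + s2e * I, profile on a 2-D grid
        A = build_A(ped).matrix
        ids = [ped.index(t) for t in data["tree_id"]]
        Z = np.zeros((len(ids), ped.n))
        Z[np.arange(len(ids)), ids] = 1.0
        w, U = np.linalg.eigh(Z @ A @ Z.T)
        y = data["y"].to_numpy()
        yt, Xt = U.T @ y, U.T @ np.ones((len(y), 1))

        def reml_ll(sa, se):
            lam = sa * w + se
            XtVX = (Xt / lam[:, None]).T @ Xt
            beta = (Xt / lam[:, None]).T @ yt / XtVX[0, 0]
            r = yt - Xt[:, 0] * beta
            return -0.5 * (
                np.sum(np.log(lam)) + np.log(XtVX[0, 0]) + np.sum(r**2 / lam)
            )

        grid_a = np.linspace(5, 120, 80)
        grid_e = np.linspace(20, 150, 80)
        ll = np.array([[reml_ll(sa, se) for se in grid_e] for sa in grid_a])
        ia, ie = np.unravel_index(np.argmax(ll), ll.shape)
        s2a_reml = grid_a[ia]
        assert s2a_mcmc == pytest.approx(s2a_reml, rel=0.15)

    def test_null_additive_variance_detected(self):
        # unrelated founders, one record each, zero additive variance:
        # the additive MAP must stay a small fraction of the residual
        rng = np.random.default_rng(4)
        n = 500
        recs = [(f"f{i}", None, None, "") for i in range(n)]
        rows = [
            {"tree_id": f"f{i}", "site": "S1", "covariate": rng.uniform(-1, 1),
             "y": rng.normal(0.0, 1.0)}
            for i in range(n)
        ]
        with pytest.warns(UserWarning, match="weakly identifiable"):
            m = assemble(
                pd.DataFrame(rows), Pedigree.from_records(recs),
                ModelSpec(order=0, traits=("y",)),
            )
        fit = fit_mcmc(m, MCMCConfig(4000, 1000, 5, seed=2))
        s2a = map_estimate(fit.draws["Sigma_A"][:, 0, 0])
        s2r = map_estimate(fit.draws["sigma2"][:, 0])
        assert s2a < 0.1 * s2r


# ---------------------------------------------------------------------------
# chain mechanics


@pytest.fixture(scope="module")
def small_fit():
    ds = simulate_dataset(target_h2=0.6, family_size=4, n_founders=6,
                          n_loci=20, seed=17)
    m = assemble(ds.phenotypes(), ds.pedigree(), ModelSpec(order=1, traits=("y",)))
    cfg = MCMCConfig(2000, 500, 5, seed=77)
    return ds, m, cfg, fit_mcmc(m, cfg)


class TestChains:
    def test_seed_determinism(self, small_fit):
        ds, m, cfg, fit = small_fit
        again = fit_mcmc(m, cfg)
        np.testing.assert_array_equal(fit.draws["Sigma_A"], again.draws["Sigma_A"])
        np.testing.assert_array_equal(fit.draws["u"], again.draws["u"])

    def test_draw_count(self, small_fit):
        _, _, cfg, fit = small_fit
        assert fit.n_draws == (cfg.iterations - cfg.burn_in) // cfg.thinning

    def test_covariance_draws_psd(self, small_fit):
        *_, fit = small_fit
        eig = np.linalg.eigvalsh(fit.draws["Sigma_A"])
        assert eig.min() >= -1e-8

    def test_config_validation(self):
        with pytest.raises(ValueError, match="burn_in"):
            MCMCConfig(100, 100, 1)
        with pytest.raises(ValueError, match="thinning"):
            MCMCConfig(100, 10, 0)

    def test_short_chain_warns(self):
        with pytest.warns(UserWarning, match="retained draws"):
            MCMCConfig(200, 100, 10)


class TestPredictAdditive:
    @staticmethod
    def _manual_fit(u_draws, order=1):
        spec = ModelSpec(order=order, traits=("y",))
        D = u_draws.shape[0]
        return FitResult(
            spec=spec,
            scale=GradientScale(-1.0, 1.0),
            config=MCMCConfig(2000, 1000, (2000 - 1000) // D, seed=0),
            sites=["S1"],
            stored_ids=["F0"],
            draws={
                "u": u_draws,
                "beta": np.zeros((D, order + 1)),
                "sigma2": np.ones((D, 1)),
                "Sigma_A": np.tile(np.eye(order + 1), (D, 1, 1)),
            },
            u_mean=None,
            p_mean=None,
            ped_ids=["F0"],
        )

    def test_zero_coefficients_zero_everywhere(self):
        fit = self._manual_fit(np.zeros((200, 1, 2)))
        for x in (-1.0, 0.2, 1.0):
            assert np.all(predict_additive(fit, "F0", x) == 0.0)

    def test_order_zero_constant_in_x(self, rng):
        draws = rng.normal(size=(200, 1, 1))
        fit = self._manual_fit(draws, order=0)
        a = predict_additive(fit, "F0", -0.7)
        b = predict_additive(fit, "F0", 0.9)
        np.testing.assert_array_equal(a, b)

    def test_midpoint_returns_intercept(self, rng):
        draws = rng.normal(size=(200, 1, 2))
        fit = self._manual_fit(draws)
        np.testing.assert_allclose(
            predict_additive(fit, "F0", 0.0), draws[:, 0, 0]
        )

    def test_unknown_individual(self, small_fit):
        *_, fit = small_fit
        with pytest.raises(KeyError):
            fit.coefficient_draws("P999999")


class TestRSquared:
    def test_near_perfect_fit_without_noise(self):
        ds = simulate_dataset(target_h2=1.0, family_size=20, n_loci=20, seed=23)
        m = assemble(ds.phenotypes(), ds.pedigree(), ModelSpec(order=2, traits=("y",)))
        fit = fit_mcmc(m, MCMCConfig(2000, 500, 5, seed=3))
        assert r_squared(fit)["total"] > 0.97

    def test_pure_noise_intercept_only(self):
        # family-structured pedigree, phenotypes pure noise: nothing to explain
        ds = simulate_dataset(target_h2=0.5, family_size=20, n_loci=10, seed=41)
        data = ds.phenotypes()
        rng = np.random.default_rng(9)
        data["y"] = rng.normal(size=len(data))
        m = assemble(data, ds.pedigree(), ModelSpec(order=0, traits=("y",)))
        fit = fit_mcmc(m, MCMCConfig(2000, 500, 5, seed=4))
        assert r_squared(fit)["total"] == pytest.approx(0.0, abs=0.05)

    def test_constructed_fixed_share(self):
        # two sites whose mean difference contributes half the variance
        rng = np.random.default_rng(31)
        n = 5000
        recs = [(f"f{i}", None, None, "") for i in range(n)]
        rows = []
        for i in range(n):
            site = "SA" if i % 2 == 0 else "SS"
            mu = 1.0 if site == "SA" else -1.0  # Var(site term) = 1
            rows.append(
                {"tree_id": f"f{i}", "site": site,
                 "covariate": rng.uniform(-1, 1),
                 "y": mu + rng.normal(0.0, 1.0)}
            )
        with pytest.warns(UserWarning, match="weakly identifiable"):
            m = assemble(pd.DataFrame(rows), Pedigree.from_records(recs),
                         ModelSpec(order=0, traits=("y",)))
        fit = fit_mcmc(m, MCMCConfig(2000, 500, 5, seed=6))
        assert r_squared(fit)["fixed"] == pytest.approx(0.5, abs=0.05)


class TestBivariate:
    def test_two_trait_fit_recovers_residual_variances(self):
        # independent traits with distinct residual variances
        ds = simulate_dataset(target_h2=0.6, family_size=6, n_founders=6,
                              n_loci=20, seed=29)
        data = ds.phenotypes().rename(columns={"y": "t1"})
        rng = np.random.default_rng(2)
        data["t2"] = rng.normal(0.0, 3.0, len(data))
        m = assemble(data, ds.pedigree(), ModelSpec(order=1, traits=("t1", "t2")))
        fit = fit_mcmc(m, MCMCConfig(3000, 1000, 5, seed=8))
        s2 = fit.draws["sigma2"].mean(axis=0)
        assert s2[1] == pytest.approx(9.0, rel=0.25)
        assert fit.draws["Sigma_A"].shape[1:] == (4, 4)

    def test_missing_trait_values_allowed(self):
        ds = simulate_dataset(target_h2=0.6, family_size=4, n_founders=4,
                              n_loci=10, seed=31)
        data = ds.phenotypes().rename(columns={"y": "t1"})
        data["t2"] = data["t1"] * 0.5
        data.loc[data.index[::2], "t2"] = np.nan
        m = assemble(data, ds.pedigree(), ModelSpec(order=0, traits=("t1", "t2")))
        fit = fit_mcmc(m, MCMCConfig(1000, 200, 4, seed=9))
        assert fit.n_draws == 200
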