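"""Design construction, Gibbs-sampler components, and evidence summaries."""

import numpy as np
import pytest
from scipy.stats import chisquare

from glvnet import (
    GLVModelError,
    GLVParameters,
    MCMCConfig,
    NoiseModel,
    PosteriorSamples,
    PriorHyperparameters,
    SpeciesSet,
    SpikeSlabGLV,
    Trajectory,
    bayes_factors,
    build_design,
    generate_dataset,
    make_knockdown_design,
    preset_engineered_network,
    run_mcmc,
    simulate,
    summarize_network,
)
from glvnet.inference import (
    RegressionDesign,
    sample_coefficients,
    sample_indicators,
    sample_variances,
)
from glvnet.synth import DEFAULT_SPECIES


def _toy_trajectory(times, abund, species=("A", "B"), **kw):
    return Trajectory(times=np.asarray(times, dtype=float),
                      abundances=np.asarray(abund, dtype=float),
                      species=species, **kw)


class TestBuildDesign:
    def test_row_count_t_minus_one(self):
        tr = _toy_trajectory(np.arange(6.0), np.full((6, 2), 1e6))
        d = build_design([tr])
        assert all(len(d.y[i]) == 5 for i in range(2))

    def test_hand_computed_covariates(self):
        # one Euler step: x(0) = (2e6, 3e6), dt = 2
        tr = _toy_trajectory([0.0, 2.0], [[2e6, 3e6], [2.5e6, 2.9e6]])
        d = build_design([tr])
        row = d.X[0][0]
        assert row[0] == pytest.approx(2e6 * 2.0)  # growth column x_i*dt
        assert row[1] == pytest.approx(2e6 * 2e6 * 2.0)  # x_i*x_A*dt
        assert row[2] == pytest.approx(2e6 * 3e6 * 2.0)  # x_i*x_B*dt
        assert d.y[0][0] == pytest.approx(0.5e6)
        assert d.delta[0][0] == 2.0

    def test_higher_order_columns(self):
        tr = _toy_trajectory(np.arange(3.0), np.full((3, 2), 1e6))
        assert build_design([tr]).n_columns == 3
        d = build_design([tr], higher_order=True)
        assert d.n_columns == 5
        # 3rd-order column: x_i * prod_{j != i} x_j * dt
        assert d.X[0][0, 3] == pytest.approx(1e6 * 1e6)
        # 4th-order column: x_i * prod_j x_j * dt
        assert d.X[0][0, 4] == pytest.approx(1e6 * 1e6 * 1e6)

    def test_censored_rows_dropped_by_default(self):
        cens = np.zeros((4, 2), dtype=bool)
        cens[1, 0] = True  # censors rows (0,1) and (1,2) for species 0
        tr = _toy_trajectory(np.arange(4.0), np.full((4, 2), 1e6),
                             censored=cens)
        d = build_design([tr])
        assert len(d.y[0]) == 1
        assert len(d.y[1]) == 3
        keep = build_design([tr], floor_policy="keep")
        assert len(keep.y[0]) == 3

    def test_all_rows_invalid_raises(self):
        tr = _toy_trajectory(np.arange(3.0), np.zeros((3, 2)))
        with pytest.raises(GLVModelError):
            build_design([tr])

    def test_mismatched_species_rejected(self):
        a = _toy_trajectory(np.arange(3.0), np.full((3, 2), 1.0))
        b = _toy_trajectory(np.arange(3.0), np.full((3, 2), 1.0),
                            species=("B", "A"))
        with pytest.raises(GLVModelError):
            build_design([a, b])


def _empty_design(p_species=1):
    sp = tuple("AB"[:p_species])
    ncol = 1 + p_species
    return RegressionDesign(
        species=sp,
        X=[np.empty((0, ncol)) for _ in sp],
        y=[np.empty(0) for _ in sp],
        delta=[np.empty(0) for _ in sp],
    )


class TestSampleCoefficients:
    def test_empty_design_draws_from_prior(self):
        d = _empty_design(1)
        rng = np.random.default_rng(0)
        z = np.ones((1, 1), dtype=int)
        rs, selfs = [], []
        for _ in range(20000):
            r, a, _ = sample_coefficients(d, z, 0.25, 1e-18, np.array([1.0]), rng)
            rs.append(r[0])
            selfs.append(a[0, 0])
        rs, selfs = np.array(rs), np.array(selfs)
        assert rs.mean() == pytest.approx(0.0, abs=3 * 0.5 / np.sqrt(len(rs)))
        assert rs.var() == pytest.approx(0.25, rel=0.05)
        assert selfs.var() == pytest.approx(1e-18, rel=0.05)

    def test_one_parameter_conjugate_posterior(self):
        # single active column (growth rate); self-interaction column zeroed
        n, v_w, v_r = 30, 4.0, 2.25
        rng_data = np.random.default_rng(1)
        x = rng_data.uniform(1.0, 2.0, n)
        beta_true = 0.7
        y = beta_true * x + rng_data.normal(0, np.sqrt(v_w), n)
        d = RegressionDesign(
            species=("A",),
            X=[np.column_stack([x, np.zeros(n)])],
            y=[y],
            delta=[np.ones(n)],
        )
        prec = x @ x / v_w + 1.0 / v_r
        mean = (x @ y / v_w) / prec
        rng = np.random.default_rng(2)
        z = np.ones((1, 1), dtype=int)
        draws = np.array([
            sample_coefficients(d, z, v_r, 1e-6, np.array([v_w]), rng)[0][0]
            for _ in range(20000)
        ])
        se = np.sqrt(1.0 / prec / len(draws))
        assert draws.mean() == pytest.approx(mean, abs=3 * se)
        assert draws.var() == pytest.approx(1.0 / prec, rel=0.05)

    def test_masked_coefficient_independent_of_data(self):
        # edge B->A masked: its draws follow the prior regardless of data
        rng_data = np.random.default_rng(3)
        x = rng_data.uniform(1e6, 2e6, (10, 2))
        d = RegressionDesign(
            species=("A", "B"),
            X=[np.column_stack([x[:, 0], x[:, 0] ** 2, x[:, 0] * x[:, 1]]),
               np.column_stack([x[:, 1], x[:, 0] * x[:, 1], x[:, 1] ** 2])],
            y=[rng_data.normal(0, 1e5, 10), rng_data.normal(0, 1e5, 10)],
            delta=[np.ones(10), np.ones(10)],
        )
        z = np.array([[1, 0], [0, 1]])
        v_a = 1e-16
        rng = np.random.default_rng(4)
        draws = np.array([
            sample_coefficients(d, z, 1.0, v_a, np.array([1e10, 1e10]), rng)[1][0, 1]
            for _ in range(20000)
        ])
        assert draws.mean() == pytest.approx(
            0.0, abs=3 * np.sqrt(v_a / len(draws)))
        assert draws.var() == pytest.approx(v_a, rel=0.05)


class TestSampleIndicators:
    def test_zero_covariate_column_keeps_prior_probability(self):
        # species B never interacts with an always-zero species A column
        n = 8
        d = RegressionDesign(
            species=("A", "B"),
            X=[np.zeros((0, 3)), np.column_stack(
                [np.full(n, 1e6), np.zeros(n), np.full(n, 1e12)])],
            y=[np.empty(0), np.random.default_rng(0).normal(0, 1e5, n)],
            delta=[np.empty(0), np.ones(n)],
        )
        rng = np.random.default_rng(5)
        z = np.ones((2, 2), dtype=int)
        freq = np.mean([
            sample_indicators(d, 1.0, 1e-16, np.array([1e10, 1e10]), z, rng,
                              edge_prior_prob=0.5)[0][1, 0]
            for _ in range(4000)
        ])
        assert freq == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(4000))

    def test_strong_edge_always_included(self, two_species_params):
        """Strong true interaction, low noise, dense sampling: the edge
        indicator is retained essentially always."""
        params = two_species_params
        times = np.linspace(0, 24, 25)
        data = [
            simulate(params, inoc, times, stochastic=True, seed=s)
            for s, inoc in enumerate([np.array([1e6, 1e6]),
                                      np.array([1e6, 1e5])])
        ]
        samples = run_mcmc(
            build_design(data),
            config=MCMCConfig(iterations=1500, burn_in=300, seed=0),
        )
        assert samples.inclusion_probabilities()[0, 1] > 0.99


class TestSampleVariances:
    def test_empty_design_draws_from_prior(self):
        d = _empty_design(1)
        priors = PriorHyperparameters()
        rng = np.random.default_rng(6)
        z = np.ones((1, 1), dtype=int)
        # v_w prior is Inv-chi2(0.1, 1e4); compare log-draw quantiles with a
        # direct scaled-inverse-chi-squared sampler
        draws = np.array([
            sample_variances(d, np.zeros(1), np.zeros((1, 1)), z, priors, rng)[2][0]
            for _ in range(20000)
        ])
        ref = 0.1 * 1e4 / np.random.default_rng(7).chisquare(0.1, 20000)
        got, want = np.log(draws), np.log(ref)
        for q in (0.25, 0.5, 0.75):
            assert np.quantile(got, q) == pytest.approx(
                np.quantile(want, q), rel=0.05)

    def test_posterior_mean_matches_scaled_inv_chi2_moment(self):
        n, true_var = 40, 9.0
        rng_data = np.random.default_rng(8)
        resid = rng_data.normal(0, np.sqrt(true_var), n)
        d = RegressionDesign(
            species=("A",),
            X=[np.zeros((n, 2))],
            y=[resid],
            delta=[np.ones(n)],
        )
        priors = PriorHyperparameters(eta_w=0.1, theta_w=1.0)
        nu = priors.eta_w + n
        tau2 = (priors.eta_w * priors.theta_w + resid @ resid) / nu
        expected_mean = nu * tau2 / (nu - 2)
        rng = np.random.default_rng(9)
        z = np.ones((1, 1), dtype=int)
        draws = np.array([
            sample_variances(d, np.zeros(1), np.zeros((1, 1)), z, priors, rng)[2][0]
            for _ in range(20000)
        ])
        sd = np.sqrt(2 * nu**2 * tau2**2 / ((nu - 2) ** 2 * (nu - 4)))
        assert draws.mean() == pytest.approx(
            expected_mean, abs=3 * sd / np.sqrt(len(draws)))

    def test_doubling_residuals_quadruples_scale(self):
        n = 25
        resid = np.random.default_rng(10).normal(0, 2.0, n)
        priors = PriorHyperparameters(eta_w=0.1, theta_w=1e-12)
        means = []
        for mult in (1.0, 2.0):
            d = RegressionDesign(
                species=("A",), X=[np.zeros((n, 2))], y=[mult * resid],
                delta=[np.ones(n)],
            )
            rng = np.random.default_rng(11)
            z = np.ones((1, 1), dtype=int)
            means.append(np.mean([
                sample_variances(d, np.zeros(1), np.zeros((1, 1)), z,
                                 priors, rng)[2][0]
                for _ in range(20000)
            ]))
        # theta_w is negligible, so the posterior scale scales with SS
        assert means[1] / means[0] == pytest.approx(4.0, rel=0.05)


class TestRunMCMC:
    def test_default_config_retains_4000_draws(self, two_species_params):
        times = np.array([0.0, 3.0, 6.0, 10.0, 15.0, 21.0])
        data = [simulate(two_species_params, np.array([1e6, 1e6]), times,
                         stochastic=True, seed=0)]
        samples = run_mcmc(build_design(data))
        assert samples.n_draws == 4000
        assert samples.config.iterations == 5000
        assert samples.config.burn_in == 1000

    def test_seeded_rerun_is_identical(self, two_species_params):
        times = np.array([0.0, 3.0, 6.0, 10.0, 15.0, 21.0])
        data = [simulate(two_species_params, np.array([1e6, 1e6]), times,
                         stochastic=True, seed=1)]
        cfg = MCMCConfig(iterations=400, burn_in=100, seed=12)
        a = run_mcmc(build_design(data), config=cfg)
        b = run_mcmc(build_design(data), config=cfg)
        np.testing.assert_array_equal(a.r, b.r)
        np.testing.assert_array_equal(a.a, b.a)
        np.testing.assert_array_equal(a.z, b.z)
        np.testing.assert_array_equal(a.v_w, b.v_w)

    def test_growth_rate_recovery_on_engineered_preset(self):
        params = preset_engineered_network(0)
        design = make_knockdown_design(DEFAULT_SPECIES)
        data, _ = generate_dataset(params, design,
                                   NoiseModel(measurement_cv=0.0), seed=2)
        samples = run_mcmc(
            build_design(data),
            config=MCMCConfig(iterations=1200, burn_in=300, seed=0),
        )
        np.testing.assert_allclose(
            samples.r.mean(axis=0), params.growth_rates, rtol=0.25
        )

    def test_posterior_calibration_on_prior_simulated_data(self):
        """Scaled-down simulation-based calibration: with data simulated from
        the prior and the model, the rank of the true growth rate among
        thinned posterior draws is uniform."""
        v_r, v_a, v_w = 0.09, 1e-19, 1e12
        sp = SpeciesSet(("A", "B"))
        times = np.array([0.0, 3.0, 6.0, 10.0, 15.0, 21.0])
        rng = np.random.default_rng(2024)
        ranks = []
        for _ in range(150):
            r = rng.normal(0, np.sqrt(v_r), 2)
            z = np.array([[1, rng.integers(0, 2)], [rng.integers(0, 2), 1]])
            a = rng.normal(0, np.sqrt(v_a), (2, 2))
            params = GLVParameters(sp, r, a, z, np.array([v_w, v_w]))
            data = [simulate(params, np.array([1e6, 1e6]), times,
                             stochastic=True, rng=rng)]
            cfg = MCMCConfig(
                iterations=420, burn_in=120, seed=int(rng.integers(2**31)),
                fixed_variances={"v_r": v_r, "v_a": v_a, "v_w": v_w},
            )
            samples = run_mcmc(build_design(data), config=cfg)
            ranks.append(int(np.sum(samples.r[::15, 0] < r[0])))
        counts = np.bincount(np.array(ranks), minlength=21)
        _, p = chisquare(counts)
        assert p > 1e-3

    def test_config_design_higher_order_mismatch_rejected(self, two_species_params):
        times = np.array([0.0, 3.0, 6.0])
        data = [simulate(two_species_params, np.array([1e6, 1e6]), times)]
        with pytest.raises(GLVModelError):
            run_mcmc(build_design(data), config=MCMCConfig(higher_order=True))


def _samples_with_frequencies(freqs: dict, n: int = 1000) -> PosteriorSamples:
    """PosteriorSamples whose indicator frequencies are exactly as given."""
    sp = ("A", "B")
    z = np.zeros((n, 2, 2), dtype=np.int8)
    z[:, 0, 0] = z[:, 1, 1] = 1
    for (i, j), f in freqs.items():
        z[: int(round(f * n)), i, j] = 1
    rng = np.random.default_rng(0)
    return PosteriorSamples(
        species=sp,
        r=rng.normal(size=(n, 2)),
        a=rng.normal(size=(n, 2, 2)),
        z=z,
        v_r=np.ones(n), v_a=np.ones(n), v_w=np.ones((n, 2)),
        config=MCMCConfig(iterations=n, burn_in=0),
        priors=PriorHyperparameters(),
    )


class TestBayesFactors:
    def test_prior_frequency_gives_bf_one(self):
        s = _samples_with_frequencies({(0, 1): 0.5})
        assert bayes_factors(s)[("B", "A")] == pytest.approx(1.0)

    def test_always_included_gives_infinity(self):
        s = _samples_with_frequencies({(0, 1): 1.0})
        assert bayes_factors(s)[("B", "A")] == np.inf

    def test_never_included_gives_zero(self):
        s = _samples_with_frequencies({(0, 1): 0.0})
        assert bayes_factors(s)[("B", "A")] == 0.0

    def test_ninety_percent_gives_nine(self):
        s = _samples_with_frequencies({(0, 1): 0.9})
        assert bayes_factors(s)[("B", "A")] == pytest.approx(9.0)

    def test_monotone_in_inclusion_frequency(self):
        bfs = [
            bayes_factors(_samples_with_frequencies({(0, 1): f}))[("B", "A")]
            for f in (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
        ]
        assert all(x < y for x, y in zip(bfs, bfs[1:]))

    def test_equals_one_at_nondefault_prior(self):
        s = _samples_with_frequencies({(0, 1): 0.2})
        assert bayes_factors(s, edge_prior_prob=0.2)[("B", "A")] == \
            pytest.approx(1.0)

    def test_pseudocount_estimator_bounds_endpoints(self):
        s = _samples_with_frequencies({(0, 1): 1.0})
        bf = bayes_factors(s, pseudocount=True)[("B", "A")]
        assert np.isfinite(bf) and bf > 1000


class TestSummarizeNetwork:
    @pytest.mark.parametrize("freq,category", [
        (0.50, "none"),        # BF = 1
        (0.80, "substantial"), # BF = 4
        (0.95, "strong"),      # BF = 19
    ])
    def test_evidence_categories(self, freq, category):
        s = _samples_with_frequencies({(0, 1): freq})
        table = summarize_network(s)
        row = table[(table.source == "B") & (table.target == "A")].iloc[0]
        assert row["category"] == category

    def test_boundary_values(self):
        # BF in [3, 10] is substantial; >10 strong; <3 none
        s = _samples_with_frequencies({(0, 1): 5 / 6})  # BF = 5
        table = summarize_network(s)
        assert table[(table.source == "B")].iloc[0]["category"] == "substantial"
        s = _samples_with_frequencies({(0, 1): 12 / 13})  # BF = 12
        table = summarize_network(s)
        assert table[(table.source == "B")].iloc[0]["category"] == "strong"

    def test_never_included_edge_has_undefined_strength(self):
        s = _samples_with_frequencies({(0, 1): 0.0})
        row = summarize_network(s)
        row = row[(row.source == "B") & (row.target == "A")].iloc[0]
        assert np.isnan(row["mean_strength"])
        assert row["sign"] == ""

    def test_twelve_interspecies_edges_for_four_species(self, wt_dataset):
        params, design, data, record = wt_dataset
        est = SpikeSlabGLV(iterations=300, burn_in=100, random_state=0)
        est.fit(data)
        assert len(est.network_) == 12


class TestEstimatorInterface:
    def test_get_set_params_round_trip(self):
        est = SpikeSlabGLV(iterations=123, theta_a=1e-12)
        params = est.get_params()
        assert params["iterations"] == 123
        est2 = SpikeSlabGLV().set_params(**params)
        assert est2.theta_a == 1e-12

    def test_fit_populates_posterior_and_network(self, two_species_params):
        times = np.array([0.0, 3.0, 6.0, 10.0, 15.0, 21.0])
        data = [simulate(two_species_params, np.array([1e6, 1e6]), times,
                         stochastic=True, seed=3)]
        est = SpikeSlabGLV(iterations=300, burn_in=100, random_state=1)
        est.fit(data)
        assert est.posterior_.n_draws == 200
        assert set(est.network_.columns) >= {
            "source", "target", "bayes_factor", "category", "mean_strength"}
        assert est.species_ == ("A", "B")
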