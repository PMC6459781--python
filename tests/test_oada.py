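"""OADA likelihood, fitting, profile CIs, AICc model selection."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import chi2

from nbdacutoff import (
    ConfigError,
    DegenerateFitError,
    ValidationError,
    aicc,
    compare_models,
    fit_oada,
    lrt_pvalue,
    oada_loglik,
    profile_ci,
    simulate_diffusion,
)
from nbdacutoff.oada import S_MAX_DEFAULT, OadaFit
from conftest import chain_network, complete_network, random_network


class TestLoglik:
    def test_two_individuals_forced_order(self):
        net = chain_network(2, w=0.7)
        for s in (0.0, 1.0, 50.0):
            assert oada_loglik(net, ("n0", "n1"), s) == pytest.approx(
                math.log(0.5)
            )

    def test_symmetric_network_all_orders_equiprobable(self):
        net = complete_network(3, 0.4)
        for s in (0.0, 2.0, 100.0):
            for order in itertools.permutations(net.individual_ids):
                assert oada_loglik(net, order, s) == pytest.approx(
                    math.log(1 / 6)
                )

    def test_asocial_limit_uniform_over_orders(self, default_net):
        order = default_net.individual_ids[:60]
        assert oada_loglik(default_net, order, 0.0) == pytest.approx(
            -math.lgamma(61)
        )

    def test_normalization_oracle(self):
        """Probabilities of all complete orders sum to one for any s."""
        for n, seed in [(4, 0), (5, 1)]:
            net = random_network(n, np.random.default_rng(seed))
            for s in (0.0, 0.5, 8.0, 300.0):
                total = sum(
                    math.exp(oada_loglik(net, order, s))
                    for order in itertools.permutations(net.individual_ids)
                )
                assert total == pytest.approx(1.0, abs=1e-10)

    def test_scale_invariance(self):
        net = random_network(6, np.random.default_rng(2))
        order = net.individual_ids[:4]
        scaled = type(net)(net.individual_ids, net.weights * 0.25)
        assert oada_loglik(net, order, 3.0) == pytest.approx(
            oada_loglik(scaled, order, 12.0)
        )

    def test_unknown_id_rejected(self, default_net):
        with pytest.raises(ValidationError):
            oada_loglik(default_net, ("ind01", "nope"), 1.0)


class TestAicc:
    def test_closed_form_value(self):
        assert aicc(-30.0, k=1, n=20) == pytest.approx(62.0 + 4 / 18)

    def test_zero_parameters_reduce_to_deviance(self):
        for n in (2, 10, 50):
            assert aicc(-12.5, k=0, n=n) == pytest.approx(25.0)

    def test_boundary_rejected(self):
        with pytest.raises(ValidationError):
            aicc(-30.0, k=1, n=2)


class TestFit:
    def test_network_following_diffusion_hits_plateau(self):
        """A diffusion tracking a chain's links exactly: s is unbounded."""
        net = chain_network(5, w=1.0)
        fit = fit_oada(net, tuple(net.individual_ids))
        assert fit.bounded_above
        assert fit.s_hat == pytest.approx(S_MAX_DEFAULT)
        assert fit.ci_upper == math.inf
        assert 0 < fit.ci_lower < S_MAX_DEFAULT
        assert fit.delta_aicc > 2

    def test_flat_likelihood_reports_null(self):
        net = complete_network(5, 0.3)
        fit = fit_oada(net, tuple(net.individual_ids))
        assert fit.s_hat == 0.0
        assert not fit.bounded_above
        assert fit.loglik_social == pytest.approx(fit.loglik_asocial)
        assert (fit.ci_lower, fit.ci_upper) == (0.0, math.inf)
        assert fit.p_lrt == 1.0

    def test_nesting_and_invariants(self, default_net):
        rng = np.random.default_rng(21)
        for _ in range(10):
            d = simulate_diffusion(default_net, 8.0, 15, rng)
            fit = fit_oada(default_net, d)
            assert fit.loglik_social >= fit.loglik_asocial - 1e-9
            assert fit.ci_lower - 1e-9 <= fit.s_hat <= fit.ci_upper + 1e-9
            assert 0 <= fit.p_lrt <= 1
            assert fit.delta_aicc == pytest.approx(
                fit.aicc_asocial - fit.aicc_social
            )
            assert fit.n_events == 15

    def test_too_few_events_degenerate(self):
        net = chain_network(4)
        with pytest.raises(DegenerateFitError):
            fit_oada(net, ("n0", "n1"))

    def test_null_simulations_rarely_exceed_chi2_critical(self, default_net):
        """At s=0 the LRT statistic respects its chi-square envelope."""
        rng = np.random.default_rng(22)
        crit = chi2.ppf(0.95, df=1)
        exceed = 0
        n_sim = 200
        for _ in range(n_sim):
            d = simulate_diffusion(default_net, 0.0, 20, rng)
            fit = fit_oada(default_net, d)
            stat = 2 * (fit.loglik_social - fit.loglik_asocial)
            exceed += stat > crit
        # boundary at s=0 makes the chi2(1) reference conservative
        assert exceed / n_sim < 0.08

    def test_recovers_moderate_s(self, default_net):
        """Median s_hat over replicates sits near the generating value."""
        rng = np.random.default_rng(23)
        s_hats = []
        for _ in range(60):
            d = simulate_diffusion(default_net, 8.0, 20, rng)
            s_hats.append(fit_oada(default_net, d).s_hat)
        assert 2.0 < float(np.median(s_hats)) < 40.0


class TestProfileCI:
    def test_matches_fit_interval(self, default_net):
        d = simulate_diffusion(default_net, 8.0, 20, np.random.default_rng(24))
        fit = fit_oada(default_net, d)
        lo, hi = profile_ci(default_net, d.order, fit)
        assert lo == pytest.approx(fit.ci_lower, abs=1e-6)
        if math.isinf(fit.ci_upper):
            assert math.isinf(hi)
        else:
            assert hi == pytest.approx(fit.ci_upper, rel=1e-4)

    def test_interval_endpoints_sit_at_likelihood_drop(self, default_net):
        """Both finite bounds lie 1.92 log-units below the maximum."""
        rng = np.random.default_rng(25)
        drop = chi2.ppf(0.95, df=1) / 2
        seen_finite = 0
        for _ in range(20):
            d = simulate_diffusion(default_net, 8.0, 20, rng)
            fit = fit_oada(default_net, d)
            for bound in (fit.ci_lower, fit.ci_upper):
                if 0 < bound < math.inf:
                    seen_finite += 1
                    ll = oada_loglik(default_net, d.order, bound)
                    assert ll == pytest.approx(
                        fit.loglik_social - drop, abs=1e-5
                    )
        assert seen_finite > 0

    def test_coverage_on_error_free_network(self, default_net):
        """True s=8 falls inside the 95% profile CI ~95% of the time."""
        rng = np.random.default_rng(26)
        n_sim = 150
        covered = 0
        for _ in range(n_sim):
            d = simulate_diffusion(default_net, 8.0, 20, rng)
            fit = fit_oada(default_net, d)
            covered += fit.ci_lower <= 8.0 <= fit.ci_upper
        assert covered / n_sim >= 0.90


class TestModelSelection:
    @pytest.mark.parametrize(
        "delta, conclusive, winner",
        [(3.0, True, "social"), (-3.0, True, "asocial"),
         (1.0, False, "none"), (2.0, False, "none"), (-2.0, False, "none")],
    )
    def test_threshold_rule(self, delta, conclusive, winner):
        fit = OadaFit(
            s_hat=1.0, loglik_social=-10.0, loglik_asocial=-11.0,
            ci_lower=0.0, ci_upper=5.0, p_lrt=0.2,
            aicc_social=20.0, aicc_asocial=20.0 + delta, delta_aicc=delta,
            n_events=10, bounded_above=False,
        )
        cmp = compare_models(fit)
        assert cmp.conclusive is conclusive
        assert cmp.winner == winner

    def test_nonpositive_threshold_rejected(self):
        fit = OadaFit(1.0, -10.0, -11.0, 0.0, 5.0, 0.2, 20.0, 21.0, 1.0, 10, False)
        with pytest.raises(ConfigError):
            compare_models(fit, threshold=0.0)

    def test_lrt_pvalue_reference_points(self):
        base = dict(
            s_hat=1.0, ci_lower=0.0, ci_upper=5.0, p_lrt=0.0,
            aicc_social=0.0, aicc_asocial=0.0, delta_aicc=0.0,
            n_events=10, bounded_above=False,
        )
        equal = OadaFit(loglik_social=-9.0, loglik_asocial=-9.0, **base)
        assert lrt_pvalue(equal) == 1.0
        at_crit = OadaFit(
            loglik_social=-9.0, loglik_asocial=-9.0 - 3.841 / 2, **base
        )
        assert lrt_pvalue(at_crit) == pytest.approx(0.05, abs=5e-4)
        assert lrt_pvalue(at_crit, boundary_correction=True) == pytest.approx(
            0.025, abs=3e-4
        )
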