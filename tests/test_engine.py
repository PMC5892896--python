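"""Engine orchestration: ticks, election, determinism, reference equality."""

import numpy as np
import pytest
from scipy import stats

from mtcsim import (
    Population,
    RunConfig,
    PopulationConfig,
    SimulationState,
    TargetingThresholds,
    hold_election,
    make_run_config,
    marginal_likelihoods,
    mtc_candidate,
    run_simulation,
    run_tick,
    stochastic_candidate,
)

from _reference import reference_run_simulation


def uniform_population(n, p_candidate=0.5, p_vote=0.5, perc_mtc=0.5,
                       perc_stoch=0.5):
    full = np.full
    return Population(
        p_candidate=full(n, float(p_candidate)),
        p_vote=full(n, float(p_vote)),
        trust_mtc=full(n, float(perc_mtc)),
        expertise_mtc=full(n, float(perc_mtc)),
        trust_stoch=full(n, float(perc_stoch)),
        expertise_stoch=full(n, float(perc_stoch)),
    )


def manual_state(pop, reach_mtc=20, reach_stoch=20, **cfg_kwargs):
    cfg = RunConfig(
        population=PopulationConfig(n_voters=pop.n_voters),
        mtc=mtc_candidate(reach_mtc),
        stochastic=stochastic_candidate(reach_stoch),
        **cfg_kwargs,
    )
    likelihoods = {
        "mtc": marginal_likelihoods(pop.trust_mtc, pop.expertise_mtc),
        "stochastic": marginal_likelihoods(pop.trust_stoch, pop.expertise_stoch),
    }
    return SimulationState(config=cfg, population=pop, likelihoods=likelihoods)


class TestRunTick:
    def test_zero_reach_leaves_state_unchanged(self, rng):
        state = manual_state(uniform_population(50), reach_mtc=0, reach_stoch=0)
        before = state.population.p_candidate.copy()
        run_tick(state, rng)
        assert np.array_equal(state.population.p_candidate, before)
        assert state.tick == 1

    def test_single_mtc_contact_posterior(self, rng):
        """A prior-0.5 voter who sees the MTC as fully credible moves to
        0.40/0.51 ≈ 0.7843 after one endorsement."""
        pop = uniform_population(1, p_vote=0.9, perc_mtc=1.0)
        state = manual_state(pop, reach_mtc=1, reach_stoch=0)
        run_tick(state, rng)
        assert pop.p_candidate[0] == pytest.approx(0.40 / 0.51, abs=1e-12)

    def test_double_contact_composes_sequentially(self, rng):
        """A voter contacted by both campaigns gets the endorse update
        then the oppose update, as two chained Bayes steps."""
        pop = uniform_population(1, p_candidate=0.6, p_vote=0.9,
                                 perc_mtc=0.8, perc_stoch=0.7)
        like_m = marginal_likelihoods(0.8, 0.8)
        like_s = marginal_likelihoods(0.7, 0.7)

        def bayes(p, lh, lnh):
            return p * lh / (p * lh + (1 - p) * lnh)

        step1 = bayes(0.6, like_m.p_rep_given_h, like_m.p_rep_given_not_h)
        want = bayes(step1, 1 - like_s.p_rep_given_h, 1 - like_s.p_rep_given_not_h)
        state = manual_state(pop, reach_mtc=1, reach_stoch=1)
        run_tick(state, rng)
        assert pop.p_candidate[0] == pytest.approx(want, abs=1e-12)

    def test_beliefs_stay_in_unit_interval(self):
        cfg = make_run_config(0.4, 0.6, 10, 50, seed=2, n_voters=300, n_ticks=1)
        rng = np.random.default_rng(cfg.seed)
        from mtcsim.engine import init_state

        state = init_state(cfg, rng)
        for _ in range(30):
            run_tick(state, rng)
            b = state.population.p_candidate
            assert b.min() >= 0.0 and b.max() <= 1.0

    def test_daily_contact_sets_cleared(self, rng):
        state = manual_state(uniform_population(50), reach_mtc=5, reach_stoch=5)
        run_tick(state, rng)
        assert state.contacted_today == {}


class TestHoldElection:
    def test_unanimous_supporters_all_vote(self, rng):
        pop = uniform_population(200, p_candidate=0.9, p_vote=1.0)
        res = hold_election(pop, rng)
        assert res.votes_mtc == 200 and res.abstentions == 0

    def test_zero_turnout(self, rng):
        pop = uniform_population(200, p_vote=0.0)
        res = hold_election(pop, rng)
        assert res.abstentions == 200
        assert np.isnan(res.share_mtc)

    def test_turnout_concentration(self, rng):
        """With p_vote = 0.5 everywhere, turnout is binomial(10,000, 0.5)
        and concentrates within 0.5 ± 0.02."""
        pop = uniform_population(10_000, p_candidate=0.9, p_vote=0.5)
        res = hold_election(pop, rng)
        assert abs(res.turnout - 0.5) < 0.02

    def test_exact_tie_split_by_fair_coin(self, rng):
        pop = uniform_population(10_000, p_candidate=0.5, p_vote=1.0)
        res = hold_election(pop, rng)
        assert abs(res.share_mtc - 0.5) < 0.02


class TestRunSimulation:
    def test_vote_conservation(self):
        res = run_simulation(make_run_config(seed=1, n_voters=500, n_ticks=10))
        assert res.votes_mtc + res.votes_stochastic + res.abstentions == 500

    def test_determinism(self):
        cfg = make_run_config(0.5, 0.6, 10, 20, seed=77, n_voters=400, n_ticks=10)
        a, b = run_simulation(cfg), run_simulation(cfg)
        assert a == b

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            run_simulation(make_run_config(n_ticks=0))

    def test_contact_log(self):
        cfg = make_run_config(seed=3, n_voters=200, n_ticks=4)
        res = run_simulation(cfg, log_contacts=True)
        log = res.config_echo["contact_log"]
        # 4 ticks x (<=20 targeted + 20 broadcast) contacts
        assert 80 <= len(log) <= 160
        assert all(0 <= t < 4 for t, _, _ in log)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(cred_mean_mtc=0.6, cred_mean_stochastic=0.6,
                 reach_mtc=20, reach_stochastic=30),
            dict(cred_mean_mtc=0.4, cred_mean_stochastic=0.5,
                 reach_mtc=10, reach_stochastic=25),
        ],
    )
    def test_reference_engine_equality(self, kwargs):
        """The vectorised engine and the naive per-agent loop engine return
        identical tallies for the same seed (n = 200 voters)."""
        cfg = make_run_config(seed=123, n_voters=200, n_ticks=10, **kwargs)
        fast = run_simulation(cfg)
        slow = reference_run_simulation(cfg)
        assert (fast.votes_mtc, fast.votes_stochastic, fast.abstentions) == (
            slow.votes_mtc, slow.votes_stochastic, slow.abstentions
        )
        assert fast.final_belief_mean == pytest.approx(
            slow.final_belief_mean, abs=1e-12
        )

    def test_update_order_insensitive(self):
        """Applying stochastic updates before MTC updates within a tick
        changes aggregate shares negligibly (double contacts are rare)."""
        diffs = []
        for seed in range(40):
            cfg = make_run_config(0.5, 0.5, 10, 20, seed=seed,
                                  n_voters=300, n_ticks=20)
            a = reference_run_simulation(cfg, update_order=("mtc", "stochastic"))
            b = reference_run_simulation(cfg, update_order=("stochastic", "mtc"))
            diffs.append(a.share_mtc - b.share_mtc)
        assert abs(np.mean(diffs)) < 0.01

    def test_strategy_off_equivalence(self):
        """With the screen fully widened the targeted campaign is
        statistically indistinguishable from broadcast of the same reach
        (two-sample test on shares over 100 seeds, α = 0.01)."""
        from mtcsim.engine import init_state
        from mtcsim import ReportLikelihoods, posterior_belief, select_contacts

        wide = TargetingThresholds(belief_low=0.0, belief_high=1.0,
                                   cred_min=0.0, vote_min=0.0)

        def run_broadcast_mtc(cfg):
            # identical engine except the MTC samples from everyone
            rng = np.random.default_rng(cfg.seed)
            state = init_state(cfg, rng)
            pop = state.population
            for _ in range(cfg.n_ticks):
                pool = np.arange(pop.n_voters)
                for cand in cfg.candidates:
                    idx = select_contacts(cand, pop, pool, rng)
                    if idx.size == 0:
                        continue
                    like = state.likelihoods[cand.id]
                    pop.p_candidate[idx] = posterior_belief(
                        pop.p_candidate[idx],
                        ReportLikelihoods(like.p_rep_given_h[idx],
                                          like.p_rep_given_not_h[idx]),
                        cand.stance,
                    )
            return hold_election(pop, rng)

        shares_wide, shares_broadcast = [], []
        for seed in range(100):
            cfg = RunConfig(
                population=PopulationConfig(n_voters=400, seed=seed),
                mtc=mtc_candidate(10), stochastic=stochastic_candidate(10),
                thresholds=wide, n_ticks=15, seed=seed,
            )
            shares_wide.append(run_simulation(cfg).share_mtc)
            shares_broadcast.append(run_broadcast_mtc(cfg).share_mtc)
        p = stats.mannwhitneyu(shares_wide, shares_broadcast).pvalue
        assert p > 0.01
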