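"""One full campaign simulation.

Model flow: spin-up (draw the electorate), a fixed number of daily
contact/update ticks, then the election.  Each tick: (1) the MTC eligible
pool is computed from start-of-tick beliefs; (2) each campaign samples its
daily contact list; (3) every contacted voter Bayes-updates
``p_candidate`` using their own perception of the contacting candidate —
all MTC contacts first, then all stochastic contacts; (4) daily contact
sets are cleared.  At the election every voter casts a ballot with
probability ``p_vote`` for the MTC candidate if ``p_candidate > 0.5``, the
stochastic candidate if ``< 0.5``, and by fair coin at exactly 0.5.

Source perceptions (trust/expertise) are fixed for the whole simulation;
only beliefs move.  That makes each voter's report likelihoods for each
candidate constants, which the engine precomputes at spin-up.

A single seeded generator drives everything, consumed in a documented
fixed order: population draw (six vectors, see
:mod:`mtcsim.electorate`); per tick, MTC contact sample then stochastic
contact sample; at the election, one turnout vector then one tie-break
vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .credibility import (
    DEFAULT_TABLE,
    CredibilityTable,
    ReportLikelihoods,
    marginal_likelihoods,
    posterior_belief,
)
from .electorate import Population, PopulationConfig, sample_population
from .campaigns import (
    CandidateSpec,
    TargetingThresholds,
    eligible_targets,
    mtc_candidate,
    select_contacts,
    stochastic_candidate,
)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one simulated campaign."""

    population: PopulationConfig = PopulationConfig()
    mtc: CandidateSpec = mtc_candidate(20)
    stochastic: CandidateSpec = stochastic_candidate(20)
    thresholds: TargetingThresholds = TargetingThresholds()
    n_ticks: int = 50
    table: CredibilityTable = DEFAULT_TABLE
    seed: int = 0

    def validate(self) -> None:
        if self.n_ticks < 1:
            raise ValueError(f"n_ticks must be >= 1, got {self.n_ticks}")
        self.population.validate()

    @property
    def candidates(self) -> tuple[CandidateSpec, CandidateSpec]:
        """Update order within a tick: MTC first, then stochastic."""
        return (self.mtc, self.stochastic)


def make_run_config(
    cred_mean_mtc: float = 0.5,
    cred_mean_stochastic: float = 0.5,
    reach_mtc: int = 20,
    reach_stochastic: int = 20,
    seed: int = 0,
    n_voters: int = 10_000,
    n_ticks: int = 50,
    **population_kwargs,
) -> RunConfig:
    """Convenience constructor covering the common sweep axes."""
    pop = PopulationConfig(
        n_voters=n_voters,
        cred_mean_mtc=cred_mean_mtc,
        cred_mean_stochastic=cred_mean_stochastic,
        seed=seed,
        **population_kwargs,
    )
    return RunConfig(
        population=pop,
        mtc=mtc_candidate(reach_mtc),
        stochastic=stochastic_candidate(reach_stochastic),
        n_ticks=n_ticks,
        seed=seed,
    )


@dataclass
class RunResult:
    """Tallies of one simulated election."""

    votes_mtc: int
    votes_stochastic: int
    abstentions: int
    turnout: float
    share_mtc: float
    final_belief_mean: float
    config_echo: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "votes_mtc": self.votes_mtc,
            "votes_stochastic": self.votes_stochastic,
            "abstentions": self.abstentions,
            "turnout": self.turnout,
            "share_mtc": self.share_mtc,
            "final_belief_mean": self.final_belief_mean,
        }
        row.update(self.config_echo)
        return row


@dataclass
class SimulationState:
    """Mutable state carried across ticks."""

    config: RunConfig
    population: Population
    # per-voter report likelihoods for each candidate (fixed all run)
    likelihoods: dict
    tick: int = 0
    # today's contact lists keyed by campaign id; cleared every tick
    contacted_today: dict = field(default_factory=dict)
    contact_log: list | None = None  # list of (tick, campaign, voter_id)


def init_state(config: RunConfig, rng: np.random.Generator,
               log_contacts: bool = False) -> SimulationState:
    """Spin-up phase: draw the electorate and precompute likelihoods."""
    pop = sample_population(config.population, rng)
    likelihoods = {
        "mtc": marginal_likelihoods(pop.trust_mtc, pop.expertise_mtc, config.table),
        "stochastic": marginal_likelihoods(
            pop.trust_stoch, pop.expertise_stoch, config.table
        ),
    }
    return SimulationState(
        config=config,
        population=pop,
        likelihoods=likelihoods,
        contact_log=[] if log_contacts else None,
    )


def run_tick(state: SimulationState, rng: np.random.Generator) -> SimulationState:
    """Advance the simulation by one day."""
    cfg = state.config
    pop = state.population
    pool = eligible_targets(pop, cfg.thresholds)
    # both contact lists are drawn from start-of-tick state
    contacts = {
        cand.id: select_contacts(cand, pop, pool, rng)
        for cand in cfg.candidates
    }
    state.contacted_today = contacts
    for cand in cfg.candidates:
        idx = contacts[cand.id]
        if idx.size == 0:
            continue
        like: ReportLikelihoods = state.likelihoods[cand.id]
        pop.p_candidate[idx] = posterior_belief(
            pop.p_candidate[idx],
            ReportLikelihoods(
                like.p_rep_given_h[idx], like.p_rep_given_not_h[idx]
            ),
            cand.stance,
        )
    if state.contact_log is not None:
        for cand in cfg.candidates:
            state.contact_log.extend(
                (state.tick, cand.id, int(v)) for v in contacts[cand.id]
            )
    state.tick += 1
    state.contacted_today = {}  # daily contact sets are cleared
    return state


def hold_election(
    population: Population,
    rng: np.random.Generator,
    config_echo: dict | None = None,
) -> RunResult:
    """Voting phase: probabilistic turnout, then majority-belief ballots."""
    n = population.n_voters
    cast = rng.random(n) < population.p_vote
    tie_coin = rng.random(n) < 0.5  # consumed every election for stream stability
    b = population.p_candidate
    prefer_mtc = (b > 0.5) | ((b == 0.5) & tie_coin)
    votes_mtc = int(np.count_nonzero(cast & prefer_mtc))
    votes_st = int(np.count_nonzero(cast & ~prefer_mtc))
    abstentions = n - votes_mtc - votes_st
    total = votes_mtc + votes_st
    return RunResult(
        votes_mtc=votes_mtc,
        votes_stochastic=votes_st,
        abstentions=abstentions,
        turnout=total / n,
        share_mtc=votes_mtc / total if total else float("nan"),
        final_belief_mean=float(b.mean()),
        config_echo=dict(config_echo or {}),
    )


def run_simulation(config: RunConfig, log_contacts: bool = False) -> RunResult:
    """Spin-up, ``n_ticks`` contact days, election.  Reproducible from seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    state = init_state(config, rng, log_contacts=log_contacts)
    for _ in range(config.n_ticks):
        run_tick(state, rng)
    echo = {
        "mu_mtc": config.population.cred_mean_mtc,
        "mu_stoch": config.population.cred_mean_stochastic,
        "reach_mtc": config.mtc.reach,
        "reach_stoch": config.stochastic.reach,
        "n_voters": config.population.n_voters,
        "n_ticks": config.n_ticks,
        "seed": config.seed,
    }
    result = hold_election(state.population, rng, config_echo=echo)
    if log_contacts:
        result.config_echo["contact_log"] = state.contact_log
    return result


def contact_log_frame(log: list) -> pd.DataFrame:
    return pd.DataFrame(log, columns=["tick", "campaign", "voter_id"])
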