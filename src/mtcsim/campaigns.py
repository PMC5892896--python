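"""Campaign contact strategies.

Two candidates compete.  The micro-targeting campaign (MTC) screens the
electorate and only contacts *persuadable* voters: those whose belief is
neither strongly for nor strongly against the candidate, who perceive the
candidate as credible, and who are likely to turn out.  The stochastic
(broadcast) campaign uses no voter information at all and contacts voters
uniformly at random — a leafleting or cold-calling campaign.

Per day (tick) a campaign contacts up to ``reach`` distinct voters; the
same voter may be contacted again on later days, and by both campaigns on
the same day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .credibility import ENDORSE, OPPOSE
from .electorate import Population

MTC = "mtc"
STOCHASTIC = "stochastic"
TARGETED = "targeted"
BROADCAST = "broadcast"

_VALID = {
    MTC: (TARGETED, ENDORSE),
    STOCHASTIC: (BROADCAST, OPPOSE),
}


@dataclass(frozen=True)
class CandidateSpec:
    """One campaign: identity, selection strategy, message stance, reach.

    The identity pins down strategy and stance: the MTC candidate targets
    and endorses the hypothesis "vote MTC"; the stochastic candidate
    broadcasts and opposes it.
    """

    id: str
    strategy: str
    stance: str
    reach: int

    def __post_init__(self) -> None:
        if self.id not in _VALID:
            raise ValueError(f"unknown candidate id {self.id!r}")
        strategy, stance = _VALID[self.id]
        if self.strategy != strategy or self.stance != stance:
            raise ValueError(
                f"candidate {self.id!r} must have strategy={strategy!r}, "
                f"stance={stance!r}"
            )
        if self.reach < 0:
            raise ValueError(f"reach must be >= 0, got {self.reach}")


def mtc_candidate(reach: int = 20) -> CandidateSpec:
    return CandidateSpec(MTC, TARGETED, ENDORSE, reach)


def stochastic_candidate(reach: int) -> CandidateSpec:
    return CandidateSpec(STOCHASTIC, BROADCAST, OPPOSE, reach)


@dataclass(frozen=True)
class TargetingThresholds:
    """The MTC screening rule.

    A voter is eligible iff
    ``belief_low < p_candidate < belief_high`` (strict: the boundaries are
    "already decided"), ``cred_mtc >= cred_min`` (inclusive), and
    ``p_vote > vote_min`` (strict).
    """

    belief_low: float = 0.25
    belief_high: float = 0.75
    cred_min: float = 0.5
    vote_min: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.belief_low < self.belief_high <= 1.0):
            raise ValueError(
                f"need 0 <= belief_low < belief_high <= 1, got "
                f"({self.belief_low}, {self.belief_high})"
            )


def eligible_targets(
    population: Population,
    thresholds: TargetingThresholds = TargetingThresholds(),
) -> np.ndarray:
    """Voter ids passing the MTC screen, evaluated on current state.

    Returns a sorted integer array.
    """
    if population.n_voters == 0:
        raise ValueError("population is empty")
    b = population.p_candidate
    mask = (
        (b > thresholds.belief_low)
        & (b < thresholds.belief_high)
        & (population.cred_mtc >= thresholds.cred_min)
        & (population.p_vote > thresholds.vote_min)
    )
    return np.flatnonzero(mask)


def sample_without_replacement(
    rng: np.random.Generator, pool: np.ndarray, k: int
) -> np.ndarray:
    """Uniform sample of min(k, |pool|) ids without replacement.

    The single sampling primitive shared by every engine so that identical
    seeds consume the random stream identically.
    """
    k = min(k, pool.shape[0])
    if k == 0:
        return np.empty(0, dtype=pool.dtype)
    return rng.choice(pool, size=k, replace=False)


def select_contacts(
    candidate: CandidateSpec,
    population: Population,
    eligible_pool: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Today's contact list for one campaign.

    Targeted campaigns sample from the eligible pool, broadcast campaigns
    from the whole electorate; both without replacement within the day, so
    no voter is contacted twice by the same campaign on one day.
    """
    if candidate.strategy == TARGETED:
        pool = np.asarray(eligible_pool)
    else:
        pool = np.arange(population.n_voters)
    return sample_without_replacement(rng, pool, candidate.reach)
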