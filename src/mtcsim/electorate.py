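"""Heterogeneous voter population.

Each voter carries a prior belief ``p_candidate`` in the hypothesis "vote
for the micro-targeting (MTC) candidate", a fixed turnout propensity
``p_vote``, and independent trust/expertise perceptions of each of the two
candidates.  All are drawn from normal distributions and clamped into
bounds, which makes the electorate heterogeneous: one voter may see a
candidate as highly credible while the next sees the same candidate poorly.

Draw order is fixed (beliefs, vote propensity, MTC trust, MTC expertise,
stochastic trust, stochastic expertise) so a given seed always produces a
bit-identical population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .credibility import credibility_score

# Bound conventions.  Beliefs and turnout propensity are clamped to
# [0.01, 1] (the asymmetric upper bound is intentional).  Source
# perceptions are clamped to [0.01, 0.99] to exclude degenerate certainty
# about sources.
BELIEF_BOUNDS = (0.01, 1.0)
PERCEPTION_BOUNDS = (0.01, 0.99)

CSV_COLUMNS = [
    "voter_id",
    "p_candidate",
    "p_vote",
    "trust_mtc",
    "expertise_mtc",
    "trust_stoch",
    "expertise_stoch",
]


@dataclass(frozen=True)
class PopulationConfig:
    """Parameters of the population draw.

    The default credibility means (0.5) sit at the centre of the swept
    grid {0.4, 0.5, 0.6}; the standard deviation 0.25 applies to every
    field and is what generates voter heterogeneity.
    """

    n_voters: int = 10_000
    belief_mean: float = 0.5
    belief_sd: float = 0.25
    vote_mean: float = 0.5
    vote_sd: float = 0.25
    cred_mean_mtc: float = 0.5
    cred_mean_stochastic: float = 0.5
    cred_sd: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_voters < 1:
            raise ValueError(f"n_voters must be >= 1, got {self.n_voters}")
        for name in ("belief_mean", "belief_sd", "vote_mean", "vote_sd",
                     "cred_mean_mtc", "cred_mean_stochastic", "cred_sd"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        for name in ("belief_sd", "vote_sd", "cred_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class Population:
    """Structure-of-arrays voter state; one entry per voter."""

    p_candidate: np.ndarray
    p_vote: np.ndarray
    trust_mtc: np.ndarray
    expertise_mtc: np.ndarray
    trust_stoch: np.ndarray
    expertise_stoch: np.ndarray

    @property
    def n_voters(self) -> int:
        return self.p_candidate.shape[0]

    @property
    def cred_mtc(self) -> np.ndarray:
        """Per-voter signalling score for the MTC candidate."""
        return credibility_score(self.trust_mtc, self.expertise_mtc)

    @property
    def cred_stoch(self) -> np.ndarray:
        return credibility_score(self.trust_stoch, self.expertise_stoch)

    def copy(self) -> "Population":
        return Population(*(getattr(self, c).copy() for c in CSV_COLUMNS[1:]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({c: getattr(self, c) for c in CSV_COLUMNS[1:]})
        df.insert(0, "voter_id", np.arange(self.n_voters))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Population":
        df = df.sort_values("voter_id")
        return cls(*(df[c].to_numpy(dtype=float) for c in CSV_COLUMNS[1:]))

    @classmethod
    def from_csv(cls, path) -> "Population":
        return cls.from_frame(pd.read_csv(path))


def _draw(rng: np.random.Generator, n: int, mean: float, sd: float,
          bounds: tuple) -> np.ndarray:
    """Normal draw clamped (not resampled) into bounds."""
    return np.clip(rng.normal(mean, sd, size=n), *bounds)


def sample_population(
    config: PopulationConfig,
    rng: np.random.Generator | None = None,
) -> Population:
    """Draw a fresh electorate.

    If ``rng`` is omitted a generator is created from ``config.seed``;
    passing an external generator lets a simulation share one seeded
    stream across the population draw and all later sampling.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_voters
    return Population(
        p_candidate=_draw(rng, n, config.belief_mean, config.belief_sd, BELIEF_BOUNDS),
        p_vote=_draw(rng, n, config.vote_mean, config.vote_sd, BELIEF_BOUNDS),
        trust_mtc=_draw(rng, n, config.cred_mean_mtc, config.cred_sd, PERCEPTION_BOUNDS),
        expertise_mtc=_draw(rng, n, config.cred_mean_mtc, config.cred_sd, PERCEPTION_BOUNDS),
        trust_stoch=_draw(rng, n, config.cred_mean_stochastic, config.cred_sd, PERCEPTION_BOUNDS),
        expertise_stoch=_draw(rng, n, config.cred_mean_stochastic, config.cred_sd, PERCEPTION_BOUNDS),
    )
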