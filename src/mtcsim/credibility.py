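"""Bayesian source-credibility belief revision.

A voter holds a subjective degree of belief ``p(h)`` in a hypothesis *h*
("the micro-targeting candidate is the right choice").  When a candidate
contacts the voter with a persuasive message, the voter revises that belief
with Bayes' rule,

    p(h | rep) = p(h) p(rep|h) / [ p(h) p(rep|h) + p(¬h) p(rep|¬h) ],

where *rep* is the candidate's report (an endorsement of *h*, or its
negation).  The report likelihoods ``p(rep|h)`` and ``p(rep|¬h)`` encode how
credible the voter finds the source.  Credibility is decomposed into two
independent components: perceived *trustworthiness* ``P(T)`` — the source's
intention to report accurately — and perceived *expertise* ``P(E)`` — its
capability to do so.  A conditional probability table gives the chance that
the source endorses the hypothesis in each of the eight
(h/¬h, T/¬T, E/¬E) states; marginalising over the voter's ``P(T)`` and
``P(E)`` yields the two report likelihoods.

Low-credibility sources sit in the *backfire* region, where
``p(rep|h) < p(rep|¬h)``: an endorsement from such a source makes the
hypothesis *less* believable.

All operations accept scalars or NumPy arrays and broadcast element-wise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Union

import numpy as np

logger = logging.getLogger("mtcsim")

ArrayLike = Union[float, np.ndarray]

#: Message directions a campaign can argue.
ENDORSE = "endorse"
OPPOSE = "oppose"

# Column order of the conditional table: (T,E), (T,¬E), (¬T,E), (¬T,¬E).
_STATE_ORDER = (("T", "E"), ("T", "notE"), ("notT", "E"), ("notT", "notE"))


def _check_unit_interval(name: str, value: ArrayLike) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return arr


@dataclass(frozen=True)
class CredibilityTable:
    """Conditional probabilities p(rep | hypothesis-state, T/¬T, E/¬E).

    ``p_rep_h`` and ``p_rep_not_h`` are four-tuples in the fixed column
    order (T,E), (T,¬E), (¬T,E), (¬T,¬E).  The default values are empirical
    conditional parameters elicited from US voters.
    """

    p_rep_h: tuple = (0.80, 0.58, 0.34, 0.18)
    p_rep_not_h: tuple = (0.22, 0.42, 0.59, 0.71)

    def __post_init__(self) -> None:
        for name in ("p_rep_h", "p_rep_not_h"):
            row = getattr(self, name)
            if len(row) != 4:
                raise ValueError(f"{name} needs 4 entries, got {len(row)}")
            _check_unit_interval(name, np.asarray(row))

    def as_dict(self) -> dict:
        """Eight entries keyed (hyp, trust, expertise) for serialization."""
        out = {}
        for hyp, row in (("H", self.p_rep_h), ("notH", self.p_rep_not_h)):
            for (t, e), p in zip(_STATE_ORDER, row):
                out[(hyp, t, e)] = float(p)
        return out

    @classmethod
    def from_dict(cls, entries: dict) -> "CredibilityTable":
        h = tuple(entries[("H", t, e)] for t, e in _STATE_ORDER)
        nh = tuple(entries[("notH", t, e)] for t, e in _STATE_ORDER)
        return cls(h, nh)


#: Default table used throughout the model.
DEFAULT_TABLE = CredibilityTable()


@dataclass(frozen=True)
class SourcePerception:
    """One voter's view of one candidate: P(T) and P(E), both in [0, 1]."""

    trust: float
    expertise: float

    def __post_init__(self) -> None:
        _check_unit_interval("trust", self.trust)
        _check_unit_interval("expertise", self.expertise)

    @property
    def credibility(self) -> float:
        return credibility_score(self.trust, self.expertise)


@dataclass(frozen=True)
class ReportLikelihoods:
    """The pair (p(rep|h), p(rep|¬h)) for one source as seen by one voter."""

    p_rep_given_h: ArrayLike
    p_rep_given_not_h: ArrayLike

    def __iter__(self):
        return iter((self.p_rep_given_h, self.p_rep_given_not_h))


def credibility_score(trust: ArrayLike, expertise: ArrayLike) -> ArrayLike:
    """Signalling score: the arithmetic mean of trust and expertise.

    Voters summarise a candidate's credibility this way, and the
    micro-targeting campaign screens on it.
    """
    t = _check_unit_interval("trust", trust)
    e = _check_unit_interval("expertise", expertise)
    out = (t + e) / 2.0
    return float(out) if out.ndim == 0 else out


def marginal_likelihoods(
    trust: ArrayLike,
    expertise: ArrayLike = None,
    table: CredibilityTable = DEFAULT_TABLE,
) -> ReportLikelihoods:
    """Marginalise the conditional table over the voter's P(T) and P(E).

    Trust and expertise are treated as independent, so each of the four
    (T/¬T, E/¬E) states is weighted by the product of the corresponding
    marginals:

        p(rep|h) = Σ_{t,e} p(rep | h, t, e) · w(t) · w(e)

    with w(T)=trust, w(¬T)=1−trust, w(E)=expertise, w(¬E)=1−expertise, and
    analogously for p(rep|¬h).

    The first argument may be a :class:`SourcePerception` instead of a
    trust value.
    """
    if isinstance(trust, SourcePerception):
        trust, expertise = trust.trust, trust.expertise
    if expertise is None:
        raise TypeError("expertise is required unless a SourcePerception is given")
    t = _check_unit_interval("trust", trust)
    e = _check_unit_interval("expertise", expertise)
    # weights in column order (T,E), (T,¬E), (¬T,E), (¬T,¬E)
    w = (t * e, t * (1.0 - e), (1.0 - t) * e, (1.0 - t) * (1.0 - e))
    p_h = sum(wi * pi for wi, pi in zip(w, table.p_rep_h))
    p_nh = sum(wi * pi for wi, pi in zip(w, table.p_rep_not_h))
    if np.ndim(p_h) == 0:
        p_h, p_nh = float(p_h), float(p_nh)
    return ReportLikelihoods(p_h, p_nh)


def posterior_belief(
    prior: ArrayLike,
    likelihoods: ReportLikelihoods,
    message: str = ENDORSE,
) -> ArrayLike:
    """Revise a belief after one message from a source.

    For an endorsement the report is "h is true" and Bayes' rule applies
    with the likelihood pair as given; for an opposing message the report
    is negated, so each likelihood ℓ is replaced by 1−ℓ.  A zero
    denominator (possible only for degenerate likelihoods) leaves the prior
    unchanged rather than producing a NaN.
    """
    p = _check_unit_interval("prior", prior)
    lh = _check_unit_interval("p_rep_given_h", likelihoods.p_rep_given_h)
    lnh = _check_unit_interval("p_rep_given_not_h", likelihoods.p_rep_given_not_h)
    if message == OPPOSE:
        lh, lnh = 1.0 - lh, 1.0 - lnh
    elif message != ENDORSE:
        raise ValueError(f"message must be {ENDORSE!r} or {OPPOSE!r}, got {message!r}")
    num = p * lh
    den = num + (1.0 - p) * lnh
    degenerate = den == 0.0
    if np.any(degenerate):
        logger.warning("zero denominator in Bayes update; returning prior unchanged")
    with np.errstate(invalid="ignore", divide="ignore"):
        post = np.where(degenerate, p, num / np.where(degenerate, 1.0, den))
    return float(post) if post.ndim == 0 else post


def is_backfire(
    trust: ArrayLike,
    expertise: ArrayLike,
    table: CredibilityTable = DEFAULT_TABLE,
) -> ArrayLike:
    """True where an endorsement from this source would lower belief.

    The backfire region is exactly p(rep|h) < p(rep|¬h).
    """
    lh, lnh = marginal_likelihoods(trust, expertise, table)
    out = np.asarray(lh) < np.asarray(lnh)
    return bool(out) if out.ndim == 0 else out
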