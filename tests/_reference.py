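"""Deliberately naive per-agent reference engine.

Re-implements one full campaign simulation with explicit Python loops and
scalar arithmetic — no vectorised model logic — as an independent oracle
for the production engine.  It shares only the random-stream protocol with
the production code (the same vector-shaped draws in the same order, and
the same without-replacement sampling primitive), so for a given seed the
two engines must return identical election tallies.
"""

from __future__ import annotations

import numpy as np

from mtcsim.campaigns import sample_without_replacement
from mtcsim.engine import RunConfig, RunResult

# Table values restated locally so this oracle does not lean on the
# package's credibility module.  Column order (T,E), (T,¬E), (¬T,E), (¬T,¬E).
_P_REP_H = (0.80, 0.58, 0.34, 0.18)
_P_REP_NOT_H = (0.22, 0.42, 0.59, 0.71)


def _scalar_likelihoods(t: float, e: float, table) -> tuple:
    w = (t * e, t * (1.0 - e), (1.0 - t) * e, (1.0 - t) * (1.0 - e))
    lh = 0
    lnh = 0
    for wi, ph, pnh in zip(w, table.p_rep_h, table.p_rep_not_h):
        lh = lh + wi * ph
        lnh = lnh + wi * pnh
    return lh, lnh


def _scalar_posterior(p: float, lh: float, lnh: float, message: str) -> float:
    if message == "oppose":
        lh, lnh = 1.0 - lh, 1.0 - lnh
    num = p * lh
    den = num + (1.0 - p) * lnh
    if den == 0.0:
        return p
    return num / den


def reference_run_simulation(config: RunConfig,
                             update_order=("mtc", "stochastic")) -> RunResult:
    """Loop-based spin-up, ticks and election; same seed protocol.

    ``update_order`` allows swapping which campaign's belief updates are
    applied first within a tick, for order-sensitivity checks.
    """
    config.validate()
    pc = config.population
    n = pc.n_voters
    rng = np.random.default_rng(config.seed)

    # spin-up: same six vector draws, clamped voter by voter
    raw = [
        rng.normal(pc.belief_mean, pc.belief_sd, size=n),
        rng.normal(pc.vote_mean, pc.vote_sd, size=n),
        rng.normal(pc.cred_mean_mtc, pc.cred_sd, size=n),
        rng.normal(pc.cred_mean_mtc, pc.cred_sd, size=n),
        rng.normal(pc.cred_mean_stochastic, pc.cred_sd, size=n),
        rng.normal(pc.cred_mean_stochastic, pc.cred_sd, size=n),
    ]
    belief = [min(max(x, 0.01), 1.0) for x in raw[0]]
    p_vote = [min(max(x, 0.01), 1.0) for x in raw[1]]
    clamp_p = lambda x: min(max(x, 0.01), 0.99)
    trust_m = [clamp_p(x) for x in raw[2]]
    exp_m = [clamp_p(x) for x in raw[3]]
    trust_s = [clamp_p(x) for x in raw[4]]
    exp_s = [clamp_p(x) for x in raw[5]]

    like = {"mtc": [], "stochastic": []}
    for i in range(n):
        like["mtc"].append(_scalar_likelihoods(trust_m[i], exp_m[i], config.table))
        like["stochastic"].append(
            _scalar_likelihoods(trust_s[i], exp_s[i], config.table)
        )

    by_id = {c.id: c for c in (config.mtc, config.stochastic)}
    thr = config.thresholds
    for _ in range(config.n_ticks):
        pool = []
        for i in range(n):
            cred = (trust_m[i] + exp_m[i]) / 2
            if (thr.belief_low < belief[i] < thr.belief_high
                    and cred >= thr.cred_min and p_vote[i] > thr.vote_min):
                pool.append(i)
        pool_arr = np.asarray(pool, dtype=np.int64)
        everyone = np.arange(n)
        # selection order is fixed: MTC draws first, then stochastic
        contacts = {
            "mtc": sample_without_replacement(rng, pool_arr, config.mtc.reach),
            "stochastic": sample_without_replacement(
                rng, everyone, config.stochastic.reach
            ),
        }
        for cid in update_order:
            for i in contacts[cid]:
                lh, lnh = like[cid][i]
                belief[i] = _scalar_posterior(
                    belief[i], lh, lnh, by_id[cid].stance
                )

    cast_u = rng.random(n)
    tie_u = rng.random(n)
    votes_m = votes_s = 0
    for i in range(n):
        if cast_u[i] < p_vote[i]:
            if belief[i] > 0.5 or (belief[i] == 0.5 and tie_u[i] < 0.5):
                votes_m += 1
            else:
                votes_s += 1
    total = votes_m + votes_s
    return RunResult(
        votes_mtc=votes_m,
        votes_stochastic=votes_s,
        abstentions=n - total,
        turnout=total / n,
        share_mtc=votes_m / total if total else float("nan"),
        final_belief_mean=float(np.mean(belief)),
    )
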