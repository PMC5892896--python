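"""Simulation sweeps and break-even estimation.

The headline experiment crosses the two candidates' population-mean
credibilities (3 × 3 grid, μ ∈ {0.4, 0.5, 0.6}) with ten stochastic-reach
ratios (stochastic reach / MTC reach, MTC reach fixed at 20) and repeats
every cell, 9,000 runs at the defaults.  Per cell the mean MTC share of
cast votes is computed; the *break-even* ratio — where that curve crosses
0.5 and the stochastic candidate draws level — is estimated by linear
interpolation between adjacent grid points.

Each run's seed is derived from the sweep's base seed and the cell
indices, so results are independent of execution order and the sweep is
embarrassingly parallel and resumable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import make_run_config, run_simulation

DEFAULT_CRED_MEANS = (0.4, 0.5, 0.6)
#: Ten reach ratios, 0.5–5.0 in steps of 0.5 (10–100 contacts/day at
#: MTC reach 20), bracketing the interesting break-even region.
DEFAULT_REACH_RATIOS = tuple(np.round(np.arange(0.5, 5.01, 0.5), 2))

RUN_CSV_COLUMNS = [
    "mu_mtc", "mu_stoch", "ratio", "rep", "seed",
    "votes_mtc", "votes_stoch", "abstentions", "share_mtc",
]


@dataclass(frozen=True)
class SweepConfig:
    cred_means_mtc: tuple = DEFAULT_CRED_MEANS
    cred_means_stoch: tuple = DEFAULT_CRED_MEANS
    reach_mtc: int = 20
    reach_ratios: tuple = DEFAULT_REACH_RATIOS
    reps: int = 100
    base_seed: int = 0
    n_workers: int = 1
    n_voters: int = 10_000
    n_ticks: int = 50

    @property
    def n_runs(self) -> int:
        return (len(self.cred_means_mtc) * len(self.cred_means_stoch)
                * len(self.reach_ratios) * self.reps)


@dataclass
class SweepResult:
    config: SweepConfig
    runs: pd.DataFrame        # one row per simulation
    cells: pd.DataFrame       # per (mu_mtc, mu_stoch, ratio): mean/sd share
    breakeven: dict           # (mu_mtc, mu_stoch) -> ratio or None


def run_seed(base_seed: int, i_mu_mtc: int, i_mu_stoch: int,
             i_ratio: int, rep: int) -> int:
    """Deterministic per-run seed from the base seed and cell indices."""
    ss = np.random.SeedSequence([base_seed, i_mu_mtc, i_mu_stoch, i_ratio, rep])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def stochastic_reach(ratio: float, reach_mtc: int) -> int:
    """Stochastic campaign reach for a given ratio, rounded to an integer."""
    return int(round(ratio * reach_mtc))


def _one_run(mu_mtc, mu_stoch, ratio, rep, seed, cfg: SweepConfig) -> dict:
    rc = make_run_config(
        cred_mean_mtc=mu_mtc,
        cred_mean_stochastic=mu_stoch,
        reach_mtc=cfg.reach_mtc,
        reach_stochastic=stochastic_reach(ratio, cfg.reach_mtc),
        seed=seed,
        n_voters=cfg.n_voters,
        n_ticks=cfg.n_ticks,
    )
    res = run_simulation(rc)
    return {
        "mu_mtc": mu_mtc, "mu_stoch": mu_stoch, "ratio": ratio,
        "rep": rep, "seed": seed,
        "votes_mtc": res.votes_mtc, "votes_stoch": res.votes_stochastic,
        "abstentions": res.abstentions, "share_mtc": res.share_mtc,
    }


def run_sweep(config: SweepConfig, progress: bool = False) -> SweepResult:
    """Execute the full grid.  Result is independent of execution order."""
    tasks = [
        (mu_m, mu_s, ratio, rep,
         run_seed(config.base_seed, i, j, k, rep), config)
        for i, mu_m in enumerate(config.cred_means_mtc)
        for j, mu_s in enumerate(config.cred_means_stoch)
        for k, ratio in enumerate(config.reach_ratios)
        for rep in range(config.reps)
    ]
    if config.n_workers > 1:
        from joblib import Parallel, delayed
        rows = Parallel(n_jobs=config.n_workers)(
            delayed(_one_run)(*t) for t in tasks
        )
    else:
        rows = [_one_run(*t) for t in tasks]
    runs = pd.DataFrame(rows, columns=RUN_CSV_COLUMNS)
    cells = aggregate_runs(runs)
    breakeven = breakeven_from_cells(cells)
    return SweepResult(config=config, runs=runs, cells=cells, breakeven=breakeven)


def aggregate_runs(runs: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean and sd of the MTC vote share."""
    g = runs.groupby(["mu_mtc", "mu_stoch", "ratio"])["share_mtc"]
    cells = g.agg(mean_share_mtc="mean", sd_share_mtc="std", n_reps="count")
    return cells.reset_index().sort_values(["mu_mtc", "mu_stoch", "ratio"])


def estimate_breakeven(ratios, mean_shares) -> float | None:
    """Smallest ratio where the interpolated share curve crosses 0.5.

    ``ratios`` must be strictly increasing.  Returns ``None`` when the
    curve stays on one side of 0.5 over the whole swept range.
    """
    r = np.asarray(ratios, dtype=float)
    s = np.asarray(mean_shares, dtype=float)
    if r.ndim != 1 or r.shape != s.shape or r.size < 2:
        raise ValueError("need matching 1-D arrays with at least 2 points")
    if np.any(np.diff(r) <= 0):
        raise ValueError("ratios must be strictly increasing")
    d = s - 0.5
    for i in range(r.size - 1):
        if d[i] == 0.0:
            return float(r[i])
        if d[i] * d[i + 1] < 0.0:
            return float(r[i] + d[i] / (d[i] - d[i + 1]) * (r[i + 1] - r[i]))
    if d[-1] == 0.0:
        return float(r[-1])
    return None


def breakeven_from_cells(cells: pd.DataFrame) -> dict:
    out = {}
    for (mu_m, mu_s), sub in cells.groupby(["mu_mtc", "mu_stoch"]):
        sub = sub.sort_values("ratio")
        if len(sub) < 2:  # a one-point curve cannot bracket a crossing
            out[(mu_m, mu_s)] = None
            continue
        out[(mu_m, mu_s)] = estimate_breakeven(
            sub["ratio"].to_numpy(), sub["mean_share_mtc"].to_numpy()
        )
    return out


def breakeven_curve(
    mu_mtc: float,
    mu_stoch: float,
    ratios,
    reps: int,
    base_seed: int = 0,
    reach_mtc: int = 20,
    n_voters: int = 10_000,
    n_ticks: int = 50,
    n_workers: int = 1,
) -> pd.DataFrame:
    """Mean MTC share vs. reach ratio for a single credibility cell."""
    cfg = SweepConfig(
        cred_means_mtc=(mu_mtc,), cred_means_stoch=(mu_stoch,),
        reach_mtc=reach_mtc, reach_ratios=tuple(ratios), reps=reps,
        base_seed=base_seed, n_voters=n_voters, n_ticks=n_ticks,
        n_workers=n_workers,
    )
    return run_sweep(cfg).cells


def plot_sweep(cells: pd.DataFrame, path=None):
    """3×3 facet plot of mean MTC share vs. reach ratio, dashed 0.5 line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mus_m = sorted(cells["mu_mtc"].unique())
    mus_s = sorted(cells["mu_stoch"].unique())
    fig, axes = plt.subplots(
        len(mus_s), len(mus_m), figsize=(3 * len(mus_m), 2.5 * len(mus_s)),
        sharex=True, sharey=True, squeeze=False,
    )
    for r, mu_s in enumerate(mus_s):
        for c, mu_m in enumerate(mus_m):
            ax = axes[r][c]
            sub = cells[(cells.mu_mtc == mu_m) & (cells.mu_stoch == mu_s)]
            sub = sub.sort_values("ratio")
            ax.plot(sub["ratio"], sub["mean_share_mtc"], marker="o", ms=3)
            ax.axhline(0.5, ls="--", c="grey", lw=1)
            ax.set_title(f"μ_mtc={mu_m}, μ_stoch={mu_s}", fontsize=8)
    for ax in axes[-1]:
        ax.set_xlabel("reach ratio")
    for row in axes:
        row[0].set_ylabel("mean MTC share")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
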