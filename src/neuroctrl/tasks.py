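"""Experiment orchestration: cohort sweeps, rankings, and the
natural-frequency variability experiment.

A *sweep* runs one control task per (subject, input region, nonlinearity),
collecting cost, inverse cost (zero for uncontrollable tasks), and the
controllable/success flags into a :class:`CostTable`.  Regions are then
ranked by mean inverse cost across subjects — the quantity used to pick
stimulation targets — and per-subject success counts feed the global
topology analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .connectome import ConnectomeMatrix
from .dynamics import DuffingParams, simulate_ll
from .errors import ValidationError
from .sdre import SDREWeights, run_control_task

__all__ = [
    "CostTable",
    "sweep",
    "rank_regions",
    "count_successes",
    "frequency_variability_experiment",
]

log = logging.getLogger(__name__)

COST_COLUMNS = ["subject_id", "region", "gamma", "cost", "cost_l1",
                "inverse_cost", "controllable", "success", "failed",
                "tracking_error", "uncontrolled_error"]


@dataclass
class CostTable:
    """Tidy per-task results; one row per (subject, region, gamma).

    Invariant: ``inverse_cost == 0`` exactly when ``cost`` is infinite,
    otherwise ``inverse_cost == 1/cost``.  Infinities round-trip through CSV
    as the literal string ``inf``.
    """

    df: pd.DataFrame

    def __post_init__(self):
        missing = set(COST_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValidationError(f"cost table missing columns {sorted(missing)}")

    def key_set(self) -> set[tuple]:
        return set(map(tuple, self.df[["subject_id", "region", "gamma"]]
                       .itertuples(index=False, name=None)))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "CostTable":
        df = pd.read_csv(path)
        df["subject_id"] = df["subject_id"].astype(str)
        return cls(df)


def _weights_from(config: RunConfig) -> SDREWeights:
    return SDREWeights(q=config.q, r=config.r,
                       gain_update_interval=config.gain_update_interval)


def sweep(cohort: list[ConnectomeMatrix], config: RunConfig,
          gamma_list: list[float] | None = None,
          regions: list[int] | None = None,
          existing: CostTable | None = None,
          compute_uncontrolled: bool = True,
          alpha_p: float | np.ndarray | None = None,
          alpha_h: float | np.ndarray | None = None) -> CostTable:
    """Run the full (subject x region x gamma) grid of control tasks.

    Deterministic for a fixed config.  Entries already present in
    ``existing`` are skipped (resumability).  Per-task failures are recorded
    in the table and never abort the sweep.  The healthy reference and the
    uncontrolled pathological trajectory are simulated once per
    (subject, gamma) and shared by that subject's tasks.
    """
    if not cohort:
        raise ValidationError("cohort is empty")
    config.validate()
    gammas = list(config.gamma_grid if gamma_list is None else gamma_list)
    a_p = config.resolved_alpha_p() if alpha_p is None else alpha_p
    a_h = config.resolved_alpha_h() if alpha_h is None else alpha_h
    weights = _weights_from(config)
    done = existing.key_set() if existing is not None else set()
    rows = [] if existing is None else [existing.df]
    new_rows = []
    for m in cohort:
        N = m.n_regions
        node_list = list(range(N)) if regions is None else list(regions)
        z0_p = np.concatenate([np.full(N, config.x0_p), np.zeros(N)])
        z0_h = np.concatenate([np.full(N, config.x0_h), np.zeros(N)])
        for gamma in gammas:
            todo = [r for r in node_list
                    if (m.subject_id, r, gamma) not in done]
            if not todo:
                continue
            p_h = DuffingParams(alpha=a_h, gamma=gamma, beta=config.beta, N=N)
            ref = simulate_ll(p_h, m.W, z0_h, config.T, config.dt)
            free = None
            if compute_uncontrolled:
                p_p = DuffingParams(alpha=a_p, gamma=gamma,
                                    beta=config.beta, N=N)
                free = simulate_ll(p_p, m.W, z0_p, config.T, config.dt)
            for r in todo:
                try:
                    res = run_control_task(
                        m.W, a_p, a_h, gamma, config.beta, r, weights,
                        z0_p=z0_p, z0_h=z0_h, T=config.T, dt=config.dt,
                        tol_track=config.tol_track, ref_traj=ref,
                        free_traj=free,
                        compute_uncontrolled=compute_uncontrolled,
                        keep_u=False)
                    row = dict(
                        subject_id=m.subject_id, region=r, gamma=gamma,
                        cost=res.cost, cost_l1=res.cost_l1,
                        inverse_cost=res.inverse_cost,
                        controllable=res.controllable, success=res.success,
                        failed=res.failed, tracking_error=res.tracking_error,
                        uncontrolled_error=res.uncontrolled_error)
                except Exception as exc:  # never abort the sweep
                    log.warning("task (%s, %d, %g) raised: %s",
                                m.subject_id, r, gamma, exc)
                    row = dict(
                        subject_id=m.subject_id, region=r, gamma=gamma,
                        cost=np.inf, cost_l1=np.inf, inverse_cost=0.0,
                        controllable=False, success=False, failed=True,
                        tracking_error=np.nan, uncontrolled_error=np.nan)
                new_rows.append(row)
            log.info("subject %s gamma %g: %d tasks done",
                     m.subject_id, gamma, len(todo))
    if new_rows:
        rows.append(pd.DataFrame(new_rows))
    df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=COST_COLUMNS)
    return CostTable(df[COST_COLUMNS])


def rank_regions(table: CostTable, gamma: float) -> pd.DataFrame:
    """Mean inverse cost per region across subjects (uncontrollable tasks
    contribute 0), with SEM = sd/sqrt(n_subjects), sorted descending.

    Ties are broken by region index, so the rank column is a stable
    permutation of 1..N.
    """
    sub = table.df[table.df["gamma"] == gamma]
    if sub.empty:
        raise ValidationError(f"no entries for gamma = {gamma}")
    grouped = sub.groupby("region")["inverse_cost"]
    mean = grouped.mean()
    n = grouped.count()
    sd = grouped.std(ddof=1).fillna(0.0)
    out = pd.DataFrame({
        "mean_inverse_cost": mean,
        "sem": sd / np.sqrt(n),
        "n_subjects": n,
    })
    out = out.sort_values(["mean_inverse_cost", "region"],
                          ascending=[False, True],
                          kind="mergesort")  # stable: ties by region index
    out["rank"] = np.arange(1, len(out) + 1)
    out["gamma"] = gamma
    return out


def count_successes(table: CostTable, gamma: float) -> pd.Series:
    """Number of successful tasks per subject (0..N)."""
    sub = table.df[table.df["gamma"] == gamma]
    if sub.empty:
        raise ValidationError(f"no entries for gamma = {gamma}")
    return sub.groupby("subject_id")["success"].sum().astype(int)


def count_controllable(table: CostTable, gamma: float) -> pd.Series:
    """Number of controllable tasks per subject (0..N)."""
    sub = table.df[table.df["gamma"] == gamma]
    if sub.empty:
        raise ValidationError(f"no entries for gamma = {gamma}")
    return sub.groupby("subject_id")["controllable"].sum().astype(int)


def frequency_variability_experiment(
        W: ConnectomeMatrix, config: RunConfig, variability_pct: float,
        n_realizations: int = 10, seed: int = 0,
        gamma: float | None = None,
        compute_uncontrolled: bool = False) -> pd.DataFrame:
    """Effect of per-node natural-frequency variability on control.

    Each realization draws one factor per node uniformly in
    [1 - p, 1 + p] (p = variability_pct/100) and scales both stiffnesses
    alpha_p and alpha_h by it — a node-specific time constant.  The full
    single-subject region sweep is then run; reported per realization are
    the number of controllable tasks and the lowest finite cost (inf when
    every task is uncontrollable).  Summarize across realizations with
    ``df[["n_controllable", "lowest_cost"]].agg(["mean", "std"])``.
    """
    if variability_pct < 0:
        raise ValidationError("variability_pct must be non-negative")
    if n_realizations < 1:
        raise ValidationError("n_realizations must be >= 1")
    rng = np.random.default_rng(seed)
    p = variability_pct / 100.0
    g = config.gamma_grid[0] if gamma is None else gamma
    a_p0 = config.resolved_alpha_p()
    a_h0 = config.resolved_alpha_h()
    N = W.n_regions
    recs = []
    for k in range(n_realizations):
        factor = rng.uniform(1.0 - p, 1.0 + p, size=N)
        table = sweep([W], config, gamma_list=[g],
                      compute_uncontrolled=compute_uncontrolled,
                      alpha_p=a_p0 * factor, alpha_h=a_h0 * factor)
        finite = table.df.loc[np.isfinite(table.df["cost"]), "cost"]
        recs.append(dict(
            realization=k,
            variability_pct=variability_pct,
            n_controllable=int(table.df["controllable"].sum()),
            n_success=int(table.df["success"].sum()),
            lowest_cost=float(finite.min()) if len(finite) else np.inf,
        ))
    return pd.DataFrame(recs)
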