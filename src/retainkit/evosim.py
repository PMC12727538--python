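"""Forward-time birth–death simulation of ecDNA copy number under selection
and imperfect mitotic retention.

Model
-----
Each cell carries an integer ecDNA copy number ``N``. At birth a cell draws
competing exponential waiting times: time to division ``t_b ~ Exp(lambda_1)``
with ``lambda_1 = lambda_base * (1 + s)`` (``s = s0`` when ``N == 0``, else
``s1``) and time to death ``t_d ~ Exp(mu)``. The earlier event wins; a
division replicates the ecDNA to ``2N`` copies, retains
``R ~ Binomial(2N, nu)`` of them (each post-replication copy segregates with
the chromosomes independently with probability ``nu``), and splits the
retained pool symmetrically: ``n1 ~ Binomial(R, 0.5)``, ``n2 = R - n1``.
An alternative mode retains whole pre-replication copies
(``R = 2 * Binomial(N, nu)``).

Because cells never interact, the global event queue factorises over cells;
the simulation executes exactly this process in vectorised unit-time slabs,
recording population size, mean copy number and the fraction of
ecDNA-positive cells on the unit time grid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimParams",
    "TrajectoryRecord",
    "birth_rate",
    "segregate",
    "simulate_population",
    "sweep",
    "mean_frequency_trajectories",
    "classify_maintenance",
    "minimum_maintained_nu",
    "NU_GRID",
]

#: Retention-rate grid used throughout the sweep analyses.
NU_GRID = (0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.97, 0.98, 0.99, 1.0)


@dataclass(frozen=True)
class SimParams:
    """Configuration of one population simulation.

    Defaults: base birth rate 0.5 and death rate 0.33 per unit time; 25 time
    units simulated; populations smaller than ``min_final_cells`` at the end
    are flagged (see ``resample_min_cells`` in :func:`simulate_population`).
    """

    k_init: int = 10
    s0: float = 0.0
    s1: float = 0.0
    lambda_base: float = 0.5
    mu: float = 0.33
    nu: float = 1.0
    t_max: float = 25.0
    min_final_cells: int = 1000
    n0: int = 1
    max_cells: int = 2_000_000
    segregation: str = "per-copy"  # or "whole-copy" (R = 2*Binomial(N, nu))
    on_overflow: str = "error"     # or "downsample"

    def __post_init__(self) -> None:
        if self.lambda_base <= 0 or self.mu <= 0:
            raise ValueError("rates must be > 0")
        if not (0.0 <= self.nu <= 1.0):
            raise ValueError("nu must be in [0, 1]")
        if self.t_max <= 0:
            raise ValueError("t_max must be > 0")
        if self.k_init < 0 or self.n0 < 1:
            raise ValueError("k_init >= 0 and n0 >= 1 required")
        if 1 + self.s0 <= 0 or 1 + self.s1 <= 0:
            raise ValueError("selection coefficients must satisfy 1 + s > 0")
        if self.segregation not in ("per-copy", "whole-copy"):
            raise ValueError(f"unknown segregation mode {self.segregation!r}")
        if self.on_overflow not in ("error", "downsample"):
            raise ValueError(f"unknown overflow policy {self.on_overflow!r}")

    def replace(self, **kw) -> "SimParams":
        return dataclasses.replace(self, **kw)


@dataclass
class TrajectoryRecord:
    """Per-unit-time population summaries of one simulation."""

    times: np.ndarray          # unit grid 0..t_max
    n_cells: np.ndarray        # live cells at each grid time (rescaled if downsampled)
    mean_copies: np.ndarray    # mean ecDNA copies per live cell (NaN once extinct)
    frac_positive: np.ndarray  # fraction of cells with >= 1 copy (0 once extinct)
    final_cells: int
    extinct: bool
    below_min_final: bool
    downsampled: bool
    attempts: int = 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "n_cells": self.n_cells,
                "mean_copies": self.mean_copies,
                "frac_positive": self.frac_positive,
            }
        )


def birth_rate(s: float, lambda_base: float = 0.5) -> float:
    """Birth rate of a cell under selection coefficient ``s``:
    ``lambda_1 = lambda_base * (1 + s)``."""
    if 1 + s <= 0:
        raise ValueError("1 + s must be > 0")
    return lambda_base * (1 + s)


def segregate(
    N: int | np.ndarray,
    nu: float,
    rng: np.random.Generator,
    mode: str = "per-copy",
) -> tuple[np.ndarray, np.ndarray]:
    """Split the ecDNA copies of dividing parent cells between two daughters.

    Vectorised over parents. Returns ``(n1, n2)`` with
    ``n1 + n2 = R <= 2N`` always.
    """
    N = np.atleast_1d(np.asarray(N, dtype=np.int64))
    if (N < 0).any():
        raise ValueError("copy numbers must be >= 0")
    if mode == "per-copy":
        R = rng.binomial(2 * N, nu)
    elif mode == "whole-copy":
        R = 2 * rng.binomial(N, nu)
    else:
        raise ValueError(f"unknown segregation mode {mode!r}")
    n1 = rng.binomial(R, 0.5)
    return n1, R - n1


def _draw_events(
    copies: np.ndarray, birth_times: np.ndarray, p: SimParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Competing exponentials per cell: (absolute event time, divides?)."""
    lam = p.lambda_base * (1 + np.where(copies > 0, p.s1, p.s0))
    t_b = rng.exponential(1.0 / lam)
    t_d = rng.exponential(1.0 / p.mu, size=len(copies))
    divides = t_b < t_d
    return birth_times + np.minimum(t_b, t_d), divides


def _simulate_once(p: SimParams, rng: np.random.Generator) -> TrajectoryRecord:
    grid = np.arange(0, int(np.floor(p.t_max)) + 1, dtype=float)
    if grid[-1] < p.t_max:
        grid = np.append(grid, p.t_max)
    n_steps = len(grid)

    copies = np.full(p.n0, p.k_init, dtype=np.int64)
    event_time, divides = _draw_events(copies, np.zeros(p.n0), p, rng)

    n_cells = np.zeros(n_steps)
    mean_copies = np.full(n_steps, np.nan)
    frac_positive = np.zeros(n_steps)
    scale = 1.0
    downsampled = False
    extinct = False

    def record(i: int) -> None:
        n_cells[i] = len(copies) * scale
        if len(copies):
            mean_copies[i] = copies.mean()
            frac_positive[i] = (copies > 0).mean()

    record(0)
    for i in range(1, n_steps):
        t_next = grid[i]
        # execute every event strictly before t_next (cells are independent,
        # so the order across cells is immaterial)
        while True:
            pending = event_time < t_next
            if not pending.any():
                break
            keep = ~pending
            div = pending & divides
            parents = copies[div]
            parent_times = event_time[div]
            copies = copies[keep]
            event_time = event_time[keep]
            divides = divides[keep]
            if len(parents):
                n1, n2 = segregate(parents, p.nu, rng, mode=p.segregation)
                d_copies = np.concatenate([n1, n2])
                d_birth = np.concatenate([parent_times, parent_times])
                d_event, d_div = _draw_events(d_copies, d_birth, p, rng)
                copies = np.concatenate([copies, d_copies])
                event_time = np.concatenate([event_time, d_event])
                divides = np.concatenate([divides, d_div])
        if len(copies) == 0:
            extinct = True
            record(i)  # zeros / NaN from initialisation
            break
        if len(copies) > p.max_cells:
            if p.on_overflow == "error":
                raise RuntimeError(
                    f"population exceeded max_cells={p.max_cells} at t={t_next}"
                )
            idx = rng.choice(len(copies), size=p.max_cells, replace=False)
            scale *= len(copies) / p.max_cells
            copies = copies[idx]
            event_time = event_time[idx]
            divides = divides[idx]
            downsampled = True
        record(i)

    if extinct:
        # frequency 0 from extinction time onward; counts stay 0
        pass
    final = int(round(n_cells[-1]))
    return TrajectoryRecord(
        times=grid,
        n_cells=n_cells,
        mean_copies=mean_copies,
        frac_positive=frac_positive,
        final_cells=final,
        extinct=extinct,
        below_min_final=final < p.min_final_cells,
        downsampled=downsampled,
    )


def simulate_population(
    params: SimParams,
    seed: int | np.random.Generator | None = None,
    resample_min_cells: bool = False,
    max_attempts: int = 25,
) -> TrajectoryRecord:
    """Simulate one growing population and record it on the unit time grid.

    With ``resample_min_cells=True`` the run is repeated (fresh randomness)
    until the final population holds at least ``params.min_final_cells``
    cells, up to ``max_attempts`` tries; the last attempt is returned
    (still flagged) if the bound is never met. The default reports the
    first run as-is, flagging small or extinct outcomes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rec = _simulate_once(params, rng)
    attempts = 1
    while resample_min_cells and rec.below_min_final and attempts < max_attempts:
        rec = _simulate_once(params, rng)
        attempts += 1
    rec.attempts = attempts
    return rec


def sweep(
    s1_values: Sequence[float],
    nu_values: Sequence[float] = NU_GRID,
    n_reps: int = 10,
    base_params: SimParams | None = None,
    seed: int = 0,
    resample_min_cells: bool = False,
) -> pd.DataFrame:
    """Replicate simulations over an (s1, nu) grid.

    Returns a tidy frame with one row per (s1, nu, replicate, time):
    ``s1, nu, replicate, time, n_cells, mean_copies, frac_positive,
    extinct, below_min_final``. Replicate seeds derive deterministically
    from ``seed`` and the grid position, so reruns are identical.
    """
    if len(s1_values) == 0 or len(nu_values) == 0:
        raise ValueError("empty parameter grid")
    base = base_params or SimParams()
    frames = []
    for ci, (s1, nu) in enumerate(
        (s1, nu) for s1 in s1_values for nu in nu_values
    ):
        p = base.replace(s1=float(s1), nu=float(nu))
        for rep in range(n_reps):
            rng = np.random.default_rng(np.random.SeedSequence([seed, ci, rep]))
            rec = simulate_population(p, seed=rng, resample_min_cells=resample_min_cells)
            df = rec.to_frame()
            df.insert(0, "s1", p.s1)
            df.insert(1, "nu", p.nu)
            df.insert(2, "replicate", rep)
            df["extinct"] = rec.extinct
            df["below_min_final"] = rec.below_min_final
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def mean_frequency_trajectories(sweep_df: pd.DataFrame) -> pd.DataFrame:
    """Across-replicate mean of the ecDNA-positive fraction per grid time.

    Extinct replicates contribute frequency 0 from their extinction time
    (already encoded in the per-replicate records): a replicate whose last
    recorded time precedes the grid end is carried forward with frequency 0.
    """
    out = []
    for (s1, nu), sub in sweep_df.groupby(["s1", "nu"]):
        times = np.sort(sub["time"].unique())
        reps = sub["replicate"].unique()
        mat = np.zeros((len(reps), len(times)))
        for ri, rep in enumerate(reps):
            r = sub[sub["replicate"] == rep].set_index("time")["frac_positive"]
            mat[ri] = r.reindex(times).fillna(0.0).to_numpy()
        out.append(
            pd.DataFrame(
                {"s1": s1, "nu": nu, "time": times, "mean_frac_positive": mat.mean(axis=0)}
            )
        )
    return pd.concat(out, ignore_index=True)


def classify_maintenance(sweep_df: pd.DataFrame, ratio: float = 0.5) -> pd.DataFrame:
    """Classify each (s1, nu) combination as maintained or lost.

    Maintained: the final across-replicate mean frequency of ecDNA-positive
    cells is at least ``ratio`` times the maximum of that mean trajectory.
    """
    traj = mean_frequency_trajectories(sweep_df)
    rows = []
    for (s1, nu), sub in traj.groupby(["s1", "nu"]):
        sub = sub.sort_values("time")
        final = sub["mean_frac_positive"].iloc[-1]
        peak = sub["mean_frac_positive"].max()
        rows.append(
            {
                "s1": s1,
                "nu": nu,
                "final_mean_frac": final,
                "peak_mean_frac": peak,
                "maintained": bool(peak > 0 and final >= ratio * peak),
            }
        )
    return pd.DataFrame(rows).sort_values(["s1", "nu"]).reset_index(drop=True)


def minimum_maintained_nu(maintenance: pd.DataFrame, s1: float) -> float:
    """Smallest grid nu classified as maintained at the given s1."""
    sub = maintenance[(maintenance["s1"] == s1) & maintenance["maintained"]]
    if sub.empty:
        return float("nan")
    return float(sub["nu"].min())


# ---------------------------------------------------------------------------
# small-scale lineage recording (event log + Newick), for modest populations


def simulate_lineage(
    params: SimParams, seed: int | np.random.Generator | None = None, max_cells: int = 100_000
) -> tuple[pd.DataFrame, str]:
    """Explicit per-cell simulation recording every lineage event.

    Intended for small populations (tree inspection / event-log tests);
    raises beyond ``max_cells`` total cells. Returns the event table
    (cell id, parent, birth time, t_b, t_d, outcome, daughter copies) and a
    Newick string of the recorded lineage with branch lengths.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = params
    events: list[dict] = []
    children: dict[int, list[int]] = {}
    # stack of (cell_id, birth_time, copies)
    stack = [(i, 0.0, p.k_init) for i in range(p.n0)]
    next_id = p.n0
    end_time: dict[int, float] = {}
    birth: dict[int, float] = {}
    while stack:
        cid, t0, n = stack.pop()
        birth[cid] = t0
        lam = birth_rate(p.s1 if n > 0 else p.s0, p.lambda_base)
        t_b = rng.exponential(1 / lam)
        t_d = rng.exponential(1 / p.mu)
        ev = {"cell": cid, "copies": n, "birth_time": t0, "t_b": t_b, "t_d": t_d}
        if t_b < t_d and t0 + t_b <= p.t_max:
            n1, n2 = segregate(n, p.nu, rng, mode=p.segregation)
            ev.update(outcome="division", n1=int(n1[0]), n2=int(n2[0]))
            end_time[cid] = t0 + t_b
            kids = [next_id, next_id + 1]
            children[cid] = kids
            stack.append((kids[0], t0 + t_b, int(n1[0])))
            stack.append((kids[1], t0 + t_b, int(n2[0])))
            next_id += 2
            if next_id > max_cells:
                raise RuntimeError("lineage recording limited to small populations")
        elif t_d <= t_b and t0 + t_d <= p.t_max:
            ev.update(outcome="death", n1=np.nan, n2=np.nan)
            end_time[cid] = t0 + t_d
        else:
            ev.update(outcome="censored", n1=np.nan, n2=np.nan)
            end_time[cid] = p.t_max
        events.append(ev)

    def newick(cid: int) -> str:
        bl = end_time[cid] - birth[cid]
        if cid in children:
            inner = ",".join(newick(k) for k in children[cid])
            return f"({inner})c{cid}:{bl:.6g}"
        return f"c{cid}:{bl:.6g}"

    roots = [newick(i) for i in range(p.n0)]
    nwk = ";".join(roots) + ";"
    return pd.DataFrame(events).sort_values("cell").reset_index(drop=True), nwk
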