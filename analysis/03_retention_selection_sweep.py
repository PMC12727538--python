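"""Sweep retention rate and selection in the birth–death ecDNA simulation.

Simulates 10 replicates per (s1, nu) combination on the standard grid,
writes tidy trajectories and the maintained/lost classification, reports
the smallest retention rate that maintains ecDNA-positive cells under
s1 = 0.8, and plots the mean frequency trajectories.

Default is a smoke-scale run (15 time units); pass --full for the standard
25 time units.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from retainkit.evosim import (
    NU_GRID,
    SimParams,
    classify_maintenance,
    mean_frequency_trajectories,
    minimum_maintained_nu,
    sweep,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/evosim"))
    ap.add_argument("--full", action="store_true", help="25 time units (default 15)")
    ap.add_argument("--s1", type=float, nargs="+", default=[0.0, 0.4, 0.8])
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    t_max = 25.0 if args.full else 15.0
    base = SimParams(k_init=10, s0=0.0, lambda_base=0.5, mu=0.33, t_max=t_max,
                     on_overflow="downsample")
    df = sweep(args.s1, NU_GRID, n_reps=10, base_params=base, seed=args.seed,
               resample_min_cells=True)
    df.to_csv(args.outdir / "trajectories.tsv", sep="\t", index=False)
    maint = classify_maintenance(df)
    maint.to_csv(args.outdir / "maintenance.tsv", sep="\t", index=False)

    if 0.8 in args.s1:
        print(f"smallest maintained nu at s1=0.8 (t_max={t_max:g}): "
              f"{minimum_maintained_nu(maint, 0.8)}")
    print(maint.to_string(index=False))

    traj = mean_frequency_trajectories(df)
    s1_vals = sorted(traj["s1"].unique())
    fig, axes = plt.subplots(1, len(s1_vals), figsize=(4 * len(s1_vals), 3.2),
                             sharey=True, squeeze=False)
    for ax, s1 in zip(axes[0], s1_vals):
        for nu, sub in traj[traj["s1"] == s1].groupby("nu"):
            ax.plot(sub["time"], sub["mean_frac_positive"], label=f"{nu:g}")
        ax.set_title(f"s1 = {s1:g}")
        ax.set_xlabel("time")
    axes[0][0].set_ylabel("mean fraction ecDNA-positive")
    axes[0][-1].legend(title="retention", fontsize=7)
    fig.tight_layout()
    fig.savefig(args.outdir / "frequency_trajectories.png", dpi=150)
    print(f"wrote {args.outdir}/trajectories.tsv, maintenance.tsv, "
          "frequency_trajectories.png")


if __name__ == "__main__":
    main()
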