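#!/usr/bin/env python
"""Run the multicellular studies and write tidy CSV results.

Subcommands:
  fusion       neck-diameter censuses of a two-spheroid fusion run
               (columns: time, neck_y, neck_z)
  crypt        clone-count censuses across replicates
               (columns: replicate, time, n_cells, n_clones)
  delta-notch  patterning trajectory of the monolayer
               (columns: time, neighbor_delta_corr)
  membrane     compartment solute totals during active pumping
               (columns: time, lower, upper, channel, both)

Example:
  python scripts/studies.py crypt --replicates 3 --t-end 300 --out crypt.csv
"""
from __future__ import annotations

import click
import pandas as pd

from particell.models import (
    build_delta_notch,
    build_membrane_pump,
    compartment_totals,
    neighbor_delta_correlation,
    run_crypt_replicate,
    run_fusion,
)


@click.group()
def main():
    """Multicellular study runners (tidy CSV output)."""


@main.command()
@click.option("--n-per-spheroid", type=int, default=500, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--t-end", type=float, default=50.0, show_default=True)
@click.option("--out", default="fusion.csv", show_default=True)
def fusion(n_per_spheroid, seed, t_end, out):
    df = run_fusion(n_per_spheroid=n_per_spheroid, seed=seed, t_end=t_end)
    df.to_csv(out, index=False)
    click.echo(f"wrote {len(df)} censuses to {out}")


@main.command()
@click.option("--replicates", type=int, default=10, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--t-end", type=float, default=1100.0, show_default=True)
@click.option("--out", default="crypt.csv", show_default=True)
def crypt(replicates, seed, t_end, out):
    frames = []
    for rep in range(replicates):
        df = run_crypt_replicate(seed=seed + rep, t_end=t_end)
        df.insert(0, "replicate", rep)
        frames.append(df)
        click.echo(f"replicate {rep}: final clones {df['n_clones'].iloc[-1]}")
    pd.concat(frames, ignore_index=True).to_csv(out, index=False)
    click.echo(f"wrote {out}")


@main.command("delta-notch")
@click.option("--nx", type=int, default=12, show_default=True)
@click.option("--ny", type=int, default=12, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--t-end", type=float, default=80.0, show_default=True)
@click.option("--induction/--no-induction", default=False, show_default=True)
@click.option("--out", default="delta_notch.csv", show_default=True)
def delta_notch(nx, ny, seed, t_end, induction, out):
    u, model = build_delta_notch(nx=nx, ny=ny, seed=seed, induction=induction)
    rows = []
    stride = max(1, int(round(1.0 / u.dt)))
    while u.time < t_end:
        u.step(stride)
        rows.append({"time": u.time, "neighbor_delta_corr": neighbor_delta_correlation(model)})
    pd.DataFrame(rows).to_csv(out, index=False)
    click.echo(f"wrote {len(rows)} censuses to {out}")


@main.command()
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--steps", type=int, default=2000, show_default=True)
@click.option("--out", default="membrane.csv", show_default=True)
def membrane(seed, steps, out):
    u = build_membrane_pump(seed=seed)
    rows = []
    for s in range(0, steps + 1, 50):
        if s:
            u.step(50)
        rows.append({"time": u.time, **compartment_totals(u)})
    pd.DataFrame(rows).to_csv(out, index=False)
    click.echo(f"wrote {len(rows)} censuses to {out}")


if __name__ == "__main__":
    main()
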