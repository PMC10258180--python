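"""Generate the synthetic study area.

Produces the desk-scale stand-in for the real study domain: fractal terrain,
clustered abandoned-mine point sources, a smooth truth wind field, the three
MET observation sources (two direct arms sampling the truth exactly, one
gridded arm smoothed and biased), wells, roads, vegetation, and drainage
zones. All artifacts are written under results/run/.

    python analysis/01_simulate_world.py [--seed 42] [--outdir results/run]
"""

import argparse
from pathlib import Path

from aumex.config import load_config
from aumex.pipeline import save_world, simulate_world


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--outdir", type=Path, default=Path("results/run"))
    args = ap.parse_args()

    cfg = load_config(seed=args.seed)
    world = simulate_world(cfg)
    save_world(world, args.outdir)

    g = world.grid
    print(f"synthetic world ({g.n_rows}x{g.n_cols} cells at {g.cell_size:.0f} m) -> {args.outdir}")
    print(f"  mines: {len(world.mines)} in {cfg.world.n_clusters} clusters")
    print(f"  MET sources: {len(world.met_sources['metars'])} airport-like, "
          f"{len(world.met_sources['met_stations'])} station-like (direct), "
          f"{len(world.met_sources['narr'])} gridded lattice points")
    print(f"  wells: {len(world.wells)}, roads: {len(world.roads)}, "
          f"drainage zones: {world.zones.n_zones}")


if __name__ == "__main__":
    main()
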