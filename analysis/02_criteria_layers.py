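"""Compute the eight criteria layers.

Static layers (mine proximity, downslope drainage, landforms, road distance,
groundwater hazard IDW, NDVI) are computed once; the two MET-sensitive layers
(wind index, topographic wind exposure) are computed for each of the seven
MET data combinations and once from the truth wind field.

    python analysis/02_criteria_layers.py [--seed 42] [--outdir results/run]
"""

import argparse
from pathlib import Path

from aumex.config import load_config
from aumex.pipeline import build_layers, load_world, save_layers


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--outdir", type=Path, default=Path("results/run"))
    args = ap.parse_args()

    cfg = load_config(seed=args.seed)
    world = load_world(cfg, args.outdir)
    layers = build_layers(cfg, world)
    save_layers(layers, args.outdir)

    print(f"criteria layers -> {args.outdir}")
    for i, label in [(1, "AUM proximity"), (2, "downslope drainage"),
                     (5, "landforms"), (6, "road distance"),
                     (7, "groundwater hazard"), (8, "NDVI")]:
        v = layers.static[i].values
        print(f"  layer {i} ({label}): range [{v.min():.3g}, {v.max():.3g}]")
    print(f"  MET layers 3-4 computed for {len(layers.met_layers)} combinations + truth")


if __name__ == "__main__":
    main()
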