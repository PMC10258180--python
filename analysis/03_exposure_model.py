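"""Fuzzify criteria, fit RF weights, and combine the exposure surfaces.

Draws concentration samples from the known-weight truth surface, fits a
random-forest regressor per MET combination to derive criterion weights from
impurity importances, and produces one exposure-potential surface per
combination by weighted linear combination.

    python analysis/03_exposure_model.py [--seed 42] [--outdir results/run]
"""

import argparse
from pathlib import Path

from aumex.config import load_config
from aumex.pipeline import build_model, load_layers, load_world, save_model


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--outdir", type=Path, default=Path("results/run"))
    args = ap.parse_args()

    cfg = load_config(seed=args.seed)
    world = load_world(cfg, args.outdir)
    layers = load_layers(cfg, args.outdir)
    model = build_model(cfg, world, layers)
    save_model(model, args.outdir)

    print(f"exposure surfaces -> {args.outdir}")
    print(f"  samples: {len(model.concentrations)} "
          f"(truth weights {world.truth.true_weights.round(2).tolist()})")
    for name, w in model.weights.items():
        print(f"  RF weights [{name}]: {w.weights.round(3).tolist()}")


if __name__ == "__main__":
    main()
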