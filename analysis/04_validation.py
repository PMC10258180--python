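"""Run the validation battery on the exposure surfaces.

Repeated random-subset GWR validation per MET combination (descriptive
statistics of R^2), one-way ANOVA across surfaces on log2 values, 10-fold
cross-validation with per-fold weight refitting, and the multi-radius
scale-variability test.

    python analysis/04_validation.py [--seed 42] [--outdir results/run]
"""

import argparse
from pathlib import Path

from aumex.config import load_config
from aumex.pipeline import load_layers, load_model, load_world, run_validation, save_validation


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--outdir", type=Path, default=Path("results/run"))
    args = ap.parse_args()

    cfg = load_config(seed=args.seed)
    world = load_world(cfg, args.outdir)
    layers = load_layers(cfg, args.outdir)
    model = load_model(cfg, args.outdir, layers)
    results = run_validation(cfg, world, layers, model)
    save_validation(results, args.outdir)

    s = results["summary"]
    print(f"validation -> {args.outdir}")
    for name, r2 in sorted(s["mean_r2"].items(), key=lambda kv: -kv[1]):
        print(f"  mean R2 [{name}]: {r2:.3f}")
    print(f"  best combination: {s['best_combination']}")
    print(f"  ANOVA across surfaces: F = {s['anova_f']:.2f}, p = {s['anova_p']:.3g}")
    print(f"  k-fold R2 range: {s['kfold_r2_min']:.3f} - {s['kfold_r2_max']:.3f} "
          f"(spread {s['kfold_r2_spread']:.3f})")


if __name__ == "__main__":
    main()
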