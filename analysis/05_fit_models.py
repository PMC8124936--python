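"""Fit the 10-model grid: 5 vegetation measures x 2 disorders.

Each fit is the Poisson-lognormal model with ICAR + iid random effects,
2 chains of 15,000 sweeps (5,000 burn-in) by default.  Writes per-fit
posterior summaries, convergence diagnostics and relative-risk surfaces
(CSV + GeoJSON with quantile bins) under results/run/fits and results/run/risk.

At the default iteration counts this is the long step (~2 minutes); pass
--iterations/--burn-in to shorten exploratory runs.
"""

import argparse
import json

from greenrisk.pipeline import RunConfig, stage_fit


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/run")
    ap.add_argument("--iterations", type=int, default=15_000)
    ap.add_argument("--burn-in", type=int, default=5_000)
    args = ap.parse_args()
    cfg = RunConfig(out_dir=args.out, seed=args.seed,
                    iterations=args.iterations, burn_in=args.burn_in)
    stage_fit(cfg)
    for d in cfg.disorders:
        for m in cfg.measures:
            diag = json.loads(
                (cfg.out / "fits" / f"{m}_{d}" / "diagnostics.json").read_text())
            print(f"{m:8s} {d:14s} psi={diag['psi_mean']:.3f} "
                  f"pD={diag['pD']:.1f} DIC={diag['DIC']:.1f} "
                  f"max R-hat={diag['max_rhat']:.3f}")


if __name__ == "__main__":
    main()
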