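"""Test the SMR surfaces for global spatial autocorrelation.

Runs the Moran's I permutation test (999 permutations, row-standardized
queen weights) on the O/E ratio of each disorder.  A small pseudo p-value
motivates the spatial random-effect structure of the main model; the gate
reports rather than blocks.
"""

import argparse
import json

from greenrisk.pipeline import RunConfig, stage_moran


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/run")
    args = ap.parse_args()
    cfg = RunConfig(out_dir=args.out, seed=args.seed)
    moran = stage_moran(cfg)
    print(json.dumps(moran, indent=2))
    for disorder, res in moran.items():
        verdict = "significant" if res["p_value"] <= 0.05 else "not significant"
        print(f"{disorder}: I={res['I']:.3f}, p={res['p_value']:.4f} "
              f"({verdict} spatial autocorrelation)")


if __name__ == "__main__":
    main()
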