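"""Assemble the cross-measure comparison tables.

Combines the per-fit posterior summaries into one table per disorder
(rows: coefficients, psi, pD, DIC; columns: vegetation measures; '*' marks
a 95% CrI excluding zero) and prints them.
"""

import argparse

import pandas as pd

from greenrisk.pipeline import RunConfig, stage_report


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", default="results/run")
    args = ap.parse_args()
    cfg = RunConfig(out_dir=args.out)
    stage_report(cfg)
    for disorder in cfg.disorders:
        print(f"\n=== {disorder} ===")
        print(pd.read_csv(cfg.out / f"report_{disorder}.csv", index_col=0)
              .to_string())


if __name__ == "__main__":
    main()
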