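"""Screen the model covariates for collinearity before fitting.

Computes the pairwise Pearson correlation matrix and per-covariate variance
inflation factors for the EVI + confounder design; the model grid should
only proceed if nothing is flagged (|r| >= 0.7 or VIF >= 10).
"""

import argparse

from greenrisk import io as grio
from greenrisk.pipeline import RunConfig
from greenrisk.standardize import collinearity_screen


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", default="results/run")
    args = ap.parse_args()
    cfg = RunConfig(out_dir=args.out)
    cov = grio.read_covariates_csv(cfg.out / "covariates.csv")
    rep = collinearity_screen(cov[["EVI", "X2", "X3", "X4", "X5", "X6"]])
    rep.pearson.to_csv(cfg.out / "pearson.csv")
    rep.vif.rename("VIF").to_csv(cfg.out / "vif.csv")
    print(rep.pearson.round(3))
    print(rep.vif.round(3))
    print("screen passed" if rep.passed
          else f"flagged: pairs={rep.flagged_pairs}, vif={rep.flagged_vif}")


if __name__ == "__main__":
    main()
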