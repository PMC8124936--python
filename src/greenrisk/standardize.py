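"""Indirect (internal) standardization and covariate assembly.

Expected counts are built by applying the study population's own
sex-specific overall rates to each unit's population structure, so that
``sum(E) == sum(O)`` for each disorder by construction — the defining
property of internal standardization.  The covariate table joins the
vegetation measure (X1) with the four marginalization dimensions (X2-X5)
and the substance-use rate (X6), followed by a Pearson/VIF collinearity
screen before modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import ZonalSummary

__all__ = [
    "DISORDERS",
    "HEALTH_COLUMNS",
    "COVARIATE_COLUMNS",
    "validate_health_table",
    "overall_sex_rates",
    "expected_counts",
    "assemble_covariates",
    "collinearity_screen",
    "CollinearityReport",
]

DISORDERS = ("psychotic", "non_psychotic")
HEALTH_COLUMNS = ("unit_id", "disorder", "sex", "cases", "population")
COVARIATE_COLUMNS = ("X1", "X2", "X3", "X4", "X5", "X6")


def validate_health_table(health: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format health table schema and invariants."""
    missing = set(HEALTH_COLUMNS) - set(health.columns)
    if missing:
        raise ValueError(f"health table missing columns {sorted(missing)}")
    if (health["cases"] < 0).any():
        raise ValueError("negative case counts")
    if (health["population"] <= 0).any():
        bad = health.loc[health["population"] <= 0, "unit_id"].unique()
        raise ValueError(f"non-positive population in units {list(bad)}")
    dup = health.duplicated(["unit_id", "disorder", "sex"])
    if dup.any():
        raise ValueError("duplicate (unit_id, disorder, sex) rows")
    return health


def overall_sex_rates(health: pd.DataFrame, disorder: str) -> pd.Series:
    """Study-wide crude rate per sex: total cases / total population.

    These are the rates that indirect standardization applies back to each
    unit's population structure.
    """
    validate_health_table(health)
    sub = health[health["disorder"] == disorder]
    if sub.empty:
        raise ValueError(f"no rows for disorder {disorder!r}")
    grouped = sub.groupby("sex")[["cases", "population"]].sum()
    if (grouped["population"] <= 0).any():
        raise ValueError("zero total population for a sex stratum")
    return grouped["cases"] / grouped["population"]


def expected_counts(rates: pd.Series, health: pd.DataFrame,
                    disorder: str) -> pd.Series:
    """Indirectly standardized expected counts E_i = sum_sex rate_sex * pop_i,sex.

    Internal standardization conserves the total: sum(E) equals sum(O) for
    the disorder, up to floating-point roundoff.
    """
    validate_health_table(health)
    sub = health[health["disorder"] == disorder]
    if sub.empty:
        raise ValueError(f"no rows for disorder {disorder!r}")
    unknown = set(sub["sex"]) - set(rates.index)
    if unknown:
        raise ValueError(f"rates missing for sex strata {sorted(unknown)}")
    pop = sub.groupby("unit_id")["population"].sum()
    zero = pop.index[pop <= 0]
    if len(zero):
        raise ValueError(f"zero total population in units {list(zero)}")
    e = (sub["population"] * sub["sex"].map(rates)).groupby(
        sub["unit_id"]).sum()
    return e.rename("E")


def assemble_covariates(veg: ZonalSummary | pd.DataFrame,
                        omi: pd.DataFrame,
                        substance: pd.DataFrame) -> pd.DataFrame:
    """Join X1 (vegetation) with X2-X5 (marginalization) and X6 (substance use).

    All three inputs must carry exactly the same unit ids, once each; the
    output is indexed by unit_id with the fixed column order X1..X6 and a
    ``measure`` attribute naming the vegetation measure used.
    """
    if isinstance(veg, ZonalSummary):
        veg_df = pd.DataFrame(
            {"unit_id": list(veg.values), "X1": list(veg.values.values())})
        measure = veg.measure
    else:
        veg_df = veg.rename(columns={veg.columns[-1]: "X1"}) if "X1" not in veg else veg
        measure = getattr(veg, "attrs", {}).get("measure", "X1")

    frames = {"vegetation": veg_df, "omi": omi, "substance": substance}
    ids: dict[str, set] = {}
    for name, df in frames.items():
        if "unit_id" not in df.columns:
            raise ValueError(f"{name} table lacks a unit_id column")
        if df["unit_id"].duplicated().any():
            dups = df.loc[df["unit_id"].duplicated(), "unit_id"].tolist()
            raise ValueError(f"duplicate unit ids in {name} table: {dups}")
        ids[name] = set(df["unit_id"])
    union = set.union(*ids.values())
    inter = set.intersection(*ids.values())
    if union != inter:
        raise ValueError(
            f"unit-id mismatch across inputs; offending ids: {sorted(union - inter)}")

    omi_needed = {"X2", "X3", "X4", "X5"}
    if not omi_needed <= set(omi.columns):
        raise ValueError(f"omi table must have columns {sorted(omi_needed)}")
    sub = substance.rename(columns={substance.columns[-1]: "X6"}) \
        if "X6" not in substance.columns else substance

    out = (veg_df.merge(omi[["unit_id", "X2", "X3", "X4", "X5"]], on="unit_id")
           .merge(sub[["unit_id", "X6"]], on="unit_id")
           .set_index("unit_id")[list(COVARIATE_COLUMNS)])
    if out.isna().any().any():
        bad = out.index[out.isna().any(axis=1)].tolist()
        raise ValueError(f"missing covariate cells in units {bad}")
    out.attrs["measure"] = measure
    return out


@dataclass
class CollinearityReport:
    """Pairwise Pearson correlations and variance inflation factors."""

    pearson: pd.DataFrame
    vif: pd.Series
    r_threshold: float
    vif_threshold: float

    @property
    def flagged_pairs(self) -> list[tuple[str, str]]:
        cols = list(self.pearson.columns)
        out = []
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                if abs(self.pearson.loc[a, b]) >= self.r_threshold:
                    out.append((a, b))
        return out

    @property
    def flagged_vif(self) -> list[str]:
        return [c for c, v in self.vif.items()
                if not np.isfinite(v) or v >= self.vif_threshold]

    @property
    def passed(self) -> bool:
        return not self.flagged_pairs and not self.flagged_vif


def collinearity_screen(cov: pd.DataFrame, r_threshold: float = 0.7,
                        vif_threshold: float = 10.0) -> CollinearityReport:
    """Pearson correlation matrix plus VIF_j = 1/(1 - R^2_j) per column.

    R^2_j comes from the least-squares regression of column j on the other
    columns (with intercept).  A perfectly collinear column yields an
    infinite VIF, reported as ``inf`` and flagged rather than erroring.
    """
    cols = [c for c in cov.columns if c != "unit_id"]
    x = cov[cols].to_numpy(dtype=float)
    n, p = x.shape
    if n < 3:
        raise ValueError("need at least 3 rows for a collinearity screen")
    sd = x.std(axis=0, ddof=1)
    dead = [c for c, s in zip(cols, sd) if s == 0]
    if dead:
        raise ValueError(f"zero-variance column(s): {dead}")

    pearson = pd.DataFrame(np.corrcoef(x, rowvar=False), index=cols,
                           columns=cols)
    vif = {}
    ones = np.ones((n, 1))
    for j, c in enumerate(cols):
        y = x[:, j]
        others = np.hstack([ones, np.delete(x, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        vif[c] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return CollinearityReport(
        pearson=pearson, vif=pd.Series(vif), r_threshold=r_threshold,
        vif_threshold=vif_threshold)
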