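"""End-to-end orchestration: synthetic inputs -> indices -> standardization ->
Moran gate -> the 10-model fitting grid -> report and risk-surface export.

A run writes a deterministic directory layout::

    out/
      units.geojson  neighbors.txt
      indices/            index rasters + zonal summaries from the scene
      health.csv  covariates.csv  expected.csv  moran.json
      fits/<measure>_<disorder>/summary.csv, diagnostics.csv/.json
      risk/<measure>_<disorder>.geojson (+ .csv)
      report_<disorder>.csv
      log.json            config echo, per-stage seeds, library versions

Stages communicate only through these files, so each stage can run as a
separate process; :func:`run_full` simply chains them.  Every stochastic
stage derives its seed deterministically from the run seed, so re-running
(or deleting fits/ and re-running) reproduces identical outputs.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as grio
from .bym import ModelData, ModelSpec, relative_risk, run_chains, summarize
from .raster import compute_index, dark_object_subtract, mask_non_vegetation, \
    percent_cover, zonal_mean
from .simulate import CONFOUNDER_MOMENTS, COUNT_SCALE, DEFAULT_BETA, \
    MEASURE_MOMENTS, SceneSpec, ScenePatch, make_lattice, sample_icar, \
    simulate_counts, simulate_population_and_rates, simulate_scene
from .spatial import build_adjacency, morans_permutation, row_standardize
from .standardize import collinearity_screen, expected_counts, overall_sex_rates

__all__ = [
    "RunConfig", "run_full", "quantile_bins", "report_table",
    "stage_geography", "stage_indices", "stage_simulate", "stage_moran",
    "stage_fit", "stage_report",
]

MEASURES = tuple(MEASURE_MOMENTS)
DISORDERS = tuple(COUNT_SCALE)


@dataclass
class RunConfig:
    """Configuration of one full synthetic-preset run."""

    out_dir: str = "runs/synthetic"
    rows: int = 14
    cols: int = 10
    measures: tuple[str, ...] = MEASURES
    disorders: tuple[str, ...] = DISORDERS
    seed: int = 0
    contiguity: str = "queen"
    mask_threshold: float = 0.0
    n_permutations: int = 999
    moran_blocking: bool = False
    chains: int = 2
    iterations: int = 15_000
    burn_in: int = 5_000
    thinning: int = 1
    beta: tuple[float, ...] = DEFAULT_BETA
    sd_u: float = 0.05
    sd_s: float = 0.15
    scene_pixels_per_cell: int = 4
    n_risk_bins: int = 5

    def __post_init__(self) -> None:
        bad = set(self.measures) - set(MEASURES)
        if bad:
            raise ValueError(f"unknown vegetation measures {sorted(bad)}; "
                             f"choose from {MEASURES}")
        bad = set(self.disorders) - set(DISORDERS)
        if bad:
            raise ValueError(f"unknown disorders {sorted(bad)}")

    @property
    def out(self) -> Path:
        return Path(self.out_dir)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        for key in ("measures", "disorders", "beta"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _stage_seed(run_seed: int, label: str) -> int:
    """Deterministic sub-seed per stage, independent of execution order."""
    return (run_seed * 1_000_003 + zlib.crc32(label.encode())) % (2 ** 31)


def quantile_bins(values: np.ndarray, n_bins: int = 5
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Equal-count choropleth bins by sample quantiles.

    Returns (bin index per value in 0..n_bins-1, interior bin edges).  Ties
    resolve to the lower bin; constant input falls back to a single bin with
    a warning.
    """
    values = np.asarray(values, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if np.ptp(values) == 0:
        warnings.warn("constant values: single-bin fallback")
        return np.zeros(values.size, dtype=int), np.array([])
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    bins = np.searchsorted(edges, values, side="left")
    return bins.astype(int), edges


def report_table(summaries: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Cross-measure comparison table for one disorder.

    ``summaries`` maps a vegetation measure to the numeric per-fit summary
    frame (rows beta0.., psi, pD, DIC; columns mean/ci_low/ci_high/
    significant).  Coefficient cells read ``mean (lo, hi)`` with ``*`` when
    the 95% CrI excludes zero.
    """
    if not summaries:
        raise ValueError("no completed fits to report")
    cols = {}
    for measure, frame in summaries.items():
        cells = {}
        for name, row in frame.iterrows():
            if name in ("pD", "DIC"):
                cells[name] = f"{row['mean']:.3f}"
            else:
                star = "*" if bool(row["significant"]) else ""
                cells[name] = (f"{row['mean']:.3f} ({row['ci_low']:.3f}, "
                               f"{row['ci_high']:.3f}){star}")
        cols[measure] = cells
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# stages (file-coupled; each re-reads its inputs from the run directory)
# ---------------------------------------------------------------------------

def stage_geography(cfg: RunConfig):
    """Lattice + contiguity; writes units.geojson and neighbors.txt."""
    cfg.out.mkdir(parents=True, exist_ok=True)
    units = build_adjacency(make_lattice(cfg.rows, cfg.cols),
                            rule=cfg.contiguity)
    grio.write_geojson(units, cfg.out / "units.geojson")
    grio.write_neighbors(units, cfg.out / "neighbors.txt")
    return units


def _scene_for_lattice(cfg: RunConfig, veg_fraction: np.ndarray) -> SceneSpec:
    """One scene aligned with the lattice: per-unit vegetation blocks.

    Each unit gets a K x K pixel tile whose leading pixels (row-major) are
    vegetation in the unit's target fraction; one unit in ten gets a water
    pixel to exercise the NDVI mask.
    """
    k = cfg.scene_pixels_per_cell
    patches = []
    for r in range(cfg.rows):
        for c in range(cfg.cols):
            i = r * cfg.cols + c
            n_veg = int(round(veg_fraction[i] * k * k))
            full_rows, rem = divmod(n_veg, k)
            if full_rows:
                patches.append(ScenePatch(r * k, r * k + full_rows,
                                          c * k, (c + 1) * k, "vegetation"))
            if rem:
                patches.append(ScenePatch(r * k + full_rows,
                                          r * k + full_rows + 1,
                                          c * k, c * k + rem, "vegetation"))
            if i % 10 == 9:
                patches.append(ScenePatch((r + 1) * k - 1, (r + 1) * k,
                                          (c + 1) * k - 1, (c + 1) * k,
                                          "waterbody"))
    return SceneSpec(rows=cfg.rows * k, cols=cfg.cols * k,
                     background="built_up", patches=patches,
                     noise_sd=0.005, pixel_size=1.0 / k)


def stage_indices(cfg: RunConfig) -> None:
    """Raster chain: synthetic scene -> correction -> indices -> zonal CSV."""
    units = grio.read_geojson(cfg.out / "units.geojson")
    rng = np.random.default_rng(_stage_seed(cfg.seed, "scene"))
    frac = rng.beta(2.0, 4.0, size=cfg.rows * cfg.cols)
    scene = _scene_for_lattice(cfg, frac)
    bands, truth = simulate_scene(scene, seed=rng)
    bands = {b: dark_object_subtract(g) for b, g in bands.items()}
    idx_dir = cfg.out / "indices"
    idx_dir.mkdir(parents=True, exist_ok=True)
    ndvi = compute_index(bands["red"], bands["nir"], index_name="NDVI")
    zonal_rows = []
    for name in ("NDVI", "EVI", "SAVI"):
        grid = compute_index(bands["red"], bands["nir"], bands["blue"], name)
        masked = mask_non_vegetation(grid, ndvi, cfg.mask_threshold)
        grio.write_raster(masked, idx_dir / f"{name}.tif")
        zonal_rows.append(zonal_mean(masked, units).to_frame())
    pc = percent_cover(truth, units, "vegetation")
    pc.measure = "Veg_RF"
    zonal_rows.append(pc.to_frame())
    pd.concat(zonal_rows).to_csv(idx_dir / "scene_zonal.csv", index=False)


def stage_simulate(cfg: RunConfig) -> None:
    """Covariates (all measures) + per-disorder health tables + expected counts."""
    n = cfg.rows * cfg.cols
    rng = np.random.default_rng(_stage_seed(cfg.seed, "covariates"))
    # one latent vegetation field scaled to each measure's published moments,
    # so measures are mutually consistent proxies; confounders independent
    z = rng.normal(size=n)
    ids = [f"u{i:03d}" for i in range(n)]
    cov = pd.DataFrame(index=pd.Index(ids, name="unit_id"))
    for m, (mu, sd) in MEASURE_MOMENTS.items():
        cov[m] = mu + sd * z
    for c, (mu, sd) in CONFOUNDER_MOMENTS.items():
        cov[c] = mu + sd * rng.normal(size=n)
    cov.to_csv(cfg.out / "covariates.csv")

    units = grio.read_geojson(cfg.out / "units.geojson")
    units.neighbors = grio.read_neighbors(cfg.out / "neighbors.txt")
    health_frames = []
    for disorder in cfg.disorders:
        drng = np.random.default_rng(_stage_seed(cfg.seed, f"health_{disorder}"))
        skeleton, rates = simulate_population_and_rates(
            n, seed=drng, disorder=disorder)
        wide = skeleton.pivot(index="unit_id", columns="sex",
                              values="population").loc[ids]
        e_gen = (wide * rates).sum(axis=1).to_numpy()
        s = sample_icar(units, tau_s=1.0, seed=drng)
        s *= cfg.sd_s / s.std(ddof=1)
        u = drng.normal(size=n)
        u = (u - u.mean()) * cfg.sd_u / u.std(ddof=1)
        x = cov[["EVI", "X2", "X3", "X4", "X5", "X6"]].to_numpy()
        o = simulate_counts(np.asarray(cfg.beta), e_gen, x, u, s, seed=drng)
        p_f = ((wide["female"] * rates["female"]) /
               (wide * rates).sum(axis=1)).to_numpy()
        o_f = drng.binomial(o.astype(int), p_f)
        split = {"female": o_f, "male": o.astype(int) - o_f}
        for sex in ("male", "female"):
            sel = skeleton["sex"] == sex
            pos = skeleton.loc[sel, "unit_id"].map(
                {u_: i for i, u_ in enumerate(ids)}).to_numpy()
            skeleton.loc[sel, "cases"] = split[sex][pos]
        health_frames.append(skeleton)
    health = pd.concat(health_frames, ignore_index=True)
    grio.write_health_csv(health, cfg.out / "health.csv")

    rows = []
    for disorder in cfg.disorders:
        rates = overall_sex_rates(health, disorder)
        e = expected_counts(rates, health, disorder).loc[ids]
        obs = (health[health["disorder"] == disorder]
               .groupby("unit_id")["cases"].sum().loc[ids])
        rows.append(pd.DataFrame({
            "unit_id": ids, "disorder": disorder,
            "O": obs.to_numpy(), "E": e.to_numpy()}))
    pd.concat(rows, ignore_index=True).to_csv(cfg.out / "expected.csv",
                                              index=False)


def stage_moran(cfg: RunConfig) -> dict:
    """Moran's I permutation gate on the per-disorder SMR surfaces."""
    wm = grio.weights_from_neighbors(
        grio.read_neighbors(cfg.out / "neighbors.txt"))
    wq = row_standardize(wm)
    expected = pd.read_csv(cfg.out / "expected.csv", dtype={"unit_id": str})
    moran = {}
    for disorder in cfg.disorders:
        sub = expected[expected["disorder"] == disorder].set_index("unit_id")
        smr = (sub["O"] / sub["E"]).loc[wm.unit_ids].to_numpy()
        res = morans_permutation(
            smr, wq, n_perm=cfg.n_permutations,
            seed=_stage_seed(cfg.seed, f"moran_{disorder}"))
        moran[disorder] = {"I": res.I, "p_value": res.p_value,
                           "n_permutations": res.n_permutations,
                           "seed": res.seed}
        if cfg.moran_blocking and res.p_value > 0.05:
            raise RuntimeError(
                f"Moran gate: no significant autocorrelation for {disorder}")
    (cfg.out / "moran.json").write_text(json.dumps(moran, indent=2))
    return moran


def stage_fit(cfg: RunConfig) -> None:
    """The measures x disorders model grid; writes fits/ and risk/."""
    wm = grio.weights_from_neighbors(
        grio.read_neighbors(cfg.out / "neighbors.txt"))
    units = grio.read_geojson(cfg.out / "units.geojson")
    cov = grio.read_covariates_csv(cfg.out / "covariates.csv").loc[wm.unit_ids]
    expected = pd.read_csv(cfg.out / "expected.csv", dtype={"unit_id": str})
    (cfg.out / "fits").mkdir(exist_ok=True)
    (cfg.out / "risk").mkdir(exist_ok=True)
    for disorder in cfg.disorders:
        sub = expected[expected["disorder"] == disorder].set_index("unit_id") \
            .loc[wm.unit_ids]
        for measure in cfg.measures:
            x = cov[[measure, "X2", "X3", "X4", "X5", "X6"]].to_numpy()
            data = ModelData(sub["O"].to_numpy(), sub["E"].to_numpy(), x, wm,
                             unit_ids=list(wm.unit_ids))
            spec = ModelSpec(
                n_covariates=6, chains=cfg.chains, iterations=cfg.iterations,
                burn_in=cfg.burn_in, thinning=cfg.thinning,
                seed=_stage_seed(cfg.seed, f"fit_{measure}_{disorder}"))
            samples = run_chains(spec, data)
            fit = summarize(samples, data, measure=measure, disorder=disorder)
            rr = relative_risk(samples, data)
            fdir = cfg.out / "fits" / f"{measure}_{disorder}"
            fdir.mkdir(parents=True, exist_ok=True)
            fit.to_frame().to_csv(fdir / "summary.csv")
            fit.diagnostics.to_csv(fdir / "diagnostics.csv")
            (fdir / "diagnostics.json").write_text(json.dumps({
                "psi_mean": fit.psi_mean, "psi_ci": list(fit.psi_ci),
                "Dbar": fit.Dbar, "pD": fit.pD, "DIC": fit.DIC,
                "max_rhat": float(fit.diagnostics["rhat"].max()),
                "mc_error_ok": bool(fit.diagnostics["mc_error_ok"].all()),
            }, indent=2))
            bins, _ = quantile_bins(rr["rr_mean"].to_numpy(), cfg.n_risk_bins)
            rr["quantile_bin"] = bins
            rr.to_csv(cfg.out / "risk" / f"{measure}_{disorder}.csv",
                      index=False)
            grio.write_geojson(units,
                               cfg.out / "risk" / f"{measure}_{disorder}.geojson",
                               properties=rr)


def stage_report(cfg: RunConfig) -> None:
    """Cross-measure comparison tables from the per-fit summary files."""
    for disorder in cfg.disorders:
        summaries = {}
        for measure in cfg.measures:
            path = cfg.out / "fits" / f"{measure}_{disorder}" / "summary.csv"
            summaries[measure] = pd.read_csv(path, index_col=0)
        report_table(summaries).to_csv(cfg.out / f"report_{disorder}.csv")


def run_full(config: RunConfig) -> Path:
    """Execute every stage in order; abort with the stage name on failure."""
    log: dict = {"config": asdict(config), "stages": {}}
    stage = "geography"
    try:
        stage_geography(config)
        stage = "indices"
        stage_indices(config)
        stage = "simulate"
        stage_simulate(config)

        stage = "collinearity"
        cov = grio.read_covariates_csv(config.out / "covariates.csv")
        screen = collinearity_screen(
            cov[["EVI", "X2", "X3", "X4", "X5", "X6"]])
        log["stages"]["collinearity"] = {
            "max_abs_offdiag_r": float(np.abs(
                screen.pearson.to_numpy()
                - np.eye(len(screen.pearson))).max()),
            "max_vif": float(screen.vif.max()),
            "passed": screen.passed,
        }

        stage = "moran"
        log["stages"]["moran"] = stage_moran(config)
        stage = "fit"
        stage_fit(config)
        stage = "report"
        stage_report(config)

        log["versions"] = _versions()
        (config.out / "log.json").write_text(json.dumps(log, indent=2))
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    return config.out


def _versions() -> dict:
    import scipy
    import shapely as shp

    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "shapely": shp.__version__}
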