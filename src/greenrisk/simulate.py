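"""Synthetic study data: lattice geographies, latent fields, counts, scenes.

The generators emulate the structure of a 140-neighbourhood areal study of
mental-health counts and vegetation: a rows x cols lattice of square units
(default 14 x 10 = 140), Normal covariates matched to the published
per-neighbourhood moments, sex-stratified populations with internal
standardization scale matched to the published count means, a spatially
structured ICAR field s plus iid heterogeneity u with a controllable
spatial fraction psi = SD(s)/(SD(s)+SD(u)), Poisson counts from the
log-linear model, and small multiband reflectance scenes with a known
land-cover truth map for exercising the raster chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .raster import BandGrid, ClassGrid, GridTransform
from .spatial import AreaUnitSet, WeightMatrix, build_adjacency

__all__ = [
    "MEASURE_MOMENTS",
    "CONFOUNDER_MOMENTS",
    "COUNT_SCALE",
    "DEFAULT_BETA",
    "SimulationSpec",
    "SceneSpec",
    "ScenePatch",
    "SyntheticDataset",
    "make_lattice",
    "sample_icar",
    "simulate_covariates",
    "simulate_population_and_rates",
    "simulate_counts",
    "simulate_scene",
    "simulate_dataset",
]

#: published per-neighbourhood mean (SD) of each vegetation measure
MEASURE_MOMENTS: dict[str, tuple[float, float]] = {
    "EVI": (0.052, 0.006),
    "NDVI": (0.561, 0.035),
    "SAVI": (0.058, 0.006),
    "Veg_RF": (20.730, 13.267),
    "Tree_OD": (6.540, 5.611),
}

#: published moments of the confounders X2..X6 (marginalization + substance use)
CONFOUNDER_MOMENTS: dict[str, tuple[float, float]] = {
    "X2": (0.250, 0.895),    # material deprivation
    "X3": (0.902, 0.838),    # ethnic concentration
    "X4": (0.723, 0.783),    # residential instability
    "X5": (-0.228, 0.393),   # dependency
    "X6": (9.988, 4.392),    # substance-use rate per 1000
}

#: published mean observed counts per neighbourhood, by disorder
COUNT_SCALE: dict[str, float] = {
    "psychotic": 282.864,
    "non_psychotic": 2239.850,
}

#: default generative coefficients (intercept chosen so the mean log relative
#: risk is ~0 at the default covariate means; slopes near published scale)
DEFAULT_BETA: tuple[float, ...] = (-0.257, -4.0, 0.12, -0.12, 0.18, -0.06, 0.04)


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic disorder dataset."""

    rows: int = 14
    cols: int = 10
    cell_size: float = 1.0
    beta: tuple[float, ...] = DEFAULT_BETA
    sd_u: float = 0.05          # marginal SD of the iid field
    sd_s: float = 0.15          # marginal SD of the ICAR field (psi_true 0.75)
    disorder: str = "psychotic"
    measure: str = "EVI"
    mean_population: float = 19_500.0   # ~ study-city population / 140 units
    population_sigma: float = 0.4       # log-normal spread of unit sizes
    sex_rate_ratio: float = 1.2         # female : male rate ratio (invented)
    seed: int = 0

    @property
    def n(self) -> int:
        return self.rows * self.cols

    @property
    def psi_true(self) -> float:
        return self.sd_s / (self.sd_s + self.sd_u)


def make_lattice(rows: int, cols: int, cell_size: float = 1.0) -> AreaUnitSet:
    """Square-cell lattice with row-major ids u000, u001, ..."""
    if rows <= 0 or cols <= 0:
        raise ValueError("lattice dimensions must be positive")
    if rows * cols < 4:
        raise ValueError("need at least 4 units")
    ids, geoms = [], []
    for r in range(rows):
        for c in range(cols):
            ids.append(f"u{r * cols + c:03d}")
            x0, y0 = c * cell_size, -r * cell_size
            geoms.append(shapely.box(x0, y0 - cell_size, x0 + cell_size, y0))
    return AreaUnitSet(unit_ids=ids, geometries=geoms)


def _icar_basis(weights: WeightMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Positive eigenpairs of the graph Laplacian of binary weights."""
    w = (weights.w != 0).astype(float).toarray()
    lap = np.diag(w.sum(axis=1)) - w
    evals, evecs = np.linalg.eigh(lap)
    pos = evals > 1e-9 * evals.max()
    return evals[pos], evecs[:, pos]


def sample_icar(weights: WeightMatrix | AreaUnitSet, tau_s: float,
                seed: int | np.random.Generator = 0,
                size: int | None = None) -> np.ndarray:
    """Exact draws from the ICAR kernel exp(-tau_s/2 sum_{i~j}(s_i-s_j)^2).

    The kernel is improper along the constant direction(s); the draw is
    restricted to the orthogonal complement of the graph Laplacian's null
    space (component indicators), so the field sums to zero within every
    connected component.  Covariance equals (tau_s * L)^+, the scaled
    Laplacian pseudo-inverse.
    """
    if isinstance(weights, AreaUnitSet):
        weights = weights.binary_weights()
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    evals, evecs = _icar_basis(weights)
    k = evals.size
    shape = (k,) if size is None else (size, k)
    eps = rng.normal(size=shape) / np.sqrt(tau_s * evals)
    return eps @ evecs.T


def simulate_covariates(n: int, moments: dict[str, tuple[float, float]] | None = None,
                        seed: int | np.random.Generator = 0,
                        measure: str = "EVI",
                        correlation: np.ndarray | None = None) -> pd.DataFrame:
    """Normal covariates X1..X6 matched to requested means and SDs.

    Defaults reproduce the published per-neighbourhood moments, with X1
    drawn on the scale of the chosen vegetation measure.  Columns are
    independent unless a correlation matrix is supplied (stress-test hook).
    """
    if moments is None:
        moments = {"X1": MEASURE_MOMENTS[measure], **CONFOUNDER_MOMENTS}
    cols = list(moments)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    p = len(cols)
    z = rng.normal(size=(n, p))
    if correlation is not None:
        z = z @ np.linalg.cholesky(np.asarray(correlation)).T
    data = {}
    for j, c in enumerate(cols):
        mu, sd = moments[c]
        if sd < 0:
            raise ValueError(f"negative SD for {c}")
        data[c] = mu + sd * z[:, j]
    out = pd.DataFrame(data, index=[f"u{i:03d}" for i in range(n)])
    out.index.name = "unit_id"
    out.attrs["measure"] = measure
    return out


def simulate_population_and_rates(
        n: int, seed: int | np.random.Generator = 0,
        disorder: str = "psychotic", mean_population: float = 19_500.0,
        population_sigma: float = 0.4, sex_rate_ratio: float = 1.2,
        target_mean_count: float | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Sex-stratified populations and base rates on the published count scale.

    Unit populations are log-normal around ``mean_population`` and split
    50/50 between sexes (the real split is unpublished; this is an invented
    preset).  Sex-specific rates are solved so that the study-wide expected
    count per unit equals the published mean for the disorder.  Returns a
    skeleton health table (cases zeroed) and the rate-per-sex series.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if target_mean_count is None:
        target_mean_count = COUNT_SCALE[disorder]
    mu = np.log(mean_population) - population_sigma ** 2 / 2.0
    pop = np.maximum(np.round(rng.lognormal(mu, population_sigma, size=n)), 2.0)
    pop_m = np.round(pop / 2.0)
    pop_f = pop - pop_m
    # rate_f = ratio * rate_m; sum_i (pop_m rate_m + pop_f rate_f) = n * target
    rate_m = n * target_mean_count / float(
        pop_m.sum() + sex_rate_ratio * pop_f.sum())
    rates = pd.Series({"male": rate_m, "female": sex_rate_ratio * rate_m},
                      name="rate")
    ids = [f"u{i:03d}" for i in range(n)]
    skeleton = pd.DataFrame({
        "unit_id": ids * 2,
        "disorder": disorder,
        "sex": ["male"] * n + ["female"] * n,
        "cases": 0,
        "population": np.concatenate([pop_m, pop_f]),
    })
    return skeleton, rates


def simulate_counts(beta: np.ndarray, E: np.ndarray, X: np.ndarray,
                    u: np.ndarray, s: np.ndarray,
                    seed: int | np.random.Generator = 0) -> np.ndarray:
    """Poisson counts O_i ~ Poisson(E_i exp(b0 + X b + u_i + s_i))."""
    E = np.asarray(E, dtype=float)
    if (E <= 0).any():
        raise ValueError("expected counts must be strictly positive")
    beta = np.asarray(beta, dtype=float)
    eta = beta[0] + np.asarray(X, float) @ beta[1:] + u + s
    if np.max(np.abs(eta)) > 30:
        raise ValueError("log relative risk exceeds overflow guard (|.| > 30)")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return rng.poisson(E * np.exp(eta)).astype(float)


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------

#: per-class reflectance presets (blue, red, nir) on [0, 1]
CLASS_REFLECTANCE: dict[str, tuple[float, float, float]] = {
    "vegetation": (0.04, 0.05, 0.45),
    "waterbody": (0.08, 0.06, 0.02),
    "built_up": (0.15, 0.18, 0.20),
    "bare_soil": (0.20, 0.25, 0.30),
}


@dataclass(frozen=True)
class ScenePatch:
    """Axis-aligned rectangle [row0, row1) x [col0, col1) of one class."""

    row0: int
    row1: int
    col0: int
    col1: int
    class_name: str
    reflectance: tuple[float, float, float] | None = None  # blue, red, nir


@dataclass
class SceneSpec:
    rows: int = 40
    cols: int = 40
    background: str = "built_up"
    patches: list[ScenePatch] = field(default_factory=list)
    noise_sd: float = 0.0
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        for p in self.patches:
            if not (0 <= p.row0 < p.row1 <= self.rows
                    and 0 <= p.col0 < p.col1 <= self.cols):
                raise ValueError(f"patch {p} outside the {self.rows}x{self.cols} grid")
            levels = p.reflectance or CLASS_REFLECTANCE.get(p.class_name)
            if levels is None:
                raise ValueError(f"no reflectance preset for class {p.class_name!r}")
            if any(not 0 <= v <= 1 for v in levels):
                raise ValueError("reflectance levels must lie in [0, 1]")


def simulate_scene(scene: SceneSpec, seed: int | np.random.Generator = 0
                   ) -> tuple[dict[str, BandGrid], ClassGrid]:
    """Paint patches over a background and add Gaussian reflectance noise.

    Overlapping patches are painted last-wins.  Returns the blue/red/nir
    bands and the ground-truth class grid.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    classes = sorted(set([scene.background] + [p.class_name for p in scene.patches]))
    legend = {i: name for i, name in enumerate(classes)}
    inverse = {name: i for i, name in legend.items()}
    shape = (scene.rows, scene.cols)
    truth = np.full(shape, inverse[scene.background], dtype=int)
    bands = {b: np.empty(shape) for b in ("blue", "red", "nir")}
    bg = CLASS_REFLECTANCE[scene.background]
    for k, b in enumerate(("blue", "red", "nir")):
        bands[b][:] = bg[k]
    for p in scene.patches:
        levels = p.reflectance or CLASS_REFLECTANCE[p.class_name]
        truth[p.row0:p.row1, p.col0:p.col1] = inverse[p.class_name]
        for k, b in enumerate(("blue", "red", "nir")):
            bands[b][p.row0:p.row1, p.col0:p.col1] = levels[k]
    tfm = GridTransform(0.0, 0.0, scene.pixel_size)
    grids = {}
    for b in ("blue", "red", "nir"):
        vals = bands[b]
        if scene.noise_sd > 0:
            vals = vals + rng.normal(0.0, scene.noise_sd, size=shape)
        grids[b] = BandGrid(vals, np.zeros(shape, bool), tfm, band_label=b)
    return grids, ClassGrid(truth, legend, np.zeros(shape, bool), tfm)


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Everything one model fit needs, plus the generative truth."""

    spec: SimulationSpec
    units: AreaUnitSet
    health: pd.DataFrame
    covariates: pd.DataFrame
    O: np.ndarray
    E_gen: np.ndarray
    u: np.ndarray
    s: np.ndarray
    rates: pd.Series


def _scale_to_sd(x: np.ndarray, sd: float) -> np.ndarray:
    """Rescale a zero-mean field to an exact target marginal SD."""
    cur = x.std(ddof=1)
    if cur == 0:
        if sd == 0:
            return x
        raise ValueError("cannot rescale a constant field to nonzero SD")
    return x * (sd / cur)


def simulate_dataset(spec: SimulationSpec) -> SyntheticDataset:
    """Generate one disorder's full dataset under the model's own mechanism.

    The latent fields are rescaled to the exact target marginal SDs, so the
    realized spatial fraction equals spec.psi_true by construction.  The
    per-sex observed counts are a binomial split of the unit total in
    proportion to the sex-specific expected counts.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    units = build_adjacency(make_lattice(spec.rows, spec.cols, spec.cell_size),
                            rule="queen")
    n = spec.n
    cov = simulate_covariates(n, seed=rng, measure=spec.measure)
    skeleton, rates = simulate_population_and_rates(
        n, seed=rng, disorder=spec.disorder,
        mean_population=spec.mean_population,
        population_sigma=spec.population_sigma,
        sex_rate_ratio=spec.sex_rate_ratio)
    wide = skeleton.pivot(index="unit_id", columns="sex", values="population")
    e_by_sex = wide * rates  # rate_sex * pop_i,sex
    e_gen = e_by_sex.sum(axis=1).to_numpy()

    s = _scale_to_sd(sample_icar(units, tau_s=1.0, seed=rng), spec.sd_s)
    u = rng.normal(size=n)
    u = _scale_to_sd(u - u.mean(), spec.sd_u)

    beta = np.asarray(spec.beta, dtype=float)
    x = cov.to_numpy()
    o_total = simulate_counts(beta, e_gen, x, u, s, seed=rng)

    p_female = (e_by_sex["female"] / e_by_sex.sum(axis=1)).to_numpy()
    o_female = rng.binomial(o_total.astype(int), p_female)
    o_male = o_total - o_female
    split = {"male": o_male, "female": o_female}
    health = skeleton.copy()
    order = {uid: i for i, uid in enumerate(wide.index)}
    for sex in ("male", "female"):
        sel = health["sex"] == sex
        pos = health.loc[sel, "unit_id"].map(order).to_numpy()
        health.loc[sel, "cases"] = split[sex][pos].astype(int)

    return SyntheticDataset(spec=spec, units=units, health=health,
                            covariates=cov, O=o_total, E_gen=e_gen,
                            u=u, s=s, rates=rates)
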