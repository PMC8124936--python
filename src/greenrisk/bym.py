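"""Poisson-lognormal spatial (BYM) model fit by Metropolis-within-Gibbs.

The model for one disorder over n areal units is

    O_i ~ Poisson(lambda_i)
    log lambda_i = log E_i + b0 + sum_j b_j X_ji + u_i + s_i

with iid Normal(0, tau_u^-1) heterogeneity u, an intrinsic CAR (ICAR)
spatially structured effect s with binary contiguity weights and joint
kernel exp(-tau_s/2 * sum_{i~j} (s_i - s_j)^2), vague Normal priors on the
covariate coefficients (precision 1e-5), a flat prior on the intercept
paired with a sum-to-zero constraint on s, and Gamma(0.001, 0.001) priors
on both precisions.

Sampling machinery mirrors the WinBUGS era: random-walk Metropolis for the
coefficients, site-wise Metropolis for the random effects, Gibbs for the
precisions.  Two exactness-preserving accelerations are used: all u_i are
updated simultaneously (they are conditionally independent given the rest),
and s is updated colour class by colour class of the contiguity graph, so
sites updated together are never neighbours.  Step sizes adapt toward ~40%
acceptance during burn-in only; the post-burn-in kernel is fixed.

The sum-to-zero constraint is imposed after every sweep by the move
(s, b0) -> (s - mean(s), b0 + mean(s)), which leaves the likelihood and the
joint prior density exactly invariant (the ICAR kernel depends only on
differences and b0 is flat).

Derived summaries: psi = SD(s)/(SD(s)+SD(u)) per draw (spatial fraction of
the latent variation), DIC = Dbar + pD with pD = Dbar - D(posterior means),
per-unit relative risks r_i = exp(b0 + X b + u_i + s_i), Gelman-Rubin
R-hat, and batch-means Monte Carlo errors with the <5%-of-SD accuracy rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.special import gammaln

from .spatial import WeightMatrix

__all__ = [
    "ModelSpec",
    "ModelData",
    "ChainState",
    "PosteriorSamples",
    "FitSummary",
    "log_likelihood",
    "icar_full_conditional",
    "update_fixed_effects",
    "update_random_effects",
    "update_precisions",
    "run_chains",
    "psi",
    "dic",
    "relative_risk",
    "diagnostics",
    "summarize",
]

#: reject any state whose |log relative risk| exceeds this (overflow guard)
_LOGR_CAP = 30.0


@dataclass(frozen=True)
class ModelSpec:
    """Priors, chain layout and seeds for one model fit."""

    n_covariates: int = 6
    beta_precision: float = 1e-5     # vague Normal prior on b1..bp
    tau_prior_a: float = 0.001       # Gamma shape, both precisions
    tau_prior_b: float = 0.001       # Gamma rate
    chains: int = 2
    iterations: int = 15_000         # total sweeps per chain
    burn_in: int = 5_000
    thinning: int = 1
    seed: int = 0
    target_accept: float = 0.4
    init_beta0: float = 0.0          # centre of the over-dispersed b0 inits

    def __post_init__(self) -> None:
        if not (self.tau_prior_a > 0 and self.tau_prior_b > 0):
            raise ValueError("Gamma prior parameters must be positive")
        if not self.iterations > self.burn_in >= 0:
            raise ValueError("need iterations > burn_in >= 0")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.chains < 2:
            raise ValueError("need >= 2 chains for the Gelman-Rubin diagnostic")

    @property
    def kept_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


class ModelData:
    """Aligned outcome, offset, design matrix and contiguity for one fit."""

    def __init__(self, O: np.ndarray, E: np.ndarray, X: np.ndarray,
                 adjacency: WeightMatrix, unit_ids: list[str] | None = None):
        self.O = np.asarray(O, dtype=float)
        self.E = np.asarray(E, dtype=float)
        self.X = np.asarray(X, dtype=float)
        n = self.O.shape[0]
        if self.X.ndim != 2 or self.X.shape[0] != n or self.E.shape[0] != n:
            raise ValueError("O, E and X are not aligned")
        if (self.E <= 0).any():
            raise ValueError("expected counts must be strictly positive")
        if (self.O < 0).any():
            raise ValueError("observed counts must be non-negative")
        w = adjacency.w
        if w.shape != (n, n):
            raise ValueError("adjacency not aligned with data")
        if (abs(w - w.T) > 0).nnz:
            raise ValueError("adjacency must be symmetric")
        self.W = (w != 0).astype(float).tocsr()
        self.card = np.asarray(self.W.sum(axis=1)).ravel()
        if (self.card == 0).any():
            isl = [i for i, m in enumerate(self.card) if m == 0]
            raise ValueError(f"island units (no neighbours) at positions {isl}; "
                             "drop them explicitly before ICAR fitting")
        self.unit_ids = list(unit_ids) if unit_ids is not None else \
            [str(i) for i in range(n)]
        self.x_mean = self.X.mean(axis=0)
        self.Xc = self.X - self.x_mean
        coo = sp.triu(self.W, k=1).tocoo()
        self.edges = np.stack([coo.row, coo.col], axis=1)
        self.n_components = connected_components(self.W, directed=False)[0]
        g = nx.from_scipy_sparse_array(self.W)
        colouring = nx.greedy_color(g, strategy="largest_first")
        n_colours = max(colouring.values()) + 1
        self.colour_classes = [
            np.array(sorted(i for i, c in colouring.items() if c == k))
            for k in range(n_colours)
        ]
        self.log_E = np.log(self.E)
        self.log_fact_O = gammaln(self.O + 1.0)

    @property
    def n(self) -> int:
        return self.O.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class ChainState:
    """All unknowns of one chain; beta[0] is the intercept."""

    beta: np.ndarray
    u: np.ndarray
    s: np.ndarray
    tau_u: float
    tau_s: float

    def copy(self) -> "ChainState":
        return ChainState(self.beta.copy(), self.u.copy(), self.s.copy(),
                          self.tau_u, self.tau_s)

    def linpred(self, data: ModelData) -> np.ndarray:
        """log relative risk: b0 + X b + u + s."""
        return self.beta[0] + data.X @ self.beta[1:] + self.u + self.s


def log_likelihood(state: ChainState, data: ModelData) -> float:
    """Poisson log likelihood sum_i [O_i log(lam_i) - lam_i - log(O_i!)]."""
    eta = state.linpred(data)
    if not np.all(np.isfinite(eta)) or np.max(np.abs(eta)) > _LOGR_CAP:
        return -np.inf
    log_lam = data.log_E + eta
    return float(np.sum(data.O * log_lam - np.exp(log_lam) - data.log_fact_O))


def icar_full_conditional(s: np.ndarray, i: int, tau_s: float,
                          adjacency: WeightMatrix | sp.spmatrix
                          ) -> tuple[float, float]:
    """Conditional of s_i under the binary-weight ICAR kernel.

    Given the joint kernel exp(-tau_s/2 sum_{i~j}(s_i-s_j)^2), the full
    conditional is Normal with mean = average of the m_i neighbour values
    and precision = m_i * tau_s.
    """
    w = adjacency.w if isinstance(adjacency, WeightMatrix) else adjacency
    row = np.asarray(w.getrow(i).todense()).ravel()
    nbrs = np.flatnonzero(row)
    if nbrs.size == 0:
        raise ValueError(f"unit {i} is an island; ICAR conditional undefined")
    return float(s[nbrs].mean()), float(nbrs.size * tau_s)


# ---------------------------------------------------------------------------
# sweep kernels (each consumes the rng in a fixed order for reproducibility)
# ---------------------------------------------------------------------------

def _metropolis_beta(state: ChainState, data: ModelData, spec: ModelSpec,
                     rng: np.random.Generator, steps: np.ndarray,
                     eta: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """One random-walk pass over b0..bp.  Returns per-coefficient accept flags.

    Covariate moves (j >= 1) propose b_j -> b_j + delta together with the
    compensating intercept shift b0 -> b0 - delta * mean(x_j).  Because b0
    carries a flat prior this is a plain Metropolis move along the
    (b_j, b0) posterior ridge created by non-centred covariates, and it is
    what keeps chains mixing when a covariate has a large mean relative to
    its spread; marginally the slopes are untouched.
    """
    accepted = np.zeros(data.p + 1)
    for j in range(data.p + 1):
        delta = steps[j] * rng.normal()
        logu = np.log(rng.uniform())
        if j == 0:
            xj = np.ones(data.n)
            d_eta = delta * xj
        else:
            xj = data.Xc[:, j - 1]  # centred column: ridge-aligned move
            d_eta = delta * xj
        new_eta = eta + d_eta
        if np.max(np.abs(new_eta)) > _LOGR_CAP:
            continue
        d_ll = delta * float(data.O @ xj) - float(lam @ np.expm1(d_eta))
        if j > 0:  # vague Normal prior; intercept is flat
            b = state.beta[j]
            d_ll -= 0.5 * spec.beta_precision * ((b + delta) ** 2 - b ** 2)
        if logu < d_ll:
            state.beta[j] += delta
            if j > 0:
                state.beta[0] -= delta * data.x_mean[j - 1]
            eta += d_eta
            lam *= np.exp(d_eta)
            accepted[j] = 1.0
    return accepted


def _metropolis_u(state: ChainState, data: ModelData,
                  rng: np.random.Generator, step: float,
                  eta: np.ndarray, lam: np.ndarray) -> float:
    """Simultaneous site-wise update of all u_i (conditionally independent)."""
    delta = step * rng.normal(size=data.n)
    logu = np.log(rng.uniform(size=data.n))
    d_ll = data.O * delta - lam * np.expm1(delta)
    d_prior = -0.5 * state.tau_u * ((state.u + delta) ** 2 - state.u ** 2)
    acc = (logu < d_ll + d_prior) & (np.abs(eta + delta) <= _LOGR_CAP)
    d_eta = np.where(acc, delta, 0.0)
    state.u += d_eta
    eta += d_eta
    lam *= np.exp(d_eta)
    return float(acc.mean())


def _metropolis_s(state: ChainState, data: ModelData,
                  rng: np.random.Generator, step: float,
                  eta: np.ndarray, lam: np.ndarray) -> float:
    """Colour-class-wise update of the ICAR field s."""
    n_acc, n_tot = 0.0, 0.0
    for idx in data.colour_classes:
        delta = step * rng.normal(size=idx.size)
        logu = np.log(rng.uniform(size=idx.size))
        nbr_sum = (data.W @ state.s)[idx]
        s_old = state.s[idx]
        s_new = s_old + delta
        d_ll = data.O[idx] * delta - lam[idx] * np.expm1(delta)
        d_prior = -0.5 * state.tau_s * (
            data.card[idx] * (s_new ** 2 - s_old ** 2)
            - 2.0 * delta * nbr_sum)
        acc = (logu < d_ll + d_prior) & (np.abs(eta[idx] + delta) <= _LOGR_CAP)
        d_eta = np.where(acc, delta, 0.0)
        state.s[idx] += d_eta
        eta[idx] += d_eta
        lam[idx] *= np.exp(d_eta)
        n_acc += acc.sum()
        n_tot += idx.size
    return float(n_acc / n_tot)


def _gibbs_precisions(state: ChainState, data: ModelData, spec: ModelSpec,
                      rng: np.random.Generator) -> None:
    a, b = spec.tau_prior_a, spec.tau_prior_b
    n = data.n
    state.tau_u = rng.gamma(a + n / 2.0,
                            1.0 / (b + 0.5 * float(state.u @ state.u)))
    sd = state.s[data.edges[:, 0]] - state.s[data.edges[:, 1]]
    state.tau_s = rng.gamma(a + (n - data.n_components) / 2.0,
                            1.0 / (b + 0.5 * float(sd @ sd)))


def _recentre(state: ChainState) -> None:
    """Impose sum(s)=0 by the likelihood-invariant move (s, b0)->(s-m, b0+m)."""
    m = state.s.mean()
    state.s -= m
    state.beta[0] += m


# public single-step wrappers (operate on a state copy is unnecessary;
# callers in tests pass throwaway states)

def update_fixed_effects(state: ChainState, data: ModelData, spec: ModelSpec,
                         rng: np.random.Generator,
                         steps: np.ndarray | float = 0.1) -> ChainState:
    steps = np.broadcast_to(np.asarray(steps, dtype=float),
                            (data.p + 1,)).copy()
    eta = state.linpred(data)
    lam = data.E * np.exp(eta)
    _metropolis_beta(state, data, spec, rng, steps, eta, lam)
    return state


def update_random_effects(state: ChainState, data: ModelData, spec: ModelSpec,
                          rng: np.random.Generator, step_u: float = 0.1,
                          step_s: float = 0.1) -> ChainState:
    eta = state.linpred(data)
    lam = data.E * np.exp(eta)
    _metropolis_u(state, data, rng, step_u, eta, lam)
    _metropolis_s(state, data, rng, step_s, eta, lam)
    _recentre(state)
    return state


def update_precisions(state: ChainState, data: ModelData, spec: ModelSpec,
                      rng: np.random.Generator) -> ChainState:
    _gibbs_precisions(state, data, spec, rng)
    return state


# ---------------------------------------------------------------------------
# full runner
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """Post-burn-in, thinned draws; leading axis is the chain."""

    beta: np.ndarray      # (chains, draws, p+1)
    u: np.ndarray         # (chains, draws, n)
    s: np.ndarray         # (chains, draws, n)
    tau_u: np.ndarray     # (chains, draws)
    tau_s: np.ndarray     # (chains, draws)
    deviance: np.ndarray  # (chains, draws)
    spec: ModelSpec
    accept_rates: dict = field(default_factory=dict)
    initial_states: list = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[1]

    def pooled(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])


def _initial_state(data: ModelData, spec: ModelSpec, chain: int) -> ChainState:
    """Over-dispersed inits: b0 offset by +/-1, precisions by a factor of 10."""
    sign = 1.0 if chain % 2 == 0 else -1.0
    beta = np.zeros(data.p + 1)
    beta[0] = spec.init_beta0 + sign * 1.0
    tau = 10.0 if chain % 2 == 0 else 0.1
    return ChainState(beta=beta, u=np.zeros(data.n), s=np.zeros(data.n),
                      tau_u=tau, tau_s=tau)


def _run_chain(data: ModelData, spec: ModelSpec, rng: np.random.Generator,
               chain: int) -> dict:
    state = _initial_state(data, spec, chain)
    init = state.copy()
    kept = spec.kept_per_chain
    n, p = data.n, data.p
    out = {
        "beta": np.empty((kept, p + 1)), "u": np.empty((kept, n)),
        "s": np.empty((kept, n)), "tau_u": np.empty(kept),
        "tau_s": np.empty(kept), "deviance": np.empty(kept),
    }
    steps_beta = np.full(p + 1, 0.05)
    # covariates on very different scales need different proposal scales
    col_sd = data.X.std(axis=0)
    steps_beta[1:] = 0.05 / np.where(col_sd > 0, col_sd, 1.0)
    step_u, step_s = 0.1, 0.1
    acc_beta = np.zeros(p + 1)
    acc_u = acc_s = 0.0
    tune_every = 100

    eta = state.linpred(data)
    lam = data.E * np.exp(eta)

    k = 0
    for it in range(spec.iterations):
        acc_beta += _metropolis_beta(state, data, spec, rng, steps_beta,
                                     eta, lam)
        acc_u += _metropolis_u(state, data, rng, step_u, eta, lam)
        acc_s += _metropolis_s(state, data, rng, step_s, eta, lam)
        _recentre(state)
        _gibbs_precisions(state, data, spec, rng)
        if (it + 1) % 500 == 0:  # limit incremental FP drift in eta/lam
            eta = state.linpred(data)
            lam = data.E * np.exp(eta)

        in_burn = it < spec.burn_in
        if in_burn and (it + 1) % tune_every == 0:
            rates_b = acc_beta / tune_every
            steps_beta *= np.exp(rates_b - spec.target_accept)
            step_u *= np.exp(acc_u / tune_every - spec.target_accept)
            step_s *= np.exp(acc_s / tune_every - spec.target_accept)
            acc_beta[:] = 0.0
            acc_u = acc_s = 0.0
        if not in_burn:
            if (it - spec.burn_in) % spec.thinning == 0 and k < kept:
                log_lam = data.log_E + eta
                dev = -2.0 * float(np.sum(
                    data.O * log_lam - lam - data.log_fact_O))
                out["beta"][k] = state.beta
                out["u"][k] = state.u
                out["s"][k] = state.s
                out["tau_u"][k] = state.tau_u
                out["tau_s"][k] = state.tau_s
                out["deviance"][k] = dev
                k += 1
        if not np.all(np.isfinite(state.beta)):
            raise FloatingPointError(
                f"chain {chain} diverged at sweep {it}: beta={state.beta}")
    out["init"] = init
    out["steps"] = {"beta": steps_beta, "u": step_u, "s": step_s}
    return out


def run_chains(spec: ModelSpec, data: ModelData) -> PosteriorSamples:
    """Run the configured chains from over-dispersed inits; deterministic in seed."""
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    chains = [
        _run_chain(data, spec, np.random.default_rng(ss), c)
        for c, ss in enumerate(seeds)
    ]
    return PosteriorSamples(
        beta=np.stack([c["beta"] for c in chains]),
        u=np.stack([c["u"] for c in chains]),
        s=np.stack([c["s"] for c in chains]),
        tau_u=np.stack([c["tau_u"] for c in chains]),
        tau_s=np.stack([c["tau_s"] for c in chains]),
        deviance=np.stack([c["deviance"] for c in chains]),
        spec=spec,
        initial_states=[c["init"] for c in chains],
    )


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def psi(samples: PosteriorSamples) -> dict:
    """Spatial fraction psi = SD(s)/(SD(s)+SD(u)) per draw, then summarised.

    SDs are the empirical standard deviations across units within a draw.
    Draws with SD(s)+SD(u)=0 are undefined and excluded (and counted).
    """
    sd_s = samples.pooled("s").std(axis=1, ddof=1)
    sd_u = samples.pooled("u").std(axis=1, ddof=1)
    tot = sd_s + sd_u
    ok = tot > 0
    vals = sd_s[ok] / tot[ok]
    if vals.size == 0:
        raise ValueError("psi undefined for every draw (all-zero fields)")
    lo, hi = np.quantile(vals, [0.025, 0.975])
    return {"mean": float(vals.mean()), "ci_low": float(lo),
            "ci_high": float(hi), "draws": vals,
            "n_undefined": int((~ok).sum())}


def _deviance_at(beta: np.ndarray, u: np.ndarray, s: np.ndarray,
                 data: ModelData) -> float:
    eta = beta[0] + data.X @ beta[1:] + u + s
    log_lam = data.log_E + eta
    return -2.0 * float(np.sum(
        data.O * log_lam - np.exp(log_lam) - data.log_fact_O))


def dic(samples: PosteriorSamples, data: ModelData) -> dict:
    """Classic DIC: Dbar + pD with pD = Dbar - D(posterior means).

    The plug-in deviance is evaluated at the posterior means of beta, u and
    s (s recentred; it already sums to zero draw-wise).
    """
    dbar = float(samples.pooled("deviance").mean())
    beta_bar = samples.pooled("beta").mean(axis=0)
    u_bar = samples.pooled("u").mean(axis=0)
    s_bar = samples.pooled("s").mean(axis=0)
    s_bar = s_bar - s_bar.mean()
    d_hat = _deviance_at(beta_bar, u_bar, s_bar, data)
    p_d = dbar - d_hat
    return {"Dbar": dbar, "pD": p_d, "DIC": dbar + p_d}


def relative_risk(samples: PosteriorSamples, data: ModelData) -> pd.DataFrame:
    """Posterior mean and 95% CrI of r_i = exp(b0 + X b + u_i + s_i)."""
    beta = samples.pooled("beta")
    eta = (beta[:, :1] + beta[:, 1:] @ data.X.T
           + samples.pooled("u") + samples.pooled("s"))
    r = np.exp(eta)
    lo, hi = np.quantile(r, [0.025, 0.975], axis=0)
    return pd.DataFrame({
        "unit_id": data.unit_ids,
        "rr_mean": r.mean(axis=0),
        "rr_ci_low": lo,
        "rr_ci_high": hi,
    })


def _gelman_rubin(chains: np.ndarray) -> float:
    """Classic potential scale reduction factor from (chains, draws)."""
    m, n = chains.shape
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else np.inf
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _batch_means_mcse(x: np.ndarray, n_batches: int = 50) -> float:
    """Monte Carlo standard error of the mean by non-overlapping batch means."""
    n = x.size
    b = max(n // n_batches, 1)
    usable = n_batches * b
    if usable > n:
        n_batches = n // b
        usable = n_batches * b
    means = x[:usable].reshape(n_batches, b).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


def _autocorr(x: np.ndarray, max_lag: int) -> np.ndarray:
    z = x - x.mean()
    var = float(z @ z)
    if var == 0:
        return np.zeros(max_lag + 1)
    return np.array([1.0] + [
        float(z[:-k] @ z[k:]) / var for k in range(1, max_lag + 1)])


def diagnostics(samples: PosteriorSamples, max_lag: int = 20,
                n_batches: int = 50) -> pd.DataFrame:
    """Per-scalar-parameter R-hat, MC error, posterior SD and the 5% rule.

    The accuracy flag follows the WinBUGS practice: the Monte Carlo error of
    the posterior mean should be below 5% of the posterior SD.
    """
    if samples.n_chains < 2:
        raise ValueError("Gelman-Rubin diagnostic needs >= 2 chains")
    rows = []
    p1 = samples.beta.shape[2]
    scalars = {f"beta{j}": samples.beta[:, :, j] for j in range(p1)}
    scalars["tau_u"] = samples.tau_u
    scalars["tau_s"] = samples.tau_s
    scalars["deviance"] = samples.deviance
    for name, arr in scalars.items():
        pooled = arr.reshape(-1)
        sd = float(pooled.std(ddof=1))
        # MCSE per chain, combined as the SE of the average of chain means
        per_chain = [_batch_means_mcse(arr[c], n_batches)
                     for c in range(arr.shape[0])]
        mcse = float(np.sqrt(np.mean(np.square(per_chain)) / arr.shape[0]))
        ac = _autocorr(pooled, min(max_lag, pooled.size - 1))
        rows.append({
            "parameter": name,
            "rhat": _gelman_rubin(arr),
            "mc_error": mcse,
            "posterior_sd": sd,
            "mc_error_ok": bool(mcse < 0.05 * sd) if sd > 0 else True,
            "acf_lag1": float(ac[1]) if ac.size > 1 else np.nan,
        })
    return pd.DataFrame(rows).set_index("parameter")


@dataclass
class FitSummary:
    """Table-shaped posterior summary for one model fit."""

    table: pd.DataFrame          # beta rows + psi: mean, CrI, significance
    psi_mean: float
    psi_ci: tuple[float, float]
    Dbar: float
    pD: float
    DIC: float
    diagnostics: pd.DataFrame
    measure: str = ""
    disorder: str = ""

    def to_frame(self) -> pd.DataFrame:
        extra = pd.DataFrame({
            "mean": [self.pD, self.DIC],
            "ci_low": [np.nan, np.nan],
            "ci_high": [np.nan, np.nan],
            "significant": [False, False],
        }, index=["pD", "DIC"])
        return pd.concat([self.table, extra])


def summarize(samples: PosteriorSamples, data: ModelData,
              measure: str = "", disorder: str = "") -> FitSummary:
    """Posterior means, 95% CrIs and significance flags, plus psi, pD, DIC.

    A coefficient is flagged significant when its 95% credible interval
    excludes zero (both bounds strictly on one side).
    """
    beta = samples.pooled("beta")
    rows = {}
    for j in range(beta.shape[1]):
        draws = beta[:, j]
        lo, hi = np.quantile(draws, [0.025, 0.975])
        rows[f"beta{j}"] = {
            "mean": float(draws.mean()), "ci_low": float(lo),
            "ci_high": float(hi), "significant": bool(lo > 0 or hi < 0),
        }
    ps = psi(samples)
    rows["psi"] = {"mean": ps["mean"], "ci_low": ps["ci_low"],
                   "ci_high": ps["ci_high"],
                   "significant": bool(ps["ci_low"] > 0)}
    table = pd.DataFrame(rows).T
    d = dic(samples, data)
    return FitSummary(
        table=table, psi_mean=ps["mean"],
        psi_ci=(ps["ci_low"], ps["ci_high"]),
        Dbar=d["Dbar"], pD=d["pD"], DIC=d["DIC"],
        diagnostics=diagnostics(samples),
        measure=measure, disorder=disorder,
    )
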