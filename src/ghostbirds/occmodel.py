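"""Bayesian hierarchical multi-species occupancy model.

The model treats detection/non-detection histories ``y[i, j, k]`` (site i,
occasion j, species k) as arising from a latent occupancy state
``z[i, k] ~ Bernoulli(psi_ik)`` observed imperfectly: conditional on
presence, ``y[i, j, k] ~ Bernoulli(p_ijk)``.  Both probabilities are
modelled on the logit scale,

    logit(p_ijk)  = alpha0_k + alphaA_k * RouteA_i + alphaB_k * RouteB_i
    logit(psi_ik) = beta0_k + beta1_k * midstory_i + beta2_k * canopy_i
                    + beta3_k * burned_i

where the route dummies encode which of three observer routes surveyed the
site (off-route observer as reference), the vegetation covariates are
standardized midstory (4.5-10 m) and canopy (20-30 m) LiDAR return
densities, and ``burned`` flags sites inside a fire perimeter.  Species
coefficients are random effects drawn from community-level normal
distributions (one mean/sd pair per coefficient family; the two route
contrasts share a family), which lets sparsely detected species borrow
strength from the community.

Hyperpriors: Normal(0, variance 1000) on each community mean and, by
default, half-normal(scale 2.25) on each community standard deviation.
The sampler is Metropolis-within-Gibbs with latent-state augmentation:
``z`` from its closed-form full conditional, species coefficients by
adaptive random-walk Metropolis (proposal scales tuned during burn-in to
roughly 20-40% acceptance), community means by conjugate normal draws and
community sds by random-walk on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

__all__ = [
    "DetectionArray",
    "SiteDesign",
    "CommunityParams",
    "SamplerConfig",
    "PosteriorSamples",
    "COEF_FAMILIES",
    "standardize",
    "unstandardize",
    "loglik_marginal",
    "full_conditional_z",
    "sample_posterior",
    "gelman_rubin",
    "summarize_posterior",
    "classify_support",
    "count_support_table",
]

# coefficient slots, in storage order, and the hyper family each belongs to
COEF_SLOTS = (
    ("alpha0", "alpha0"),
    ("alpha_routeA", "alpha_route"),
    ("alpha_routeB", "alpha_route"),
    ("beta0", "beta0"),
    ("beta_mid", "beta_mid"),
    ("beta_can", "beta_can"),
    ("beta_burn", "beta_burn"),
)
COEF_FAMILIES = ("alpha0", "alpha_route", "beta0", "beta_mid", "beta_can", "beta_burn")

MISSING = -1  # sentinel for unsurveyed occasions in the y array


# ---------------------------------------------------------------------------
# data containers


@dataclass
class DetectionArray:
    """Binary detection histories with missing occasions.

    ``y`` has shape (M, J, K) with entries in {0, 1, -1}; -1 marks
    occasions beyond a site's survey effort.  The missing pattern must be
    a per-site prefix length shared across species (``n_occasions``).
    """

    y: np.ndarray
    species_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if self.y.ndim != 3:
            raise ValueError("y must be (sites, occasions, species)")
        vals = np.unique(self.y)
        if not np.isin(vals, [MISSING, 0, 1]).all():
            raise ValueError("y entries must be 0, 1 or -1 (missing)")
        if self.K < 1:
            raise ValueError("need at least one species")
        observed = self.y[:, :, 0] != MISSING
        if not (observed.sum(axis=1) >= 1).all():
            raise ValueError("every site needs at least one surveyed occasion")
        if ((self.y == MISSING) != (self.y[:, :, :1] == MISSING)).any():
            raise ValueError("missing pattern must be shared across species")

    @property
    def M(self) -> int:
        return self.y.shape[0]

    @property
    def J(self) -> int:
        return self.y.shape[1]

    @property
    def K(self) -> int:
        return self.y.shape[2]

    @property
    def n_occasions(self) -> np.ndarray:
        """Number of surveyed occasions per site."""
        return (self.y[:, :, 0] != MISSING).sum(axis=1)

    def detection_counts(self) -> np.ndarray:
        """Per site x species count of occasions with a detection."""
        return (self.y == 1).sum(axis=1)


@dataclass
class SiteDesign:
    """Per-site occupancy/detection covariates, standardized.

    ``route`` codes the observer route: 0 = off-route (reference),
    1 = route A, 2 = route B.  ``standardizers`` keeps the (mean, sd)
    used to standardize each continuous covariate so the same scaling can
    be applied later to prediction rasters.
    """

    midstory: np.ndarray
    canopy: np.ndarray
    burned: np.ndarray
    route: np.ndarray
    standardizers: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.midstory = np.asarray(self.midstory, dtype=float)
        self.canopy = np.asarray(self.canopy, dtype=float)
        self.burned = np.asarray(self.burned, dtype=float)
        self.route = np.asarray(self.route, dtype=int)
        M = self.midstory.shape[0]
        for name in ("canopy", "burned", "route"):
            if getattr(self, name).shape != (M,):
                raise ValueError("site covariates must be 1-D of equal length")
        if not np.isin(self.burned, [0.0, 1.0]).all():
            raise ValueError("burned flag must be binary")
        if not np.isin(self.route, [0, 1, 2]).all():
            raise ValueError("route codes must be 0 (off-route), 1 or 2")

    @property
    def M(self) -> int:
        return self.midstory.shape[0]

    def occupancy_matrix(self) -> np.ndarray:
        """(M, 4) design matrix [1, midstory, canopy, burned]."""
        return np.column_stack(
            [np.ones(self.M), self.midstory, self.canopy, self.burned]
        )

    def route_matrix(self) -> np.ndarray:
        """(M, 3) detection design [1, I(route A), I(route B)]."""
        X = np.zeros((self.M, 3))
        X[:, 0] = 1.0
        X[:, 1] = self.route == 1
        X[:, 2] = self.route == 2
        return X


@dataclass
class CommunityParams:
    """Species-level coefficients plus the community hyperparameters.

    ``coefs`` maps each slot name of :data:`COEF_SLOTS` to a length-K
    array; ``hyper`` maps each family to its (mean, sd).
    """

    coefs: dict[str, np.ndarray]
    hyper: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = {s for s, _ in COEF_SLOTS} - set(self.coefs)
        if missing:
            raise ValueError(f"missing coefficient slots: {sorted(missing)}")
        K = self.K
        for name, arr in self.coefs.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (K,):
                raise ValueError("coefficient arrays must share length K")
            if not np.isfinite(arr).all():
                raise ValueError(f"non-finite coefficients in {name}")
            self.coefs[name] = arr
        for fam, (_, sd) in self.hyper.items():
            if sd < 0:
                raise ValueError(f"hyper sd for {fam} must be >= 0")

    @property
    def K(self) -> int:
        return len(next(iter(self.coefs.values())))

    def alpha_matrix(self) -> np.ndarray:
        """(K, 3) detection coefficients [alpha0, alphaA, alphaB]."""
        c = self.coefs
        return np.column_stack([c["alpha0"], c["alpha_routeA"], c["alpha_routeB"]])

    def beta_matrix(self) -> np.ndarray:
        """(K, 4) occupancy coefficients [beta0, mid, can, burn]."""
        c = self.coefs
        return np.column_stack([c["beta0"], c["beta_mid"], c["beta_can"], c["beta_burn"]])


# ---------------------------------------------------------------------------
# standardization


def standardize(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Center and scale to sample mean 0, sample sd 1 (n-1 denominator).

    Returns the standardized vector and the (mean, sd) pair, which must be
    retained to apply the identical scaling to prediction rasters.
    """
    x = np.asarray(values, dtype=float)
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant vector")
    return (x - mean) / sd, mean, sd


def unstandardize(z: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return np.asarray(z, dtype=float) * sd + mean


# ---------------------------------------------------------------------------
# likelihood


def _probabilities(params: CommunityParams, design: SiteDesign) -> tuple[np.ndarray, np.ndarray]:
    """psi (M, K) and per-site detection probability p (M, K)."""
    psi = expit(design.occupancy_matrix() @ params.beta_matrix().T)
    p_route = expit(params.alpha_matrix() @ np.array(
        [[1.0, 0.0, 0.0], [1.0, 1.0, 0.0], [1.0, 0.0, 1.0]]).T)  # (K, 3)
    p = p_route[:, design.route].T
    return psi, p


def loglik_marginal(params: CommunityParams, y: DetectionArray, design: SiteDesign) -> float:
    """Log-likelihood with the latent occupancy states summed out.

    For each site x species cell the contribution is
    ``psi * prod_j p^y (1-p)^(1-y)`` plus, when no detection occurred,
    ``(1 - psi)``; missing occasions are skipped.  Detection probability
    varies only through the route, so the per-cell product reduces to a
    binomial kernel in the detection count.  Everything is evaluated in
    log space.
    """
    if design.M != y.M or params.K != y.K:
        raise ValueError("dimension mismatch between params, data and design")
    psi, p = _probabilities(params, design)
    d = y.detection_counts()           # (M, K)
    n = y.n_occasions[:, None]         # (M, 1)
    with np.errstate(divide="ignore"):
        log_psi = np.log(psi)
        log_1mpsi = np.log1p(-psi)
        log_p = np.log(p)
        log_1mp = np.log1p(-p)
    cond = log_psi + d * log_p + (n - d) * log_1mp
    never = d == 0
    total = np.where(never, np.logaddexp(cond, log_1mpsi), cond)
    return float(total.sum())


def full_conditional_z(psi: float, p, y) -> float:
    """P(z = 1 | y, psi, p) for one site x species history.

    Any detection implies presence.  With an all-zero history the
    posterior odds are ``psi * prod_j (1 - p_j)`` against ``1 - psi``.
    Missing occasions (-1 or NaN) are ignored.
    """
    y = np.asarray(y, dtype=float).ravel()
    p_arr = np.broadcast_to(np.asarray(p, dtype=float), y.shape)
    obs = ~(np.isnan(y) | (y == MISSING))
    if np.any(y[obs] == 1):
        return 1.0
    num = psi * float(np.prod(1.0 - p_arr[obs]))
    return num / (num + (1.0 - psi))


# ---------------------------------------------------------------------------
# sampler


@dataclass
class SamplerConfig:
    """MCMC settings.

    ``iterations`` counts post-burn-in iterations per chain (so the number
    of retained draws per chain is ``iterations / thin``); ``burn_in``
    iterations precede them and are discarded.  ``hyper_mean_var`` is the
    variance of the vague normal hyperprior on community means;
    ``hyper_sd_scale`` the scale of the half-normal hyperprior on
    community sds.  With ``hierarchical=False`` species coefficients get
    independent Normal(0, ``hyper_mean_var``) priors and the community
    level is dropped — useful for single-species fits where a flat-ish
    fixed prior is wanted.
    """

    chains: int = 3
    iterations: int = 20_000
    burn_in: int = 5_000
    thin: int = 5
    hyper_mean_var: float = 1000.0
    hyper_sd_scale: float = 2.25
    hierarchical: bool = True
    adapt_interval: int = 50
    store_z: bool = True
    max_init_retries: int = 10

    def __post_init__(self) -> None:
        if self.iterations % self.thin != 0:
            raise ValueError("thin must divide iterations")
        if min(self.chains, self.iterations, self.thin) < 1 or self.burn_in < 0:
            raise ValueError("invalid sampler settings")

    @property
    def n_draws(self) -> int:
        return self.iterations // self.thin


@dataclass
class PosteriorSamples:
    """Thinned multi-chain draws of all parameters and latent states.

    ``draws`` is (chains, n_draws, P) aligned with ``param_names``;
    ``z`` is (chains, n_draws, M, K) uint8 (or None if not stored).
    """

    draws: np.ndarray
    param_names: list[str]
    z: np.ndarray | None
    config: SamplerConfig
    seed: int
    species_names: list[str] | None = None
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def pooled(self) -> np.ndarray:
        """(chains * n_draws, P) matrix of pooled draws."""
        return self.draws.reshape(-1, self.draws.shape[-1])

    def by_name(self, name: str) -> np.ndarray:
        """(chains, n_draws) draws of one named parameter."""
        return self.draws[:, :, self.param_names.index(name)]


def _param_names(K: int, hierarchical: bool, species: list[str] | None) -> list[str]:
    labels = species if species is not None else [str(k) for k in range(K)]
    names = [f"{slot}[{lab}]" for slot, _ in COEF_SLOTS for lab in labels]
    if hierarchical:
        names += [f"mu_{fam}" for fam in COEF_FAMILIES]
        names += [f"sd_{fam}" for fam in COEF_FAMILIES]
    return names


def _normal_logpdf(x, mean, sd):
    return -0.5 * ((x - mean) / sd) ** 2 - np.log(sd) - 0.5 * math.log(2 * math.pi)


class _ChainState:
    """Mutable per-chain state for the Metropolis-within-Gibbs sweep."""

    def __init__(self, y: DetectionArray, design: SiteDesign,
                 config: SamplerConfig, rng: np.random.Generator):
        self.rng = rng
        self.cfg = config
        self.M, self.J, self.K = y.M, y.J, y.K
        self.d = y.detection_counts().astype(float)       # (M, K)
        self.n = y.n_occasions.astype(float)              # (M,)
        self.detected = self.d > 0
        self.Xocc = design.occupancy_matrix()             # (M, 4)
        self.G = np.zeros((self.M, 3))                    # route one-hot
        self.G[np.arange(self.M), design.route] = 1.0
        self.Rmat = np.array([[1.0, 0.0, 0.0], [1.0, 1.0, 0.0], [1.0, 0.0, 1.0]])
        self.route = design.route
        # parameters
        K = self.K
        self.mu = np.zeros(6)
        self.sig = np.ones(6)
        jitter = 0.5
        self.alpha = self.mu[0] + jitter * rng.standard_normal((K, 3))
        self.beta = jitter * rng.standard_normal((K, 4))
        self.beta[:, 0] += self.mu[2]
        self.z = np.where(self.detected, 1.0, (rng.random((self.M, K)) < 0.5) * 1.0)
        # adaptation state
        self.a_scale = np.full((3, K), 0.5)
        self.b_scale = np.full((4, K), 0.5)
        self.s_scale = np.full(6, 0.5)
        self.a_acc = np.zeros((3, K))
        self.b_acc = np.zeros((4, K))
        self.s_acc = np.zeros(6)
        self.total_acc = {"alpha": 0.0, "beta": 0.0}
        self.total_prop = {"alpha": 0.0, "beta": 0.0}

    # family index helpers: mu/sig order follows COEF_FAMILIES
    _ALPHA_FAM = (0, 1, 1)      # alpha slots -> family index
    _BETA_FAM = (2, 3, 4, 5)    # beta slots -> family index

    def _prior_mean_sd(self, fam_idx: int) -> tuple[float, float]:
        if self.cfg.hierarchical:
            return self.mu[fam_idx], self.sig[fam_idx]
        return 0.0, math.sqrt(self.cfg.hyper_mean_var)

    def _detection_loglik(self, alpha: np.ndarray, D: np.ndarray, Nz: np.ndarray) -> np.ndarray:
        """Per-species detection log-likelihood given z-weighted route stats."""
        eta = alpha @ self.Rmat.T            # (K, 3) logit p by route
        return (D.T * log_expit(eta) + (Nz - D).T * log_expit(-eta)).sum(axis=1)

    def _occupancy_loglik(self, logit_psi: np.ndarray) -> np.ndarray:
        """Per-species Bernoulli log-likelihood of the current z field."""
        return (self.z * log_expit(logit_psi)
                + (1.0 - self.z) * log_expit(-logit_psi)).sum(axis=0)

    def update_z(self) -> None:
        logit_psi = self.Xocc @ self.beta.T               # (M, K)
        psi = expit(logit_psi)
        p = expit((self.alpha @ self.Rmat.T))[:, self.route].T  # (M, K)
        # odds of presence given an all-zero history: psi (1-p)^n vs 1-psi
        q0 = psi * (1.0 - p) ** self.n[:, None]
        prob = q0 / (q0 + (1.0 - psi))
        draw = self.rng.random((self.M, self.K)) < prob
        self.z = np.where(self.detected, 1.0, draw * 1.0)
        self.logit_psi = logit_psi

    def update_alpha(self) -> None:
        w = self.z * self.d
        D = self.G.T @ w                                   # (3, K)
        Nz = self.G.T @ (self.z * self.n[:, None])         # (3, K)
        ll = self._detection_loglik(self.alpha, D, Nz)
        for s in range(3):
            fam = self._ALPHA_FAM[s]
            m, sd = self._prior_mean_sd(fam)
            prop = self.alpha.copy()
            prop[:, s] = self.alpha[:, s] + self.a_scale[s] * self.rng.standard_normal(self.K)
            ll_new = self._detection_loglik(prop, D, Nz)
            logr = (ll_new - ll
                    + _normal_logpdf(prop[:, s], m, sd)
                    - _normal_logpdf(self.alpha[:, s], m, sd))
            accept = np.log(self.rng.random(self.K)) < logr
            self.alpha[accept, s] = prop[accept, s]
            ll = np.where(accept, ll_new, ll)
            self.a_acc[s] += accept
            self.total_acc["alpha"] += accept.sum()
            self.total_prop["alpha"] += self.K

    def update_beta(self) -> None:
        logit_psi = self.Xocc @ self.beta.T
        ll = self._occupancy_loglik(logit_psi)
        for s in range(4):
            fam = self._BETA_FAM[s]
            m, sd = self._prior_mean_sd(fam)
            step = self.b_scale[s] * self.rng.standard_normal(self.K)
            new_logit = logit_psi + np.outer(self.Xocc[:, s], step)
            ll_new = self._occupancy_loglik(new_logit)
            new_col = self.beta[:, s] + step
            logr = (ll_new - ll
                    + _normal_logpdf(new_col, m, sd)
                    - _normal_logpdf(self.beta[:, s], m, sd))
            accept = np.log(self.rng.random(self.K)) < logr
            self.beta[accept, s] = new_col[accept]
            logit_psi[:, accept] += np.outer(self.Xocc[:, s], step)[:, accept]
            ll = np.where(accept, ll_new, ll)
            self.b_acc[s] += accept
            self.total_acc["beta"] += accept.sum()
            self.total_prop["beta"] += self.K

    def _family_values(self, fam_idx: int) -> np.ndarray:
        fam = COEF_FAMILIES[fam_idx]
        if fam == "alpha0":
            return self.alpha[:, 0]
        if fam == "alpha_route":
            return self.alpha[:, 1:3].ravel()
        slot = {"beta0": 0, "beta_mid": 1, "beta_can": 2, "beta_burn": 3}[fam]
        return self.beta[:, slot]

    def update_hyper(self) -> None:
        if not self.cfg.hierarchical:
            return
        for f in range(6):
            x = self._family_values(f)
            n = x.size
            sig2 = self.sig[f] ** 2
            prec = n / sig2 + 1.0 / self.cfg.hyper_mean_var
            mean = (x.sum() / sig2) / prec
            self.mu[f] = mean + math.sqrt(1.0 / prec) * self.rng.standard_normal()
            # log-scale random walk for the community sd, half-normal prior
            t = math.log(self.sig[f])
            t_new = t + self.s_scale[f] * self.rng.standard_normal()
            ss = float(((x - self.mu[f]) ** 2).sum())
            A2 = self.cfg.hyper_sd_scale ** 2

            def logpost(tv: float) -> float:
                s2 = math.exp(2 * tv)
                return (-n * tv - ss / (2 * s2)      # normal likelihood
                        - s2 / (2 * A2)              # half-normal prior
                        + tv)                        # Jacobian of log transform

            if math.log(self.rng.random()) < logpost(t_new) - logpost(t):
                self.sig[f] = math.exp(t_new)
                self.s_acc[f] += 1

    def adapt(self, interval: int) -> None:
        for acc, scale in ((self.a_acc, self.a_scale),
                           (self.b_acc, self.b_scale)):
            rate = acc / interval
            scale *= np.clip(np.exp(rate - 0.3), 0.5, 2.0)
            acc[:] = 0.0
        rate = self.s_acc / interval
        self.s_scale *= np.clip(np.exp(rate - 0.3), 0.5, 2.0)
        self.s_acc[:] = 0.0

    def snapshot(self) -> np.ndarray:
        cols = [self.alpha[:, 0], self.alpha[:, 1], self.alpha[:, 2],
                self.beta[:, 0], self.beta[:, 1], self.beta[:, 2], self.beta[:, 3]]
        vec = np.concatenate(cols)
        if self.cfg.hierarchical:
            vec = np.concatenate([vec, self.mu, self.sig])
        return vec


def sample_posterior(y: DetectionArray, design: SiteDesign,
                     config: SamplerConfig | None = None,
                     seed: int = 0) -> PosteriorSamples:
    """Draw from the joint posterior of the community occupancy model.

    Runs ``config.chains`` independent chains (seeded via
    ``numpy.random.SeedSequence(seed).spawn``), each with
    ``config.burn_in`` adaptation iterations followed by
    ``config.iterations`` sampling iterations thinned by ``config.thin``.
    Latent states are initialized at 1 wherever the species was detected
    and at random elsewhere; coefficients start at the hyperprior means
    plus a small per-chain jitter so chains are overdispersed.
    """
    config = config or SamplerConfig()
    if design.M != y.M:
        raise ValueError("design and detection data disagree on site count")
    names = _param_names(y.K, config.hierarchical, y.species_names)
    n_draws = config.n_draws
    draws = np.empty((config.chains, n_draws, len(names)))
    z_store = (np.empty((config.chains, n_draws, y.M, y.K), dtype=np.uint8)
               if config.store_z else None)
    seeds = np.random.SeedSequence(seed).spawn(config.chains)
    acc_alpha = acc_beta = prop = 0.0
    for c in range(config.chains):
        rng = np.random.default_rng(seeds[c])
        state = None
        for _ in range(config.max_init_retries):
            state = _ChainState(y, design, config, rng)
            state.update_z()
            if np.isfinite(state._occupancy_loglik(state.logit_psi)).all():
                break
        total = config.burn_in + config.iterations
        kept = 0
        for it in range(total):
            state.update_z()
            state.update_alpha()
            state.update_beta()
            state.update_hyper()
            if it < config.burn_in:
                if (it + 1) % config.adapt_interval == 0:
                    state.adapt(config.adapt_interval)
            else:
                j = it - config.burn_in
                if (j + 1) % config.thin == 0:
                    draws[c, kept] = state.snapshot()
                    if z_store is not None:
                        z_store[c, kept] = state.z.astype(np.uint8)
                    kept += 1
        acc_alpha += state.total_acc["alpha"]
        acc_beta += state.total_acc["beta"]
        prop += state.total_prop["alpha"]
    acceptance = {
        "alpha": acc_alpha / max(prop, 1.0),
        "beta": acc_beta / max(prop, 1.0),
    }
    return PosteriorSamples(draws=draws, param_names=names, z=z_store,
                            config=config, seed=seed,
                            species_names=y.species_names,
                            acceptance=acceptance)


# ---------------------------------------------------------------------------
# diagnostics and summaries


def gelman_rubin(samples: PosteriorSamples | np.ndarray,
                 param_names: list[str] | None = None) -> pd.Series:
    """Potential scale reduction factor per parameter.

    Uses the classic between/within-chain variance form
    ``sqrt(((n-1)/n * W + B/n) / W)``; parameters with zero within-chain
    variance are reported as NaN (undefined).
    """
    if isinstance(samples, PosteriorSamples):
        arr = samples.draws
        param_names = samples.param_names
    else:
        arr = np.asarray(samples)
        if arr.ndim == 2:
            arr = arr[:, :, None]
    m, n, P = arr.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 chains with at least 2 draws")
    chain_means = arr.mean(axis=1)                     # (m, P)
    W = arr.var(axis=1, ddof=1).mean(axis=0)           # (P,)
    B_over_n = chain_means.var(axis=0, ddof=1)         # B/n
    with np.errstate(divide="ignore", invalid="ignore"):
        var_plus = (n - 1) / n * W + B_over_n
        rhat = np.sqrt(var_plus / W)
    rhat = np.where(W > 0, rhat, np.nan)
    idx = param_names if param_names is not None else range(P)
    return pd.Series(rhat, index=idx, name="rhat")


def summarize_posterior(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior mean, sd and central 95% interval per parameter.

    Draws are pooled across chains; interval endpoints are the 2.5% and
    97.5% quantiles under the linear-interpolation quantile rule (numpy
    default), so e.g. draws 1..100 give (3.475, 97.525).
    """
    pooled = samples.pooled()
    lo, hi = np.percentile(pooled, [2.5, 97.5], axis=0)
    return pd.DataFrame({
        "mean": pooled.mean(axis=0),
        "sd": pooled.std(axis=0, ddof=1),
        "q2.5": lo,
        "q97.5": hi,
    }, index=pd.Index(samples.param_names, name="parameter"))


OCC_COVARIATES = {"beta_mid": "midstory_density",
                  "beta_can": "canopy_density",
                  "beta_burn": "burned"}


def classify_support(summary: pd.DataFrame,
                     covariates: tuple[str, ...] = ("beta_mid", "beta_can", "beta_burn"),
                     ) -> pd.DataFrame:
    """Direction and strength of each species x covariate effect.

    An effect is *strong* iff the 95% credible interval excludes 0
    strictly — an endpoint exactly at 0 counts as overlapping, hence
    weak.  Direction is the sign of the posterior mean.
    """
    rows = []
    for name in summary.index:
        if "[" not in name:
            continue
        slot, label = name[:-1].split("[", 1)
        if slot not in covariates:
            continue
        mean, lo, hi = summary.loc[name, ["mean", "q2.5", "q97.5"]]
        rows.append({
            "species": label,
            "covariate": OCC_COVARIATES.get(slot, slot),
            "slot": slot,
            "mean": mean,
            "q2.5": lo,
            "q97.5": hi,
            "direction": "negative" if mean < 0 else "positive",
            "strong": bool(lo > 0 or hi < 0),
        })
    return pd.DataFrame(rows)


def count_support_table(classification: pd.DataFrame,
                        covariates: tuple[str, ...] = ("beta_mid", "beta_can"),
                        ) -> pd.DataFrame:
    """Species counts by effect sign, with strong counts alongside.

    Rows cover each vegetation covariate plus the 'either' and 'both'
    rollups across the pair; the strong columns count species whose 95%
    interval excludes zero (for rollups: on at least one / on both
    covariates respectively).
    """
    sub = classification[classification["slot"].isin(covariates)]
    piv_neg = sub.pivot(index="species", columns="slot", values="mean") < 0
    strong = sub.pivot(index="species", columns="slot", values="strong").astype(bool)
    strong_neg = strong & piv_neg
    strong_pos = strong & ~piv_neg
    rows = {}
    for slot in covariates:
        rows[OCC_COVARIATES.get(slot, slot)] = {
            "n_negative": int(piv_neg[slot].sum()),
            "n_negative_strong": int(strong_neg[slot].sum()),
            "n_positive": int((~piv_neg[slot]).sum()),
            "n_positive_strong": int(strong_pos[slot].sum()),
        }
    rows["either"] = {
        "n_negative": int(piv_neg.any(axis=1).sum()),
        "n_negative_strong": int(strong_neg.any(axis=1).sum()),
        "n_positive": int((~piv_neg).any(axis=1).sum()),
        "n_positive_strong": int(strong_pos.any(axis=1).sum()),
    }
    rows["both"] = {
        "n_negative": int(piv_neg.all(axis=1).sum()),
        "n_negative_strong": int(strong_neg.all(axis=1).sum()),
        "n_positive": int((~piv_neg).all(axis=1).sum()),
        "n_positive_strong": int(strong_pos.all(axis=1).sum()),
    }
    return pd.DataFrame(rows).T.rename_axis("covariate")
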