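"""Synthetic landscapes, communities and surveys.

This module generates data with the statistical structure the analysis
assumes, so every downstream stage (ghost-forest classification,
occupancy modelling, richness, habitat-change accounting) can be
exercised end-to-end without field or LiDAR downloads:

* two-epoch grids of seven vegetation-structure metrics (three height
  metrics in metres and four return-density fractions) with spatial
  autocorrelation from smoothed Gaussian noise;
* a clustered ghost-forest transition confined to low-lying unburned
  cells, implemented as a multiplicative reduction of midstory
  (4.5-10 m) and canopy (20-30 m) densities between epochs, plus an
  independent structural perturbation inside a burned perimeter;
* a bird community whose species-level coefficients are drawn from
  community hyperparameters, and repeat-survey detection histories with
  route-specific detection probability and missing occasions.

Defaults emulate the study design the analysis was built around:
156 survey points (two observer routes plus off-route points) spaced at
least 400 m apart, up to 3 occasions per site, 248 classifier points,
and community hyperparameters giving mean occupancy near 0.4 and mean
detection near 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .occmodel import CommunityParams, DetectionArray, SiteDesign, standardize
from .rasters import LAYER_MID_HEIGHTS, METRIC_NAMES, SyntheticLandscape

__all__ = [
    "CommunityHyper",
    "SurveyDesign",
    "default_community_hyper",
    "draw_community_params",
    "simulate_landscape",
    "simulate_biomass_change",
    "sample_sites",
    "sample_metric_points",
    "build_site_design",
    "simulate_community_dataset",
    "simulate_detections",
]


@dataclass
class CommunityHyper:
    """Community-level (mean, sd) pairs governing species coefficients.

    All values live on the logit scale.  The two route-contrast detection
    coefficients share the single ``alpha_route`` family.
    """

    alpha0: tuple[float, float]
    alpha_route: tuple[float, float]
    beta0: tuple[float, float]
    beta_mid: tuple[float, float]
    beta_can: tuple[float, float]
    beta_burn: tuple[float, float]

    def __post_init__(self) -> None:
        for fam in ("alpha0", "alpha_route", "beta0",
                    "beta_mid", "beta_can", "beta_burn"):
            mean, sd = getattr(self, fam)
            if sd < 0:
                raise ValueError(f"hyper sd for {fam} must be >= 0")

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {
            "alpha0": self.alpha0,
            "alpha_route": self.alpha_route,
            "beta0": self.beta0,
            "beta_mid": self.beta_mid,
            "beta_can": self.beta_can,
            "beta_burn": self.beta_burn,
        }


def default_community_hyper() -> CommunityHyper:
    """Defaults giving mean occupancy ~0.4 and mean detection ~0.5.

    The burned effect is negative on average (most forest species avoid
    recently burned stands) and the canopy effect positive (the community
    skews towards closed-forest species), with between-species sds large
    enough that individual species take either sign.
    """
    return CommunityHyper(
        alpha0=(0.0, 0.75),
        alpha_route=(0.0, 0.5),
        beta0=(-0.4, 1.0),
        beta_mid=(0.25, 0.75),
        beta_can=(0.5, 0.75),
        beta_burn=(-0.5, 0.75),
    )


def draw_community_params(hyper: CommunityHyper, n_species: int,
                          seed: int = 0) -> CommunityParams:
    """Draw species-level coefficients as normal random effects.

    Each coefficient of each species is an independent draw from the
    normal law of its hyper family; both route contrasts come from the
    shared ``alpha_route`` family.
    """
    if n_species < 1:
        raise ValueError("need at least one species")
    h = hyper.as_dict()
    rng = np.random.default_rng(seed)
    slot_family = {
        "alpha0": "alpha0",
        "alpha_routeA": "alpha_route",
        "alpha_routeB": "alpha_route",
        "beta0": "beta0",
        "beta_mid": "beta_mid",
        "beta_can": "beta_can",
        "beta_burn": "beta_burn",
    }
    coefs = {}
    for slot, fam in slot_family.items():
        mean, sd = h[fam]
        coefs[slot] = rng.normal(mean, sd, size=n_species)
    return CommunityParams(coefs=coefs, hyper=h)


# ---------------------------------------------------------------------------
# landscape


def _smooth_field(rng: np.random.Generator, dims: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Unit-variance spatially autocorrelated Gaussian surface."""
    f = gaussian_filter(rng.standard_normal(dims), sigma, mode="wrap")
    return (f - f.mean()) / f.std()


def simulate_landscape(dims: tuple[int, int] = (720, 720),
                       ghost_fraction: float = 0.08,
                       burn_fraction: float = 0.12,
                       lowlying_fraction: float = 0.30,
                       seed: int = 0,
                       cell_size: float = 12.0,
                       reduction: float | tuple[float, float] = (0.05, 0.55),
                       smooth_sigma: float = 4.0) -> SyntheticLandscape:
    """Generate a two-epoch landscape of vegetation-structure metrics.

    The baseline epoch has seven spatially autocorrelated surfaces
    (heights in metres, densities in [0, 1]).  The later epoch equals the
    baseline except that ghost-transition cells — a clustered set inside
    the low-lying unburned mask covering ``ghost_fraction`` of the grid —
    have midstory and canopy density multiplied by a per-cell, per-layer
    severity factor drawn uniformly from the ``reduction`` range (a
    scalar gives every cell that factor), and burned cells get an
    independent structural knock-down of all layers.  The heterogeneous
    severity emulates real transitions, which span barely-detectable
    thinning to near-total dieback, so the ghost and unaffected classes
    genuinely overlap in structure space.

    Fractions are of the whole grid; a configuration error is raised when
    the low-lying unburned area cannot contain the requested ghost area.
    """
    for name, frac in (("ghost", ghost_fraction), ("burn", burn_fraction),
                       ("lowlying", lowlying_fraction)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name}_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_cells = dims[0] * dims[1]

    def expit(x):
        return 1.0 / (1.0 + np.exp(-x))

    # one dominant stature factor drives heights and canopy density (they
    # are strongly cross-correlated in LiDAR summaries of closed forest);
    # midstory and lower-canopy density carry mostly their own factors
    f_stature = _smooth_field(rng, dims, smooth_sigma)
    f_mid = _smooth_field(rng, dims, smooth_sigma)
    f_low = _smooth_field(rng, dims, smooth_sigma)
    f_under = _smooth_field(rng, dims, smooth_sigma)
    e1, e2, e3, e4 = (_smooth_field(rng, dims, smooth_sigma) for _ in range(4))

    canopy = expit(-1.9 + 1.1 * (0.90 * f_stature + 0.44 * e1))
    midstory = expit(-1.2 + 0.8 * (0.30 * f_stature + 0.95 * f_mid))
    lower = expit(-1.5 + 0.7 * (0.40 * f_stature + 0.92 * f_low))
    understory = 0.4 * expit(-1.5 + 0.5 * f_under)
    total = np.clip(midstory + lower + canopy + understory, 0.0, 1.0)
    mean_h = 4.0 + 16.0 * expit(0.2 + 1.1 * (0.78 * f_stature + 0.63 * e2))
    max_h = mean_h * (1.4 + 0.5 * expit(0.78 * f_stature + 0.63 * e3))
    sd_h = 1.0 + 4.0 * expit(0.75 * f_stature + 0.66 * e4)

    baseline = {
        "mean_height": mean_h,
        "max_height": max_h,
        "sd_height": sd_h,
        "midstory_density": midstory,
        "lower_canopy_density": lower,
        "canopy_density": canopy,
        "total_density": total,
    }

    # strata: contiguous burn perimeter and low-lying area from their own
    # (more coherent) smoothed fields; low-lying excludes burned
    f_burn = _smooth_field(rng, dims, 3.0 * smooth_sigma)
    f_elev = _smooth_field(rng, dims, 3.0 * smooth_sigma)
    burned = (f_burn >= np.quantile(f_burn, 1.0 - burn_fraction)
              if burn_fraction > 0 else np.zeros(dims, dtype=bool))
    lowlying = (f_elev <= np.quantile(f_elev, lowlying_fraction)
                if lowlying_fraction > 0 else np.zeros(dims, dtype=bool))
    lowlying &= ~burned

    n_ghost = int(round(ghost_fraction * n_cells))
    if n_ghost > int(lowlying.sum()):
        raise ValueError(
            "grid too small / fractions infeasible: ghost area exceeds the "
            "low-lying unburned area")
    ghost = np.zeros(dims, dtype=bool)
    if n_ghost > 0:
        # clustered transition: threshold a smoothed field inside the mask
        f_ghost = _smooth_field(rng, dims, 2.0 * smooth_sigma)
        vals = f_ghost[lowlying]
        cut = np.sort(vals)[-n_ghost]
        ghost = lowlying & (f_ghost >= cut)

    later = {name: arr.copy() for name, arr in baseline.items()}
    # per-cell, per-layer mortality severity: saltwater kill is patchy and
    # canopy dieback is only loosely coupled to midstory shrub loss, so
    # each layer draws its own factor
    lo, hi = ((reduction, reduction) if np.isscalar(reduction)
              else reduction)
    n_g = int(ghost.sum())
    later["midstory_density"][ghost] *= rng.uniform(lo, hi, n_g)
    later["canopy_density"][ghost] *= rng.uniform(lo, hi, n_g)
    # total density is the all-bands return fraction: returns lost from
    # the midstory and canopy bands leave the total, but the opened
    # canopy lets salt-tolerant shrub/herbaceous understory proliferate,
    # compensating much of the loss (which is why total density is a
    # poor ghost-forest predictor in practice)
    lost = ((baseline["midstory_density"] - later["midstory_density"])
            + (baseline["canopy_density"] - later["canopy_density"]))
    compensation = rng.uniform(0.3, 1.2, n_g)
    later["total_density"][ghost] = np.clip(
        later["total_density"][ghost] - lost[ghost] * (1.0 - compensation),
        0.0, 1.0)
    if burned.any():
        # fire knock-down: strong loss in all vegetation layers, with
        # cell-level variation, plus reduced heights
        u = rng.random(int(burned.sum()))
        for name in ("midstory_density", "lower_canopy_density",
                     "canopy_density", "total_density"):
            later[name][burned] *= 0.15 + 0.35 * u
        v = rng.random(int(burned.sum()))
        for name in ("mean_height", "max_height", "sd_height"):
            later[name][burned] *= 0.5 + 0.3 * v
    for name in ("midstory_density", "lower_canopy_density",
                 "canopy_density", "total_density"):
        np.clip(later[name], 0.0, 1.0, out=later[name])

    return SyntheticLandscape(
        metrics_baseline=baseline,
        metrics_later=later,
        ghost_mask=ghost,
        burned_mask=burned,
        lowlying_mask=lowlying,
        cell_size=cell_size,
        params={
            "seed": seed, "ghost_fraction": ghost_fraction,
            "burn_fraction": burn_fraction,
            "lowlying_fraction": lowlying_fraction,
            "reduction": reduction, "smooth_sigma": smooth_sigma,
        },
    )


def simulate_biomass_change(landscape: SyntheticLandscape) -> np.ndarray:
    """Binary ghost label per cell from a biomass-change proxy.

    The proxy is the sum over vegetation layers of return density times
    the layer mid-height — any monotone structural index works because
    only the sign of the 2001-to-2014 analogue change is used.  A cell is
    labelled ghost (True) where the proxy strictly decreased and
    unaffected (False) where it did not.
    """
    def proxy(book):
        return sum(book[name] * h for name, h in LAYER_MID_HEIGHTS.items())

    return proxy(landscape.metrics_later) < proxy(landscape.metrics_baseline)


# ---------------------------------------------------------------------------
# survey design


@dataclass
class SurveyDesign:
    """Survey-point locations, observer routes and effort.

    ``route`` uses the occupancy model's codes (0 = off-route observer,
    1 = route A, 2 = route B); ``n_occasions`` is the per-site number of
    surveyed occasions in {1, 2, 3}.
    """

    rows: np.ndarray
    cols: np.ndarray
    route: np.ndarray
    n_occasions: np.ndarray
    min_spacing: float
    cell_size: float

    def __post_init__(self) -> None:
        M = len(self.rows)
        for name in ("cols", "route", "n_occasions"):
            if len(getattr(self, name)) != M:
                raise ValueError("survey-design fields must share length")
        if not np.isin(self.n_occasions, [1, 2, 3]).all():
            raise ValueError("occasion counts must be in {1, 2, 3}")
        if M > 1:
            x = self.cols * self.cell_size
            y = self.rows * self.cell_size
            d2 = (x[:, None] - x[None, :]) ** 2 + (y[:, None] - y[None, :]) ** 2
            np.fill_diagonal(d2, np.inf)
            if d2.min() < (self.min_spacing - 1e-9) ** 2:
                raise ValueError("site spacing below the stated minimum")

    @property
    def M(self) -> int:
        return len(self.rows)


def _place_points(mask: np.ndarray, n_points: int, min_spacing_cells: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Greedy blue-noise placement of points at a minimum spacing.

    Candidate cells are visited in random order; accepting a point blocks
    a disk of radius ``min_spacing_cells`` around it.  Raises when the
    candidate list is exhausted before ``n_points`` are placed.
    """
    H, W = mask.shape
    r = int(np.ceil(min_spacing_cells))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    disk = (dy ** 2 + dx ** 2) < min_spacing_cells ** 2
    dyi, dxi = dy[disk], dx[disk]
    blocked = np.zeros((H, W), dtype=bool)
    cand = np.flatnonzero(mask)
    rng.shuffle(cand)
    rows = np.empty(n_points, dtype=int)
    cols = np.empty(n_points, dtype=int)
    placed = 0
    for idx in cand:
        i, j = divmod(int(idx), W)
        if blocked[i, j]:
            continue
        rows[placed], cols[placed] = i, j
        placed += 1
        if placed == n_points:
            return rows, cols
        yy = np.clip(i + dyi, 0, H - 1)
        xx = np.clip(j + dxi, 0, W - 1)
        blocked[yy, xx] = True
    raise ValueError(
        f"could only place {placed} of {n_points} points at the requested "
        "spacing; enlarge the grid or relax the spacing")


def sample_sites(landscape: SyntheticLandscape, n_sites: int = 156,
                 min_spacing: float = 400.0,
                 route_split: tuple[float, float, float] = (65 / 312, 65 / 312, 91 / 156),
                 seed: int = 0) -> SurveyDesign:
    """Place survey points on the landscape with a minimum spacing.

    ``route_split`` gives the (route A, route B, off-route) assignment
    probabilities; the default mirrors a design of 65 roadside-route
    points split over two routes plus 91 supplementary off-route points
    out of 156.  Route points get 3 occasions; off-route points get a
    uniform 1-3, matching single-season effort that varies off-route.
    """
    probs = np.asarray(route_split, dtype=float)
    if probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
        raise ValueError("route_split must be probabilities summing to 1")
    rng = np.random.default_rng(seed)
    anywhere = np.ones(landscape.shape, dtype=bool)
    rows, cols = _place_points(anywhere, n_sites,
                               min_spacing / landscape.cell_size, rng)
    draw = rng.choice(3, size=n_sites, p=probs)       # 0=A, 1=B, 2=off
    route = np.where(draw == 2, 0, draw + 1)
    n_occ = np.where(route > 0, 3, rng.integers(1, 4, size=n_sites))
    return SurveyDesign(rows=rows, cols=cols, route=route,
                        n_occasions=n_occ, min_spacing=min_spacing,
                        cell_size=landscape.cell_size)


def sample_metric_points(landscape: SyntheticLandscape, n_points: int = 248,
                         min_spacing: float = 200.0, seed: int = 0):
    """Sample a labelled metric table for classifier training.

    Points are restricted to the low-lying unburned area (the stratum in
    which the ghost-forest transition can occur), spaced to limit spatial
    dependence, with the later-epoch metric values as predictors and the
    biomass-change label as the response.  Returns a DataFrame with the
    seven metric columns of :data:`ghostbirds.rasters.METRIC_NAMES` plus
    a binary ``ghost`` column.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows, cols = _place_points(landscape.lowlying_mask, n_points,
                               min_spacing / landscape.cell_size, rng)
    labels = simulate_biomass_change(landscape)[rows, cols]
    data = {name: landscape.metrics_later[name][rows, cols]
            for name in METRIC_NAMES}
    data["ghost"] = labels.astype(int)
    return pd.DataFrame(data)


def simulate_community_dataset(hyper: CommunityHyper, n_species: int = 30,
                               n_sites: int = 150, n_occasions: int = 3,
                               burn_prob: float = 0.3,
                               route_split: tuple[float, float, float] = (0.2, 0.2, 0.6),
                               seed: int = 0,
                               ) -> tuple[CommunityParams, DetectionArray, SiteDesign]:
    """Simulate a community dataset directly at the model's level.

    Site covariates are drawn already standardized (standard normal
    midstory and canopy, Bernoulli burned flag), every site gets the full
    ``n_occasions``, and detection histories follow the model's
    generative law.  This bypasses the landscape layer for parameter
    recovery studies where only the model's own structure matters.
    """
    rng = np.random.default_rng(seed)
    probs = np.asarray(route_split, dtype=float)
    params = draw_community_params(hyper, n_species,
                                   seed=int(rng.integers(2 ** 31)))
    route = np.where((draw := rng.choice(3, size=n_sites, p=probs)) == 2,
                     0, draw + 1)
    site_design = SiteDesign(
        midstory=rng.standard_normal(n_sites),
        canopy=rng.standard_normal(n_sites),
        burned=(rng.random(n_sites) < burn_prob).astype(float),
        route=route,
        standardizers={"midstory_density": (0.0, 1.0),
                       "canopy_density": (0.0, 1.0)},
    )
    survey = SurveyDesign(rows=np.zeros(n_sites, dtype=int),
                          cols=np.arange(n_sites),
                          route=route,
                          n_occasions=np.full(n_sites, n_occasions),
                          min_spacing=0.0, cell_size=1.0)
    y = simulate_detections(params, survey, site_design,
                            seed=int(rng.integers(2 ** 31)))
    return params, y, site_design


def build_site_design(landscape: SyntheticLandscape, survey: SurveyDesign,
                      epoch: str = "later") -> SiteDesign:
    """Extract and standardize occupancy covariates at the survey points.

    Midstory and canopy density are read from the requested epoch
    (``later`` by default — surveys are contemporaneous with the later
    LiDAR acquisition), standardized over sites with the constants
    retained for raster prediction; the burned flag comes from the fire
    perimeter mask.
    """
    book = (landscape.metrics_later if epoch == "later"
            else landscape.metrics_baseline)
    mid_raw = book["midstory_density"][survey.rows, survey.cols]
    can_raw = book["canopy_density"][survey.rows, survey.cols]
    mid, m_mean, m_sd = standardize(mid_raw)
    can, c_mean, c_sd = standardize(can_raw)
    burned = landscape.burned_mask[survey.rows, survey.cols].astype(float)
    return SiteDesign(
        midstory=mid, canopy=can, burned=burned, route=survey.route,
        standardizers={"midstory_density": (m_mean, m_sd),
                       "canopy_density": (c_mean, c_sd)},
    )


def simulate_detections(params: CommunityParams, survey: SurveyDesign,
                        site_design: SiteDesign, seed: int = 0,
                        ) -> DetectionArray:
    """Simulate detection histories from the occupancy model's generative law.

    ``z[i, k] ~ Bernoulli(psi_ik)`` then, for each surveyed occasion,
    ``y[i, j, k] ~ Bernoulli(z[i, k] * p_ik)`` with route-specific
    detection; occasions beyond a site's effort are marked missing (-1).
    """
    rng = np.random.default_rng(seed)
    M, K = site_design.M, params.K
    J = int(survey.n_occasions.max())
    psi = 1.0 / (1.0 + np.exp(-(site_design.occupancy_matrix()
                                @ params.beta_matrix().T)))
    p = 1.0 / (1.0 + np.exp(-(site_design.route_matrix()
                              @ params.alpha_matrix().T)))
    z = (rng.random((M, K)) < psi).astype(np.int8)
    y = (rng.random((M, J, K)) < (z * p)[:, None, :]).astype(np.int8)
    occ = np.arange(J)[None, :, None] >= survey.n_occasions[:, None, None]
    y[np.broadcast_to(occ, y.shape)] = -1
    return DetectionArray(y=y)
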