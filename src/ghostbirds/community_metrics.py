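"""Species richness from latent states, richness regressions, PIF scores.

Site-level species richness is derived inside the MCMC: within each
retained draw the latent occupancy states are summed over species,
``S_i = sum_k z_ik``, giving a full posterior distribution of richness
per site that carries the occupancy model's detection correction and
uncertainty.  Richness (posterior median per site) is then related to
each vegetation metric by ordinary least squares, and the conservation
value of the species responding to the ghost-forest gradient is
summarized by group-averaged Partners-in-Flight (PIF) priority scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .occmodel import PosteriorSamples

__all__ = [
    "RichnessPosterior",
    "richness_posterior",
    "regress_richness",
    "group_pif_scores",
    "make_pif_table",
]


@dataclass
class RichnessPosterior:
    """Per-site posterior of species richness.

    ``draws`` is (n_draws_total, M) over pooled chains; summaries use the
    posterior median and the central 95% interval.
    """

    draws: np.ndarray
    n_species: int

    def __post_init__(self) -> None:
        if self.draws.min() < 0 or self.draws.max() > self.n_species:
            raise ValueError("richness draws must lie in [0, K]")

    @property
    def median(self) -> np.ndarray:
        return np.median(self.draws, axis=0)

    @property
    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def interval(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        tail = 100 * (1 - level) / 2
        lo, hi = np.percentile(self.draws, [tail, 100 - tail], axis=0)
        return lo, hi

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.interval()
        return pd.DataFrame({"median": self.median, "q2.5": lo, "q97.5": hi},
                            index=pd.RangeIndex(self.draws.shape[1], name="site"))


def richness_posterior(samples: PosteriorSamples | np.ndarray) -> RichnessPosterior:
    """Sum latent occupancy states over species within each MCMC draw.

    Accepts either posterior samples with stored z draws or a raw z array
    of shape (..., M, K); leading axes are pooled.
    """
    if isinstance(samples, PosteriorSamples):
        if samples.z is None:
            raise ValueError("posterior was sampled with store_z=False")
        z = samples.z
    else:
        z = np.asarray(samples)
    K = z.shape[-1]
    S = z.sum(axis=-1, dtype=int)
    return RichnessPosterior(draws=S.reshape(-1, S.shape[-1]), n_species=K)


def regress_richness(medians, metric) -> dict:
    """OLS of per-site richness on one vegetation metric.

    Returns slope, intercept and the two-sided t-test p-value on the
    slope.  A constant covariate is degenerate and raises.
    """
    x = np.asarray(metric, dtype=float)
    y = np.asarray(medians, dtype=float)
    if x.std() == 0:
        raise ValueError("constant covariate: regression undefined")
    res = stats.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "p_value": float(res.pvalue), "r": float(res.rvalue)}


def make_pif_table(species_names: list[str], seed: int = 0,
                   low: int = 4, high: int = 14) -> pd.Series:
    """Synthetic conservation-priority scores, uniform integers in [low, high].

    Stands in for the expert-derived PIF score table of a real species
    list (the observed scores in comparable communities span roughly this
    range); scores are positive integers indexed by species label.
    """
    rng = np.random.default_rng(seed)
    scores = rng.integers(low, high + 1, size=len(species_names))
    return pd.Series(scores, index=pd.Index(species_names, name="species"),
                     name="pif_score")


def group_pif_scores(classification: pd.DataFrame, pif: pd.Series,
                     covariates: tuple[str, ...] = ("beta_mid", "beta_can"),
                     ) -> dict:
    """Average priority score of ghost- vs unaffected-associated species.

    The ghost-associated group holds species with at least one strongly
    supported *negative* vegetation-density effect (they favour the
    reduced midstory/canopy of ghost forest); the unaffected group holds
    those with at least one strongly supported positive effect.  A
    species with opposite strong effects appears in both groups.  Empty
    groups yield NaN means.
    """
    sub = classification[classification["slot"].isin(covariates)]
    strong = sub[sub["strong"]]
    ghost_species = sorted(set(strong.loc[strong["mean"] < 0, "species"]))
    unaff_species = sorted(set(strong.loc[strong["mean"] > 0, "species"]))

    def mean_score(group):
        return float(pif.loc[group].mean()) if group else float("nan")

    return {
        "ghost_species": ghost_species,
        "unaffected_species": unaff_species,
        "ghost_mean_score": mean_score(ghost_species),
        "unaffected_mean_score": mean_score(unaff_species),
    }
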