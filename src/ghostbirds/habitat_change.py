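"""Decadal habitat loss/gain accounting from two-epoch occupancy surfaces.

For each species, occupancy probability is predicted over the whole
covariate raster for both epochs using the survey-site coefficient
estimates (posterior means by default) and the survey-site
standardization constants, the two surfaces are differenced
(delta-psi = later - baseline), and the difference is thresholded at
+-0.3: cells with delta-psi < -0.3 count as habitat loss, cells with
delta-psi > 0.3 as habitat gain (strict inequalities; the threshold makes
the accounting conservative against estimation noise).  Cell counts are
converted to hectares (a 48-m cell is 0.2304 ha) and totalled within
spatial strata — the whole area, the burned perimeter, and unburned
low-lying forest — to separate fire-driven from saltwater-driven change.

The burned covariate is held at its observed status in both epoch
predictions, so delta-psi isolates vegetation-structure change rather
than re-counting the fire effect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .occmodel import PosteriorSamples, summarize_posterior
from .rasters import CovariateRaster, SyntheticLandscape, aggregate_mask, aggregate_raster

__all__ = [
    "predict_occupancy",
    "delta_psi",
    "classify_change",
    "summarize_area",
    "stratified_change",
    "species_coefficients",
]

CELL_AREA_HA_48M = 0.2304  # 48 m x 48 m


def predict_occupancy(raster: CovariateRaster, coefficients,
                      standardizers: dict[str, tuple[float, float]],
                      ) -> np.ndarray:
    """Per-cell occupancy probability for one species.

    ``coefficients`` is (beta0, beta_mid, beta_can, beta_burn); densities
    are standardized with the survey-site constants before applying the
    logit-linear predictor.  Invalid cells are NaN.
    """
    b0, b_mid, b_can, b_burn = np.asarray(coefficients, dtype=float)
    try:
        m_mean, m_sd = standardizers["midstory_density"]
        c_mean, c_sd = standardizers["canopy_density"]
    except (KeyError, TypeError) as err:
        raise ValueError("standardizers must provide (mean, sd) for "
                         "midstory_density and canopy_density") from err
    mid = (raster.midstory - m_mean) / m_sd
    can = (raster.canopy - c_mean) / c_sd
    eta = b0 + b_mid * mid + b_can * can + b_burn * raster.burned
    psi = expit(eta)
    return np.where(raster.valid, psi, np.nan)


def delta_psi(psi_early: np.ndarray, psi_late: np.ndarray) -> np.ndarray:
    """Change in occupancy probability, later minus earlier epoch."""
    if psi_early.shape != psi_late.shape:
        raise ValueError("epoch grids must share a shape")
    return psi_late - psi_early


def classify_change(delta: np.ndarray, threshold: float = 0.3) -> np.ndarray:
    """Categorize each cell as loss (-1), gain (+1) or neither (0).

    Loss requires delta < -threshold and gain delta > +threshold, both
    strict, so a change of exactly -0.3 is *not* a loss.  NaN cells map
    to 0.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    out = np.zeros(delta.shape, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        out[delta < -threshold] = -1
        out[delta > threshold] = 1
    return out


def summarize_area(change: np.ndarray, mask: np.ndarray,
                   cell_area_ha: float = CELL_AREA_HA_48M) -> dict:
    """Loss/gain/net hectares of a change map inside one stratum mask."""
    if mask.shape != change.shape:
        raise ValueError("stratum mask must be on the change grid")
    sub = change[mask]
    loss = float((sub == -1).sum() * cell_area_ha)
    gain = float((sub == 1).sum() * cell_area_ha)
    return {"loss_ha": loss, "gain_ha": gain, "net_ha": gain - loss}


def species_coefficients(samples_or_summary) -> pd.DataFrame:
    """Posterior-mean occupancy coefficients per species.

    Accepts :class:`PosteriorSamples` or an existing summary frame;
    returns a (species x 4) frame with columns beta0, beta_mid, beta_can,
    beta_burn.
    """
    summary = (summarize_posterior(samples_or_summary)
               if isinstance(samples_or_summary, PosteriorSamples)
               else samples_or_summary)
    rows: dict[str, dict[str, float]] = {}
    for name in summary.index:
        if "[" not in name:
            continue
        slot, label = name[:-1].split("[", 1)
        if slot in ("beta0", "beta_mid", "beta_can", "beta_burn"):
            rows.setdefault(label, {})[slot] = float(summary.loc[name, "mean"])
    frame = pd.DataFrame(rows).T[["beta0", "beta_mid", "beta_can", "beta_burn"]]
    frame.index.name = "species"
    return frame


def stratified_change(landscape: SyntheticLandscape,
                      coefficients: pd.DataFrame,
                      standardizers: dict[str, tuple[float, float]],
                      factor: int = 4,
                      threshold: float = 0.3,
                      extra_strata: dict[str, np.ndarray] | None = None,
                      ) -> pd.DataFrame:
    """Per-species habitat-change table over the standard spatial strata.

    Both epochs are aggregated to the coarse grid (48 m for the default
    factor of 4 on 12-m cells), occupancy is predicted per species with
    its posterior-mean coefficients, delta-psi is thresholded, and
    hectares are totalled within: the whole area, the burned perimeter,
    the unburned low-lying stratum, and any ``extra_strata`` masks given
    on the fine grid (e.g. the ghost-transition stratum).
    """
    early = aggregate_raster(landscape.covariate_raster("baseline"), factor)
    late = aggregate_raster(landscape.covariate_raster("later"), factor)
    strata = {
        "whole_area": np.ones(early.shape, dtype=bool) & early.valid,
        "burned": aggregate_mask(landscape.burned_mask, factor) & early.valid,
        "lowlying_unburned": aggregate_mask(landscape.lowlying_mask, factor)
        & early.valid,
    }
    for name, mask in (extra_strata or {}).items():
        strata[name] = aggregate_mask(mask, factor) & early.valid
    cell_area = late.cell_area_ha
    records = []
    for species, row in coefficients.iterrows():
        coefs = row[["beta0", "beta_mid", "beta_can", "beta_burn"]].to_numpy()
        psi_early = predict_occupancy(early, coefs, standardizers)
        psi_late = predict_occupancy(late, coefs, standardizers)
        change = classify_change(delta_psi(psi_early, psi_late), threshold)
        for stratum, mask in strata.items():
            area = summarize_area(change, mask, cell_area)
            records.append({"species": species, "stratum": stratum, **area})
    return pd.DataFrame(records).set_index(["species", "stratum"])
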