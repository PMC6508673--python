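"""Gridded vegetation-structure containers and resolution changes.

Vegetation structure is carried on a square grid of cells (12 m edge by
default, matching the resolution at which LiDAR return fractions are
typically binned).  Two containers live here:

``CovariateRaster``
    the pair of occupancy covariates (midstory density 4.5-10 m, canopy
    density 20-30 m) plus a burned flag and a validity mask for one epoch.

``SyntheticLandscape``
    a full two-epoch landscape: all seven structure metrics per epoch,
    the ghost-transition / burned / low-lying masks, and the cell size.

Occupancy prediction over large extents is done at a coarser resolution
(48 m cells, i.e. an aggregation factor of 4) for speed; ``aggregate_raster``
implements the block-mean / majority-vote downsampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Names of the seven vegetation-structure metrics, in canonical order.
METRIC_NAMES = (
    "mean_height",
    "max_height",
    "sd_height",
    "midstory_density",   # vegetation density 4.5-10 m
    "lower_canopy_density",  # 10-20 m
    "canopy_density",     # 20-30 m
    "total_density",
)

DENSITY_METRICS = (
    "midstory_density",
    "lower_canopy_density",
    "canopy_density",
    "total_density",
)

#: Mid-height (m) of each density layer, used by the biomass proxy.
LAYER_MID_HEIGHTS = {
    "midstory_density": 7.25,
    "lower_canopy_density": 15.0,
    "canopy_density": 25.0,
}


@dataclass
class CovariateRaster:
    """Occupancy covariates for one epoch on a square-cell grid."""

    midstory: np.ndarray
    canopy: np.ndarray
    burned: np.ndarray
    valid: np.ndarray
    cell_size: float
    epoch: str = ""

    def __post_init__(self) -> None:
        self.midstory = np.asarray(self.midstory, dtype=float)
        self.canopy = np.asarray(self.canopy, dtype=float)
        self.burned = np.asarray(self.burned, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        shapes = {self.midstory.shape, self.canopy.shape,
                  self.burned.shape, self.valid.shape}
        if len(shapes) != 1:
            raise ValueError("all raster layers must share one grid shape")
        if self.cell_size <= 0:
            raise ValueError("cell edge length must be positive")
        ok = self.valid
        for name, arr in (("midstory", self.midstory), ("canopy", self.canopy)):
            vals = arr[ok]
            if vals.size and (np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 1 + 1e-9):
                raise ValueError(f"{name} density outside [0, 1] on valid cells")

    @property
    def shape(self) -> tuple[int, int]:
        return self.midstory.shape

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size ** 2 / 10_000.0


@dataclass
class SyntheticLandscape:
    """Two-epoch metric surfaces plus the spatial strata of the study design.

    ``metrics_baseline`` / ``metrics_later`` map each metric name to a 2-D
    array.  ``ghost_mask`` marks cells whose midstory and canopy densities
    were reduced between epochs (the ghost-forest transition); it is a
    subset of ``lowlying_mask``, which itself excludes burned cells.
    """

    metrics_baseline: dict[str, np.ndarray]
    metrics_later: dict[str, np.ndarray]
    ghost_mask: np.ndarray
    burned_mask: np.ndarray
    lowlying_mask: np.ndarray
    cell_size: float = 12.0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = self.shape
        for book in (self.metrics_baseline, self.metrics_later):
            missing = set(METRIC_NAMES) - set(book)
            if missing:
                raise ValueError(f"missing metric surfaces: {sorted(missing)}")
            for name in METRIC_NAMES:
                if book[name].shape != shape:
                    raise ValueError("metric surfaces must share one grid shape")
        for name in ("ghost_mask", "burned_mask", "lowlying_mask"):
            m = getattr(self, name)
            if m.shape != shape or m.dtype != bool:
                raise ValueError(f"{name} must be a boolean array of shape {shape}")
        if np.any(self.ghost_mask & ~self.lowlying_mask):
            raise ValueError("ghost-transition cells must lie inside the "
                             "low-lying unburned mask")
        if np.any(self.lowlying_mask & self.burned_mask):
            raise ValueError("low-lying mask must exclude burned cells")

    @property
    def shape(self) -> tuple[int, int]:
        return self.metrics_baseline["midstory_density"].shape

    @property
    def extent_m(self) -> tuple[float, float]:
        return (self.shape[0] * self.cell_size, self.shape[1] * self.cell_size)

    def covariate_raster(self, epoch: str) -> CovariateRaster:
        """Extract the two occupancy covariates for ``epoch``.

        The burned flag is the observed 2001-2014 burn status in both
        epochs, so that occupancy change isolates vegetation-structure
        change rather than re-attributing the fire effect.
        """
        if epoch == "baseline":
            book = self.metrics_baseline
        elif epoch == "later":
            book = self.metrics_later
        else:
            raise ValueError("epoch must be 'baseline' or 'later'")
        return CovariateRaster(
            midstory=book["midstory_density"],
            canopy=book["canopy_density"],
            burned=self.burned_mask,
            valid=np.ones(self.shape, dtype=bool),
            cell_size=self.cell_size,
            epoch=epoch,
        )


def _pad_to_multiple(arr: np.ndarray, factor: int, fill) -> np.ndarray:
    h, w = arr.shape
    ph = (-h) % factor
    pw = (-w) % factor
    if ph == 0 and pw == 0:
        return arr
    return np.pad(arr, ((0, ph), (0, pw)), constant_values=fill)


def _block_view(arr: np.ndarray, factor: int) -> np.ndarray:
    h, w = arr.shape
    return arr.reshape(h // factor, factor, w // factor, factor).swapaxes(1, 2)


def block_reduce_mean(arr: np.ndarray, valid: np.ndarray, factor: int) -> tuple[np.ndarray, np.ndarray]:
    """Block mean of ``arr`` over valid cells; returns (means, n_valid).

    Blocks with no valid cell get NaN.
    """
    a = _pad_to_multiple(np.where(valid, arr, 0.0), factor, 0.0)
    v = _pad_to_multiple(valid.astype(float), factor, 0.0)
    n = _block_view(v, factor).sum(axis=(2, 3))
    s = _block_view(a, factor).sum(axis=(2, 3))
    with np.errstate(invalid="ignore"):
        means = np.where(n > 0, s / np.maximum(n, 1), np.nan)
    return means, n


def aggregate_raster(fine: CovariateRaster, factor: int) -> CovariateRaster:
    """Downsample a covariate raster by an integer ``factor``.

    Densities are block-averaged over valid fine cells; the burned flag is
    the majority vote within the block; a coarse cell is valid when at
    least half of its fine cells are valid (edge blocks created by padding
    are handled through the validity mask).  The cell edge length scales by
    ``factor``, so a factor of 4 on a 12-m grid yields 48-m cells of
    0.2304 ha.
    """
    if factor < 1:
        raise ValueError("aggregation factor must be >= 1")
    if factor == 1:
        return fine
    mid, n = block_reduce_mean(fine.midstory, fine.valid, factor)
    can, _ = block_reduce_mean(fine.canopy, fine.valid, factor)
    burn_frac, _ = block_reduce_mean(fine.burned.astype(float), fine.valid, factor)
    valid = n >= (factor * factor) / 2.0
    burned = np.where(valid, burn_frac > 0.5, False)
    # block means of in-range densities stay in range; clip guards rounding
    mid = np.where(valid, np.clip(mid, 0.0, 1.0), np.nan)
    can = np.where(valid, np.clip(can, 0.0, 1.0), np.nan)
    return CovariateRaster(
        midstory=mid,
        canopy=can,
        burned=burned,
        valid=valid,
        cell_size=fine.cell_size * factor,
        epoch=fine.epoch,
    )


def aggregate_mask(mask: np.ndarray, factor: int, rule: str = "majority") -> np.ndarray:
    """Downsample a boolean stratum mask by block majority (or ``any``)."""
    m = _pad_to_multiple(mask.astype(float), factor, 0.0)
    frac = _block_view(m, factor).mean(axis=(2, 3))
    if rule == "majority":
        return frac > 0.5
    if rule == "any":
        return frac > 0
    raise ValueError("rule must be 'majority' or 'any'")
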