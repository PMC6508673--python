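"""File interchange: rasters as GeoTIFF, histories as CSV, configs as YAML.

Landscapes are written as a single multi-band GeoTIFF (one band per
metric per epoch, then the three stratum masks) with a JSON sidecar
naming the bands and recording the cell size and generator parameters.
Detection histories travel as long-format CSV
(site_id, occasion, species_id, detected) with missing occasions simply
absent.  Posterior draws are stored as a compressed .npz with a JSON
manifest of parameter names and sampler settings.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .occmodel import DetectionArray, PosteriorSamples, SamplerConfig
from .rasters import METRIC_NAMES, SyntheticLandscape
from .synthdata import CommunityHyper

__all__ = [
    "save_landscape", "load_landscape",
    "detections_to_csv", "detections_from_csv",
    "save_posterior", "load_posterior",
    "load_hyper_yaml", "save_hyper_yaml",
]

_MASKS = ("ghost_mask", "burned_mask", "lowlying_mask")


def save_landscape(landscape: SyntheticLandscape, path: str | Path) -> None:
    """Write a landscape as multi-band GeoTIFF + JSON sidecar."""
    path = Path(path)
    bands, names = [], []
    for epoch, book in (("baseline", landscape.metrics_baseline),
                        ("later", landscape.metrics_later)):
        for metric in METRIC_NAMES:
            bands.append(book[metric].astype(np.float32))
            names.append(f"{epoch}:{metric}")
    for mask in _MASKS:
        bands.append(getattr(landscape, mask).astype(np.float32))
        names.append(mask)
    tifffile.imwrite(path, np.stack(bands), photometric="minisblack")
    sidecar = {
        "bands": names,
        "cell_size_m": landscape.cell_size,
        "params": landscape.params,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_landscape(path: str | Path) -> SyntheticLandscape:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    stack = tifffile.imread(path)
    layers = dict(zip(sidecar["bands"], stack))
    books = {"baseline": {}, "later": {}}
    for name, arr in layers.items():
        if ":" in name:
            epoch, metric = name.split(":", 1)
            books[epoch][metric] = arr.astype(float)
    return SyntheticLandscape(
        metrics_baseline=books["baseline"],
        metrics_later=books["later"],
        ghost_mask=layers["ghost_mask"].astype(bool),
        burned_mask=layers["burned_mask"].astype(bool),
        lowlying_mask=layers["lowlying_mask"].astype(bool),
        cell_size=sidecar["cell_size_m"],
        params=sidecar.get("params", {}),
    )


def detections_to_csv(y: DetectionArray, path: str | Path) -> None:
    """Long-format detection CSV; missing occasions are omitted rows."""
    M, J, K = y.y.shape
    site, occ, spp = np.meshgrid(np.arange(M), np.arange(J), np.arange(K),
                                 indexing="ij")
    flat = y.y.ravel()
    keep = flat != -1
    frame = pd.DataFrame({
        "site_id": site.ravel()[keep],
        "occasion": occ.ravel()[keep],
        "species_id": spp.ravel()[keep],
        "detected": flat[keep],
    })
    frame.to_csv(path, index=False)


def detections_from_csv(path: str | Path) -> DetectionArray:
    frame = pd.read_csv(path)
    M = frame["site_id"].max() + 1
    J = frame["occasion"].max() + 1
    K = frame["species_id"].max() + 1
    y = np.full((M, J, K), -1, dtype=np.int8)
    y[frame["site_id"], frame["occasion"], frame["species_id"]] = frame["detected"]
    return DetectionArray(y=y)


def save_posterior(samples: PosteriorSamples, path: str | Path) -> None:
    """Posterior draws as compressed npz + JSON manifest alongside."""
    path = Path(path)
    arrays = {"draws": samples.draws}
    if samples.z is not None:
        arrays["z"] = samples.z
    np.savez_compressed(path, **arrays)
    manifest = {
        "param_names": samples.param_names,
        "species_names": samples.species_names,
        "seed": samples.seed,
        "acceptance": samples.acceptance,
        "config": {k: getattr(samples.config, k) for k in
                   ("chains", "iterations", "burn_in", "thin",
                    "hyper_mean_var", "hyper_sd_scale", "hierarchical")},
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_posterior(path: str | Path) -> PosteriorSamples:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path) as data:
        draws = data["draws"]
        z = data["z"] if "z" in data.files else None
    return PosteriorSamples(
        draws=draws,
        param_names=manifest["param_names"],
        z=z,
        config=SamplerConfig(**manifest["config"]),
        seed=manifest["seed"],
        species_names=manifest["species_names"],
        acceptance=manifest.get("acceptance", {}),
    )


def save_hyper_yaml(hyper: CommunityHyper, path: str | Path) -> None:
    payload = {fam: list(map(float, pair))
               for fam, pair in hyper.as_dict().items()}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def load_hyper_yaml(path: str | Path) -> CommunityHyper:
    payload = yaml.safe_load(Path(path).read_text())
    return CommunityHyper(**{fam: tuple(pair) for fam, pair in payload.items()})
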