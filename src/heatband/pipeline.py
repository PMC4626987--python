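"""End-to-end orchestration: synth -> bias-correct -> ATmax -> counts ->
time slices -> trends, with a run manifest for reproducibility.

Every stage persists NetCDF under the output directory; the manifest records
the configuration hash, seed, package version and a SHA-256 checksum of each
output variable's raw bytes, so two runs with the same config and seed can be
verified byte-identical without re-reading the science.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import __version__
from .apparent import daily_atmax
from .bias import bias_correct_member
from .config import PipelineConfig
from .heatdays import (
    DEFAULT_SCHEME,
    annual_counts,
    change_map,
    ensemble_mean,
    timeslice_mean,
)
from .io import read_netcdf, write_netcdf
from .synth import generate_ensemble, generate_reference_climatology
from .trends import ensemble_percentiles, trend_map

logger = logging.getLogger(__name__)


def _var_checksums(ds: xr.Dataset) -> dict[str, str]:
    return {
        name: hashlib.sha256(np.ascontiguousarray(ds[name].values).tobytes()).hexdigest()
        for name in sorted(ds.data_vars)
    }


def extract_city_series(
    counts: xr.Dataset, points: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Nearest-cell annual series for named points.

    ``points`` needs columns city, lat, lon. Points outside the grid's
    bounding box are excluded (listed in the returned report) and the run
    continues. Equidistant points tie-break toward the lower cell index.

    Returns a tidy frame (city, year, category, count) and the exclusion list.
    """
    lat = counts["lat"].values
    lon = counts["lon"].values
    half_dlat = np.diff(lat).max() / 2 if lat.size > 1 else np.inf
    half_dlon = np.diff(lon).max() / 2 if lon.size > 1 else np.inf
    rows = []
    excluded: list[str] = []
    for rec in points.itertuples(index=False):
        if not (lat.min() - half_dlat <= rec.lat <= lat.max() + half_dlat) or not (
            lon.min() - half_dlon <= rec.lon <= lon.max() + half_dlon
        ):
            excluded.append(rec.city)
            continue
        # argmin returns the first minimum -> lower index on ties
        i = int(np.argmin(np.abs(lat - rec.lat)))
        j = int(np.argmin(np.abs(lon - rec.lon)))
        cell = counts.isel(lat=i, lon=j)
        for cat in counts.data_vars:
            for year, val in zip(cell["year"].values, cell[cat].values):
                rows.append((rec.city, int(year), cat, int(val)))
    if excluded:
        logger.warning("points outside grid excluded: %s", excluded)
    return pd.DataFrame(rows, columns=["city", "year", "category", "count"]), excluded


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the configured stages; returns (and writes) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.synth.seed,
        "version": __version__,
        "stages": [],
        "outputs": {},
    }

    def record(stage: str, path: Path, ds: xr.Dataset) -> None:
        manifest["outputs"][str(path.relative_to(outdir))] = _var_checksums(ds)
        if stage not in manifest["stages"]:
            manifest["stages"].append(stage)

    stages = config.stages
    members: dict[str, xr.Dataset] = {}
    reference = None

    if "synth" in stages:
        logger.info("stage synth: %d members, %d-%d, %dx%d grid",
                    config.synth.n_members, config.synth.year_start,
                    config.synth.year_end, config.synth.n_lat, config.synth.n_lon)
        ensemble = generate_ensemble(config.synth)
        reference = generate_reference_climatology(config.synth)
        write_netcdf(reference, outdir / "reference_climatology.nc")
        record("synth", outdir / "reference_climatology.nc", reference)
        for name, ds in ensemble:
            path = outdir / f"{name}.nc"
            write_netcdf(ds, path)
            record("synth", path, ds)
            members[name] = ds

    if "bias" in stages:
        if reference is None:
            reference = read_netcdf(outdir / "reference_climatology.nc")
        corrected = {}
        for name, ds in members.items():
            bc = bias_correct_member(ds, reference, config.baseline)
            path = outdir / f"{name}_bc.nc"
            write_netcdf(bc, path)
            record("bias", path, bc)
            corrected[name] = bc
        members = corrected

    atmax: dict[str, xr.DataArray] = {}
    if "atmax" in stages:
        for name, ds in members.items():
            at = daily_atmax(ds["tmax"], ds["rh"], ds["wind"])
            path = outdir / f"{name}_atmax.nc"
            write_netcdf(at, path)
            record("atmax", path, at.to_dataset())
            atmax[name] = at

    counts: dict[str, xr.Dataset] = {}
    if "counts" in stages:
        for name, at in atmax.items():
            c = annual_counts(at, DEFAULT_SCHEME)
            path = outdir / f"{name}_counts.nc"
            write_netcdf(c, path)
            record("counts", path, c)
            counts[name] = c

    if "slices" in stages and counts:
        member_baselines = [timeslice_mean(c, config.baseline) for c in counts.values()]
        base = ensemble_mean(member_baselines)
        path = outdir / "slice_baseline.nc"
        write_netcdf(base, path)
        record("slices", path, base)
        for y0, y1 in config.slices:
            fut = ensemble_mean([timeslice_mean(c, (y0, y1)) for c in counts.values()])
            delta = change_map(fut, base)
            for tag, ds in (("mean", fut), ("change", delta)):
                path = outdir / f"slice_{y0}_{y1}_{tag}.nc"
                write_netcdf(ds, path)
                record("slices", path, ds)

    if "trends" in stages and counts:
        stacked = {
            cat: xr.concat([c[cat] for c in counts.values()], dim="member")
            for cat in config.trend_categories
        }
        for cat, arr in stacked.items():
            env = ensemble_percentiles(arr)
            write_netcdf(env, outdir / f"envelope_{cat}.nc")
            record("trends", outdir / f"envelope_{cat}.nc", env)
            median = env["median"]
            tm = trend_map(
                median,
                window=config.window,
                n_iter=config.n_iter,
                seed=config.seed,
                denominator=config.denominator,
                alternative=config.alternative,
            )
            path = outdir / f"trend_{cat}.nc"
            write_netcdf(tm, path)
            record("trends", path, tm)

        if config.cities and counts:
            points = pd.read_csv(config.cities)
            median_counts = xr.Dataset(
                {
                    cat: xr.concat([c[cat] for c in counts.values()], dim="member").median("member")
                    for cat in counts[next(iter(counts))].data_vars
                }
            )
            series, excluded = extract_city_series(median_counts, points)
            series.to_csv(outdir / "city_series.csv", index=False)
            manifest["excluded_cities"] = excluded

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
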