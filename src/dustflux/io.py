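"""File formats, configuration and pipeline orchestration.

Gridded products travel as NetCDF (classic format via scipy), series
and tables as CSV, reports as JSON, configuration as YAML.  Every file
written here embeds the package version and a hash of the run
configuration for provenance.  All numerics live in the stage modules;
this module only wires them together.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import __version__
from . import deposition as dep
from . import flux as fx
from . import regional as rg
from . import retrieval as rt
from . import sensitivity as sens
from . import synthetic as syn
from . import trends
from .grids import GridDef

log = logging.getLogger("dustflux")

GRANULE_VARS = ("backscatter_532", "pdr", "cad_score", "lat", "lon", "time")

_CONFIG_KEYS = {
    "seed",
    "out_dir",
    "log_level",
    "grid",
    "retrieval",
    "flux",
    "granule",
    "series",
    "regions",
    "transects",
    "seasons",
    "dmee_sweep_values",
    "lidar_ratio_sweep_values",
}


@dataclass
class PipelineConfig:
    """Validated end-to-end run configuration with documented defaults."""

    seed: int = 0
    out_dir: str = "dustflux_out"
    log_level: str = "INFO"
    grid: GridDef = field(default_factory=GridDef)
    retrieval: rt.RetrievalParams = field(default_factory=rt.RetrievalParams)
    flux: fx.FluxParams = field(default_factory=fx.FluxParams)
    granule: dict = field(default_factory=dict)
    series: dict = field(default_factory=dict)
    dmee_sweep_values: tuple = (0.37, 0.5)
    lidar_ratio_sweep_values: tuple = (30.0, 60.0)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        kw = dict(raw)
        if "grid" in kw:
            g = dict(kw["grid"])
            if "alt_edges" in g:
                g["alt_edges"] = tuple(g["alt_edges"])
            kw["grid"] = GridDef(**g)
        if "retrieval" in kw:
            r = dict(kw["retrieval"])
            if "cad_window" in r:
                r["cad_window"] = tuple(r["cad_window"])
            kw["retrieval"] = rt.RetrievalParams(**r)
        if "flux" in kw:
            kw["flux"] = fx.FluxParams(**kw["flux"])
        kw.pop("regions", None)
        kw.pop("transects", None)
        kw.pop("seasons", None)
        return cls(**kw)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "seed": self.seed,
                "grid": asdict(self.grid),
                "retrieval": asdict(self.retrieval),
                "flux": asdict(self.flux),
                "granule": self.granule,
                "series": self.series,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stamp(ds: xr.Dataset, config: PipelineConfig | None) -> xr.Dataset:
    ds.attrs["dustflux_version"] = __version__
    if config is not None:
        ds.attrs["config_hash"] = config.config_hash()
    return ds


def write_netcdf(ds: xr.Dataset, path, config: PipelineConfig | None = None) -> None:
    ds = _stamp(ds.copy(), config)
    clean = ds.copy()
    for name, var in ds.variables.items():
        if var.dtype == bool:
            clean[name] = var.astype("int8")
    clean.to_netcdf(path, engine="scipy")


def read_netcdf(path) -> xr.Dataset:
    return xr.open_dataset(path, engine="scipy").load()


def write_granule(granule: xr.Dataset, path, fmt: str = "netcdf") -> None:
    """Write a granule as NetCDF or long-format CSV."""
    path = Path(path)
    if fmt == "netcdf":
        g = granule.copy()
        g["time"] = ("profile", granule["time"].values.astype("datetime64[M]").astype(str))
        write_netcdf(g, path)
    elif fmt == "csv":
        df = (
            granule[["backscatter_532", "pdr", "cad_score"]]
            .to_dataframe()
            .reset_index()
        )
        meta = granule[["lat", "lon"]].to_dataframe().reset_index()
        df = df.merge(meta, on="profile")
        df["time"] = granule.attrs.get("month", "")
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown granule format {fmt!r}")


def read_granules(path) -> xr.Dataset:
    """Read a granule file (NetCDF or CSV) and validate its schema.

    Missing mandatory variables raise with the variable named.
    """
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path)
        needed = {"profile", "level", "backscatter_532", "pdr", "cad_score", "lat", "lon"}
        missing = needed - set(df.columns)
        if missing:
            raise ValueError(f"granule CSV missing columns: {sorted(missing)}")
        wide = df.set_index(["profile", "level"])
        ds = xr.Dataset(
            {
                v: (("profile", "level"), wide[v].unstack().values)
                for v in ("backscatter_532", "pdr", "cad_score")
            },
            coords={"level": np.sort(df["level"].unique())},
        )
        per_prof = df.groupby("profile").first()
        ds["lat"] = ("profile", per_prof["lat"].values)
        ds["lon"] = ("profile", per_prof["lon"].values)
        tcol = per_prof["time"] if "time" in per_prof else pd.Series([""] * len(per_prof))
        ds["time"] = ("profile", np.asarray(tcol.astype(str).values, dtype="datetime64[M]"))
        ds.attrs["month"] = str(tcol.iloc[0]) if len(tcol) else ""
        return ds
    ds = read_netcdf(path)
    missing = [v for v in GRANULE_VARS if v not in ds]
    if missing:
        raise ValueError(f"granule file missing variables: {missing}")
    ds["time"] = ("profile", np.asarray(ds["time"].values, dtype="datetime64[M]"))
    return ds


def write_series(series: pd.DataFrame, path) -> None:
    series.to_csv(path, index=False)


def read_series(path) -> pd.DataFrame:
    return pd.read_csv(path)


# -- pipeline ---------------------------------------------------------------


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate -> retrieve -> flux -> deposit -> stats -> sweeps.

    Synthetic granules, winds and regional series are generated from
    the config seed; each stage's outputs are written under
    ``config.out_dir`` and the bundle of in-memory results is returned.
    Stage failures propagate with the stage name prefixed.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    log.info("run_pipeline: seed=%d hash=%s", config.seed, config.config_hash())

    def stage(name, fn):
        log.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    def _simulate():
        gspec = syn.GranuleSpec(seed=config.seed, **config.granule)
        granule = syn.make_granule(gspec)
        winds = syn.make_winds(config.grid, u0=5.0)
        sspec = syn.SeriesSpec(seed=config.seed + 1, **config.series)
        series = syn.make_series(sspec)
        write_granule(granule, out / "granule.nc")
        write_netcdf(winds, out / "winds.nc", config)
        write_series(series, out / "series.csv")
        return granule, winds, series

    granule, winds, series = stage("simulate", _simulate)
    bundle["granule"], bundle["winds"], bundle["series"] = granule, winds, series

    def _retrieve():
        screened, report = rt.screen(granule, config.retrieval)
        grid_ds = rt.grid_monthly(screened, config.grid, config.retrieval)
        write_netcdf(grid_ds, out / "dust_grid.nc", config)
        return grid_ds, report

    dust_grid, screen_report = stage("retrieve", _retrieve)
    bundle["dust_grid"], bundle["screen_report"] = dust_grid, screen_report

    def _flux():
        ff = fx.flux_profiles(dust_grid, winds, config.flux)
        write_netcdf(ff, out / "flux.nc", config)
        return ff

    flux_field = stage("flux", _flux)
    bundle["flux_field"] = flux_field

    def _deposit():
        d = dep.divergence_deposition(flux_field, grid=config.grid)
        write_netcdf(d, out / "deposition.nc", config)
        return d

    deposition_field = stage("deposit", _deposit)
    bundle["deposition"] = deposition_field

    def _stats():
        wide = series.pivot_table(index="year", columns="variable", values="value")
        res = {
            var: trends.trend_test(wide.index.values, wide[var].values)
            for var in wide.columns
        }
        regional = series.assign(region="ALL")
        report = rg.region_report(regional)
        (out / "region_report.json").write_text(
            json.dumps(report, default=_jsonify, indent=2)
        )
        return {"trends": res, "region_report": report}

    bundle["stats"] = stage("stats", _stats)

    def _sensitivity():
        dm = sens.dmee_sweep(dust_grid, winds, config.dmee_sweep_values, grid=config.grid)
        lr = sens.lidar_ratio_sweep(
            granule, config.lidar_ratio_sweep_values, config.grid, config.retrieval
        )
        (out / "sensitivity.json").write_text(
            json.dumps({"dmee": dm.__dict__, "lidar_ratio": lr.__dict__},
                       default=_jsonify, indent=2)
        )
        return {"dmee": dm, "lidar_ratio": lr}

    bundle["sensitivity"] = stage("sensitivity", _sensitivity)
    return bundle


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if hasattr(obj, "__dict__"):
        return obj.__dict__
    return str(obj)
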