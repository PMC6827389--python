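"""Raster and tabular I/O for multi-year outbreak landscapes.

A landscape series bundles the time-invariant layers (potential-host map,
long-term mean annual temperature) with the annual binary attack maps and
the regional disturbed-timber volume series that drives the outbreak-stage
covariate.

Supported raster dialects: single-band TIFF (via tifffile) and ESRI ASCII
grid (``.asc``/``.txt``). Grids are handled row-major with 0-based
(row, col) indexing; any georeferencing found in the file headers is kept
as opaque metadata and written back verbatim where the format allows.
NODATA cells in the host map are treated as non-host; NODATA temperature
is tolerated off-host.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "LandscapeSeries",
    "read_raster",
    "write_raster",
    "read_landscape",
    "write_probability_map",
    "read_probability_map",
    "write_landscape",
]

PROB_NODATA = -1.0  # sentinel for cells without a prediction

_ASC_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


class AlignmentError(ValueError):
    """Grid shapes or georeferencing do not match across layers."""


class SequenceError(ValueError):
    """Attack-map years are not consecutive or do not match the map count."""


class CoverageError(ValueError):
    """The regional volume table does not cover the attack-map years."""


@dataclass
class LandscapeSeries:
    """Aligned raster stack plus the annual regional volume series.

    Attributes
    ----------
    host : (H, W) uint8 array, 1 where the cell holds mature host trees.
    attacks : (Y, H, W) uint8 array, 1 where the cell was attacked that year.
    temperature : (H, W) float array, long-term mean annual temperature (degC).
    regional_volume : pandas Series indexed by year — annual timber volume
        disturbed in the surrounding region.
    years : (Y,) int array of consecutive calendar years, one per attack map.
    cell_size_m : grid resolution in metres (30 in typical survey data).
    meta : opaque georeferencing/source metadata.
    """

    host: np.ndarray
    attacks: np.ndarray
    temperature: np.ndarray
    regional_volume: pd.Series
    years: np.ndarray
    cell_size_m: float = 30.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.host = np.asarray(self.host, dtype=np.uint8)
        self.attacks = np.asarray(self.attacks, dtype=np.uint8)
        self.temperature = np.asarray(self.temperature, dtype=np.float64)
        self.years = np.asarray(self.years, dtype=np.int64)
        if not isinstance(self.regional_volume, pd.Series):
            self.regional_volume = pd.Series(self.regional_volume)
        self.regional_volume.index = self.regional_volume.index.astype(int)
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        h, w = self.host.shape
        if self.temperature.shape != (h, w):
            raise AlignmentError(
                f"temperature grid {self.temperature.shape} does not match host grid {(h, w)}"
            )
        if self.attacks.ndim != 3 or self.attacks.shape[1:] != (h, w):
            raise AlignmentError(
                f"attack stack {self.attacks.shape} does not match host grid {(h, w)}"
            )
        if len(self.years) != self.attacks.shape[0]:
            raise SequenceError(
                f"{self.attacks.shape[0]} attack maps but {len(self.years)} year labels"
            )
        if len(self.years) and np.any(np.diff(self.years) != 1):
            raise SequenceError(f"years are not consecutive: {self.years.tolist()}")
        for arr, name in ((self.host, "host map"), (self.attacks, "attack maps")):
            bad = ~np.isin(arr, (0, 1))
            if bad.any():
                where = np.argwhere(bad)[0]
                raise ValueError(
                    f"{name} contain non-binary value {arr[tuple(where)]} "
                    f"at index {tuple(int(i) for i in where)}"
                )
        on_host = self.host.astype(bool)
        if not np.isfinite(self.temperature[on_host]).all():
            raise ValueError("temperature is not finite on all host cells")
        missing = set(self.years.tolist()) - set(self.regional_volume.index.tolist())
        if missing:
            raise CoverageError(f"regional volume series missing years {sorted(missing)}")

    # -- convenience -----------------------------------------------------
    @property
    def n_years(self) -> int:
        return int(self.attacks.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return self.host.shape

    @property
    def cell_area_ha(self) -> float:
        return (self.cell_size_m / 100.0) ** 2

    def attack_map(self, year: int) -> np.ndarray:
        idx = int(np.flatnonzero(self.years == year)[0])
        return self.attacks[idx]

    def annual_attack_counts(self) -> pd.Series:
        """Attacked cells per year (sum of each attack map)."""
        return pd.Series(self.attacks.sum(axis=(1, 2)).astype(int), index=self.years)


# -- raster codecs --------------------------------------------------------

def _read_ascii_grid(path: Path) -> tuple[np.ndarray, dict]:
    header: dict = {}
    lines = path.read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _ASC_HEADER_KEYS:
            header[parts[0].lower()] = float(parts[1])
            body_start = i + 1
        else:
            break
    grid = np.loadtxt(lines[body_start:], ndmin=2)
    nodata = header.get("nodata_value")
    if nodata is not None:
        grid = np.where(grid == nodata, np.nan, grid)
    if "nrows" in header and grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: body shape {grid.shape} disagrees with header")
    return grid, {"format": "ascii_grid", **header}


def _write_ascii_grid(grid: np.ndarray, path: Path, meta: Mapping | None, nodata: float) -> None:
    meta = dict(meta or {})
    h, w = grid.shape
    out = np.where(np.isnan(grid), nodata, grid)
    hdr = (
        f"ncols {w}\n"
        f"nrows {h}\n"
        f"xllcorner {meta.get('xllcorner', 0.0)}\n"
        f"yllcorner {meta.get('yllcorner', 0.0)}\n"
        f"cellsize {meta.get('cellsize', 30.0)}\n"
        f"NODATA_value {nodata}\n"
    )
    # %.9g round-trips float32 exactly through decimal text
    body = "\n".join(" ".join(f"{v:.9g}" for v in row) for row in np.asarray(out, np.float32))
    path.write_text(hdr + body + "\n")


def read_raster(path) -> tuple[np.ndarray, dict]:
    """Read a single-band raster (.tif/.tiff via tifffile, .asc/.txt ESRI grid).

    Returns the 2-D array (NODATA as NaN for ASCII grids) and a metadata dict.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if arr.ndim != 2:
            raise ValueError(f"{path}: expected a single-band raster, got shape {arr.shape}")
        return np.asarray(arr), {"format": "tiff"}
    if path.suffix.lower() in (".asc", ".txt"):
        return _read_ascii_grid(path)
    raise ValueError(f"unsupported raster format: {path.suffix!r}")


def write_raster(grid: np.ndarray, path, meta: Mapping | None = None,
                 nodata: float = PROB_NODATA) -> None:
    path = Path(path)
    grid = np.asarray(grid)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(np.where(np.isnan(grid), nodata, grid), np.float32))
    elif path.suffix.lower() in (".asc", ".txt"):
        _write_ascii_grid(grid, path, meta, nodata)
    else:
        raise ValueError(f"unsupported raster format: {path.suffix!r}")


# -- landscape-level I/O ---------------------------------------------------

def read_landscape(
    host_path,
    attack_paths: Mapping[int, object] | Sequence,
    temperature_path,
    volume_table_path,
    cell_size: float = 30.0,
) -> LandscapeSeries:
    """Read and validate a landscape series from rasters plus a volume CSV.

    ``attack_paths`` maps year -> raster path (or is a sequence of
    (year, path) pairs, or of paths whose names contain a 4-digit year).
    The volume table must have ``year`` and ``volume`` columns. Host cells
    flagged NODATA are treated as non-host; attack rasters must be strictly
    binary.
    """
    if isinstance(attack_paths, Mapping):
        pairs = sorted((int(y), p) for y, p in attack_paths.items())
    else:
        pairs = []
        for item in attack_paths:
            if isinstance(item, (tuple, list)):
                pairs.append((int(item[0]), item[1]))
            else:
                m = re.search(r"(\d{4})", Path(item).stem)
                if not m:
                    raise ValueError(f"cannot infer year from attack raster name {item!r}")
                pairs.append((int(m.group(1)), item))
        pairs.sort()
    years = np.array([y for y, _ in pairs], dtype=np.int64)

    host_raw, meta = read_raster(host_path)
    host = np.where(np.isnan(host_raw), 0, host_raw)
    if not np.isin(host, (0, 1)).all():
        bad = np.argwhere(~np.isin(host, (0, 1)))[0]
        raise ValueError(f"host map has non-binary value at {tuple(int(i) for i in bad)}")

    attacks = []
    for year, p in pairs:
        grid, _ = read_raster(p)
        grid = np.where(np.isnan(grid), 0, grid)
        if grid.shape != host.shape:
            raise AlignmentError(
                f"attack raster for {year} has shape {grid.shape}, host map {host.shape}"
            )
        bad = ~np.isin(grid, (0, 1))
        if bad.any():
            where = tuple(int(i) for i in np.argwhere(bad)[0])
            raise ValueError(
                f"attack raster for {year} has non-binary value {grid[where]} at {where}"
            )
        attacks.append(grid)

    temperature, _ = read_raster(temperature_path)
    vol = pd.read_csv(volume_table_path)
    cols = {c.lower(): c for c in vol.columns}
    if "year" not in cols or "volume" not in cols:
        raise ValueError("volume table needs 'year' and 'volume' columns")
    volume = pd.Series(
        vol[cols["volume"]].to_numpy(float), index=vol[cols["year"]].to_numpy(int)
    ).sort_index()

    return LandscapeSeries(
        host=host.astype(np.uint8),
        attacks=np.stack(attacks).astype(np.uint8) if attacks else
        np.zeros((0,) + host.shape, np.uint8),
        temperature=temperature,
        regional_volume=volume,
        years=years,
        cell_size_m=cell_size,
        meta=meta,
    )


def write_landscape(series: LandscapeSeries, outdir, raster_format: str = "asc") -> dict:
    """Write a landscape series to a directory in the layout read_landscape expects.

    Returns the paths written (host, attacks mapping, temperature, volumes).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = {"asc": ".asc", "tif": ".tif", "tiff": ".tif"}[raster_format]
    meta = {"cellsize": series.cell_size_m, **series.meta}
    host_path = outdir / f"host{ext}"
    write_raster(series.host.astype(np.float32), host_path, meta, nodata=-9999)
    temp_path = outdir / f"temperature{ext}"
    write_raster(series.temperature, temp_path, meta, nodata=-9999)
    attack_paths = {}
    for i, year in enumerate(series.years):
        p = outdir / f"attack_{int(year)}{ext}"
        write_raster(series.attacks[i].astype(np.float32), p, meta, nodata=-9999)
        attack_paths[int(year)] = p
    vol_path = outdir / "volumes.csv"
    pd.DataFrame(
        {"year": series.regional_volume.index, "volume": series.regional_volume.to_numpy()}
    ).to_csv(vol_path, index=False)
    return {
        "host": host_path,
        "attacks": attack_paths,
        "temperature": temp_path,
        "volumes": vol_path,
    }


def write_probability_map(grid: np.ndarray, path, meta: Mapping | None = None) -> None:
    """Write a predicted-probability surface; sentinel -1 marks unscored cells.

    Values must be finite and in [0, 1] wherever a prediction exists.
    Round-trips bit-exactly (float32) through read_probability_map.
    """
    grid = np.asarray(grid, dtype=np.float32)
    scored = grid != PROB_NODATA
    vals = grid[scored]
    if vals.size and (not np.isfinite(vals).all() or vals.min() < 0 or vals.max() > 1):
        raise ValueError("probabilities must be finite and within [0, 1] on scored cells")
    write_raster(grid, path, meta, nodata=PROB_NODATA)


def read_probability_map(path) -> np.ndarray:
    """Read a probability surface written by write_probability_map."""
    grid, _ = read_raster(path)
    return np.where(np.isnan(grid), PROB_NODATA, grid).astype(np.float32)
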