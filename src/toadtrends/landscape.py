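"""Buffer-based landscape composition, structure and change metrics.

Land cover is represented as a categorical integer raster. Around each
monitoring site a circular buffer is cut out (cells whose *centers* fall
inside the circle), and per buffer we compute

* the composition: proportions of merged land-use classes (a simplex),
* the Shannon diversity index of that composition,
* the number of patches (maximal 4-connected same-class regions),
* total edge length between unlike classes, and
* the Bray-Curtis distance between the compositions of two map dates,
  used as a proxy for landscape transformation.

Connectivity is rook (4-neighbour) throughout, which makes the edge length
the exact class-boundary length at cell resolution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import braycurtis

logger = logging.getLogger(__name__)

#: default merged land-use identities, in reporting order
MERGED_CLASSES = (
    "agricultural land",
    "woodland",
    "water",
    "urbanised area",
    "biologically valuable grasslands",
    "railways",
)

#: default mapping from the 11 raw land-use components to the 6 merged ones
DEFAULT_RECLASS = {
    "buildings": "urbanised area",
    "roads": "urbanised area",
    "covered": "urbanised area",
    "uncovered": "urbanised area",
    "grass and shrubs": "urbanised area",
    "railways": "railways",
    "water": "water",
    "woodland": "woodland",
    "arable land": "agricultural land",
    "agricultural grasslands": "agricultural land",
    "biologically valuable grasslands": "biologically valuable grasslands",
}


class BufferOutsideRasterError(ValueError):
    """The requested buffer circle does not intersect the raster extent."""


class EmptyBufferError(ValueError):
    """Every cell inside the buffer is nodata."""


@dataclass
class LandRaster:
    """Georeferenced categorical grid.

    ``origin_x_m``/``origin_y_m`` locate the *outer* corner of cell ``[0, 0]``
    (top-left); rows run north-to-south, so the center of cell ``(i, j)`` is
    ``(origin_x + (j + .5) * cell, origin_y - (i + .5) * cell)``.
    """

    grid: np.ndarray
    cell_size_m: float
    origin_x_m: float
    origin_y_m: float
    legend: dict[int, str]
    date_tag: str = ""
    nodata_code: int = -1

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=int)
        if self.grid.ndim != 2:
            raise ValueError("raster grid must be 2-D")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        codes = np.unique(self.grid)
        missing = [c for c in codes if c != self.nodata_code and c not in self.legend]
        if missing:
            raise ValueError(f"codes {missing} present in grid but absent from legend")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of all cell centers, shaped like ``grid``."""
        nrows, ncols = self.grid.shape
        xs = self.origin_x_m + (np.arange(ncols) + 0.5) * self.cell_size_m
        ys = self.origin_y_m - (np.arange(nrows) + 0.5) * self.cell_size_m
        return np.meshgrid(xs, ys)


@dataclass
class ReclassTable:
    """Total mapping raw class name -> merged class name."""

    mapping: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_RECLASS))
    merged_classes: tuple[str, ...] = MERGED_CLASSES

    def __post_init__(self) -> None:
        bad = {v for v in self.mapping.values()} - set(self.merged_classes)
        if bad:
            raise ValueError(f"mapping targets {bad} not among merged classes")

    def code_to_merged(self, legend: Mapping[int, str]) -> dict[int, str]:
        """Resolve raster codes to merged class names via the raster legend."""
        out = {}
        for code, raw in legend.items():
            if raw in self.mapping:
                out[code] = self.mapping[raw]
            elif raw in self.merged_classes:
                out[code] = raw  # raster already uses merged identities
            else:
                raise KeyError(f"raw class {raw!r} (code {code}) missing from reclass table")
        return out

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReclassTable":
        df = pd.read_csv(path)
        return cls(mapping=dict(zip(df.iloc[:, 0], df.iloc[:, 1])))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"raw_class": list(self.mapping), "merged_class": list(self.mapping.values())}
        ).to_csv(path, index=False)


@dataclass
class BufferProfile:
    """All landscape metrics for one site at one buffer radius."""

    site_id: str
    radius_m: float
    proportions: pd.Series  # simplex over merged classes
    shannon: float
    n_patches: int
    edge_length_m: float
    bray_curtis_change: float | None = None


# ---------------------------------------------------------------------------
# buffer extraction


def extract_buffer(
    raster: LandRaster, x_m: float, y_m: float, radius_m: float
) -> tuple[np.ma.MaskedArray, int]:
    """Cut the circular buffer around ``(x_m, y_m)`` out of ``raster``.

    Cells whose centers lie within ``radius_m`` are kept; everything else
    (including nodata cells) is masked. Returns the masked bounding-box
    sub-grid and the number of included (non-nodata) cells.
    """
    cs = raster.cell_size_m
    nrows, ncols = raster.grid.shape
    # bounding box of the circle in cell indices
    j0 = int(np.floor((x_m - radius_m - raster.origin_x_m) / cs))
    j1 = int(np.ceil((x_m + radius_m - raster.origin_x_m) / cs))
    i0 = int(np.floor((raster.origin_y_m - (y_m + radius_m)) / cs))
    i1 = int(np.ceil((raster.origin_y_m - (y_m - radius_m)) / cs))
    if j1 <= 0 or i1 <= 0 or j0 >= ncols or i0 >= nrows:
        raise BufferOutsideRasterError(
            f"buffer at ({x_m}, {y_m}) r={radius_m} lies outside the raster extent"
        )
    clipped = j0 < 0 or i0 < 0 or j1 > ncols or i1 > nrows
    i0c, i1c = max(i0, 0), min(i1, nrows)
    j0c, j1c = max(j0, 0), min(j1, ncols)

    sub = raster.grid[i0c:i1c, j0c:j1c]
    xs = raster.origin_x_m + (np.arange(j0c, j1c) + 0.5) * cs
    ys = raster.origin_y_m - (np.arange(i0c, i1c) + 0.5) * cs
    xx, yy = np.meshgrid(xs, ys)
    inside = (xx - x_m) ** 2 + (yy - y_m) ** 2 <= radius_m**2
    if not inside.any():
        raise BufferOutsideRasterError(
            f"buffer at ({x_m}, {y_m}) r={radius_m} contains no cell center"
        )
    if clipped:
        logger.warning(
            "buffer at (%s, %s) r=%s partially outside raster; using intersection",
            x_m, y_m, radius_m,
        )
    mask = ~inside | (sub == raster.nodata_code)
    masked = np.ma.MaskedArray(sub, mask=mask)
    n_included = int((~masked.mask).sum())
    n_in_circle = int(inside.sum())
    if n_included < 0.5 * n_in_circle:
        warnings.warn(
            f"buffer at ({x_m}, {y_m}) r={radius_m}: more than half the cells are nodata",
            stacklevel=2,
        )
    return masked, n_included


# ---------------------------------------------------------------------------
# per-buffer metrics


def composition(
    sub_grid: np.ma.MaskedArray,
    reclass: ReclassTable,
    legend: Mapping[int, str],
) -> pd.Series:
    """Proportions of merged classes among unmasked cells (sums to 1)."""
    values = np.ma.compressed(sub_grid)
    if values.size == 0:
        raise EmptyBufferError("no data in buffer")
    code_map = reclass.code_to_merged(legend)
    counts = pd.Series(0.0, index=list(reclass.merged_classes))
    codes, n = np.unique(values, return_counts=True)
    for code, k in zip(codes, n):
        counts[code_map[int(code)]] += k
    return counts / counts.sum()


def shannon_index(p: Sequence[float] | pd.Series) -> float:
    """Shannon diversity H = -sum p_i ln p_i (zero proportions contribute 0)."""
    p = np.asarray(p, dtype=float)
    if (p < -1e-12).any():
        raise ValueError("proportions must be non-negative")
    pos = p[p > 0]
    return float(-(pos * np.log(pos)).sum())


_ROOK = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def patch_count(sub_grid: np.ndarray | np.ma.MaskedArray) -> int:
    """Number of maximal 4-connected same-class regions of unmasked cells."""
    grid = np.ma.asarray(sub_grid)
    total = 0
    for code in np.unique(np.ma.compressed(grid)):
        binary = (grid == code).filled(False)
        _, n = ndimage.label(binary, structure=_ROOK)
        total += n
    return total


def edge_length(sub_grid: np.ndarray | np.ma.MaskedArray, cell_size_m: float) -> float:
    """Total boundary length between unlike classes inside the buffer.

    Counts rook-adjacent unmasked pairs with differing class and multiplies
    by the cell size; the buffer's outer rim and masked neighbours contribute
    nothing.
    """
    grid = np.ma.asarray(sub_grid)
    data, mask = grid.data, np.ma.getmaskarray(grid)
    n_pairs = 0
    # vertical neighbours
    ok = ~mask[:-1, :] & ~mask[1:, :]
    n_pairs += int((ok & (data[:-1, :] != data[1:, :])).sum())
    # horizontal neighbours
    ok = ~mask[:, :-1] & ~mask[:, 1:]
    n_pairs += int((ok & (data[:, :-1] != data[:, 1:])).sum())
    return n_pairs * cell_size_m


def bray_curtis_change(p_early: pd.Series, p_late: pd.Series) -> float:
    """Bray-Curtis distance between two composition vectors (in [0, 1])."""
    if list(p_early.index) != list(p_late.index):
        raise ValueError("compositions are over different class sets")
    if p_early.sum() == 0 or p_late.sum() == 0:
        raise ValueError("compositions must be non-empty")
    return float(braycurtis(np.asarray(p_early, float), np.asarray(p_late, float)))


# ---------------------------------------------------------------------------
# assembly


def profile_sites(
    sites: pd.DataFrame,
    rasters: Mapping[str, LandRaster],
    reclass: ReclassTable,
    radii_m: Iterable[float] = (100.0, 500.0, 1000.0),
) -> list[BufferProfile]:
    """One :class:`BufferProfile` per site x radius.

    ``sites`` needs columns ``site_id, x_m, y_m``. When more than one raster
    date is supplied the change metric compares the earliest against the
    latest ``date_tag`` (lexicographic order, e.g. years as strings); all
    other metrics are computed on the latest date.
    """
    if not rasters:
        raise ValueError("at least one raster date required")
    dates = sorted(rasters)
    primary = rasters[dates[-1]]
    earliest = rasters[dates[0]] if len(dates) > 1 else None

    profiles: list[BufferProfile] = []
    for row in sites.itertuples(index=False):
        for radius in radii_m:
            try:
                sub, _ = extract_buffer(primary, row.x_m, row.y_m, radius)
                props = composition(sub, reclass, primary.legend)
                change = None
                if earliest is not None:
                    sub0, _ = extract_buffer(earliest, row.x_m, row.y_m, radius)
                    props0 = composition(sub0, reclass, earliest.legend)
                    change = bray_curtis_change(props0, props)
                profiles.append(
                    BufferProfile(
                        site_id=str(row.site_id),
                        radius_m=float(radius),
                        proportions=props,
                        shannon=shannon_index(props),
                        n_patches=patch_count(sub),
                        edge_length_m=edge_length(sub, primary.cell_size_m),
                        bray_curtis_change=change,
                    )
                )
            except (BufferOutsideRasterError, EmptyBufferError) as exc:
                raise type(exc)(f"site {row.site_id!r}, radius {radius}: {exc}") from exc
    return profiles


def profiles_to_frame(profiles: Sequence[BufferProfile]) -> pd.DataFrame:
    """Flatten profiles to one row per site x radius for CSV export."""
    rows = []
    for pr in profiles:
        row: dict = {"site_id": pr.site_id, "radius_m": pr.radius_m}
        row.update({f"p_{k}": v for k, v in pr.proportions.items()})
        row.update(
            shannon=pr.shannon,
            n_patches=pr.n_patches,
            edge_length_m=pr.edge_length_m,
            bray_curtis_change=pr.bray_curtis_change,
        )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (plain-text raster interchange)


def write_ascii_grid(raster: LandRaster, path: str | Path) -> None:
    nrows, ncols = raster.grid.shape
    yll = raster.origin_y_m - nrows * raster.cell_size_m
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {raster.origin_x_m}\n"
        f"yllcorner {yll}\n"
        f"cellsize {raster.cell_size_m}\n"
        f"NODATA_value {raster.nodata_code}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.grid, fmt="%d")


def read_ascii_grid(
    path: str | Path, legend: Mapping[int, str], date_tag: str = ""
) -> LandRaster:
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        grid = np.loadtxt(fh, dtype=int)
    grid = grid.reshape(int(header["nrows"]), int(header["ncols"]))
    cs = header["cellsize"]
    return LandRaster(
        grid=grid,
        cell_size_m=cs,
        origin_x_m=header["xllcorner"],
        origin_y_m=header["yllcorner"] + int(header["nrows"]) * cs,
        legend=dict(legend),
        date_tag=date_tag,
        nodata_code=int(header["nodata_value"]),
    )
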