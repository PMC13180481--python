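"""Synthetic count time series and categorical land-cover rasters.

The generator provides ground-truth-labelled inputs with the statistical
structure the downstream analysis assumes: negative-binomially distributed
annual counts (variance mu + mu^2/theta) over latent trends that can realise
each of the four trend labels, and spatially clustered multi-class rasters
with a controllable amount of between-date change.

Latent trend shapes
-------------------
constant
    flat log-mean; ground truth for the "non-significant" label.
linear
    log-mean changes by ``per_year_log_change`` per year; monotone
    increase/decrease ground truth.
step
    a mid-series jump of ``per_year_log_change * span`` (so the begin-end
    per-year change matches the linear shape with the same parameter).
hump
    equal endpoints with a smooth mid-series excursion of height
    ``amplitude_log`` on the log scale; ground truth for the "flexible"
    (significant but non-monotonic) label.

Series may contain gaps — unobserved interior years — as most real volunteer
monitoring series do, but the first and last observed year are always
retained because the headline begin-end contrast is evaluated at them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .landscape import LandRaster
from .trends import CountSeries

Shape = Literal["constant", "linear", "step", "hump"]

_SHAPES = ("constant", "linear", "step", "hump")

#: minimum number of observed years for a series to enter the trend analysis
MIN_OBSERVATIONS = 6


class SeriesTooShortError(ValueError):
    """Requested series has fewer observations than the eligibility floor."""


@dataclass(frozen=True)
class TrendScenario:
    """Parameters of one simulated population's latent trend and sampling."""

    shape: Shape = "constant"
    intercept_log: float = np.log(100.0)
    per_year_log_change: float = 0.0
    amplitude_log: float = 0.0
    dispersion_theta: float = 5.0
    year_range: tuple[int, int] = (1981, 2022)
    n_obs: int = 15
    gap_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        first, last = self.year_range
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.n_obs < MIN_OBSERVATIONS:
            raise SeriesTooShortError(
                f"n_obs={self.n_obs} is below the {MIN_OBSERVATIONS}-year eligibility floor"
            )
        if self.n_obs > last - first + 1:
            raise ValueError("n_obs exceeds the number of years in year_range")
        if self.dispersion_theta <= 0:
            raise ValueError("dispersion_theta must be positive")
        if not 0.0 <= self.gap_fraction <= 1.0:
            raise ValueError("gap_fraction must be in [0, 1]")


def latent_log_mean(scenario: TrendScenario, years: np.ndarray) -> np.ndarray:
    """Log expected count at each (observed) year.

    The trend is parameterised on the observed span: ``t`` runs from 0 at the
    first observed year to ``span`` at the last, so hump endpoints coincide
    with the series endpoints regardless of gapping.
    """
    years = np.asarray(years, dtype=float)
    t = years - years.min()
    span = years.max() - years.min()
    if scenario.shape == "constant":
        return np.full_like(t, scenario.intercept_log)
    if scenario.shape == "linear":
        return scenario.intercept_log + scenario.per_year_log_change * t
    if scenario.shape == "step":
        jump = scenario.per_year_log_change * span
        return scenario.intercept_log + jump * (t >= span / 2.0)
    # hump: smooth parabola, equal endpoints, peak amplitude_log at midspan
    u = t / span if span > 0 else t
    return scenario.intercept_log + scenario.amplitude_log * 4.0 * u * (1.0 - u)


def _observed_years(scenario: TrendScenario, rng: np.random.Generator) -> np.ndarray:
    first, last = scenario.year_range
    all_years = np.arange(first, last + 1)
    n = scenario.n_obs
    if rng.random() < scenario.gap_fraction and n < all_years.size:
        # gapped series over the full range; endpoints always retained
        interior = rng.choice(all_years[1:-1], size=n - 2, replace=False)
        years = np.sort(np.concatenate([[first, last], interior]))
    else:
        # consecutive block of n years somewhere in the range
        start = rng.integers(first, last - n + 2)
        years = np.arange(start, start + n)
    return years


def simulate_count_series(scenario: TrendScenario, site_id: str = "site",
                          x_m: float = 0.0, y_m: float = 0.0) -> CountSeries:
    """Draw one NB count series under the scenario's latent trend.

    Deterministic given ``scenario.seed``: the same scenario always yields
    the same observed years and counts.
    """
    rng = np.random.default_rng(scenario.seed)
    years = _observed_years(scenario, rng)
    mu = np.exp(latent_log_mean(scenario, years))
    if not np.all(np.isfinite(mu)):
        raise ValueError("latent mean is non-finite for some year")
    theta = scenario.dispersion_theta
    counts = rng.negative_binomial(theta, theta / (theta + mu))
    return CountSeries(
        site_id=site_id,
        x_m=x_m,
        y_m=y_m,
        records=list(zip(years.tolist(), counts.astype(int).tolist())),
    )


def simulate_population_set(
    n_per_shape: Mapping[Shape, int],
    base_scenario: TrendScenario,
) -> list[tuple[CountSeries, TrendScenario]]:
    """Labelled collection of series for scoring classification accuracy.

    Per-series seeds are derived deterministically from the base seed and the
    (shape, index) position, so the whole set reproduces bit-identically and
    individual series are independent draws.
    """
    out: list[tuple[CountSeries, TrendScenario]] = []
    for shape_idx, shape in enumerate(_SHAPES):
        n = int(n_per_shape.get(shape, 0))
        for i in range(n):
            ss = np.random.SeedSequence(
                entropy=base_scenario.seed, spawn_key=(shape_idx, i)
            )
            child_seed = int(ss.generate_state(1)[0] % (2**31))
            scen = dataclasses.replace(base_scenario, shape=shape, seed=child_seed)
            sid = f"{shape}_{i:04d}"
            series = simulate_count_series(scen, site_id=sid)
            out.append((series, scen))
    return out


# ---------------------------------------------------------------------------
# rasters


@dataclass(frozen=True)
class RasterScenario:
    """Parameters of a synthetic categorical raster pair (two map dates)."""

    n_rows: int = 200
    n_cols: int = 200
    cell_size_m: float = 1.0
    class_codes: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    class_weights: tuple[float, ...] = (0.35, 0.2, 0.05, 0.25, 0.1, 0.05)
    patch_scale: float = 5.0
    change_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_codes) < 2:
            raise ValueError("need at least two classes")
        if len(self.class_weights) != len(self.class_codes):
            raise ValueError("class_weights and class_codes length mismatch")
        if abs(sum(self.class_weights) - 1.0) > 1e-9:
            raise ValueError("class_weights must sum to 1")
        if self.patch_scale <= 0 or self.cell_size_m <= 0:
            raise ValueError("patch_scale and cell_size_m must be positive")
        if not 0.0 <= self.change_fraction <= 1.0:
            raise ValueError("change_fraction must be in [0, 1]")


def simulate_raster_pair(
    scenario: RasterScenario,
    legend: Mapping[int, str] | None = None,
    origin_x_m: float = 0.0,
    origin_y_m: float | None = None,
) -> tuple[LandRaster, LandRaster]:
    """Two map dates of a spatially clustered categorical raster.

    Date 1 is built by thresholding Gaussian-smoothed white noise at the
    class-weight quantiles, which matches the requested composition to
    within one cell per class while producing contiguous patches of typical
    size ``patch_scale`` cells. Date 2 reassigns exactly
    ``round(change_fraction * n_cells)`` randomly chosen cells to a
    different class (weighted by the remaining class weights).
    """
    rng = np.random.default_rng(scenario.seed)
    nr, nc = scenario.n_rows, scenario.n_cols
    n_cells = nr * nc
    noise = rng.standard_normal((nr, nc))
    f = ndimage.gaussian_filter(noise, sigma=scenario.patch_scale)
    order = np.argsort(f, axis=None, kind="stable")
    grid1 = np.empty(n_cells, dtype=int)
    bounds = np.round(np.cumsum(scenario.class_weights) * n_cells).astype(int)
    start = 0
    for code, stop in zip(scenario.class_codes, bounds):
        grid1[order[start:stop]] = code
        start = stop
    grid1 = grid1.reshape(nr, nc)

    n_change = int(round(scenario.change_fraction * n_cells))
    grid2 = grid1.copy()
    if n_change > 0:
        flat = grid2.ravel()
        idx = rng.choice(n_cells, size=n_change, replace=False)
        codes = np.asarray(scenario.class_codes)
        weights = np.asarray(scenario.class_weights, dtype=float)
        for cell in idx:
            others = codes != flat[cell]
            w = weights[others]
            flat[cell] = rng.choice(codes[others], p=w / w.sum())

    if legend is None:
        legend = {c: f"class_{c}" for c in scenario.class_codes}
    if origin_y_m is None:
        origin_y_m = nr * scenario.cell_size_m
    common = dict(
        cell_size_m=scenario.cell_size_m,
        origin_x_m=origin_x_m,
        origin_y_m=origin_y_m,
        legend=dict(legend),
    )
    return (
        LandRaster(grid=grid1, date_tag="date1", **common),
        LandRaster(grid=grid2, date_tag="date2", **common),
    )


# ---------------------------------------------------------------------------
# export


def write_counts_csv(
    series_list: Sequence[CountSeries], path: str | Path
) -> pd.DataFrame:
    """Write long-format (site_id, year, count) CSV; returns the frame."""
    rows = [
        {"site_id": s.site_id, "year": year, "count": count}
        for s in series_list
        for year, count in s.records
    ]
    df = pd.DataFrame(rows, columns=["site_id", "year", "count"])
    df.to_csv(path, index=False)
    return df


def write_sites_csv(series_list: Sequence[CountSeries], path: str | Path) -> pd.DataFrame:
    df = pd.DataFrame(
        [{"site_id": s.site_id, "x_m": s.x_m, "y_m": s.y_m} for s in series_list]
    )
    df.to_csv(path, index=False)
    return df


def write_truth_json(
    labelled: Sequence[tuple[CountSeries, TrendScenario]], path: str | Path
) -> None:
    """Ground-truth sidecar for scoring classification against scenarios."""
    truth = {
        series.site_id: dataclasses.asdict(scenario) for series, scenario in labelled
    }
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=list)
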