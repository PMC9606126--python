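"""Radius-scanning regressions and source-area estimation.

The "source area" of a pollen diversity measure is located by regressing it
against the matching plant diversity measure evaluated at each radius of a
grid from 0.5 to 1000 m, and taking the radius with the highest adjusted R².
Three diversity kinds are scanned: per-site richness, per-dataset BD_Total,
and per-site local contributions to beta diversity (LCBD).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .beta_diversity import bd_total_at_radius, beta_div_presence, presence_at_radius
from .io_core import DatasetPartition, PlantSurvey, DATASET_KEYS

#: Default scan radii (m); covers every band boundary the survey design uses.
DEFAULT_RADIUS_GRID = (
    0.5, 1.5, 3, 6, 10, 20, 30, 40, 50, 70, 100, 150, 200, 250,
    300, 350, 400, 450, 500, 550, 600, 700, 800, 900, 1000,
)

SIGNIFICANCE_LEVEL = 0.05


def validate_radius_grid(grid: Sequence[float]) -> np.ndarray:
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1 or len(g) < 1:
        raise ValueError("radius grid must be a non-empty 1-D sequence")
    if not (np.diff(g) > 0).all():
        raise ValueError("radius grid must be strictly increasing")
    if g[0] < 0.5 - 1e-12 or g[-1] > 1000 + 1e-12:
        raise ValueError("radius grid must lie within [0.5, 1000] m")
    return g


@dataclass
class RegressionSummary:
    """OLS of a pollen diversity value on a plant diversity value at one radius."""

    radius: float
    n: int
    slope: float
    intercept: float
    r2: float
    adj_r2: float  # NaN when the predictor has zero variance
    p_value: float
    significant: bool


@dataclass
class ScalingResult:
    """Per-radius regression summaries plus the argmax radius (source area)."""

    diversity_kind: str  # "richness" | "bd_total" | "lcbd"
    summaries: list[RegressionSummary]
    source_area_m: float  # radius of maximal adjusted R²; ties -> smallest

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.summaries])


def adjusted_r2(r2: float, n: int) -> float:
    """One-predictor adjusted R²: 1 - (1 - R²)(n - 1)/(n - 2)."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def _regress(plant: np.ndarray, pollen: np.ndarray, radius: float) -> RegressionSummary:
    n = len(plant)
    if np.ptp(plant) == 0:  # zero predictor variance: undefined fit
        return RegressionSummary(radius, n, np.nan, np.nan, np.nan, np.nan,
                                 np.nan, False)
    fit = stats.linregress(plant, pollen)
    r2 = fit.rvalue ** 2
    adj = adjusted_r2(r2, n)
    p = float(fit.pvalue)
    return RegressionSummary(
        radius=radius, n=n, slope=float(fit.slope),
        intercept=float(fit.intercept), r2=float(r2), adj_r2=float(adj),
        p_value=p, significant=bool(p < SIGNIFICANCE_LEVEL),
    )


def _finalize(kind: str, summaries: list[RegressionSummary]) -> ScalingResult:
    valid = [(s.adj_r2, s.radius) for s in summaries if np.isfinite(s.adj_r2)]
    if not valid:
        raise ValueError("adjusted R² undefined at every radius")
    best = max(valid, key=lambda t: (t[0], -t[1]))  # ties -> smallest radius
    return ScalingResult(diversity_kind=kind, summaries=summaries,
                         source_area_m=best[1])


# ---------------------------------------------------------------------------
# plant-side curves


def cumulative_richness(survey: PlantSurvey,
                        grid: Sequence[float] = DEFAULT_RADIUS_GRID) -> pd.DataFrame:
    """Cumulative species counts per site at each radius (sites x radii).

    Entry (site, r) counts species whose first-appearance distance is <= r;
    rows are non-decreasing left to right.
    """
    g = validate_radius_grid(grid)
    if len(survey) == 0:
        raise ValueError("empty plant survey")
    dist = survey.records.pivot_table(index="site_id", columns="species",
                                      values="first_distance_m", aggfunc="first")
    arr = dist.to_numpy()[:, :, None] <= g[None, None, :]
    counts = np.nansum(arr, axis=1).astype(int)
    return pd.DataFrame(counts, index=dist.index, columns=g)


def new_species_by_band(survey: PlantSurvey,
                        grid: Sequence[float] = DEFAULT_RADIUS_GRID) -> pd.DataFrame:
    """First-appearance counts binned into radius bands, split by habitat of record.

    Bands are (r_{k-1}, r_k] with the first band [0, r_0]; the grand total per
    dataset equals the number of distinct (site, species) first appearances.
    """
    g = validate_radius_grid(grid)
    edges = np.concatenate([[-np.inf], g])
    df = survey.records.copy()
    df["band"] = pd.cut(df["first_distance_m"], bins=edges,
                        labels=[f"<= {r:g} m" for r in g])
    out = df.groupby(["band", "habitat"], observed=False).size().unstack(fill_value=0)
    out.index.name = "band"
    return out


# ---------------------------------------------------------------------------
# scans


def fit_scaling_regressions(pollen_values: Mapping[str, float],
                            survey: PlantSurvey,
                            grid: Sequence[float] = DEFAULT_RADIUS_GRID,
                            dataset: Sequence[str] | None = None,
                            kind: str = "richness") -> ScalingResult:
    """Scan radii regressing per-site pollen values on plant cumulative richness.

    At each radius the plant predictor is the cumulative species count; sites
    with no plant record inside the radius contribute richness 0 rather than
    being dropped. Radii where the predictor has zero variance are reported
    with an undefined adjusted R² and excluded from the argmax.
    """
    site_ids = sorted(dataset) if dataset is not None else sorted(pollen_values)
    site_ids = [s for s in site_ids if s in pollen_values]
    if len(site_ids) < 4:
        raise ValueError(f"need >= 4 sites with pollen values, got {len(site_ids)}")
    g = validate_radius_grid(grid)
    pollen = np.array([pollen_values[s] for s in site_ids], dtype=float)
    curve = cumulative_richness(survey, g).reindex(site_ids).fillna(0)
    summaries = [
        _regress(curve[r].to_numpy(dtype=float), pollen, float(r)) for r in g
    ]
    return _finalize(kind, summaries)


def bd_total_scan(pollen_bd: Mapping[str, float], survey: PlantSurvey,
                  partition: DatasetPartition,
                  grid: Sequence[float] = DEFAULT_RADIUS_GRID,
                  sqrt_transform: bool = True) -> ScalingResult:
    """Scan radii regressing per-dataset pollen BD_Total on plant BD_Total.

    One point per analysis dataset (the six region/habitat datasets in the
    full design); n is reported at each radius.
    """
    keys = [k for k in DATASET_KEYS if k in pollen_bd and len(partition[k]) >= 2]
    if len(keys) < 3:
        raise ValueError(f"need >= 3 datasets with pollen BD_Total, got {len(keys)}")
    g = validate_radius_grid(grid)
    pollen = np.array([pollen_bd[k] for k in keys], dtype=float)
    summaries = []
    for r in g:
        plant = np.array([
            bd_total_at_radius(survey, partition[k], float(r),
                               sqrt_transform).bd_total
            for k in keys
        ])
        summaries.append(_regress(plant, pollen, float(r)))
    return _finalize("bd_total", summaries)


def lcbd_scan(pollen_lcbd: Mapping[str, float], survey: PlantSurvey,
              dataset: Sequence[str],
              grid: Sequence[float] = DEFAULT_RADIUS_GRID,
              sqrt_transform: bool = True) -> ScalingResult:
    """Scan radii regressing per-site pollen LCBD on plant LCBD at each radius."""
    site_ids = [s for s in sorted(dataset) if s in pollen_lcbd]
    if len(site_ids) < 4:
        raise ValueError(f"need >= 4 sites with pollen LCBD, got {len(site_ids)}")
    g = validate_radius_grid(grid)
    pollen = np.array([pollen_lcbd[s] for s in site_ids], dtype=float)
    summaries = []
    for r in g:
        y, species = presence_at_radius(survey, site_ids, float(r))
        if not species:
            summaries.append(RegressionSummary(float(r), len(site_ids), np.nan,
                                               np.nan, np.nan, np.nan, np.nan,
                                               False))
            continue
        res = beta_div_presence(y, sqrt_transform)
        if res.lcbd is None:
            summaries.append(RegressionSummary(float(r), len(site_ids), np.nan,
                                               np.nan, np.nan, np.nan, np.nan,
                                               False))
            continue
        summaries.append(_regress(res.lcbd, pollen, float(r)))
    return _finalize("lcbd", summaries)


def completeness_ratio(recorded_species: int, reference_species: int) -> float:
    """Percentage of a reference species pool captured by the survey,
    100 * recorded / reference, rounded to one decimal."""
    if reference_species <= 0:
        raise ValueError("reference species pool must be > 0")
    return round(100.0 * recorded_species / reference_species, 1)
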