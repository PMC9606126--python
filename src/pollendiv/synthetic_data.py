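"""Synthetic landscapes, plant surveys and pollen rain with known ground truth.

The generator emulates the study design of a two-region modern-pollen
calibration: a species-poor and a species-rich region, each with forested and
open sites, a concentric-band habitat mosaic around every site, and moss-
polster-like pollen samples whose expected composition integrates vegetation
over distance with an exponential dispersal kernel.

Model sketch, per site:

* The landscape around a site is a set of concentric annuli (bands) delimited
  by the scan radius grid. Each band carries habitat mixing weights; the
  central bands (<= 10 m) are pure site habitat, outer bands mix in the other
  habitat with intensity controlled by the region's mosaic grain.
* Every species of the regional pool has a log-normal commonness and a
  habitat affinity (forest, open, or generalist for pool-overlap species).
  Band occupancy is Bernoulli with rate 1 - exp(-commonness * affinity-weighted
  habitat weight * band intensity); band intensities scale with annulus area
  and are calibrated so that a median species of the focal habitat appears
  within 10 m with probability equal to the fine-scale richness parameter.
  A species' first-appearance distance is drawn area-uniformly inside its
  innermost occupied band.
* Expected pollen proportions aggregate species into pollen types (many-to-one,
  consecutive blocks within each pool segment), weight them by pollen
  productivity (PPE) and by the kernel mass of each occupied band,
  integral of 2*pi*r*exp(-r/lambda) over the annulus (annulus-area weighting),
  then mix in a long-distance regional background; forest sites receive extra
  background scaled by the canopy interception factor. Counts are multinomial.

The effective source radius R_eff — the radius containing 85% of the
kernel-weighted pollen mass within the survey limit — has a closed form in
lambda and is recorded in the ground truth so that end-to-end source-area
recovery can be scored against a known target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .io_core import (
    HABITATS,
    MAX_SURVEY_RADIUS_M,
    PlantSurvey,
    PollenDataset,
    PPETable,
    REGIONS,
    SiteMeta,
    write_plant_survey,
    write_pollen_counts,
    write_ppe_table,
)
from .spatial_scaling import DEFAULT_RADIUS_GRID

KERNEL_MASS_QUANTILE = 0.85


# ---------------------------------------------------------------------------
# dispersal kernel


def _kernel_cdf_unnorm(r: np.ndarray | float, lam: float) -> np.ndarray | float:
    """Integral of 2*pi*r'*exp(-r'/lam) dr' from 0 to r (unnormalised)."""
    r = np.asarray(r, dtype=float)
    return 2.0 * np.pi * lam * (lam - np.exp(-r / lam) * (r + lam))


def band_kernel_mass(band_edges: np.ndarray, lam: float) -> np.ndarray:
    """Kernel-weighted mass of each annulus (0, e1], (e1, e2], ..."""
    edges = np.concatenate([[0.0], np.asarray(band_edges, dtype=float)])
    cdf = _kernel_cdf_unnorm(edges, lam)
    return np.diff(cdf)


def effective_source_radius(lam: float, r_max: float = MAX_SURVEY_RADIUS_M,
                            mass: float = KERNEL_MASS_QUANTILE) -> float:
    """Radius containing ``mass`` of the kernel-weighted pollen load in (0, r_max]."""
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    total = _kernel_cdf_unnorm(r_max, lam)
    return float(brentq(lambda r: _kernel_cdf_unnorm(r, lam) - mass * total,
                        1e-9, r_max))


def lambda_for_source_radius(r_eff: float, r_max: float = MAX_SURVEY_RADIUS_M,
                             mass: float = KERNEL_MASS_QUANTILE) -> float:
    """Invert :func:`effective_source_radius` for the kernel scale lambda."""
    if not 0 < r_eff < r_max:
        raise ValueError("r_eff must lie strictly inside (0, r_max)")
    return float(brentq(
        lambda lam: effective_source_radius(lam, r_max, mass) - r_eff,
        1e-3, 10.0 * r_max))


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults are the two-region study conditions."""

    #: sites per (region, habitat) stratum — the 10/11/19/20 study design
    n_sites: dict = field(default_factory=lambda: {
        "region_poor_forest": 10, "region_poor_open": 11,
        "region_rich_forest": 19, "region_rich_open": 20,
    })
    #: habitat species-pool sizes per stratum; poor < rich, forest < open
    pool_sizes: dict = field(default_factory=lambda: {
        "region_poor_forest": 60, "region_poor_open": 90,
        "region_rich_forest": 120, "region_rich_open": 160,
    })
    #: fraction of the smaller habitat pool shared as generalists (per region)
    pool_overlap: float = 0.15
    #: probability a median-commonness focal-habitat species appears <= 10 m
    fine_scale_richness: float = 0.30
    #: habitat mixing intensity of outer bands, per region (rich = finer mosaic)
    mosaic_grain: dict = field(default_factory=lambda: {
        "region_poor": 0.15, "region_rich": 0.30,
    })
    #: exponential dispersal scale (m); default gives R_eff ~ 150 m
    dispersal_lambda: float = 44.2
    #: mean species per pollen type (many-to-one taxonomy)
    aggregation_factor: float = 2.5
    #: log-sd of log-normal per-type true pollen productivity (median 1)
    ppe_sigma: float = 0.6
    #: multiplier on the productivity of forest (tree) pollen types
    tree_productivity: float = 3.0
    #: canopy dominants per region: a few tree species holding most of the
    #: forest pool's abundance mass, emulating plantation/oakwood dominance
    n_canopy_species: int = 3
    #: fraction of forest-pool abundance mass held by the canopy dominants
    canopy_dominance: float = 0.7
    #: number of pollen types whose true productivity is exposed as a PPE table
    n_ppe_taxa: int = 25
    #: long-distance background pollen fraction at open sites
    background_fraction: float = 0.02
    #: extra background at forest sites: eps_forest = eps * (1 + canopy)
    canopy_interception: float = 0.2
    #: grains counted per sample
    pollen_sum: int = 2000
    #: log-sd of log-normal species commonness
    commonness_sigma: float = 1.2
    #: log-sd of per-(site, species) abundance heterogeneity (spatial patchiness)
    patchiness_sigma: float = 1.0
    #: sub-linear growth of survey detection effort with annulus area (the
    #: outer zones are sampled along transects, not exhaustively)
    survey_effort_exponent: float = 0.8
    #: if False, patchiness only modulates occupancy (presence), not the
    #: abundance of species that are present
    patchiness_on_abundance: bool = True
    band_edges: tuple = DEFAULT_RADIUS_GRID

    def __post_init__(self):
        for name in ("pool_overlap", "fine_scale_richness",
                     "background_fraction", "canopy_dominance"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if not 0 < self.canopy_interception <= 1:
            raise ValueError("canopy_interception must be in (0, 1]")
        for v in self.mosaic_grain.values():
            if not 0 <= v <= 1:
                raise ValueError("mosaic grain must be in [0, 1]")
        if self.dispersal_lambda <= 0:
            raise ValueError("dispersal_lambda must be > 0")
        if self.pollen_sum < 943:
            raise ValueError("pollen_sum must be >= 943 so rarefaction at the "
                             "default depth is possible")


def preset_config(name: str) -> SyntheticConfig:
    """Named study conditions.

    ``two-region``
        The default two-region, 10/11/19/20-site design with contrasting
        pool sizes and mosaic grain.
    ``strong-signal``
        A single-stratum, 40-site landscape tuned for source-area recovery:
        one-to-one species/pollen-type map, uniform productivity, little
        background, and a kernel whose effective source radius is 150 m.
    """
    if name == "two-region":
        return SyntheticConfig()
    if name == "strong-signal":
        return SyntheticConfig(
            n_sites={"region_poor_forest": 0, "region_poor_open": 0,
                     "region_rich_forest": 0, "region_rich_open": 40},
            pool_sizes={"region_poor_forest": 0, "region_poor_open": 0,
                        "region_rich_forest": 150, "region_rich_open": 150},
            pool_overlap=0.0,
            fine_scale_richness=0.30,
            mosaic_grain={"region_poor": 0.0, "region_rich": 0.6},
            dispersal_lambda=lambda_for_source_radius(150.0),
            aggregation_factor=1.0,
            ppe_sigma=0.0,
            tree_productivity=1.0,
            n_canopy_species=0,
            n_ppe_taxa=0,
            background_fraction=0.02,
            canopy_interception=0.1,
            pollen_sum=2000,
            commonness_sigma=0.8,
            patchiness_sigma=1.2,
            patchiness_on_abundance=False,
        )
    raise ValueError(f"unknown preset {name!r}")


# ---------------------------------------------------------------------------
# species pools and pollen taxonomy


@dataclass
class SpeciesPool:
    """Regional species pools with commonness and habitat affinity."""

    names: list[str]  # all species of both regions
    region_of: dict  # species -> region
    affinity: dict  # species -> (forest_weight, open_weight), sums to 1
    commonness: dict  # species -> positive real
    canopy_dominants: list[str] = field(default_factory=list)


@dataclass
class GroundTruth:
    """Planted generator truth used as the oracle for end-to-end tests."""

    dispersal_lambda: float
    r_eff: float
    pool: SpeciesPool
    species_to_type: dict
    productivity: dict  # pollen type -> true relative productivity (all types)
    ppe: dict  # pollen type -> PPE exposed to the analyst (subset)
    band_edges: tuple

    def summary(self) -> dict:
        per_region = {
            r: sum(1 for s in self.pool.names if self.pool.region_of[s] == r)
            for r in REGIONS
        }
        return {
            "dispersal_lambda": self.dispersal_lambda,
            "r_eff_m": self.r_eff,
            "n_species": len(self.pool.names),
            "n_species_per_region": per_region,
            "n_pollen_types": len(set(self.species_to_type.values())),
            "kernel_mass_quantile": KERNEL_MASS_QUANTILE,
        }


def _build_pools(config: SyntheticConfig, rng: np.random.Generator) -> SpeciesPool:
    names, region_of, affinity, commonness = [], {}, {}, {}
    dominants: list[str] = []
    for region in REGIONS:
        f_size = config.pool_sizes[f"{region}_forest"]
        o_size = config.pool_sizes[f"{region}_open"]
        n_shared = int(round(config.pool_overlap * min(f_size, o_size)))
        segments = [
            ("forest", f_size - n_shared, (1.0, 0.0)),
            ("open", o_size - n_shared, (0.0, 1.0)),
            ("shared", n_shared, (0.5, 0.5)),
        ]
        for seg, size, aff in segments:
            seg_names = []
            for i in range(size):
                sp = f"sp_{region}_{seg}_{i:03d}"
                names.append(sp)
                seg_names.append(sp)
                region_of[sp] = region
                affinity[sp] = aff
                commonness[sp] = float(
                    rng.lognormal(mean=0.0, sigma=config.commonness_sigma))
            if seg == "forest" and config.n_canopy_species > 0 and seg_names:
                # concentrate canopy_dominance of the pool's abundance mass in
                # a few dominant tree species (plantation / oakwood canopy)
                k = min(config.n_canopy_species, len(seg_names))
                total = sum(commonness[s] for s in seg_names)
                d = config.canopy_dominance
                for s in seg_names[k:]:
                    commonness[s] *= (1.0 - d)
                rest = sum(commonness[s] for s in seg_names[k:])
                share = d * rest / (1.0 - d) / k if d < 1 else total / k
                for s in seg_names[:k]:
                    commonness[s] = share
                dominants.extend(seg_names[:k])
    return SpeciesPool(names=names, region_of=region_of, affinity=affinity,
                       commonness=commonness, canopy_dominants=dominants)


def _build_taxonomy(pool: SpeciesPool, config: SyntheticConfig,
                    rng: np.random.Generator) -> tuple[dict, dict, dict]:
    """Group consecutive species of each pool segment into pollen types, draw a
    true productivity for every type (forest/tree types boosted), and expose
    the ``n_ppe_taxa`` highest producers as the analyst's PPE table."""
    species_to_type: dict[str, str] = {}
    type_counter = 0
    # consecutive blocking within (region, segment) so a type never mixes
    # habitats or regions — a genus-like taxonomy
    by_block: dict[str, list[str]] = {}
    for sp in pool.names:
        block = sp.rsplit("_", 1)[0]  # sp_<region>_<segment>
        by_block.setdefault(block, []).append(sp)
    for block, members in by_block.items():
        i = 0
        while i < len(members):
            if config.aggregation_factor <= 1.0:
                size = 1
            else:
                size = 1 + rng.poisson(config.aggregation_factor - 1.0)
            type_name = f"T{type_counter:03d}_{block.removeprefix('sp_')}"
            for sp in members[i:i + size]:
                species_to_type[sp] = type_name
            type_counter += 1
            i += size
    all_types = sorted(set(species_to_type.values()))
    productivity = {}
    for t in all_types:
        boost = config.tree_productivity if t.endswith("_forest") else 1.0
        productivity[t] = float(boost * rng.lognormal(0.0, config.ppe_sigma))
    n_ppe = min(config.n_ppe_taxa, len(all_types))
    top = sorted(all_types, key=lambda t: -productivity[t])[:n_ppe]
    ppe = {t: productivity[t] for t in sorted(top)}
    return species_to_type, productivity, ppe


# ---------------------------------------------------------------------------
# landscape and survey


@dataclass
class Landscape:
    """Per-site band habitat weights plus everything drawn before the survey."""

    sites: list[SiteMeta]
    band_edges: np.ndarray
    #: (n_sites, n_bands, 2) habitat weights, last axis ordered as HABITATS
    weights: np.ndarray
    #: (n_sites, n_species) log-normal site-level abundance factors (patchiness)
    patchiness: np.ndarray
    pool: SpeciesPool
    config: SyntheticConfig

    @property
    def n_bands(self) -> int:
        return len(self.band_edges)


@dataclass
class SurveyRealization:
    """A realised survey: the long-format records plus the latent occupancy."""

    survey: PlantSurvey
    #: (n_sites, n_species, n_bands) boolean band occupancy
    occupancy: np.ndarray
    species_order: list[str]


def _spawn(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, *key)))


def generate_landscape(config: SyntheticConfig, seed: int = 0) -> Landscape:
    """Draw site metadata, band habitat mosaics and the regional species pools.

    The central bands (outer radius <= 10 m) are pure site habitat; each outer
    band mixes in the other habitat with weight ``mosaic_grain * U(0, 1)``.
    """
    rng = _spawn(seed, 0)
    sites: list[SiteMeta] = []
    code = {"region_poor": "P", "region_rich": "R"}
    for region in REGIONS:
        for habitat in HABITATS:
            for i in range(config.n_sites[f"{region}_{habitat}"]):
                sites.append(SiteMeta(
                    site_id=f"{code[region]}-{habitat[0].upper()}{i + 1:02d}",
                    region=region, habitat=habitat))
    edges = np.asarray(config.band_edges, dtype=float)
    n_bands = len(edges)
    weights = np.zeros((len(sites), n_bands, len(HABITATS)))
    central = edges <= 10.0
    # sites sit inside continuous habitat: mixing with the other habitat is
    # absent in the central bands and grows with distance
    distance_ramp = np.sqrt(edges / edges[-1])
    for i, site in enumerate(sites):
        own = HABITATS.index(site.habitat)
        other = 1 - own
        grain = config.mosaic_grain[site.region]
        mix = grain * rng.uniform(size=n_bands) * distance_ramp
        mix[central] = 0.0
        weights[i, :, own] = 1.0 - mix
        weights[i, :, other] = mix
    pool = _build_pools(config, rng)
    patchiness = rng.lognormal(0.0, config.patchiness_sigma,
                               size=(len(sites), len(pool.names)))
    # continuous plantation/oakwood canopies: dominant trees are not patchy
    dom_cols = [j for j, s in enumerate(pool.names)
                if s in set(pool.canopy_dominants)]
    patchiness[:, dom_cols] = 1.0
    return Landscape(sites=sites, band_edges=edges, weights=weights,
                     patchiness=patchiness, pool=pool, config=config)


def _band_intensities(config: SyntheticConfig, edges: np.ndarray) -> np.ndarray:
    """Per-band occupancy intensity.

    Cumulative intensity grows with the surveyed area as a sub-linear power
    (transect sampling of the outer zones), normalised so a commonness-1,
    affinity-1 species appears <= 10 m with probability equal to the
    fine-scale richness parameter."""
    full = np.concatenate([[0.0], edges])
    gamma = config.survey_effort_exponent
    a10 = np.pi * 10.0 ** 2
    cum = ((np.pi * full ** 2) / a10) ** gamma
    nu10 = -np.log1p(-config.fine_scale_richness)  # cumulative intensity <= 10 m
    return nu10 * np.diff(cum)


def simulate_plant_survey(landscape: Landscape, config: SyntheticConfig,
                          seed: int = 0) -> SurveyRealization:
    """Realise band occupancy and the long-format first-appearance survey."""
    rng = _spawn(seed, 1)
    edges = landscape.band_edges
    nu = _band_intensities(config, edges)
    species = [s for s in landscape.pool.names]
    aff = np.array([landscape.pool.affinity[s] for s in species])  # (S, 2)
    com = np.array([landscape.pool.commonness[s] for s in species])  # (S,)
    region_mask = np.array([
        [landscape.pool.region_of[s] == site.region for s in species]
        for site in landscape.sites
    ])  # (n_sites, S)
    # affinity-weighted habitat weight per site/species/band
    w = np.einsum("ibh,sh->isb", landscape.weights, aff)
    rate = (com[None, :] * landscape.patchiness)[:, :, None] * w * nu[None, None, :]
    q = 1.0 - np.exp(-rate)
    occ = (rng.random(q.shape) < q) & region_mask[:, :, None]

    inner = np.concatenate([[0.0], edges[:-1]])
    records = []
    first_band = np.where(occ.any(axis=2), occ.argmax(axis=2), -1)
    for i, site in enumerate(landscape.sites):
        for j in np.flatnonzero(first_band[i] >= 0):
            b = first_band[i, j]
            u = rng.random()
            r = float(np.sqrt(inner[b] ** 2 + u * (edges[b] ** 2 - inner[b] ** 2)))
            f, o = aff[j]
            if f > o:
                habitat = "forest"
            elif o > f:
                habitat = "open"
            else:  # generalist: credit the habitat dominant in the trigger band
                habitat = HABITATS[int(np.argmax(landscape.weights[i, b]))]
            records.append((site.site_id, species[j], round(r, 2), habitat))
    import pandas as pd

    survey = PlantSurvey(records=pd.DataFrame(
        records, columns=["site_id", "species", "first_distance_m", "habitat"]))
    return SurveyRealization(survey=survey, occupancy=occ, species_order=species)


# ---------------------------------------------------------------------------
# pollen rain


def simulate_pollen(landscape: Landscape, realization: SurveyRealization,
                    config: SyntheticConfig, seed: int = 0
                    ) -> tuple[PollenDataset, GroundTruth]:
    """Draw multinomial pollen counts from kernel-weighted realised vegetation.

    Expected proportion of pollen type t at site i:

        p_t ∝ (1 - eps_i) * sum_{s in t} sum_b occ[i,s,b] * commonness_s *
               weight[i,s,b] * PPE_t * K_b   +   eps_i * pi_t(region)

    where K_b is the kernel mass of band b and pi the regional mean local
    composition. Forest sites use eps_i = eps * (1 + canopy_interception).
    """
    rng = _spawn(seed, 2)
    taxonomy_rng = _spawn(seed, 3)
    species_to_type, productivity, ppe_map = _build_taxonomy(
        landscape.pool, config, taxonomy_rng)
    species = realization.species_order
    types = sorted(set(species_to_type.values()))
    type_index = {t: k for k, t in enumerate(types)}
    sp_type = np.array([type_index[species_to_type[s]] for s in species])
    prod_vec = np.array([productivity[t] for t in types])
    com = np.array([landscape.pool.commonness[s] for s in species])
    aff = np.array([landscape.pool.affinity[s] for s in species])
    kmass = band_kernel_mass(landscape.band_edges, config.dispersal_lambda)

    w = np.einsum("ibh,sh->isb", landscape.weights, aff)
    if config.patchiness_on_abundance:
        abundance = com[None, :] * landscape.patchiness  # (n_sites, S)
    else:
        abundance = np.broadcast_to(com[None, :],
                                    landscape.patchiness.shape).copy()
    contrib = (realization.occupancy * w * abundance[:, :, None]
               * kmass[None, None, :]).sum(axis=2)  # (n_sites, S)
    n_sites = len(landscape.sites)
    local = np.zeros((n_sites, len(types)))
    np.add.at(local.T, sp_type, contrib.T)
    local *= prod_vec[None, :]
    totals = local.sum(axis=1)
    if (totals <= 0).any():
        bad = [landscape.sites[i].site_id for i in np.flatnonzero(totals <= 0)]
        raise ValueError(f"sites with zero expected pollen load: {bad}")
    local /= totals[:, None]

    regions = np.array([s.region for s in landscape.sites])
    background = {}
    for region in REGIONS:
        mask = regions == region
        if mask.any():
            background[region] = local[mask].mean(axis=0)

    counts = np.zeros((n_sites, len(types)), dtype=np.int64)
    eps0 = config.background_fraction
    for i, site in enumerate(landscape.sites):
        eps = eps0 * (1.0 + config.canopy_interception) \
            if site.habitat == "forest" else eps0
        p = (1.0 - eps) * local[i] + eps * background[site.region]
        counts[i] = rng.multinomial(config.pollen_sum, p / p.sum())

    pollen = PollenDataset(sites=list(landscape.sites), taxa=types,
                           counts=counts)
    truth = GroundTruth(
        dispersal_lambda=config.dispersal_lambda,
        r_eff=effective_source_radius(config.dispersal_lambda),
        pool=landscape.pool,
        species_to_type=species_to_type,
        productivity=productivity,
        ppe=ppe_map,
        band_edges=tuple(landscape.band_edges.tolist()),
    )
    return pollen, truth


def simulate_study(config: SyntheticConfig | str = "two-region", seed: int = 0
                   ) -> tuple[PollenDataset, PlantSurvey, PPETable, GroundTruth]:
    """One-call generation of a complete synthetic study."""
    if isinstance(config, str):
        config = preset_config(config)
    landscape = generate_landscape(config, seed)
    realization = simulate_plant_survey(landscape, config, seed)
    pollen, truth = simulate_pollen(landscape, realization, config, seed)
    ppe = PPETable(ppe=dict(truth.ppe)) if truth.ppe else PPETable(ppe={})
    return pollen, realization.survey, ppe, truth


def make_fixture_suite(preset: str = "two-region", seed: int = 0,
                       outdir: str | Path = "fixtures") -> dict[str, Path]:
    """Write pollen.csv, plants.csv, ppe.csv and truth.json for a preset.

    Deterministic: the same preset and seed produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pollen, survey, ppe, truth = simulate_study(preset, seed)
    header = f"preset={preset} seed={seed}"
    paths = {
        "pollen": outdir / "pollen.csv",
        "plants": outdir / "plants.csv",
        "ppe": outdir / "ppe.csv",
        "truth": outdir / "truth.json",
    }
    write_pollen_counts(pollen, paths["pollen"], header_comment=header)
    write_plant_survey(survey, paths["plants"], header_comment=header)
    write_ppe_table(ppe, paths["ppe"], header_comment=header)
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump({"preset": preset, "seed": seed, **truth.summary()}, fh,
                  indent=2, sort_keys=True)
        fh.write("\n")
    return paths
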