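"""Domain containers and delimited-table readers/writers shared by all stages.

The on-disk contracts are deliberately plain: a wide CSV/TSV for pollen counts
(``site_id, region, habitat, <taxon columns...>``), a long CSV/TSV for the plant
survey (``site_id, species, first_distance_m, habitat``) and a two-column CSV
for pollen productivity estimates (``taxon, ppe``). Delimiter is auto-detected
from the file extension (``.tsv`` -> tab, anything else -> comma).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("pollendiv")

REGIONS = ("region_poor", "region_rich")
HABITATS = ("forest", "open")

#: The six analysis datasets: each region in full plus its habitat subsets.
DATASET_KEYS = (
    "region_poor_complete",
    "region_poor_forest",
    "region_poor_open",
    "region_rich_complete",
    "region_rich_forest",
    "region_rich_open",
)

MAX_SURVEY_RADIUS_M = 1000.0


class ValidationError(ValueError):
    """An input table violates the documented contract."""


class ShallowSampleError(ValueError):
    """A pollen sample's total count is below the requested rarefaction depth."""

    def __init__(self, site_id: str, total: int, depth: int):
        self.site_id = site_id
        self.total = total
        self.depth = depth
        super().__init__(
            f"site {site_id!r}: total {total} grains < rarefaction depth {depth}"
        )


@dataclass(frozen=True)
class SiteMeta:
    """Identity and stratification of one sampling site."""

    site_id: str
    region: str  # one of REGIONS
    habitat: str  # one of HABITATS

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValidationError(
                f"site {self.site_id!r}: region {self.region!r} not in {REGIONS}"
            )
        if self.habitat not in HABITATS:
            raise ValidationError(
                f"site {self.site_id!r}: habitat {self.habitat!r} not in {HABITATS}"
            )


@dataclass
class PollenDataset:
    """Sites x pollen-type integer count matrix with per-site metadata.

    ``counts[i, j]`` is the number of grains of pollen type ``taxa[j]``
    identified in the sample from ``sites[i]``.
    """

    sites: list[SiteMeta]
    taxa: list[str]
    counts: np.ndarray  # (n_sites, n_taxa) non-negative integers

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sites), len(self.taxa)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sites)} sites x {len(self.taxa)} taxa"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                bad = np.argwhere(as_int != self.counts)[0]
                raise ValidationError(
                    f"non-integer count at site {self.sites[bad[0]].site_id!r}, "
                    f"taxon {self.taxa[bad[1]]!r}"
                )
            self.counts = as_int
        if (self.counts < 0).any():
            bad = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at site {self.sites[bad[0]].site_id!r}, "
                f"taxon {self.taxa[bad[1]]!r}"
            )
        ids = [s.site_id for s in self.sites]
        dup = {x for x in ids if ids.count(x) > 1}
        if dup:
            raise ValidationError(f"duplicate site_id(s): {sorted(dup)}")
        dup_taxa = {t for t in self.taxa if self.taxa.count(t) > 1}
        if dup_taxa:
            raise ValidationError(f"duplicate taxon name(s): {sorted(dup_taxa)}")
        empty = [t for t, col in zip(self.taxa, self.counts.T) if col.sum() == 0]
        if empty:
            logger.info("taxa with all-zero counts retained: %s", empty)

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    @property
    def totals(self) -> np.ndarray:
        """Per-site pollen sum (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def presence_matrix(self) -> np.ndarray:
        """Raw (full-count) presence/absence, sites x taxa, dtype int8."""
        return (self.counts > 0).astype(np.int8)

    def subset(self, site_ids: Sequence[str]) -> "PollenDataset":
        """Row-subset preserving site order of ``site_ids``."""
        index = {s.site_id: i for i, s in enumerate(self.sites)}
        rows = [index[sid] for sid in site_ids]
        return PollenDataset(
            sites=[self.sites[i] for i in rows],
            taxa=list(self.taxa),
            counts=self.counts[rows].copy(),
        )


@dataclass
class PlantSurvey:
    """Long-format plant records: one first-appearance distance per (site, species).

    ``first_distance_m`` is the radius at which the species was first recorded,
    in metres within [0, 1000]; "present within radius r" means
    ``first_distance_m <= r`` (closed interval).
    """

    records: pd.DataFrame  # columns: site_id, species, first_distance_m, habitat

    REQUIRED = ("site_id", "species", "first_distance_m", "habitat")

    def __post_init__(self):
        df = pd.DataFrame(self.records)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"plant survey missing column(s): {missing}")
        df = df.loc[:, list(self.REQUIRED)].copy()
        df["first_distance_m"] = pd.to_numeric(df["first_distance_m"])
        bad = df[
            (df["first_distance_m"] < 0)
            | (df["first_distance_m"] > MAX_SURVEY_RADIUS_M)
        ]
        if len(bad):
            raise ValidationError(
                "first_distance_m outside [0, 1000] for records: "
                + ", ".join(
                    f"({r.site_id}, {r.species}, {r.first_distance_m})"
                    for r in bad.head(10).itertuples()
                )
            )
        dups = df[df.duplicated(["site_id", "species"], keep=False)]
        if len(dups):
            offenders = sorted(
                set(zip(dups["site_id"], dups["species"]))
            )
            raise ValidationError(
                f"duplicate (site_id, species) pairs: {offenders[:10]}"
            )
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def site_ids(self) -> list[str]:
        return sorted(self.records["site_id"].unique())

    def for_sites(self, site_ids: Sequence[str]) -> pd.DataFrame:
        return self.records[self.records["site_id"].isin(set(site_ids))]


@dataclass
class PPETable:
    """Pollen-type -> relative pollen productivity estimate (strictly positive)."""

    ppe: dict[str, float]
    reference_taxon: str | None = None

    def __post_init__(self):
        clean: dict[str, float] = {}
        for taxon, value in self.ppe.items():
            v = float(value)
            if not v > 0:
                raise ValidationError(f"PPE for {taxon!r} must be > 0, got {value}")
            clean[taxon.strip()] = v
        self.ppe = clean

    def __contains__(self, taxon: str) -> bool:
        return taxon.strip() in self.ppe

    def __getitem__(self, taxon: str) -> float:
        return self.ppe[taxon.strip()]


@dataclass
class DatasetPartition:
    """The six analysis datasets as named site-id lists."""

    datasets: dict[str, list[str]]

    def __post_init__(self):
        missing = [k for k in DATASET_KEYS if k not in self.datasets]
        if missing:
            raise ValidationError(f"partition missing dataset(s): {missing}")
        for region in REGIONS:
            complete = set(self.datasets[f"{region}_complete"])
            forest = set(self.datasets[f"{region}_forest"])
            open_ = set(self.datasets[f"{region}_open"])
            if forest & open_:
                raise ValidationError(
                    f"{region}: forest and open subsets overlap: {forest & open_}"
                )
            if complete != forest | open_:
                raise ValidationError(
                    f"{region}: complete set is not the union of its subsets"
                )

    def __getitem__(self, key: str) -> list[str]:
        return self.datasets[key]

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.datasets.items()}


# ---------------------------------------------------------------------------
# readers / writers


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def read_pollen_counts(path: str | Path) -> PollenDataset:
    """Read a wide pollen count table (site_id, region, habitat, taxon columns)."""
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    required = ["site_id", "region", "habitat"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    taxa = [c for c in df.columns if c not in required]
    if not taxa:
        raise ValidationError(f"{path}: no taxon columns found")
    sites = [
        SiteMeta(str(r.site_id), str(r.region), str(r.habitat))
        for r in df.itertuples()
    ]
    return PollenDataset(sites=sites, taxa=[t.strip() for t in taxa],
                         counts=df[taxa].to_numpy())


def write_pollen_counts(pollen: PollenDataset, path: str | Path,
                        header_comment: str | None = None) -> None:
    df = pd.DataFrame(pollen.counts, columns=pollen.taxa)
    df.insert(0, "habitat", [s.habitat for s in pollen.sites])
    df.insert(0, "region", [s.region for s in pollen.sites])
    df.insert(0, "site_id", pollen.site_ids)
    _write_with_header(df, path, header_comment)


def read_plant_survey(path: str | Path) -> PlantSurvey:
    """Read a long-format plant survey table."""
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    return PlantSurvey(records=df)


def write_plant_survey(survey: PlantSurvey, path: str | Path,
                       header_comment: str | None = None) -> None:
    _write_with_header(survey.records, path, header_comment)


def read_ppe_table(path: str | Path) -> PPETable:
    """Read a two-column (taxon, ppe) table."""
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    if not {"taxon", "ppe"}.issubset(df.columns):
        raise ValidationError(f"{path}: PPE table needs columns 'taxon' and 'ppe'")
    return PPETable(ppe=dict(zip(df["taxon"].astype(str), df["ppe"])))


def write_ppe_table(ppe: PPETable, path: str | Path,
                    header_comment: str | None = None) -> None:
    df = pd.DataFrame(sorted(ppe.ppe.items()), columns=["taxon", "ppe"])
    _write_with_header(df, path, header_comment)


def _write_with_header(df: pd.DataFrame, path: str | Path,
                       header_comment: str | None) -> None:
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep=sep, index=False)


def partition_datasets(pollen: PollenDataset) -> DatasetPartition:
    """Split sites into the six analysis datasets by (region, habitat).

    Order-invariant: datasets are sorted site-id lists, so shuffling the input
    rows yields an identical partition.
    """
    datasets: dict[str, list[str]] = {k: [] for k in DATASET_KEYS}
    for s in pollen.sites:
        datasets[f"{s.region}_complete"].append(s.site_id)
        datasets[f"{s.region}_{s.habitat}"].append(s.site_id)
    for k in datasets:
        datasets[k] = sorted(datasets[k])
        if not datasets[k]:
            logger.warning("dataset %s is empty", k)
    return DatasetPartition(datasets=datasets)
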