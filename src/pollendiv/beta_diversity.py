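"""Total-variance beta diversity of presence/absence community tables.

Beta diversity is measured as the total variance of the site-by-species table
(BD_Total), obtained from pairwise dissimilarities: with D the Jaccard
dissimilarity matrix, A = -0.5 * D∘D is Gower-centred to G; the diagonal of G
gives per-site sums of squares SS_i, SS_total = Σ SS_i, and

    BD_Total = SS_total / (n - 1),        LCBD_i = SS_i / SS_total.

The identity SS_total = (1/n) Σ_{i<j} D_ij² makes a brute-force cross-check
possible and is enforced in the test suite. Because BD_Total is a variance per
degree of freedom it is comparable across tables with different numbers of
sites — the property that lets complete datasets be compared with their
habitat subsets.

By default the Jaccard dissimilarities are square-root transformed before the
decomposition. sqrt(Jaccard) is Euclidean-embeddable, which guarantees all
SS_i >= 0 and keeps BD_Total within [0, 1]; a flag disables the transform for
sensitivity analyses.

LCBD significance is assessed by permuting values independently within each
species column, which preserves species occupancy frequencies while breaking
site identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io_core import PlantSurvey, logger


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities in [0, 1] with zero diagonal."""

    values: np.ndarray
    sqrt_transformed: bool = False

    def __post_init__(self):
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError(f"dissimilarity matrix must be square, got {d.shape}")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("dissimilarity matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix diagonal is not zero")
        if d.min() < -1e-12 or d.max() > 1 + 1e-12:
            raise ValueError("dissimilarities must lie in [0, 1]")
        self.values = d

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class BetaDivResult:
    """Total variance decomposition of one community table."""

    ss_total: float
    bd_total: float
    lcbd: np.ndarray | None  # None when ss_total == 0 (undefined, not 0/0)
    n_sites: int
    lcbd_pvalues: np.ndarray | None = None


def jaccard_dissimilarity(presence: np.ndarray,
                          sqrt_transform: bool = True) -> DissimilarityMatrix:
    """Pairwise Jaccard dissimilarity of a binary sites x taxa matrix.

    D_ij = 1 - a/(a+b+c) with a = shared presences and b, c the presences
    unique to each site; joint absences are ignored. A pair of all-zero rows
    gets D = 0 (logged). With ``sqrt_transform`` the square root of each
    dissimilarity is returned, flagged on the result.
    """
    y = np.asarray(presence)
    if y.ndim != 2 or y.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 sites")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("presence matrix must be binary")
    if y.sum() == 0:
        raise ValueError("no taxon present anywhere")
    empty = np.flatnonzero(y.sum(axis=1) == 0)
    if empty.size:
        logger.info("all-zero site rows (pairwise D to each other = 0): %s",
                    empty.tolist())
    d = squareform(pdist(y.astype(bool), metric="jaccard"))
    if sqrt_transform:
        d = np.sqrt(d)
    return DissimilarityMatrix(values=d, sqrt_transformed=sqrt_transform)


def beta_div(d: DissimilarityMatrix) -> BetaDivResult:
    """Decompose a dissimilarity matrix into SS_total, BD_Total and LCBD."""
    dv = d.values
    n = d.n
    if n < 2:
        raise ValueError("need at least 2 sites")
    a = -0.5 * dv * dv
    row_means = a.mean(axis=1, keepdims=True)
    g = a - row_means - row_means.T + a.mean()
    ss_i = np.diag(g).copy()
    ss_total = float(ss_i.sum())
    if ss_total <= 1e-14:
        return BetaDivResult(ss_total=0.0, bd_total=0.0, lcbd=None, n_sites=n)
    return BetaDivResult(
        ss_total=ss_total,
        bd_total=ss_total / (n - 1),
        lcbd=ss_i / ss_total,
        n_sites=n,
    )


def beta_div_presence(presence: np.ndarray,
                      sqrt_transform: bool = True) -> BetaDivResult:
    """Convenience: Jaccard + total-variance decomposition in one call."""
    return beta_div(jaccard_dissimilarity(presence, sqrt_transform))


def ss_total_bruteforce(d: DissimilarityMatrix) -> float:
    """Independent pairwise formula SS_total = (1/n) Σ_{i<j} D_ij²."""
    dv = d.values
    n = d.n
    iu = np.triu_indices(n, k=1)
    return float((dv[iu] ** 2).sum() / n)


def lcbd_permutation_test(presence: np.ndarray, n_perm: int = 999,
                          rng_seed: int = 0,
                          sqrt_transform: bool = True) -> np.ndarray:
    """Permutation p-values for each site's LCBD.

    Each permutation shuffles values independently within every species
    column; p_i = (#{perm: LCBD_perm_i >= LCBD_obs_i} + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(presence)
    obs = beta_div_presence(y, sqrt_transform)
    n = y.shape[0]
    if obs.lcbd is None:
        logger.warning("constant community table: LCBD undefined, all p = 1")
        return np.ones(n)
    rng = np.random.default_rng(rng_seed)
    exceed = np.zeros(n)
    for _ in range(n_perm):
        perm = np.empty_like(y)
        for j in range(y.shape[1]):
            perm[:, j] = y[rng.permutation(n), j]
        res = beta_div_presence(perm, sqrt_transform)
        lcbd_perm = np.full(n, 1.0 / n) if res.lcbd is None else res.lcbd
        exceed += lcbd_perm >= obs.lcbd - 1e-15
    return (exceed + 1.0) / (n_perm + 1.0)


def presence_at_radius(survey: PlantSurvey, site_ids: list[str],
                       radius: float) -> tuple[np.ndarray, list[str]]:
    """Binary sites x species matrix of the survey truncated at ``radius``.

    A species is present at a site iff its first-appearance distance is
    <= radius (closed interval). Returns (matrix, species order); row order
    follows ``site_ids``.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    sub = survey.for_sites(site_ids)
    sub = sub[sub["first_distance_m"] <= radius]
    species = sorted(sub["species"].unique())
    sp_index = {s: j for j, s in enumerate(species)}
    site_index = {s: i for i, s in enumerate(site_ids)}
    y = np.zeros((len(site_ids), len(species)), dtype=np.int8)
    for r in sub.itertuples():
        y[site_index[r.site_id], sp_index[r.species]] = 1
    return y, species


def bd_total_at_radius(survey: PlantSurvey, site_ids: list[str], radius: float,
                       sqrt_transform: bool = True) -> BetaDivResult:
    """Plant BD_Total for the species present within ``radius`` of each site."""
    y, species = presence_at_radius(survey, site_ids, radius)
    if not species:
        raise ValueError(f"no species within radius {radius} m at any site")
    return beta_div_presence(y, sqrt_transform)
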