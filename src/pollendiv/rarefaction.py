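"""Rarefaction of pollen count assemblages by subsampling without replacement.

Each sample is reduced to a common grain sum (``depth``) by drawing grains
without replacement — a multivariate hypergeometric draw, equivalent to
shuffling the grain pool and keeping the first ``depth`` grains. Richness
(number of pollen types present in the draw) is summarised as the median over
repeated draws, which is the statistic carried into all downstream analyses.

Defaults follow the calibration protocol: depth 943 grains (the smallest
pollen sum in the study design) and 100 repetitions; productivity-adjusted
assemblages use depth 520 (see :mod:`pollendiv.ppe_adjustment`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import PollenDataset, ShallowSampleError, logger

DEFAULT_DEPTH = 943
DEFAULT_REPS = 100


@dataclass
class RarefactionResult:
    """Per-site rarefied richness summaries at a common depth."""

    site_ids: list[str]
    depth: int
    n_reps: int
    richness_median: np.ndarray  # per site; may be half-integer for even n_reps
    richness_reps: np.ndarray | None = None  # (n_sites, n_reps) integer richness
    excluded: list[str] | None = None  # site_ids too shallow for the depth

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(self.site_ids, self.richness_median.tolist()))


def _site_rng(master_seed: int, site_index: int) -> np.random.Generator:
    """Per-site stream derived from the master seed.

    Seeds are split with :class:`numpy.random.SeedSequence` spawn keys so the
    stream of a site depends only on its index, never on how many other sites
    are processed.
    """
    return np.random.default_rng(np.random.SeedSequence(master_seed).spawn(
        site_index + 1)[site_index])


def rarefy_sample(counts: np.ndarray, depth: int,
                  rng: int | np.random.Generator) -> np.ndarray:
    """Draw ``depth`` grains without replacement from one count vector.

    Returns an integer vector of the same length summing to ``depth`` with
    every element <= the original count (multivariate hypergeometric draw).
    """
    counts = np.asarray(counts, dtype=np.int64)
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    total = int(counts.sum())
    if total < depth:
        raise ShallowSampleError("<unnamed>", total, depth)
    if total == depth:
        return counts.copy()
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return gen.multivariate_hypergeometric(counts, depth)


def rarefied_richness(counts: np.ndarray, depth: int,
                      n_reps: int = DEFAULT_REPS,
                      rng: int | np.random.Generator = 0) -> float:
    """Median number of pollen types over ``n_reps`` rarefied draws.

    The median of an even number of integer richness values may be a
    half-integer; it is returned unrounded.
    """
    reps = rarefied_richness_reps(counts, depth, n_reps, rng)
    return float(np.median(reps))


def rarefied_richness_reps(counts: np.ndarray, depth: int, n_reps: int,
                           rng: int | np.random.Generator) -> np.ndarray:
    """Per-draw richness values (vector of ``n_reps`` integers)."""
    counts = np.asarray(counts, dtype=np.int64)
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    total = int(counts.sum())
    if total < depth:
        raise ShallowSampleError("<unnamed>", total, depth)
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if total == depth:
        return np.full(n_reps, int((counts > 0).sum()))
    draws = gen.multivariate_hypergeometric(counts, depth, size=n_reps)
    return (draws > 0).sum(axis=1)


def expected_rarefied_richness(counts: np.ndarray, depth: int) -> float:
    """Exact expectation of rarefied richness: sum of per-taxon detection
    probabilities under the multivariate hypergeometric draw.

    P(taxon t missed) = C(total - n_t, depth) / C(total, depth), evaluated in
    log space for numerical stability.
    """
    from scipy.special import gammaln

    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if total < depth:
        raise ShallowSampleError("<unnamed>", total, depth)

    def log_choose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    expectation = 0.0
    for n_t in counts[counts > 0]:
        if total - n_t < depth:
            miss = 0.0
        else:
            miss = np.exp(log_choose(total - n_t, depth) - log_choose(total, depth))
        expectation += 1.0 - miss
    return float(expectation)


def rarefy_dataset(pollen: PollenDataset, depth: int = DEFAULT_DEPTH,
                   n_reps: int = DEFAULT_REPS, rng_seed: int = 0,
                   keep_reps: bool = False) -> RarefactionResult:
    """Rarefy every site of a dataset to a common depth.

    Deterministic for a given ``rng_seed``: each site's random stream is
    derived from the master seed and the site's position, so results are
    reproducible and unaffected by processing order. Sites with fewer grains
    than ``depth`` are excluded with a warning and listed in ``excluded``.
    """
    if pollen.n_sites == 0:
        raise ValueError("empty pollen dataset")
    totals = pollen.totals
    shallow = [sid for sid, t in zip(pollen.site_ids, totals) if t < depth]
    if shallow:
        logger.warning("sites too shallow for depth %d, excluded: %s", depth, shallow)
    kept_ids: list[str] = []
    medians: list[float] = []
    all_reps: list[np.ndarray] = []
    for i, (site, row) in enumerate(zip(pollen.sites, pollen.counts)):
        if totals[i] < depth:
            continue
        reps = rarefied_richness_reps(row, depth, n_reps, _site_rng(rng_seed, i))
        kept_ids.append(site.site_id)
        medians.append(float(np.median(reps)))
        if keep_reps:
            all_reps.append(reps)
    if not kept_ids:
        raise ValueError(f"no site reaches rarefaction depth {depth}")
    return RarefactionResult(
        site_ids=kept_ids,
        depth=depth,
        n_reps=n_reps,
        richness_median=np.array(medians),
        richness_reps=np.vstack(all_reps) if keep_reps else None,
        excluded=shallow,
    )
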