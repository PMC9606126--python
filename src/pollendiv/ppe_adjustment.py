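"""Pollen-productivity correction of count assemblages.

Taxa differ strongly in how much pollen they shed per unit plant abundance;
heavy producers (e.g. *Pinus*, *Betula*) flood the pollen rain and depress the
detection probability of everything else. Dividing each taxon's count by its
relative pollen productivity estimate (PPE) rebalances the assemblage before
richness is re-computed at a common depth.

Adjusted counts are non-integer, so "subsampling without replacement" is no
longer defined for them. Resampling therefore draws grains multinomially with
probabilities proportional to the adjusted values (default), or — as a
sensitivity mode — rounds the adjusted values to integers and draws without
replacement (``law="round-then-hypergeometric"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import PollenDataset, PPETable, logger
from .rarefaction import DEFAULT_REPS, RarefactionResult, _site_rng

DEFAULT_ADJUSTED_DEPTH = 520


@dataclass
class AdjustedCounts:
    """Sites x taxa matrix of productivity-adjusted (real-valued) counts."""

    site_ids: list[str]
    taxa: list[str]
    values: np.ndarray  # (n_sites, n_taxa) non-negative reals
    adjusted_taxa: list[str]  # taxa that had a PPE and were divided
    unadjusted_taxa: list[str]  # taxa passed through with raw counts


def adjust_counts(pollen: PollenDataset, ppe: PPETable) -> AdjustedCounts:
    """Divide each taxon's counts by its PPE; taxa without a PPE keep raw counts.

    Taxon matching is exact-string after whitespace trimming; unmatched names
    are flagged and logged, never fuzzy-matched.
    """
    values = pollen.counts.astype(float).copy()
    adjusted, unadjusted = [], []
    for j, taxon in enumerate(pollen.taxa):
        if taxon in ppe:
            values[:, j] /= ppe[taxon]
            adjusted.append(taxon)
        else:
            unadjusted.append(taxon)
    if unadjusted:
        logger.info("taxa without a PPE kept unadjusted: %s", unadjusted)
    return AdjustedCounts(
        site_ids=pollen.site_ids,
        taxa=list(pollen.taxa),
        values=values,
        adjusted_taxa=adjusted,
        unadjusted_taxa=unadjusted,
    )


def _resample_row(values: np.ndarray, depth: int, n_reps: int,
                  gen: np.random.Generator, law: str) -> np.ndarray:
    """Per-draw richness for one site's adjusted values."""
    total = values.sum()
    if total <= 0:
        raise ValueError("all-zero adjusted sample")
    if law == "multinomial":
        draws = gen.multinomial(depth, values / total, size=n_reps)
    elif law == "round-then-hypergeometric":
        ints = np.rint(values).astype(np.int64)
        if ints.sum() < depth:
            raise ValueError(
                f"rounded adjusted total {ints.sum()} < depth {depth}; "
                "use the multinomial law for shallow adjusted samples"
            )
        draws = gen.multivariate_hypergeometric(ints, depth, size=n_reps)
    else:
        raise ValueError(f"unknown resampling law {law!r}")
    return (draws > 0).sum(axis=1)


def resample_adjusted(adjusted: AdjustedCounts, depth: int = DEFAULT_ADJUSTED_DEPTH,
                      n_reps: int = DEFAULT_REPS, rng_seed: int = 0,
                      law: str = "multinomial") -> RarefactionResult:
    """Resample adjusted assemblages to ``depth`` grains; median richness per site.

    Probabilities are normalised per site, so multiplying every PPE (hence
    every adjusted value) by a constant leaves the richness distribution
    unchanged.
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    medians = []
    for i, row in enumerate(adjusted.values):
        reps = _resample_row(row, depth, n_reps, _site_rng(rng_seed, i), law)
        medians.append(float(np.median(reps)))
    return RarefactionResult(
        site_ids=list(adjusted.site_ids),
        depth=depth,
        n_reps=n_reps,
        richness_median=np.array(medians),
    )
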