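"""Empirical null by chromosome permutation, and permutation-based FDR.

Chromosomes are redistributed across individuals *within* populations: for
every (chromosome, population) block the per-sample diploid genotype vectors
are shuffled across the population's samples.  Within-chromosome structure is
preserved exactly while cross-chromosome association is destroyed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from icld.composite_ld import PairScanResult
from icld.genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)


def permute_chromosomes(
    matrix: GenotypeMatrix, seed: int | np.random.Generator = 0
) -> GenotypeMatrix:
    """Return a copy with chromosomes randomly reassigned to individuals.

    Independently for each chromosome and each population, the genotype rows
    of that chromosome block are permuted across the population's samples.
    Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = matrix.copy()
    chroms = matrix.chroms
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        for pop, rows in matrix.pop_indices().items():
            perm = rng.permutation(len(rows))
            out.genotypes[np.ix_(rows, cols)] = matrix.genotypes[np.ix_(rows[perm], cols)]
    return out


def empirical_fdr(
    observed_p: np.ndarray,
    permuted_p_replicates: list[np.ndarray],
    monotone: bool = False,
) -> np.ndarray:
    """Per-pair empirical FDR from chromosome-permutation replicates.

    FDR(t) = [mean over replicates of #{permuted p <= t}] / #{observed p <= t},
    evaluated at each observed pair's own p (ties use <=) and clipped to
    [0, 1].  The raw count ratio is not monotone in t; ``monotone=True``
    applies q-value-style smoothing (each pair gets the minimum FDR over
    thresholds at or above its own p).
    """
    obs = np.asarray(observed_p, dtype=float)
    if obs.size == 0:
        return obs.copy()
    if not permuted_p_replicates:
        raise ValueError("at least one permutation replicate is required")
    order = np.argsort(obs, kind="mergesort")
    sorted_obs = obs[order]
    # observed count at each pair's own p, with <= tie handling
    n_obs_le = np.searchsorted(sorted_obs, obs, side="right").astype(float)
    n_perm_le = np.zeros_like(obs)
    for rep in permuted_p_replicates:
        rep_sorted = np.sort(np.asarray(rep, dtype=float))
        n_perm_le += np.searchsorted(rep_sorted, obs, side="right")
    n_perm_le /= len(permuted_p_replicates)
    with np.errstate(invalid="ignore", divide="ignore"):
        fdr = np.where(n_obs_le > 0, n_perm_le / n_obs_le, 1.0)
    fdr = np.clip(fdr, 0.0, 1.0)
    if monotone:
        ranked = fdr[order]
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(fdr)
        out[order] = ranked
        return out
    return fdr


@dataclass
class LinkSet:
    """Pairs significant at the configured empirical-FDR cutoff.

    ``pairs`` is a subset of the scan table restricted to pairs with
    FDR <= ``fdr_cutoff`` and positive pooled association; ``p_threshold``
    is the largest combined p among retained pairs (NaN when empty).
    """

    pairs: pd.DataFrame
    fdr_cutoff: float
    p_threshold: float
    seed: int

    def __len__(self) -> int:
        return len(self.pairs)

    def drop_variants(self, variant_idx: np.ndarray) -> "LinkSet":
        """Remove pairs containing any of the given variant indices."""
        bad = set(np.asarray(variant_idx).tolist())
        keep = ~(
            self.pairs["a_idx"].isin(bad) | self.pairs["b_idx"].isin(bad)
        ).to_numpy()
        return LinkSet(
            pairs=self.pairs[keep].reset_index(drop=True),
            fdr_cutoff=self.fdr_cutoff,
            p_threshold=self.p_threshold,
            seed=self.seed,
        )


def link_set(
    scan: PairScanResult,
    fdr: np.ndarray,
    fdr_cutoff: float = 0.05,
    positive_only: bool = True,
    seed: int = 0,
) -> LinkSet:
    """Select the significant link set at an empirical-FDR cutoff.

    By default only positively associated pairs (pooled D > 0) are retained,
    matching the restriction of the analysis to positive associations.
    """
    table = scan.table.copy()
    table["fdr"] = np.asarray(fdr, dtype=float)
    keep = table["fdr"].to_numpy() <= fdr_cutoff
    if positive_only:
        keep &= table["d_pooled"].to_numpy() > 0
    pairs = table[keep].reset_index(drop=True)
    p_thr = float(pairs["p_combined"].max()) if len(pairs) else float("nan")
    if not len(pairs):
        logger.info("empty link set at FDR <= %g", fdr_cutoff)
    return LinkSet(pairs=pairs, fdr_cutoff=fdr_cutoff, p_threshold=p_thr, seed=seed)
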