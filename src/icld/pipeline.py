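"""Full iterative detection pipeline.

Step 1 runs once: cross-chromosome pair scan, chromosome-permutation null,
empirical FDR, significant link set.  Then, iteratively: per-sample nAB is
computed over the current link set (pairs containing previously flagged
variants removed), the variance and clustering-support tests are run against
the permuted nulls, and — while either test shows a significant departure from the permuted
null — the genome-wide candidate scan flags variants predicted by nAB.
Iteration stops when neither step-2 test is significant or the iteration cap
is reached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from icld.composite_ld import LDScanConfig, PairScanResult, scan_pairs
from icld.error_model import CandidateScanConfig, candidate_scan
from icld.genotype_io import GenotypeMatrix
from icld.nab_profile import (
    NabProfile,
    clustering_support_by_population,
    compute_nab,
    nab_variance_test,
)
from icld.permutation_null import LinkSet, empirical_fdr, link_set, permute_chromosomes

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    fdr_cutoff: float = 0.05
    n_permutations: int = 3
    # the clustering-support rank test needs a finer-grained null than the
    # 3 scan permutations (its minimal p is 1/(R+1)); profiles over the link
    # set are cheap to recompute, so a larger dedicated null is used
    n_cluster_permutations: int = 100
    prescreen_alpha: float = 0.01
    q_cutoff: float = 0.05
    max_iterations: int = 5
    stop_alpha: float = 0.05
    k_max: int = 9
    max_pairs: int | None = None
    exact_prescreen_factor: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        for name in ("fdr_cutoff", "prescreen_alpha", "q_cutoff", "stop_alpha"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class IterationRecord:
    iteration: int
    n_links: int
    variance: pd.DataFrame
    clustering: pd.DataFrame
    significant: bool
    n_flagged: int


@dataclass
class PipelineResult:
    scan: PairScanResult | None
    links: LinkSet | None
    fdr: np.ndarray | None
    candidates: pd.DataFrame
    profiles: list[NabProfile] = field(default_factory=list)
    iterations: list[IterationRecord] = field(default_factory=list)
    stop_reason: str = ""

    @property
    def flagged(self) -> pd.DataFrame:
        if self.candidates.empty:
            return self.candidates
        return self.candidates[self.candidates["flagged"]]


def _empty_candidates(matrix: GenotypeMatrix) -> pd.DataFrame:
    table = matrix.variants[["chrom", "pos", "ref", "alt"]].copy()
    table["prescreen_p"] = np.nan
    table["lrt_p"] = np.nan
    table["bh_q"] = 1.0
    table["flagged"] = False
    table["iteration"] = 0
    return table


def step1_links(
    matrix: GenotypeMatrix, config: PipelineConfig
) -> tuple[PairScanResult, list[GenotypeMatrix], np.ndarray, LinkSet]:
    """Pair scan, permutation replicates, empirical FDR and the link set."""
    scan_cfg = LDScanConfig(
        exact_prescreen_factor=config.exact_prescreen_factor,
        max_pairs=config.max_pairs,
        seed=config.seed,
    )
    logger.info("step 1: scanning cross-chromosome pairs (seed=%d)", config.seed)
    scan = scan_pairs(matrix, scan_cfg)
    rng = np.random.default_rng(config.seed)
    perm_matrices = [
        permute_chromosomes(matrix, rng) for _ in range(config.n_permutations)
    ]
    perm_p = [scan_pairs(pm, scan_cfg).table["p_combined"].to_numpy() for pm in perm_matrices]
    fdr = empirical_fdr(scan.table["p_combined"].to_numpy(), perm_p)
    links = link_set(scan, fdr, fdr_cutoff=config.fdr_cutoff, seed=config.seed)
    logger.info(
        "step 1: %d links at FDR <= %g (p threshold %g)",
        len(links), config.fdr_cutoff, links.p_threshold,
    )
    return scan, perm_matrices, fdr, links


def run_pipeline(matrix: GenotypeMatrix, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full iterative error-detection pipeline on a genotype matrix."""
    if config is None:
        config = PipelineConfig()
    scan, perm_matrices, fdr, links = step1_links(matrix, config)

    result = PipelineResult(
        scan=scan, links=links, fdr=fdr, candidates=_empty_candidates(matrix)
    )
    if len(links) == 0:
        result.stop_reason = "no significant links: dataset appears homogeneous"
        logger.info(result.stop_reason)
        return result

    flagged_idx: np.ndarray = np.array([], dtype=int)
    current_links = links
    for iteration in range(1, config.max_iterations + 1):
        current_links = current_links.drop_variants(flagged_idx)
        if len(current_links) == 0:
            result.stop_reason = "link set exhausted after removing flagged variants"
            logger.info(result.stop_reason)
            break
        profile = compute_nab(matrix, current_links)
        profile.permuted = [
            compute_nab(pm, current_links).values for pm in perm_matrices
        ]
        result.profiles.append(profile)

        perm_profiles = [
            NabProfile(v, profile.samples, profile.n_pairs) for v in profile.permuted
        ]
        variance = nab_variance_test(profile, perm_profiles)
        cluster_rng = np.random.default_rng(config.seed + 7919 * iteration)
        cluster_perm_profiles = [
            compute_nab(permute_chromosomes(matrix, cluster_rng), current_links)
            for _ in range(config.n_cluster_permutations)
        ]
        clustering = clustering_support_by_population(
            profile, cluster_perm_profiles, k_max=config.k_max, seed=config.seed
        )
        var_sig = bool((variance["p"].dropna() < config.stop_alpha).any())
        clu_sig = bool((clustering["p"].dropna() < config.stop_alpha).any())
        significant = var_sig or clu_sig
        logger.info(
            "iteration %d: %d links, variance significant=%s, clustering significant=%s",
            iteration, len(current_links), var_sig, clu_sig,
        )

        n_flagged = 0
        if significant or config.max_iterations == 1:
            cand = candidate_scan(
                matrix,
                profile,
                CandidateScanConfig(config.prescreen_alpha, config.q_cutoff),
                iteration=iteration,
                exclude=flagged_idx,
                links=current_links,
            )
            newly = np.flatnonzero(cand["flagged"].to_numpy())
            n_flagged = len(newly)
            # merge: keep earlier iterations' flags, update the rest
            keep_old = np.isin(np.arange(matrix.n_variants), flagged_idx)
            merged = result.candidates.copy()
            merged.loc[~keep_old, ["prescreen_p", "lrt_p", "bh_q", "flagged", "iteration"]] = (
                cand.loc[~keep_old, ["prescreen_p", "lrt_p", "bh_q", "flagged", "iteration"]]
            )
            result.candidates = merged
            flagged_idx = np.union1d(flagged_idx, newly)

        result.iterations.append(
            IterationRecord(
                iteration=iteration,
                n_links=len(current_links),
                variance=variance,
                clustering=clustering,
                significant=significant,
                n_flagged=n_flagged,
            )
        )
        if not significant:
            result.stop_reason = "step-2 tests non-significant: burden homogeneous"
            logger.info(result.stop_reason)
            break
        if n_flagged == 0:
            result.stop_reason = "no new variants flagged"
            logger.info(result.stop_reason)
            break
    else:
        result.stop_reason = "maximum iterations reached"
        logger.info(result.stop_reason)
    return result
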