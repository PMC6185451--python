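"""Genotype- and depth-based characterization of flagged candidates.

Candidates are compared against frequency-matched background variants using
signals expected of recurrent false heterozygotes: exact Hardy-Weinberg
heterozygote excess, transition/transversion composition, and (when AD depth
fields are present) binomial allele imbalance at heterozygous calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import binomtest

from icld.genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _hwe_het_log_probs(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact conditional distribution of heterozygote counts.

    Given ``n`` diploid samples and ``n_minor`` minor-allele copies, returns
    the attainable heterozygote counts (same parity as ``n_minor``) and their
    log-probabilities under random union of gametes.
    """
    n_major = 2 * n - n_minor
    hets = np.arange(n_minor % 2, min(n_minor, n_major) + 1, 2)
    n_hom_minor = (n_minor - hets) // 2
    n_hom_major = n - hets - n_hom_minor
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(n_hom_minor + 1)
        - gammaln(n_hom_major + 1)
        - (gammaln(2 * n + 1) - gammaln(n_minor + 1) - gammaln(n_major + 1))
    )
    return hets, logp


def hwe_excess_het_test(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Exact one-tailed HWE test toward heterozygote *excess*.

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the probabilities of configurations with at least the
    observed number of heterozygotes.  Monomorphic input gives p = 1.
    """
    n = n_hom_minor + n_het + n_hom_major
    if n <= 0:
        raise ValueError("empty genotype counts")
    n_minor = 2 * n_hom_minor + n_het
    if n_minor == 0 or n_minor == 2 * n:
        return 1.0
    hets, logp = _hwe_het_log_probs(n, n_minor)
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    return float(np.clip(probs[hets >= n_het].sum(), 0.0, 1.0))


def hwe_excess_het_pvalues(matrix: GenotypeMatrix, variant_idx: np.ndarray) -> np.ndarray:
    """Pooled-cohort heterozygote-excess p per selected variant."""
    out = np.empty(len(variant_idx))
    for k, j in enumerate(np.asarray(variant_idx)):
        g = matrix.genotypes[:, j]
        g = g[g != MISSING]
        out[k] = hwe_excess_het_test(int((g == 2).sum()), int((g == 1).sum()), int((g == 0).sum()))
    return out


def allele_imbalance_test(ref_depth: int, alt_depth: int) -> float:
    """Two-sided exact binomial p of read support deviating from 50/50."""
    total = ref_depth + alt_depth
    if total < 1:
        raise ValueError("zero total depth")
    return float(binomtest(alt_depth, total, 0.5).pvalue)


def is_transition(ref: str, alt: str) -> bool:
    return (ref.upper(), alt.upper()) in _TRANSITIONS


def tstv_summary(variants: pd.DataFrame) -> dict[str, float]:
    """Transition/transversion counts and ratio for a variant set."""
    n_ts = n_tv = 0
    for ref, alt in zip(variants["ref"], variants["alt"]):
        if len(ref) != 1 or len(alt) != 1 or ref == alt:
            continue
        if is_transition(ref, alt):
            n_ts += 1
        else:
            n_tv += 1
    ratio = n_ts / n_tv if n_tv else float("inf") if n_ts else float("nan")
    return {"transitions": n_ts, "transversions": n_tv, "ts_tv_ratio": ratio}


def match_background(
    candidate_idx: np.ndarray,
    pool_idx: np.ndarray,
    maf: np.ndarray,
    bin_width: float = 0.01,
    seed: int = 0,
) -> np.ndarray:
    """Frequency-matched background sample, one per candidate where possible.

    Pool variants are binned by MAF at ``bin_width`` resolution and sampled
    without replacement from each candidate's bin (seeded).
    """
    rng = np.random.default_rng(seed)
    maf = np.asarray(maf, dtype=float)
    pool_idx = np.asarray(pool_idx)
    pool_idx = pool_idx[~np.isin(pool_idx, candidate_idx)]
    bins = np.floor(maf / bin_width).astype(int)
    chosen: list[int] = []
    pool_by_bin: dict[int, list[int]] = {}
    for j in pool_idx:
        pool_by_bin.setdefault(bins[j], []).append(int(j))
    for b in pool_by_bin.values():
        rng.shuffle(b)
    for j in np.asarray(candidate_idx):
        b = pool_by_bin.get(bins[j])
        if b:
            chosen.append(b.pop())
        else:
            logger.warning("no background variant available in MAF bin %d", bins[j])
    return np.array(sorted(chosen), dtype=int)


@dataclass
class DiagnosticReport:
    per_variant: pd.DataFrame
    summary: pd.DataFrame


def diagnose(
    matrix: GenotypeMatrix,
    candidate_idx: np.ndarray,
    bin_width: float = 0.01,
    seed: int = 0,
) -> DiagnosticReport:
    """Compare candidates against frequency-matched background variants.

    Runs the heterozygote-excess test and Ts/Tv classification per variant;
    when the matrix carries AD depths, adds the median allele-imbalance p
    over putatively heterozygous calls with at least one read on each allele.
    """
    candidate_idx = np.asarray(candidate_idx, dtype=int)
    maf_cols = matrix.maf_columns()
    maf = np.nanmax(matrix.variants[maf_cols].to_numpy(), axis=1)
    pool = np.flatnonzero(maf > 0)
    background_idx = match_background(candidate_idx, pool, maf, bin_width, seed)

    rows = []
    for label, idx in (("candidate", candidate_idx), ("background", background_idx)):
        if len(idx) == 0:
            continue
        hwe_p = hwe_excess_het_pvalues(matrix, idx)
        for k, j in enumerate(idx):
            ref = matrix.variants["ref"].iloc[j]
            alt = matrix.variants["alt"].iloc[j]
            ai_p = np.nan
            if matrix.depths is not None:
                het = np.flatnonzero(matrix.genotypes[:, j] == 1)
                ps = [
                    allele_imbalance_test(int(matrix.depths[i, j, 0]), int(matrix.depths[i, j, 1]))
                    for i in het
                    if matrix.depths[i, j, 0] >= 1 and matrix.depths[i, j, 1] >= 1
                ]
                if ps:
                    ai_p = float(np.median(ps))
            rows.append(
                (
                    label,
                    matrix.variants["chrom"].iloc[j],
                    matrix.variants["pos"].iloc[j],
                    maf[j],
                    hwe_p[k],
                    "transition" if is_transition(ref, alt) else "transversion",
                    ai_p,
                )
            )
    per_variant = pd.DataFrame(
        rows,
        columns=["set", "chrom", "pos", "maf", "hwe_excess_het_p", "substitution", "allele_imbalance_p"],
    )
    summaries = []
    for label, grp in per_variant.groupby("set"):
        ts = (grp["substitution"] == "transition").sum()
        tv = (grp["substitution"] == "transversion").sum()
        summaries.append(
            (
                label,
                len(grp),
                float(grp["hwe_excess_het_p"].median()),
                float((grp["hwe_excess_het_p"] < 0.05).mean()),
                ts / tv if tv else float("nan"),
            )
        )
    summary = pd.DataFrame(
        summaries,
        columns=["set", "n", "median_hwe_p", "frac_hwe_p_lt_05", "ts_tv_ratio"],
    )
    return DiagnosticReport(per_variant=per_variant, summary=summary)
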