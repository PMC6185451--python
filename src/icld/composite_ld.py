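"""Composite genotypic LD between variants on different chromosomes.

For two unphased biallelic loci with minor alleles A and B, the 3x3 table of
joint genotype counts (n1..n9) yields a maximum-likelihood weighted count of
AB gametes

    sigma_AB = 2*n1 + n2 + n4 + n5/2

and the composite disequilibrium D_AB = sigma_AB/n - 2*pA*pB.  Equivalently,
with genotypes g coded as minor-allele counts, sigma_AB = sum(gA*gB)/2 and
D_AB is half the genotype covariance — which is what the vectorized pair scan
exploits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import log_ndtr
from scipy.stats import chi2, hypergeom

from icld.genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

_EPS = np.finfo(float).eps
_DENOM_FLOOR = 1e-12


@dataclass(frozen=True)
class GenotypeCrossTab:
    """3x3 joint genotype counts; rows = A/A, A/a, a/a, cols = B/B, B/b, b/b."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (3, 3) or (c < 0).any():
            raise ValueError("cross-tab must be a non-negative 3x3 count table")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def flat(self) -> np.ndarray:
        """Counts n1..n9 in row-major order."""
        return self.counts.ravel()


@dataclass
class PairStats:
    """Composite-LD summary for one variant pair in one population."""

    sigma_ab: float
    n: int
    p_a: float
    p_b: float
    d_ab: float
    p_approx: float | None = None
    p_exact: float | None = None


def cross_tab(genotypes_a: np.ndarray, genotypes_b: np.ndarray) -> GenotypeCrossTab:
    """Tabulate joint genotypes of two loci with pairwise deletion of missing."""
    ga = np.asarray(genotypes_a)
    gb = np.asarray(genotypes_b)
    if ga.shape != gb.shape:
        raise ValueError("genotype vectors must have equal length")
    ok = (ga != MISSING) & (gb != MISSING)
    ga, gb = ga[ok], gb[ok]
    counts = np.zeros((3, 3), dtype=np.int64)
    # row 0 is A/A (two minor alleles), so index by 2 - g
    np.add.at(counts, (2 - ga, 2 - gb), 1)
    return GenotypeCrossTab(counts)


def sigma_ab(tab: GenotypeCrossTab) -> float:
    """ML-weighted count of AB gametes: 2*n1 + n2 + n4 + n5/2."""
    c = tab.counts
    return 2.0 * c[0, 0] + c[0, 1] + c[1, 0] + c[1, 1] / 2.0


def _freqs(tab: GenotypeCrossTab) -> tuple[float, float]:
    c = tab.counts
    n = tab.n
    p_a = (2 * c[0, :].sum() + c[1, :].sum()) / (2.0 * n)
    p_b = (2 * c[:, 0].sum() + c[:, 1].sum()) / (2.0 * n)
    return float(p_a), float(p_b)


def pair_stats(tab: GenotypeCrossTab) -> PairStats:
    """Compute sigma_AB, allele frequencies and D_AB for one table."""
    n = tab.n
    if n == 0:
        raise ValueError("empty cross-tab")
    p_a, p_b = _freqs(tab)
    s = sigma_ab(tab)
    d = s / n - 2.0 * p_a * p_b
    return PairStats(sigma_ab=s, n=n, p_a=p_a, p_b=p_b, d_ab=d)


def t2_stat(tab: GenotypeCrossTab) -> float:
    """Chi-square-based T2 statistic for composite LD.

    T2 = n * D_AB^2 / [(pA(1-pA)+D_A)(pB(1-pB)+D_B)] where D_A, D_B are the
    within-locus Hardy-Weinberg disequilibrium coefficients (homozygote
    excess).  The denominator is floored to avoid division by zero on
    degenerate tables.
    """
    c = tab.counts
    n = tab.n
    st = pair_stats(tab)
    d_a = c[0, :].sum() / n - st.p_a**2
    d_b = c[:, 0].sum() / n - st.p_b**2
    va = st.p_a * (1.0 - st.p_a) + d_a
    vb = st.p_b * (1.0 - st.p_b) + d_b
    denom = va * vb
    if denom < _DENOM_FLOOR:
        return 0.0
    return n * st.d_ab**2 / denom


def t2_pvalue(tab: GenotypeCrossTab) -> float:
    """Approximate two-sided p-value of T2 against chi-square with 1 df."""
    c = tab.counts
    n = tab.n
    st = pair_stats(tab)
    d_a = c[0, :].sum() / n - st.p_a**2
    d_b = c[:, 0].sum() / n - st.p_b**2
    denom = (st.p_a * (1 - st.p_a) + d_a) * (st.p_b * (1 - st.p_b) + d_b)
    if denom < _DENOM_FLOOR:
        logger.warning("degenerate cross-tab in T2; returning p = 1")
        return 1.0
    return float(chi2.sf(n * st.d_ab**2 / denom, df=1))


def carrier_table(tab: GenotypeCrossTab) -> tuple[int, int, int, int]:
    """Collapse the 3x3 table to carrier status: (k, nA, nB, n).

    ``k`` counts samples carrying at least one minor allele at both loci,
    ``nA``/``nB`` are the carrier margins.
    """
    c = tab.counts
    k = int(c[:2, :2].sum())
    n_a = int(c[:2, :].sum())
    n_b = int(c[:, :2].sum())
    return k, n_a, n_b, tab.n


def exact_pvalue_positive(tab: GenotypeCrossTab) -> float:
    """One-tailed exact p for *positive* association of minor alleles.

    Defined on the 2x2 carrier-status table under the hypergeometric null:
    the probability of at least the observed number of double-carriers given
    the carrier margins.  Degenerate margins give p = 1.
    """
    k, n_a, n_b, n = carrier_table(tab)
    if n == 0 or n_a in (0, n) or n_b in (0, n):
        return 1.0
    return float(hypergeom.sf(k - 1, n, n_a, n_b))


def exact_pvalue_negative(tab: GenotypeCrossTab) -> float:
    """One-tailed exact p for depletion of double-carriers (repulsion)."""
    k, n_a, n_b, n = carrier_table(tab)
    if n == 0 or n_a in (0, n) or n_b in (0, n):
        return 1.0
    return float(hypergeom.cdf(k, n, n_a, n_b))


def combine_pvalues(p_list: Sequence[float]) -> float:
    """Fisher's method: -2*sum(ln p) against chi-square with 2k df.

    Each p is floored at machine epsilon before taking logs.
    """
    ps = np.asarray(p_list, dtype=float)
    if ps.size == 0:
        raise ValueError("cannot combine an empty p-value list")
    if np.any((ps <= 0) | (ps > 1)):
        ps = np.clip(ps, _EPS, 1.0)
    stat = -2.0 * np.sum(np.log(np.maximum(ps, _EPS)))
    return float(chi2.sf(stat, df=2 * ps.size))


@dataclass
class LDScanConfig:
    """Configuration of the cross-chromosome pair scan.

    ``exact_prescreen_factor``/nSNP^2 is the approximate-p cutoff below which
    the exact test is run; ``max_pairs`` optionally subsamples the candidate
    cross-chromosome pairs with a seeded uniform draw.
    """

    exact_prescreen_factor: float = 100.0
    max_pairs: int | None = None
    seed: int = 0
    negative: bool = False
    min_samples: int = 2


@dataclass
class PairScanResult:
    """Outcome of :func:`scan_pairs`.

    ``table`` has one row per tested cross-chromosome pair with columns
    ``a_idx``, ``b_idx``, ``p_approx`` (Fisher-combined T2 p), ``p_exact``
    (Fisher-combined exact p; NaN when not prescreened), ``p_combined``
    (exact where available, approximate otherwise) and ``d_pooled``.
    """

    table: pd.DataFrame
    n_snp: int
    exact_threshold: float
    populations: list[str]
    seed: int

    @property
    def p_combined(self) -> np.ndarray:
        return self.table["p_combined"].to_numpy()

    def annotate(self, variants: pd.DataFrame) -> pd.DataFrame:
        t = self.table.copy()
        for side in ("a", "b"):
            idx = t[f"{side}_idx"].to_numpy()
            t[f"chrom_{side}"] = variants["chrom"].to_numpy()[idx]
            t[f"pos_{side}"] = variants["pos"].to_numpy()[idx]
        return t


def _pair_moment_matrices(g_pop: np.ndarray):
    """Cross-pair joint moments with pairwise deletion, via masked matmuls.

    Returns (n, sumA, sumB, sumAB, sumA2, sumB2) where entry (i, j) of each
    matrix is the corresponding sum over samples non-missing at both variant
    i and variant j.
    """
    mask = (g_pop != MISSING).astype(np.float64)
    gz = np.where(g_pop == MISSING, 0, g_pop).astype(np.float64)
    gz2 = gz * gz
    n = mask.T @ mask
    s_a = gz.T @ mask
    s_ab = gz.T @ gz
    s_a2 = gz2.T @ mask
    return n, s_a, s_a.T, s_ab, s_a2, s_a2.T


def cross_chromosome_pairs(chroms: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays (i, j), i < j, of all pairs spanning two chromosomes."""
    m = len(chroms)
    iu, ju = np.triu_indices(m, k=1)
    keep = chroms[iu] != chroms[ju]
    return iu[keep].astype(np.int64), ju[keep].astype(np.int64)


def scan_pairs(matrix: GenotypeMatrix, config: LDScanConfig | None = None) -> PairScanResult:
    """Scan all cross-chromosome variant pairs for composite LD.

    Per population the T2 approximate p is computed for every candidate pair;
    per-population p-values are combined with Fisher's method.  The exact
    one-tailed carrier test is run only for pairs whose combined approximate
    p falls below ``exact_prescreen_factor / nSNP^2``, and its combined value
    replaces ``p_combined`` for those pairs.
    """
    if config is None:
        config = LDScanConfig()
    chroms = matrix.chroms
    if len(np.unique(chroms)) < 2:
        raise ValueError("pair scan requires variants on at least 2 chromosomes")

    iu, ju = cross_chromosome_pairs(chroms)
    if config.max_pairs is not None and config.max_pairs < len(iu):
        rng = np.random.default_rng(config.seed)
        pick = np.sort(rng.choice(len(iu), size=config.max_pairs, replace=False))
        iu, ju = iu[pick], ju[pick]
    n_pairs = len(iu)
    n_snp = matrix.n_variants
    exact_threshold = config.exact_prescreen_factor / float(n_snp) ** 2

    pop_rows = matrix.pop_indices()
    fisher_stat = np.zeros(n_pairs)
    n_testable = np.zeros(n_pairs, dtype=np.int32)
    d_pooled = np.zeros(n_pairs)
    n_total = np.zeros(n_pairs)
    pop_logp: dict[str, np.ndarray] = {}

    for pop, rows in pop_rows.items():
        g_pop = matrix.genotypes[rows]
        n, s_a, s_b, s_ab, s_a2, s_b2 = _pair_moment_matrices(g_pop)
        n_p = n[iu, ju]
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_a = s_a[iu, ju] / n_p
            mean_b = s_b[iu, ju] / n_p
            cov = s_ab[iu, ju] / n_p - mean_a * mean_b
            var_a = s_a2[iu, ju] / n_p - mean_a**2
            var_b = s_b2[iu, ju] / n_p - mean_b**2
            denom = var_a * var_b / 4.0  # vA*vB in gamete-frequency units
            t2 = np.where(denom > _DENOM_FLOOR, n_p * (cov / 2.0) ** 2 / denom, 0.0)
        testable = (n_p >= config.min_samples) & (denom > _DENOM_FLOOR)
        # chi2(1 df) upper tail: sf(t) = 2*Phi(-sqrt(t)); log form is stable
        logp = np.where(
            testable,
            np.log(2.0) + log_ndtr(-np.sqrt(np.where(testable, t2, 0.0))),
            0.0,
        )
        fisher_stat += np.where(testable, -2.0 * np.maximum(logp, np.log(_EPS)), 0.0)
        n_testable += testable.astype(np.int32)
        pop_logp[pop] = np.where(testable, logp, np.nan)
        # pooled D is the sample-size-weighted average of per-population D
        d_pooled += np.where(testable, n_p * cov / 2.0, 0.0)
        n_total += np.where(testable, n_p, 0.0)

    any_testable = n_testable > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        if len(pop_rows) == 1:
            # Fisher's method with k = 1 is the identity: sf(-2*ln p, 2) = p
            p_approx = np.where(any_testable, np.exp(-fisher_stat / 2.0), np.nan)
        else:
            p_approx = np.where(
                any_testable, chi2.sf(fisher_stat, df=2 * n_testable), np.nan
            )
        d_pooled = np.where(any_testable, d_pooled / np.maximum(n_total, 1.0), np.nan)

    p_exact = np.full(n_pairs, np.nan)
    prescreened = np.flatnonzero(any_testable & (p_approx < exact_threshold))
    for k in prescreened:
        ps = []
        for pop, rows in pop_rows.items():
            if np.isnan(pop_logp[pop][k]):
                continue
            tab = cross_tab(
                matrix.genotypes[rows, iu[k]], matrix.genotypes[rows, ju[k]]
            )
            if config.negative:
                ps.append(exact_pvalue_negative(tab))
            else:
                ps.append(exact_pvalue_positive(tab))
        if ps:
            p_exact[k] = combine_pvalues(ps)

    p_combined = np.where(np.isnan(p_exact), p_approx, p_exact)
    table = pd.DataFrame(
        {
            "a_idx": iu.astype(np.int32),
            "b_idx": ju.astype(np.int32),
            "p_approx": p_approx,
            "p_exact": p_exact,
            "p_combined": p_combined,
            "d_pooled": d_pooled,
        }
    )
    table = table[any_testable].reset_index(drop=True)
    return PairScanResult(
        table=table,
        n_snp=n_snp,
        exact_threshold=exact_threshold,
        populations=list(pop_rows),
        seed=config.seed,
    )
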