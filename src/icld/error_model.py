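"""Variant-level error calling from the per-sample nAB burden.

Every variant is first screened with a fast per-population logistic model of
minor-allele presence per chromosome copy on z(nAB) (slope LRT, populations
combined with Fisher's method).  Variants with combined p < 0.01 then get the
full mixed-model likelihood-ratio test:

    full:  presence ~ z_nab + (1|population) + (0 + z_nab|population) + (1|sample)
    null:  presence ~ (1|population) + (1|sample)

fitted by a deterministic Laplace approximation of the marginal likelihood,
with the LRT referred to chi-square with 2 df (fixed slope + random-slope
variance; conservative under boundary effects).  BH correction is applied
across all variants entering the mixed model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

from icld.composite_ld import combine_pvalues
from icld.genotype_io import MISSING, GenotypeMatrix
from icld.nab_profile import NabProfile

logger = logging.getLogger(__name__)

_EPS = np.finfo(float).eps


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(ranked, 1.0)
    return q


# ---------------------------------------------------------------------------
# fast logistic prescreen
# ---------------------------------------------------------------------------

def _binom2_loglik(eta: np.ndarray, k: np.ndarray) -> float:
    # binomial(n=2) logistic log-likelihood, per-sample counts k of 2
    return float(np.sum(k * eta - 2.0 * np.logaddexp(0.0, eta)))


def _fit_logistic_binom2(
    k: np.ndarray, x: np.ndarray, ridge: float = 1e-8, max_iter: int = 50
) -> tuple[np.ndarray, float, bool]:
    """Newton fit of logit P(allele) = b0 + b1*x on per-sample counts k of 2.

    A tiny ridge on the slope keeps separated data finite.  Returns
    (coefficients, unpenalized log-likelihood, separation flag).
    """
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    pen = np.array([0.0, ridge])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (k - 2.0 * mu) - 2.0 * pen * beta
        w = 2.0 * mu * (1.0 - mu)
        hess = (X * w[:, None]).T @ X + 2.0 * np.diag(pen + 1e-12)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta_new = beta + step
        if not np.all(np.isfinite(beta_new)):
            break
        beta = beta_new
        if np.max(np.abs(step)) < 1e-10:
            break
    separated = bool(abs(beta[1]) > 8.0)
    eta = X @ beta
    return beta, _binom2_loglik(eta, k), separated


def _logistic_slope_lrt(k: np.ndarray, x: np.ndarray) -> tuple[float, bool]:
    """LRT p (1 df) of the z(nAB) slope against intercept-only."""
    n = len(k)
    p_hat = np.clip(k.sum() / (2.0 * n), 1e-12, 1 - 1e-12)
    eta0 = np.log(p_hat / (1.0 - p_hat))
    ll0 = _binom2_loglik(np.full(n, eta0), k)
    if np.ptp(x) == 0:
        return 1.0, False
    _, ll1, separated = _fit_logistic_binom2(k, x)
    stat = max(2.0 * (ll1 - ll0), 0.0)
    return float(chi2.sf(stat, df=1)), separated


def prescreen(
    variant_genotypes: np.ndarray, nab_profile: NabProfile
) -> tuple[float, bool]:
    """Per-population logistic LRT of allele presence on z(nAB), combined.

    Populations where the variant is monomorphic (among non-missing samples)
    are omitted from the Fisher combination.  Returns (combined p, separation
    flag); a variant absent everywhere returns p = NaN.
    """
    z = nab_profile.zscores()
    pops = nab_profile.samples["population"].to_numpy()
    g = np.asarray(variant_genotypes)
    ps: list[float] = []
    separated = False
    for pop in sorted(set(pops)):
        rows = pops == pop
        gp = g[rows]
        ok = gp != MISSING
        if not ok.any():
            continue
        k = gp[ok].astype(float)
        if k.min() == k.max():
            continue  # monomorphic here
        p, sep = _logistic_slope_lrt(k, z[rows][ok])
        ps.append(p)
        separated |= sep
    if not ps:
        return float("nan"), False
    return combine_pvalues(ps), separated


# ---------------------------------------------------------------------------
# Laplace-approximate logistic mixed model
# ---------------------------------------------------------------------------

class _GlmmDesign:
    """Two-rows-per-sample logistic design with block random effects.

    Genotype 2 -> responses (1, 1); 1 -> (1, 0) with the carrying copy
    arbitrary but fixed; 0 -> (0, 0).  The sample grouping factor absorbs
    the arbitrariness of the heterozygote copy assignment.
    """

    def __init__(
        self,
        g: np.ndarray,
        z: np.ndarray,
        pop_codes: np.ndarray,
        with_slope_effects: bool,
    ) -> None:
        ok = g != MISSING
        g, z, pop_codes = g[ok], z[ok], pop_codes[ok]
        s = len(g)
        self.y = np.empty(2 * s)
        self.y[0::2] = (g >= 1).astype(float)
        self.y[1::2] = (g == 2).astype(float)
        zz = np.repeat(z, 2)
        pp = np.repeat(pop_codes, 2)
        ss = np.repeat(np.arange(s), 2)
        n_pop = int(pop_codes.max()) + 1 if s else 0
        self.with_slope = with_slope_effects
        # fixed effects
        if with_slope_effects:
            self.X = np.column_stack([np.ones(2 * s), zz])
        else:
            self.X = np.ones((2 * s, 1))
        # random-effect design: [pop intercepts | pop slopes? | sample intercepts]
        blocks = [np.eye(n_pop)[pp]]
        self.block_sizes = [n_pop]
        if with_slope_effects:
            blocks.append(np.eye(n_pop)[pp] * zz[:, None])
            self.block_sizes.append(n_pop)
        blocks.append(np.eye(s)[ss])
        self.block_sizes.append(s)
        self.Z = np.concatenate(blocks, axis=1)
        self.q = self.Z.shape[1]
        self.n_fixed = self.X.shape[1]

    def block_index(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.block_sizes)), self.block_sizes)


def _laplace_loglik(design: _GlmmDesign, log_sigmas: np.ndarray) -> float:
    """Laplace-approximate marginal log-likelihood at given block variances.

    Fixed effects are folded into the joint penalized mode (profiled), and
    only the random effects are integrated out.
    """
    sig2 = np.exp(2.0 * np.asarray(log_sigmas))
    prec = 1.0 / sig2[design.block_index()]  # diag of D^-1, length q
    A = np.concatenate([design.X, design.Z], axis=1)
    p, q = design.n_fixed, design.q
    pen = np.concatenate([np.zeros(p), prec])
    theta = np.zeros(p + q)
    y = design.y

    def nll(t: np.ndarray) -> float:
        eta = A @ t
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta) + 0.5 * np.sum(pen * t * t))

    f = nll(theta)
    for _ in range(100):
        eta = A @ theta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = A.T @ (mu - y) + pen * theta
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        H = (A * w[:, None]).T @ A
        H[np.diag_indices_from(H)] += pen + 1e-10
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return -np.inf
        # backtracking line search on the penalized objective
        alpha = 1.0
        for _ls in range(30):
            cand = theta - alpha * step
            fc = nll(cand)
            if fc <= f:
                theta, f = cand, fc
                break
            alpha *= 0.5
        else:
            break
        if np.max(np.abs(alpha * step)) < 1e-8:
            break

    eta = A @ theta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    Zw = design.Z * w[:, None]
    H_bb = Zw.T @ design.Z
    H_bb[np.diag_indices_from(H_bb)] += prec
    sign, logdet = np.linalg.slogdet(H_bb)
    if sign <= 0:
        return -np.inf
    b = theta[p:]
    ll_data = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    ll = (
        ll_data
        - 0.5 * float(np.sum(prec * b * b))
        - 0.5 * float(np.sum(np.log(sig2[design.block_index()])))
        - 0.5 * logdet
    )
    return ll


def _fit_glmm(design: _GlmmDesign, x0: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Optimize the Laplace marginal over log standard deviations."""
    n_blocks = len(design.block_sizes)
    if x0 is None:
        x0 = np.full(n_blocks, -0.5)

    def neg(ls: np.ndarray) -> float:
        ls = np.clip(ls, -6.0, 3.0)
        return -_laplace_loglik(design, ls)

    res = optimize.minimize(
        neg, x0, method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
    )
    best = -res.fun
    return float(best), np.clip(res.x, -6.0, 3.0)


def mixed_lrt(
    variant_genotypes: np.ndarray,
    nab_profile: NabProfile,
    populations: np.ndarray | None = None,
) -> float:
    """Mixed-model LRT p for allele presence predicted by z(nAB).

    Full model: fixed z(nAB) slope, population random intercept, population
    random z(nAB) slope, sample random intercept.  Null model drops both nAB
    terms.  p from chi-square with 2 df.  If the fit degenerates the fixed
    part is still bounded by a safeguard evaluation at the null's variance
    components, keeping ll_full >= ll_null.
    """
    z = nab_profile.zscores()
    if populations is None:
        populations = nab_profile.samples["population"].to_numpy()
    pop_codes = pd.Categorical(populations).codes.astype(int)
    g = np.asarray(variant_genotypes)
    ok = g != MISSING
    if not ok.any() or np.ptp(g[ok]) == 0:
        return 1.0
    if np.ptp(z) == 0:
        return 1.0

    null_design = _GlmmDesign(g, z, pop_codes, with_slope_effects=False)
    ll_null, theta_null = _fit_glmm(null_design)

    full_design = _GlmmDesign(g, z, pop_codes, with_slope_effects=True)
    # start the full fit from the null's variance components, with a near-zero
    # random-slope variance: guarantees ll_full >= ll_null up to optimizer noise
    x0 = np.array([theta_null[0], -6.0, theta_null[1]])
    ll_full, _ = _fit_glmm(full_design, x0=x0)
    ll_full = max(ll_full, _laplace_loglik(full_design, x0))

    stat = max(2.0 * (ll_full - ll_null), 0.0)
    return float(chi2.sf(stat, df=2))


# ---------------------------------------------------------------------------
# genome-wide candidate scan
# ---------------------------------------------------------------------------

@dataclass
class CandidateScanConfig:
    prescreen_alpha: float = 0.01
    q_cutoff: float = 0.05


def candidate_scan(
    matrix: GenotypeMatrix,
    nab_profile: NabProfile,
    config: CandidateScanConfig | None = None,
    iteration: int = 1,
    exclude: np.ndarray | None = None,
    links=None,
) -> pd.DataFrame:
    """Prescreen every variant, run the mixed LRT on survivors, BH-correct.

    Returns a per-variant candidate table with columns ``chrom``, ``pos``,
    ``ref``, ``alt``, ``prescreen_p``, ``lrt_p``, ``bh_q``, ``flagged`` and
    ``iteration``.  Variants failing the prescreen get q = 1; ``exclude``
    marks variant indices (e.g. previously flagged) to skip entirely.

    When ``links`` (the link set the profile was computed from) is given,
    variants that are themselves members of linked pairs are tested against a
    leave-one-variant-out profile: the contributions of pairs containing the
    tested variant are subtracted from nAB first.  Without this, a variant in
    the link set is regressed on a predictor partly built from its own
    genotypes — pure circularity when the link set is small.
    """
    if config is None:
        config = CandidateScanConfig()
    m = matrix.n_variants
    pre_p = np.full(m, np.nan)
    lrt_p = np.full(m, np.nan)
    q = np.ones(m)
    flagged = np.zeros(m, dtype=bool)
    skip = np.zeros(m, dtype=bool)
    if exclude is not None and len(exclude):
        skip[np.asarray(exclude)] = True

    if nab_profile.n_pairs == 0 or nab_profile.values.std() == 0:
        logger.warning("degenerate nAB profile: candidate scan returns no candidates")
        table = matrix.variants[["chrom", "pos", "ref", "alt"]].copy()
        table["prescreen_p"] = pre_p
        table["lrt_p"] = lrt_p
        table["bh_q"] = q
        table["flagged"] = flagged
        table["iteration"] = iteration
        return table

    # leave-one-variant-out profiles for link-set members
    loo_profiles: dict[int, NabProfile] = {}
    if links is not None:
        pairs = links.pairs if hasattr(links, "pairs") else links
        from icld.nab_profile import pair_contributions

        member_pairs: dict[int, list[tuple[int, int]]] = {}
        for a, b in zip(pairs["a_idx"].to_numpy(), pairs["b_idx"].to_numpy()):
            member_pairs.setdefault(int(a), []).append((int(a), int(b)))
            member_pairs.setdefault(int(b), []).append((int(a), int(b)))
        for j, jp in member_pairs.items():
            adjusted = nab_profile.values.copy()
            for a, b in jp:
                adjusted -= pair_contributions(matrix, a, b)
            loo_profiles[j] = NabProfile(
                values=np.maximum(adjusted, 0.0),
                samples=nab_profile.samples,
                n_pairs=max(nab_profile.n_pairs - len(jp), 0),
            )

    def profile_for(j: int) -> NabProfile:
        return loo_profiles.get(j, nab_profile)

    for j in range(m):
        if skip[j]:
            continue
        prof_j = profile_for(j)
        if prof_j.values.std() == 0:
            continue  # LOO predictor degenerate for this variant
        p, _sep = prescreen(matrix.genotypes[:, j], prof_j)
        pre_p[j] = p

    tested = np.flatnonzero(~np.isnan(pre_p) & (pre_p < config.prescreen_alpha) & ~skip)
    for j in tested:
        lrt_p[j] = mixed_lrt(matrix.genotypes[:, j], profile_for(j))
    # BH across the full scanned set: the LRT p where the full model ran, the
    # prescreen p otherwise, so q carries genome-wide multiplicity.  Only
    # mixed-model-tested variants are flaggable.
    scanned = np.flatnonzero(~np.isnan(pre_p) & ~skip)
    if len(scanned):
        p_for_bh = pre_p[scanned].copy()
        is_tested = np.isin(scanned, tested)
        p_for_bh[is_tested] = lrt_p[scanned[is_tested]]
        q[scanned] = bh_adjust(p_for_bh)
        flagged[tested] = q[tested] <= config.q_cutoff

    table = matrix.variants[["chrom", "pos", "ref", "alt"]].copy()
    table["prescreen_p"] = pre_p
    table["lrt_p"] = lrt_p
    table["bh_q"] = q
    table["flagged"] = flagged
    table["iteration"] = iteration
    return table
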