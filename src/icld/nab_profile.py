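"""Per-sample contribution to the linkage signal (nAB) and its structure.

Each sample's nAB sums its weight in the sigma_AB estimator over all
significant positively-associated pairs: 2 for the double-minor-homozygote
configuration, 1 for minor-homozygote x heterozygote, 0.5 for the double
heterozygote, 0 otherwise — i.e. gA*gB/2 with genotypes as minor-allele
counts.  Excess variance and multi-cluster structure of nAB relative to
chromosome-permuted nulls indicate batch-structured error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from icld.genotype_io import MISSING, GenotypeMatrix
from icld.permutation_null import LinkSet

logger = logging.getLogger(__name__)


@dataclass
class NabProfile:
    """Per-sample nAB values over a link set, plus permuted replicates."""

    values: np.ndarray
    samples: pd.DataFrame
    n_pairs: int
    permuted: list[np.ndarray] = field(default_factory=list)

    def zscores(self) -> np.ndarray:
        """Global z-transform of nAB across the full analyzed cohort."""
        sd = self.values.std()
        if sd == 0:
            return np.zeros_like(self.values)
        return (self.values - self.values.mean()) / sd

    def per_population(self) -> dict[str, np.ndarray]:
        pops = self.samples["population"].to_numpy()
        return {p: self.values[pops == p] for p in sorted(set(pops))}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.samples["sample_id"],
                "population": self.samples["population"],
                "nab": self.values,
                "z_nab": self.zscores(),
            }
        )


def compute_nab(matrix: GenotypeMatrix, links: LinkSet | pd.DataFrame) -> NabProfile:
    """Sum each sample's contribution to sigma_AB over the significant pairs.

    Samples missing at either member of a pair contribute 0 for that pair,
    so that the per-pair contributions still sum exactly to that pair's
    sigma_AB under pairwise deletion.
    """
    pairs = links.pairs if isinstance(links, LinkSet) else links
    values = np.zeros(matrix.n_samples)
    if len(pairs) == 0:
        logger.warning("empty link set: nAB profile is all zeros")
        return NabProfile(values=values, samples=matrix.samples.copy(), n_pairs=0)
    a_idx = pairs["a_idx"].to_numpy()
    b_idx = pairs["b_idx"].to_numpy()
    ga = matrix.genotypes[:, a_idx].astype(np.float64)
    gb = matrix.genotypes[:, b_idx].astype(np.float64)
    ga[ga == MISSING] = 0.0
    gb[gb == MISSING] = 0.0
    values = (ga * gb).sum(axis=1) / 2.0
    return NabProfile(values=values, samples=matrix.samples.copy(), n_pairs=len(pairs))


def pair_contributions(matrix: GenotypeMatrix, a_idx: int, b_idx: int) -> np.ndarray:
    """Per-sample contribution of a single pair (gA*gB/2, missing -> 0)."""
    ga = matrix.genotypes[:, a_idx].astype(np.float64)
    gb = matrix.genotypes[:, b_idx].astype(np.float64)
    ga[ga == MISSING] = 0.0
    gb[gb == MISSING] = 0.0
    return ga * gb / 2.0


def nab_variance_test(
    profile: NabProfile, permuted_profiles: list[NabProfile] | None = None
) -> pd.DataFrame:
    """Variance of observed nAB versus chromosome-permuted replicates.

    Per population, reports var(observed)/mean(var(permuted)) and a one-tailed
    one-sample t-test p of the observed variance exceeding the replicate
    distribution.  Degenerate cases (all-zero profiles) are flagged.
    """
    reps = permuted_profiles if permuted_profiles is not None else [
        NabProfile(v, profile.samples, profile.n_pairs) for v in profile.permuted
    ]
    if len(reps) < 1:
        raise ValueError("variance test requires permutation replicates")
    rows = []
    obs_by_pop = profile.per_population()
    for pop, obs in obs_by_pop.items():
        perm_vars = np.array(
            [r.per_population()[pop].var(ddof=1) for r in reps], dtype=float
        )
        obs_var = obs.var(ddof=1) if len(obs) > 1 else 0.0
        mean_perm = perm_vars.mean()
        if obs_var == 0.0 and mean_perm == 0.0:
            logger.warning("constant nAB in population %s; variance test skipped", pop)
            rows.append((pop, np.nan, np.nan))
            continue
        if mean_perm == 0.0:
            # all permuted replicates constant: rank-based p
            ratio = np.inf
            p = 1.0 / (len(perm_vars) + 1.0)
        else:
            ratio = obs_var / mean_perm
            if len(perm_vars) >= 2 and perm_vars.std(ddof=1) > 0:
                t_res = stats.ttest_1samp(perm_vars, obs_var, alternative="less")
                p = float(t_res.pvalue)
            else:
                p = 1.0 / (len(perm_vars) + 1.0) if obs_var > mean_perm else 1.0
        rows.append((pop, float(ratio), p))
    return pd.DataFrame(rows, columns=["population", "variance_ratio", "p"])


@dataclass
class MixtureFit:
    """Gaussian mixture fits of a 1-D nAB distribution for K = 1..k_max."""

    aicc: dict[int, float]
    loglik: dict[int, float]
    params: dict[int, dict[str, np.ndarray]]
    best_k: int
    assignments: np.ndarray
    aicc_weights: dict[int, float]

    def support_statistic(self) -> float:
        """AICc(K=1) - AICc(best K); 0 when one component is best."""
        return self.aicc[1] - self.aicc[self.best_k]


def _aicc(loglik: float, m: int, n: int) -> float:
    return -2.0 * loglik + 2.0 * m + 2.0 * m * (m + 1) / (n - m - 1)


def fit_mixture(values: np.ndarray, k_max: int = 9, seed: int = 0) -> MixtureFit:
    """EM fits of 1..k_max univariate Gaussians, scored by AICc.

    AICc uses m = 3K - 1 free parameters; K values with n <= m + 1 are
    skipped (AICc undefined).  Best K is the smallest K within 2 AICc units
    of the minimum.  Components are initialized with seeded k-means++.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    n = len(x)
    if n < 2:
        raise ValueError("mixture fit needs at least 2 samples")
    aicc: dict[int, float] = {}
    loglik: dict[int, float] = {}
    params: dict[int, dict[str, np.ndarray]] = {}
    models: dict[int, GaussianMixture] = {}
    for k in range(1, k_max + 1):
        m = 3 * k - 1
        if n <= m + 1:
            break
        gm = GaussianMixture(
            n_components=k,
            covariance_type="diag",
            # variance floor: keeps single points from collapsing a component
            # and inflating the likelihood (spurious extra clusters)
            reg_covar=2.5e-3 * max(x.var(), 1e-12) + 1e-12,
            max_iter=300,
            n_init=1 if k == 1 else 3,
            init_params="k-means++",
            random_state=seed,
            tol=1e-6,
        )
        gm.fit(x)
        ll = float(gm.score(x) * n)
        aicc[k] = _aicc(ll, m, n)
        loglik[k] = ll
        params[k] = {
            "means": gm.means_.ravel().copy(),
            "variances": gm.covariances_.ravel().copy(),
            "weights": gm.weights_.copy(),
        }
        models[k] = gm
    if not aicc:
        raise ValueError("too few samples for any mixture fit")
    a_min = min(aicc.values())
    best_k = min(k for k, a in aicc.items() if a <= a_min + 2.0)
    rel = {k: np.exp(-(a - a_min) / 2.0) for k, a in aicc.items()}
    total = sum(rel.values())
    weights = {k: v / total for k, v in rel.items()}
    assignments = models[best_k].predict(x)
    return MixtureFit(
        aicc=aicc,
        loglik=loglik,
        params=params,
        best_k=best_k,
        assignments=assignments,
        aicc_weights=weights,
    )


def clustering_support_test(
    observed_fit: MixtureFit, permuted_fits: list[MixtureFit]
) -> float:
    """Empirical one-tailed p of multi-cluster support versus permuted nulls.

    The statistic is AICc(K=1) - AICc(best K); the p-value is the rank of the
    observed statistic within the permuted statistics, (1 + #{perm >= obs}) /
    (1 + R).
    """
    if len(permuted_fits) < 3:
        logger.warning("fewer than 3 permuted fits: clustering-support p unreliable")
    obs = observed_fit.support_statistic()
    perm = np.array([f.support_statistic() for f in permuted_fits])
    return float((1 + np.sum(perm >= obs)) / (1 + len(perm)))


def clustering_support_by_population(
    profile: NabProfile,
    permuted_profiles: list[NabProfile],
    k_max: int = 9,
    seed: int = 0,
) -> pd.DataFrame:
    """Run fit_mixture + clustering_support_test per population."""
    rows = []
    obs_by_pop = profile.per_population()
    for pop, obs in obs_by_pop.items():
        if obs.std() == 0:
            rows.append((pop, np.nan, 1, 1.0))
            continue
        fit = fit_mixture(obs, k_max=k_max, seed=seed)
        perm_fits = []
        for r, rep in enumerate(permuted_profiles):
            v = rep.per_population()[pop]
            if v.std() == 0:
                continue
            perm_fits.append(fit_mixture(v, k_max=k_max, seed=seed + 1 + r))
        p = clustering_support_test(fit, perm_fits) if perm_fits else 1.0
        rows.append((pop, fit.support_statistic(), fit.best_k, p))
    return pd.DataFrame(rows, columns=["population", "support", "best_k", "p"])
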