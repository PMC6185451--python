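"""Synthetic genotype datasets with known truth.

Three generators:

* clean multi-chromosome HWE genotypes with no cross-chromosome association
  (each chromosome sampled independently),
* batch-structured recurrent false-heterozygote error injection at a
  configurable fraction of sites in a configurable subset of individuals,
* a two-locus Wright-Fisher simulator with recombination followed by
  epistatic selection on gamete fitnesses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from icld.genotype_io import GenotypeMatrix, classify_maf, recompute_pop_mafs

logger = logging.getLogger(__name__)

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class BatchSimConfig:
    """Design of a batch-error validation dataset.

    The error-containing batch holds ``batch_fraction`` of individuals;
    errors are injected into ``affected_fraction`` of the batch at
    ``error_site_fraction`` of the sites, as false heterozygotes.
    """

    n_individuals: int = 100
    n_variants: int = 2000
    n_chromosomes: int = 10
    n_populations: int = 1
    maf_spectrum: str = "uniform"  # "uniform" on [maf_low, maf_high] or "beta"
    maf_low: float = 0.05
    maf_high: float = 0.5
    beta_a: float = 0.3
    beta_b: float = 1.5
    batch_fraction: float = 0.2
    affected_fraction: float = 0.5
    error_site_fraction: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("batch_fraction", "affected_fraction", "error_site_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


def _draw_mafs(config: BatchSimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.maf_spectrum == "uniform":
        return rng.uniform(config.maf_low, config.maf_high, size=config.n_variants)
    if config.maf_spectrum == "beta":
        raw = rng.beta(config.beta_a, config.beta_b, size=config.n_variants) / 2.0
        return np.clip(raw, config.maf_low, config.maf_high)
    raise ValueError(f"unknown MAF spectrum {config.maf_spectrum!r}")


def simulate_genotypes(config: BatchSimConfig) -> GenotypeMatrix:
    """Clean unlinked HWE genotypes across chromosomes.

    Per variant a MAF is drawn from the configured spectrum and diploid
    genotypes are sampled as Binomial(2, maf) independently per sample; no
    cross-chromosome correlation exists by construction.  The drawn MAF is
    recorded in the variant table as ``sim_maf``.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_variants
    mafs = _draw_mafs(config, rng)
    draws = rng.binomial(2, mafs[None, :], size=(n, m)).astype(np.int8)

    # fold to pooled-minor coding; ties keep the simulated allele as minor
    alt_freq = draws.mean(axis=0) / 2.0
    minor_is_alt = alt_freq <= 0.5
    g = np.where(minor_is_alt[None, :], draws, 2 - draws).astype(np.int8)

    chrom_of = np.repeat(
        np.arange(config.n_chromosomes), int(np.ceil(m / config.n_chromosomes))
    )[:m]
    ref_i = rng.integers(0, 4, size=m)
    alt_i = (ref_i + rng.integers(1, 4, size=m)) % 4
    variants = pd.DataFrame(
        {
            "chrom": [f"chr{c + 1}" for c in chrom_of],
            "pos": np.concatenate(
                [np.arange(1, (chrom_of == c).sum() + 1) * 100 for c in range(config.n_chromosomes)]
            ),
            "ref": _BASES[ref_i],
            "alt": _BASES[alt_i],
            "minor_is_alt": minor_is_alt,
            "sim_maf": mafs,
        }
    )
    pops = np.repeat(
        [f"POP{k + 1}" for k in range(config.n_populations)],
        int(np.ceil(n / config.n_populations)),
    )[:n]
    samples = pd.DataFrame(
        {"sample_id": [f"S{i:04d}" for i in range(n)], "population": pops}
    )
    matrix = GenotypeMatrix(genotypes=g, variants=variants, samples=samples)
    recompute_pop_mafs(matrix)
    classify_maf(matrix)
    return matrix


@dataclass
class ErrorTruth:
    """Ground truth of an error injection."""

    site_idx: np.ndarray
    batch_idx: np.ndarray
    affected_idx: np.ndarray
    n_injected: int
    n_unchanged: int
    realized_rate: float


def inject_errors(
    matrix: GenotypeMatrix, config: BatchSimConfig
) -> tuple[GenotypeMatrix, ErrorTruth]:
    """Inject batch-structured false heterozygotes into a clean matrix.

    Selects ``error_site_fraction`` of sites and the affected individuals
    (a seeded draw of ``batch_fraction`` of samples, of which
    ``affected_fraction`` carry errors); at each selected (site, individual)
    a homozygous-major genotype 0 becomes 1.  Genotypes already 1 or 2 are
    left unchanged and counted.  The realized per-site-per-individual error
    rate over the whole matrix is reported.
    """
    rng = np.random.default_rng(config.seed + 1)
    n, m = matrix.n_samples, matrix.n_variants
    n_sites = max(1, round(config.error_site_fraction * m))
    n_batch = max(1, round(config.batch_fraction * n))
    n_affected = max(1, round(config.affected_fraction * n_batch))
    site_idx = np.sort(rng.choice(m, size=n_sites, replace=False))
    batch_idx = np.sort(rng.choice(n, size=n_batch, replace=False))
    affected_idx = np.sort(rng.choice(batch_idx, size=n_affected, replace=False))

    out = matrix.copy()
    n_injected = n_unchanged = 0
    for j in site_idx:
        for i in affected_idx:
            if out.genotypes[i, j] == 0:
                out.genotypes[i, j] = 1
                n_injected += 1
            else:
                n_unchanged += 1
    if n_unchanged:
        logger.info("%d selected genotypes already carried the minor allele", n_unchanged)
    recompute_pop_mafs(out)
    classify_maf(out)
    truth = ErrorTruth(
        site_idx=site_idx,
        batch_idx=batch_idx,
        affected_idx=affected_idx,
        n_injected=n_injected,
        n_unchanged=n_unchanged,
        realized_rate=n_injected / (n * m),
    )
    return out, truth


@dataclass
class SelectionScenario:
    """Two-locus Wright-Fisher scenario with epistatic gamete fitnesses."""

    n_AB: int
    n_Ab: int
    n_aB: int
    n_ab: int
    s_AB: float = 0.0
    s_Ab: float = 0.0
    s_aB: float = 0.0
    s_ab: float = 0.0
    r: float = 0.5
    generations: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_AB, self.n_Ab, self.n_aB, self.n_ab) < 0:
            raise ValueError("gamete counts must be non-negative")
        if not 0 <= self.r <= 0.5:
            raise ValueError("recombination probability must be in [0, 0.5]")

    @property
    def counts(self) -> np.ndarray:
        return np.array([self.n_AB, self.n_Ab, self.n_aB, self.n_ab], dtype=np.int64)

    @property
    def fitness(self) -> np.ndarray:
        return 1.0 + np.array([self.s_AB, self.s_Ab, self.s_aB, self.s_ab])


def _d_coefficient(counts: np.ndarray) -> np.ndarray:
    """Gametic D = p_AB - p_A * p_B (vectorized over leading axes)."""
    total = counts.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / total[..., None]
        p_a = p[..., 0] + p[..., 1]
        p_b = p[..., 0] + p[..., 2]
        return p[..., 0] - p_a * p_b


def _wf_step(
    counts: np.ndarray, fitness: np.ndarray, r: float, rng: np.random.Generator
) -> np.ndarray:
    """One generation, vectorized over replicate rows: recombination then selection."""
    counts = counts.astype(np.int64)
    total = counts.sum(axis=-1)
    alive = total > 0
    out = counts.copy()
    if not alive.any():
        return out
    c = counts[alive].astype(float)
    tot = c.sum(axis=-1)
    p = c / tot[:, None]
    n_pairs = (tot // 2).astype(np.int64)
    # coupling (AB x ab) and repulsion (Ab x aB) pairings after random pairing
    pr_coup = np.clip(2.0 * p[:, 0] * p[:, 3], 0.0, 1.0)
    pr_rep = np.clip(2.0 * p[:, 1] * p[:, 2], 0.0, 1.0)
    x = rng.binomial(rng.binomial(n_pairs, pr_coup), r)
    y = rng.binomial(rng.binomial(n_pairs, pr_rep), r)
    new = counts[alive].copy()
    x = np.minimum(x, np.minimum(new[:, 0], new[:, 3]))
    y = np.minimum(y, np.minimum(new[:, 1], new[:, 2]))
    new[:, 0] += y - x
    new[:, 3] += y - x
    new[:, 1] += x - y
    new[:, 2] += x - y
    # Wright-Fisher multinomial resampling weighted by gamete fitness
    w = new * fitness[None, :]
    wsum = w.sum(axis=-1)
    probs = w / wsum[:, None]
    out[alive] = rng.multinomial(total[alive], probs)
    return out


def wf_two_locus(scenario: SelectionScenario) -> pd.DataFrame:
    """Single Wright-Fisher trajectory of gamete counts and D.

    Each generation applies recombination (binomial draws of state-changing
    gamete pairings at probability r) and then multinomial Wright-Fisher
    resampling with fitnesses 1 + s per gamete class.
    """
    rng = np.random.default_rng(scenario.seed)
    counts = scenario.counts[None, :]
    rows = [
        (0, *counts[0], float(_d_coefficient(counts[0].astype(float)))),
    ]
    for t in range(1, scenario.generations + 1):
        counts = _wf_step(counts, scenario.fitness, scenario.r, rng)
        rows.append((t, *counts[0], float(_d_coefficient(counts[0].astype(float)))))
        if counts.sum() == 0:
            break
    return pd.DataFrame(rows, columns=["generation", "n_AB", "n_Ab", "n_aB", "n_ab", "D"])


def wf_ensemble_d(
    scenario: SelectionScenario, n_replicates: int = 10000, seed: int | None = None
) -> np.ndarray:
    """D trajectories for many replicates, shape (n_replicates, generations+1).

    Vectorized across replicates; used for mean-trajectory comparisons such
    as the neutral decay E[D_t] = D_0 * (1 - r)^t.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    counts = np.tile(scenario.counts, (n_replicates, 1))
    d = np.empty((n_replicates, scenario.generations + 1))
    d[:, 0] = _d_coefficient(counts.astype(float))
    for t in range(1, scenario.generations + 1):
        counts = _wf_step(counts, scenario.fitness, scenario.r, rng)
        d[:, t] = _d_coefficient(counts.astype(float))
    return d
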