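"""Genotype matrix I/O: VCF reading/writing, population maps, MAF classes.

Genotypes are stored as counts of the *minor* allele (0, 1, 2) with ``MISSING``
(-1) as the sentinel for missing calls.  The minor allele is determined once
from the pooled analyzed samples and used consistently across populations, so
that cross-population combination of pair statistics has a fixed allele
orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.
MISSING: int = -1

_SEX_CHROMS = {"X", "Y", "MT", "M", "chrX", "chrY", "chrMT", "chrM"}
_BASES = {"A", "C", "G", "T"}


class GenotypeIOError(RuntimeError):
    """Raised for malformed inputs or empty sample overlap."""


@dataclass
class GenotypeMatrix:
    """Samples x variants matrix of minor-allele counts plus metadata.

    Attributes
    ----------
    genotypes:
        ``(n_samples, n_variants)`` int8 array with values in ``{0, 1, 2}``
        or ``MISSING``.
    variants:
        Per-variant table with at least ``chrom``, ``pos``, ``ref``, ``alt``,
        ``minor_is_alt`` and one ``maf_<pop>`` column per population
        (per-population minor-allele frequency, folded into ``[0, 0.5]``).
    samples:
        Per-sample table with ``sample_id`` and ``population`` columns
        (plus optional truth columns for simulated data).
    depths:
        Optional ``(n_samples, n_variants, 2)`` array of (ref, alt) read
        depths when the source VCF carried AD fields.
    """

    genotypes: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame
    depths: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=np.int8)
        if g.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x variants)")
        bad = ~np.isin(g, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype values must be 0, 1, 2 or MISSING")
        if g.shape[0] != len(self.samples):
            raise ValueError("sample table does not match genotype rows")
        if g.shape[1] != len(self.variants):
            raise ValueError("variant table does not match genotype columns")
        self.genotypes = g

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def populations(self) -> list[str]:
        return sorted(self.samples["population"].unique())

    def pop_indices(self) -> dict[str, np.ndarray]:
        """Row indices of each population, in sample-table order."""
        return {
            pop: np.flatnonzero((self.samples["population"] == pop).to_numpy())
            for pop in self.populations
        }

    @property
    def chroms(self) -> np.ndarray:
        return self.variants["chrom"].to_numpy()

    def maf_columns(self) -> list[str]:
        return [c for c in self.variants.columns if c.startswith("maf_")]

    def subset_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            genotypes=self.genotypes[:, index].copy(),
            variants=self.variants.iloc[index].reset_index(drop=True),
            samples=self.samples.copy(),
            depths=None if self.depths is None else self.depths[:, index].copy(),
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        mat = GenotypeMatrix(
            genotypes=self.genotypes[index].copy(),
            variants=self.variants.copy(),
            samples=self.samples.iloc[index].reset_index(drop=True),
            depths=None if self.depths is None else self.depths[index].copy(),
        )
        recompute_pop_mafs(mat)
        return mat

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            genotypes=self.genotypes.copy(),
            variants=self.variants.copy(),
            samples=self.samples.copy(),
            depths=None if self.depths is None else self.depths.copy(),
        )


def _pop_minor_freq(column: np.ndarray) -> float:
    """Frequency of the pooled-minor allele among non-missing calls."""
    ok = column != MISSING
    if not ok.any():
        return np.nan
    return float(column[ok].mean() / 2.0)


def recompute_pop_mafs(matrix: GenotypeMatrix) -> None:
    """Refresh the per-population folded MAF columns in place."""
    for pop, rows in matrix.pop_indices().items():
        freqs = np.array(
            [_pop_minor_freq(matrix.genotypes[rows, j]) for j in range(matrix.n_variants)]
        )
        matrix.variants[f"maf_{pop}"] = np.minimum(freqs, 1.0 - freqs)


def read_popmap(path: str | Path, min_pop_size: int = 95) -> pd.DataFrame:
    """Read a ``sample_id<TAB>population`` table, dropping small populations.

    Populations with fewer than ``min_pop_size`` samples are removed, mirroring
    the default requirement of at least 95 individuals per analyzed population.
    """
    popmap = pd.read_csv(
        path, sep="\t", header=None, names=["sample_id", "population"], dtype=str,
        comment="#",
    )
    if popmap["sample_id"].duplicated().any():
        raise GenotypeIOError("duplicate sample ids in population map")
    sizes = popmap["population"].value_counts()
    keep = sizes[sizes >= min_pop_size].index
    dropped = sorted(set(sizes.index) - set(keep))
    if dropped:
        logger.warning(
            "dropping %d population(s) below %d samples: %s",
            len(dropped), min_pop_size, ", ".join(dropped),
        )
    return popmap[popmap["population"].isin(keep)].reset_index(drop=True)


def _read_bed(path: str | Path) -> dict[str, np.ndarray]:
    bed = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], comment="#",
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    regions: dict[str, np.ndarray] = {}
    for chrom, grp in bed.groupby("chrom"):
        iv = grp[["start", "end"]].to_numpy()
        iv = iv[np.argsort(iv[:, 0])]
        regions[chrom] = iv
    return regions


def _in_regions(regions: dict[str, np.ndarray], chrom: str, pos: int) -> bool:
    """pos is 1-based VCF coordinate; BED intervals are 0-based half-open."""
    iv = regions.get(chrom)
    if iv is None:
        return False
    z = pos - 1
    k = np.searchsorted(iv[:, 0], z, side="right") - 1
    return k >= 0 and z < iv[k, 1]


def read_genotypes(
    vcf_path: str | Path,
    popmap_path: str | Path,
    region_bed: str | Path | None = None,
    min_pop_size: int = 95,
    load_depth: bool = False,
) -> GenotypeMatrix:
    """Read biallelic autosomal SNPs from a VCF into a :class:`GenotypeMatrix`.

    The minor allele is determined per variant from pooled non-missing
    genotypes (ties go to ALT) and genotypes are recoded to minor-allele
    counts.  Samples absent from the population map are dropped with a
    warning; indels, multiallelic records and sex chromosomes are skipped.
    """
    from cyvcf2 import VCF

    popmap = read_popmap(popmap_path, min_pop_size=min_pop_size)
    try:
        vcf = VCF(str(vcf_path), gts012=True)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise GenotypeIOError(f"cannot parse VCF {vcf_path}: {exc}") from exc

    vcf_samples = list(vcf.samples)
    mapped = set(popmap["sample_id"])
    keep_samples = [s for s in vcf_samples if s in mapped]
    n_unmapped = len(vcf_samples) - len(keep_samples)
    if n_unmapped:
        logger.warning("%d VCF sample(s) absent from the population map; dropped", n_unmapped)
    if not keep_samples:
        raise GenotypeIOError("no overlap between VCF samples and population map")
    vcf.close()
    vcf = VCF(str(vcf_path), gts012=True, samples=keep_samples)
    order = list(vcf.samples)

    regions = _read_bed(region_bed) if region_bed is not None else None

    alt_counts: list[np.ndarray] = []
    records: list[tuple] = []
    depth_rows: list[np.ndarray] = []
    n_skipped = 0
    has_ad = "AD" in [f["ID"] for f in vcf.header_iter() if f.type == "FORMAT"] if load_depth else False
    for var in vcf:
        if len(var.ALT) != 1 or var.REF not in _BASES or var.ALT[0] not in _BASES:
            n_skipped += 1
            continue
        if var.CHROM in _SEX_CHROMS:
            n_skipped += 1
            continue
        if regions is not None and not _in_regions(regions, var.CHROM, var.POS):
            continue
        g = np.asarray(var.gt_types, dtype=np.int8)  # 0/1/2 alt copies, 3 unknown
        g[g == 3] = MISSING
        alt_counts.append(g)
        records.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        if has_ad:
            ad = var.format("AD")
            if ad is not None and ad.shape[1] >= 2:
                depth_rows.append(np.clip(ad[:, :2], 0, None).astype(np.int32))
            else:
                depth_rows.append(np.full((len(order), 2), -1, dtype=np.int32))
    vcf.close()
    if n_skipped:
        logger.info("skipped %d non-biallelic-SNP or sex-chromosome record(s)", n_skipped)
    if not records:
        raise GenotypeIOError("no analyzable variants in VCF")

    G = np.stack(alt_counts, axis=1)  # samples x variants, alt-allele counts
    variants = pd.DataFrame(records, columns=["chrom", "pos", "ref", "alt"])

    # Fold to minor-allele counts using the pooled frequency; ties keep ALT.
    minor_is_alt = np.ones(G.shape[1], dtype=bool)
    for j in range(G.shape[1]):
        f = _pop_minor_freq(G[:, j])
        if np.isfinite(f) and f > 0.5:
            ok = G[:, j] != MISSING
            G[ok, j] = 2 - G[ok, j]
            minor_is_alt[j] = False
    variants["minor_is_alt"] = minor_is_alt

    pops = dict(zip(popmap["sample_id"], popmap["population"]))
    samples = pd.DataFrame({"sample_id": order, "population": [pops[s] for s in order]})

    matrix = GenotypeMatrix(
        genotypes=G,
        variants=variants,
        samples=samples,
        depths=np.stack(depth_rows, axis=1) if depth_rows else None,
    )
    recompute_pop_mafs(matrix)
    classify_maf(matrix)
    return matrix


def classify_maf(
    matrix: GenotypeMatrix,
    common_threshold: float = 0.05,
    rare_threshold: float = 0.01,
) -> pd.Series:
    """Label variants common / rare / below_threshold by per-population MAF.

    A variant is *common* when its MAF exceeds ``common_threshold`` in at
    least one population, *rare* when it exceeds ``rare_threshold`` in at
    least one population but stays at or below ``common_threshold`` in all,
    and *below_threshold* otherwise.  The label column ``freq_class`` is
    added to the variant table and returned.
    """
    maf_cols = matrix.maf_columns()
    if not maf_cols:
        recompute_pop_mafs(matrix)
        maf_cols = matrix.maf_columns()
    mafs = matrix.variants[maf_cols].to_numpy()
    with np.errstate(invalid="ignore"):
        any_common = np.nanmax(mafs, axis=1) > common_threshold
        any_rare = np.nanmax(mafs, axis=1) > rare_threshold
    labels = np.where(any_common, "common", np.where(any_rare, "rare", "below_threshold"))
    matrix.variants["freq_class"] = labels
    return matrix.variants["freq_class"]


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as an uncompressed VCF 4.2 with GT (and AD) fields."""
    variants = matrix.variants
    order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].to_numpy()))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if matrix.depths is not None:
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        for chrom in pd.unique(variants["chrom"].iloc[order]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples["sample_id"])
            + "\n"
        )
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j in order:
            row = variants.iloc[j]
            g = matrix.genotypes[:, j]
            if not row["minor_is_alt"]:
                g = np.where(g == MISSING, MISSING, 2 - g)
            fields = [
                str(row["chrom"]), str(row["pos"]), ".", row["ref"], row["alt"],
                ".", "PASS", ".",
            ]
            if matrix.depths is None:
                fields.append("GT")
                fields.extend(gt_strings[int(x)] for x in g)
            else:
                fields.append("GT:AD")
                for i, x in enumerate(g):
                    rd, ad = matrix.depths[i, j]
                    fields.append(f"{gt_strings[int(x)]}:{rd},{ad}")
            fh.write("\t".join(fields) + "\n")


def write_popmap(matrix: GenotypeMatrix, path: str | Path) -> None:
    matrix.samples[["sample_id", "population"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_candidates(table: pd.DataFrame, path: str | Path) -> None:
    """Write a candidate table as TSV, deterministically ordered by (chrom, pos)."""
    cols = ["chrom", "pos", "ref", "alt", "prescreen_p", "lrt_p", "bh_q", "flagged", "iteration"]
    out = table.copy()
    for c in cols:
        if c not in out.columns:
            out[c] = np.nan
    out = out[cols].sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    out["flagged"] = out["flagged"].map(lambda v: "true" if bool(v) else "false")
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
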