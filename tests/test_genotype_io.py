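import numpy as np
import pandas as pd
import pytest

from icld.genotype_io import (
    MISSING,
    GenotypeIOError,
    GenotypeMatrix,
    classify_maf,
    read_genotypes,
    read_popmap,
    recompute_pop_mafs,
    write_candidates,
    write_popmap,
    write_vcf,
)
from icld.synthetic_data import BatchSimConfig, simulate_genotypes


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=chr1>\n##contig=<ID=chr2>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsampleA\tsampleB\tsampleC\n"
)


def write_tiny_vcf(path, body):
    path.write_text(VCF_HEADER + body)


def write_tiny_popmap(path, pops=("P", "P", "P")):
    path.write_text(
        "".join(f"sample{s}\t{p}\n" for s, p in zip("ABC", pops))
    )


class TestReadGenotypes:
    def test_direct_coding(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        popmap = tmp_path / "p.tsv"
        write_tiny_vcf(vcf, "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n")
        write_tiny_popmap(popmap)
        m = read_genotypes(vcf, popmap, min_pop_size=1)
        assert np.array_equal(m.genotypes[:, 0], [0, 1, 2])

    def test_minor_allele_folding(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        popmap = tmp_path / "p.tsv"
        # alt frequency 5/6 > 0.5: recode to count the REF (minor) allele
        write_tiny_vcf(vcf, "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t1/1\t1/1\t0/1\n")
        write_tiny_popmap(popmap)
        m = read_genotypes(vcf, popmap, min_pop_size=1)
        assert np.array_equal(m.genotypes[:, 0], [0, 0, 1])
        assert not m.variants["minor_is_alt"].iloc[0]
        assert m.variants["maf_P"].iloc[0] == pytest.approx(1 / 6)

    def test_triallelic_excluded(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        popmap = tmp_path / "p.tsv"
        write_tiny_vcf(
            vcf,
            "chr1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            "chr1\t200\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n",
        )
        write_tiny_popmap(popmap)
        m = read_genotypes(vcf, popmap, min_pop_size=1)
        assert m.n_variants == 1
        assert m.variants["pos"].iloc[0] == 200

    def test_indel_and_sex_chromosome_excluded(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        popmap = tmp_path / "p.tsv"
        body = (
            "chr1\t100\t.\tAT\tA\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            "chr1\t200\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        )
        write_tiny_vcf(vcf, body)
        write_tiny_popmap(popmap)
        m = read_genotypes(vcf, popmap, min_pop_size=1)
        assert m.n_variants == 1

    def test_missing_genotype_sentinel(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        popmap = tmp_path / "p.tsv"
        write_tiny_vcf(vcf, "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t./.\t0/1\t1/1\n")
        write_tiny_popmap(popmap)
        m = read_genotypes(vcf, popmap, min_pop_size=1)
        assert m.genotypes[0, 0] == MISSING

    def test_unmapped_samples_dropped(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        popmap = tmp_path / "p.tsv"
        write_tiny_vcf(vcf, "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n")
        popmap.write_text("sampleA\tP\nsampleB\tP\n")
        m = read_genotypes(vcf, popmap, min_pop_size=1)
        assert m.n_samples == 2

    def test_zero_overlap_is_error(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        popmap = tmp_path / "p.tsv"
        write_tiny_vcf(vcf, "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n")
        popmap.write_text("other\tP\n")
        with pytest.raises(GenotypeIOError):
            read_genotypes(vcf, popmap, min_pop_size=1)

    def test_bed_region_restriction(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        popmap = tmp_path / "p.tsv"
        bed = tmp_path / "r.bed"
        write_tiny_vcf(
            vcf,
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            "chr1\t500\t.\tC\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n",
        )
        write_tiny_popmap(popmap)
        bed.write_text("chr1\t0\t200\n")  # half-open, 0-based
        m = read_genotypes(vcf, popmap, region_bed=bed, min_pop_size=1)
        assert m.n_variants == 1 and m.variants["pos"].iloc[0] == 100


class TestRoundTrip:
    def test_simulate_write_read_identical(self, tmp_path):
        cfg = BatchSimConfig(n_individuals=25, n_variants=40, n_chromosomes=3, seed=21)
        m = simulate_genotypes(cfg)
        vcf = tmp_path / "sim.vcf"
        popmap = tmp_path / "sim.popmap.tsv"
        write_vcf(m, vcf)
        write_popmap(m, popmap)
        back = read_genotypes(vcf, popmap, min_pop_size=1)
        # writer sorts by (chrom, pos); align before comparing
        key_orig = list(zip(m.variants["chrom"], m.variants["pos"]))
        key_back = list(zip(back.variants["chrom"], back.variants["pos"]))
        order = [key_orig.index(k) for k in key_back]
        assert np.array_equal(back.genotypes, m.genotypes[:, order])
        assert list(back.samples["sample_id"]) == list(m.samples["sample_id"])

    def test_ad_depth_round_trip(self, tmp_path):
        cfg = BatchSimConfig(n_individuals=8, n_variants=10, n_chromosomes=2, seed=23)
        m = simulate_genotypes(cfg)
        rng = np.random.default_rng(0)
        m.depths = rng.integers(0, 30, size=(8, 10, 2)).astype(np.int32)
        vcf, popmap = tmp_path / "d.vcf", tmp_path / "d.pop"
        write_vcf(m, vcf)
        write_popmap(m, popmap)
        back = read_genotypes(vcf, popmap, min_pop_size=1, load_depth=True)
        key_orig = list(zip(m.variants["chrom"], m.variants["pos"]))
        key_back = list(zip(back.variants["chrom"], back.variants["pos"]))
        order = [key_orig.index(k) for k in key_back]
        assert np.array_equal(back.depths, m.depths[:, order])

    def test_rewrite_byte_identical(self, tmp_path):
        cfg = BatchSimConfig(n_individuals=10, n_variants=15, seed=22)
        m = simulate_genotypes(cfg)
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_vcf(m, p1)
        write_vcf(m, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestPopmap:
    def test_min_pop_size_filter(self, tmp_path):
        path = tmp_path / "pm.tsv"
        path.write_text("a\tBIG\nb\tBIG\nc\tBIG\nd\tSMALL\n")
        pm = read_popmap(path, min_pop_size=3)
        assert set(pm["population"]) == {"BIG"}

    def test_duplicate_sample_rejected(self, tmp_path):
        path = tmp_path / "pm.tsv"
        path.write_text("a\tP\na\tQ\n")
        with pytest.raises(GenotypeIOError):
            read_popmap(path, min_pop_size=1)


class TestClassifyMaf:
    def _matrix(self, maf_by_pop):
        # two populations, frequencies injected directly
        g = np.zeros((4, len(maf_by_pop)), dtype=np.int8)
        variants = pd.DataFrame(
            {
                "chrom": ["chr1"] * len(maf_by_pop),
                "pos": range(1, len(maf_by_pop) + 1),
                "ref": ["A"] * len(maf_by_pop),
                "alt": ["G"] * len(maf_by_pop),
                "minor_is_alt": [True] * len(maf_by_pop),
            }
        )
        samples = pd.DataFrame(
            {"sample_id": list("abcd"), "population": ["P1", "P1", "P2", "P2"]}
        )
        m = GenotypeMatrix(genotypes=g, variants=variants, samples=samples)
        m.variants["maf_P1"] = [x[0] for x in maf_by_pop]
        m.variants["maf_P2"] = [x[1] for x in maf_by_pop]
        return m

    def test_classification_rule(self):
        m = self._matrix([(0.06, 0.01), (0.03, 0.04), (0.005, 0.009)])
        labels = classify_maf(m)
        assert list(labels) == ["common", "rare", "below_threshold"]

    def test_invariant_to_population_order(self):
        a = self._matrix([(0.06, 0.01), (0.03, 0.04)])
        b = self._matrix([(0.01, 0.06), (0.04, 0.03)])
        assert list(classify_maf(a)) == list(classify_maf(b))

    def test_boundary_exactly_five_percent_is_rare(self):
        m = self._matrix([(0.05, 0.05)])
        assert classify_maf(m).iloc[0] == "rare"


class TestWriteCandidates:
    def _table(self):
        return pd.DataFrame(
            {
                "chrom": ["chr2", "chr1"],
                "pos": [5, 10],
                "ref": ["A", "C"],
                "alt": ["G", "T"],
                "prescreen_p": [0.5, 1e-6],
                "lrt_p": [np.nan, 1e-7],
                "bh_q": [1.0, 1e-5],
                "flagged": [False, True],
                "iteration": [1, 1],
            }
        )

    def test_empty_table_header_only(self, tmp_path):
        out = tmp_path / "c.tsv"
        write_candidates(self._table().iloc[:0], out)
        lines = out.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("chrom\tpos")

    def test_flagged_row(self, tmp_path):
        out = tmp_path / "c.tsv"
        write_candidates(self._table(), out)
        lines = out.read_text().splitlines()
        assert len(lines) == 3
        # sorted by (chrom, pos): chr1 first
        assert lines[1].startswith("chr1\t10") and "true" in lines[1]

    def test_deterministic_bytes(self, tmp_path):
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_candidates(self._table(), a)
        write_candidates(self._table(), b)
        assert a.read_bytes() == b.read_bytes()
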