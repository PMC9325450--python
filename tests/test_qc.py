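"""QC filtering, SNP region classification and subgroup sharing."""

import numpy as np
import pandas as pd
import pytest

from lotus_popgen import qc
from lotus_popgen.containers import GeneModel, site_table
from lotus_popgen.vcfio import PopmapError, read_inputs, read_popmap, read_vcf
from tests.conftest import toy_matrix


def make_sites(rows):
    """rows: list of (depth, mq, maf, call_fraction)."""
    n = len(rows)
    depth, mq, maf, cf = (np.array(col, dtype=float) for col in zip(*rows))
    return site_table(
        chrom=["chr1"] * n,
        pos=100 * (1 + np.arange(n)),
        ref=["A"] * n,
        alt=["T"] * n,
        depth=depth,
        rms_mq=mq,
        call_fraction=cf,
        maf=maf,
    )


class TestFilterSites:
    def test_boundary_values_pass(self):
        # depth 4, MQ 20, MAF 0.05, missingness exactly 0.10: all inclusive
        sites = make_sites([(4.0, 20.0, 0.05, 0.90)])
        mask, summary = qc.filter_sites(sites)
        assert mask.all()
        assert summary["n_pass"] == 1

    @pytest.mark.parametrize(
        "row, failing",
        [
            ((3.0, 40.0, 0.3, 1.0), "fail_depth"),
            ((10.0, 19.9, 0.3, 1.0), "fail_mq"),
            ((10.0, 40.0, 0.049, 1.0), "fail_maf"),
            ((10.0, 40.0, 0.3, 0.89), "fail_miss"),
        ],
    )
    def test_each_threshold_independently_rejects(self, row, failing):
        sites = make_sites([row])
        mask, summary = qc.filter_sites(sites)
        assert not mask.any()
        assert summary[failing] == 1
        for key in ("fail_depth", "fail_mq", "fail_maf", "fail_miss"):
            if key != failing:
                assert summary[key] == 0

    def test_hand_built_table_matches_predicate_oracle(self):
        rng = np.random.default_rng(42)
        rows = [
            (4.0, 20.0, 0.05, 0.90),
            (3.99, 20.0, 0.05, 0.90),
            (4.0, 19.99, 0.05, 0.90),
            (4.0, 20.0, 0.0499, 0.90),
            (4.0, 20.0, 0.05, 0.8999),
            (0.0, 0.0, 0.0, 0.0),
            (100.0, 60.0, 0.5, 1.0),
        ] + [
            (
                float(rng.integers(0, 12)),
                float(rng.integers(0, 60)),
                float(rng.integers(0, 11)) / 20.0,
                float(rng.integers(80, 101)) / 100.0,
            )
            for _ in range(13)
        ]
        sites = make_sites(rows)
        mask, summary = qc.filter_sites(sites)
        # independent oracle: evaluate the four predicates per site
        expected = np.array(
            [
                (d >= 4.0) and (mq >= 20.0) and (maf >= 0.05) and ((1 - cf) <= 0.1)
                for d, mq, maf, cf in rows
            ]
        )
        np.testing.assert_array_equal(mask, expected)
        assert summary["n_pass"] == expected.sum()

    def test_idempotent_on_passing_sites(self):
        rng = np.random.default_rng(7)
        rows = [
            (rng.uniform(0, 10), rng.uniform(0, 50), rng.uniform(0, 0.5), rng.uniform(0.8, 1))
            for _ in range(50)
        ]
        sites = make_sites(rows)
        mask, _ = qc.filter_sites(sites)
        surviving = sites[mask].reset_index(drop=True)
        mask2, summary2 = qc.filter_sites(surviving)
        assert mask2.all()
        assert summary2["n_pass"] == summary2["n_total"]

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            qc.FilterThresholds(min_maf=0.7)
        with pytest.raises(ValueError):
            qc.FilterThresholds(max_miss=1.5)
        with pytest.raises(ValueError):
            qc.FilterThresholds(min_depth=-1)


def classify_oracle(sites, genes, flank_bp=0):
    """Quadratic-scan oracle over all genes with explicit precedence."""
    out = []
    for chrom, pos in zip(sites["chrom"], sites["pos"]):
        cat = "intergenic"
        in_gene = False
        for g in genes:
            if g.chrom != chrom:
                continue
            if g.start <= pos <= g.end:
                in_gene = True
                if any(s <= pos <= e for s, e in g.exons):
                    cat = "exonic"
                    break
                cat = "intronic"
        if not in_gene and cat == "intergenic" and flank_bp > 0:
            kinds = set()
            for g in genes:
                if g.chrom != chrom:
                    continue
                before = g.start - flank_bp <= pos < g.start
                after = g.end < pos <= g.end + flank_bp
                if g.strand == "+":
                    if before:
                        kinds.add("upstream")
                    if after:
                        kinds.add("downstream")
                else:
                    if before:
                        kinds.add("downstream")
                    if after:
                        kinds.add("upstream")
            if kinds:
                cat = "upstream" if "upstream" in kinds else "downstream"
        out.append(cat)
    return np.asarray(out, dtype=object)


class TestClassifySnpRegions:
    GENE = GeneModel("g1", "chr1", 100, 200, "+", ((100, 160),))

    def site_at(self, pos, chrom="chr1"):
        return make_sites([(10.0, 40.0, 0.3, 1.0)]).assign(pos=[pos], chrom=[chrom])

    def test_exon_containment(self):
        assert qc.classify_snp_regions(self.site_at(150), [self.GENE])[0] == "exonic"

    def test_gene_body_outside_exons_is_intronic(self):
        assert qc.classify_snp_regions(self.site_at(180), [self.GENE])[0] == "intronic"

    def test_unannotated_chromosome_is_intergenic(self):
        cats = qc.classify_snp_regions(self.site_at(150, chrom="chrX"), [self.GENE])
        assert cats[0] == "intergenic"

    def test_strand_aware_flanks(self):
        plus = GeneModel("gp", "chr1", 1000, 2000, "+", ((1000, 2000),))
        minus = GeneModel("gm", "chr1", 5000, 6000, "-", ((5000, 6000),))
        cats = qc.classify_snp_regions(
            make_sites([(10, 40, 0.3, 1.0)] * 4).assign(pos=[950, 2050, 4950, 6050]),
            [plus, minus],
            flank_bp=100,
        )
        assert list(cats) == ["upstream", "downstream", "downstream", "upstream"]

    def test_random_snps_match_quadratic_oracle(self, rng):
        genes = []
        cursor = 1
        for i in range(30):
            start = cursor + int(rng.integers(50, 300))
            length = int(rng.integers(100, 800))
            end = start + length - 1
            n_ex = int(rng.integers(1, 4))
            cuts = np.sort(rng.choice(np.arange(1, length), 2 * n_ex - 1, replace=False))
            bounds = np.concatenate(([0], cuts, [length]))
            exons = tuple(
                (start + int(bounds[2 * e]), start + int(bounds[2 * e + 1]) - 1)
                for e in range(n_ex)
            )
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"g{i}", "chr1", start, end, strand, exons))
            cursor = end
        n = 1000
        pos = np.sort(rng.choice(cursor + 500, size=n, replace=False)) + 1
        sites = make_sites([(10, 40, 0.3, 1.0)] * n).assign(pos=pos)
        for flank in (0, 120):
            got = qc.classify_snp_regions(sites, genes, flank_bp=flank)
            want = classify_oracle(sites, genes, flank_bp=flank)
            np.testing.assert_array_equal(got, want)

    def test_categories_partition_the_snp_set(self, rng):
        genes = [self.GENE, GeneModel("g2", "chr1", 400, 900, "-", ((400, 500), (700, 900)))]
        pos = np.sort(rng.choice(1200, size=300, replace=False)) + 1
        sites = make_sites([(10, 40, 0.3, 1.0)] * 300).assign(pos=pos)
        cats = qc.classify_snp_regions(sites, genes, flank_bp=50)
        props = qc.region_proportions(cats)
        assert sum(props.values()) == pytest.approx(1.0)
        counts = sum((cats == c).sum() for c in qc.REGION_CATEGORIES)
        assert counts == 300


def sharing_oracle(dosage, groups):
    """Exhaustive set algebra over per-site carrier sets."""
    present = {}
    for label, rows in groups.items():
        cols = set()
        for j in range(dosage.shape[1]):
            if any(dosage[i, j] in (1, 2) for i in rows):
                cols.add(j)
        present[label] = cols
    labels = sorted(present)
    common = set.intersection(*(present[g] for g in labels))
    unique = {
        g: present[g] - set.union(*(present[h] for h in labels if h != g))
        for g in labels
    }
    return present, common, unique


class TestSnpSharing:
    def popmap(self, geno, groups):
        return {s: g for g, rows in groups.items() for s in (geno.samples[i] for i in rows)}

    def test_private_alt_is_unique_not_common(self):
        geno = toy_matrix([[1, 0], [0, 1], [0, 2], [0, 1]])
        popmap = {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}
        res = qc.snp_sharing(geno, popmap)
        assert res["unique"]["A"] == 1  # site 0 carried only in A
        assert res["common"] == 1  # site 1 carried in both

    def test_carrier_in_every_subgroup_counts_as_common(self):
        geno = toy_matrix([[1, 1], [2, 1], [1, 2]])
        popmap = {"s1": "A", "s2": "B", "s3": "C"}
        res = qc.snp_sharing(geno, popmap)
        assert res["common"] == 2

    def test_empty_subgroup_rejected(self):
        geno = toy_matrix([[1, 0], [0, 1]])
        with pytest.raises(KeyError):
            qc.snp_sharing(geno, {"s1": "A"})  # s2 unmapped

    def test_random_matrices_match_set_oracle(self, rng):
        for _ in range(20):
            n_samples, n_sites = 12, 50
            dosage = rng.choice([-1, 0, 1, 2], size=(n_samples, n_sites), p=[0.1, 0.5, 0.25, 0.15])
            geno = toy_matrix(dosage)
            groups = {"A": range(0, 4), "B": range(4, 8), "C": range(8, 12)}
            popmap = self.popmap(geno, groups)
            res = qc.snp_sharing(geno, popmap)
            present, common, unique = sharing_oracle(dosage, {g: list(r) for g, r in groups.items()})
            assert res["common"] == len(common)
            for g in groups:
                assert res["per_group_total"][g] == len(present[g])
                assert res["unique"][g] == len(unique[g])
            # invariants
            assert sum(res["unique"].values()) <= sum(res["per_group_total"].values())
            assert res["common"] <= min(res["per_group_total"].values())

    def test_sample_permutation_invariance(self, rng):
        dosage = rng.choice([-1, 0, 1, 2], size=(9, 40))
        geno = toy_matrix(dosage)
        popmap = {s: "ABC"[i % 3] for i, s in enumerate(geno.samples)}
        res1 = qc.snp_sharing(geno, popmap)
        perm = list(rng.permutation(geno.samples))
        res2 = qc.snp_sharing(geno.take_samples(perm), popmap)
        assert res1["common"] == res2["common"]
        assert res1["unique"] == res2["unique"]


TRIALLELIC_VCF = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=10000>
##INFO=<ID=DP,Number=1,Type=Integer,Description="d">
##INFO=<ID=MQ,Number=1,Type=Float,Description="m">
##FORMAT=<ID=GT,Number=1,Type=String,Description="g">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
chr1\t100\t.\tA\tT\t.\tPASS\tDP=10;MQ=40\tGT\t0/1\t./.
chr1\t200\t.\tA\tT,G\t.\tPASS\tDP=10;MQ=40\tGT\t0/1\t0/2
chr1\t300\t.\tAC\tA\t.\tPASS\tDP=10;MQ=40\tGT\t0/1\t0/0
chr1\t400\t.\tG\tC\t.\tPASS\tDP=7;MQ=35.5\tGT\t1/1\t0/0
"""


class TestReadInputs:
    def test_non_biallelic_records_skipped(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(TRIALLELIC_VCF)
        geno = read_vcf(str(path))
        assert geno.n_sites == 2  # triallelic and indel rows dropped
        assert list(geno.sites["pos"]) == [100, 400]

    def test_genotype_coding_conventions(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(TRIALLELIC_VCF)
        geno = read_vcf(str(path))
        assert geno.dosage[0, 0] == 1  # 0/1
        assert geno.dosage[1, 0] == -1  # ./.
        assert geno.dosage[0, 1] == 2  # 1/1
        assert geno.sites["maf"].iloc[0] == pytest.approx(0.5)
        assert geno.sites["call_fraction"].iloc[0] == pytest.approx(0.5)

    def test_unmapped_sample_raises_listing_offender(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(TRIALLELIC_VCF)
        gff = tmp_path / "t.gff3"
        gff.write_text("##gff-version 3\n")
        popmap = tmp_path / "p.tsv"
        popmap.write_text("sample\tgroup\ns1\tA\n")
        with pytest.raises(PopmapError, match="s2"):
            read_inputs(str(vcf), str(gff), str(popmap))

    def test_popmap_parsing(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("sample\tgroup\na\tX\nb\tY\n")
        assert read_popmap(str(p)) == {"a": "X", "b": "Y"}
        p.write_text("a\tX\na\tY\n")
        with pytest.raises(PopmapError, match="duplicate"):
            read_popmap(str(p))
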