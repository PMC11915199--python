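import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score, silhouette_score

from braya import genotypes as g
from braya import synthdata as sd
from _oracles import average_linkage_heights, ibs_allele_sharing

TINY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=1000>
##INFO=<ID=AO,Number=1,Type=Integer,Description="x">
##INFO=<ID=SAF,Number=1,Type=Integer,Description="x">
##INFO=<ID=SAR,Number=1,Type=Integer,Description="x">
##INFO=<ID=RPR,Number=1,Type=Integer,Description="x">
##INFO=<ID=RPL,Number=1,Type=Integer,Description="x">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
1\t10\t.\tA\tC\t50\tPASS\tAO=4;SAF=2;SAR=2;RPR=2;RPL=2\tGT:DP\t0/0/1:20\t1/1/1:25
1\t20\t.\tG\tT\t50\tPASS\tAO=4;SAF=2;SAR=2;RPR=2;RPL=2\tGT:DP\t././.:.\t0/1/1:30
"""


class TestReadVcf:
    def test_dosage_counts_alt_alleles_and_missing(self, tmp_path):
        path = tmp_path / "tiny.vcf"
        path.write_text(TINY_VCF)
        sites, table = g.read_vcf(str(path), ploidy=3)
        assert [s.pos for s in sites] == [10, 20]
        assert table.dosage[0, 0] == 1  # 0/0/1
        assert table.dosage[1, 0] == 3  # 1/1/1
        assert np.isnan(table.dosage[0, 1])  # ././.
        assert table.dosage[1, 1] == 2
        assert table.depth[0, 0] == 20
        assert np.isnan(table.depth[0, 1])

    def test_ploidy_mismatch_is_an_explicit_error(self, tmp_path):
        path = tmp_path / "tiny.vcf"
        path.write_text(TINY_VCF)
        with pytest.raises(g.PloidyMismatchError):
            g.read_vcf(str(path), ploidy=2)

    def test_vcf_roundtrip_through_generator(self, tmp_path):
        cfg = sd.GenotypeSimConfig(
            n_clusters=1, clones_per_cluster=(3,), n_snps=5,
            between_dissimilarity={}, within_dissimilarity=0.01, seed=4,
        )
        sim = sd.simulate_genotypes(cfg)
        path = tmp_path / "sim.vcf"
        sim.to_vcf(str(path))
        _, table = g.read_vcf(str(path), ploidy=3)
        assert table.sample_ids == sim.table.sample_ids
        np.testing.assert_array_equal(
            np.nan_to_num(table.dosage, nan=-1.0),
            np.nan_to_num(sim.table.dosage, nan=-1.0),
        )


class TestSiteQualityFilter:
    def _rec(self, qual=50, ao=4, saf=2, sar=2, rpr=2, rpl=2, pos=1):
        return g.SiteRecord(
            chrom="1", pos=pos, ref="A", alt=("C",), qual=qual,
            info={"AO": ao, "SAF": saf, "SAR": sar, "RPR": rpr, "RPL": rpl},
        )

    def test_passing_record_satisfies_all_six_rules(self):
        kept = g.site_quality_filter([self._rec()])
        assert len(kept) == 1  # 50/4 = 12.5 > 10 and all balances positive

    @pytest.mark.parametrize(
        "kwargs, reason",
        [
            ({"qual": 0.5}, "qual"),
            ({"qual": 30, "ao": 4}, "qual_ao"),  # 30/4 = 7.5 <= 10
            ({"saf": 0, "sar": 4}, "saf"),  # one-strand alt support
            ({"sar": 0, "saf": 4}, "sar"),
            ({"rpr": 1}, "rpr"),
            ({"rpl": 1}, "rpl"),
        ],
    )
    def test_each_rule_rejects_with_its_reason(self, kwargs, reason):
        kept, report = g.site_quality_filter([self._rec(**kwargs)], return_report=True)
        assert kept == []
        assert report["reason"].iloc[0] == reason

    def test_missing_annotation_rejects_not_keeps(self):
        rec = g.SiteRecord("1", 5, "A", ("C",), 50, {"AO": 4, "SAF": 2, "SAR": 2, "RPR": 2})
        kept, report = g.site_quality_filter([rec], return_report=True)
        assert kept == []
        assert report["reason"].iloc[0] == "missing:RPL"

    def test_order_preserved(self):
        recs = [self._rec(pos=i) for i in (3, 1, 2)]
        kept = g.site_quality_filter(recs)
        assert [r.pos for r in kept] == [3, 1, 2]


class TestMinorAlleleFrequency:
    @pytest.mark.parametrize(
        "dosages, expected",
        [
            ([0, 1, 2, 3], 0.5),  # 6 alt of 12 alleles
            ([0, 0, 0, 1], 1 / 12),
            ([2, 2, 2], 1 / 3),  # constant dosage, but alleles still mixed: f = 6/9
            ([0, 0, 0], 0.0),  # fixed for the reference allele
            ([3, 3], 0.0),  # fixed for the alternate allele
        ],
    )
    def test_allele_counting(self, dosages, expected):
        assert g.minor_allele_frequency(dosages, ploidy=3) == pytest.approx(expected)

    def test_all_missing_is_an_error(self):
        with pytest.raises(ValueError, match="missing"):
            g.minor_allele_frequency([np.nan, np.nan], ploidy=3)


def _table(dosage, depth=None, ploidy=3, n_alt=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    depth = np.full((n, m), 50.0) if depth is None else np.asarray(depth, dtype=float)
    loci = None if n_alt is None else pd.DataFrame({"n_alt": n_alt})
    return g.GenotypeTable(
        sample_ids=[f"s{i}" for i in range(n)],
        locus_ids=[f"1:{j}" for j in range(m)],
        dosage=dosage,
        depth=depth,
        ploidy=ploidy,
        loci=loci,
    )


class TestSnpSetFilter:
    def test_low_maf_and_depth_and_multiallelic_removed(self):
        dosage = np.array(
            [[0, 0, 1, 0], [0, 1, 2, 1], [0, 2, 3, 2], [1, 3, 0, 3]], dtype=float
        )
        depth = np.full((4, 4), 50.0)
        depth[:, 2] = 8.0  # mean depth below 10
        table = _table(dosage, depth, n_alt=[1, 1, 1, 2])
        kept, report = g.snp_set_filter(table)
        assert kept.locus_ids == ["1:1"]
        reasons = dict(zip(report["locus_id"], report["reason"]))
        assert reasons["1:0"] == "low_maf"  # MAF 1/12 < 0.15
        assert reasons["1:2"] == "depth"
        assert reasons["1:3"] == "multiallelic"

    def test_monotone_in_filter_strictness(self, genotype_sim):
        table = genotype_sim.table
        loose = g.SnpSetFilterParams(maf_min=0.0, depth_min=0.0, depth_max=np.inf)
        strict = g.SnpSetFilterParams(maf_min=0.2, depth_min=20.0, depth_max=100.0)
        kept_loose, _ = g.snp_set_filter(table, loose)
        kept_strict, _ = g.snp_set_filter(table, strict)
        assert set(kept_strict.locus_ids) <= set(kept_loose.locus_ids)

    def test_invariant_to_locus_order(self, genotype_sim):
        table = genotype_sim.table
        rng = np.random.default_rng(0)
        perm = rng.permutation(table.n_loci)
        shuffled = table.subset_loci(perm)
        kept_a, _ = g.snp_set_filter(table)
        kept_b, _ = g.snp_set_filter(shuffled)
        assert set(kept_a.locus_ids) == set(kept_b.locus_ids)

    def test_empty_output_warns_not_raises(self):
        table = _table([[0, 0], [0, 0]])
        with pytest.warns(UserWarning, match="every locus"):
            kept, _ = g.snp_set_filter(table)
        assert kept.n_loci == 0


class TestIbsMatrix:
    def test_matches_allele_sharing_oracle_on_all_dosage_pairs(self):
        for d1 in range(4):
            for d2 in range(4):
                table = _table([[d1], [d2]])
                got = g.ibs_matrix(table).ibs[0, 1]
                assert got == pytest.approx(ibs_allele_sharing(d1, d2, 3)), (d1, d2)

    def test_identical_and_maximally_different_samples(self):
        assert g.ibs_matrix(_table([[0, 1, 2], [0, 1, 2]])).ibs[0, 1] == 1.0
        assert g.ibs_matrix(_table([[0], [3]])).ibs[0, 1] == 0.0
        assert g.ibs_matrix(_table([[1], [2]])).ibs[0, 1] == pytest.approx(2 / 3)

    def test_diploid_reduction(self):
        # hand-computed diploid dosage IBS: 1 - |di - dj| / 2
        expected = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.5], [0.0, 0.5, 1.0]])
        table = _table([[0], [1], [2]], ploidy=2)
        np.testing.assert_allclose(g.ibs_matrix(table).ibs, expected)

    def test_symmetric_unit_diagonal_bounded(self, genotype_sim):
        m = g.ibs_matrix(genotype_sim.table)
        np.testing.assert_allclose(m.ibs, m.ibs.T)
        np.testing.assert_allclose(np.diag(m.ibs), 1.0)
        assert np.nanmin(m.ibs) >= 0.0 and np.nanmax(m.ibs) <= 1.0

    def test_pair_without_shared_loci_warns_and_is_nan(self):
        dosage = np.array([[1.0, np.nan], [np.nan, 2.0]])
        table = _table(dosage)
        with pytest.warns(UserWarning, match="share no"):
            m = g.ibs_matrix(table)
        assert np.isnan(m.ibs[0, 1])
        assert m.n_loci_used[0, 1] == 0


class TestHierarchicalCluster:
    def test_identical_samples_merge_first_at_zero(self):
        table = _table([[0, 1, 2], [0, 1, 2], [3, 3, 3]])
        tree = g.hierarchical_cluster(g.ibs_matrix(table))
        assert tree.merge_heights()[0] == 0.0
        assert set(tree.cut(2)[:2]) == {tree.cut(2)[0]}

    def test_average_linkage_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = rng.integers(4, 7)
            a = rng.random((n, n))
            dissim = (a + a.T) / 2
            np.fill_diagonal(dissim, 0.0)
            tree = g.hierarchical_cluster(dissim, linkage="average")
            np.testing.assert_allclose(
                tree.merge_heights(), average_linkage_heights(dissim), atol=1e-10
            )

    def test_cut_at_three_recovers_generator_clusters(self, genotype_sim):
        tree = g.hierarchical_cluster(g.ibs_matrix(genotype_sim.table))
        labels = tree.cut(3)
        assert adjusted_rand_score(genotype_sim.labels.to_numpy(), labels) == 1.0

    def test_non_symmetric_input_rejected(self):
        bad = np.array([[0.0, 0.1], [0.2, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            g.hierarchical_cluster(bad)

    def test_newick_export_contains_all_leaves(self, genotype_sim):
        import dendropy

        tree = g.hierarchical_cluster(g.ibs_matrix(genotype_sim.table))
        parsed = dendropy.Tree.get(
            data=tree.to_newick(), schema="newick", preserve_underscores=True
        )
        leaves = {leaf.taxon.label for leaf in parsed.leaf_node_iter()}
        assert leaves == set(genotype_sim.table.sample_ids)


class TestPca:
    def test_duplicate_samples_get_identical_scores(self):
        table = _table([[0, 1, 2, 3], [0, 1, 2, 3], [3, 2, 1, 0]])
        res = g.pca_genotypes(table)
        np.testing.assert_allclose(
            res.scores.iloc[0].to_numpy(), res.scores.iloc[1].to_numpy(), atol=1e-10
        )

    def test_variance_explained_is_a_decreasing_percent_decomposition(self, genotype_sim):
        res = g.pca_genotypes(genotype_sim.table)
        v = res.variance_explained
        assert np.all(np.diff(v) <= 1e-9)
        assert v.sum() <= 100.0 + 1e-6
        assert np.all(v >= 0)

    def test_first_components_separate_the_clusters(self, genotype_sim):
        res = g.pca_genotypes(genotype_sim.table)
        score = silhouette_score(
            res.scores.iloc[:, :2].to_numpy(), genotype_sim.labels.to_numpy()
        )
        assert score > 0

    def test_single_sample_rejected(self):
        table = _table([[0, 1]])
        with pytest.raises(ValueError):
            g.pca_genotypes(table)


class TestGenomewideRescale:
    def test_zero_dissimilarity(self):
        assert g.genomewide_rescale(0.0, 1000, 1e6) == (0, 0.0)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            g.genomewide_rescale(1.5, 1000, 1e6)
        with pytest.raises(ValueError):
            g.genomewide_rescale(0.5, 0, 1e6)

    @given(
        frac=st.floats(0, 1),
        n=st.integers(1, 10**7),
        size=st.floats(1e3, 1e9),
    )
    @settings(max_examples=50, deadline=None)
    def test_count_and_percent_are_consistent(self, frac, n, size):
        count, pct = g.genomewide_rescale(frac, n, size, ndigits=10)
        assert count == round(frac * n)
        assert pct == pytest.approx(100 * count / size, abs=1e-9)
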