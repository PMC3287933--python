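"""Container invariants, readers and preparation filters."""

import numpy as np
import pandas as pd
import pytest

from snpset.data_model import (
    GenotypeMatrix,
    ParseError,
    SnpSet,
    ValidationError,
    classify_variant_frequency,
    compute_maf,
    compute_population_pcs,
    filter_low_burden_genes,
    filter_singleton_variants,
    read_annotations,
    read_genotypes,
    read_samples,
    standardize_columns,
    write_genotypes,
)


def _gm(values, sample_prefix="S", variant_prefix="V"):
    values = np.asarray(values, dtype=float)
    return GenotypeMatrix(
        values,
        [f"{sample_prefix}{i}" for i in range(values.shape[0])],
        [f"{variant_prefix}{j}" for j in range(values.shape[1])],
    )


class TestGenotypeMatrix:
    def test_rejects_bad_entries(self):
        with pytest.raises(ValidationError, match="0/1/2"):
            _gm([[0, 3], [1, 2]])

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValidationError, match="unique"):
            GenotypeMatrix(np.zeros((2, 1)), ["a", "a"], ["v"])

    def test_rejects_shape_mismatch(self):
        with pytest.raises(ValidationError, match="shape"):
            GenotypeMatrix(np.zeros((2, 2)), ["a", "b"], ["v"])

    def test_mean_imputation_of_missing(self):
        g = _gm([[0, 1], [2, np.nan], [1, 1]])
        dos = g.dosages()
        assert dos[1, 1] == pytest.approx(1.0)  # mean of non-missing (1, 1)
        assert not np.isnan(dos).any()


class TestGenotypeIO:
    def test_tsv_roundtrip_exact(self, tmp_path):
        g = _gm([[0, 1], [2, 0], [1, np.nan]])
        path = tmp_path / "geno.tsv"
        write_genotypes(g, path)
        back = read_genotypes(path, format="tsv")
        assert back.sample_ids == g.sample_ids
        assert back.variant_ids == g.variant_ids
        np.testing.assert_array_equal(np.isnan(back.values), np.isnan(g.values))
        np.testing.assert_array_equal(
            back.values[~np.isnan(g.values)], g.values[~np.isnan(g.values)]
        )

    def test_tsv_parse_error_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample_id\tV1\nS1\t0\nS2\tx\n")
        with pytest.raises(ParseError, match="3"):
            read_genotypes(path, format="tsv")

    def test_vcf_additive_coding_and_minor_allele_orientation(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
            "1\t100\tv1\tA\tT\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\tv2\tA\tT\t.\t.\t.\tGT\t1/1\t1/1\t0/1\n"
        )
        g = read_genotypes(vcf, format="vcf")
        # v1: ALT is the minor allele -> direct coding
        np.testing.assert_array_equal(g.values[:, 0], [0, 1, 2])
        # v2: ALT frequency 5/6 -> recode so counts refer to REF (minor)
        np.testing.assert_array_equal(g.values[:, 1], [0, 0, 1])

    def test_vcf_non_diploid_names_variant(self, tmp_path):
        vcf = tmp_path / "hap.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "1\t100\tvx\tA\tT\t.\t.\t.\tGT\t0\t0/1\n"
        )
        with pytest.raises(ParseError, match="vx"):
            read_genotypes(vcf, format="vcf")


class TestSampleReader:
    def _write(self, tmp_path, text):
        p = tmp_path / "samples.tsv"
        p.write_text(text)
        return p

    def test_counts_affected(self, tmp_path):
        p = self._write(
            tmp_path,
            "sample_id\tstatus\tage\tsex\tenvironment\n"
            "a\t1\t50\t0\t1\nb\t0\t41\t1\t0\nc\t0\t60\t0\t0\nd\t1\t55\t1\t1\n",
        )
        df = read_samples(p)
        assert df["status"].sum() == 2 and len(df) == 4

    def test_missing_required_column(self, tmp_path):
        p = self._write(tmp_path, "sample_id\tage\tsex\tenvironment\na\t50\t0\t1\n")
        with pytest.raises(ValidationError, match="status"):
            read_samples(p)

    def test_unknown_columns_ignored_with_warning(self, tmp_path, caplog):
        p = self._write(
            tmp_path,
            "sample_id\tstatus\tage\tsex\tenvironment\tshoe_size\na\t1\t50\t0\t1\t43\n",
        )
        with caplog.at_level("WARNING"):
            df = read_samples(p)
        assert "shoe_size" not in df.columns
        assert any("shoe_size" in r.message for r in caplog.records)

    def test_bad_status_and_duplicates(self, tmp_path):
        p = self._write(
            tmp_path, "sample_id\tstatus\tage\tsex\tenvironment\na\t2\t50\t0\t1\n"
        )
        with pytest.raises(ValidationError, match="status"):
            read_samples(p)
        p2 = self._write(
            tmp_path,
            "sample_id\tstatus\tage\tsex\tenvironment\na\t1\t50\t0\t1\na\t0\t41\t1\t0\n",
        )
        with pytest.raises(ValidationError, match="duplicated"):
            read_samples(p2)


class TestAnnotationReader:
    def test_sets_preserve_file_order(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text(
            "variant_id\tgene\tfunctional_class\n"
            "v1\tGA\tsynonymous\nv2\tGA\tnonsynonymous\nv3\tGB\tnonsynonymous\n"
            "v4\tGA\tsynonymous\nv5\tGB\tsynonymous\n"
        )
        ann, sets = read_annotations(p)
        assert [s.gene for s in sets] == ["GA", "GB"]
        assert sets[0].variant_ids == ["v1", "v2", "v4"]
        assert sets[1].variant_ids == ["v3", "v5"]

    def test_variant_in_two_genes_rejected(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text(
            "variant_id\tgene\tfunctional_class\nv1\tGA\tsynonymous\nv1\tGB\tsynonymous\n"
        )
        with pytest.raises(ValidationError, match="v1"):
            read_annotations(p)

    def test_empty_file_gives_empty_collections(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("")
        ann, sets = read_annotations(p)
        assert ann.empty and sets == []

    def test_bad_functional_class(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("variant_id\tgene\tfunctional_class\nv1\tGA\tmissense\n")
        with pytest.raises(ValidationError, match="functional_class"):
            read_annotations(p)


class TestMafAndClassification:
    @pytest.mark.parametrize(
        "column, expected",
        [
            ([0, 0, 1, 2], 3 / 8),
            ([0, 0, 0, 0], 0.0),
            ([2, 2, 2, 1], 1 / 8),  # raw 7/8 folds to 1/8
        ],
    )
    def test_maf_arithmetic_and_folding(self, column, expected):
        g = _gm(np.asarray(column)[:, None])
        assert compute_maf(g)["maf"].iloc[0] == pytest.approx(expected)

    def test_all_missing_variant_named_in_error(self):
        g = _gm(np.full((3, 1), np.nan))
        with pytest.raises(ValidationError, match="V0"):
            compute_maf(g)

    def test_maf_invariant_to_sample_order(self, rng):
        vals = rng.integers(0, 3, size=(30, 5)).astype(float)
        g = _gm(vals)
        perm = rng.permutation(30)
        g2 = GenotypeMatrix(vals[perm], [g.sample_ids[i] for i in perm], g.variant_ids)
        np.testing.assert_allclose(
            compute_maf(g)["maf"], compute_maf(g2)["maf"], atol=1e-15
        )

    @pytest.mark.parametrize(
        "maf, expected",
        [(0.005, "rare"), (0.05, "common"), (0.01, "common")],  # strict < 1% boundary
    )
    def test_frequency_classification(self, maf, expected):
        ann = pd.DataFrame({"variant_id": ["v"], "maf": [maf]})
        assert classify_variant_frequency(ann)["frequency_class"].iloc[0] == expected


class TestVariantAndGeneFilters:
    def test_singleton_and_monomorphic_removed_doubleton_kept(self):
        # V0: 1 carrier; V1: 2 carriers; V2: 0 carriers
        g = _gm([[1, 1, 0], [0, 1, 0], [0, 0, 0], [0, 0, 0]])
        kept, removed = filter_singleton_variants(g)
        assert kept.variant_ids == ["V1"]
        assert set(removed) == {"V0", "V2"}

    @pytest.mark.parametrize("carriers, retained", [(6, False), (7, True)])
    def test_gene_burden_threshold_at_one_percent_of_697(self, carriers, retained):
        n = 697
        col = np.zeros((n, 1))
        col[:carriers, 0] = 1
        g = _gm(col)
        ann = pd.DataFrame(
            {"variant_id": ["V0"], "gene": ["GA"], "frequency_class": ["rare"]}
        )
        kept, removed = filter_low_burden_genes(g, [SnpSet("GA", ["V0"])], ann)
        assert ([s.gene for s in kept] == ["GA"]) is retained

    def test_gene_with_only_common_variants_retained(self):
        g = _gm([[1], [2], [0]])
        ann = pd.DataFrame(
            {"variant_id": ["V0"], "gene": ["GA"], "frequency_class": ["common"]}
        )
        kept, _ = filter_low_burden_genes(g, [SnpSet("GA", ["V0"])], ann)
        assert [s.gene for s in kept] == ["GA"]

    def test_filters_idempotent(self, small_replicate):
        g1, _ = filter_singleton_variants(small_replicate.genotypes)
        ann_in = small_replicate.annotations
        ann_in = ann_in[ann_in["variant_id"].isin(g1.variant_ids)]
        ann = classify_variant_frequency(compute_maf(g1, ann_in))
        sets1, _ = filter_low_burden_genes(g1, small_replicate.snp_sets, ann)
        g2, removed2 = filter_singleton_variants(g1)
        sets2, removed_genes2 = filter_low_burden_genes(g2, sets1, ann)
        assert removed2 == [] and removed_genes2 == []
        assert [s.gene for s in sets2] == [s.gene for s in sets1]


class TestPopulationPCs:
    def _two_cluster_genotypes(self, rng, n_per=40, p=60):
        f = np.column_stack([rng.uniform(0.1, 0.3, p), rng.uniform(0.6, 0.9, p)])
        vals = np.vstack(
            [rng.binomial(2, f[:, 0], size=(n_per, p)), rng.binomial(2, f[:, 1], size=(n_per, p))]
        ).astype(float)
        return _gm(vals), np.repeat([0, 1], n_per)

    def test_pc1_separates_planted_clusters(self, rng):
        from sklearn.metrics import silhouette_score

        g, labels = self._two_cluster_genotypes(rng)
        scores = compute_population_pcs(g, maf_min=0.05, k=2)
        assert silhouette_score(scores[:, :1], labels) > 0.9

    def test_matches_eigendecomposition_oracle(self, rng):
        g, _ = self._two_cluster_genotypes(rng, n_per=15, p=20)
        scores = compute_population_pcs(g, maf_min=0.05, k=2)
        X = g.dosages()
        X = X[:, compute_maf(g)["maf"].to_numpy() > 0.05]
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        for j, col in enumerate(evecs[:, ::-1].T[:2]):
            proj = Xc @ col
            r = abs(np.corrcoef(proj, scores[:, j])[0, 1])
            assert r == pytest.approx(1.0, abs=1e-8)

    def test_identical_rows_give_zero_scores(self):
        g = _gm(np.tile([1, 0, 2, 1], (6, 1)))
        scores = compute_population_pcs(g, maf_min=0.10, k=2)
        assert np.abs(scores).max() < 1e-12

    def test_rank_one_data_second_pc_is_zero(self, rng):
        base = np.array([0, 1, 2, 1, 0, 1], dtype=float)
        vals = np.column_stack([base, base, base])
        g = _gm(vals)
        scores = compute_population_pcs(g, maf_min=0.05, k=2)
        assert np.abs(scores[:, 1]).max() < 1e-8

    def test_orthogonality_and_variant_order_invariance(self, rng):
        g, _ = self._two_cluster_genotypes(rng)
        s1 = compute_population_pcs(g, maf_min=0.05, k=2)
        gram = s1.T @ s1
        assert abs(gram[0, 1]) < 1e-8 * max(gram[0, 0], gram[1, 1])
        perm = rng.permutation(g.n_variants)
        g2 = GenotypeMatrix(
            g.values[:, perm], g.sample_ids, [g.variant_ids[j] for j in perm]
        )
        s2 = compute_population_pcs(g2, maf_min=0.05, k=2)
        np.testing.assert_allclose(s1, s2, atol=1e-8)

    def test_spacing_filter_greedy_scan(self):
        vals = np.tile([0, 1, 2, 1, 0, 2, 1, 1], (4, 1)).T.astype(float)
        g = _gm(vals)
        ann = pd.DataFrame(
            {
                "variant_id": g.variant_ids,
                "chrom": ["1"] * 4,
                "pos": [100, 30_000, 60_000, 120_000],
            }
        )
        # spacing 50 kb keeps positions 100 and 60_000 and 120_000 -> 3 variants
        scores = compute_population_pcs(g, ann, maf_min=0.05, min_spacing=50_000, k=2)
        assert scores.shape == (8, 2)


class TestStandardize:
    def test_example_and_constant_flag(self):
        out, flags = standardize_columns(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))
        np.testing.assert_allclose(out[:, 0], [-1, 0, 1])
        np.testing.assert_allclose(out[:, 1], [0, 0, 0])
        assert list(flags) == [False, True]

    def test_postconditions_on_random_input(self, rng):
        m = rng.normal(size=(50, 6)) * rng.uniform(0.5, 10, 6)
        out, flags = standardize_columns(m)
        assert not flags.any()
        assert np.abs(out.mean(axis=0)).max() < 1e-12
        np.testing.assert_allclose(out.std(axis=0, ddof=1), 1.0, atol=1e-12)
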