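"""Allelic attribution of expression and per-copy normalisation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hgtscan import allelexpr
from hgtscan.presets import expression_validation_config
from hgtscan.simcohort import simulate_cohort


def gt_rows(tumor, sources):
    """sources: {source: {allele: copies}} -> long genotype rows for one site."""
    rows = []
    for source, alleles in sources.items():
        for allele, copies in alleles.items():
            rows.append(("g1", "chr7", 100, tumor, source, allele, copies))
    return pd.DataFrame(
        rows, columns=["gene", "chrom", "pos", "tumor", "source", "allele", "copies"]
    )


class TestInformativeAlleles:
    def test_allele_in_all_sources_not_informative(self):
        gt = gt_rows("t1", {"host": {"A": 1, "G": 1}, "cancer": {"A": 2, "G": 0}, "HT": {"A": 1}})
        inf = allelexpr.find_informative_alleles(gt)
        # A is in host+cancer+HT; G only in host
        assert list(inf["allele"]) == ["G"]
        assert list(inf["source"]) == ["host"]

    def test_ht_only_allele_informative_with_copy_one(self):
        gt = gt_rows("t1", {"host": {"A": 2}, "cancer": {"A": 2}, "HT": {"G": 1}})
        inf = allelexpr.find_informative_alleles(gt)
        # A is shared by host and cancer; only the HT-private G is informative
        assert len(inf) == 1
        assert list(inf["allele"]) == ["G"]
        assert list(inf["source"]) == ["HT"]
        assert list(inf["copies"]) == [1]

    def test_matches_set_membership_oracle(self):
        """10^4 random genotype triples agree with a brute-force enumeration
        over per-allele source sets."""
        rng = np.random.default_rng(0)
        rows = []
        truth = []
        for case in range(10_000):
            tumor = f"t{case}"
            host = int(rng.integers(0, 3))
            cancer = int(rng.integers(0, 3))
            ht = int(rng.integers(0, 2)) if rng.random() < 0.7 else None
            sources = {
                "host": {"A": 2 - host, "G": host},
                "cancer": {"A": 2 - cancer, "G": cancer},
            }
            if ht is not None:
                sources["HT"] = {"A": 1 - ht, "G": ht}
            for source, alleles in sources.items():
                for allele, copies in alleles.items():
                    rows.append(("g", "chr1", 1, tumor, source, allele, copies))
            # oracle: direct set logic
            for allele in "AG":
                carrying = [s for s, al in sources.items() if al.get(allele, 0) > 0]
                if len(carrying) == 1:
                    truth.append((tumor, allele, carrying[0], sources[carrying[0]][allele]))
        gt = pd.DataFrame(
            rows, columns=["gene", "chrom", "pos", "tumor", "source", "allele", "copies"]
        )
        inf = allelexpr.find_informative_alleles(gt)
        got = set(zip(inf["tumor"], inf["allele"], inf["source"], inf["copies"]))
        assert got == set(truth)


def counts_frame(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "pos", "sample", "allele", "count"])


class TestPerCopyExpression:
    def test_copy_number_division(self):
        """30 reads on a 1-copy allele equal 60 reads on a 2-copy allele."""
        inf = pd.DataFrame(
            [
                ("g1", "chr7", 100, "t1", "G", "HT", 1),
                ("g1", "chr7", 100, "t1", "A", "cancer", 2),
            ],
            columns=["gene", "chrom", "pos", "tumor", "allele", "source", "copies"],
        )
        counts = counts_frame(
            [("g1", "chr7", 100, "t1", "G", 30), ("g1", "chr7", 100, "t1", "A", 60)]
        )
        rec = allelexpr.per_copy_expression(counts, inf, sample_size_factors=pd.Series({"t1": 1.0}))
        by_source = rec.set_index("source")["mean"]
        assert by_source["HT"] == pytest.approx(30.0)
        assert by_source["cancer"] == pytest.approx(30.0)

    def test_median_of_ratios_hand_computation(self):
        """A sample with every count doubled gets size factor 2 and identical
        per-copy values."""
        genes = [f"g{i}" for i in range(9)]
        base = np.array([10, 20, 30, 40, 50, 60, 70, 80, 90], dtype=float)
        counts = pd.DataFrame({"s1": base, "s2": 2 * base}, index=genes)
        sf = allelexpr.size_factors(counts)
        # geometric reference = sqrt(2)*base; ratios 1/sqrt2 and sqrt2
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0, rel=1e-12)

        inf = pd.DataFrame(
            [("g0", "chr7", 1, s, "A", "cancer", 2) for s in ("s1", "s2")],
            columns=["gene", "chrom", "pos", "tumor", "allele", "source", "copies"],
        )
        rows = [("g0", "chr7", 1, "s1", "A", 40), ("g0", "chr7", 1, "s2", "A", 80)]
        rec = allelexpr.per_copy_expression(counts_frame(rows), inf, sample_size_factors=sf)
        vals = rec.set_index("source")
        # identical per-copy values after normalisation -> zero-width CI
        assert vals.loc["cancer", "ci_high"] - vals.loc["cancer", "ci_low"] == pytest.approx(0, abs=1e-9)

    def test_library_size_rescaling_invariance(self):
        """Rescaling each sample's library by its own factor leaves every
        per-copy ratio unchanged (median-of-ratios removes library size up to
        one common constant)."""
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(20)]
        samples = ["s1", "s2", "s3"]
        factors = {"s1": 0.5, "s2": 2.0, "s3": 4.0}
        rows = []
        inf_rows = []
        for g in genes:
            for s in samples:
                rows.append((g, "chr7", 5, s, "A", int(rng.integers(10, 200)) * 8))
                inf_rows.append((g, "chr7", 5, s, "A", "cancer", 2))
        counts = counts_frame(rows)
        inf = pd.DataFrame(
            inf_rows, columns=["gene", "chrom", "pos", "tumor", "allele", "source", "copies"]
        )
        rec1 = allelexpr.per_copy_expression(counts, inf)
        scaled = counts.copy()
        scaled["count"] = (scaled["count"] * scaled["sample"].map(factors)).astype(int)
        rec2 = allelexpr.per_copy_expression(scaled, inf)
        merged = rec1.merge(rec2, on=["gene", "source"], suffixes=("_a", "_b"))
        ratio = merged["mean_b"] / merged["mean_a"]
        np.testing.assert_allclose(ratio, ratio.iloc[0], rtol=1e-9)

    def test_pooling_order_invariance(self):
        """Reordering the input rows (tumors-within-genes vs genes-within-
        tumors) does not change the pooled means."""
        rng = np.random.default_rng(2)
        rows, inf_rows = [], []
        for g in ("g1", "g2"):
            for s in ("s1", "s2", "s3", "s4"):
                rows.append((g, "chr7", 9, s, "G", int(rng.integers(5, 80))))
                inf_rows.append((g, "chr7", 9, s, "G", "HT", 1))
        counts = counts_frame(rows)
        inf = pd.DataFrame(
            inf_rows, columns=["gene", "chrom", "pos", "tumor", "allele", "source", "copies"]
        )
        sf = pd.Series(1.0, index=["s1", "s2", "s3", "s4"])
        rec_a = allelexpr.per_copy_expression(counts, inf, sample_size_factors=sf)
        shuffled = counts.sample(frac=1.0, random_state=3).reset_index(drop=True)
        rec_b = allelexpr.per_copy_expression(shuffled, inf, sample_size_factors=sf)
        pd.testing.assert_frame_equal(rec_a, rec_b)

    def test_min_reads_filter(self):
        inf = pd.DataFrame(
            [("g1", "chr7", 100, "t1", "G", "HT", 1)],
            columns=["gene", "chrom", "pos", "tumor", "allele", "source", "copies"],
        )
        counts = counts_frame([("g1", "chr7", 100, "t1", "G", 3)])
        rec = allelexpr.per_copy_expression(
            counts, inf, sample_size_factors=pd.Series({"t1": 1.0}), min_reads=5
        )
        assert len(rec) == 0


class TestCompareSources:
    @staticmethod
    def records_from(means):
        rows = []
        for gene, (ht, cancer) in means.items():
            rows.append((gene, "HT", ht, ht, ht, 3, 100))
            rows.append((gene, "cancer", cancer, cancer, cancer, 3, 100))
        return pd.DataFrame(
            rows, columns=["gene", "source", "mean", "ci_low", "ci_high", "n_tumors", "total_reads"]
        )

    def test_identical_vectors(self):
        rec = self.records_from({f"g{i}": (float(i + 1), float(i + 1)) for i in range(10)})
        res = allelexpr.compare_sources(rec, "HT", "cancer")
        assert res.pearson_r == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)

    def test_zero_variance_undefined(self):
        rec = self.records_from({f"g{i}": (5.0, float(i)) for i in range(5)})
        res = allelexpr.compare_sources(rec, "HT", "cancer")
        assert np.isnan(res.pearson_r)

    def test_too_few_genes(self):
        rec = self.records_from({"g1": (1.0, 2.0), "g2": (2.0, 3.0)})
        with pytest.raises(ValueError):
            allelexpr.compare_sources(rec, "HT", "cancer")

    def test_null_correlation_calibration(self):
        """Independent expression vectors over 73 genes: |r| < 0.3 in at
        least 95 of 100 seeds."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.lognormal(3.0, 0.8, size=73)
            y = rng.lognormal(3.0, 0.8, size=73)
            r = stats.pearsonr(x, y)[0]
            hits += abs(r) < 0.3
        assert hits >= 95


@pytest.fixture(scope="module")
def expression_cohorts():
    return [simulate_cohort(expression_validation_config(seed)) for seed in range(4)]


def normalized_points(cohort):
    inf = allelexpr.find_informative_alleles(cohort.rna_genotypes)
    totals = cohort.rna_counts.pivot_table(
        index="gene", columns="sample", values="count", aggfunc="sum", fill_value=0
    )
    sf = allelexpr.size_factors(totals)
    merged = inf.merge(
        cohort.rna_counts.rename(columns={"sample": "tumor"}),
        on=["gene", "chrom", "pos", "tumor", "allele"],
    )
    merged["per_copy"] = merged["count"] / merged["tumor"].map(sf) / merged["copies"]
    return merged


class TestGenerativeRecovery:
    def test_ht_expression_matches_cancer_program(self, expression_cohorts):
        """The transferred copy is transcribed at cancer-like per-copy rates:
        within carrier tumors, per-gene Welch tests (1% level, genes with
        >= 3 observations per source) find no HT/cancer difference for
        >= 90% of genes."""
        consistent, total = 0, 0
        for cohort in expression_cohorts:
            pts = normalized_points(cohort)
            pts = pts[pts["tumor"].isin(cohort.truth.carrier_ids)]
            for gene, grp in pts.groupby("gene"):
                ht = grp[grp["source"] == "HT"]["per_copy"]
                cancer = grp[grp["source"] == "cancer"]["per_copy"]
                if len(ht) >= 3 and len(cancer) >= 3:
                    _, p = stats.ttest_ind(ht, cancer, equal_var=False)
                    consistent += p > 0.01
                    total += 1
        assert total >= 20
        assert consistent / total >= 0.90

    def test_ht_follows_cancer_not_host(self, expression_cohorts):
        """r(HT, cancer) exceeds r(HT, host) in every replicate: the element
        is reprogrammed to the cancer's expression program."""
        for cohort in expression_cohorts:
            inf = allelexpr.find_informative_alleles(cohort.rna_genotypes)
            rec = allelexpr.per_copy_expression(cohort.rna_counts, inf)
            r_cancer = allelexpr.compare_sources(rec, "HT", "cancer").pearson_r
            r_host = allelexpr.compare_sources(rec, "HT", "host").pearson_r
            assert r_cancer > r_host
            assert r_cancer > 0.8
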