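"""Allelic deconvolution of bulk tumor RNA expression.

Bulk tumor RNA mixes transcripts from three DNA sources: the transferred
element (HT), the cancer's constitutive parental chromosomes, and the
infiltrating cells of the tumor's own host.  An allele is *informative*
for a source when, in that tumor's genotype configuration, it is carried by
exactly that one source; reads on informative alleles can then be
attributed unambiguously.

Counts are normalised by median-of-ratios size factors, divided by the
informative allele's genomic copy number in its source, and pooled per
(gene, source) across tumors with SEM-based 95% confidence intervals.
Source programs are compared gene-wise by least-squares regression and
Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

Z95 = 1.959963984540054
DEFAULT_MIN_READS = 5
SOURCES = ("HT", "cancer", "host")


@dataclass(frozen=True)
class InformativeAllele:
    gene: str
    chrom: str
    pos: int
    tumor: str
    allele: str
    source: str
    copies: int


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    p_value: float
    n_genes: int


def find_informative_alleles(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Single-source alleles per (gene, site, tumor).

    ``genotypes`` is long-form with columns gene, chrom, pos, tumor, source,
    allele, copies (one row per allele a source carries; copies > 0).  An
    allele is informative when exactly one source carries it; the emitted
    copy number is that source's.
    """
    present = genotypes[genotypes["copies"] > 0]
    key = ["gene", "chrom", "pos", "tumor", "allele"]
    n_sources = present.groupby(key, sort=False)["source"].transform("nunique")
    informative = present[n_sources == 1]
    return (
        informative[["gene", "chrom", "pos", "tumor", "allele", "source", "copies"]]
        .sort_values(key, ignore_index=True)
    )


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors from a gene x sample total-count matrix.

    Genes with a zero count in any sample are excluded from the geometric
    reference, as is standard for this normalisation.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample")
    log_ref = np.log(mat[positive]).mean(axis=1)
    ratios = np.log(mat[positive]) - log_ref[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def per_copy_expression(
    allele_counts: pd.DataFrame,
    informative: pd.DataFrame,
    sample_size_factors: pd.Series | None = None,
    min_reads: int = DEFAULT_MIN_READS,
) -> pd.DataFrame:
    """Pooled per-copy expression per (gene, source).

    ``allele_counts`` is long-form (gene, chrom, pos, sample, allele, count).
    Counts on informative alleles are divided by the sample's size factor
    (computed from per-gene total counts when not supplied) and by the
    allele's copy number, then pooled across tumors.  Genes with fewer than
    ``min_reads`` informative reads in a source are dropped.  Returns
    gene/source/mean/ci_low/ci_high/n_tumors/total_reads.
    """
    if sample_size_factors is None:
        totals = allele_counts.pivot_table(
            index="gene", columns="sample", values="count", aggfunc="sum", fill_value=0
        )
        sample_size_factors = size_factors(totals)
    zero = sample_size_factors[sample_size_factors <= 0]
    if len(zero):
        import warnings

        warnings.warn(f"excluding samples with zero size factor: {list(zero.index)}")
        sample_size_factors = sample_size_factors[sample_size_factors > 0]

    merged = informative.merge(
        allele_counts.rename(columns={"sample": "tumor"}),
        on=["gene", "chrom", "pos", "tumor", "allele"],
        how="inner",
    )
    merged = merged[merged["tumor"].isin(sample_size_factors.index)]
    merged["normalized"] = merged["count"] / merged["tumor"].map(sample_size_factors)
    merged["per_copy"] = merged["normalized"] / merged["copies"]

    rows = []
    for (gene, source), grp in merged.groupby(["gene", "source"], sort=True):
        if grp["count"].sum() < min_reads:
            continue
        vals = grp["per_copy"].to_numpy()
        mean = float(vals.mean())
        sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
        rows.append(
            (gene, source, mean, mean - Z95 * sem, mean + Z95 * sem, len(vals), int(grp["count"].sum()))
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "source", "mean", "ci_low", "ci_high", "n_tumors", "total_reads"],
    )


def compare_sources(records: pd.DataFrame, source_x: str, source_y: str) -> RegressionResult:
    """OLS fit and Pearson correlation of per-gene means between two sources.

    Requires >= 3 genes informative in both sources; zero variance in either
    vector leaves r undefined (NaN).
    """
    wide = records.pivot_table(index="gene", columns="source", values="mean")
    both = wide[[source_x, source_y]].dropna()
    n = len(both)
    if n < 3:
        raise ValueError(f"need >= 3 genes with means in both sources; got {n}")
    x = both[source_x].to_numpy()
    y = both[source_y].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return RegressionResult(float("nan"), float("nan"), float("nan"), float("nan"), float("nan"), n)
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n_genes=n,
    )
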