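"""Readers and writers for the pipeline's on-disk formats.

Tabular data travel as TSV (site tables wide by sample for compactness),
copy-number segments as 5-column BED, junctions as BEDPE, truth and reports
as JSON.  Site counts can additionally be exported to VCF with AD-style
allele depths (one sample column per tumor and host) via pysam.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "is_transversion"]
BED_CN_COLUMNS = ["chrom", "start", "end", "sample", "total_cn"]
BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "support", "strand1", "strand2",
]


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix(df: pd.DataFrame, path) -> None:
    """Sample-column matrix with a leading row index column."""
    df.to_csv(path, sep="\t", index=True, index_label="row")


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="row")
    df.index.name = None
    return df


def write_bed_segments(segments: pd.DataFrame, path) -> None:
    segments[BED_CN_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_bed_segments(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=BED_CN_COLUMNS)


def write_bedpe(junctions: pd.DataFrame, path) -> None:
    junctions[BEDPE_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_bedpe(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=BEDPE_COLUMNS)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_vcf(
    sites: pd.DataFrame,
    ref_counts: pd.DataFrame,
    alt_counts: pd.DataFrame,
    chrom_lengths: dict[str, int],
    path,
) -> None:
    """Biallelic site counts as a VCF with per-sample AD fields."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Allelic depths for the ref and alt alleles">'
    )
    for chrom, length in chrom_lengths.items():
        header.contigs.add(chrom, length=length)
    samples = list(ref_counts.columns)
    for s in samples:
        header.add_sample(s)
    ref_mat = ref_counts.to_numpy()
    alt_mat = alt_counts.to_numpy()
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for i in range(len(sites)):
            rec = vf.new_record(
                contig=sites["chrom"].iat[i],
                start=int(sites["pos"].iat[i]) - 1,
                alleles=(sites["ref"].iat[i], sites["alt"].iat[i]),
            )
            for j, s in enumerate(samples):
                rec.samples[s]["AD"] = (int(ref_mat[i, j]), int(alt_mat[i, j]))
            vf.write(rec)


def read_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(sites, ref_counts, alt_counts) from an AD-carrying VCF."""
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        site_rows, refs, alts = [], [], []
        for rec in vf:
            site_rows.append((rec.contig, rec.pos, rec.alleles[0], rec.alleles[1]))
            ad = [rec.samples[s]["AD"] for s in samples]
            refs.append([a[0] for a in ad])
            alts.append([a[1] for a in ad])
    sites = pd.DataFrame(site_rows, columns=["chrom", "pos", "ref", "alt"])
    return (
        sites,
        pd.DataFrame(refs, columns=samples),
        pd.DataFrame(alts, columns=samples),
    )


def write_site_counts_tsv(sites, ref_counts, alt_counts, path) -> None:
    """Long-form per-site, per-sample allele depths."""
    long = []
    for s in ref_counts.columns:
        sub = sites.copy()
        sub["sample"] = s
        sub["ref_reads"] = ref_counts[s].to_numpy()
        sub["alt_reads"] = alt_counts[s].to_numpy()
        long.append(sub)
    pd.concat(long, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_site_counts_tsv(path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    long = pd.read_csv(path, sep="\t")
    site_cols = [c for c in SITE_COLUMNS if c in long.columns]
    sites = long[site_cols].drop_duplicates().reset_index(drop=True)
    key = ["chrom", "pos"]
    idx = sites.set_index(key).index
    ref = long.pivot_table(index=key, columns="sample", values="ref_reads").loc[idx].reset_index(drop=True)
    alt = long.pivot_table(index=key, columns="sample", values="alt_reads").loc[idx].reset_index(drop=True)
    ref.columns.name = None
    alt.columns.name = None
    return sites, ref, alt
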