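"""Inference of the transferred haplotype's genotype by parental subtraction.

Inside step segments a carrier tumor carries the cancer's parental
chromosomes plus one transferred copy.  The parental allele dosage at a
biallelic site is known from the non-carrier tumors (which carry the same
clonal founder genome without the transfer), so the transferred copy's
allele can be read off the carriers' allele counts: the observed alternate
dosage is either a_p (transferred copy carries the reference allele) or
a_p + 1 (alternate).  Both hypotheses are scored by binomial likelihoods of
the purity-adjusted mixture and combined across carriers by summing
log-likelihoods; weak evidence yields an undetermined call.

Following the study design the inference defaults to biallelic transversion
variants — transitions overlap the dominant somatic C>T mutation classes and
are also the sites most exposed to recurrent mutation in any downstream
population-genetic comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from . import genostate
from .intervals import cn_matrix, sites_in_intervals

DEFAULT_LLR_THRESHOLD = 3.0  # |delta log L| below this -> undetermined
_EPS = 1e-9


@dataclass(frozen=True)
class HTGenotype:
    chrom: str
    pos: int
    ht_allele: str  # 'ref' | 'alt' | 'undetermined'
    log_likelihood_ratio: float  # positive favours alt
    parental_dosage: int
    reason: str | None = None


def infer_ht_genotypes(
    sites: pd.DataFrame,
    ref_counts: pd.DataFrame,
    alt_counts: pd.DataFrame,
    samples: pd.DataFrame,
    cn_segments: pd.DataFrame,
    step_segments: pd.DataFrame,
    carrier_ids: list[str],
    noncarrier_ids: list[str],
    transversions_only: bool = True,
    llr_threshold: float = DEFAULT_LLR_THRESHOLD,
    min_depth: int = genostate.DEFAULT_MIN_DEPTH,
) -> list[HTGenotype]:
    """Call the transferred haplotype's allele at sites in step segments.

    ``samples`` must map tumors to purity and matched hosts; host read
    counts provide the contamination dosage.  Sites where the carriers'
    copy number is not consistently parental + 1 are returned undetermined
    with a reason.
    """
    mask = sites_in_intervals(
        sites["chrom"].to_numpy(), sites["pos"].to_numpy(), step_segments
    )
    if transversions_only and "is_transversion" in sites:
        mask &= sites["is_transversion"].to_numpy()
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []

    tumors = samples[samples["kind"] == "tumor"].set_index("sample_id")
    purity = {t: float(tumors.loc[t, "purity"]) for t in list(carrier_ids) + list(noncarrier_ids)}
    host_of = {t: tumors.loc[t, "matched_host"] for t in carrier_ids}

    sub_sites = sites.iloc[idx].reset_index(drop=True)
    cn_all = cn_matrix(cn_segments, sub_sites, list(carrier_ids) + list(noncarrier_ids))

    # parental dosage from non-carrier ML genotypes (modal alt-copy count)
    nc_ref = ref_counts.iloc[idx][list(noncarrier_ids)].to_numpy()
    nc_alt = alt_counts.iloc[idx][list(noncarrier_ids)].to_numpy()
    nc_p = np.array([purity[t] for t in noncarrier_ids])
    nc_cn = cn_all[list(noncarrier_ids)].to_numpy()
    nc_host = np.zeros_like(nc_ref, dtype=float)
    for j, t in enumerate(noncarrier_ids):
        h = tumors.loc[t, "matched_host"]
        if h in ref_counts.columns:
            nc_host[:, j] = genostate.host_dosage_fractions(
                ref_counts.iloc[idx][h].to_numpy(), alt_counts.iloc[idx][h].to_numpy(), min_depth
            )
    k_nc, state_nc, _ = genostate.classify_genotypes(
        nc_ref, nc_alt, nc_p[None, :], nc_cn, np.nan_to_num(nc_host, nan=0.0), min_depth
    )

    out: list[HTGenotype] = []
    car_ref = ref_counts.iloc[idx][list(carrier_ids)].to_numpy()
    car_alt = alt_counts.iloc[idx][list(carrier_ids)].to_numpy()
    car_cn = cn_all[list(carrier_ids)].to_numpy()
    car_p = np.array([purity[t] for t in carrier_ids])
    car_host = np.zeros_like(car_ref, dtype=float)
    for j, t in enumerate(carrier_ids):
        h = host_of[t]
        if h in ref_counts.columns:
            car_host[:, j] = genostate.host_dosage_fractions(
                ref_counts.iloc[idx][h].to_numpy(), alt_counts.iloc[idx][h].to_numpy(), min_depth
            )
    car_host = np.nan_to_num(car_host, nan=0.0)

    for i in range(len(sub_sites)):
        chrom = sub_sites["chrom"].iat[i]
        pos = int(sub_sites["pos"].iat[i])
        valid_nc = k_nc[i] >= 0
        if not valid_nc.any():
            out.append(HTGenotype(chrom, pos, "undetermined", 0.0, -1, "no non-carrier calls"))
            continue
        a_p, tied = _modal(k_nc[i][valid_nc])
        if a_p is None:
            out.append(HTGenotype(chrom, pos, "undetermined", 0.0, -1, "parental dosage tied"))
            continue
        c_parental = int(np.median(nc_cn[i][valid_nc]))
        c_expected = c_parental + 1
        if not np.all(car_cn[i] == c_expected):
            out.append(
                HTGenotype(chrom, pos, "undetermined", 0.0, a_p,
                           "inconsistent carrier copy number")
            )
            continue
        ll = np.zeros(2)
        used = 0
        for j in range(len(carrier_ids)):
            depth = car_ref[i, j] + car_alt[i, j]
            if depth < min_depth:
                continue
            p = car_p[j]
            denom = p * c_expected + 2.0 * (1.0 - p)
            for hyp, extra in enumerate((0, 1)):
                dose = min(a_p + extra, c_expected)
                q = (p * dose + (1.0 - p) * 2.0 * car_host[i, j]) / denom
                ll[hyp] += binom.logpmf(car_alt[i, j], depth, np.clip(q, _EPS, 1 - _EPS))
            used += 1
        if used == 0:
            out.append(HTGenotype(chrom, pos, "undetermined", 0.0, a_p, "no carrier coverage"))
            continue
        llr = float(ll[1] - ll[0])
        if abs(llr) < llr_threshold:
            call = "undetermined"
            reason = "weak evidence"
        else:
            call = "alt" if llr > 0 else "ref"
            reason = None
        out.append(HTGenotype(chrom, pos, call, llr, a_p, reason))
    return out


def _modal(values):
    vals, counts = np.unique(values, return_counts=True)
    top = counts.max()
    winners = vals[counts == top]
    if len(winners) > 1:
        return None, True
    return int(winners[0]), False


def genotypes_to_frame(calls: list[HTGenotype]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.chrom, c.pos, c.ht_allele, c.log_likelihood_ratio, c.parental_dosage, c.reason)
            for c in calls
        ],
        columns=["chrom", "pos", "ht_allele", "llr", "parental_dosage", "reason"],
    )
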