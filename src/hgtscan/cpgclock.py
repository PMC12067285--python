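"""CpG molecular-clock dating of the horizontal-transfer event.

C>T substitutions at CpG dinucleotides accumulate at an approximately
constant rate per site per year per chromosome copy, which makes their
density a clock.  The transferred haplotype arrived carrying none of the
cancer's somatic mutations, so its own (C>T)G density measures the time
since the transfer.

The estimator is a parental subtraction.  In "step segments" — copy-number
segments whose modal state in non-carrier tumors is 0, 1 or 2 and exactly
one higher in carriers — the per-copy (C>T)G density of the cancer's
parental chromosomes is measured in non-carrier tumors per 1-kb bin.  The
expected parental count is subtracted from each carrier's observed bin
count (adjusting for copy number); the residual mutation mass is attributed
to the transferred copy.  The mean residual per CpG site across all bins,
averaged over carriers with its SE, divided by the per-copy substitution
rate, gives the age of the event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .intervals import modal_value

DEFAULT_RATE_DIPLOID = 6.87e-7  # substitutions / site / year / diploid genome
Z95 = 1.959963984540054


@dataclass
class DensityEstimate:
    """Per-copy (C>T)G density in mutations per CpG site per chromosome copy."""

    mean: float
    se: float
    ci_low: float
    ci_high: float
    per_tumor: dict[str, float]
    n_bins: int
    n_cpg_sites: int


@dataclass
class ClockEstimate:
    parental: DensityEstimate
    ht: DensityEstimate
    ht_range: tuple[float, float]  # min/max per-carrier mean
    rate_per_copy: float
    age_years: int
    age_raw: float
    age_ci: tuple[float, float]


def select_informative_segments(
    cn_segments: pd.DataFrame,
    carrier_ids,
    noncarrier_ids,
    max_parental_cn: int = 2,
) -> pd.DataFrame:
    """Step segments usable for the clock.

    Keeps segments where the non-carrier modal copy number is in
    {0..max_parental_cn} and the carrier modal state is exactly one higher.
    Returns chrom/start/end/parental_cn.
    """
    rows = []
    for (c, s, e), grp in cn_segments.groupby(["chrom", "start", "end"]):
        m_non, tie_non = modal_value(grp[grp["sample"].isin(noncarrier_ids)]["total_cn"])
        m_car, tie_car = modal_value(grp[grp["sample"].isin(carrier_ids)]["total_cn"])
        if tie_non or tie_car or m_non is None or m_car is None:
            continue
        if 0 <= m_non <= max_parental_cn and m_car == m_non + 1:
            rows.append((c, int(s), int(e), int(m_non)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "parental_cn"])


def _bins_in_segments(bins: pd.DataFrame, segments: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(bin mask, parental CN per selected bin) for bins inside step segments."""
    mask = np.zeros(len(bins), dtype=bool)
    pcn = np.zeros(len(bins), dtype=np.int64)
    bc = bins["chrom"].to_numpy()
    bs = bins["start"].to_numpy()
    be = bins["end"].to_numpy()
    for _, seg in segments.iterrows():
        hit = (bc == seg["chrom"]) & (bs >= seg["start"]) & (be <= seg["end"])
        mask |= hit
        pcn[hit] = seg["parental_cn"]
    return mask, pcn[mask]


def parental_density(
    mutations_cpg: pd.DataFrame,
    bins: pd.DataFrame,
    segments: pd.DataFrame,
    noncarrier_ids,
) -> tuple[pd.Series, DensityEstimate]:
    """Per-bin and cohort parental (C>T)G density from non-carrier tumors.

    ``mutations_cpg`` is the per-bin CpG C>T count table (bins x tumors);
    per bin the density is the non-carrier mean of count / (CpG sites x
    parental copies).  The cohort summary averages per-tumor densities with
    a normal-approximation 95% CI across tumors.  Bins without CpG sites
    are excluded.
    """
    mask, pcn_sel = _bins_in_segments(bins, segments)
    idx = bins.index[mask]
    cpg = bins.loc[mask, "cpg_sites"].to_numpy().astype(float)
    # bins without CpG sites carry no clock signal; parental-CN-0 segments
    # carry no parental DNA to measure
    keep = (cpg > 0) & (pcn_sel > 0)
    if not keep.any():
        raise ConfigError("no usable bins inside step segments")
    idx = idx[keep]
    cpg = cpg[keep]
    pcn = pcn_sel[keep].astype(float)
    counts = mutations_cpg.loc[idx, list(noncarrier_ids)].to_numpy()

    per_bin = (counts / (cpg * pcn)[:, None]).mean(axis=1)
    per_tumor = counts.sum(axis=0) / (cpg * pcn).sum()
    mean = float(per_tumor.mean())
    se = float(per_tumor.std(ddof=1) / np.sqrt(len(per_tumor))) if len(per_tumor) > 1 else float("nan")
    est = DensityEstimate(
        mean=mean,
        se=se,
        ci_low=mean - Z95 * se,
        ci_high=mean + Z95 * se,
        per_tumor=dict(zip(noncarrier_ids, per_tumor)),
        n_bins=int(len(cpg)),
        n_cpg_sites=int(cpg.sum()),
    )
    return pd.Series(per_bin, index=idx, name="parental_density_per_bin"), est


def ht_density(
    mutations_cpg: pd.DataFrame,
    bins: pd.DataFrame,
    segments: pd.DataFrame,
    per_bin_parental: pd.Series,
    carrier_ids,
) -> DensityEstimate:
    """Subtraction estimator of the transferred copy's (C>T)G density.

    Per carrier and bin the residual is observed count minus the expected
    parental mass (per-bin parental density x parental copies x CpG sites);
    the per-carrier density is the summed residual over summed CpG sites.
    Negative residuals are counting noise and are retained; the cohort mean
    is only clamped at zero in the reported ``mean`` (raw value kept in
    ``per_tumor``).  SE is taken across carriers.
    """
    mask, pcn = _bins_in_segments(bins, segments)
    sel = bins.loc[mask]
    use = sel.index.intersection(per_bin_parental.index)
    if len(use) == 0:
        raise ConfigError("no overlap between carrier bins and parental densities")
    sel = sel.loc[use]
    pcn = pd.Series(pcn, index=bins.index[mask]).loc[use].to_numpy().astype(float)
    cpg = sel["cpg_sites"].to_numpy().astype(float)
    counts = mutations_cpg.loc[use, list(carrier_ids)].to_numpy()
    expected = (per_bin_parental.loc[use].to_numpy() * pcn * cpg)[:, None]
    resid = counts - expected
    per_carrier = resid.sum(axis=0) / cpg.sum()
    raw_mean = float(per_carrier.mean())
    se = float(per_carrier.std(ddof=1) / np.sqrt(len(per_carrier))) if len(per_carrier) > 1 else float("nan")
    mean = max(raw_mean, 0.0)
    return DensityEstimate(
        mean=mean,
        se=se,
        ci_low=raw_mean - Z95 * se,
        ci_high=raw_mean + Z95 * se,
        per_tumor=dict(zip(carrier_ids, per_carrier)),
        n_bins=int(len(cpg)),
        n_cpg_sites=int(cpg.sum()),
    )


def density_to_years(
    d_h: float,
    se: float = float("nan"),
    rate_diploid: float = DEFAULT_RATE_DIPLOID,
) -> tuple[int, float, tuple[float, float]]:
    """Convert a per-copy density to an age in years.

    The per-copy rate is half the diploid rate; age = density / rate,
    rounded to the nearest year for reporting (raw float returned too).
    The 95% CI propagates the SE of the density.
    """
    if rate_diploid <= 0:
        raise ConfigError("rate must be positive")
    r = rate_diploid / 2.0
    raw = d_h / r
    ci = ((d_h - Z95 * se) / r, (d_h + Z95 * se) / r)
    return int(round(raw)), raw, ci


def estimate_clock(
    mutations_cpg: pd.DataFrame,
    bins: pd.DataFrame,
    cn_segments: pd.DataFrame,
    carrier_ids,
    noncarrier_ids,
    rate_diploid: float = DEFAULT_RATE_DIPLOID,
) -> ClockEstimate:
    """End-to-end clock: segments -> parental density -> subtraction -> age."""
    segments = select_informative_segments(cn_segments, carrier_ids, noncarrier_ids)
    if len(segments) == 0:
        raise ConfigError("no step segments found; nothing to date")
    per_bin, parental = parental_density(mutations_cpg, bins, segments, noncarrier_ids)
    ht = ht_density(mutations_cpg, bins, segments, per_bin, carrier_ids)
    years, raw, ci = density_to_years(ht.mean, ht.se, rate_diploid)
    per_carrier = np.array(list(ht.per_tumor.values()))
    return ClockEstimate(
        parental=parental,
        ht=ht,
        ht_range=(float(per_carrier.min()), float(per_carrier.max())),
        rate_per_copy=rate_diploid / 2.0,
        age_years=years,
        age_raw=raw,
        age_ci=ci,
    )
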