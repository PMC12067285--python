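"""Validation of candidate transfer regions by three lines of evidence.

1. Copy-number step: every copy-number segment intersecting the region must
   sit exactly one integer state higher in carrier tumors than in
   non-carriers (modal states per group).
2. Somatic-VAF pattern: in carrier regions of copy number 3, somatic
   mutations introduced on parental chromosomes before the gain would ride
   2 of 3 copies; a horizontally transferred haplotype arrives free of the
   cancer's somatic mutations, so mutations should sit on 1 of 3 copies
   (purity-corrected VAF 1/3).  The test compares per-mutation binomial
   likelihoods of the two dosages.
3. Mutation-density deficit: DNA acquired recently carries fewer somatic
   mutations per copy than DNA present since the lineage's origin.  Window
   densities (mutations per 10 kb per chromosome copy) inside the region are
   compared with an equal number of immediately flanking windows by Welch's
   two-sided t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import binom

from .intervals import modal_value

DEFAULT_DENSITY_WINDOW = 10_000
MIN_VAF_MUTATIONS = 10


@dataclass
class HallmarkReport:
    """Joint evidence for one region in one carrier-vs-rest contrast."""

    chrom: str
    start: int
    end: int
    cn_step: int | None
    cn_step_pass: bool
    vaf_fraction_two_thirds: float | None
    vaf_pattern_pass: bool | None  # None = undetermined
    percent_reduction: float
    t_statistic: float
    p_value: float
    density_footprint: list[float] = field(default_factory=list)
    density_flank: list[float] = field(default_factory=list)
    flank_imbalanced: bool = False


def copy_number_step(
    region: tuple[str, int, int],
    cn_segments: pd.DataFrame,
    carrier_ids,
    noncarrier_ids,
) -> tuple[pd.DataFrame, int | None, bool]:
    """Modal copy-number step per segment intersecting the region.

    Returns (per-segment table, overall step, pass).  The hallmark passes
    only if every intersecting segment steps by exactly +1; modal ties make
    a segment indeterminate and fail the hallmark.
    """
    chrom, start, end = region
    sub = cn_segments[
        (cn_segments["chrom"] == chrom)
        & (cn_segments["start"] < end)
        & (cn_segments["end"] > start)
    ]
    rows = []
    for (s, e), grp in sub.groupby(["start", "end"]):
        car = grp[grp["sample"].isin(carrier_ids)]["total_cn"]
        non = grp[grp["sample"].isin(noncarrier_ids)]["total_cn"]
        m_car, tie_car = modal_value(car)
        m_non, tie_non = modal_value(non)
        indeterminate = tie_car or tie_non or m_car is None or m_non is None
        step = None if indeterminate else m_car - m_non
        rows.append((chrom, int(s), int(e), m_car, m_non, step, indeterminate))
    table = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "carrier_modal", "noncarrier_modal", "step", "indeterminate"],
    )
    if len(table) == 0:
        return table, None, False
    ok = (~table["indeterminate"]) & (table["step"] == 1)
    overall = table["step"].iloc[0] if table["step"].nunique(dropna=True) == 1 else None
    return table, (int(overall) if overall is not None and not pd.isna(overall) else None), bool(ok.all())


def vaf_pattern_test(
    mutations: pd.DataFrame,
    purity,
    total_cn: int = 3,
    fail_fraction: float = 0.05,
    min_mutations: int = MIN_VAF_MUTATIONS,
) -> tuple[float | None, bool | None]:
    """Fraction of somatic mutations favouring dosage 2/3 over 1/3.

    ``mutations`` needs ref_reads/alt_reads columns; ``purity`` may be a
    scalar or a per-row array.  The hallmark passes when fewer than
    ``fail_fraction`` of mutations favour the 2-of-3 dosage (the footprint
    of a parental-chromosome duplication rather than a transfer).  Fewer
    than ``min_mutations`` mutations -> (fraction, None) undetermined.
    """
    n = len(mutations)
    if n < min_mutations:
        frac = _fraction_two_thirds(mutations, purity, total_cn) if n else None
        return frac, None
    frac = _fraction_two_thirds(mutations, purity, total_cn)
    return frac, bool(frac < fail_fraction)


def _fraction_two_thirds(mutations, purity, total_cn):
    alt = mutations["alt_reads"].to_numpy()
    depth = alt + mutations["ref_reads"].to_numpy()
    p = np.broadcast_to(np.asarray(purity, dtype=float), alt.shape)
    denom = p * total_cn + 2.0 * (1.0 - p)
    q1 = p * 1.0 / denom
    q2 = p * 2.0 / denom
    ll1 = binom.logpmf(alt, depth, q1)
    ll2 = binom.logpmf(alt, depth, q2)
    return float(np.mean(ll2 > ll1))


def window_densities(
    region: tuple[str, int, int],
    bins: pd.DataFrame,
    counts: pd.Series,
    cn_of_window,
    window: int = DEFAULT_DENSITY_WINDOW,
    chrom_length: int | None = None,
    exclude: pd.DataFrame | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Per-copy mutation densities for footprint and flanking windows.

    ``bins`` is the 1-kb bin table (chrom/start/end) and ``counts`` the
    per-bin mutation counts of one tumor; windows of ``window`` bp are
    assembled from whole bins.  Flank windows are drawn immediately adjacent
    to the region, split evenly between the two sides, truncated at
    chromosome ends, at the extent of binned data and at ``exclude``
    intervals; if fewer flank windows than footprint windows are available
    the maximum available is used and the imbalance flagged.

    Returns (footprint densities, flank densities, imbalanced).
    """
    chrom, start, end = region
    on = (bins["chrom"] == chrom).to_numpy()
    bin_width = int(bins["end"].iat[0] - bins["start"].iat[0])
    bstart = bins.loc[on, "start"].to_numpy()
    bcounts = counts.to_numpy()[on] if isinstance(counts, pd.Series) else np.asarray(counts)[on]
    lookup = dict(zip(bstart.tolist(), bcounts.tolist()))

    def density_of(ws: int):
        """Per-copy density of window [ws, ws+window), or None if unusable."""
        bin_starts = range(ws, ws + window, bin_width)
        if any(b not in lookup for b in bin_starts):
            return None
        if exclude is not None and len(exclude):
            hit = exclude[
                (exclude["chrom"] == chrom)
                & (exclude["start"] < ws + window)
                & (exclude["end"] > ws)
            ]
            if len(hit):
                return None
        cn = cn_of_window(chrom, ws, ws + window)
        if cn is None or cn <= 0:
            return None
        return sum(lookup[b] for b in bin_starts) / cn

    foot = []
    for ws in range(start, end - window + 1, window):
        d = density_of(ws)
        if d is not None:
            foot.append(d)

    def walk(edge: int, step: int, limit: int) -> list[float]:
        """Contiguous usable windows from the region edge outwards."""
        out: list[float] = []
        ws = edge if step > 0 else edge - window
        while len(out) < limit:
            if ws < 0 or (chrom_length is not None and ws + window > chrom_length):
                break
            d = density_of(ws)
            if d is None:
                break
            out.append(d)
            ws += step * window
        return out

    want = len(foot)
    left = walk(start, -1, want)
    right = walk(end, +1, want)
    n_left = min(len(left), (want + 1) // 2)
    n_right = min(len(right), want - n_left)
    if n_left + n_right < want:  # truncated side: top up from the other
        n_left = min(len(left), want - n_right)
    flank = left[:n_left] + right[:n_right]
    imbalanced = len(flank) < want
    return np.asarray(foot, dtype=float), np.asarray(flank, dtype=float), imbalanced


def mutation_density_contrast(
    footprint: np.ndarray, flank: np.ndarray
) -> tuple[float, float, float]:
    """Welch two-sided t-test of per-copy densities; returns
    (percent_reduction, t, p)."""
    foot = np.asarray(footprint, dtype=float)
    fla = np.asarray(flank, dtype=float)
    if len(foot) == 0 or len(fla) == 0:
        return float("nan"), float("nan"), float("nan")
    reduction = 100.0 * (1.0 - foot.mean() / fla.mean()) if fla.mean() > 0 else float("nan")
    t, p = stats.ttest_ind(foot, fla, equal_var=False)
    return float(reduction), float(t), float(p)


def evaluate_region(
    region: tuple[str, int, int],
    cn_segments: pd.DataFrame,
    carrier_ids,
    noncarrier_ids,
    mutations: pd.DataFrame,
    purity_by_sample: dict[str, float],
    bins: pd.DataFrame,
    counts_all: pd.DataFrame,
    carrier_for_density: str,
    chrom_length: int | None = None,
    exclude: pd.DataFrame | None = None,
    window: int = DEFAULT_DENSITY_WINDOW,
) -> HallmarkReport:
    """Assemble the three hallmarks for one region.

    ``mutations`` holds carrier somatic mutations within the region (one row
    per mutation per tumor with read counts); the density contrast is
    computed for ``carrier_for_density``.
    """
    chrom, start, end = region
    _, step, step_pass = copy_number_step(region, cn_segments, carrier_ids, noncarrier_ids)

    in_region = (
        (mutations["chrom"] == chrom)
        & (mutations["pos"] > start)
        & (mutations["pos"] <= end)
        & mutations["sample"].isin(carrier_ids)
    )
    muts = mutations[in_region]
    pur = muts["sample"].map(purity_by_sample).to_numpy() if len(muts) else np.array([])
    frac23, vaf_pass = vaf_pattern_test(muts, pur)

    def cn_of_window(c, s, e):
        sub = cn_segments[
            (cn_segments["chrom"] == c)
            & (cn_segments["sample"] == carrier_for_density)
            & (cn_segments["start"] < e)
            & (cn_segments["end"] > s)
        ]
        if len(sub) == 0:
            return None
        mode, tied = modal_value(sub["total_cn"])
        return None if tied else mode

    foot, fla, imbalanced = window_densities(
        region, bins, counts_all[carrier_for_density], cn_of_window,
        window=window, chrom_length=chrom_length, exclude=exclude,
    )
    reduction, t, p = mutation_density_contrast(foot, fla)
    return HallmarkReport(
        chrom=chrom, start=start, end=end,
        cn_step=step, cn_step_pass=step_pass,
        vaf_fraction_two_thirds=frac23, vaf_pattern_pass=vaf_pass,
        percent_reduction=reduction, t_statistic=t, p_value=p,
        density_footprint=list(foot), density_flank=list(fla),
        flank_imbalanced=imbalanced,
    )
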