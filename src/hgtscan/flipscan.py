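"""Flipping-SNP calling and candidate-region detection.

A "flipping SNP" is a germline SNP whose per-tumor genotype state conflicts
with the lineage consensus: heterozygous where the cancer is consensus
homozygous (the signature of an introduced non-parental haplotype) or the
reverse.  The screen is restricted to genomic segments of copy number >= 2
that demonstrably retain both parental homologues (a minimum density of
consensus-heterozygous SNPs), because a transfer replacing a haplotype in a
region that has lost heterozygosity is indistinguishable from simple LOH.

Regions of anomalously high flip density per tumor are found by flagging
fixed-width windows that are outliers under two complementary statistics —
a robust z-score built from the median absolute deviation of the tumor's
genome-wide window counts, and the Cook's distance of the window in an
ordinary least-squares regression of the tumor's counts on the cohort-median
window profile (which isolates tumor-specific excess from shared artefacts).
Runs of flagged windows are merged into candidate regions.  Only hom->het
flips seed regions; het->hom flips are reported but carry no transfer
signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .errors import ConfigError
from .genostate import CONS_HET, CONS_HOM, HET, HOM_ALT, HOM_REF
from .intervals import merge_intervals, modal_value

DEFAULT_WINDOW = 100_000
DEFAULT_Z_MIN = 3.5
DEFAULT_MIN_RUN = 3
DEFAULT_MERGE_GAP = 500_000
DEFAULT_FALLBACK_ALPHA = 1e-3
DEFAULT_MIN_HET_FRACTION = 0.05
MIN_WINDOWS = 100


@dataclass(frozen=True)
class CandidateRegion:
    chrom: str
    start: int
    end: int
    sample_id: str
    peak_robust_z: float
    n_flipping_snps: int
    mean_flip_density: float  # hom->het flips per window


def screened_segments(
    cn_segments: pd.DataFrame,
    sites: pd.DataFrame,
    consensus: np.ndarray,
    min_cn: int = 2,
    min_het_fraction: float = DEFAULT_MIN_HET_FRACTION,
) -> pd.DataFrame:
    """Segments eligible for the screen.

    A segment qualifies when its modal copy number across tumors is at least
    ``min_cn`` and at least ``min_het_fraction`` of its consensus-determined
    SNPs are consensus heterozygous (evidence that both parental homologues
    are retained).
    """
    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    keep = []
    for (c, s, e), sub in cn_segments.groupby(["chrom", "start", "end"]):
        mode, tied = modal_value(sub["total_cn"])
        if tied or mode is None or mode < min_cn:
            continue
        on = (chrom == c) & (pos > s) & (pos <= e)
        det = consensus[on] != 2  # CONS_UNDETERMINED
        if det.sum() == 0:
            continue
        het_frac = (consensus[on] == CONS_HET).sum() / det.sum()
        if het_frac >= min_het_fraction:
            keep.append((c, int(s), int(e)))
    return merge_intervals(pd.DataFrame(keep, columns=["chrom", "start", "end"]))


def call_flipping_snps(
    states: np.ndarray,
    consensus: np.ndarray,
    sites: pd.DataFrame,
    tumor_ids: list[str],
    screened: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One FlipCall per (site, tumor) conflict with the lineage consensus.

    Returns a table with columns site_index, chrom, pos, sample_id and
    direction ('hom->het' or 'het->hom').
    """
    st = np.asarray(states)
    cons = np.asarray(consensus)
    hom2het = (cons[:, None] == CONS_HOM) & (st == HET)
    het2hom = (cons[:, None] == CONS_HET) & ((st == HOM_REF) | (st == HOM_ALT))
    if screened is not None and len(screened):
        from .intervals import sites_in_intervals

        mask = sites_in_intervals(
            sites["chrom"].to_numpy(), sites["pos"].to_numpy(), screened
        )
        hom2het &= mask[:, None]
        het2hom &= mask[:, None]
    rows = []
    for direction, mat in (("hom->het", hom2het), ("het->hom", het2hom)):
        si, ti = np.nonzero(mat)
        for i, t in zip(si, ti):
            rows.append(
                (int(i), sites["chrom"].iat[i], int(sites["pos"].iat[i]), tumor_ids[t], direction)
            )
    return pd.DataFrame(
        rows, columns=["site_index", "chrom", "pos", "sample_id", "direction"]
    ).sort_values(["sample_id", "chrom", "pos"], ignore_index=True)


def _cooks_distance(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Cook's distance of each point in the OLS fit of y on [1, x].

    Closed form for the two-parameter model; degenerates gracefully to the
    intercept-only model when x has no variance.
    """
    n = len(y)
    xbar = x.mean()
    sxx = float(((x - xbar) ** 2).sum())
    if sxx > 1e-12:
        p = 2
        beta = float(((x - xbar) * (y - y.mean())).sum()) / sxx
        alpha = y.mean() - beta * xbar
        resid = y - (alpha + beta * x)
        lev = 1.0 / n + (x - xbar) ** 2 / sxx
    else:
        p = 1
        resid = y - y.mean()
        lev = np.full(n, 1.0 / n)
    dof = max(n - p, 1)
    s2 = float((resid**2).sum()) / dof
    if s2 <= 0:
        return np.zeros(n)
    return resid**2 * lev / (p * s2 * (1.0 - lev) ** 2)


def detect_candidate_regions(
    flips: pd.DataFrame,
    screened: pd.DataFrame,
    tumor_ids: list[str],
    window: int = DEFAULT_WINDOW,
    z_min: float = DEFAULT_Z_MIN,
    min_run: int = DEFAULT_MIN_RUN,
    merge_gap: int = DEFAULT_MERGE_GAP,
    cooks_threshold: float | None = None,
    fallback_alpha: float = DEFAULT_FALLBACK_ALPHA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tumor candidate regions of excess hom->het flip density.

    Windows of fixed width tile the screened segments.  A window is flagged
    for a tumor when its robust z-score exceeds ``z_min`` AND its Cook's
    distance in the regression of the tumor's window counts on the cohort
    median profile exceeds ``cooks_threshold`` (default 4 / n_windows).  When
    the tumor's MAD is zero the z-score is replaced by a Poisson upper-tail
    test at ``fallback_alpha`` against the tumor's mean window count.  Runs
    of >= ``min_run`` flagged windows (bridging gaps up to ``merge_gap``)
    become candidate regions.

    Returns ``(regions, window_stats)``.
    """
    if window <= 0:
        raise ConfigError("window width must be positive")
    wins = []
    for _, seg in merge_intervals(screened).iterrows():
        start = int(seg["start"]) // window * window
        for s in range(start, int(seg["end"]), window):
            wins.append((seg["chrom"], s, s + window))
    windows = (
        pd.DataFrame(wins, columns=["chrom", "start", "end"])
        .drop_duplicates()
        .sort_values(["chrom", "start"], ignore_index=True)
    )
    n_win = len(windows)
    if n_win < MIN_WINDOWS:
        raise ConfigError(
            f"screen requires >= {MIN_WINDOWS} windows genome-wide for MAD stability; got {n_win}"
        )
    if cooks_threshold is None:
        cooks_threshold = 4.0 / n_win

    counts = np.zeros((n_win, len(tumor_ids)), dtype=np.int64)
    t_index = {t: i for i, t in enumerate(tumor_ids)}
    hom2het = flips[flips["direction"] == "hom->het"]
    for chrom, sub in hom2het.groupby("chrom"):
        wmask = windows["chrom"] == chrom
        wstart = windows.loc[wmask, "start"].to_numpy()
        widx = np.flatnonzero(wmask.to_numpy())
        if len(wstart) == 0:
            continue
        pos = sub["pos"].to_numpy()
        j = np.searchsorted(wstart, pos - 1, side="right") - 1
        ok = (j >= 0) & (pos - 1 < wstart[np.clip(j, 0, len(wstart) - 1)] + window)
        t_arr = sub["sample_id"].map(t_index).to_numpy()
        np.add.at(counts, (widx[j[ok]], t_arr[ok]), 1)

    med = np.median(counts, axis=0)
    mad = np.median(np.abs(counts - med[None, :]), axis=0)
    robust_z = np.full(counts.shape, np.nan)
    stat_flag = np.zeros(counts.shape, dtype=bool)
    for t in range(counts.shape[1]):
        if mad[t] > 0:
            robust_z[:, t] = 0.6745 * (counts[:, t] - med[t]) / mad[t]
            stat_flag[:, t] = robust_z[:, t] > z_min
        else:
            # MAD degenerate (most windows carry zero flips): Poisson upper
            # tail against a background rate estimated from the zero fraction
            # (robust to a minority of true-signal windows, which would
            # otherwise inflate a plain mean)
            zero_frac = (counts[:, t] == 0).mean()
            if zero_frac == 0:
                lam = counts[:, t].mean()
            elif zero_frac == 1.0:
                continue  # no flips at all for this tumor
            else:
                lam = -np.log(zero_frac)
            pv = poisson.sf(counts[:, t] - 1, max(lam, 1e-12))
            stat_flag[:, t] = (counts[:, t] > 0) & (pv < fallback_alpha)

    cooks = np.zeros(counts.shape)
    profile = np.median(counts, axis=1).astype(float)
    for t in range(counts.shape[1]):
        cooks[:, t] = _cooks_distance(counts[:, t].astype(float), profile)
    flagged = stat_flag & (cooks > cooks_threshold)

    stats_df = pd.DataFrame(
        {
            "chrom": np.repeat(windows["chrom"].to_numpy(), len(tumor_ids)),
            "start": np.repeat(windows["start"].to_numpy(), len(tumor_ids)),
            "end": np.repeat(windows["end"].to_numpy(), len(tumor_ids)),
            "sample_id": np.tile(np.array(tumor_ids, dtype=object), n_win),
            "flip_count": counts.ravel(),
            "robust_z": robust_z.ravel(),
            "cooks_distance": cooks.ravel(),
            "flagged": flagged.ravel(),
        }
    )

    regions = []
    wchrom = windows["chrom"].to_numpy()
    wstart = windows["start"].to_numpy()
    wend = windows["end"].to_numpy()
    for t, tid in enumerate(tumor_ids):
        fidx = np.flatnonzero(flagged[:, t])
        if len(fidx) == 0:
            continue
        run: list[int] = []
        for i in fidx:
            if run and (wchrom[i] != wchrom[run[-1]] or wstart[i] - wend[run[-1]] > merge_gap):
                regions.extend(_close_run(run, t, tid, windows, counts, robust_z, hom2het, min_run, window))
                run = []
            run.append(int(i))
        regions.extend(_close_run(run, t, tid, windows, counts, robust_z, hom2het, min_run, window))

    regions_df = pd.DataFrame(
        [r.__dict__ for r in regions],
        columns=[
            "chrom", "start", "end", "sample_id",
            "peak_robust_z", "n_flipping_snps", "mean_flip_density",
        ],
    )
    return regions_df, stats_df


def _close_run(run, t, tid, windows, counts, robust_z, hom2het, min_run, window):
    if len(run) < min_run:
        return []
    chrom = windows["chrom"].iat[run[0]]
    start = int(windows["start"].iat[run[0]])
    end = int(windows["end"].iat[run[-1]])
    sub = hom2het[
        (hom2het["sample_id"] == tid)
        & (hom2het["chrom"] == chrom)
        & (hom2het["pos"] > start)
        & (hom2het["pos"] <= end)
    ]
    with np.errstate(invalid="ignore"):
        peak = float(np.nanmax(robust_z[run, t])) if not np.all(np.isnan(robust_z[run, t])) else float("nan")
    n_windows_span = (end - start) / window
    return [
        CandidateRegion(
            chrom=chrom,
            start=start,
            end=end,
            sample_id=tid,
            peak_robust_z=peak,
            n_flipping_snps=int(len(sub)),
            mean_flip_density=float(len(sub) / n_windows_span),
        )
    ]
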