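"""Small genomic-interval helpers shared across pipeline stages.

Intervals follow BED conventions (0-based, half-open); site positions are
1-based as in VCF.  Segmentations are assumed to share one partition across
samples (the copy-number caller upstream emits a common grid), which keeps
lookups to plain ``searchsorted`` calls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def sites_in_intervals(chrom: np.ndarray, pos: np.ndarray, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean mask of 1-based sites falling inside BED intervals."""
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    mask = np.zeros(len(pos), dtype=bool)
    for c, sub in intervals.groupby("chrom"):
        on = chrom == c
        if not on.any():
            continue
        p = pos[on]
        hit = np.zeros(p.shape, dtype=bool)
        for start, end in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            hit |= (p > start) & (p <= end)
        mask[np.flatnonzero(on)[hit]] = True
    return mask


def cn_matrix(cn_segments: pd.DataFrame, sites: pd.DataFrame, sample_ids) -> pd.DataFrame:
    """Total copy number per (site, sample) from a shared-partition BED table.

    Positions not covered by any segment get CN 0 (treated as excluded
    downstream, since the screen needs CN >= 2).
    """
    out = pd.DataFrame(
        0, index=sites.index, columns=list(sample_ids), dtype=np.int64
    )
    for (c, s), sub in cn_segments.groupby(["chrom", "sample"]):
        if s not in out.columns:
            continue
        on = sites["chrom"].to_numpy() == c
        if not on.any():
            continue
        p = sites["pos"].to_numpy()[on]
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cns = sub["total_cn"].to_numpy()
        idx = np.searchsorted(starts, p - 1, side="right") - 1
        valid = (idx >= 0) & (p - 1 < ends[np.clip(idx, 0, len(ends) - 1)])
        vals = np.zeros(p.shape, dtype=np.int64)
        vals[valid] = cns[idx[valid]]
        out.loc[on, s] = vals
    return out


def modal_value(values) -> tuple[int | None, bool]:
    """Most frequent integer state; returns (mode, tied)."""
    vals, counts = np.unique(np.asarray(values), return_counts=True)
    if len(vals) == 0:
        return None, False
    top = counts.max()
    winners = vals[counts == top]
    if len(winners) > 1:
        return None, True
    return int(winners[0]), False


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Minimum of the two mutual overlap fractions of intervals ``a`` and ``b``."""
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    ov = max(0, hi - lo)
    la = a[1] - a[0]
    lb = b[1] - b[0]
    if la <= 0 or lb <= 0:
        return 0.0
    return min(ov / la, ov / lb)


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Union of possibly-overlapping BED intervals, per chromosome."""
    rows = []
    for c, sub in intervals.groupby("chrom"):
        sub = sub.sort_values("start")
        cur_s, cur_e = None, None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((c, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((c, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
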