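"""Interval-union coverage arithmetic on half-open genomic intervals."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of half-open intervals as sorted disjoint intervals."""
    if starts.size == 0:
        return starts.astype(np.int64), ends.astype(np.int64)
    order = np.argsort(starts, kind="mergesort")
    s, e = starts[order], ends[order]
    out_s, out_e = [int(s[0])], [int(e[0])]
    for i in range(1, s.size):
        if s[i] <= out_e[-1]:
            out_e[-1] = max(out_e[-1], int(e[i]))
        else:
            out_s.append(int(s[i]))
            out_e.append(int(e[i]))
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def union_coverage(bins: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """Base pairs of each bin covered by the union of ``intervals``.

    Both frames use columns chrom/start/end with 0-based half-open
    coordinates. Intervals extending beyond the last bin end of their
    chromosome are clipped with a warning (likely an assembly mismatch).
    """
    covered = np.zeros(len(bins), dtype=np.int64)
    if len(intervals) == 0:
        return covered
    iv_by_chrom = {c: sub for c, sub in intervals.groupby("chrom", sort=False)}
    clipped = 0
    for chrom, sub in bins.groupby("chrom", sort=False):
        iv = iv_by_chrom.get(chrom)
        if iv is None:
            continue
        chrom_end = int(sub["end"].max())
        s = iv["start"].to_numpy(np.int64)
        e = iv["end"].to_numpy(np.int64)
        clipped += int((e > chrom_end).sum())
        e = np.minimum(e, chrom_end)
        keep = e > s
        ms, me = merge_intervals(s[keep], e[keep])
        if ms.size == 0:
            continue
        cum = np.concatenate(([0], np.cumsum(me - ms)))
        for row, (a, b) in zip(sub.index, sub[["start", "end"]].to_numpy()):
            i0 = int(np.searchsorted(me, a, side="right"))
            i1 = int(np.searchsorted(ms, b, side="left"))
            if i1 <= i0:
                continue
            total = int(cum[i1] - cum[i0])
            total -= max(0, int(a - ms[i0]))
            total -= max(0, int(me[i1 - 1] - b))
            covered[bins.index.get_loc(row)] = total
    if clipped:
        log.warning("%d intervals extended beyond the binned chromosome end; clipped", clipped)
    return covered


def read_bed(path) -> pd.DataFrame:
    """First three columns of a BED file as chrom/start/end."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2])
    df.columns = ["chrom", "start", "end"]
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["end"] < df["start"]).any():
        raise ValueError(f"interval with end < start in {path}")
    return df
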