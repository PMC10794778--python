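"""G/C-stratified methylation dynamics between developmental stages.

500-kb bins are stratified into 12 equal-size groups by G/C content
(group 1 = most A/T-rich), the gain or loss of methylation between two
stages is summarised per group, and bins are cross-classified into nine
susceptibility groups: demethylation-resistant / -intermediate /
-susceptible tertiles (ranked by level in the globally hypomethylated
stage) crossed with methylation-susceptible / -intermediate / -resistant
tertiles (ranked by level in the globally remethylated stage). The
labels follow the figure abbreviations DR/DI/DS x MS/MI/MR;
"methylation-sensitive" and "methylation-susceptible" are the same MS
label. Chromosome-territory effects are probed by comparing whole-genome
methylation ranks between chromosomes, and annotations (constitutive
LADs, PMDs, HMDs) are scored as per-bin union-overlap fractions with the
thresholds used in the circos-style summaries (50/70/90/98%).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .intervals import union_coverage
from .stats import RankSumResult, wilcoxon_rank_sum

log = logging.getLogger(__name__)

DEMETH_LABELS = ("DR", "DI", "DS")  # top, middle, bottom tertile in the hypomethylated stage
METH_LABELS = ("MS", "MI", "MR")  # top, middle, bottom tertile in the remethylated stage

OVERLAP_THRESHOLDS = (0.5, 0.7, 0.9, 0.98)


def _usable_mask(binmeth: pd.DataFrame) -> np.ndarray:
    mask = ~binmeth["gc_fraction"].isna().to_numpy()
    if "usable" in binmeth.columns:
        mask &= binmeth["usable"].to_numpy()
    return mask


def assign_gc_groups(binmeth: pd.DataFrame, n_groups: int = 12) -> pd.DataFrame:
    """Split usable bins into ``n_groups`` contiguous equal-size G/C groups.

    Bins are sorted by G/C fraction ascending (ties broken by chrom, start)
    and cut into equal groups; group 1 is the most A/T-rich. When the usable
    count is not divisible by ``n_groups``, the remainder bins with the
    lowest covered-CpG counts are dropped first (logged). Returns a copy
    with a nullable-integer ``gc_group`` column (NA = not grouped).
    """
    out = binmeth.copy()
    usable = out[_usable_mask(out)]
    if len(usable) < n_groups:
        raise ValueError(f"{len(usable)} usable bins < n_groups={n_groups}")
    r = len(usable) % n_groups
    if r:
        drop = usable.sort_values(
            ["covered_cpgs", "chrom", "start"], kind="mergesort"
        ).index[:r]
        log.info("assign_gc_groups: dropped %d bins (lowest covered CpGs) for divisibility", r)
        usable = usable.drop(index=drop)
    size = len(usable) // n_groups
    ordered = usable.sort_values(
        ["gc_fraction", "chrom", "start"], ascending=True, kind="mergesort"
    ).index
    group = pd.Series(pd.NA, index=out.index, dtype="Int64")
    for g in range(n_groups):
        group.loc[ordered[g * size : (g + 1) * size]] = g + 1
    out["gc_group"] = group
    return out


def stage_delta(
    binmeth_a: pd.DataFrame, binmeth_b: pd.DataFrame, grouped: pd.DataFrame
) -> tuple[pd.DataFrame, RankSumResult]:
    """Per-G/C-group methylation change from stage A to stage B.

    Both bin methylomes must cover the identical bin set. Per group the
    count-weighted mean level at each stage and delta = B - A are reported;
    the returned test compares the per-bin deltas of the most G/C-rich group
    against the most A/T-rich group (exact Wilcoxon rank-sum), as in the
    figure asterisks.
    """
    for col in ("chrom", "start"):
        if not binmeth_a[col].equals(binmeth_b[col]):
            n_bad = int((binmeth_a[col] != binmeth_b[col]).sum())
            raise ValueError(f"bin sets differ between stages ({n_bad} mismatching {col})")
    groups = grouped["gc_group"]
    level_a = binmeth_a["level"].to_numpy(float)
    level_b = binmeth_b["level"].to_numpy(float)
    per_bin = pd.DataFrame(
        {
            "gc_group": groups.to_numpy(),
            "meth_a": binmeth_a["meth_sum"].to_numpy(),
            "tot_a": binmeth_a["total_sum"].to_numpy(),
            "meth_b": binmeth_b["meth_sum"].to_numpy(),
            "tot_b": binmeth_b["total_sum"].to_numpy(),
            "delta": level_b - level_a,
        }
    ).dropna(subset=["gc_group"])
    agg = per_bin.groupby("gc_group").agg(
        n=("delta", "size"),
        meth_a=("meth_a", "sum"),
        tot_a=("tot_a", "sum"),
        meth_b=("meth_b", "sum"),
        tot_b=("tot_b", "sum"),
        mean_bin_delta=("delta", "mean"),
    )
    agg["level_a"] = agg["meth_a"] / agg["tot_a"]
    agg["level_b"] = agg["meth_b"] / agg["tot_b"]
    agg["delta"] = agg["level_b"] - agg["level_a"]
    table = agg.reset_index()[
        ["gc_group", "n", "level_a", "level_b", "delta", "mean_bin_delta"]
    ]
    lo, hi = int(table["gc_group"].min()), int(table["gc_group"].max())
    deltas_hi = per_bin.loc[per_bin["gc_group"] == hi, "delta"].dropna()
    deltas_lo = per_bin.loc[per_bin["gc_group"] == lo, "delta"].dropna()
    test = wilcoxon_rank_sum(deltas_hi.to_numpy(), deltas_lo.to_numpy())
    return table, test


def _tertile_labels(
    binmeth: pd.DataFrame, index: pd.Index, labels: tuple[str, str, str], tertile_size: int
) -> tuple[pd.Series, int]:
    """Rank ``index`` rows by level descending (ties by chrom, start) and cut
    into three tertiles labelled top/middle/bottom. Returns labels and the
    number of level ties spanning a tertile boundary."""
    sub = binmeth.loc[index]
    ordered = sub.sort_values(
        ["level", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    ).index
    lab = pd.Series("", index=index, dtype=object)
    lab.loc[ordered[:tertile_size]] = labels[0]
    lab.loc[ordered[tertile_size : 2 * tertile_size]] = labels[1]
    lab.loc[ordered[2 * tertile_size :]] = labels[2]
    levels = binmeth.loc[ordered, "level"].to_numpy(float)
    boundary_ties = sum(
        int(levels[b - 1] == levels[b]) for b in (tertile_size, 2 * tertile_size)
    )
    return lab, boundary_ties


def classify_susceptibility(
    binmeth_hypo: pd.DataFrame,
    binmeth_remeth: pd.DataFrame,
    tertile_size: int | None = None,
    annotations: dict[str, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nine-group susceptibility classification of 500-kb bins.

    Bins are ranked by methylation level in the globally hypomethylated
    stage (DR = top tertile, resists demethylation) and independently in
    the globally remethylated stage (MS = top tertile, gains methylation
    readily); ``nine_group`` is the cross product (e.g. "DR-MR").

    ``tertile_size`` defaults to N // 3 (remainder bins with lowest combined
    covered-CpG counts are left unclassified); if given explicitly the
    usable bin count must equal 3 x tertile_size. ``annotations`` maps a
    name (e.g. "clad_overlap", "pmd_overlap") to a per-bin fraction aligned
    with ``binmeth_hypo``; group means are added to the summary.

    Returns (per-bin label table, nine-group summary table).
    """
    for col in ("chrom", "start"):
        if not binmeth_hypo[col].equals(binmeth_remeth[col]):
            raise ValueError("bin sets differ between the two stages")
    mask = (
        _usable_mask(binmeth_hypo)
        & ~binmeth_hypo["level"].isna().to_numpy()
        & ~binmeth_remeth["level"].isna().to_numpy()
    )
    usable_idx = binmeth_hypo.index[mask]
    n = len(usable_idx)
    if tertile_size is None:
        tertile_size = n // 3
        r = n - 3 * tertile_size
        if r:
            combined_cov = (
                binmeth_hypo.loc[usable_idx, "covered_cpgs"]
                + binmeth_remeth.loc[usable_idx, "covered_cpgs"]
            )
            drop = (
                pd.DataFrame(
                    {
                        "cov": combined_cov,
                        "chrom": binmeth_hypo.loc[usable_idx, "chrom"],
                        "start": binmeth_hypo.loc[usable_idx, "start"],
                    }
                )
                .sort_values(["cov", "chrom", "start"], kind="mergesort")
                .index[:r]
            )
            usable_idx = usable_idx.drop(drop)
            log.info("classify_susceptibility: %d bins left unclassified for divisibility", r)
    if tertile_size < 1 or len(usable_idx) != 3 * tertile_size:
        raise ValueError(
            f"usable bin count {len(usable_idx)} must equal 3 x tertile_size "
            f"({3 * tertile_size}); adjust filtering or tertile_size"
        )
    demeth, ties_d = _tertile_labels(binmeth_hypo, usable_idx, DEMETH_LABELS, tertile_size)
    meth, ties_m = _tertile_labels(binmeth_remeth, usable_idx, METH_LABELS, tertile_size)
    if ties_d or ties_m:
        log.info("tertile boundaries split %d tied levels (deterministic order)", ties_d + ties_m)
    labels = pd.DataFrame(
        {
            "chrom": binmeth_hypo.loc[usable_idx, "chrom"],
            "start": binmeth_hypo.loc[usable_idx, "start"],
            "end": binmeth_hypo.loc[usable_idx, "end"],
            "gc_fraction": binmeth_hypo.loc[usable_idx, "gc_fraction"],
            "level_hypo": binmeth_hypo.loc[usable_idx, "level"],
            "level_remeth": binmeth_remeth.loc[usable_idx, "level"],
            "demeth_class": demeth,
            "meth_class": meth,
        },
        index=usable_idx,
    )
    labels["nine_group"] = labels["demeth_class"] + "-" + labels["meth_class"]
    agg = {
        "n": ("nine_group", "size"),
        "level_hypo": ("level_hypo", "mean"),
        "level_remeth": ("level_remeth", "mean"),
        "gc_fraction": ("gc_fraction", "mean"),
    }
    if annotations:
        for name, values in annotations.items():
            labels[name] = pd.Series(np.asarray(values, dtype=float), index=binmeth_hypo.index).loc[
                usable_idx
            ]
            agg[name] = (name, "mean")
    summary = labels.groupby("nine_group").agg(**agg).reset_index()
    return labels, summary


def compare_chromosome_ranks(
    binmeth: pd.DataFrame, ranks: pd.Series, chrom_a: str, chrom_b: str
) -> dict:
    """Wilcoxon rank-sum comparison of two chromosomes' methylation ranks.

    ``ranks`` is the per-usable-bin rank vector over all autosomal bins
    (1 = least methylated). Reports each chromosome's bin count and median
    rank and the two-sided test.
    """
    chroms = binmeth.loc[ranks.index, "chrom"]
    out = {}
    samples = []
    for key, chrom in (("a", chrom_a), ("b", chrom_b)):
        vals = ranks[chroms == chrom].to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError(f"chromosome {chrom!r} has no ranked bins")
        out[f"chrom_{key}"] = chrom
        out[f"n_{key}"] = int(vals.size)
        out[f"median_rank_{key}"] = float(np.median(vals))
        samples.append(vals)
    test = wilcoxon_rank_sum(samples[0], samples[1])
    out["statistic"] = test.statistic
    out["p_value"] = test.p_value
    out["method"] = test.method
    return out


def overlap_fraction(
    bins: pd.DataFrame,
    intervals: pd.DataFrame,
    thresholds: tuple[float, ...] = OVERLAP_THRESHOLDS,
    name: str = "overlap",
) -> pd.DataFrame:
    """Per-bin union-overlap fraction with an interval set, plus boolean
    threshold flags (columns ``{name}_gt_{pct}``)."""
    covered = union_coverage(bins, intervals)
    width = (bins["end"] - bins["start"]).to_numpy()
    frac = covered / width
    out = bins[["chrom", "start", "end"]].copy()
    out[f"{name}_fraction"] = frac
    for t in thresholds:
        out[f"{name}_gt_{int(round(t * 100))}"] = frac > t
    return out
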