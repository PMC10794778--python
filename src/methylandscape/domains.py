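"""Partially and highly methylated domain (PMD/HMD) calling.

The genome is divided into 10-kb bins and each informative bin is compared
with the sample's global CpG methylation level: below -> small PMD, above ->
small HMD (exact equality is uninformative). Adjacent same-state bins are
combined into a single domain; short runs of uninformative (uncovered) bins
inside a domain are bridged, never opposite-state bins. Only domains
strictly larger than 100 kb are retained.

Oocyte-lineage methylomes (globally almost unmethylated) are poor substrates
for PMD calling; callers should warn when the global level is very low.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .intervals import union_coverage

log = logging.getLogger(__name__)

PMD, HMD, UNINFORMATIVE = -1, 1, 0
_KIND_NAME = {PMD: "PMD", HMD: "HMD"}

DOMAIN_COLUMNS = ["chrom", "start", "end", "kind", "mean_level", "n_small_bins"]

OOCYTE_LINEAGE_GLOBAL_LEVEL = 0.2  # below this, warn: near-complete demethylation


def call_small_states(
    binmeth_10kb: pd.DataFrame, global_level: float, min_cpgs_informative: int = 1
) -> pd.DataFrame:
    """Assign each small bin a state: PMD (-1), HMD (+1) or uninformative (0).

    A bin is informative when it has >= ``min_cpgs_informative`` covered
    CpGs and a defined level.
    """
    out = binmeth_10kb.copy()
    level = out["level"].to_numpy(dtype=float)
    informative = (out["covered_cpgs"].to_numpy() >= min_cpgs_informative) & ~np.isnan(level)
    state = np.zeros(len(out), dtype=np.int8)
    state[informative & (level < global_level)] = PMD
    state[informative & (level > global_level)] = HMD
    out["state"] = state
    if global_level < OOCYTE_LINEAGE_GLOBAL_LEVEL:
        log.warning(
            "global level %.3f < %.2f: near-complete demethylation "
            "(oocyte-lineage-like); PMD calls are unreliable here",
            global_level,
            OOCYTE_LINEAGE_GLOBAL_LEVEL,
        )
    return out


def merge_domains(
    states: pd.DataFrame,
    bridge_max_bins: int = 5,
    min_domain_size: int = 100_000,
) -> pd.DataFrame:
    """Combine adjacent same-state small bins into domains.

    Up to ``bridge_max_bins`` consecutive uninformative bins inside a run are
    bridged; an opposite-state bin always closes the run. Domain coordinates
    span the first to the last informative bin of the run; the mean level is
    count-weighted over informative bins. Domains with end - start <=
    ``min_domain_size`` are discarded (the size filter is strict).
    """
    rows = []
    for chrom, sub in states.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        st = sub["state"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        meth = sub["meth_sum"].to_numpy()
        total = sub["total_sum"].to_numpy()

        kind = 0
        first = last = -1
        msum = tsum = 0
        nbins = 0
        gap = 0

        def close():
            nonlocal kind, first, last, msum, tsum, nbins, gap
            if kind != 0:
                start, end = int(starts[first]), int(ends[last])
                if end - start > min_domain_size:
                    rows.append(
                        {
                            "chrom": chrom,
                            "start": start,
                            "end": end,
                            "kind": _KIND_NAME[kind],
                            "mean_level": msum / tsum if tsum else np.nan,
                            "n_small_bins": nbins,
                        }
                    )
            kind, first, last, msum, tsum, nbins, gap = 0, -1, -1, 0, 0, 0, 0

        for i in range(len(sub)):
            s = int(st[i])
            if s == UNINFORMATIVE:
                if kind != 0:
                    gap += 1
                    if gap > bridge_max_bins:
                        close()
                continue
            if kind == 0:
                kind = s
                first = i
            elif s != kind:
                close()
                kind = s
                first = i
            last = i
            gap = 0
            msum += int(meth[i])
            tsum += int(total[i])
            nbins += 1
        close()
    if not rows:
        return pd.DataFrame(columns=DOMAIN_COLUMNS)
    return pd.DataFrame(rows, columns=DOMAIN_COLUMNS)


def call_domains(
    binmeth_10kb: pd.DataFrame,
    global_level: float,
    min_cpgs_informative: int = 1,
    bridge_max_bins: int = 5,
    min_domain_size: int = 100_000,
) -> pd.DataFrame:
    """call_small_states followed by merge_domains."""
    states = call_small_states(binmeth_10kb, global_level, min_cpgs_informative)
    return merge_domains(states, bridge_max_bins, min_domain_size)


def total_domain_size(domains: pd.DataFrame, kind: str) -> int:
    """Total base pairs covered by domains of one kind."""
    sub = domains[domains["kind"] == kind]
    return int((sub["end"] - sub["start"]).sum())


def domain_overlap_fraction(domains: pd.DataFrame, bins: pd.DataFrame, kind: str) -> np.ndarray:
    """Per-bin fraction covered by domains of ``kind``."""
    sub = domains[domains["kind"] == kind][["chrom", "start", "end"]]
    covered = union_coverage(bins, sub)
    width = (bins["end"] - bins["start"]).to_numpy()
    return covered / width


def domain_gc_distribution(
    domains: pd.DataFrame, bins_500kb: pd.DataFrame, kind: str = "PMD"
) -> pd.DataFrame:
    """Per-G/C-group distribution of domain overlap over 500-kb bins.

    ``bins_500kb`` must carry a ``gc_group`` column (1 = most A/T-rich).
    Returns one row per group with the count, mean and median overlap
    fraction, mirroring the box-plot summaries of domain placement along the
    G/C gradient.
    """
    if "gc_group" not in bins_500kb.columns:
        raise ValueError("bins_500kb needs a gc_group column (see assign_gc_groups)")
    frac = domain_overlap_fraction(domains, bins_500kb, kind)
    df = pd.DataFrame(
        {"gc_group": bins_500kb["gc_group"].to_numpy(), "overlap_fraction": frac}
    ).dropna(subset=["gc_group"])
    out = (
        df.groupby("gc_group")["overlap_fraction"]
        .agg(n="size", mean_overlap="mean", median_overlap="median")
        .reset_index()
    )
    return out


def write_domains_bed(domains: pd.DataFrame, path, kind: str | None = None) -> None:
    """BED6: name = kind, score = round(1000 * mean_level), strand = '.'."""
    sub = domains if kind is None else domains[domains["kind"] == kind]
    bed = sub[["chrom", "start", "end", "kind"]].copy()
    bed["score"] = np.round(1000 * sub["mean_level"].to_numpy(dtype=float)).astype(int)
    bed["strand"] = "."
    bed.to_csv(path, sep="\t", index=False, header=False)
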