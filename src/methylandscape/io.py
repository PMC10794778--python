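"""Reading per-CpG methylation calls and aggregating them into bins.

Supported on-disk dialects:

* Bismark cytosine report — tab-separated, 1-based, stranded:
  ``chrom  pos  strand  meth  unmeth  context  [trinucleotide]``.
  Only CpG-context rows are used; plus- and minus-strand counts of one CpG
  dinucleotide are folded onto the 0-based position of the plus-strand C.
* Coverage / bedGraph-like — either 4 columns
  ``chrom  pos  meth  unmeth`` or the 6-column Bismark coverage flavour
  ``chrom  start  end  pct  meth  unmeth``; assumed already strand-merged,
  coordinate base declared by the caller.

In memory a methylome is one strand-merged record per CpG site; methylation
levels are fractions throughout, percent only at presentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SITE_COLUMNS = ["chrom", "pos", "meth", "unmeth"]


@dataclass
class CpGMethylome:
    """Per-CpG strand-merged counts for one sample.

    ``sites`` has columns chrom, pos (0-based plus-strand C), meth, unmeth,
    one row per covered CpG, sorted by (chrom, pos).
    """

    sample_id: str
    sites: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def depth(self) -> np.ndarray:
        return (self.sites["meth"] + self.sites["unmeth"]).to_numpy()

    def total_counts(self) -> int:
        return int(self.sites["meth"].sum() + self.sites["unmeth"].sum())


class GlobalLevel(NamedTuple):
    level: float
    n_sites: int


def _finalize_sites(df: pd.DataFrame) -> pd.DataFrame:
    df = (
        df.groupby(["chrom", "pos"], as_index=False, sort=False)[["meth", "unmeth"]]
        .sum()
        .sort_values(["chrom", "pos"], kind="mergesort", ignore_index=True)
    )
    df["pos"] = df["pos"].astype(np.int64)
    df["meth"] = df["meth"].astype(np.int64)
    df["unmeth"] = df["unmeth"].astype(np.int64)
    return df


def read_cytosine_report(path, sample_id: str | None = None) -> CpGMethylome:
    """Parse a Bismark-style cytosine report and merge strands.

    Minus-strand records are folded onto the plus-strand C (1-based minus pos
    p maps to 0-based p-2); a minus record with no plus partner is still
    folded, and counted in ``meta['unpaired_minus']``.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            dtype={0: str, 1: np.int64, 2: str, 3: np.int64, 4: np.int64, 5: str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed cytosine report {path}: {exc}") from exc
    if df.shape[1] < 6:
        raise ValueError(
            f"cytosine report {path} has {df.shape[1]} columns, expected >= 6"
        )
    df = df.iloc[:, :6]
    df.columns = ["chrom", "pos1", "strand", "meth", "unmeth", "context"]
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        i = int(np.flatnonzero(bad_strand.to_numpy())[0])
        raise ValueError(f"malformed strand field at line {i + 1} of {path}")
    cpg = df[df["context"].isin(["CG", "CpG"])]
    meta: dict = {"non_cpg_rows_skipped": int(len(df) - len(cpg))}
    if cpg.empty:
        log.warning("%s contains no CpG-context rows", path)
        sites = pd.DataFrame(columns=SITE_COLUMNS)
        sites = sites.astype({"pos": np.int64, "meth": np.int64, "unmeth": np.int64})
        return CpGMethylome(sample_id or str(path), sites, meta)
    plus = cpg["strand"] == "+"
    pos0 = np.where(plus, cpg["pos1"] - 1, cpg["pos1"] - 2)
    if (pos0 < 0).any():
        raise ValueError(f"minus-strand CpG record at position 1 in {path}")
    merged = pd.DataFrame(
        {"chrom": cpg["chrom"].to_numpy(), "pos": pos0,
         "meth": cpg["meth"].to_numpy(), "unmeth": cpg["unmeth"].to_numpy()}
    )
    plus_keys = set(zip(cpg.loc[plus, "chrom"], cpg.loc[plus, "pos1"] - 1))
    minus_keys = zip(cpg.loc[~plus, "chrom"], cpg.loc[~plus, "pos1"] - 2)
    unpaired = sum(1 for k in minus_keys if k not in plus_keys)
    if unpaired:
        log.warning("%d minus-strand records had no plus partner in %s", unpaired, path)
    meta["unpaired_minus"] = int(unpaired)
    return CpGMethylome(sample_id or str(path), _finalize_sites(merged), meta)


def read_coverage(path, coord_base: int = 1, sample_id: str | None = None) -> CpGMethylome:
    """Parse a 4-column (chrom,pos,meth,unmeth) or 6-column Bismark coverage
    file; positions are converted from ``coord_base`` to 0-based."""
    if coord_base not in (0, 1):
        raise ValueError("coord_base must be 0 or 1")
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 4:
        df.columns = ["chrom", "pos", "meth", "unmeth"]
    elif df.shape[1] >= 6:
        df = df.iloc[:, [0, 1, 4, 5]]
        df.columns = ["chrom", "pos", "meth", "unmeth"]
    else:
        raise ValueError(f"coverage file {path} has {df.shape[1]} columns, expected 4 or 6")
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(np.int64) - coord_base
    return CpGMethylome(sample_id or str(path), _finalize_sites(df), {})


def read_site_table(path, sample_id: str | None = None) -> CpGMethylome:
    """Read the package's own headered per-CpG TSV (0-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path} lacks columns {missing}")
    return CpGMethylome(sample_id or str(path), _finalize_sites(df[SITE_COLUMNS]), {})


def write_site_table(methylome: CpGMethylome, path) -> None:
    methylome.sites.to_csv(path, sep="\t", index=False)


def filter_acg_tcg(methylome: CpGMethylome, genome) -> CpGMethylome:
    """Keep only CpGs preceded by A or T (ACG/TCG trinucleotides).

    Applied to NOMe-seq / scCOOL-seq data, where GpC positions carry the
    accessibility signal and only ACG/TCG CpGs report endogenous methylation.
    CpGs at a chromosome start (no preceding base) are dropped and counted.
    """
    from .binning import chrom_sequence

    keep_parts = []
    dropped = 0
    no_prev = 0
    for chrom, sub in methylome.sites.groupby("chrom", sort=False):
        seq = chrom_sequence(genome, chrom)
        pos = sub["pos"].to_numpy()
        at_start = pos == 0
        no_prev += int(at_start.sum())
        prev = np.array([seq[p - 1] if p > 0 else "" for p in pos])
        ok = ~at_start & ((prev == "A") | (prev == "T"))
        dropped += int((~ok).sum())
        keep_parts.append(sub[ok])
    sites = (
        pd.concat(keep_parts, ignore_index=True)
        if keep_parts
        else methylome.sites.iloc[0:0]
    )
    meta = dict(methylome.meta)
    meta["acg_tcg_dropped"] = dropped
    meta["acg_tcg_no_preceding_base"] = no_prev
    return CpGMethylome(methylome.sample_id, sites.reset_index(drop=True), meta)


def aggregate_cells(methylomes: Sequence[CpGMethylome], sample_id: str | None = None) -> CpGMethylome:
    """Sum per-site counts across single cells into one pseudobulk methylome."""
    if not methylomes:
        raise ValueError("aggregate_cells needs at least one methylome")
    sites = _finalize_sites(pd.concat([m.sites for m in methylomes], ignore_index=True))
    sid = sample_id or f"aggregate({len(methylomes)} cells)"
    return CpGMethylome(sid, sites, {"n_cells": len(methylomes)})


def global_methylation(methylome: CpGMethylome, depth_min: int = 5) -> GlobalLevel:
    """Global CpG methylation level: sum(meth)/sum(meth+unmeth) over sites
    with depth >= ``depth_min`` (default 5). The methylome is expected to be
    restricted to autosomes already."""
    depth = methylome.depth()
    use = depth >= depth_min
    total = int(depth[use].sum())
    if total == 0:
        raise ValueError(
            f"no CpG site with depth >= {depth_min} in sample {methylome.sample_id}"
        )
    meth = int(methylome.sites.loc[use, "meth"].sum())
    return GlobalLevel(meth / total, int(use.sum()))


def assign_sites_to_bins(methylome: CpGMethylome, bins: pd.DataFrame) -> np.ndarray:
    """Index of the containing bin for every site (-1 if none)."""
    out = np.full(len(methylome.sites), -1, dtype=np.int64)
    by_chrom = {c: sub for c, sub in bins.groupby("chrom", sort=False)}
    offset = 0
    for chrom, sub in methylome.sites.groupby("chrom", sort=False):
        n = len(sub)
        b = by_chrom.get(chrom)
        if b is not None:
            starts = b["start"].to_numpy()
            ends = b["end"].to_numpy()
            idx = np.searchsorted(starts, sub["pos"].to_numpy(), side="right") - 1
            ok = (idx >= 0) & (sub["pos"].to_numpy() < ends[np.clip(idx, 0, len(b) - 1)])
            rows = b.index.to_numpy()[np.clip(idx, 0, len(b) - 1)]
            out[offset : offset + n] = np.where(ok, rows, -1)
        offset += n
    return out


def bin_methylation(
    methylome: CpGMethylome, bins: pd.DataFrame, site_depth_min: int = 5
) -> pd.DataFrame:
    """Aggregate qualifying sites into per-bin counts.

    The bin level is the count-weighted mean sum(meth)/sum(meth+unmeth), not
    the mean of per-site levels. Sites on chromosomes absent from ``bins``
    (e.g. sex chromosomes when bins cover autosomes only) are ignored.
    ``site_depth_min`` defaults to the same depth >= 5 used for the global
    level; set 1 for aggregated single-cell data.
    """
    depth = methylome.depth()
    use = depth >= site_depth_min
    bin_idx = assign_sites_to_bins(methylome, bins)
    use &= bin_idx >= 0
    meth_sum = np.zeros(len(bins), dtype=np.int64)
    total_sum = np.zeros(len(bins), dtype=np.int64)
    covered = np.zeros(len(bins), dtype=np.int64)
    idx = bin_idx[use]
    np.add.at(meth_sum, idx, methylome.sites.loc[use, "meth"].to_numpy())
    np.add.at(total_sum, idx, depth[use])
    np.add.at(covered, idx, 1)
    out = bins.copy()
    out["meth_sum"] = meth_sum
    out["total_sum"] = total_sum
    out["covered_cpgs"] = covered
    with np.errstate(invalid="ignore", divide="ignore"):
        out["level"] = np.where(total_sum > 0, meth_sum / np.maximum(total_sum, 1), np.nan)
    return out


def filter_bins(
    binmeth: pd.DataFrame,
    min_covered_cpgs: int = 10,
    max_n_fraction: float = 0.5,
    exclude_partial: bool = True,
    min_usable: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Mark bins usable for ranking/grouping; returns (table, casualty log).

    A bin is unusable if its covered-CpG count is below ``min_covered_cpgs``,
    its N fraction exceeds ``max_n_fraction``, its G/C fraction is undefined,
    or it is a partial terminal bin and ``exclude_partial`` is set.
    """
    covered = binmeth["covered_cpgs"].to_numpy()
    usable = covered >= min_covered_cpgs
    drop_cov = int((~usable).sum())
    high_n = binmeth["n_fraction"].to_numpy() > max_n_fraction
    undef_gc = binmeth["gc_fraction"].isna().to_numpy()
    usable &= ~high_n & ~undef_gc
    if exclude_partial:
        usable &= ~binmeth["partial"].to_numpy()
    out = binmeth.copy()
    out["usable"] = usable
    logdict = {
        "n_bins": int(len(out)),
        "n_usable": int(usable.sum()),
        "dropped_low_coverage": drop_cov,
        "dropped_high_n_fraction": int(high_n.sum()),
        "dropped_undefined_gc": int(undef_gc.sum()),
        "dropped_partial": int((binmeth["partial"].to_numpy() & ~usable).sum())
        if exclude_partial
        else 0,
    }
    if min_usable is not None and logdict["n_usable"] < min_usable:
        raise ValueError(
            f"only {logdict['n_usable']} usable bins; downstream analysis "
            f"requires at least {min_usable}"
        )
    log.info("bin filter: %s", logdict)
    return out, logdict


def write_bin_methylome(binmeth: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end", "level", "covered_cpgs", "meth_sum", "total_sum"]
    extra = [c for c in ("gc_fraction", "usable") if c in binmeth.columns]
    binmeth[cols + extra].to_csv(path, sep="\t", index=False, float_format="%.6g")
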