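"""Fixed-width genome tiling with per-bin G/C composition and CpG annotation.

Chromosomes are tiled into non-overlapping bins (500 kb for landscape
classification, 10 kb for domain calling). Each bin carries its G/C fraction
computed over non-N bases, its N fraction, and the number of CpG dinucleotides
lying fully inside the bin. All coordinates are 0-based half-open
(BED convention); bases are handled case-insensitively, so soft-masked
repeats count toward G/C content.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

_A, _C, _G, _T = (ord(b) for b in "ACGT")

BIN_COLUMNS = ["chrom", "start", "end", "gc_fraction", "n_fraction", "cpg_count", "partial"]


def chrom_sequence(genome, chrom: str) -> str:
    """Fetch the full sequence of one chromosome as an upper-case string.

    ``genome`` may be a plain mapping of name -> sequence string or any
    pyfaidx-style object supporting ``genome[chrom]``.
    """
    try:
        seq = genome[chrom]
    except KeyError:
        raise KeyError(f"chromosome {chrom!r} not found in genome") from None
    if not isinstance(seq, str):
        seq = str(seq)
    return seq.upper()


def _seq_array(genome, chrom: str) -> np.ndarray:
    seq = chrom_sequence(genome, chrom)
    if len(seq) == 0:
        raise ValueError(f"chromosome {chrom!r} has an empty sequence")
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _cpg_positions(arr: np.ndarray) -> np.ndarray:
    """0-based positions of the C of every plus-strand CpG."""
    if arr.size < 2:
        return np.empty(0, dtype=np.int64)
    return np.flatnonzero((arr[:-1] == _C) & (arr[1:] == _G)).astype(np.int64)


def enumerate_cpgs(genome, chrom: str) -> np.ndarray:
    """Return strictly increasing 0-based CpG positions on ``chrom``.

    A position qualifies iff sequence[pos] == 'C' and sequence[pos+1] == 'G'
    (case-insensitive); dinucleotides containing N never qualify.
    """
    return _cpg_positions(_seq_array(genome, chrom))


def tile_genome(genome, bin_width: int, autosomes: Sequence[str]) -> pd.DataFrame:
    """Tile the given autosomes into fixed-width bins.

    Returns a DataFrame with columns chrom, start, end, gc_fraction,
    n_fraction, cpg_count, partial. The last bin of a chromosome may be
    shorter than ``bin_width`` and is flagged ``partial``; whether it is used
    downstream is a filtering decision, not a tiling one. ``gc_fraction`` is
    (G+C)/(non-N bases) and is NaN for all-N bins. ``cpg_count`` counts CpGs
    whose two bases both lie inside the bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not autosomes:
        raise ValueError("no autosomes given")
    frames = []
    for chrom in autosomes:
        arr = _seq_array(genome, chrom)
        length = arr.size
        acgt = (arr == _A) | (arr == _C) | (arr == _G) | (arr == _T)
        gc = (arr == _C) | (arr == _G)
        cum_gc = np.concatenate(([0], np.cumsum(gc)))
        cum_acgt = np.concatenate(([0], np.cumsum(acgt)))
        cpgs = _cpg_positions(arr)

        starts = np.arange(0, length, bin_width, dtype=np.int64)
        ends = np.minimum(starts + bin_width, length)
        widths = ends - starts
        non_n = cum_acgt[ends] - cum_acgt[starts]
        gc_counts = cum_gc[ends] - cum_gc[starts]
        with np.errstate(invalid="ignore", divide="ignore"):
            gc_frac = np.where(non_n > 0, gc_counts / np.maximum(non_n, 1), np.nan)
        n_frac = (widths - non_n) / widths
        # CpG fully inside the bin: pos >= start and pos + 1 <= end - 1
        cpg_count = np.searchsorted(cpgs, ends - 1, side="left") - np.searchsorted(
            cpgs, starts, side="left"
        )
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "gc_fraction": gc_frac,
                    "n_fraction": n_frac,
                    "cpg_count": cpg_count.astype(np.int64),
                    "partial": widths < bin_width,
                }
            )
        )
    bins = pd.concat(frames, ignore_index=True)
    return bins


def mean_autosomal_gc(bins: pd.DataFrame) -> float:
    """Unweighted mean of defined per-bin G/C fractions.

    This is the cutoff separating "high G/C" from "low G/C" bins in landscape
    plots (about 0.419 for mouse mm10 autosomal 500-kb bins).
    """
    gc = bins["gc_fraction"].to_numpy(dtype=float)
    defined = ~np.isnan(gc)
    if not defined.any():
        raise ValueError("no bin has a defined gc_fraction")
    return float(gc[defined].mean())


def write_bin_table(bins: pd.DataFrame, path) -> None:
    bins.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_bins_bed(bins: pd.DataFrame, path) -> None:
    """Write bins as BED4 (name = gc_fraction to 4 decimals, '.' if undefined)."""
    out = bins[["chrom", "start", "end"]].copy()
    out["name"] = [
        "." if np.isnan(v) else f"{v:.4f}" for v in bins["gc_fraction"].to_numpy(float)
    ]
    out.to_csv(path, sep="\t", index=False, header=False)


def genome_from_fasta(path):
    """Open an (indexed) FASTA for random access."""
    from pyfaidx import Fasta

    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


def autosome_names(genome, exclude: Iterable[str] = ("X", "Y", "M", "MT")) -> list[str]:
    """Heuristic autosome list: every contig whose name (sans 'chr') is not in
    ``exclude`` and contains no underscore (drops unplaced scaffolds)."""
    names = list(genome.keys()) if not isinstance(genome, Mapping) else list(genome)
    excl = {e.upper() for e in exclude}
    out = []
    for name in names:
        core = name[3:] if name.lower().startswith("chr") else name
        if core.upper() in excl or "_" in name:
            continue
        out.append(name)
    return out
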