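"""Three-class megabase-scale methylome profiling.

A methylome is summarised by (i) its global CpG methylation level and
(ii) its methylation score: the mean level of the top-K most G/C-rich 500-kb
bins minus the mean level of the top-K most A/T-rich bins (K = 1,000 at
genome scale). Classes:

* Class I  — A/T-rich bins more methylated (score <= 0), global level >= 50%
  (typical of somatic tissues);
* Class II — A/T-rich bins more methylated, global level < 50%
  (globally demethylating cells: preimplantation embryos, early PGCs);
* Class III — inverted pattern, G/C-rich bins strictly more methylated
  (score > 0; trophoblast, early epiblast, prospermatogonia, oocytes,
  placenta, many cultured lines).

Classification uses the sign of the score; the rank-sum test comparing the
two bin sets is reported alongside, as in the published figures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .stats import RankSumResult, wilcoxon_rank_sum


@dataclass
class MethylomeProfile:
    sample_id: str
    global_level: float
    score: float
    class_label: str
    n_usable_bins: int
    wilcoxon: RankSumResult


def _usable(bins: pd.DataFrame) -> pd.DataFrame:
    if "usable" in bins.columns:
        bins = bins[bins["usable"]]
    return bins[~bins["gc_fraction"].isna()]


def select_extreme_gc_bins(bins: pd.DataFrame, k: int = 1000) -> tuple[pd.Index, pd.Index]:
    """Indices of the k most G/C-rich and k most A/T-rich usable bins.

    Ties at the k-th boundary are broken by (chrom, start) lexicographic
    order so the selection is deterministic across runs and platforms.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    usable = _usable(bins)
    if len(usable) < 2 * k:
        raise ValueError(
            f"need at least {2 * k} usable bins for k={k}, have {len(usable)}; "
            "use a smaller k"
        )
    order = usable.sort_values(
        ["gc_fraction", "chrom", "start"], ascending=[True, True, True], kind="mergesort"
    ).index
    at_rich = order[:k]
    gc_rich = order[len(order) - k :]
    return pd.Index(gc_rich), pd.Index(at_rich)


def methylation_score(binmeth: pd.DataFrame, gc_rich: pd.Index, at_rich: pd.Index) -> float:
    """mean(level over gc_rich) - mean(level over at_rich), in [-1, 1].

    Bins with undefined level are dropped from their own set; an empty set
    after dropping is an error.
    """
    score_parts = []
    for name, idx in (("G/C-rich", gc_rich), ("A/T-rich", at_rich)):
        levels = binmeth.loc[idx, "level"].to_numpy(dtype=float)
        levels = levels[~np.isnan(levels)]
        if levels.size == 0:
            raise ValueError(f"no defined bin levels in the {name} set")
        score_parts.append(float(levels.mean()))
    return score_parts[0] - score_parts[1]


def classify(global_level: float, score: float) -> str:
    """Class label from global level and methylation score.

    Class III requires a strictly positive score (an "inverted" landscape);
    score <= 0 falls to Class I when the global level is >= 0.5, else II.
    """
    if score > 0:
        return "III"
    return "I" if global_level >= 0.5 else "II"


def rank_bins(binmeth: pd.DataFrame) -> pd.Series:
    """Ascending methylation ranks of usable bins (1 = least methylated),
    midranks for ties; indexed like the usable rows of ``binmeth``."""
    usable = binmeth
    if "usable" in usable.columns:
        usable = usable[usable["usable"]]
    usable = usable[~usable["level"].isna()]
    if len(usable) == 0:
        raise ValueError("no usable bin with a defined level")
    ranks = rankdata(usable["level"].to_numpy(dtype=float), method="average")
    return pd.Series(ranks, index=usable.index, name="rank")


def profile_methylome(
    sample_id: str,
    binmeth: pd.DataFrame,
    global_level: float,
    k: int = 1000,
) -> MethylomeProfile:
    """Full landscape profile of one sample from its 500-kb bin methylome."""
    gc_rich, at_rich = select_extreme_gc_bins(binmeth, k=k)
    score = methylation_score(binmeth, gc_rich, at_rich)
    label = classify(global_level, score)
    ranks = rank_bins(binmeth)
    test = wilcoxon_rank_sum(
        ranks.reindex(gc_rich).dropna().to_numpy(),
        ranks.reindex(at_rich).dropna().to_numpy(),
    )
    n_usable = int(binmeth["usable"].sum()) if "usable" in binmeth.columns else len(binmeth)
    return MethylomeProfile(sample_id, float(global_level), score, label, n_usable, test)


def profiles_table(profiles) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in profiles],
            "global_level": [p.global_level for p in profiles],
            "score": [p.score for p in profiles],
            "class": [p.class_label for p in profiles],
            "p_value": [p.wilcoxon.p_value for p in profiles],
            "test_method": [p.wilcoxon.method for p in profiles],
            "n_usable_bins": [p.n_usable_bins for p in profiles],
        }
    )
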