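"""In-silico zygote methylome at diploid genome formation.

Direct WGBS of zygotes immediately after fertilisation is generally
unavailable, so the zygote methylome is estimated from sperm and oocyte
WGBS: at every CpG covered by at least ``depth_min`` reads (default 4) in
BOTH gametes, the two gametes' counts are equalised to the smaller depth d
and combined 50:50, giving a site level (sperm_meth' + oocyte_meth') / 2d.

Depth equalisation modes:

* ``"rescale"`` (default) — deterministic proportional rescaling with
  round-half-up: meth' = round(meth * d / depth), unmeth' = d - meth'.
  Reproducible without a seed.
* ``"subsample"`` — seeded hypergeometric read subsampling, faithful to
  read-level downsampling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CpGMethylome


def _rescale(meth: np.ndarray, depth: np.ndarray, d: np.ndarray) -> np.ndarray:
    return np.floor(meth * d / depth + 0.5).astype(np.int64)


def reconstruct_zygote(
    sperm: CpGMethylome,
    oocyte: CpGMethylome,
    depth_min: int = 4,
    mode: str = "rescale",
    seed: int | None = None,
) -> CpGMethylome:
    """Combine sperm and oocyte methylomes into an estimated zygote methylome.

    Only CpG sites with depth >= ``depth_min`` in both gametes are retained;
    the output counts at each site are (sperm_meth' + oocyte_meth',
    2d - meth_sum) at equalised depth d = min(sperm depth, oocyte depth).
    """
    if mode not in ("rescale", "subsample"):
        raise ValueError(f"unknown equalisation mode {mode!r}")
    merged = sperm.sites.merge(
        oocyte.sites, on=["chrom", "pos"], suffixes=("_s", "_o"), how="inner"
    )
    depth_s = (merged["meth_s"] + merged["unmeth_s"]).to_numpy(np.int64)
    depth_o = (merged["meth_o"] + merged["unmeth_o"]).to_numpy(np.int64)
    keep = (depth_s >= depth_min) & (depth_o >= depth_min)
    merged = merged[keep]
    if merged.empty:
        raise ValueError(
            f"no CpG site with depth >= {depth_min} in both sperm and oocyte"
        )
    depth_s, depth_o = depth_s[keep], depth_o[keep]
    d = np.minimum(depth_s, depth_o)
    meth_s = merged["meth_s"].to_numpy(np.int64)
    meth_o = merged["meth_o"].to_numpy(np.int64)
    if mode == "rescale":
        meth_s_eq = _rescale(meth_s, depth_s, d)
        meth_o_eq = _rescale(meth_o, depth_o, d)
    else:
        rng = np.random.default_rng(seed)
        meth_s_eq = rng.hypergeometric(meth_s, depth_s - meth_s, d)
        meth_o_eq = rng.hypergeometric(meth_o, depth_o - meth_o, d)
    meth = meth_s_eq + meth_o_eq
    sites = pd.DataFrame(
        {
            "chrom": merged["chrom"].to_numpy(),
            "pos": merged["pos"].to_numpy(np.int64),
            "meth": meth,
            "unmeth": 2 * d - meth,
        }
    ).reset_index(drop=True)
    sample_id = f"zygote({sperm.sample_id}+{oocyte.sample_id})"
    return CpGMethylome(sample_id, sites, {"mode": mode, "depth_min": depth_min})
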