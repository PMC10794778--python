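"""Synthetic genomes and WGBS count data with known ground truth.

The generator emulates the statistical structure the landscape analyses
assume: per-bin G/C content with isochore-like spatial autocorrelation,
CpG density increasing with G/C, class-specific G/C-coupled bin-level mean
methylation (Class I/II/III), injected low-methylation domains, two-stage
reprogramming dynamics driven by a shared latent "lamina proximity"
variable, and independent gamete pairs. Per-site counts are binomial at
the bin-level mean with negative-binomial sequencing depth. Everything is
a pure function of (config, seed).

Two genome tiers are supported: with explicit sequence (i.i.d. bases per
bin at the target G/C, so CpG frequency emerges proportional to gc^2) for
FASTA round-trips at small scale, and sequence-free (analytic bin G/C plus
Poisson-placed CpG positions at rate proportional to gc^2) for large
landscapes such as the 4,800-bin configuration matching the mouse
autosomal usable-bin count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as _st

from .io import CpGMethylome

# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class DepthModel:
    """Per-site sequencing depth: negative binomial with ``mean`` and
    overdispersion ``dispersion`` (variance = mean + dispersion * mean^2);
    dispersion 0 gives Poisson depth."""

    mean: float = 15.0
    dispersion: float = 0.3

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.dispersion <= 0:
            return rng.poisson(self.mean, n)
        r = 1.0 / self.dispersion
        p = r / (r + self.mean)
        return rng.negative_binomial(r, p, n)


@dataclass(frozen=True)
class ClassModel:
    """Bin-level mean methylation mu = clip(intercept + gc_slope * gc + noise).

    Class I/II have a negative G/C slope (A/T-rich bins more methylated),
    Class III a positive one; ``noise_sd`` is Gaussian noise on the level
    scale, drawn independently per 500-kb bin.
    """

    label: str
    intercept: float
    gc_slope: float
    noise_sd: float = 0.02

    def __post_init__(self):
        if self.label in ("I", "II") and self.gc_slope > 0:
            raise ValueError(f"Class {self.label} requires a non-positive G/C slope")
        if self.label == "III" and self.gc_slope <= 0:
            raise ValueError("Class III requires a positive G/C slope")


CLASS_I = ClassModel("I", intercept=0.85, gc_slope=-0.3)
CLASS_II = ClassModel("II", intercept=0.35, gc_slope=-0.3)
CLASS_III = ClassModel("III", intercept=0.55, gc_slope=+0.3)
CLASS_MODELS = {"I": CLASS_I, "II": CLASS_II, "III": CLASS_III}


@dataclass(frozen=True)
class SimulationConfig:
    """Genome-scale simulation parameters.

    Defaults give a desk-scale genome (4 chromosomes x 60 Mb = 480 bins of
    500 kb, so 12 G/C groups x 40 bins exist); ``landscape_4800`` scales the
    same model to 4,800 usable bins. G/C is Beta-distributed around 0.42
    (the mouse autosomal mean) with a ~2 Mb correlation length via a
    Gaussian-copula AR(1) process. ``mean_cpg_density`` is CpGs per bp at
    the mean G/C; the per-bin rate scales with gc^2.
    """

    seed: int = 0
    n_chromosomes: int = 4
    chrom_length: int = 60_000_000
    bin_width: int = 500_000
    gc_mean: float = 0.42
    gc_sd: float = 0.035
    gc_corr_length: float = 2_000_000.0
    mean_cpg_density: float = 0.01
    emit_sequence: bool = False

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


def landscape_4800(seed: int = 0, mean_cpg_density: float = 2e-4) -> SimulationConfig:
    """A 4,800-bin landscape (8 chromosomes x 300 Mb at 500 kb), the usable
    mouse autosomal bin count; CpG density lowered so site tables stay small
    (about 100 CpGs per bin)."""
    return SimulationConfig(
        seed=seed,
        n_chromosomes=8,
        chrom_length=300_000_000,
        mean_cpg_density=mean_cpg_density,
    )


# ---------------------------------------------------------------------------
# genome


@dataclass
class GenomeTruth:
    """A simulated genome: per-500-kb-bin G/C truth, CpG positions, and
    (optionally) explicit sequence."""

    config: SimulationConfig
    bins: pd.DataFrame  # chrom/start/end/gc_fraction/n_fraction/cpg_count/partial
    cpg_positions: dict[str, np.ndarray]
    sequences: dict[str, str] | None = None
    _site_cache: dict = field(default_factory=dict, repr=False)

    @property
    def autosomes(self) -> list[str]:
        return list(dict.fromkeys(self.bins["chrom"]))

    def site_table(self) -> pd.DataFrame:
        """All CpG sites as a chrom/pos frame in bin order."""
        parts = [
            pd.DataFrame({"chrom": c, "pos": p}) for c, p in self.cpg_positions.items()
        ]
        return pd.concat(parts, ignore_index=True)

    def site_bin_index(self) -> np.ndarray:
        """Row index into ``bins`` of each site of ``site_table()``."""
        if "bin_index" not in self._site_cache:
            offsets = {}
            counts = self.bins.groupby("chrom", sort=False).size()
            running = 0
            for chrom, n in counts.items():
                offsets[chrom] = running
                running += int(n)
            chunks = []
            for chrom, pos in self.cpg_positions.items():
                chunks.append(offsets[chrom] + pos // self.config.bin_width)
            self._site_cache["bin_index"] = np.concatenate(chunks).astype(np.int64)
        return self._site_cache["bin_index"]

    def tile(self, bin_width: int) -> pd.DataFrame:
        """Bin table at another width (e.g. 10 kb for domain calling); each
        small bin inherits the G/C of its parent 500-kb bin."""
        rows = []
        for chrom in self.autosomes:
            parent = self.bins[self.bins["chrom"] == chrom]
            gc = parent["gc_fraction"].to_numpy()
            length = int(parent["end"].max())
            starts = np.arange(0, length, bin_width, dtype=np.int64)
            ends = np.minimum(starts + bin_width, length)
            pos = self.cpg_positions[chrom]
            cpg = np.searchsorted(pos, ends - 1) - np.searchsorted(pos, starts)
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts,
                        "end": ends,
                        "gc_fraction": gc[
                            np.minimum(starts // self.config.bin_width, len(gc) - 1)
                        ],
                        "n_fraction": 0.0,
                        "cpg_count": cpg.astype(np.int64),
                        "partial": ends - starts < bin_width,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _gc_profile(config: SimulationConfig, rng: np.random.Generator, n_bins: int) -> np.ndarray:
    """AR(1) Gaussian copula mapped through a Beta marginal."""
    rho = math.exp(-config.bin_width / config.gc_corr_length)
    z = np.empty(n_bins)
    z[0] = rng.standard_normal()
    innov = rng.standard_normal(n_bins - 1) if n_bins > 1 else np.empty(0)
    for i in range(1, n_bins):
        z[i] = rho * z[i - 1] + math.sqrt(1 - rho * rho) * innov[i - 1]
    m, v = config.gc_mean, config.gc_sd**2
    ab = m * (1 - m) / v - 1
    a, b = m * ab, (1 - m) * ab
    u = np.clip(_st.norm.cdf(z), 1e-9, 1 - 1e-9)
    return _st.beta.ppf(u, a, b)


def _sequence_for_bin(rng: np.random.Generator, width: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    draw = bases[rng.choice(4, size=width, p=probs)]
    return draw.tobytes().decode("ascii")


def simulate_genome(config: SimulationConfig, gc_profile=None) -> GenomeTruth:
    """Generate a genome truth from ``config`` (seeded by ``config.seed``).

    With ``emit_sequence`` the per-bin realized G/C is within sampling error
    (far below 0.02 at 500 kb) of the target profile and CpGs come from the
    actual sequence; without it the targets are taken as truth and CpG
    positions are Poisson-placed at rate mean_cpg_density * (gc/gc_mean)^2.
    ``gc_profile`` optionally fixes the per-bin target G/C of every
    chromosome (array of length bins-per-chromosome, e.g. a gradient),
    replacing the autocorrelated random profile.
    """
    if config.mean_cpg_density <= 0 or config.mean_cpg_density > 0.5:
        raise ValueError("mean_cpg_density must be in (0, 0.5]")
    rng = np.random.default_rng(config.seed)
    bin_rows = []
    cpgs: dict[str, np.ndarray] = {}
    seqs: dict[str, str] | None = {} if config.emit_sequence else None
    for chrom in config.chrom_names():
        length = config.chrom_length
        n_bins = math.ceil(length / config.bin_width)
        if gc_profile is not None:
            gc = np.asarray(gc_profile, dtype=float)
            if gc.size != n_bins:
                raise ValueError(f"gc_profile length {gc.size} != {n_bins} bins per chromosome")
            if np.any((gc <= 0) | (gc >= 1)):
                raise ValueError("gc_profile values must lie strictly in (0, 1)")
        else:
            gc = _gc_profile(config, rng, n_bins)
        starts = np.arange(0, length, config.bin_width, dtype=np.int64)
        ends = np.minimum(starts + config.bin_width, length)
        if config.emit_sequence:
            parts = [
                _sequence_for_bin(rng, int(e - s), float(g))
                for s, e, g in zip(starts, ends, gc)
            ]
            seq = "".join(parts)
            seqs[chrom] = seq
            from .binning import enumerate_cpgs, tile_genome

            sub = tile_genome({chrom: seq}, config.bin_width, [chrom])
            cpgs[chrom] = enumerate_cpgs({chrom: seq}, chrom)
            bin_rows.append(sub)
        else:
            rate = config.mean_cpg_density * (gc / config.gc_mean) ** 2
            pos_chunks = []
            counts = np.zeros(n_bins, dtype=np.int64)
            for i, (s, e) in enumerate(zip(starts, ends)):
                width = int(e - s)
                n = rng.poisson(rate[i] * max(width - 1, 0))
                if n == 0:
                    continue
                p = np.unique(rng.integers(0, width - 1, size=n))
                if p.size > 1:  # no overlapping CpGs: pos and pos+1 cannot both be a C
                    p = p[np.concatenate(([True], np.diff(p) > 1))]
                pos_chunks.append(s + p)
                counts[i] = p.size
            cpgs[chrom] = (
                np.concatenate(pos_chunks) if pos_chunks else np.empty(0, dtype=np.int64)
            )
            bin_rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts,
                        "end": ends,
                        "gc_fraction": gc,
                        "n_fraction": 0.0,
                        "cpg_count": counts,
                        "partial": ends - starts < config.bin_width,
                    }
                )
            )
    bins = pd.concat(bin_rows, ignore_index=True)
    return GenomeTruth(config, bins, cpgs, seqs)


# ---------------------------------------------------------------------------
# methylomes


@dataclass
class MethylomeTruth:
    class_label: str
    bin_means: np.ndarray  # expected level per 500-kb bin (after noise + PMDs)
    pmd_intervals: pd.DataFrame  # chrom/start/end/level (possibly empty)


def simulate_pmd_intervals(
    truth: GenomeTruth,
    seed: int,
    n_domains: int = 20,
    min_length: int = 150_000,
    max_length: int = 2_000_000,
    level: float = 0.3,
    grid: int = 10_000,
    min_gap: int = 200_000,
) -> pd.DataFrame:
    """Non-overlapping low-methylation intervals on the 10-kb grid.

    Lengths are uniform multiples of ``grid`` in [min_length, max_length];
    intervals keep at least ``min_gap`` bp apart so injected domains stay
    individually resolvable. ~20 domains of mean ~1 Mb on a 240-Mb genome is
    a conservative PMD load (real PMD-rich methylomes reach tens of percent
    of the genome).
    """
    rng = np.random.default_rng(seed)
    chrom_lengths = {
        c: int(truth.bins.loc[truth.bins["chrom"] == c, "end"].max())
        for c in truth.autosomes
    }
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    attempts = 0
    while len(rows) < n_domains and attempts < 200 * n_domains:
        attempts += 1
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        length = grid * int(rng.integers(min_length // grid, max_length // grid + 1))
        max_start = chrom_lengths[chrom] - length
        if max_start <= 0:
            continue
        start = grid * int(rng.integers(0, max_start // grid + 1))
        end = start + length
        if any(start - min_gap < e and end + min_gap > s for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        rows.append({"chrom": chrom, "start": start, "end": end, "level": level})
    if len(rows) < n_domains:
        raise ValueError("could not place the requested domains; genome too small")
    return (
        pd.DataFrame(rows)
        .sort_values(["chrom", "start"], ignore_index=True)
    )


def _site_means(
    truth: GenomeTruth, bin_means: np.ndarray, pmd_intervals: pd.DataFrame | None
) -> np.ndarray:
    p = bin_means[truth.site_bin_index()].copy()
    if pmd_intervals is not None and len(pmd_intervals):
        sites = truth.site_table()
        pos = sites["pos"].to_numpy()
        chrom_arr = sites["chrom"].to_numpy()
        for row in pmd_intervals.itertuples(index=False):
            mask = (chrom_arr == row.chrom) & (pos >= row.start) & (pos < row.end)
            p[mask] = row.level
    return p


def simulate_methylome(
    truth: GenomeTruth,
    class_model: ClassModel,
    seed: int,
    depth_model: DepthModel = DepthModel(),
    pmd_intervals: pd.DataFrame | None = None,
    sample_id: str | None = None,
) -> tuple[CpGMethylome, MethylomeTruth]:
    """Per-CpG counts for one methylome under a class model.

    Bin mean mu = clip(intercept + slope * gc + noise, 0.01, 0.99); within
    injected intervals the site-level mean is replaced by the interval's
    level. Depth is negative-binomial per site; methylated counts are
    binomial. Sites drawing depth 0 are absent from the output (uncovered).
    """
    rng = np.random.default_rng(seed)
    gc = truth.bins["gc_fraction"].to_numpy(dtype=float)
    noise = rng.normal(0.0, class_model.noise_sd, gc.size) if class_model.noise_sd > 0 else 0.0
    mu = np.clip(class_model.intercept + class_model.gc_slope * gc + noise, 0.01, 0.99)
    p_site = _site_means(truth, mu, pmd_intervals)
    sites = truth.site_table()
    depth = depth_model.sample(rng, len(sites))
    meth = rng.binomial(depth, p_site)
    covered = depth > 0
    out = pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy()[covered],
            "pos": sites["pos"].to_numpy()[covered],
            "meth": meth[covered].astype(np.int64),
            "unmeth": (depth - meth)[covered].astype(np.int64),
        }
    )
    sid = sample_id or f"sim-class{class_model.label}-seed{seed}"
    meta = {"class_label": class_model.label, "seed": seed}
    iv = (
        pmd_intervals.copy()
        if pmd_intervals is not None
        else pd.DataFrame(columns=["chrom", "start", "end", "level"])
    )
    return CpGMethylome(sid, out, meta), MethylomeTruth(class_model.label, mu, iv)


# ---------------------------------------------------------------------------
# two-stage dynamics


@dataclass
class StagePairTruth:
    latent: np.ndarray  # lamina-proximity latent per bin (higher = more A/T-like)
    hypo_means: np.ndarray
    remeth_means: np.ndarray
    labels: pd.DataFrame  # per-bin truth tertile labels (DR/DI/DS, MS/MI/MR)
    degenerate: bool


def _truth_tertiles(
    bins: pd.DataFrame, values: np.ndarray, labels: tuple[str, str, str]
) -> pd.Series:
    order = (
        pd.DataFrame(
            {"v": values, "chrom": bins["chrom"].to_numpy(), "start": bins["start"].to_numpy()}
        )
        .sort_values(["v", "chrom", "start"], ascending=[False, True, True], kind="mergesort")
        .index
    )
    t = len(order) // 3
    lab = pd.Series("", index=bins.index, dtype=object)
    lab.iloc[order[:t]] = labels[0]
    lab.iloc[order[t : 2 * t]] = labels[1]
    lab.iloc[order[2 * t : 3 * t]] = labels[2]
    return lab


def simulate_stage_pair(
    truth: GenomeTruth,
    seed: int,
    depth_model: DepthModel = DepthModel(),
    latent_noise_sd: float = 0.5,
    hypo_base: float = 0.30,
    hypo_span: float = 0.12,
    remeth_base: float = 0.70,
    remeth_span: float = 0.12,
) -> tuple[CpGMethylome, CpGMethylome, StagePairTruth]:
    """A hypomethylated / remethylated sample pair with shared latent structure.

    The latent lamina-proximity variable is the negated standardised G/C
    plus Gaussian noise; bins with high latent (A/T-rich, lamina-proximal)
    retain methylation in the hypomethylated stage (demethylation-resistant)
    and gain little in the remethylated stage (methylation-resistant),
    mirroring the reprogramming behaviour of compartment-B-like regions.
    Truth tertiles are computed from the noiseless stage means.
    """
    rng = np.random.default_rng(seed)
    gc = truth.bins["gc_fraction"].to_numpy(dtype=float)
    gz = (gc - gc.mean()) / gc.std() if gc.std() > 0 else np.zeros_like(gc)
    latent = -gz + (
        rng.normal(0.0, latent_noise_sd, gc.size) if latent_noise_sd > 0 else 0.0
    )
    hypo = np.clip(hypo_base + hypo_span * latent, 0.02, 0.98)
    remeth = np.clip(remeth_base - remeth_span * latent, 0.02, 0.98)
    degenerate = bool(np.allclose(hypo.std(), 0) or np.allclose(remeth.std(), 0))

    from .dynamics import DEMETH_LABELS, METH_LABELS

    labels = pd.DataFrame(
        {
            "chrom": truth.bins["chrom"],
            "start": truth.bins["start"],
            "true_demeth": _truth_tertiles(truth.bins, hypo, DEMETH_LABELS),
            "true_meth": _truth_tertiles(truth.bins, remeth, METH_LABELS),
        }
    )

    def draw(bin_means: np.ndarray, stage: str, stage_seed: int) -> CpGMethylome:
        srng = np.random.default_rng(stage_seed)
        p = bin_means[truth.site_bin_index()]
        sites = truth.site_table()
        depth = depth_model.sample(srng, len(sites))
        meth = srng.binomial(depth, p)
        cov = depth > 0
        df = pd.DataFrame(
            {
                "chrom": sites["chrom"].to_numpy()[cov],
                "pos": sites["pos"].to_numpy()[cov],
                "meth": meth[cov].astype(np.int64),
                "unmeth": (depth - meth)[cov].astype(np.int64),
            }
        )
        return CpGMethylome(f"sim-{stage}-seed{seed}", df, {"seed": seed})

    m_hypo = draw(hypo, "hypomethylated", seed * 2 + 1)
    m_remeth = draw(remeth, "remethylated", seed * 2 + 2)
    return m_hypo, m_remeth, StagePairTruth(latent, hypo, remeth, labels, degenerate)


# ---------------------------------------------------------------------------
# gametes


def simulate_gametes(
    truth: GenomeTruth,
    seed: int,
    sperm_level: float = 0.85,
    oocyte_level: float = 0.40,
    depth_model: DepthModel = DepthModel(),
    low_depth_fraction: float = 0.0,
) -> tuple[CpGMethylome, CpGMethylome, np.ndarray]:
    """Independent sperm and oocyte methylomes over the same CpG set.

    ``low_depth_fraction`` forces that fraction of sites to depth < 4 in the
    sperm methylome (for exercising the zygote depth filter); the returned
    boolean array marks the forced sites in site-table order.
    """
    rng = np.random.default_rng(seed)
    sites = truth.site_table()
    n = len(sites)
    forced = np.zeros(n, dtype=bool)
    if low_depth_fraction > 0:
        forced[rng.random(n) < low_depth_fraction] = True

    def draw(level: float, cap_low: bool, sub_seed: int, name: str) -> CpGMethylome:
        srng = np.random.default_rng(sub_seed)
        depth = depth_model.sample(srng, n)
        if cap_low:
            depth = np.where(forced, srng.integers(0, 4, n), depth)
        meth = srng.binomial(depth, level)
        cov = depth > 0
        df = pd.DataFrame(
            {
                "chrom": sites["chrom"].to_numpy()[cov],
                "pos": sites["pos"].to_numpy()[cov],
                "meth": meth[cov].astype(np.int64),
                "unmeth": (depth - meth)[cov].astype(np.int64),
            }
        )
        return CpGMethylome(f"sim-{name}-seed{seed}", df, {"seed": seed})

    sperm = draw(sperm_level, True, seed * 2 + 101, "sperm")
    oocyte = draw(oocyte_level, False, seed * 2 + 102, "oocyte")
    return sperm, oocyte, forced


# ---------------------------------------------------------------------------
# writers


def write_fasta(truth: GenomeTruth, path, line_width: int = 60) -> None:
    if truth.sequences is None:
        raise ValueError("genome was simulated without sequence (emit_sequence=False)")
    with open(path, "w") as fh:
        for chrom, seq in truth.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def write_cytosine_report(
    methylome: CpGMethylome, path, split_strands_seed: int | None = None
) -> None:
    """Write counts in the Bismark cytosine-report dialect (1-based, stranded).

    By default all counts go on the plus-strand row (a minus row with zero
    counts is still emitted for the partner G). With ``split_strands_seed``
    the counts are split binomially between the strands, exercising the
    strand-merge path of the reader.
    """
    sites = methylome.sites
    meth = sites["meth"].to_numpy()
    unmeth = sites["unmeth"].to_numpy()
    if split_strands_seed is not None:
        rng = np.random.default_rng(split_strands_seed)
        meth_p = rng.binomial(meth, 0.5)
        unmeth_p = rng.binomial(unmeth, 0.5)
    else:
        meth_p, unmeth_p = meth, unmeth
    with open(path, "w") as fh:
        for i, row in enumerate(sites.itertuples(index=False)):
            pos1 = row.pos + 1
            fh.write(
                f"{row.chrom}\t{pos1}\t+\t{meth_p[i]}\t{unmeth_p[i]}\tCG\tCGN\n"
                f"{row.chrom}\t{pos1 + 1}\t-\t{meth[i] - meth_p[i]}\t{unmeth[i] - unmeth_p[i]}\tCG\tCGN\n"
            )


def write_truth_bins(truth: GenomeTruth, path) -> None:
    truth.bins.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        for key, value in vars(config).items():
            fh.write(f"{key}\t{value}\n")


__all__ = [
    "DepthModel",
    "ClassModel",
    "CLASS_I",
    "CLASS_II",
    "CLASS_III",
    "CLASS_MODELS",
    "SimulationConfig",
    "landscape_4800",
    "GenomeTruth",
    "MethylomeTruth",
    "StagePairTruth",
    "simulate_genome",
    "simulate_pmd_intervals",
    "simulate_methylome",
    "simulate_stage_pair",
    "simulate_gametes",
    "write_fasta",
    "write_cytosine_report",
    "write_truth_bins",
    "write_config",
    "replace",
]
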