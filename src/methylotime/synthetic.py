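"""Synthetic single-cell bisulfite datasets with known pseudo-time structure.

The generator emulates the data model of a parallel scRNA-seq / scBS-seq
mouse-ESC experiment: each cell has a latent pseudo-time (lower = more
pluripotent), cells come from a naive 2i-like or a serum-like culture group,
and methylation is observed as sparse per-cytosine read counts in CpG and
non-CpG (CHG/CHH) contexts.

Ground truth is explicit: a subset of genomic intervals ("markers"), aligned
to a fixed tiling grid, carries methylation that tracks pseudo-time on the
logistic scale, while background intervals sit at a context-specific
constant.  CpG markers are always positively associated with pseudo-time;
non-CpG markers may also run in the negative direction, modelled as loci that
start high and demethylate along the trajectory.  Coverage is sparse: each
cell covers a Poisson-distributed handful of cytosines per interval, each at
a small zero-truncated-Poisson read depth (depth 1 gives the binary
single-read calls typical of scBS-seq).

Group structure: the 2i-like group occupies a narrow early segment of the
trajectory (naive ground state), the serum-like group spreads uniformly over
the full trajectory width, and ``group_shift`` sets the difference between
the two group means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quant import GenomicInterval, write_cx_report

GROUP_2I = "2i"
GROUP_SERUM = "serum"


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for one synthetic dataset."""

    n_cells: int = 75
    n_cells_2i: int = 14  # remaining cells are serum-like
    n_chroms: int = 5
    chrom_length: int = 300_000
    interval_size: int = 3000  # marker-placement grid (window step multiple)
    n_marker_intervals_cpg: int = 10
    n_marker_intervals_noncpg: int = 10
    frac_negative_noncpg_markers: float = 0.3
    effect_size: float = 0.1  # logit-scale methylation change per time unit
    background_meth_cpg: float = 0.30
    background_meth_noncpg: float = 0.02
    mean_sites_covered_per_interval: float = 15.0
    read_depth_distribution: tuple = ("zt_poisson", 1.5)
    pseudo_time_range: tuple[float, float] = (0.0, 24.0)  # serum-like group width
    #: time units between group means; None = 2 pooled within-group SDs,
    #: the strong 2i/serum separation the model is meant to resolve
    group_shift: float | None = None
    naive_width_fraction: float = 0.25  # 2i-like width relative to serum-like
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(
            n_cells=self.n_cells,
            n_cells_2i=self.n_cells_2i,
            n_chroms=self.n_chroms,
            chrom_length=self.chrom_length,
            interval_size=self.interval_size,
        )
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if self.n_cells_2i >= self.n_cells:
            raise ValueError("n_cells_2i must leave at least one serum-like cell")
        for name in ("frac_negative_noncpg_markers", "background_meth_cpg",
                     "background_meth_noncpg", "naive_width_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.pseudo_time_range
        if not lo < hi:
            raise ValueError("pseudo_time_range must satisfy min < max")
        if self.background_meth_noncpg >= self.background_meth_cpg:
            raise ValueError(
                "background_meth_noncpg must be below background_meth_cpg "
                "(non-CpG methylation is the rarer class)"
            )

    @property
    def effective_group_shift(self) -> float:
        """group_shift, defaulting to 2 pooled within-group standard deviations
        of the uniform pseudo-time distributions."""
        if self.group_shift is not None:
            return self.group_shift
        lo, hi = self.pseudo_time_range
        width = hi - lo
        s1_sq = (width * self.naive_width_fraction) ** 2 / 12.0
        s2_sq = width**2 / 12.0
        n1 = self.n_cells_2i
        n2 = self.n_cells - n1
        pooled = np.sqrt(((n1 - 1) * s1_sq + (n2 - 1) * s2_sq) / (n1 + n2 - 2))
        return float(2.0 * pooled)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}

    @property
    def n_tiles(self) -> int:
        return self.n_chroms * (self.chrom_length // self.interval_size)


@dataclass(frozen=True)
class MarkerInterval:
    interval: GenomicInterval
    context_class: str  # "CpG" or "nonCpG"
    direction: int  # +1 or -1
    effect_size: float


@dataclass
class SyntheticTruth:
    """Ground truth for one dataset: per-cell state and planted markers."""

    sample_ids: list[str]
    pseudo_time: np.ndarray
    group_label: list[str]
    marker_intervals: list[MarkerInterval]
    background_intervals: list[GenomicInterval]
    t_max: float  # upper end of the trajectory (anchor for "-" markers)

    def markers_of(self, context_class: str) -> list[GenomicInterval]:
        return [m.interval for m in self.marker_intervals if m.context_class == context_class]

    def samples_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "group": self.group_label,
                "pseudo_time": self.pseudo_time,
            }
        )

    def markers_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (m.interval.id, m.context_class, "+" if m.direction > 0 else "-", m.effect_size)
                for m in self.marker_intervals
            ],
            columns=["interval", "context_class", "direction", "effect_size"],
        )


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _tiles(config: SyntheticConfig) -> list[GenomicInterval]:
    out = []
    per_chrom = config.chrom_length // config.interval_size
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        for k in range(per_chrom):
            s = k * config.interval_size
            out.append(GenomicInterval(chrom, s, s + config.interval_size))
    return out


def generate_truth(config: SyntheticConfig) -> SyntheticTruth:
    """Draw per-cell pseudo-times, group labels and planted marker intervals.

    Pseudo-times are uniform within group-specific ranges: the 2i-like group
    over a narrow early segment, the serum-like group over the full
    ``pseudo_time_range`` width, offset so the group means differ by exactly
    ``group_shift``.  Marker tiles are sampled without adjacency (at least one
    background tile between markers) so marker identity stays unambiguous at
    the feature level even under half-overlapping quantification windows.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.pseudo_time_range
    width = hi - lo
    w2i = width * config.naive_width_fraction
    n2i = config.n_cells_2i
    nser = config.n_cells - n2i
    # serum mean - 2i mean = group_shift; 2i anchored at the trajectory start
    shift = config.effective_group_shift
    serum_lo = lo + shift + w2i / 2.0 - width / 2.0
    t2i = rng.uniform(lo, lo + w2i, size=n2i)
    tser = rng.uniform(serum_lo, serum_lo + width, size=nser)
    pseudo_time = np.concatenate([t2i, tser])
    groups = [GROUP_2I] * n2i + [GROUP_SERUM] * nser
    order = rng.permutation(config.n_cells)
    pseudo_time = pseudo_time[order]
    groups = [groups[i] for i in order]
    sample_ids = [f"cell_{i:03d}" for i in range(config.n_cells)]

    tiles = _tiles(config)
    n_markers = config.n_marker_intervals_cpg + config.n_marker_intervals_noncpg
    capacity = (len(tiles) + 1) // 2  # non-adjacent placement
    if n_markers > capacity:
        raise ValueError(
            f"requested {n_markers} marker intervals but the genome holds at most "
            f"{capacity} non-adjacent tiles ({len(tiles)} tiles total); "
            "increase n_chroms or chrom_length"
        )
    chosen: list[int] = []
    taken = np.zeros(len(tiles), dtype=bool)
    for idx in rng.permutation(len(tiles)):
        if len(chosen) == n_markers:
            break
        if taken[idx]:
            continue
        chosen.append(idx)
        taken[max(0, idx - 1) : idx + 2] = True
    if len(chosen) < n_markers:  # permutation order can strand capacity
        for idx in range(len(tiles)):
            if len(chosen) == n_markers:
                break
            if not taken[idx]:
                chosen.append(idx)
                taken[max(0, idx - 1) : idx + 2] = True
    if len(chosen) < n_markers:
        raise ValueError(
            f"could only place {len(chosen)} of {n_markers} non-adjacent marker intervals"
        )

    markers: list[MarkerInterval] = []
    cpg_idx = chosen[: config.n_marker_intervals_cpg]
    noncpg_idx = chosen[config.n_marker_intervals_cpg :]
    for idx in cpg_idx:  # CpG markers are all positively associated
        markers.append(MarkerInterval(tiles[idx], "CpG", +1, config.effect_size))
    n_neg = int(round(config.frac_negative_noncpg_markers * len(noncpg_idx)))
    for j, idx in enumerate(noncpg_idx):
        direction = -1 if j < n_neg else +1
        markers.append(MarkerInterval(tiles[idx], "nonCpG", direction, config.effect_size))
    marker_set = {m.interval for m in markers}
    background = [t for t in tiles if t not in marker_set]
    t_max = max(float(pseudo_time.max()), serum_lo + width, lo + w2i)
    return SyntheticTruth(sample_ids, pseudo_time, groups, markers, background, t_max)


def _draw_depths(rng: np.random.Generator, dist: tuple, size: int) -> np.ndarray:
    name, *params = dist
    if name == "zt_poisson":
        lam = float(params[0])
        # zero-truncated Poisson via inverse-cdf shift
        d = rng.poisson(lam, size=size)
        while (zero := d == 0).any():
            d[zero] = rng.poisson(lam, size=int(zero.sum()))
        return d
    if name == "fixed":
        return np.full(size, int(params[0]), dtype=np.int64)
    raise ValueError(f"unknown read-depth distribution {name!r}")


def _marker_prob(m: MarkerInterval, t: float, background: float, t_max: float) -> float:
    """Site methylation probability for a marker interval at pseudo-time t."""
    if m.direction > 0:
        x = _logit(background) + m.effect_size * t
    else:
        # demethylating locus: high at trajectory start, background at the end
        x = _logit(background) + m.effect_size * (t_max - t)
    return float(_logistic(np.array([x]))[0])


def simulate_methylome(
    truth: SyntheticTruth, config: SyntheticConfig, cell_index: int
) -> pd.DataFrame:
    """Simulate one cell's sparse cytosine report.

    Each interval receives Poisson(``mean_sites_covered_per_interval``)
    covered CpG sites and the same expectation of non-CpG sites (split CHG/CHH
    uniformly); per covered site the read depth is drawn from the configured
    distribution and the methylated count is Binomial(depth, p_site), with
    p_site the context background except at marker intervals of the matching
    context, where it follows the logistic pseudo-time rule.
    """
    if not 0 <= cell_index < config.n_cells:
        raise ValueError(f"cell_index {cell_index} out of range [0, {config.n_cells})")
    rng = np.random.default_rng([config.seed, 1, cell_index])
    t = float(truth.pseudo_time[cell_index])
    marker_by_interval = {m.interval: m for m in truth.marker_intervals}
    chroms, positions, strands, meths, unmeths, contexts = [], [], [], [], [], []
    intervals = truth.background_intervals + [m.interval for m in truth.marker_intervals]
    for interval in sorted(intervals):
        width = interval.end - interval.start
        marker = marker_by_interval.get(interval)
        for context_class in ("CpG", "nonCpG"):
            n_sites = rng.poisson(config.mean_sites_covered_per_interval)
            if n_sites == 0:
                continue
            n_sites = min(n_sites, width)
            bg = (
                config.background_meth_cpg
                if context_class == "CpG"
                else config.background_meth_noncpg
            )
            if marker is not None and marker.context_class == context_class:
                p = _marker_prob(marker, t, bg, truth.t_max)
            else:
                p = bg
            offs = rng.choice(width, size=n_sites, replace=False)
            pos = interval.start + np.sort(offs) + 1  # 1-based
            depth = _draw_depths(rng, config.read_depth_distribution, n_sites)
            meth = rng.binomial(depth, p)
            strand = np.where(rng.random(n_sites) < 0.5, "+", "-")
            if context_class == "CpG":
                ctx = np.full(n_sites, "CpG", dtype=object)
            else:
                ctx = np.where(rng.random(n_sites) < 0.5, "CHG", "CHH")
            chroms.append(np.full(n_sites, interval.chrom, dtype=object))
            positions.append(pos)
            strands.append(strand)
            meths.append(meth)
            unmeths.append(depth - meth)
            contexts.append(ctx)
    frame = pd.DataFrame(
        {
            "chrom": np.concatenate(chroms),
            "pos": np.concatenate(positions).astype(np.int64),
            "strand": np.concatenate(strands),
            "count_meth": np.concatenate(meths).astype(np.int64),
            "count_unmeth": np.concatenate(unmeths).astype(np.int64),
            "context": np.concatenate(contexts),
        }
    )
    return frame.sort_values(["chrom", "pos"], kind="mergesort", ignore_index=True)


def simulate_expression(
    truth: SyntheticTruth,
    n_genes: int = 2000,
    n_marker_genes: int = 50,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a genes x cells TPM matrix tied to pseudo-time.

    Marker genes have log2(TPM+1) linear in (centred) pseudo-time with mixed
    slope signs plus Gaussian noise; the remaining genes are independent of
    pseudo-time.  Returns ``(tpm, gene_truth)`` where ``gene_truth`` records
    each marker gene's slope.
    """
    if n_marker_genes > n_genes:
        raise ValueError("n_marker_genes cannot exceed n_genes")
    rng = np.random.default_rng([seed, 2])
    t = np.asarray(truth.pseudo_time, float)
    tc = t - t.mean()
    n_cells = len(t)
    log_expr = np.empty((n_genes, n_cells))
    slopes = np.zeros(n_genes)
    base = rng.uniform(1.0, 6.0, size=n_genes)
    for g in range(n_genes):
        if g < n_marker_genes:
            sign = 1.0 if (g % 2 == 0) else -1.0
            slope = sign * rng.uniform(0.10, 0.20)
            slopes[g] = slope
            mu = 3.0 + slope * tc
        else:
            mu = np.full(n_cells, base[g])
        log_expr[g] = mu + (rng.normal(0.0, noise_sd, size=n_cells) if noise_sd > 0 else 0.0)
    log_expr = np.clip(log_expr, 0.0, None)
    tpm = np.exp2(log_expr) - 1.0
    genes = [f"gene_{g:04d}" for g in range(n_genes)]
    tpm_df = pd.DataFrame(tpm, index=genes, columns=truth.sample_ids)
    gene_truth = pd.DataFrame(
        {"gene": genes, "is_marker": [g < n_marker_genes for g in range(n_genes)],
         "slope": slopes}
    )
    return tpm_df, gene_truth


def spike_low_conversion(
    records: pd.DataFrame, failure_rate: float, seed: int = 0
) -> pd.DataFrame:
    """Model bisulfite conversion failure at rate ``failure_rate``.

    Each unmethylated read (any context) is independently mis-read as
    methylated with probability ``failure_rate``; returns a new methylome.
    """
    if not 0.0 <= failure_rate <= 1.0:
        raise ValueError("failure_rate must be in [0, 1]")
    out = records.copy()
    if failure_rate == 0.0:
        return out
    rng = np.random.default_rng([seed, 3])
    flips = rng.binomial(out["count_unmeth"].to_numpy(np.int64), failure_rate)
    out["count_meth"] = out["count_meth"].to_numpy(np.int64) + flips
    out["count_unmeth"] = out["count_unmeth"].to_numpy(np.int64) - flips
    return out


def simulate_cohort(
    config: SyntheticConfig, truth: SyntheticTruth | None = None
) -> tuple[SyntheticTruth, dict[str, pd.DataFrame]]:
    """Generate truth (unless given) and all cells' methylomes."""
    if truth is None:
        truth = generate_truth(config)
    methylomes = {
        sid: simulate_methylome(truth, config, i) for i, sid in enumerate(truth.sample_ids)
    }
    return truth, methylomes


def external_cohort(
    config: SyntheticConfig,
    truth: SyntheticTruth,
    pseudo_times: Sequence[float],
    prefix: str = "ext",
    seed_offset: int = 1000,
) -> tuple[SyntheticTruth, dict[str, pd.DataFrame]]:
    """Simulate an external cohort at fixed pseudo-times on the same marker truth."""
    n = len(pseudo_times)
    ext_truth = SyntheticTruth(
        sample_ids=[f"{prefix}_{i:03d}" for i in range(n)],
        pseudo_time=np.asarray(pseudo_times, float),
        group_label=["external"] * n,
        marker_intervals=truth.marker_intervals,
        background_intervals=truth.background_intervals,
        t_max=truth.t_max,
    )
    ext_config = replace(config, n_cells=max(n, 2), n_cells_2i=1, seed=config.seed + seed_offset)
    methylomes = {
        sid: simulate_methylome(ext_truth, ext_config, i)
        for i, sid in enumerate(ext_truth.sample_ids)
    }
    return ext_truth, methylomes


def write_dataset(
    outdir: str | Path,
    config: SyntheticConfig,
    with_expression: bool = False,
    n_genes: int = 2000,
    n_marker_genes: int = 50,
) -> SyntheticTruth:
    """Write a complete synthetic dataset to ``outdir``.

    Produces one cytosine report per cell (``<sample>.cx.tsv``), a sample
    sheet ``samples.tsv`` (sample_id, group, pseudo_time), the marker truth
    ``truth_markers.tsv``, ``chrom_sizes.tsv`` and optionally ``tpm.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth, methylomes = simulate_cohort(config)
    for sid, frame in methylomes.items():
        write_cx_report(frame, outdir / f"{sid}.cx.tsv")
    truth.samples_frame().to_csv(outdir / "samples.tsv", sep="\t", index=False)
    truth.markers_frame().to_csv(outdir / "truth_markers.tsv", sep="\t", index=False)
    pd.Series(config.chrom_sizes).rename_axis("chrom").to_frame("size").to_csv(
        outdir / "chrom_sizes.tsv", sep="\t", header=False
    )
    if with_expression:
        tpm, gene_truth = simulate_expression(
            truth, n_genes=n_genes, n_marker_genes=n_marker_genes, seed=config.seed
        )
        tpm.rename_axis("gene").to_csv(outdir / "tpm.tsv", sep="\t")
        gene_truth.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    return truth
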