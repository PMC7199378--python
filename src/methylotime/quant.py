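"""Sliding-window methylation quantification from cytosine-level calls.

Input is the Bismark-style cytosine report dialect (one row per cytosine:
chromosome, 1-based position, strand, methylated read count, unmethylated
read count, context, trinucleotide).  A sample's methylome is held as a
pandas DataFrame with one row per covered cytosine; :class:`CytosineRecord`
is the per-row value type used at the single-site level.

The quantification scheme: windows of ``w`` bp every ``s`` bp along each
chromosome; a window's methylation level for a sample is the unweighted mean
of per-site methylation rates (methylated / total reads) over the covered
cytosines of the requested context class inside the window.  Windows in which
any sample has fewer than ``min_covered_cytosines`` covered cytosines are
discarded, which yields a dense samples x intervals matrix with no missing
values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONTEXTS = ("CpG", "CHG", "CHH")
NONCPG_CONTEXTS = ("CHG", "CHH")
#: context-class names accepted by quantification functions
CONTEXT_CLASSES = ("CpG", "nonCpG", "combined")

RECORD_COLUMNS = ["chrom", "pos", "strand", "count_meth", "count_unmeth", "context"]

# canonical trinucleotide written per context when none is known
_TRINUCLEOTIDE = {"CpG": "CGG", "CHG": "CAG", "CHH": "CAT"}


class CxReportError(ValueError):
    """Malformed cytosine-report input."""


@dataclass(frozen=True, slots=True)
class CytosineRecord:
    """One cytosine's calls: position, strand, context and read counts."""

    chrom: str
    pos: int  # 1-based
    strand: str
    count_meth: int
    count_unmeth: int
    context: str

    @property
    def total(self) -> int:
        return self.count_meth + self.count_unmeth

    @property
    def covered(self) -> bool:
        return self.total > 0


@dataclass(frozen=True, order=True, slots=True)
class GenomicInterval:
    """0-based half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @classmethod
    def from_id(cls, interval_id: str) -> "GenomicInterval":
        chrom, _, span = interval_id.rpartition(":")
        start, _, end = span.partition("-")
        return cls(chrom, int(start), int(end))


@dataclass(frozen=True, slots=True)
class WindowConfig:
    """Sliding-window scheme: window size w, step s, minimum covered cytosines."""

    window_size: int = 3000
    step_size: int = 1500
    min_covered_cytosines: int = 4

    def __post_init__(self) -> None:
        if not (self.window_size >= self.step_size > 0):
            raise ValueError("require window_size >= step_size > 0")
        if self.min_covered_cytosines < 1:
            raise ValueError("min_covered_cytosines must be >= 1")


@dataclass
class MethylationMatrix:
    """Samples x genomic-interval methylation levels for one context class."""

    context_class: str
    intervals: list[GenomicInterval]
    samples: list[str]
    values: np.ndarray  # shape (n_samples, n_intervals), all in [0, 1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.intervals)):
            raise ValueError("matrix shape does not match samples x intervals")

    @property
    def interval_ids(self) -> list[str]:
        return [iv.id for iv in self.intervals]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.interval_ids)

    def subset_intervals(self, intervals: Sequence[GenomicInterval]) -> "MethylationMatrix":
        index = {iv: j for j, iv in enumerate(self.intervals)}
        missing = [iv.id for iv in intervals if iv not in index]
        if missing:
            raise KeyError(f"intervals absent from matrix: {missing}")
        cols = [index[iv] for iv in intervals]
        return MethylationMatrix(
            self.context_class, list(intervals), list(self.samples), self.values[:, cols]
        )

    def write_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"#context_class={self.context_class}\n")
            self.to_dataframe().rename_axis("sample_id").to_csv(fh, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "MethylationMatrix":
        path = Path(path)
        context_class = "combined"
        with path.open() as fh:
            first = fh.readline()
            if first.startswith("#context_class="):
                context_class = first.strip().split("=", 1)[1]
                df = pd.read_csv(fh, sep="\t", index_col=0)
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t", index_col=0)
        intervals = [GenomicInterval.from_id(c) for c in df.columns]
        return cls(context_class, intervals, [str(s) for s in df.index], df.to_numpy(float))


@dataclass(frozen=True)
class GroupSummary:
    """Mean methylation and coefficient of variation for one pseudo-time group."""

    group_index: str  # roman numeral I..V
    member_samples: tuple[str, ...]
    mean_methylation: float
    cv: float


@dataclass
class MetageneProfile:
    """Per-bin mean methylation across scaled gene regions (12 bins per region)."""

    region_labels: list[str]
    values: np.ndarray  # length 12 * n_regions; NaN where no site fell in a bin
    windows_per_region: int = 12
    skipped: dict[str, int] = field(default_factory=dict)  # region -> genes skipped


# ---------------------------------------------------------------------------
# cytosine-report I/O
# ---------------------------------------------------------------------------

def records_to_frame(records: Iterable[CytosineRecord] | pd.DataFrame) -> pd.DataFrame:
    """Normalize a methylome to its DataFrame form (one row per cytosine)."""
    if isinstance(records, pd.DataFrame):
        return records
    rows = [(r.chrom, r.pos, r.strand, r.count_meth, r.count_unmeth, r.context) for r in records]
    if not rows:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[CytosineRecord]:
    return [
        CytosineRecord(str(c), int(p), str(s), int(m), int(u), str(ctx))
        for c, p, s, m, u, ctx in frame[RECORD_COLUMNS].itertuples(index=False)
    ]


def read_cx_report(path: str | Path) -> pd.DataFrame:
    """Read a Bismark-style cytosine report TSV into a methylome DataFrame.

    Columns: chrom, 1-based position, strand, methylated count, unmethylated
    count, context (CpG/CHG/CHH); a seventh trinucleotide column is accepted
    and ignored.  Raises :class:`CxReportError` with the offending line number
    on malformed input.
    """
    path = Path(path)
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise CxReportError(f"{path}:{lineno}: expected >=6 tab-separated fields")
            chrom, pos, strand, meth, unmeth, context = parts[:6]
            if context not in CONTEXTS:
                raise CxReportError(
                    f"{path}:{lineno}: unknown context {context!r} (expected one of {CONTEXTS})"
                )
            try:
                row = (chrom, int(pos), strand, int(meth), int(unmeth), context)
            except ValueError as exc:
                raise CxReportError(f"{path}:{lineno}: {exc}") from None
            if row[3] < 0 or row[4] < 0:
                raise CxReportError(f"{path}:{lineno}: negative read count")
            rows.append(row)
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_cx_report(records: Iterable[CytosineRecord] | pd.DataFrame, path: str | Path) -> None:
    """Write a methylome as a 7-column cytosine report TSV."""
    frame = records_to_frame(records)
    with Path(path).open("w") as fh:
        for chrom, pos, strand, meth, unmeth, context in frame[RECORD_COLUMNS].itertuples(
            index=False
        ):
            tri = _TRINUCLEOTIDE[context]
            fh.write(f"{chrom}\t{pos}\t{strand}\t{meth}\t{unmeth}\t{context}\t{tri}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return {str(c): int(s) for c, s in zip(df["chrom"], df["size"])}


# ---------------------------------------------------------------------------
# sample-level QC: bisulfite conversion efficiency
# ---------------------------------------------------------------------------

def conversion_efficiency(records: Iterable[CytosineRecord] | pd.DataFrame) -> float:
    """Estimate bisulfite conversion efficiency from apparent non-CpG methylation.

    Non-CpG methylation is rare, so apparent methylation at CHG/CHH sites is
    dominated by unconverted (i.e. failed-conversion) cytosines; efficiency is
    1 - (methylated non-CpG reads / total non-CpG reads) over covered sites.
    """
    frame = records_to_frame(records)
    noncpg = frame[frame["context"].isin(NONCPG_CONTEXTS)]
    total = int(noncpg["count_meth"].sum() + noncpg["count_unmeth"].sum())
    if total == 0:
        raise ValueError("conversion efficiency undefined: no covered non-CpG sites")
    return 1.0 - float(noncpg["count_meth"].sum()) / total


def filter_samples_by_conversion(
    samples: Mapping[str, pd.DataFrame | Iterable[CytosineRecord]],
    cutoff: float = 0.95,
) -> tuple[list[str], pd.DataFrame]:
    """Drop samples with conversion efficiency below ``cutoff``.

    Returns the retained sample ids (input order preserved) and a per-sample
    report with each sample's efficiency and retention flag.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must be in (0, 1]")
    rows = []
    retained = []
    for sample_id, recs in samples.items():
        eff = conversion_efficiency(recs)
        keep = eff >= cutoff
        rows.append((sample_id, eff, keep))
        if keep:
            retained.append(sample_id)
    report = pd.DataFrame(rows, columns=["sample_id", "conversion_efficiency", "retained"])
    return retained, report


# ---------------------------------------------------------------------------
# per-site and per-window methylation
# ---------------------------------------------------------------------------

def site_methylation_rate(record: CytosineRecord) -> float:
    """Methylated reads over total reads at a single cytosine."""
    total = record.count_meth + record.count_unmeth
    if total < 1:
        raise ValueError(f"uncovered site {record.chrom}:{record.pos} has no reads")
    return record.count_meth / total


def make_windows(chrom_sizes: Mapping[str, int], wc: WindowConfig) -> list[GenomicInterval]:
    """Sliding windows [k*s, min(k*s + w, L)) per chromosome, while k*s < L."""
    windows: list[GenomicInterval] = []
    for chrom in chrom_sizes:
        length = int(chrom_sizes[chrom])
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive size {length}")
        start = 0
        while start < length:
            windows.append(GenomicInterval(chrom, start, min(start + wc.window_size, length)))
            start += wc.step_size
    return windows


def _context_mask(frame: pd.DataFrame, context_class: str) -> pd.Series:
    if context_class == "CpG":
        return frame["context"] == "CpG"
    if context_class == "nonCpG":
        return frame["context"].isin(NONCPG_CONTEXTS)
    if context_class == "combined":
        return pd.Series(True, index=frame.index)
    raise ValueError(f"unknown context class {context_class!r}")


def window_methylation(
    records: Iterable[CytosineRecord] | pd.DataFrame,
    interval: GenomicInterval,
    context_class: str = "CpG",
) -> tuple[float, int]:
    """Mean per-site methylation rate inside one interval for one sample.

    A 1-based position ``pos`` is inside the 0-based half-open interval when
    ``start < pos <= end``.  Returns ``(level, n_covered)``; the level is NaN
    when no covered cytosine of the requested context class falls inside.
    """
    frame = records_to_frame(records)
    covered = (frame["count_meth"] + frame["count_unmeth"]) > 0
    mask = (
        covered
        & _context_mask(frame, context_class)
        & (frame["chrom"] == interval.chrom)
        & (frame["pos"] > interval.start)
        & (frame["pos"] <= interval.end)
    )
    sub = frame[mask]
    n = len(sub)
    if n == 0:
        return float("nan"), 0
    rates = sub["count_meth"] / (sub["count_meth"] + sub["count_unmeth"])
    return float(rates.mean()), n


def _window_sums_one_sample(
    frame: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    wc: WindowConfig,
    context_class: str,
    chrom_offsets: Mapping[str, tuple[int, int]],
    n_windows: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate per-window rate sums and covered-site counts for one sample."""
    sums = np.zeros(n_windows)
    counts = np.zeros(n_windows, dtype=np.int64)
    covered = (frame["count_meth"] + frame["count_unmeth"]) > 0
    frame = frame[covered & _context_mask(frame, context_class)]
    w, s = wc.window_size, wc.step_size
    max_overlap = math.ceil(w / s)
    for chrom, grp in frame.groupby("chrom", sort=False):
        if chrom not in chrom_offsets:
            continue
        offset, n_chrom = chrom_offsets[chrom]
        p0 = grp["pos"].to_numpy(np.int64) - 1  # 0-based
        rate = (grp["count_meth"] / (grp["count_meth"] + grp["count_unmeth"])).to_numpy(float)
        base = p0 // s
        for d in range(max_overlap):
            k = base - d
            valid = (k >= 0) & (k < n_chrom) & (k * s + w > p0)
            if not valid.any():
                continue
            idx = offset + k[valid]
            np.add.at(sums, idx, rate[valid])
            np.add.at(counts, idx, 1)
    return sums, counts


def build_matrix(
    samples: Mapping[str, pd.DataFrame | Iterable[CytosineRecord]],
    chrom_sizes: Mapping[str, int],
    wc: WindowConfig,
    context_class: str = "CpG",
) -> MethylationMatrix:
    """Build the samples x intervals methylation matrix for one context class.

    Only windows in which *every* sample has at least
    ``wc.min_covered_cytosines`` covered cytosines of the context class are
    retained, so the result has no missing values.
    """
    if not samples:
        raise ValueError("need at least one sample")
    windows = make_windows(chrom_sizes, wc)
    chrom_offsets: dict[str, tuple[int, int]] = {}
    offset = 0
    for chrom in chrom_sizes:
        n_chrom = sum(1 for iv in windows if iv.chrom == chrom)
        chrom_offsets[chrom] = (offset, n_chrom)
        offset += n_chrom
    sample_ids = list(samples)
    levels = np.empty((len(sample_ids), len(windows)))
    min_counts = np.full(len(windows), np.iinfo(np.int64).max)
    for i, sid in enumerate(sample_ids):
        frame = records_to_frame(samples[sid])
        sums, counts = _window_sums_one_sample(
            frame, chrom_sizes, wc, context_class, chrom_offsets, len(windows)
        )
        with np.errstate(invalid="ignore"):
            levels[i] = sums / counts
        min_counts = np.minimum(min_counts, counts)
    keep = min_counts >= wc.min_covered_cytosines
    if not keep.any():
        raise ValueError(
            "no interval has >= "
            f"{wc.min_covered_cytosines} covered cytosines in every sample; "
            "consider larger windows or denser data"
        )
    kept = [iv for iv, k in zip(windows, keep) if k]
    return MethylationMatrix(context_class, kept, sample_ids, levels[:, keep])


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------

#: default decomposition of a gene into 10 regions (x12 bins = 120 windows)
DEFAULT_REGIONS = (
    "upstream",
    "five_prime_utr",
    "first_exon",
    "first_intron",
    "internal_exons",
    "internal_introns",
    "last_exon",
    "last_intron",
    "three_prime_utr",
    "downstream",
)


def read_bed12(path: str | Path) -> pd.DataFrame:
    names = [
        "chrom", "start", "end", "name", "score", "strand",
        "thick_start", "thick_end", "rgb", "block_count", "block_sizes", "block_starts",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=names, comment="#")
    return df


def _gene_blocks(row) -> list[tuple[int, int]]:
    """Exon blocks of a BED12 row as absolute [start, end) pairs."""
    sizes = [int(x) for x in str(row.block_sizes).rstrip(",").split(",")]
    starts = [int(x) for x in str(row.block_starts).rstrip(",").split(",")]
    return [(row.start + s, row.start + s + z) for s, z in zip(starts, sizes)]


def _region_blocks(row, region: str, flank: int) -> list[tuple[int, int]] | None:
    """Blocks (genome order) for one named region of one gene, or None if absent."""
    exons = _gene_blocks(row)
    minus = row.strand == "-"
    introns = [(a2, b1) for (_, a2), (b1, _) in zip(exons[:-1], exons[1:])]
    if region == "upstream":
        return [(row.start - flank, row.start)] if not minus else [(row.end, row.end + flank)]
    if region == "downstream":
        return [(row.end, row.end + flank)] if not minus else [(row.start - flank, row.start)]
    if region in ("first_exon", "last_exon"):
        first = region == "first_exon"
        return [exons[0] if first != minus else exons[-1]]
    if region in ("first_intron", "last_intron"):
        if not introns:
            return None
        first = region == "first_intron"
        return [introns[0] if first != minus else introns[-1]]
    if region == "internal_exons":
        inner = exons[1:-1]
        return inner or None
    if region == "internal_introns":
        inner = introns[1:-1]
        return inner or None
    if region in ("five_prime_utr", "three_prime_utr"):
        if row.thick_start >= row.thick_end:  # non-coding: no UTRs
            return None
        left = [(max(a, row.start), min(b, row.thick_start)) for a, b in exons]
        left = [(a, b) for a, b in left if a < b]
        right = [(max(a, row.thick_end), b) for a, b in exons]
        right = [(a, b) for a, b in right if a < b]
        five = left if not minus else right
        three = right if not minus else left
        blocks = five if region == "five_prime_utr" else three
        return blocks or None
    if region == "gene_body":
        return [(row.start, row.end)]
    raise ValueError(f"unknown region {region!r}")


def metagene_profile(
    samples: Mapping[str, pd.DataFrame | Iterable[CytosineRecord]],
    gene_models: pd.DataFrame,
    regions: Sequence[str] = DEFAULT_REGIONS,
    windows_per_region: int = 12,
    context_class: str = "CpG",
    flank: int = 1500,
) -> tuple[MetageneProfile, dict[str, MetageneProfile]]:
    """Scaled metagene methylation profile pooled over genes.

    Each region of each gene is rescaled to ``windows_per_region`` equal bins
    (minus-strand genes reversed so bin 1 is 5'-most) and covered-site rates
    are pooled across genes.  Returns the profile pooled over all samples and
    a per-sample profile dict.  Genes lacking a region (e.g. single-exon genes
    have no introns) are skipped for that region and counted in ``skipped``.
    """
    n_bins = windows_per_region * len(regions)
    per_sample_sums = {sid: np.zeros(n_bins) for sid in samples}
    per_sample_counts = {sid: np.zeros(n_bins, dtype=np.int64) for sid in samples}
    skipped: dict[str, int] = {r: 0 for r in regions}

    frames = {}
    for sid, recs in samples.items():
        frame = records_to_frame(recs)
        covered = (frame["count_meth"] + frame["count_unmeth"]) > 0
        frame = frame[covered & _context_mask(frame, context_class)].copy()
        frame["rate"] = frame["count_meth"] / (frame["count_meth"] + frame["count_unmeth"])
        frames[sid] = frame

    for row in gene_models.itertuples(index=False):
        minus = row.strand == "-"
        for r_idx, region in enumerate(regions):
            blocks = _region_blocks(row, region, flank)
            if blocks is None:
                skipped[region] += 1
                continue
            total_len = sum(b - a for a, b in blocks)
            if total_len <= 0:
                skipped[region] += 1
                continue
            for sid, frame in frames.items():
                sub = frame[frame["chrom"] == row.chrom]
                if sub.empty:
                    continue
                cum = 0
                for a, b in blocks:
                    hit = sub[(sub["pos"] > a) & (sub["pos"] <= b)]
                    if not hit.empty:
                        off = (hit["pos"].to_numpy(np.int64) - 1 - a) + cum
                        if minus:
                            off = total_len - 1 - off
                        bins = np.minimum(
                            off * windows_per_region // total_len, windows_per_region - 1
                        )
                        idx = r_idx * windows_per_region + bins
                        np.add.at(per_sample_sums[sid], idx, hit["rate"].to_numpy(float))
                        np.add.at(per_sample_counts[sid], idx, 1)
                    cum += b - a

    labels = [f"{r}.{k + 1}" for r in regions for k in range(windows_per_region)]
    per_sample = {}
    for sid in samples:
        with np.errstate(invalid="ignore"):
            vals = per_sample_sums[sid] / per_sample_counts[sid]
        per_sample[sid] = MetageneProfile(labels, vals, windows_per_region, dict(skipped))
    tot_sums = np.sum([per_sample_sums[s] for s in samples], axis=0)
    tot_counts = np.sum([per_sample_counts[s] for s in samples], axis=0)
    with np.errstate(invalid="ignore"):
        pooled = MetageneProfile(labels, tot_sums / tot_counts, windows_per_region, dict(skipped))
    return pooled, per_sample


# ---------------------------------------------------------------------------
# pseudo-time group summaries (groups I..V)
# ---------------------------------------------------------------------------

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


def group_summary(
    global_levels: Mapping[str, float],
    pseudo_time: Mapping[str, float],
    n_groups: int = 5,
) -> list[GroupSummary]:
    """Split samples into pseudo-time-ordered groups; mean and CV per group.

    Samples are sorted by pseudo-time and cut into ``n_groups`` contiguous
    blocks as equal as possible, any remainder going to the earliest groups.
    CV is the sample standard deviation over the group mean.
    """
    sample_ids = list(global_levels)
    if n_groups > len(sample_ids):
        raise ValueError(f"n_groups={n_groups} exceeds {len(sample_ids)} samples")
    order = sorted(sample_ids, key=lambda s: pseudo_time[s])
    n = len(order)
    base, rem = divmod(n, n_groups)
    sizes = [base + (1 if g < rem else 0) for g in range(n_groups)]
    out = []
    start = 0
    for g, size in enumerate(sizes):
        members = tuple(order[start : start + size])
        start += size
        vals = np.array([global_levels[s] for s in members], float)
        m = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        cv = sd / m if m != 0 else float("nan")
        label = _ROMAN[g] if g < len(_ROMAN) else str(g + 1)
        out.append(GroupSummary(label, members, m, cv))
    return out


def global_methylation(
    samples: Mapping[str, pd.DataFrame | Iterable[CytosineRecord]],
    context_class: str = "CpG",
) -> dict[str, float]:
    """Genome-wide mean per-site methylation rate per sample."""
    out = {}
    for sid, recs in samples.items():
        frame = records_to_frame(recs)
        covered = (frame["count_meth"] + frame["count_unmeth"]) > 0
        sub = frame[covered & _context_mask(frame, context_class)]
        rates = sub["count_meth"] / (sub["count_meth"] + sub["count_unmeth"])
        out[sid] = float(rates.mean()) if len(sub) else float("nan")
    return out
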