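"""Cytosine-report I/O, conversion QC and window quantification."""

import math

import numpy as np
import pandas as pd
import pytest

from methylotime import (
    CytosineRecord,
    GenomicInterval,
    WindowConfig,
    build_matrix,
    conversion_efficiency,
    filter_samples_by_conversion,
    group_summary,
    make_windows,
    metagene_profile,
    read_cx_report,
    site_methylation_rate,
    window_methylation,
    write_cx_report,
)
from methylotime.quant import CxReportError, MethylationMatrix, records_to_frame


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def test_cx_report_parses_fields(tmp_path):
    p = tmp_path / "a.cx.tsv"
    p.write_text("chr1\t100\t+\t3\t1\tCpG\tCGA\n")
    frame = read_cx_report(p)
    assert len(frame) == 1
    row = frame.iloc[0]
    assert (row.chrom, row.pos, row.strand) == ("chr1", 100, "+")
    assert (row.count_meth, row.count_unmeth, row.context) == (3, 1, "CpG")


def test_cx_report_empty_file(tmp_path):
    p = tmp_path / "empty.cx.tsv"
    p.write_text("")
    assert len(read_cx_report(p)) == 0


@pytest.mark.parametrize(
    "line, fragment",
    [
        ("chr1\t100\t+\t3\t1\tCXX\tCGA", "context"),
        ("chr1\t100\t+\t3\tCpG", "fields"),
        ("chr1\tx\t+\t3\t1\tCpG\tCGA", "invalid literal"),
    ],
)
def test_cx_report_malformed_line_names_line_number(tmp_path, line, fragment):
    p = tmp_path / "bad.cx.tsv"
    p.write_text("chr1\t5\t+\t1\t0\tCpG\tCGA\n" + line + "\n")
    with pytest.raises(CxReportError, match=r":2:") as err:
        read_cx_report(p)
    assert fragment.lower() in str(err.value).lower()


def test_write_read_round_trip(tmp_path, small_methylomes):
    sid, frame = next(iter(small_methylomes.items()))
    p = tmp_path / f"{sid}.cx.tsv"
    write_cx_report(frame, p)
    back = read_cx_report(p)
    pd.testing.assert_frame_equal(
        back.reset_index(drop=True), frame.reset_index(drop=True), check_dtype=False
    )


# ---------------------------------------------------------------------------
# conversion efficiency
# ---------------------------------------------------------------------------

def _noncpg_frame(meth, unmeth):
    return pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "pos": [10, 20],
            "strand": ["+", "+"],
            "count_meth": [meth, 0],
            "count_unmeth": [unmeth, 0],
            "context": ["CHH", "CpG"],
        }
    )


def test_conversion_efficiency_arithmetic():
    # 6 methylated of 100 non-CpG reads -> 0.94, below the 95% cutoff
    assert conversion_efficiency(_noncpg_frame(6, 94)) == pytest.approx(0.94)
    assert conversion_efficiency(_noncpg_frame(0, 50)) == 1.0


def test_conversion_efficiency_requires_noncpg_coverage():
    frame = pd.DataFrame(
        {"chrom": ["chr1"], "pos": [1], "strand": ["+"], "count_meth": [1],
         "count_unmeth": [0], "context": ["CpG"]}
    )
    with pytest.raises(ValueError, match="non-CpG"):
        conversion_efficiency(frame)


def test_conversion_filter_boundary():
    clean = _noncpg_frame(0, 99)
    dirty = _noncpg_frame(6, 94)
    retained, report = filter_samples_by_conversion({"a": clean, "b": dirty})
    assert retained == ["a"]
    assert report.set_index("sample_id").loc["b", "conversion_efficiency"] == pytest.approx(0.94)
    # cutoff 1.0: any methylated non-CpG read removes the sample
    retained, _ = filter_samples_by_conversion({"a": clean, "c": _noncpg_frame(1, 999)}, cutoff=1.0)
    assert retained == ["a"]


# ---------------------------------------------------------------------------
# per-site rate and windows
# ---------------------------------------------------------------------------

def test_site_rate():
    rec = CytosineRecord("chr1", 5, "+", 3, 1, "CpG")
    assert site_methylation_rate(rec) == 0.75
    assert site_methylation_rate(CytosineRecord("chr1", 5, "+", 1, 0, "CpG")) == 1.0
    assert site_methylation_rate(CytosineRecord("chr1", 5, "+", 0, 1, "CpG")) == 0.0
    with pytest.raises(ValueError):
        site_methylation_rate(CytosineRecord("chr1", 5, "+", 0, 0, "CpG"))


def test_make_windows_stated_scheme():
    wc = WindowConfig(3000, 1500, 4)
    got = make_windows({"c": 6000}, wc)
    assert [(w.start, w.end) for w in got] == [(0, 3000), (1500, 4500), (3000, 6000), (4500, 6000)]


def test_make_windows_tiling_and_short_chromosome():
    assert all(
        w.end - w.start == 1000 for w in make_windows({"c": 4000}, WindowConfig(1000, 1000, 1))
    )
    short = make_windows({"c": 1000}, WindowConfig(3000, 1500, 1))
    assert [(w.start, w.end) for w in short] == [(0, 1000)]


def test_window_methylation_mean_and_context_partition():
    rows = [
        ("chr1", 10, "+", 1, 0, "CpG"),   # rate 1.0
        ("chr1", 20, "+", 0, 1, "CpG"),   # rate 0.0
        ("chr1", 30, "+", 1, 1, "CpG"),   # 0.5
        ("chr1", 40, "-", 2, 2, "CpG"),   # 0.5
        ("chr1", 50, "+", 1, 0, "CHH"),   # other context
        ("chr1", 55, "+", 1, 1, "CHG"),
    ]
    frame = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count_meth",
                                        "count_unmeth", "context"])
    iv = GenomicInterval("chr1", 0, 100)
    level, n = window_methylation(frame, iv, "CpG")
    assert (level, n) == (0.5, 4)
    level, n = window_methylation(frame, iv, "nonCpG")
    assert n == 2 and level == pytest.approx(0.75)


def test_window_boundary_convention():
    # 1-based pos is inside [start, end) iff start < pos <= end
    frame = pd.DataFrame(
        [("chr1", 1500, "+", 1, 0, "CpG"), ("chr1", 1501, "+", 1, 0, "CpG"),
         ("chr1", 3000, "+", 1, 0, "CpG"), ("chr1", 3001, "+", 1, 0, "CpG")],
        columns=["chrom", "pos", "strand", "count_meth", "count_unmeth", "context"],
    )
    _, n = window_methylation(frame, GenomicInterval("chr1", 1500, 3000), "CpG")
    assert n == 2  # 1501..3000 inclusive


# ---------------------------------------------------------------------------
# matrix construction vs brute force
# ---------------------------------------------------------------------------

def brute_force_window(frame, interval, context_class):
    """Independent per-site recomputation used as the quantification oracle."""
    wanted = {"CpG": {"CpG"}, "nonCpG": {"CHG", "CHH"}}[context_class]
    rates = []
    for row in frame.itertuples(index=False):
        total = row.count_meth + row.count_unmeth
        if total == 0 or row.context not in wanted or row.chrom != interval.chrom:
            continue
        if interval.start < row.pos <= interval.end:
            rates.append(row.count_meth / total)
    return (float(np.mean(rates)) if rates else math.nan, len(rates))


@pytest.mark.parametrize("context_class", ["CpG", "nonCpG"])
def test_build_matrix_matches_brute_force(small_methylomes, small_config, context_class):
    wc = WindowConfig(3000, 1500, 4)
    matrix = build_matrix(small_methylomes, small_config.chrom_sizes, wc, context_class)
    for i, sid in enumerate(matrix.samples):
        for j, iv in enumerate(matrix.intervals):
            level, n = brute_force_window(small_methylomes[sid], iv, context_class)
            assert n >= wc.min_covered_cytosines
            assert matrix.values[i, j] == pytest.approx(level, abs=1e-12)


def test_build_matrix_min_coverage_filter():
    def sample(n_first_window):
        pos = np.concatenate(
            [np.arange(1, n_first_window + 1) * 10, 1000 + np.arange(1, 6) * 10]
        )
        return pd.DataFrame(
            {"chrom": "chr1", "pos": pos, "strand": "+",
             "count_meth": 1, "count_unmeth": 0, "context": "CpG"}
        )

    wc = WindowConfig(1000, 1000, 4)
    matrix = build_matrix({"a": sample(10), "b": sample(3)}, {"chr1": 2000}, wc, "CpG")
    # sample b covers only 3 cytosines in [0,1000) -> that interval dropped
    assert [iv.id for iv in matrix.intervals] == ["chr1:1000-2000"]


def test_build_matrix_errors_when_nothing_survives():
    sparse = pd.DataFrame(
        {"chrom": ["chr1"], "pos": [10], "strand": ["+"], "count_meth": [1],
         "count_unmeth": [0], "context": ["CpG"]}
    )
    with pytest.raises(ValueError, match="larger windows"):
        build_matrix({"a": sparse}, {"chr1": 2000}, WindowConfig(1000, 1000, 4), "CpG")


def test_build_matrix_single_dense_sample_keeps_all_windows():
    frame = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, 2001, 5), "strand": "+",
         "count_meth": 1, "count_unmeth": 1, "context": "CpG"}
    )
    matrix = build_matrix({"a": frame}, {"chr1": 2000}, WindowConfig(1000, 500, 4), "CpG")
    assert len(matrix.intervals) == 4
    assert np.allclose(matrix.values, 0.5)


def test_build_matrix_invariant_to_record_order(small_methylomes, small_config):
    wc = WindowConfig(3000, 1500, 4)
    shuffled = {
        sid: frame.sample(frac=1.0, random_state=3)
        for sid, frame in small_methylomes.items()
    }
    a = build_matrix(small_methylomes, small_config.chrom_sizes, wc, "CpG")
    b = build_matrix(shuffled, small_config.chrom_sizes, wc, "CpG")
    assert a.interval_ids == b.interval_ids
    np.testing.assert_allclose(a.values, b.values)


def test_noncpg_matrix_pools_chg_and_chh(small_methylomes, small_config):
    wc = WindowConfig(3000, 3000, 4)
    pooled = build_matrix(small_methylomes, small_config.chrom_sizes, wc, "nonCpG")
    for i, sid in enumerate(pooled.samples):
        frame = small_methylomes[sid]
        union = frame[frame["context"].isin(["CHG", "CHH"])]
        for j, iv in enumerate(pooled.intervals):
            level, _ = brute_force_window(union, iv, "nonCpG")
            assert pooled.values[i, j] == pytest.approx(level, abs=1e-12)


def test_matrix_tsv_round_trip(tmp_path, small_methylomes, small_config):
    wc = WindowConfig(3000, 1500, 4)
    matrix = build_matrix(small_methylomes, small_config.chrom_sizes, wc, "CpG")
    p = tmp_path / "m.tsv"
    matrix.write_tsv(p)
    back = MethylationMatrix.read_tsv(p)
    assert back.context_class == "CpG"
    assert back.interval_ids == matrix.interval_ids
    np.testing.assert_allclose(back.values, matrix.values)


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------

def _bed12_row(chrom="chr1", start=3000, end=9000, strand="+", blocks=((0, 2000), (4000, 6000))):
    sizes = ",".join(str(b - a) for a, b in blocks)
    starts = ",".join(str(a) for a, _ in blocks)
    return pd.DataFrame(
        [[chrom, start, end, "g1", 0, strand, start, end, "0", len(blocks), sizes, starts]],
        columns=["chrom", "start", "end", "name", "score", "strand", "thick_start",
                 "thick_end", "rgb", "block_count", "block_sizes", "block_starts"],
    )


def test_metagene_profile_length_is_regions_times_bins(small_methylomes):
    genes = _bed12_row()
    regions = ["upstream", "first_exon", "first_intron", "last_exon", "downstream"]
    pooled, per_sample = metagene_profile(small_methylomes, genes, regions=regions)
    assert len(pooled.values) == 12 * len(regions)
    assert all(len(p.values) == 12 * len(regions) for p in per_sample.values())


def test_metagene_uniform_field_is_flat():
    # constant methylation 0.3 at every third base -> every bin averages 0.3
    pos = np.arange(1, 12001, 3)
    frame = pd.DataFrame(
        {"chrom": "chr1", "pos": pos, "strand": "+", "count_meth": 3,
         "count_unmeth": 7, "context": "CpG"}
    )
    genes = _bed12_row(start=3000, end=9000)
    pooled, _ = metagene_profile(
        {"s": frame}, genes, regions=["upstream", "first_exon", "downstream"]
    )
    assert np.allclose(pooled.values[np.isfinite(pooled.values)], 0.3)


def test_metagene_bin_assignment_matches_hand_calculation():
    # 200 bp single-exon toy gene on [100, 300); 12 bins of 16.67 bp
    genes = _bed12_row(start=100, end=300, blocks=((0, 200),))
    # site at 1-based pos 101 -> offset 0 -> bin 0; pos 300 -> offset 199 -> bin 11
    frame = pd.DataFrame(
        {"chrom": "chr1", "pos": [101, 300], "strand": "+",
         "count_meth": [1, 0], "count_unmeth": [0, 1], "context": "CpG"}
    )
    pooled, _ = metagene_profile({"s": frame}, genes, regions=["first_exon"])
    assert pooled.values[0] == 1.0
    assert pooled.values[11] == 0.0
    assert np.isnan(pooled.values[1:11]).all()


def test_metagene_minus_strand_reversed():
    genes = _bed12_row(start=100, end=300, strand="-", blocks=((0, 200),))
    frame = pd.DataFrame(
        {"chrom": "chr1", "pos": [101], "strand": "+", "count_meth": [1],
         "count_unmeth": [0], "context": "CpG"}
    )
    pooled, _ = metagene_profile({"s": frame}, genes, regions=["first_exon"])
    assert pooled.values[11] == 1.0  # genome-left site is the 3'-most bin


def test_metagene_skip_report_counts_missing_regions():
    genes = _bed12_row(blocks=((0, 6000),))  # single exon: no introns
    frame = pd.DataFrame(
        {"chrom": "chr1", "pos": [3500], "strand": "+", "count_meth": [1],
         "count_unmeth": [0], "context": "CpG"}
    )
    pooled, _ = metagene_profile({"s": frame}, genes, regions=["first_exon", "first_intron"])
    assert pooled.skipped["first_intron"] == 1


# ---------------------------------------------------------------------------
# pseudo-time group summaries
# ---------------------------------------------------------------------------

def test_group_summary_equal_fifths_for_75_samples():
    levels = {f"s{i}": 0.1 + 0.001 * i for i in range(75)}
    times = {f"s{i}": float(i) for i in range(75)}
    groups = group_summary(levels, times, n_groups=5)
    assert [len(g.member_samples) for g in groups] == [15] * 5
    assert [g.group_index for g in groups] == ["I", "II", "III", "IV", "V"]
    # group I holds the lowest pseudo-times
    assert set(groups[0].member_samples) == {f"s{i}" for i in range(15)}


def test_group_summary_remainder_to_earliest_groups():
    levels = {f"s{i}": 0.5 for i in range(7)}
    times = {f"s{i}": float(i) for i in range(7)}
    groups = group_summary(levels, times, n_groups=5)
    assert [len(g.member_samples) for g in groups] == [2, 2, 1, 1, 1]
    assert all(g.cv == 0.0 for g in groups if len(g.member_samples) > 1)


def test_group_summary_too_many_groups():
    with pytest.raises(ValueError):
        group_summary({"a": 0.1}, {"a": 1.0}, n_groups=5)
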