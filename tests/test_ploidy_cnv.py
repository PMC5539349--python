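import numpy as np
import pandas as pd
import pytest

from coolsuite import ploidy_cnv as pc
from coolsuite.intervals import GenomicInterval


# -- ploidy ------------------------------------------------------------------

def test_reference_cell_is_2n():
    counts = {"ref": (10_000, 1_000), "x": (10_000, 1_000)}
    est = {e.cell: e for e in pc.estimate_ploidy(counts, ["ref"])}
    assert est["x"].ploidy == pytest.approx(2.0)
    assert est["x"].ploidy_class == "2N"


def test_half_ratio_is_haploid():
    counts = {"ref": (10_000, 1_000), "pb": (5_000, 1_000)}
    est = {e.cell: e for e in pc.estimate_ploidy(counts, ["ref"])}
    assert est["pb"].ploidy == pytest.approx(1.0)
    assert est["pb"].ploidy_class == "1N"


def test_intermediate_ratio_2n_4n():
    counts = {"ref": (10_000, 1_000), "s": (15_000, 1_000)}
    est = {e.cell: e for e in pc.estimate_ploidy(counts, ["ref"])}
    assert est["s"].ploidy == pytest.approx(3.0)
    assert est["s"].ploidy_class == "2N-4N"


def test_reference_mean_normalizes_to_exactly_2():
    counts = {"r1": (9_000, 1_000), "r2": (11_000, 1_000), "r3": (10_000, 1_000)}
    est = pc.estimate_ploidy(counts, ["r1", "r2", "r3"])
    assert np.mean([e.ploidy for e in est]) == pytest.approx(2.0, abs=1e-12)


def test_zero_lambda_is_outlier_no_division():
    counts = {"ref": (10_000, 1_000), "bad": (10_000, 0)}
    est = {e.cell: e for e in pc.estimate_ploidy(counts, ["ref"])}
    assert est["bad"].ploidy_class == "outlier"
    assert np.isnan(est["bad"].ploidy)


def test_no_reference_raises():
    with pytest.raises(ValueError):
        pc.estimate_ploidy({"x": (1, 1)}, [])


def test_ploidy_recovery_simulated(rng):
    """>= 95% correct classes for simulated 1N/2N/4N cells."""
    true = {"1N": 1, "2N": 2, "4N": 4}
    counts, expected = {}, {}
    for i in range(60):
        cls = ["1N", "2N", "4N"][i % 3]
        g = rng.poisson(true[cls] * 10_000)
        l = rng.poisson(1_000)
        counts[f"c{i}"] = (int(g), int(l))
        expected[f"c{i}"] = cls
    refs = [f"ref{i}" for i in range(5)]
    for r in refs:
        counts[r] = (int(rng.poisson(20_000)), int(rng.poisson(1_000)))
    est = pc.estimate_ploidy(counts, refs)
    correct = sum(
        1 for e in est if e.cell in expected and e.ploidy_class == expected[e.cell]
    )
    assert correct / 60 >= 0.95


# -- binning and normalization -----------------------------------------------

def test_bins_tile_chromosome():
    bins = pc.make_bins({"chr1": 10_000_000}, 1_000_000)
    assert len(bins) == 10
    assert bins[0].start == 0 and bins[-1].end == 10_000_000
    for a, b in zip(bins, bins[1:]):
        assert a.end == b.start  # no gaps, no overlaps


def test_bin_counts_conserve_reads(rng):
    positions = pd.DataFrame(
        {"chrom": "chr1", "pos": rng.integers(0, 5_000_000, 500)}
    )
    m = pc.bin_read_positions({"a": positions}, {"chr1": 5_000_000})
    assert m["a"].sum() == 500


def test_identical_cells_log2_zero():
    idx = pd.MultiIndex.from_tuples(
        [("chr1", i * 10, i * 10 + 10) for i in range(20)],
        names=["chrom", "start", "end"],
    )
    raw = pd.DataFrame({c: np.full(20, 100) for c in "abc"}, index=idx)
    norm = pc.bin_and_normalize(raw)
    assert np.allclose(norm.to_numpy(), 0.0)


def test_simulated_gain_log2(rng):
    idx = pd.MultiIndex.from_tuples(
        [("chr1", i, i + 1) for i in range(50)] + [("chr2", i, i + 1) for i in range(50)],
        names=["chrom", "start", "end"],
    )
    base = rng.poisson(2_000, size=(100, 4)).astype(float)
    base[50:, 0] *= 1.5  # first cell gains chr2 at 1.5x
    raw = pd.DataFrame(base, index=idx, columns=["s1", "s2", "s3", "s4"])
    norm = pc.bin_and_normalize(raw)
    chr2_a = norm.loc["chr2", "s1"].mean()
    assert chr2_a == pytest.approx(np.log2(1.5), abs=0.1)


def test_zero_median_bins_masked():
    idx = pd.MultiIndex.from_tuples(
        [("chr1", i, i + 1) for i in range(5)], names=["chrom", "start", "end"]
    )
    raw = pd.DataFrame({c: [100, 100, 0, 100, 100] for c in "abc"}, index=idx)
    norm = pc.bin_and_normalize(raw)
    assert norm.iloc[2].isna().all()


# -- CV ----------------------------------------------------------------------

def test_cv_constant_zero():
    idx = pd.MultiIndex.from_tuples(
        [("chr1", i, i + 1) for i in range(10)], names=["chrom", "start", "end"]
    )
    norm = pd.DataFrame({"a": np.zeros(10)}, index=idx)  # log2 of constant = 0
    assert pc.per_cell_cv(norm)["a"] == pytest.approx(0.0)


def test_cv_poisson_scaling(rng):
    idx = pd.MultiIndex.from_tuples(
        [("chr1", i, i + 1) for i in range(400)], names=["chrom", "start", "end"]
    )
    cvs = []
    for lam in (25, 100, 400):
        raw = pd.DataFrame(
            {c: rng.poisson(lam, 400).astype(float) for c in "abcdef"}, index=idx
        )
        norm = pc.bin_and_normalize(raw)
        cvs.append(pc.per_cell_cv(norm).mean())
    # CV ~ sqrt(lambda)/lambda: decreasing, and ~0.1 at lambda=100
    assert cvs[0] > cvs[1] > cvs[2]
    assert cvs[1] == pytest.approx(0.1, rel=0.3)


# -- chromosome flags --------------------------------------------------------

def _cnv_matrix(rng, multipliers, n_cells=6, bins_per_chrom=40, lam=1_000):
    tuples, rows = [], []
    for chrom, mult_by_cell in multipliers.items():
        for i in range(bins_per_chrom):
            tuples.append((chrom, i, i + 1))
            rows.append(
                [rng.poisson(lam * mult_by_cell.get(c, 1.0)) for c in range(n_cells)]
            )
    idx = pd.MultiIndex.from_tuples(tuples, names=["chrom", "start", "end"])
    return pd.DataFrame(
        np.array(rows, dtype=float), index=idx,
        columns=[f"c{c}" for c in range(n_cells)],
    )


def test_trisomy_flagged(rng):
    raw = _cnv_matrix(rng, {"chr1": {}, "chr2": {0: 1.5}})
    flags = pc.flag_chromosome_cnv(pc.bin_and_normalize(raw))
    assert flags.loc["chr2", "c0"] == "gain"
    assert flags.loc["chr1", "c0"] == "neutral"
    assert (flags.loc["chr2", flags.columns != "c0"] == "neutral").all()


def test_monosomy_flagged(rng):
    raw = _cnv_matrix(rng, {"chr1": {}, "chr2": {0: 0.5}})
    flags = pc.flag_chromosome_cnv(pc.bin_and_normalize(raw))
    assert flags.loc["chr2", "c0"] == "loss"


def test_euploid_specificity(rng):
    raw = _cnv_matrix(rng, {f"chr{i}": {} for i in range(1, 5)}, n_cells=50)
    flags = pc.flag_chromosome_cnv(pc.bin_and_normalize(raw))
    assert (flags.to_numpy() == "neutral").all()


def test_few_bins_untested(rng):
    raw = _cnv_matrix(rng, {"chr1": {}, "tiny": {}}, bins_per_chrom=40)
    tiny = raw.index.get_level_values("chrom") == "tiny"
    raw = raw[~tiny | (raw.index.get_level_values("start") < 2)]
    flags = pc.flag_chromosome_cnv(pc.bin_and_normalize(raw))
    assert flags.loc["tiny", "c0"] == "untested"


# -- replication timing ------------------------------------------------------

def _tiles(values):
    idx = pd.MultiIndex.from_tuples(
        [("chr1", i * 100, (i + 1) * 100) for i in range(len(values))],
        names=["chrom", "start", "end"],
    )
    return pd.Series(np.asarray(values, dtype=float), index=idx)


def _labels(n, pattern):
    out = []
    for i in range(n):
        label = pattern[i % len(pattern)]
        out.append((GenomicInterval("chr1", i * 100, (i + 1) * 100), label))
    return out


def test_s_phase_cell_lead_exceeds_lag(rng):
    n = 200
    labels = _labels(n, ["leading", "lagging"])
    counts = [
        rng.poisson(200 if lab == "leading" else 100) for _, lab in labels
    ]
    lead, lag, p = pc.replication_lead_lag(_tiles(counts), labels)
    assert lead > lag
    assert p < 0.01


def test_g2_cell_no_difference(rng):
    n = 200
    labels = _labels(n, ["leading", "lagging"])
    counts = rng.poisson(400, n)
    lead, lag, p = pc.replication_lead_lag(_tiles(counts), labels)
    assert p > 0.05
    assert lead == pytest.approx(lag, rel=0.05)


def test_shuffled_labels_kill_difference(rng):
    n = 400
    ordered = _labels(n, ["leading", "lagging"])
    counts = [rng.poisson(200 if lab == "leading" else 100) for _, lab in ordered]
    perm = rng.permutation(n)
    shuffled = [
        (ordered[i][0], ordered[perm[i]][1]) for i in range(n)
    ]
    lead, lag, p = pc.replication_lead_lag(_tiles(counts), shuffled)
    assert abs(lead - lag) < 15  # ~null difference at means 150


def test_missing_label_class_undefined():
    labels = _labels(10, ["leading"])
    lead, lag, p = pc.replication_lead_lag(_tiles(np.ones(10)), labels)
    assert np.isnan(lag) and np.isnan(p)


# -- sex inference -----------------------------------------------------------

def _sex_counts(x_reads, chr1_reads, nbins=10):
    tuples = [("chrX", i, i + 1) for i in range(nbins)] + [
        ("chr1", i, i + 1) for i in range(nbins)
    ]
    idx = pd.MultiIndex.from_tuples(tuples, names=["chrom", "start", "end"])
    vals = [x_reads / nbins] * nbins + [chr1_reads / nbins] * nbins
    return pd.Series(vals, index=idx)


def test_infer_sex_xx_xy(rng):
    sizes = {"chrX": 1_000_000, "chr1": 1_000_000}
    xx = _sex_counts(rng.poisson(10_000), 10_000)
    xy = _sex_counts(rng.poisson(5_000), 10_000)
    assert pc.infer_sex(xx, sizes) == "female"
    assert pc.infer_sex(xy, sizes) == "male"


def test_infer_sex_equal_length_ratio():
    sizes = {"chrX": 1_000_000, "chr1": 1_000_000}
    xx = _sex_counts(10_000, 10_000)
    # ratio 1.0 for an XX cell on length-matched chromosomes
    assert pc.infer_sex(xx, sizes) == "female"


def test_infer_sex_no_autosome_reads():
    sizes = {"chrX": 1_000_000, "chr1": 1_000_000}
    with pytest.raises(ValueError):
        pc.infer_sex(_sex_counts(10_000, 0), sizes)
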