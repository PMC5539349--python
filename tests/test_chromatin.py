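import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coolsuite import chromatin, quantify, synthdata
from coolsuite.intervals import GenomicInterval


# ---------------------------------------------------------------------------
# independent brute-force oracle: enumerate every window, test with
# scipy.stats.chi2_contingency, merge overlapping keepers with a naive loop
# ---------------------------------------------------------------------------

def brute_force_scan(counts, chrom_sizes, params):
    regions = []
    genome_c = counts["meth"].sum()
    genome_t = counts["unmeth"].sum()
    bg_rate = genome_c / (genome_c + genome_t)
    for chrom, size in chrom_sizes.items():
        sub = counts[counts["chrom"] == chrom]
        kept = []
        for start in range(0, size, params.step_bp):
            end = min(start + params.window_bp, size)
            inside = sub[(sub["pos"] >= start) & (sub["pos"] < end)]
            wc, wt = int(inside["meth"].sum()), int(inside["unmeth"].sum())
            table = [[wc, wt], [genome_c - wc, genome_t - wt]]
            if min(wc + wt, genome_c - wc + genome_t - wt) == 0 or \
               min(genome_c, genome_t) == 0:
                p = 1.0
            else:
                try:
                    p = stats.chi2_contingency(table, correction=False).pvalue
                except ValueError:
                    p = 1.0
            if wc + wt == 0:
                continue
            rate = wc / (wc + wt)
            direction_ok = (
                rate > bg_rate if params.direction == "enriched" else rate < bg_rate
            )
            if p <= params.p_cutoff and direction_ok:
                kept.append((start, end, p))
        # naive merge of overlapping windows
        i = 0
        while i < len(kept):
            s, e, p = kept[i]
            j = i + 1
            while j < len(kept) and kept[j][0] < e:
                e = max(e, kept[j][1])
                p = min(p, kept[j][2])
                j += 1
            inside = sub[(sub["pos"] >= s) & (sub["pos"] < e)]
            if e - s >= params.min_region_bp and len(inside) >= params.min_gch_sites:
                regions.append((chrom, s, e, len(inside), p))
            i = j
    return regions


def _random_counts(rng, size, n_sites, open_intervals, p_open=0.8, p_closed=0.05,
                   depth=30):
    pos = np.sort(rng.choice(size, n_sites, replace=False))
    p = np.full(n_sites, p_closed)
    for s, e in open_intervals:
        p[(pos >= s) & (pos < e)] = p_open
    meth = rng.binomial(depth, p)
    return pd.DataFrame(
        {"chrom": "c", "pos": pos, "strand": "+", "meth": meth,
         "unmeth": depth - meth}
    )


def test_window_test_hand_computed():
    # direct evaluation of the 2x2 chi-square formula
    wc, wt, gc, gt = 30, 10, 1_000_000, 9_000_000
    a, b = wc, wt
    c, d = gc - wc, gt - wt
    n = a + b + c + d
    expected = n * (a * d - b * c) ** 2 / (
        (a + b) * (c + d) * (a + c) * (b + d)
    )
    stat, p = chromatin.window_test(wc, wt, gc, gt)
    assert stat == pytest.approx(expected, rel=1e-12)
    assert p < 1e-15
    # agrees with scipy's chi2_contingency without correction
    scipy_res = stats.chi2_contingency([[a, b], [c, d]], correction=False)
    assert stat == pytest.approx(scipy_res.statistic, rel=1e-9)


def test_window_test_independence_null():
    # window rate exactly equals background rate -> statistic 0, p = 1
    stat, p = chromatin.window_test(10, 90, 100, 900)
    assert stat == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0)


def test_window_test_degenerate():
    assert chromatin.window_test(0, 0, 1000, 1000) == (0.0, 1.0)
    assert chromatin.window_test(0, 0, 0, 0) == (0.0, 1.0)


def test_window_test_rejects_bad_margins():
    with pytest.raises(ValueError):
        chromatin.window_test(10, 0, 5, 100)


def test_params_presets():
    assert chromatin.NDR_PRESET.window_bp == 120
    assert chromatin.NDR_PRESET.p_cutoff == 1e-15
    assert chromatin.NDR_PRESET.min_region_bp == 140
    assert chromatin.NDR_PRESET.min_gch_sites == 5
    assert chromatin.NUCLEOSOME_PRESET.window_bp == 40
    assert chromatin.NUCLEOSOME_PRESET.p_cutoff == 1e-3
    assert chromatin.NUCLEOSOME_PRESET.min_region_bp == 60
    assert chromatin.NUCLEOSOME_PRESET.min_gch_sites == 3


def test_params_validation():
    with pytest.raises(ValueError):
        chromatin.WindowTestParams(20, 40, 0.5, 60, 3, "enriched")
    with pytest.raises(ValueError):
        chromatin.WindowTestParams(40, 20, 0.5, 60, 3, "sideways")


@pytest.mark.parametrize("preset", [chromatin.NDR_PRESET, chromatin.NUCLEOSOME_PRESET])
def test_oracle_equivalence_random_chromosomes(preset, rng):
    size = 50_000
    for rep in range(4):
        opens = [(s, s + rng.integers(150, 400)) for s in rng.choice(size - 500, 5)]
        counts = _random_counts(rng, size, 2_500, opens)
        got = chromatin.scan_and_call(counts, {"c": size}, preset)
        expected = brute_force_scan(counts, {"c": size}, preset)
        assert len(got) == len(expected)
        for r, (chrom, s, e, n_sites, p) in zip(got, expected):
            assert (r.interval.chrom, r.interval.start, r.interval.end) == (chrom, s, e)
            assert r.n_gch_sites == n_sites
            assert r.min_p == pytest.approx(p, rel=1e-6)


def test_isolated_open_region_called(rng):
    # 240-bp open region on a closed background: exactly one NDR covering it
    size = 50_000
    counts = _random_counts(
        rng, size, 3_000, [(20_000, 20_240)], p_open=0.85, p_closed=0.02, depth=40
    )
    got = chromatin.scan_and_call(counts, {"c": size}, chromatin.NDR_PRESET)
    assert len(got) == 1
    r = got[0]
    assert r.interval.start <= 20_000 + 60 and r.interval.start >= 20_000 - 120
    assert abs(r.interval.start - 20_000) <= 120
    assert abs(r.interval.end - 20_240) <= 120
    # matches the brute-force oracle on the same counts
    oracle = brute_force_scan(counts, {"c": size}, chromatin.NDR_PRESET)
    assert len(oracle) == 1
    assert (r.interval.start, r.interval.end) == oracle[0][1:3]


def test_narrow_region_not_called(rng):
    # planted open region of width 100 -> merged region fails the 140-bp rule
    size = 30_000
    counts = _random_counts(
        rng, size, 1_800, [(15_000, 15_100)], p_open=0.85, p_closed=0.02, depth=40
    )
    # with trimmed boundaries the supporting sites span < 140 bp -> rejected
    got = chromatin.scan_and_call(counts, {"c": size}, chromatin.NDR_PRESET, trim=True)
    assert not any(
        r.interval.overlaps(GenomicInterval("c", 15_000, 15_100)) for r in got
    )


def test_min_sites_rejection(rng):
    # significant merged region with only 4 covered GCH sites is rejected
    size = 20_000
    pos = np.array([10_000, 10_050, 10_100, 10_150])
    df = pd.DataFrame(
        {"chrom": "c", "pos": pos, "strand": "+", "meth": 200, "unmeth": 0}
    )
    bg_pos = np.arange(0, 9_000, 10)
    bg = pd.DataFrame(
        {"chrom": "c", "pos": bg_pos, "strand": "+",
         "meth": 1, "unmeth": 30}
    )
    counts = pd.concat([bg, df], ignore_index=True)
    got = chromatin.scan_and_call(counts, {"c": size}, chromatin.NDR_PRESET)
    assert all(not r.interval.contains_point("c", 10_100) for r in got)
    relaxed = chromatin.WindowTestParams(120, 20, 1e-15, 140, 4, "enriched")
    got4 = chromatin.scan_and_call(counts, {"c": size}, relaxed)
    assert any(r.interval.contains_point("c", 10_100) for r in got4)


def test_p_cutoff_monotonicity(rng):
    size = 50_000
    opens = [(s, s + 250) for s in (10_000, 25_000, 40_000)]
    counts = _random_counts(rng, size, 2_500, opens, depth=20)
    prev = None
    for cutoff in (1e-5, 1e-10, 1e-15, 1e-20):
        params = chromatin.WindowTestParams(120, 20, cutoff, 140, 5, "enriched")
        got = chromatin.scan_and_call(counts, {"c": size}, params)
        spans = set()
        for r in got:
            spans.add((r.interval.start, r.interval.end))
        if prev is not None:
            # every region at the stricter cutoff lies within some looser region
            for s, e in spans:
                assert any(ps <= s and e <= pe for ps, pe in prev)
        prev = spans


def test_classification_promoter_proximal_distal():
    tss = pd.DataFrame({"gene": ["g"], "chrom": ["c"], "tss": [10_000], "strand": ["+"]})
    assert chromatin.classify_ndr(GenomicInterval("c", 9_900, 10_100), tss) == "promoter"
    assert chromatin.classify_ndr(GenomicInterval("c", 10_500, 10_700), tss) == "proximal"
    assert chromatin.classify_ndr(GenomicInterval("c", 40_000, 40_200), tss) == "distal"
    assert chromatin.classify_ndr(GenomicInterval("d", 9_900, 10_100), tss) == "distal"


def test_wide_ndr_fraction():
    def rec(w):
        return chromatin.NdrRecord(
            GenomicInterval("c", 0, w), 10, 50, 50, 1e-20, "proximal"
        )

    assert chromatin.wide_ndr_fraction([rec(150), rec(200), rec(400), rec(500)]) == 0.5
    assert chromatin.wide_ndr_fraction([rec(150), rec(300)]) == 0.0  # strict >
    assert np.isnan(chromatin.wide_ndr_fraction([]))


def test_differential_ndrs(rng):
    ndrs = [GenomicInterval("c", 0, 200), GenomicInterval("c", 1_000, 1_200),
            GenomicInterval("c", 2_000, 2_200)]

    def counts(levels, depth=400):
        rows = []
        for iv, lvl in zip(ndrs, levels):
            for p in range(iv.start, iv.end, 20):
                m = rng.binomial(depth, lvl)
                rows.append(("c", p, "+", m, depth - m))
        return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "meth", "unmeth"])

    a = counts([0.8, 0.5, 0.55])
    b = counts([0.05, 0.5, 0.45])
    out = chromatin.differential_ndrs(ndrs, a, b)
    assert bool(out.iloc[0].differential) and out.iloc[0].direction == "A"
    assert not out.iloc[1].differential
    # large counts but delta 0.1 < min_delta: q tiny yet not differential
    assert out.iloc[2].q < 0.05
    assert not out.iloc[2].differential


def test_differential_identical_groups_null(rng):
    ndrs = [GenomicInterval("c", i * 500, i * 500 + 200) for i in range(10)]
    rows = [("c", p, "+", 5, 5) for iv in ndrs for p in range(iv.start, iv.end, 20)]
    g = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "meth", "unmeth"])
    out = chromatin.differential_ndrs(ndrs, g, g.copy())
    assert not out["differential"].any()


def test_differential_uncovered_untested():
    ndrs = [GenomicInterval("c", 0, 200)]
    a = pd.DataFrame({"chrom": ["c"], "pos": [50], "strand": ["+"],
                      "meth": [5], "unmeth": [5]})
    b = a.iloc[:0]
    out = chromatin.differential_ndrs(ndrs, a, b)
    assert not out.iloc[0].tested
    assert not out.iloc[0].differential


def test_empty_input_empty_output():
    empty = pd.DataFrame(columns=["chrom", "pos", "strand", "meth", "unmeth"])
    assert chromatin.scan_and_call(empty, {"c": 10_000}, chromatin.NDR_PRESET) == []
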