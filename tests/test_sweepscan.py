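"""Windowed Fst / θπ-ratio scan and region logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herdscan import sweepscan
from herdscan.errors import CohortError, ConfigError, DataError
from herdscan.genio import MISSING
from herdscan.sweepscan import RegionSet, WindowSpec

from conftest import make_table


# -- Weir–Cockerham components ----------------------------------------------

def wc_components_symbolic(n1, alt1, het1, n2, alt2, het2):
    """Independent transcription of the two-population variance components,
    evaluated in exact rational arithmetic."""
    from sympy import Rational

    r = 2
    n1, n2 = Rational(n1), Rational(n2)
    p1, p2 = Rational(alt1) / (2 * n1), Rational(alt2) / (2 * n2)
    h1, h2 = Rational(het1) / n1, Rational(het2) / n2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - Rational(r - 1, r) * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - Rational(r - 1, r) * s2
        - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return float(a), float(b), float(c)


def test_wc_components_match_symbolic_oracle():
    """nA=6, pA=1/3, hA=1/3; nB=4, pB=3/4, hB=1/2 — exact-fraction oracle."""
    # group A: 6 samples, alt count 4 (freq 1/3), 2 hets
    da = np.array([1, 1, 2, 0, 0, 0])
    # group B: 4 samples, alt count 6 (freq 3/4), 2 hets
    db = np.array([2, 2, 1, 1])
    a, b, c = sweepscan.site_fst_components(da[:, None], db[:, None])
    ax, bx, cx = wc_components_symbolic(6, 4, 2, 4, 6, 2)
    assert a[0] == pytest.approx(ax, abs=1e-12)
    assert b[0] == pytest.approx(bx, abs=1e-12)
    assert c[0] == pytest.approx(cx, abs=1e-12)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_wc_components_random_vs_symbolic(seed):
    rng = np.random.default_rng(seed)
    n1, n2 = int(rng.integers(2, 12)), int(rng.integers(2, 12))
    da = rng.integers(0, 3, n1)
    db = rng.integers(0, 3, n2)
    if da.sum() + db.sum() in (0, 2 * (n1 + n2)):
        return  # monomorphic overall: defined as zeros, checked elsewhere
    a, b, c = sweepscan.site_fst_components(da[:, None], db[:, None])
    ax, bx, cx = wc_components_symbolic(
        n1, int(da.sum()), int((da == 1).sum()), n2, int(db.sum()), int((db == 1).sum())
    )
    np.testing.assert_allclose([a[0], b[0], c[0]], [ax, bx, cx], atol=1e-12)


def test_wc_fixed_difference_gives_fst_one():
    da = np.zeros((10, 1), dtype=int)
    db = np.full((10, 1), 2, dtype=int)
    a, b, c = sweepscan.site_fst_components(da, db)
    assert a[0] / (a[0] + b[0] + c[0]) == pytest.approx(1.0)


def test_wc_no_differentiation_estimator_can_be_negative():
    """Equal frequencies and heterozygosities: the unbiased estimator's
    numerator is ≤ 0."""
    d = np.array([[1] * 10 + [0] * 5 + [2] * 5]).T  # p=0.5, some hets
    a, _, _ = sweepscan.site_fst_components(d, d.copy())
    assert a[0] <= 0


def test_wc_monomorphic_site_yields_zero_components():
    d = np.zeros((8, 1), dtype=int)
    a, b, c = sweepscan.site_fst_components(d, d.copy())
    assert (a[0], b[0], c[0]) == (0.0, 0.0, 0.0)


# -- windows -----------------------------------------------------------------

def test_window_tiling_coverage():
    """Every bp is covered by between 1 and ceil(size/step) windows."""
    spec = WindowSpec(size_bp=50_000, step_bp=20_000)
    L = 257_123
    windows = sweepscan._windows_for_chrom(L, spec)
    cover = np.zeros(L + 1, dtype=int)
    for s, e in windows:
        cover[s : e + 1] += 1
    cover = cover[1:]
    assert cover.min() >= 1
    assert cover.max() <= int(np.ceil(spec.size_bp / spec.step_bp))


def test_window_fst_single_site_equals_site_ratio():
    dos = np.array([[0], [1], [2], [2], [0], [1]], dtype=np.int16)
    table = make_table(dos, positions=[25_000])
    fst = sweepscan.window_fst(table, [0, 1, 2], [3, 4, 5], WindowSpec())
    a, b, c = sweepscan.site_fst_components(dos[:3], dos[3:])
    assert fst["fst"].iloc[0] == pytest.approx(a[0] / (a[0] + b[0] + c[0]))


def test_window_fst_is_ratio_of_sums_not_mean_of_ratios():
    """Constructed two-site window where the two aggregations differ."""
    rng = np.random.default_rng(44)
    da = np.column_stack([np.repeat([0, 1], 5), np.repeat([0, 2], 5)]).astype(np.int16)
    db = np.column_stack([np.repeat([1, 2], 5), np.repeat([2, 0], 5)]).astype(np.int16)
    table = make_table(np.vstack([da, db]), positions=[100, 200])
    ga, gb = np.arange(10), np.arange(10, 20)
    a, b, c = sweepscan.site_fst_components(table.dosage[ga], table.dosage[gb])
    ratio_of_sums = a.sum() / (a + b + c).sum()
    mean_of_ratios = np.mean(a / (a + b + c))
    assert ratio_of_sums != pytest.approx(mean_of_ratios, abs=1e-6)
    fst = sweepscan.window_fst(table, ga, gb, WindowSpec())
    assert fst["fst"].iloc[0] == pytest.approx(ratio_of_sums, abs=1e-12)


def test_window_fst_monomorphic_window_undefined():
    dos = np.zeros((8, 1), dtype=np.int16)
    table = make_table(dos, positions=[10])
    fst = sweepscan.window_fst(table, [0, 1, 2, 3], [4, 5, 6, 7])
    assert np.isnan(fst["fst"]).all()


def test_window_fst_group_errors():
    table = make_table(np.zeros((4, 1), dtype=np.int16))
    with pytest.raises(CohortError):
        sweepscan.window_fst(table, [], [0, 1])
    with pytest.raises(CohortError):
        sweepscan.window_fst(table, [0, 1], [1, 2])


# -- π -----------------------------------------------------------------------

def pi_pairwise_oracle(dosages):
    """Average pairwise allele difference, brute-forced over allele pairs."""
    out = []
    for j in range(dosages.shape[1]):
        alleles = []
        for d in dosages[:, j]:
            if d != MISSING:
                alleles += [1] * d + [0] * (2 - d)
        n = len(alleles)
        if n < 2:
            out.append(0.0)
            continue
        diff = sum(
            abs(alleles[i] - alleles[k])
            for i in range(n)
            for k in range(i + 1, n)
        )
        out.append(diff / (n * (n - 1) / 2))
    return np.array(out)


def test_window_pi_two_heterozygotes():
    """One site, both samples 0/1: π_site = 8/12; window π = (8/12)/50000."""
    dos = np.array([[1], [1]], dtype=np.int16)
    table = make_table(dos, positions=[10])
    pi = sweepscan.window_pi(table, [0, 1], WindowSpec(), chrom_lengths={"1": 50_000})
    assert pi["pi"].iloc[0] == pytest.approx((8 / 12) / 50_000)


def test_site_pi_matches_pairwise_difference_oracle():
    rng = np.random.default_rng(45)
    dos = rng.integers(0, 3, size=(6, 40)).astype(np.int16)
    dos[rng.random(dos.shape) < 0.2] = MISSING
    np.testing.assert_allclose(
        sweepscan.site_pi(dos), pi_pairwise_oracle(dos), atol=1e-12
    )


def test_window_pi_empty_window_is_zero():
    dos = np.array([[1], [1]], dtype=np.int16)
    table = make_table(dos, positions=[60_001], chrom="1")
    pi = sweepscan.window_pi(table, [0, 1], WindowSpec())
    first = pi[(pi.start == 1)]
    assert first["pi"].iloc[0] == 0.0


def test_sample_duplication_changes_pi_by_finite_sample_factor():
    """π is an unbiased per-pair estimator: duplicating every sample only
    rescales by the allele-count combinatorics, verified against the oracle."""
    rng = np.random.default_rng(46)
    dos = rng.integers(0, 3, size=(4, 10)).astype(np.int16)
    doubled = np.vstack([dos, dos])
    np.testing.assert_allclose(
        sweepscan.site_pi(doubled), pi_pairwise_oracle(doubled), atol=1e-12
    )


# -- log2 ratio and selection --------------------------------------------------

def test_log2_pi_ratio_values():
    assert sweepscan.log2_pi_ratio(1e-4, 1e-4) == pytest.approx(0.0)
    assert sweepscan.log2_pi_ratio(2e-4, 1e-4) == pytest.approx(1.0)
    assert np.isnan(sweepscan.log2_pi_ratio(0.0, 1e-4))
    assert np.isnan(sweepscan.log2_pi_ratio(1e-4, 0.0))


def _stats_frame(values, start0=1, width=50_000):
    rows = []
    for i, v in enumerate(values):
        s = start0 + 20_000 * i
        rows.append(("1", s, s + width - 1, 10, v))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "fst"])
    df["log2_ratio"] = df["fst"]
    return df


def test_select_top_windows_counts():
    rng = np.random.default_rng(47)
    vals = rng.permutation(100) / 100.0
    thr, regions = sweepscan.select_top_windows(_stats_frame(vals), "fst", 0.95)
    sel = (vals > thr).sum()
    assert sel == 5


def test_select_top_windows_sort_oracle():
    rng = np.random.default_rng(48)
    vals = rng.normal(size=1000)
    vals[rng.random(1000) < 0.05] = np.nan
    stats = _stats_frame(vals)
    thr, regions = sweepscan.select_top_windows(stats, "fst", 0.95)
    defined = vals[np.isfinite(vals)]
    want_thr = np.quantile(defined, 0.95)
    assert thr == pytest.approx(want_thr, abs=1e-12)
    want = stats.loc[np.isfinite(vals) & (vals > want_thr)]
    want_set = RegionSet(
        [(str(r.chrom), int(r.start), int(r.end)) for r in want.itertuples()]
    )
    assert regions.intervals == want_set.intervals


def test_select_top_windows_degenerate_and_errors():
    with pytest.warns(UserWarning):
        thr, regions = sweepscan.select_top_windows(
            _stats_frame([0.3] * 30), "fst", 0.95
        )
    assert len(regions) == 0
    with pytest.raises(DataError):
        sweepscan.select_top_windows(_stats_frame([0.1] * 10), "fst", 0.95)
    with pytest.raises(ConfigError):
        sweepscan.select_top_windows(_stats_frame([0.1] * 30), "pi", 0.95)


# -- region combination --------------------------------------------------------

def test_combine_regions_examples():
    A = RegionSet([("1", 100, 200)])
    B = RegionSet([("1", 150, 250)])
    inter = sweepscan.combine_regions(A, B, "intersection")
    union = sweepscan.combine_regions(A, B, "union")
    assert inter.intervals == [("1", 150, 200)]
    assert union.intervals == [("1", 100, 250)]
    C = RegionSet([("2", 300, 400)])
    assert sweepscan.combine_regions(A, C, "intersection").intervals == []


def test_combine_regions_per_bp_oracle():
    """Randomized interval sets vs per-bp membership on a 1-Mb toy chromosome."""
    rng = np.random.default_rng(49)
    L = 1_000_000

    def random_set():
        iv = []
        for _ in range(rng.integers(3, 12)):
            s = int(rng.integers(1, L - 10_000))
            e = s + int(rng.integers(1, 50_000))
            iv.append(("1", s, min(e, L)))
        return RegionSet(iv)

    for _ in range(5):
        A, B = random_set(), random_set()
        in_a = np.zeros(L + 1, dtype=bool)
        in_b = np.zeros(L + 1, dtype=bool)
        for _, s, e in A.intervals:
            in_a[s : e + 1] = True
        for _, s, e in B.intervals:
            in_b[s : e + 1] = True
        for mode, want in (("intersection", in_a & in_b), ("union", in_a | in_b)):
            got = np.zeros(L + 1, dtype=bool)
            for _, s, e in sweepscan.combine_regions(A, B, mode).intervals:
                got[s : e + 1] = True
            np.testing.assert_array_equal(got, want)


def test_combine_regions_bad_mode():
    A = RegionSet([("1", 1, 10)])
    with pytest.raises(ConfigError):
        sweepscan.combine_regions(A, A, "xor")


# -- planted-sweep behaviour on the reference cohort ---------------------------

def test_planted_sweeps_dominate_both_statistics(pipeline_run):
    """Planted sweep windows occupy the extreme tail of both Fst and the
    θπ-ratio, and the top-5% intersection covers the sweeps while staying
    below 7% of the genome."""
    stats = pd.read_csv(
        f"{pipeline_run['out_dir']}/window_stats.tsv", sep="\t", dtype={"chrom": str}
    )
    truth = pipeline_run["truth"]
    sweeps = [(str(s["chrom"]), s["start"], s["end"]) for s in truth.sweeps]

    def overlaps_sweep(row):
        return any(
            c == row.chrom and row.start <= e and row.end >= s for c, s, e in sweeps
        )

    in_sweep = stats.apply(overlaps_sweep, axis=1).to_numpy()
    # the maximum background value sits below the median planted value
    assert np.nanmedian(stats.fst[in_sweep]) > np.nanmax(stats.fst[~in_sweep])
    assert np.nanmedian(stats.log2_ratio[in_sweep]) > np.nanmax(
        stats.log2_ratio[~in_sweep]
    )
    _, fst_regions = sweepscan.select_top_windows(stats, "fst", 0.95)
    _, pi_regions = sweepscan.select_top_windows(stats, "log2_ratio", 0.95)
    inter = sweepscan.combine_regions(fst_regions, pi_regions, "intersection")
    genome_bp = pipeline_run["config"].n_chrom * pipeline_run["config"].chrom_length_bp
    assert inter.total_bp() < 0.07 * genome_bp
    covered = 0
    total = 0
    for c, s, e in sweeps:
        pos = np.arange(s, e + 1, 1000)
        covered += inter.contains(c, pos).sum()
        total += len(pos)
    assert covered / total >= 0.9
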