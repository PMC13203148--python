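"""Rare-allele candidate screen and gene annotation."""

import numpy as np
import pandas as pd
import pytest

from herdscan import twinscreen
from herdscan.errors import CohortError, ConfigError
from herdscan.genio import MISSING, Gene, GeneModel
from herdscan.sweepscan import RegionSet

from conftest import make_table


def _twin_table(alt_count, n=57, missing=0):
    """One-variant table with the requested ALT count in a diploid cohort."""
    dos = np.zeros((n, 1), dtype=np.int16)
    n_hom = max(0, alt_count - n)
    n_het = alt_count - 2 * n_hom
    dos[:n_het, 0] = 1
    dos[n_het : n_het + n_hom, 0] = 2
    dos[n - missing :, 0] = MISSING
    return make_table(dos)


def test_allele_freq_reference_values():
    """57 diploids, 10 ALT alleles → 10/114 = 0.0877193; with one missing
    genotype and 11 ALT alleles → 11/112 = 0.0982143."""
    f = twinscreen.allele_freq(_twin_table(10), np.arange(57))
    assert f["freq"].iloc[0] == pytest.approx(10 / 114)
    assert round(f["freq"].iloc[0], 7) == 0.0877193
    f2 = twinscreen.allele_freq(_twin_table(11, missing=1), np.arange(57))
    assert f2["n_alleles"].iloc[0] == 112
    assert round(f2["freq"].iloc[0], 7) == 0.0982143


def test_allele_freq_edge_cases():
    f = twinscreen.allele_freq(_twin_table(0), np.arange(57))
    assert f["freq"].iloc[0] == 0.0
    dos = np.full((3, 1), MISSING, dtype=np.int16)
    f = twinscreen.allele_freq(make_table(dos), np.arange(3))
    assert np.isnan(f["freq"].iloc[0]) and f["n_alleles"].iloc[0] == 0
    with pytest.raises(CohortError):
        twinscreen.allele_freq(_twin_table(0), np.array([], dtype=int))


def test_rare_in_all_controls_quantifier():
    freqs = {f"p{i}": np.array([0.04, 0.04, np.nan]) for i in range(5)}
    freqs["p5"] = np.array([0.04, 0.06, np.nan])
    mask = twinscreen.rare_in_all_controls(freqs, 0.05)
    # variant 0: rare everywhere; variant 1: 0.06 in one population fails the
    # "all" quantifier; variant 2: undefined everywhere -> excluded
    assert mask.tolist() == [True, False, False]
    with pytest.raises(ConfigError):
        twinscreen.rare_in_all_controls({}, 0.05)


def test_rare_in_all_controls_randomized_oracle():
    rng = np.random.default_rng(51)
    m = 200
    freqs = {
        f"p{i}": np.where(rng.random(m) < 0.1, np.nan, rng.random(m) * 0.1)
        for i in range(6)
    }
    mask = twinscreen.rare_in_all_controls(freqs, 0.05)
    for j in range(m):
        vals = [freqs[k][j] for k in freqs]
        defined = [v for v in vals if np.isfinite(v)]
        want = bool(defined) and all(v < 0.05 for v in defined)
        assert mask[j] == want


def _screen_setup():
    """3 variants: in-region rare-enriched, boundary-mac, out-of-region."""
    n = 57
    dos = np.zeros((n, 3), dtype=np.int16)
    dos[:10, 0] = 1  # minor count 10 -> passes mac=10
    dos[:9, 1] = 1  # minor count 9 -> fails
    dos[:12, 2] = 1  # in rare set but outside regions
    table = make_table(dos, positions=[100, 200, 900])
    regions = RegionSet([("1", 50, 500)])
    rare = np.array([True, True, True])
    return table, regions, rare


def test_screen_candidates_gates():
    table, regions, rare = _screen_setup()
    out = twinscreen.screen_candidates(table, np.arange(57), regions, rare, mac=10)
    assert out["pos"].tolist() == [100]
    assert out["twin_freq"].iloc[0] == pytest.approx(10 / 114)
    # mac boundary: count 9 excluded, count 10 admitted
    assert 200 not in out["pos"].tolist()


def test_screen_minor_allele_orientation():
    """mac applies to the minor allele: a near-fixed ALT with few REF copies
    is judged by the REF count."""
    n = 57
    dos = np.full((n, 1), 2, dtype=np.int16)
    dos[:5, 0] = 1  # ref count 5 < mac
    table = make_table(dos)
    out = twinscreen.screen_candidates(
        table, np.arange(n), RegionSet([("1", 1, 1000)]), np.array([True]), mac=10
    )
    assert len(out) == 0


def test_screen_missing_rate_gate():
    n = 57
    dos = np.zeros((n, 1), dtype=np.int16)
    dos[:10, 0] = 1
    dos[50:, 0] = MISSING  # 7/57 ≈ 12.3% missing > 10%
    table = make_table(dos)
    out = twinscreen.screen_candidates(
        table, np.arange(n), RegionSet([("1", 1, 1000)]), np.array([True])
    )
    assert len(out) == 0


def test_screen_is_pure_conjunction():
    """The screen equals an independent per-variant evaluation of all four
    gates, so gate order cannot matter."""
    rng = np.random.default_rng(52)
    n, m = 57, 120
    dos = rng.choice([0, 1, 2, MISSING], size=(n, m), p=[0.7, 0.15, 0.05, 0.1]).astype(
        np.int16
    )
    pos = np.sort(rng.choice(100_000, m, replace=False)) + 1
    table = make_table(dos, positions=pos)
    regions = RegionSet([("1", 10_000, 40_000), ("1", 60_000, 90_000)])
    rare = rng.random(m) < 0.5
    out = twinscreen.screen_candidates(table, np.arange(n), regions, rare, mac=5)
    got = set(out["pos"].tolist())
    want = set()
    for j in range(m):
        col = dos[:, j]
        called = col[col != MISSING]
        alt = int(called.sum())
        minor = min(alt, 2 * len(called) - alt)
        miss = 1 - len(called) / n
        if (
            regions.contains("1", np.array([pos[j]]))[0]
            and rare[j]
            and minor >= 5
            and miss <= 0.1
        ):
            want.add(int(pos[j]))
    assert got == want


def test_screen_empty_regions_warns_not_errors():
    table, _, rare = _screen_setup()
    with pytest.warns(UserWarning):
        out = twinscreen.screen_candidates(
            table, np.arange(57), RegionSet([]), rare
        )
    assert len(out) == 0


# -- annotation ---------------------------------------------------------------

def _model():
    return GeneModel(
        genes=[
            Gene("GA", "1", 10_000, 20_000, "+"),
            Gene("GB", "1", 200_000, 210_000, "+"),
            Gene("GC", "1", 300_000, 310_000, "-"),
        ]
    )


def _cands(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "twin_freq"])


def test_annotate_genic_and_nearest():
    snps = _cands(
        [
            ("1", 15_000, 0.1),  # inside GA -> genic
            ("1", 130_000, 0.1),  # 70 kb upstream of GB -> nearest at 70 kb
            ("1", 205_000, 0.1),  # inside GB
        ]
    )
    snp_table, gene_table = twinscreen.annotate_snps(snps, _model(), near_bp=100_000)
    rows = {r.pos: r for r in snp_table.itertuples()}
    assert rows[15_000].relation == "genic" and rows[15_000].distance_bp == 0
    assert rows[130_000].relation == "intergenic-nearest"
    assert rows[130_000].gene == "GB" and rows[130_000].distance_bp == 70_000
    assert set(gene_table["gene"]) == {"GA", "GB"}
    gb = gene_table.set_index("gene").loc["GB"]
    assert gb["n_snps"] == 2


def test_annotate_strand_aware_flanks():
    snps = _cands(
        [
            ("1", 199_500, 0.1),  # 500 bp before GB (+) -> upstream
            ("1", 210_400, 0.1),  # 400 bp after GB (+) -> downstream
            ("1", 310_900, 0.1),  # 900 bp after GC (-) -> upstream by strand
        ]
    )
    snp_table, _ = twinscreen.annotate_snps(snps, _model())
    rel = dict(zip(snp_table["pos"], snp_table["relation"]))
    assert rel[199_500] == "upstream"
    assert rel[210_400] == "downstream"
    assert rel[310_900] == "upstream"


def test_annotate_exonic_intronic_with_exon_structure():
    model = _model()
    model.exons["GA"] = [(10_000, 12_000), (18_000, 20_000)]
    snps = _cands([("1", 11_000, 0.1), ("1", 15_000, 0.1)])
    snp_table, _ = twinscreen.annotate_snps(snps, model)
    rel = dict(zip(snp_table["pos"], snp_table["relation"]))
    assert rel[11_000] == "exonic" and rel[15_000] == "intronic"


def test_annotate_unknown_chromosome_unannotated():
    snps = _cands([("9", 1000, 0.1)])
    snp_table, gene_table = twinscreen.annotate_snps(snps, _model())
    assert snp_table["relation"].iloc[0] == "unannotated"
    assert len(gene_table) == 0


def test_annotate_matches_bruteforce_nearest_scan():
    rng = np.random.default_rng(53)
    genes = []
    start = 1000
    for i in range(30):
        g_start = start + int(rng.integers(0, 20_000))
        g_end = g_start + int(rng.integers(500, 15_000))
        genes.append(Gene(f"g{i}", "1", g_start, g_end, "+"))
        start = g_end + 500
    model = GeneModel(genes=genes)
    positions = rng.integers(1, start + 100_000, size=200)
    snps = _cands([("1", int(p), 0.1) for p in np.unique(positions)])
    snp_table, _ = twinscreen.annotate_snps(snps, model, near_bp=100_000, flank_bp=1000)
    first = snp_table.drop_duplicates(subset=["pos"], keep="first").set_index("pos")
    for p in first.index:
        overlaps = [g for g in genes if g.start <= p <= g.end]
        dists = [(max(g.start - p, p - g.end, 0), g.name) for g in genes]
        dmin, _ = min(dists)
        row = first.loc[p]
        if overlaps:
            assert row["relation"] in ("genic", "exonic", "intronic")
            assert row["distance_bp"] == 0
        elif dmin <= 1000:
            assert row["relation"] in ("upstream", "downstream")
            assert row["distance_bp"] == dmin
        elif dmin <= 100_000:
            assert row["relation"] == "intergenic-nearest"
            assert row["distance_bp"] == dmin
        else:
            assert row["relation"] == "unannotated"


def test_candidate_frequencies_self_consistent(pipeline_run):
    """Every screened SNP's reported twin frequency reproduces from the
    genotype table via allele_freq."""
    cands = pd.read_csv(
        f"{pipeline_run['out_dir']}/candidate_snps.tsv", sep="\t", dtype={"chrom": str}
    )
    table = pipeline_run["table"]
    twin = table.sample_index(cohort="twin")
    freqs = twinscreen.allele_freq(table, twin)
    key = {(c, p): f for c, p, f in zip(freqs["chrom"], freqs["pos"], freqs["freq"])}
    assert len(cands) > 0
    for row in cands.itertuples():
        assert row.twin_freq == pytest.approx(key[(str(row.chrom), row.pos)], abs=1e-9)
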