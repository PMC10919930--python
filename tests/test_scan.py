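import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import traitscan as ts
from traitscan.scan import (
    FLAG_COLLINEAR,
    FLAG_LOW_COMPLEXITY,
    FLAG_MONOMORPHIC,
    FLAG_SINGLETON,
    FLAG_ZERO_RESIDUAL,
    ScanEngine,
)

from conftest import make_alignment, make_traits


# ---------------------------------------------------------------------------
# single-column model fits
# ---------------------------------------------------------------------------

def test_worked_anova_example(six_species_column, six_species_traits):
    """Two allele groups with log masses (10,11,12) vs (1,2,3):
    between-group SS = 121.5, within = 4, so F = 121.5 on (1, 4) df."""
    r = ts.fit_column_model(six_species_column, six_species_traits)
    assert r.F == pytest.approx(121.5, rel=1e-12)
    assert (r.df_num, r.df_den) == (1, 4)
    assert r.n_used == 6 and r.n_classes == 2


def test_monomorphic_column_skipped(six_species_traits):
    col = ts.ColumnData(column=1, species=list("abcdef"), alleles=list("TTTTTT"))
    r = ts.fit_column_model(col, six_species_traits)
    assert r.p_value is None
    assert FLAG_MONOMORPHIC in r.flags


def test_missing_data_excludes_species(six_species_traits):
    # gap and N drop species a, d: groups become (11,12) vs (2,3)
    col = ts.ColumnData(
        column=1, species=list("abcdef"), alleles=[None, "T", "T", None, "C", "C"]
    )
    r = ts.fit_column_model(col, six_species_traits)
    assert r.n_used == 4
    y1, y2 = np.array([11.0, 12.0]), np.array([2.0, 3.0])
    ssb = 2 * (y1.mean() - 7.0) ** 2 + 2 * (y2.mean() - 7.0) ** 2
    ssw = ((y1 - y1.mean()) ** 2).sum() + ((y2 - y2.mean()) ** 2).sum()
    assert r.F == pytest.approx((ssb / 1) / (ssw / 2), rel=1e-12)


def test_collinear_with_habitat_skipped(six_species_traits):
    """Aquatic all T, terrestrial all C: the allele factor has no estimable
    df once habitat is in the model."""
    col = ts.ColumnData(column=1, species=list("abcdef"), alleles=list("TTTCCC"))
    r = ts.fit_column_model(col, six_species_traits, with_habitat=True)
    assert r.p_value is None
    assert FLAG_COLLINEAR in r.flags


def test_zero_residual_reports_p_zero():
    traits = make_traits(
        species=list("abcd"),
        log_mass=[5, 5, 2, 2],
        habitat=["aquatic"] * 2 + ["terrestrial"] * 2,
    )
    col = ts.ColumnData(column=1, species=list("abcd"), alleles=list("TTCC"))
    r = ts.fit_column_model(col, traits)
    assert r.p_value == 0.0
    assert FLAG_ZERO_RESIDUAL in r.flags


def test_singleton_class_flagged_but_tested(six_species_traits):
    col = ts.ColumnData(column=1, species=list("abcdef"), alleles=list("TCCCCC"))
    r = ts.fit_column_model(col, six_species_traits)
    assert FLAG_SINGLETON in r.flags
    assert r.p_value is not None


# ---------------------------------------------------------------------------
# cross-check against statsmodels OLS partial F (independent route)
# ---------------------------------------------------------------------------

def _statsmodels_partial_f(alleles, y, habitat, with_habitat):
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame({"y": y, "allele": alleles, "habitat": habitat}).dropna()
    reduced = "y ~ 1" if not with_habitat else "y ~ C(habitat)"
    full = reduced + " + C(allele)"
    m0 = smf.ols(reduced, data=df).fit()
    m1 = smf.ols(full, data=df).fit()
    tbl = anova_lm(m0, m1)
    return float(tbl["F"].iloc[1]), float(tbl["Pr(>F)"].iloc[1])


@pytest.mark.parametrize("with_habitat", [False, True])
def test_matches_statsmodels_on_random_columns(with_habitat):
    rng = np.random.default_rng(42)
    n = 18
    species = [f"s{i}" for i in range(n)]
    habitat = ["aquatic"] * 8 + ["terrestrial"] * 10
    for trial in range(20):
        y = rng.normal(5, 2, size=n)
        n_classes = rng.integers(2, 4)
        alleles = rng.choice(list("ACGT")[:n_classes], size=n)
        # ensure polymorphic and not habitat-collinear
        if len(set(alleles)) < 2:
            continue
        traits = make_traits(species, y, habitat)
        col = ts.ColumnData(column=1, species=species, alleles=list(alleles))
        r = ts.fit_column_model(col, traits, with_habitat=with_habitat)
        if r.p_value is None or r.p_value == 0.0:
            continue
        F_sm, p_sm = _statsmodels_partial_f(alleles, y, habitat, with_habitat)
        assert r.F == pytest.approx(F_sm, rel=1e-8)
        assert r.p_value == pytest.approx(p_sm, rel=1e-8)


def test_log_base_invariance(six_species_column, six_species_traits):
    """Rescaling log-mass (changing the logarithm base) leaves F unchanged."""
    r1 = ts.fit_column_model(six_species_column, six_species_traits)
    scaled = six_species_traits.copy()
    scaled["log_mass"] = scaled["log_mass"] / np.log(10)  # natural log -> log10
    r2 = ts.fit_column_model(six_species_column, scaled)
    assert r2.F == pytest.approx(r1.F, rel=1e-12)
    assert r2.p_value == pytest.approx(r1.p_value, rel=1e-10)


# ---------------------------------------------------------------------------
# whole-alignment scan
# ---------------------------------------------------------------------------

def test_scan_row_order_invariance(small_sim_config):
    cfg = small_sim_config
    traits = ts.simulate_trait_table(cfg)
    aln, _ = ts.simulate_alignment(traits, cfg)
    res1 = ts.scan_alignment(aln, traits, low_complexity=False)
    order = np.random.default_rng(0).permutation(aln.n_species)
    aln2 = ts.AlignmentMatrix(
        ids=[aln.ids[i] for i in order], chars=aln.chars[order]
    )
    res2 = ts.scan_alignment(aln2, traits, low_complexity=False)
    pd.testing.assert_frame_equal(res1, res2)


def test_scan_planted_column_is_top_hit(small_sim_config):
    cfg = small_sim_config
    traits = ts.simulate_trait_table(cfg)
    aln, truth = ts.simulate_alignment(traits, cfg)
    res = ts.scan_alignment(aln, traits, low_complexity=False)
    type1_cols = truth.planted_sites.loc[
        truth.planted_sites.pattern == "type1", "column"
    ]
    allele = res[res.model == "allele"].set_index("column")
    assert allele["p_value"].idxmin() in set(type1_cols)


def test_tested_set_independent_of_traits(small_sim_config):
    cfg = small_sim_config
    traits = ts.simulate_trait_table(cfg)
    aln, _ = ts.simulate_alignment(traits, cfg)
    eng = ScanEngine(aln, traits)
    shuffled = ts.permute_traits(traits, rng=np.random.default_rng(7))
    eng2 = ScanEngine(aln, shuffled)
    for wh in (False, True):
        assert np.array_equal(eng.tested_mask(wh), eng2.tested_mask(wh))
        assert np.array_equal(eng.cols, eng2.cols)


# ---------------------------------------------------------------------------
# permutation machinery and FDR
# ---------------------------------------------------------------------------

def test_stratified_permutation_preserves_group_multisets(six_species_traits):
    rng = np.random.default_rng(1)
    for _ in range(20):
        perm = ts.permute_traits(six_species_traits, stratified=True, rng=rng)
        for hab in ("aquatic", "terrestrial"):
            orig = sorted(
                six_species_traits.loc[
                    six_species_traits.habitat == hab, "log_mass"
                ]
            )
            new = sorted(perm.loc[perm.habitat == hab, "log_mass"])
            assert orig == new
        assert list(perm["habitat"]) == list(six_species_traits["habitat"])


def test_unstratified_two_species_identity_or_swap():
    traits = make_traits(["x", "y"], [1.0, 2.0], ["aquatic", "terrestrial"])
    rng = np.random.default_rng(2)
    seen = set()
    for _ in range(50):
        perm = ts.permute_traits(traits, stratified=False, rng=rng)
        seen.add(tuple(perm["log_mass"]))
    assert seen == {(1.0, 2.0), (2.0, 1.0)}


def test_fdr_from_counts_examples():
    assert ts.fdr_from_counts(10, [1.0]) == pytest.approx(0.1)
    assert ts.fdr_from_counts(5, [0, 1, 1, 2]) == pytest.approx(0.2)
    assert ts.fdr_from_counts(0, [0, 1]) is None


def test_estimate_fdr_determinism_and_undefined(small_sim_config):
    cfg = small_sim_config
    traits = ts.simulate_trait_table(cfg)
    aln, _ = ts.simulate_alignment(traits, cfg)
    kw = dict(thresholds=[1e-3, 1e-12], n_perm=30, n_runs=2, seed=99)
    e1 = ts.estimate_fdr(aln, traits, **kw)
    e2 = ts.estimate_fdr(aln, traits, **kw)
    assert e1[0].mean_hits_permuted == e2[0].mean_hits_permuted
    assert e1[0].per_run_mean_hits == e2[0].per_run_mean_hits
    assert e1[0].hits_original > 0 and e1[0].fdr is not None
    # at an absurdly small threshold nothing is hit: fdr undefined, not 0
    if e1[1].hits_original == 0:
        assert e1[1].fdr is None


def test_permuted_hits_counted_on_identical_tested_set(small_sim_config):
    """Monomorphic columns never contribute hits, permuted or not."""
    cfg = small_sim_config
    traits = ts.simulate_trait_table(cfg)
    aln, _ = ts.simulate_alignment(traits, cfg)
    eng = ScanEngine(aln, traits)
    n_tested = int(eng.tested_mask(False).sum())
    est = ts.estimate_fdr(aln, traits, [0.9999], n_perm=5, n_runs=1, seed=0)
    assert est[0].hits_original <= n_tested
    assert max(est[0].per_run_mean_hits) <= n_tested


def test_null_p_values_marginally_uniform():
    """Across many independent null datasets with iid-normal trait vectors,
    the F-test p-values are uniform: the pooled rate of p <= 0.01 falls
    within 4 binomial SEs of 0.01."""
    tot = hit = 0
    for seed in range(30):
        cfg = ts.default_config(seed=seed, n_columns=200)
        cfg.plants = []
        cfg.clade_assignments = {s: "all" for s in cfg.species}
        cfg.mass_log_means = {"all": 8.0}
        traits = ts.simulate_trait_table(cfg)
        aln, _ = ts.simulate_alignment(traits, cfg)
        eng = ScanEngine(aln, traits)
        F, _, _ = eng.stats(eng.y0, False)
        p = eng.p_values(F, False)
        m = eng.tested_mask(False)
        tot += int(m.sum())
        hit += int((p[m] <= 0.01).sum())
    se = np.sqrt(tot * 0.01 * 0.99)
    assert abs(hit - 0.01 * tot) <= 4 * se


# ---------------------------------------------------------------------------
# low-complexity flag
# ---------------------------------------------------------------------------

def test_homopolymer_window_flagged():
    aln = make_alignment(
        {"ref": "A" * 30 + "ACGTCCGTAGGATC" * 3, "o": "A" * 30 + "ACGTCCGTAGGATC" * 3}
    )
    assert ts.flag_low_complexity(aln, 5)
    assert not ts.flag_low_complexity(aln, 55)


def test_gap_rich_window_flagged():
    aln = make_alignment({"ref": "ACGTT" + "-" * 30, "o": "ACGTA" + "-" * 30})
    assert ts.flag_low_complexity(aln, 20)


def test_dinucleotide_repeat_flagged():
    ctx = "ACGGTCATCGTAAGCT"
    aln = make_alignment({"ref": ctx + "ATATATATATATATATATATAT" + ctx})
    assert ts.flag_low_complexity(aln, len(ctx) + 11)
    assert not ts.flag_low_complexity(aln, 8)


def test_synthetic_low_complexity_block_mostly_flagged():
    cfg = ts.default_config(seed=3, n_columns=700)
    cfg.low_complexity_blocks = [ts.LowComplexityBlock(start=200, length=200, unit="CA")]
    cfg.plants = []
    traits = ts.simulate_trait_table(cfg)
    aln, _ = ts.simulate_alignment(traits, cfg)
    from traitscan.scan import flag_low_complexity_all

    flags = flag_low_complexity_all(aln)
    block = flags[199:399]
    assert block.mean() >= 0.9


def test_scan_carries_low_complexity_flag(small_sim_config):
    cfg = small_sim_config
    cfg.low_complexity_blocks = [ts.LowComplexityBlock(start=50, length=40, unit="A")]
    traits = ts.simulate_trait_table(cfg)
    aln, _ = ts.simulate_alignment(traits, cfg)
    res = ts.scan_alignment(aln, traits)
    mid = res[(res.model == "allele") & (res.column == 70)]
    assert FLAG_LOW_COMPLEXITY in mid.iloc[0]["flags"]
    # advisory only: flagged columns are still present in the table
    assert len(res[res.model == "allele"]) == aln.n_columns
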