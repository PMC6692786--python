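"""Nested-model LRT mechanics, BH adjustment, co-localization handling,
control-status bookkeeping and the phospho screen."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from cnvbuffer.associations import (
    benjamini_hochberg,
    classify_control_status,
    deduplicate_colocalized,
    fit_nested_lrt,
    intersect_variants,
    screen_pairs,
    screen_phospho,
)
from cnvbuffer.cohort import site_to_gene


def _base(n, rng, k=3):
    return np.column_stack([np.ones(n)] + [rng.normal(size=n) for _ in range(k)])


# --- fit_nested_lrt --------------------------------------------------------


def test_orthogonal_added_predictor_gives_zero_lrt(rng):
    n = 64
    base = np.column_stack([np.ones(n), np.tile([1.0, -1.0], n // 2)])
    y = rng.normal(size=n)
    added = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)
    # orthogonalize added against base AND response exactly
    full = np.column_stack([base, y])
    coef, *_ = np.linalg.lstsq(full, added, rcond=None)
    added_perp = added - full @ coef
    beta7, lrt, p = fit_nested_lrt(y, base, added_perp)
    assert lrt == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0, abs=1e-6)


def test_lrt_nonnegative_for_random_inputs(rng):
    for _ in range(50):
        n = int(rng.integers(30, 120))
        base = _base(n, rng)
        y = rng.normal(size=n)
        added = rng.normal(size=n)
        _, lrt, p = fit_nested_lrt(y, base, added)
        assert lrt >= 0.0
        assert 0.0 < p <= 1.0


def test_lrt_equals_rss_ratio_from_independent_fit(rng):
    """Oracle: recompute both models with statsmodels OLS."""
    for seed in range(10):
        r = np.random.default_rng(seed)
        n = 200
        base = _base(n, r)
        added = r.normal(size=n)
        y = base @ r.normal(size=base.shape[1]) + 0.3 * added + r.normal(0, 0.8, n)
        beta7, lrt, p = fit_nested_lrt(y, base, added)
        rss0 = sm.OLS(y, base).fit().ssr
        full = np.column_stack([base, added])
        fit1 = sm.OLS(y, full).fit()
        expected = n * np.log(rss0 / fit1.ssr)
        assert lrt == pytest.approx(expected, abs=1e-8)
        assert beta7 == pytest.approx(fit1.params[-1], abs=1e-10)
        assert p == pytest.approx(stats.chi2.sf(expected, 1), abs=1e-10)


def test_beta_recovery_coverage():
    """y = 0.5*T + 0.3*G + noise: the fitted beta lands inside its 95% CI
    for the vast majority of replicates."""
    hits = 0
    n = 368
    n_rep = 200
    for seed in range(n_rep):
        r = np.random.default_rng(seed)
        t = r.normal(size=n)
        g = r.choice([-2, -1, 0, 1, 2], size=n, p=[0.05, 0.2, 0.5, 0.2, 0.05]).astype(float)
        y = 0.5 * t + 0.3 * g + r.normal(0, 0.5, n)
        base = np.column_stack([np.ones(n), t])
        full = np.column_stack([base, g])
        fit = sm.OLS(y, full).fit()
        lo, hi = fit.conf_int()[-1]
        hits += lo <= 0.3 <= hi
    assert hits / n_rep >= 0.93


def test_constant_and_collinear_added_predictor_rejected(rng):
    n = 50
    base = _base(n, rng)
    y = rng.normal(size=n)
    with pytest.raises(ValueError):
        fit_nested_lrt(y, base, np.ones(n))
    with pytest.raises(ValueError):
        fit_nested_lrt(y, base, base @ np.array([0.5, 1.0, -2.0, 0.25]))


def test_permutation_null_p_values_uniform():
    """Permuting the added predictor breaks any association: p-values from
    2,000 permutations are uniform."""
    r = np.random.default_rng(3)
    n = 150
    base = _base(n, r, k=2)
    y = base @ np.array([1.0, 0.5, -0.3]) + r.normal(0, 1, n)
    added = y + r.normal(0, 0.5, n)  # strongly associated before permutation
    ps = []
    for _ in range(2000):
        perm = r.permutation(added)
        _, _, p = fit_nested_lrt(y, base, perm)
        ps.append(p)
    ks = stats.kstest(ps, "uniform")
    assert ks.pvalue > 0.01


# --- Benjamini-Hochberg ----------------------------------------------------


def _bh_bruteforce(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


@pytest.mark.parametrize(
    "p,expected",
    [
        ([0.04], [0.04]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.001, 0.9], [0.002, 0.9]),
    ],
)
def test_bh_hand_examples(p, expected):
    np.testing.assert_allclose(benjamini_hochberg(p), expected, atol=1e-12)


def test_bh_matches_bruteforce_step_up(rng):
    for size in (1, 2, 10, 1000, 10_000):
        p = rng.uniform(1e-8, 1.0, size)
        np.testing.assert_allclose(
            benjamini_hochberg(p), _bh_bruteforce(p), atol=1e-12
        )


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        benjamini_hochberg([0.0, 0.5])


# --- screens ---------------------------------------------------------------


def test_screen_skips_missing_controller_and_homodimer(small_cohort_z):
    cohort, _ = small_cohort_z
    g = list(cohort.genes)
    res, skipped = screen_pairs(
        cohort, [("NOT_A_GENE", g[0]), (g[1], g[1]), (g[2], g[3])], variant="cnv"
    )
    assert len(res) == 1
    reasons = set(skipped["reason"])
    assert "controller_missing_from_cnv" in reasons
    assert "homodimer" in reasons


def test_screen_results_invariant_to_pair_order(small_cohort_z):
    cohort, truth = small_cohort_z
    pairs = [(x, y) for x, y, _ in truth.edges[:30]]
    res1, _ = screen_pairs(cohort, pairs, variant="cnv")
    res2, _ = screen_pairs(cohort, list(reversed(pairs)), variant="cnv")
    pd.testing.assert_frame_equal(res1, res2)


def test_screen_recovers_true_edges(small_cohort_z):
    cohort, truth = small_cohort_z
    true_pairs = [(x, y) for x, y, _ in truth.edges[:40]]
    rng = np.random.default_rng(1)
    genes = list(cohort.genes)
    null_pairs = [tuple(rng.choice(genes, 2, replace=False)) for _ in range(400)]
    res, _ = screen_pairs(cohort, true_pairs + null_pairs, variant="cnv")
    res = res.set_index(["controller", "controlled"])
    hit = [res.loc[p, "fdr"] < 0.05 for p in true_pairs if p in res.index]
    assert np.mean(hit) >= 0.8


def test_intersect_strict_threshold():
    cnv = pd.DataFrame(
        {"controller": ["a", "b"], "controlled": ["x", "y"], "fdr": [0.049, 0.05]}
    )
    mrna = pd.DataFrame(
        {"controller": ["a", "b"], "controlled": ["x", "y"], "fdr": [0.01, 0.01]}
    )
    assert intersect_variants(cnv, mrna) == {("a", "x")}


# --- co-localization deduplication ----------------------------------------


def _cnv_matrix(rng, columns, corr_pairs=()):
    n = 100
    data = {c: rng.choice([-1, 0, 1], n).astype(float) for c in columns}
    for a, b, noise in corr_pairs:
        data[b] = np.where(rng.random(n) < noise, rng.choice([-1, 0, 1], n), data[a])
    return pd.DataFrame(data)


def test_dedup_single_controller_per_chromosome_passthrough(rng):
    cnv_res = pd.DataFrame(
        {"controller": ["a", "b"], "controlled": ["y", "y"], "p": [0.01, 0.02]}
    )
    pairs = {("a", "y"), ("b", "y")}
    out = deduplicate_colocalized(
        pairs, cnv_res, cnv_res, {"a": "chr1", "b": "chr2"},
        _cnv_matrix(rng, ["a", "b"]),
    )
    assert out == pairs


def test_dedup_borda_tie_resolved_by_cnv_p(rng):
    # ranks: cnv list a=1,b=2; mrna list a=2,b=1 -> borda tie; smaller cnv p wins
    cnv_res = pd.DataFrame(
        {"controller": ["a", "b"], "controlled": ["y", "y"], "p": [0.001, 0.01]}
    )
    mrna_res = pd.DataFrame(
        {"controller": ["a", "b"], "controlled": ["y", "y"], "p": [0.02, 0.002]}
    )
    cnv = _cnv_matrix(rng, ["a", "b"], corr_pairs=[("a", "b", 0.05)])  # high corr
    assert np.corrcoef(cnv["a"], cnv["b"])[0, 1] > 0.5
    out = deduplicate_colocalized(
        {("a", "y"), ("b", "y")}, cnv_res, mrna_res,
        {"a": "chr3", "b": "chr3"}, cnv,
    )
    assert out == {("a", "y")}


def test_dedup_low_cnv_correlation_keeps_both(rng):
    cnv_res = pd.DataFrame(
        {"controller": ["a", "b"], "controlled": ["y", "y"], "p": [0.001, 0.01]}
    )
    cnv = _cnv_matrix(rng, ["a", "b"])  # independent draws
    assert abs(np.corrcoef(cnv["a"], cnv["b"])[0, 1]) < 0.5
    out = deduplicate_colocalized(
        {("a", "y"), ("b", "y")}, cnv_res, cnv_res,
        {"a": "chr3", "b": "chr3"}, cnv,
    )
    assert out == {("a", "y"), ("b", "y")}


def test_dedup_never_removes_a_controlled_gene(rng):
    genes = [f"g{i}" for i in range(12)]
    cnv = _cnv_matrix(
        rng, genes, corr_pairs=[(genes[i], genes[i + 1], 0.05) for i in (0, 4, 8)]
    )
    chrom = {g: f"chr{i % 3}" for i, g in enumerate(genes)}
    pairs = set()
    rows = []
    r = np.random.default_rng(5)
    for y in ("t1", "t2", "t3"):
        for x in r.choice(genes, 5, replace=False):
            pairs.add((x, y))
            rows.append((x, y, float(r.uniform(1e-5, 0.05))))
    res = pd.DataFrame(rows, columns=["controller", "controlled", "p"])
    out = deduplicate_colocalized(pairs, res, res, chrom, cnv)
    assert {y for _, y in out} == {y for _, y in pairs}
    assert out <= pairs


def test_dedup_missing_position_warns_and_passes_through(rng):
    res = pd.DataFrame(
        {"controller": ["a"], "controlled": ["y"], "p": [0.01]}
    )
    with pytest.warns(UserWarning):
        out = deduplicate_colocalized(
            {("a", "y")}, res, res, {}, _cnv_matrix(rng, ["a"])
        )
    assert out == {("a", "y")}


# --- control status --------------------------------------------------------


def test_control_status_simple_chain():
    table = classify_control_status({("A", "B"), ("B", "C")})
    status = dict(zip(table["gene"], table["status"]))
    assert status == {"A": "controlling", "B": "both", "C": "controlled"}


def test_control_status_matches_set_algebra(rng):
    genes = [f"g{i}" for i in range(30)]
    pairs = {
        (a, b)
        for a, b in zip(rng.choice(genes, 60), rng.choice(genes, 60))
        if a != b
    }
    table = classify_control_status(pairs)
    controlling = {x for x, _ in pairs}
    controlled = {y for _, y in pairs}
    for _, row in table.iterrows():
        g = row["gene"]
        expected = (
            "both"
            if g in controlling and g in controlled
            else "controlling" if g in controlling else "controlled"
        )
        assert row["status"] == expected
    assert set(table["gene"]) == controlling | controlled


def test_control_status_empty_raises():
    with pytest.raises(ValueError):
        classify_control_status(set())


# --- phospho screen --------------------------------------------------------


def test_phospho_site_collinear_with_parent_protein_skipped(small_cohort_z):
    from cnvbuffer.cohort import OmicsCohort

    cohort, truth = small_cohort_z
    # make one site an exact copy of its parent protein
    site = cohort.phospho.columns[0]
    parent = site_to_gene(site)
    phospho = cohort.phospho.copy()
    phospho[site] = cohort.protein[parent]
    cohort = OmicsCohort(
        cnv=cohort.cnv, mrna=cohort.mrna, protein=cohort.protein,
        phospho=phospho, covariates=cohort.covariates,
    )
    y = next(g for g in cohort.genes if g != parent)
    _, skipped = screen_phospho(cohort, [(parent, y)])
    assert any("collinear" in r for r in skipped["reason"])


def test_phospho_recovers_regulatory_sites(small_cohort_z):
    cohort, truth = small_cohort_z
    reg_pairs = [(site_to_gene(s), y) for s, y, _ in truth.phospho_regulators]
    res, _ = screen_phospho(cohort, reg_pairs)
    reg_sites = {(s, y) for s, y, _ in truth.phospho_regulators}
    hit = res[[(s, y) in reg_sites for s, y in zip(res["phosphosite"], res["controlled"])]]
    # small fixture (n=120, 30% phospho missingness): expect clear majority
    # recovery; the full-power check at n=368 lives in the acceptance suite
    assert (hit["fdr"] < 0.05).mean() >= 0.6


def test_phospho_final_set_requires_protein_significance(small_cohort_z):
    cohort, truth = small_cohort_z
    reg = truth.phospho_regulators[0]
    pair = (site_to_gene(reg[0]), reg[1])
    res_with, _ = screen_phospho(cohort, [pair], protein_significant={pair})
    res_without, _ = screen_phospho(cohort, [pair], protein_significant=set())
    assert res_with["in_final_set"].any()
    assert not res_without["in_final_set"].any()
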