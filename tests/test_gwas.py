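import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from heatgwas.gwas import (
    BayesCRegressor,
    ChainConfig,
    PosteriorSamples,
    build_design,
    merge_adjacent,
    run_bayes_c,
    run_bayes_cpi,
    summarize_heritability,
    window_variance,
)


def _toy_design_inputs(n=24):
    rng = np.random.default_rng(0)
    animals = [f"a{i}" for i in range(n)]
    meta = pd.DataFrame({
        "animal_id": animals,
        "sex": (["barrow", "gilt", "gilt", "barrow",
                 "gilt", "barrow", "barrow", "gilt"] * n)[:n],
        "sire_breed": (["Duroc", "Landrace", "Yorkshire"] * n)[:n],
        "farrowing_group": (["f1", "f2"] * n)[:n],
        "pen": (["p1", "p1", "p2", "p2"] * n)[:n],
    })
    traits = pd.DataFrame({"Normal-Alert": rng.normal(size=n)}, index=animals)
    dosages = pd.DataFrame(rng.integers(0, 3, (n, 10)).astype(float),
                           index=animals, columns=[f"m{j}" for j in range(10)])
    return traits, meta, dosages


def test_build_design_dummy_coding_arithmetic():
    traits, meta, dosages = _toy_design_inputs()
    design = build_design(traits, "Normal-Alert", meta, dosages)
    # intercept + (2-1) sex + (3-1) breeds + (4-1) contemporary groups = 7
    assert design.X.shape[1] == 7
    assert np.linalg.matrix_rank(design.X) == 7
    np.testing.assert_allclose(design.Z.mean(axis=0), 0.0, atol=1e-12)


def test_build_design_excludes_missing_trait():
    traits, meta, dosages = _toy_design_inputs()
    traits.loc["a3", "Normal-Alert"] = np.nan
    design = build_design(traits, "Normal-Alert", meta, dosages)
    assert "a3" not in design.animal_ids
    assert len(design.y) == len(traits) - 1


def test_build_design_warns_on_tiny_contemporary_cells():
    traits, meta, dosages = _toy_design_inputs()
    meta.loc[0, "pen"] = "p_solo"
    with pytest.warns(UserWarning, match="contemporary"):
        build_design(traits, "Normal-Alert", meta, dosages)


# ---------------------------------------------------------------- sampler basics


def _fit(Z, y, **kw):
    defaults = dict(pi=0.95, n_iter=600, burn_in=100, thin=5, random_state=2)
    defaults.update(kw)
    return BayesCRegressor(**defaults).fit(Z, y)


def test_pi_one_gives_null_model(rng):
    Z = rng.integers(0, 3, (40, 30)).astype(float)
    y = rng.normal(size=40)
    est = _fit(Z, y, pi=1.0)
    s = est.samples_
    assert np.all(s.effects == 0.0)
    assert np.all(s.genomic_var == 0.0)
    assert np.all(s.h2 == 0.0)


def test_chain_reproducible(rng):
    Z = rng.integers(0, 3, (40, 30)).astype(float)
    y = rng.normal(size=40)
    a = _fit(Z, y, random_state=7).samples_
    b = _fit(Z, y, random_state=7).samples_
    np.testing.assert_array_equal(a.h2, b.h2)
    np.testing.assert_array_equal(a.effects, b.effects)


def test_saved_state_count_and_h2_bounds(rng):
    Z = rng.integers(0, 3, (40, 30)).astype(float)
    y = rng.normal(size=40)
    s = _fit(Z, y, n_iter=1000, burn_in=100, thin=9).samples_
    assert s.n_saved == (1000 - 100) // 9
    assert np.all((s.h2 >= 0) & (s.h2 <= 1))


def test_genomic_variance_consistency_oracle(rng):
    """Saved genomic variance equals var over animals of Zu recomputed independently."""
    Z = rng.integers(0, 3, (50, 40)).astype(float)
    u_true = np.zeros(40); u_true[5] = 1.0
    y = Z @ u_true + rng.normal(size=50)
    s = _fit(Z, y, pi=0.9).samples_
    G = s.Z @ s.effects.T
    np.testing.assert_allclose(s.genomic_var, G.var(axis=0, ddof=1), rtol=1e-10)


def test_planted_marker_has_top_inclusion(rng):
    Z = rng.integers(0, 3, (200, 100)).astype(float)
    u_true = np.zeros(100); u_true[42] = 1.0
    g = (Z - Z.mean(0)) @ u_true
    e = rng.normal(0, g.std(), 200)   # marker explains ~50% of variance
    est = _fit(Z, g + e, pi=0.99, n_iter=2000, burn_in=500, thin=5)
    assert est.inclusion_freq_.argmax() == 42


def test_bayescpi_pi_identified_by_signal(rng):
    """With a sparse planted architecture, the sampled pi concentrates near
    1 - (number of causal markers) / m, and the per-iteration pi trace is
    emitted for convergence plotting.

    (On a pure-noise trait pi is only weakly identified: every marker's
    Bayes factor has expectation 1 under the null, so a uniform prior
    leaves the included-marker count as a near-driftless random walk.)"""
    n, m, n_qtl = 500, 1000, 10
    Z = rng.integers(0, 3, (n, m)).astype(float)
    qtl = rng.choice(m, n_qtl, replace=False)
    g = (Z - Z.mean(0))[:, qtl] @ rng.normal(0, 1.0, n_qtl)
    g *= np.sqrt(0.5 / g.var(ddof=1))
    y = g + rng.normal(0, np.sqrt(0.5), n)
    cfg = ChainConfig(n_iter=3000, burn_in=100, thin=1, pi="estimate", seed=4)
    animals = [f"a{i}" for i in range(n)]
    from heatgwas.gwas import GwasDesign
    design = GwasDesign(y=y, X=np.ones((n, 1)), Z=Z - Z.mean(0),
                        animal_ids=animals, marker_ids=[f"m{j}" for j in range(m)],
                        fixed_effect_names=["intercept"],
                        allele_freq=Z.mean(0) / 2.0)
    s = run_bayes_cpi(design, cfg)
    pi_hat = s.pi.mean()
    assert 1 - 3 * n_qtl / m <= pi_hat < 1.0   # ~ 1 - k_true/m
    assert len(s.pi_trace) >= 3000             # trace for convergence plots


def test_sklearn_estimator_contract(rng):
    est = BayesCRegressor(pi=0.9, n_iter=300, burn_in=50, thin=5)
    est2 = clone(est)
    assert est2.get_params()["pi"] == 0.9
    Z = rng.integers(0, 3, (30, 10)).astype(float)
    y = rng.normal(size=30)
    est.fit(Z, y)
    pred = est.predict(Z)
    assert pred.shape == (30,)
    assert np.isfinite(est.score(Z, y))


# ---------------------------------------------------------------- ridge oracle


def test_ridge_oracle_equivalence(rng):
    """pi=0 with fixed variances is Bayesian ridge; posterior means must match
    the closed-form solution within Monte-Carlo error.  Across 100
    coordinates the 3-MC-SE band is applied with an order-statistics
    allowance: a correct sampler's standardized deviations are ~N(0,1), so
    their RMS must be ~1 and only isolated coordinates may graze past 3."""
    n, m = 50, 100
    Z = rng.integers(0, 3, (n, m)).astype(float)
    u_true = rng.normal(0, 0.2, m)
    y = (Z - Z.mean(0)) @ u_true + rng.normal(0, 1.0, n)

    est = BayesCRegressor(pi=0.0, fix_variances=True,
                          prior_var_genetic=0.10, prior_var_residual=0.10,
                          n_iter=22_000, burn_in=2_000, thin=4, random_state=11)
    est.fit(Z, y)
    s = est.samples_

    Zc = Z - Z.mean(0)
    freq = Z.mean(0) / 2.0
    sum2pq = np.sum(2 * freq * (1 - freq))
    lam = 0.10 / (0.10 / sum2pq)      # sigma2_e / sigma2_u
    ridge = np.linalg.solve(Zc.T @ Zc + lam * np.eye(m), Zc.T @ (y - y.mean()))

    # batch-means Monte-Carlo SE per coordinate
    S = s.effects.shape[0]
    nb = 20
    batches = s.effects[: S - S % nb].reshape(nb, -1, m).mean(axis=1)
    se = batches.std(axis=0, ddof=1) / np.sqrt(nb)
    z = np.abs(s.effects.mean(axis=0) - ridge) / se
    assert np.sqrt((z**2).mean()) <= 1.3, f"RMS standardized deviation {np.sqrt((z**2).mean()):.2f}"
    assert (z <= 3).mean() >= 0.97, f"{(z > 3).sum()} of {m} coordinates beyond 3 MC-SE"
    assert z.max() <= 5.0, f"worst deviation {z.max():.2f} MC-SE"


# ---------------------------------------------------------------- summaries


def test_summarize_heritability_constant_chain():
    s = PosteriorSamples(*(np.zeros(120),) * 4, h2=np.full(120, 0.2),
                         effects=np.zeros((120, 1)), indicators=np.zeros((120, 1), dtype=np.uint8),
                         beta=np.zeros((120, 1)), pi_trace=np.zeros(120), marker_ids=["m"])
    mean, sd = summarize_heritability(s)
    assert mean == pytest.approx(0.2, abs=1e-12) and sd == pytest.approx(0.0, abs=1e-12)


def test_summarize_heritability_alternating_tail():
    h2 = np.concatenate([np.full(50, 0.2), np.tile([0.1, 0.3], 50)])
    s = PosteriorSamples(*(np.zeros(150),) * 4, h2=h2,
                         effects=np.zeros((150, 1)), indicators=np.zeros((150, 1), dtype=np.uint8),
                         beta=np.zeros((150, 1)), pi_trace=np.zeros(150), marker_ids=["m"])
    _, sd = summarize_heritability(s)
    assert sd == pytest.approx(np.std(np.tile([0.1, 0.3], 50), ddof=1), abs=1e-12)
    assert sd == pytest.approx(0.1005, abs=1e-3)


def test_summarize_heritability_requires_100_samples():
    s = PosteriorSamples(*(np.zeros(99),) * 4, h2=np.zeros(99),
                         effects=np.zeros((99, 1)), indicators=np.zeros((99, 1), dtype=np.uint8),
                         beta=np.zeros((99, 1)), pi_trace=np.zeros(99), marker_ids=["m"])
    with pytest.raises(ValueError):
        summarize_heritability(s)


# ---------------------------------------------------------------- windows


def _manual_samples(Z, effects_per_sample, marker_ids):
    S = effects_per_sample.shape[0]
    G = Z @ effects_per_sample.T
    gv = G.var(axis=0, ddof=1)
    return PosteriorSamples(
        sigma2_u=np.ones(S), sigma2_e=np.ones(S), pi=np.full(S, 0.9),
        genomic_var=gv, h2=gv / (gv + 1),
        effects=effects_per_sample,
        indicators=(effects_per_sample != 0).astype(np.uint8),
        beta=np.zeros((S, 1)), pi_trace=np.zeros(S),
        marker_ids=marker_ids, Z=Z,
    )


def test_window_variance_single_window_is_100(rng):
    Z = rng.integers(0, 3, (60, 5)).astype(float)
    Z -= Z.mean(0)
    U = rng.normal(size=(20, 5))
    mm = pd.DataFrame({"marker_id": [f"m{j}" for j in range(5)],
                       "chromosome": "1",
                       "position_bp": [100, 2000, 50_000, 600_000, 999_999]})
    s = _manual_samples(Z, U, list(mm["marker_id"]))
    w = window_variance(s, mm)
    assert len(w) == 1
    assert w.loc[0, "pct"] == pytest.approx(100.0)
    assert w.loc[0, "n_snps"] == 5


def test_window_variance_two_independent_markers_split_evenly(rng):
    # two equal-effect, equal-frequency, independent markers on different chromosomes
    Z = rng.binomial(2, 0.5, size=(4000, 2)).astype(float)
    Z -= Z.mean(0)
    U = np.ones((30, 2))
    mm = pd.DataFrame({"marker_id": ["m0", "m1"], "chromosome": ["1", "2"],
                       "position_bp": [500_000, 500_000]})
    w = window_variance(_manual_samples(Z, U, ["m0", "m1"]), mm)
    assert len(w) == 2
    np.testing.assert_allclose(w["pct"], 50.0, atol=5.0)


def test_window_share_sums_near_100_unlinked(rng):
    Z = rng.integers(0, 3, (150, 60)).astype(float)
    u_true = np.zeros(60); u_true[7] = 1.0; u_true[31] = -0.8
    y = (Z - Z.mean(0)) @ u_true + rng.normal(0, 0.5, 150)
    est = _fit(Z, y, pi=0.95, n_iter=1200, burn_in=200, thin=5)
    mm = pd.DataFrame({"marker_id": est.samples_.marker_ids,
                       "chromosome": np.repeat(["1", "2", "3"], 20),
                       "position_bp": np.tile(np.arange(20) * 500_000 + 1, 3)})
    w = window_variance(est.samples_, mm)
    assert 90.0 <= w["pct"].sum() <= 110.0


def test_merge_adjacent_rules():
    w = pd.DataFrame({
        "chromosome": ["1", "1", "1", "1", "2", "2", "3"],
        "window_mb": [2, 3, 7, 9, 4, 5, 1],
        "pct": [4.0, 6.0, 3.5, 2.0, 3.5, 5.0, 4.5],
        "n_snps": 1,
    })
    out = merge_adjacent(w, threshold=3.0)
    chr1 = out[out["chromosome"] == "1"]
    assert list(chr1["window_mb"]) == [3, 7, 9]      # 4%/6% adjacent -> keep 6%
    chr2 = out[out["chromosome"] == "2"]
    assert list(chr2["window_mb"]) == [5]            # 3.5/5 adjacent -> keep 5
    assert list(out[out["chromosome"] == "3"]["window_mb"]) == [1]


def test_merge_adjacent_run_of_three():
    w = pd.DataFrame({
        "chromosome": ["1"] * 3,
        "window_mb": [10, 11, 12],
        "pct": [3.5, 5.0, 4.0],
        "n_snps": 1,
    })
    out = merge_adjacent(w, threshold=3.0)
    assert list(out["window_mb"]) == [11]


def test_merge_adjacent_non_adjacent_unchanged():
    w = pd.DataFrame({
        "chromosome": ["1", "1"],
        "window_mb": [2, 9],
        "pct": [4.0, 6.0],
        "n_snps": 1,
    })
    out = merge_adjacent(w, threshold=3.0)
    assert len(out) == 2
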