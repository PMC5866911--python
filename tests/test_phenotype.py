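import datetime as dt

import numpy as np
import pandas as pd
import pytest

from heatgwas.phenotype import (
    MAX_PINGS_PER_DAY,
    category_profile,
    daily_counts,
    pairwise_traits,
    standardize_deviations,
    trait_correlations,
    trait_names,
)

D = dt.date


def _days(mapping):
    return pd.DataFrame({
        "date": list(mapping),
        "max_thi_c": 20.0,
        "category": list(mapping.values()),
    })


# ---------------------------------------------------------------- daily counts


def test_daily_counts_from_raw_detections():
    ts = [f"2015-07-01 08:00:{s:02d}" for s in (0, 20, 40)]
    det = pd.DataFrame({"animal_id": ["a1"] * 3, "timestamp": ts})
    out = daily_counts(det)
    assert len(out) == 1 and out.loc[0, "pings"] == 3


def test_daily_counts_deduplicates():
    det = pd.DataFrame({
        "animal_id": ["a1", "a1", "a1"],
        "timestamp": ["2015-07-01 08:00:00"] * 2 + ["2015-07-01 08:00:20"],
    })
    assert daily_counts(det).loc[0, "pings"] == 2


def test_daily_counts_roster_zero_fill():
    det = pd.DataFrame({"animal_id": ["a1"], "timestamp": ["2015-07-01 08:00:00"]})
    roster = pd.DataFrame({
        "animal_id": ["a1", "a1"],
        "date": [D(2015, 7, 1), D(2015, 7, 2)],
    })
    out = daily_counts(det, roster=roster).set_index("date")["pings"]
    assert out[D(2015, 7, 1)] == 1 and out[D(2015, 7, 2)] == 0


def test_daily_counts_full_day_at_feeder():
    """An animal detected continuously every 20 s for 24 h hits the 4320 cap."""
    ts = pd.date_range("2015-07-01", periods=MAX_PINGS_PER_DAY, freq="20s")
    det = pd.DataFrame({"animal_id": "a1", "timestamp": ts})
    out = daily_counts(det)
    assert out["pings"].tolist() == [MAX_PINGS_PER_DAY]


def test_daily_counts_passthrough_validates_cap():
    bad = pd.DataFrame({"animal_id": ["a1"], "date": [D(2015, 7, 1)],
                        "pings": [MAX_PINGS_PER_DAY + 1]})
    with pytest.raises(ValueError):
        daily_counts(bad)


# ---------------------------------------------------------------- category profile


def test_category_profile_means():
    pings = pd.DataFrame({
        "animal_id": ["a1", "a1", "a1"],
        "date": [D(2015, 7, 1), D(2015, 7, 2), D(2015, 7, 3)],
        "pings": [150, 100, 200],
    })
    days = _days({D(2015, 7, 1): "Alert", D(2015, 7, 2): "Normal", D(2015, 7, 3): "Normal"})
    prof = category_profile(pings, days).set_index("category")
    assert prof.loc["Alert", "mean_pings"] == 150 and prof.loc["Alert", "n_days"] == 1
    assert prof.loc["Normal", "mean_pings"] == 150 and prof.loc["Normal", "n_days"] == 2
    assert "Danger" not in prof.index


def test_category_profile_unknown_date_is_hard_error():
    pings = pd.DataFrame({"animal_id": ["a1"], "date": [D(2015, 8, 9)], "pings": [10]})
    days = _days({D(2015, 7, 1): "Normal"})
    with pytest.raises(ValueError, match="2015-08-09"):
        category_profile(pings, days)


# ---------------------------------------------------------------- standardization


def _profile(means, category="Normal"):
    return pd.DataFrame({
        "animal_id": list(means),
        "category": category,
        "mean_pings": list(means.values()),
        "n_days": 5,
    })


def _meta(animals, breed="Landrace", sex="gilt"):
    return pd.DataFrame({"animal_id": animals, "sire_breed": breed, "sex": sex})


def test_standardize_two_animals():
    prof = _profile({"a1": 100.0, "a2": 200.0})
    z = standardize_deviations(prof, _meta(["a1", "a2"])).set_index("animal_id")["z"]
    assert z["a1"] == pytest.approx(-0.70710678, abs=1e-6)
    assert z["a2"] == pytest.approx(0.70710678, abs=1e-6)


def test_standardize_mean0_sd1_per_category(small_sim):
    prof = category_profile(small_sim.pings, small_sim.day_classes)
    z = standardize_deviations(prof, small_sim.meta)
    for _, grp in z.groupby("category"):
        assert abs(grp["z"].mean()) < 1e-10
        assert abs(grp["z"].std(ddof=1) - 1.0) < 1e-10


def test_standardize_degenerate_category():
    prof = _profile({"a1": 100.0, "a2": 100.0, "a3": 100.0})
    with pytest.raises(ValueError, match="degenerate"):
        standardize_deviations(prof, _meta(["a1", "a2", "a3"]))


def test_standardize_location_invariance_within_breed_sex(small_sim):
    """Adding a constant to every animal of one breed-sex cell leaves z unchanged."""
    prof = category_profile(small_sim.pings, small_sim.day_classes)
    meta = small_sim.meta
    cell = (meta["sire_breed"] == "Duroc") & (meta["sex"] == "gilt")
    cell_ids = set(meta.loc[cell, "animal_id"])
    shifted = prof.copy()
    shifted.loc[shifted["animal_id"].isin(cell_ids), "mean_pings"] += 500.0
    z0 = standardize_deviations(prof, meta)
    z1 = standardize_deviations(shifted, meta)
    np.testing.assert_allclose(z0["z"], z1["z"], atol=1e-9)


# ---------------------------------------------------------------- pairwise traits


def test_pairwise_traits_cardinality_and_sign(toy_z):
    traits = pairwise_traits(toy_z)
    pair_cols = trait_names()
    assert len(pair_cols) == 6
    assert traits.loc["a1", pair_cols].notna().sum() == 6
    # z(Normal)=1.0, z(Alert)=-0.5 -> Normal-Alert = 1.5
    assert traits.loc["a1", "Normal-Alert"] == pytest.approx(1.5)


def test_pairwise_traits_excludes_single_category(toy_z):
    z = pd.concat([toy_z, pd.DataFrame([{"animal_id": "solo", "category": "Normal", "z": 0.3}])])
    traits = pairwise_traits(z)
    assert "solo" not in traits.index


def test_pairwise_traits_antisymmetry(toy_z):
    fwd = pairwise_traits(toy_z)
    rev = pairwise_traits(toy_z, categories=("Emergency", "Danger", "Alert", "Normal"))
    for a, b in [("Normal", "Alert"), ("Danger", "Emergency"), ("Alert", "Danger")]:
        np.testing.assert_allclose(
            fwd[f"{a}-{b}"].to_numpy(), -rev[f"{b}-{a}"].to_numpy(), atol=1e-12)


def test_pairwise_traits_partial_categories():
    z = pd.DataFrame({
        "animal_id": ["a1", "a1", "a2", "a2"],
        "category": ["Normal", "Alert", "Normal", "Danger"],
        "z": [1.0, 0.5, -1.0, 0.25],
    })
    traits = pairwise_traits(z)
    assert traits.loc["a1", "Normal-Alert"] == pytest.approx(0.5)
    assert np.isnan(traits.loc["a1", "Normal-Danger"])
    assert traits.loc["a2", "Normal-Danger"] == pytest.approx(-1.25)


# ---------------------------------------------------------------- correlations


def test_trait_correlations_against_numpy_oracle(rng):
    vals = rng.normal(size=(5, 6))
    traits = pd.DataFrame(vals, columns=trait_names(),
                          index=[f"a{i}" for i in range(5)])
    corr = trait_correlations(traits)
    oracle = np.corrcoef(vals, rowvar=False)
    np.testing.assert_allclose(corr.to_numpy(), oracle, atol=1e-12)
    np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T)
    np.testing.assert_allclose(np.diag(corr.to_numpy()), 1.0)


def test_trait_correlations_min_pairs():
    traits = pd.DataFrame({
        "Normal-Alert": [1.0, 2.0, np.nan, np.nan],
        "Normal-Danger": [np.nan, 2.0, 1.0, 3.0],
    }, index=list("abcd"))
    traits = traits.reindex(columns=trait_names())
    corr = trait_correlations(traits)
    assert np.isnan(corr.loc["Normal-Alert", "Normal-Danger"])  # only 1 complete pair


def test_roundtrip_no_genetics_traits_uncorrelated_with_truth():
    """With var_genetic = 0, derived traits carry no genetic signal."""
    from heatgwas.simulate import SimConfig, simulate_all

    cfg = SimConfig(n_animals=240, n_snps=200, n_qtl=5, var_genetic=0.0, seed=21)
    sim = simulate_all(cfg)
    assert sim.truth.realized_h2 == 0.0
    assert np.all(sim.truth.genetic_values.to_numpy() == 0.0)
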