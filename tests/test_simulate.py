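import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from polypharm import (
    GlmmSpec,
    default_config,
    expected_summary,
    fit_random_intercept_logit,
    simulate_population,
)
from polypharm.rates import AGE_BANDS, assign_age_band
from polypharm.simulate import SimConfig, write_population


def flat_config(baselines, seed=0, **kw):
    """Config with no covariate effects and no random effects unless
    overridden, so every patient shares one probability vector."""
    defaults = dict(
        seed=seed,
        n_practices=20,
        patients_per_practice_mean=100.0,
        age_band_dist={b: 1 / 7 for b in AGE_BANDS},
        care_home_prob_by_band={b: 0.0 for b in AGE_BANDS},
        class_baselines=baselines,
        age_offsets={b: 0.0 for b in AGE_BANDS},
        simd_slope=0.0,
        sex_offset=0.0,
        care_home_offset=0.0,
        frailty_sd=0.0,
        practice_sd=0.0,
        cooccurrence_boosts={},
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def test_same_seed_reproduces_byte_identical_files(formulary, tmp_path):
    cfg = default_config(formulary, "2010", seed=5)
    cfg.n_practices, cfg.patients_per_practice_mean = 5, 40.0
    out = []
    for sub in ("a", "b"):
        pats, recs, _ = simulate_population(cfg, formulary)
        p, r = write_population(pats, recs, tmp_path / sub)
        out.append((p.read_bytes(), r.read_bytes()))
    assert out[0] == out[1]


def test_all_zero_prevalence_gives_no_records(formulary):
    cfg = flat_config({c: -30.0 for c in formulary.class_codes})
    pats, recs, _ = simulate_population(cfg, formulary)
    assert len(recs) == 0
    assert len(pats) > 0


def test_single_class_binomial_rate(formulary):
    """One class at p = 0.3 with no effects: the dispensed fraction must
    fall within 3 binomial SEs of 0.3."""
    p = 0.3
    cfg = flat_config({"2.4": float(logit(p))},
                      n_practices=50, patients_per_practice_mean=200.0, seed=21)
    pats, recs, _ = simulate_population(cfg, formulary)
    n = len(pats)
    frac = recs["patient_id"].nunique() / n
    se = np.sqrt(p * (1 - p) / n)
    assert abs(frac - p) < 3 * se


def test_invalid_configs_rejected_before_generation(formulary):
    bad = flat_config({"2.4": -1.0})
    bad.simd_dist = (0.5, 0.5, 0.5, 0.0, 0.0)
    with pytest.raises(ValueError, match="simd_dist"):
        simulate_population(bad, formulary)
    bad2 = flat_config({"2.4": -1.0})
    bad2.frailty_sd = -1.0
    with pytest.raises(ValueError, match="SD"):
        simulate_population(bad2, formulary)
    bad3 = flat_config({"2.4": -1.0})
    bad3.care_home_prob_by_band = {b: 1.5 for b in AGE_BANDS}
    with pytest.raises(ValueError, match="care_home"):
        simulate_population(bad3, formulary)


def poisson_binomial(probs):
    """Independent-class count distribution by direct convolution."""
    dist = np.array([1.0])
    for p in probs:
        dist = np.convolve(dist, [1 - p, p])
    return dist


def test_expected_summary_matches_poisson_binomial_enumeration(formulary):
    """Independent classes, no random effects: the exact path must equal
    the Poisson-binomial distribution computed by convolution."""
    codes = ["1.1", "2.4", "2.9.1", "4.7.1", "5.1.1", "10.1.1"]
    baselines = {c: v for c, v in zip(codes, [-2.0, -1.0, -0.5, -1.5, -2.5, -0.8])}
    cfg = flat_config(baselines)
    s = expected_summary(cfg, formulary)
    assert s["method"] == "exact"
    probs = expit(np.array(list(baselines.values())))
    dist = poisson_binomial(probs)
    assert s["band_fractions"]["0"] == pytest.approx(dist[0], abs=1e-12)
    assert s["band_fractions"]["1-4"] == pytest.approx(dist[1:5].sum(), abs=1e-12)
    assert s["band_fractions"]["5-9"] == pytest.approx(dist[5:].sum(), abs=1e-12)
    assert s["mean_n_classes"] == pytest.approx(probs.sum(), abs=1e-12)


def test_excluded_classes_never_enter_band_fractions(formulary):
    """A device class can be dispensed but must not move the count."""
    cfg_with = flat_config({"2.4": 0.0, "13.13": 5.0})  # dressings ~ certain
    cfg_without = flat_config({"2.4": 0.0, "13.13": -30.0})
    a = expected_summary(cfg_with, formulary)
    b = expected_summary(cfg_without, formulary)
    assert a["band_fractions"] == pytest.approx(b["band_fractions"], abs=1e-12)


def test_raising_one_class_prevalence_raises_heavy_polypharmacy(formulary):
    codes = ["1.1", "2.4", "2.9.1", "4.7.1", "5.1.1", "10.1.1"]
    lo = flat_config({c: -0.4 for c in codes})
    hi = flat_config({c: -0.4 for c in codes})
    hi.class_baselines = dict(hi.class_baselines)
    hi.class_baselines["2.4"] = 1.5
    p5_lo = 1 - expected_summary(lo, formulary)["band_fractions"]["0"] - \
        expected_summary(lo, formulary)["band_fractions"]["1-4"]
    p5_hi = 1 - expected_summary(hi, formulary)["band_fractions"]["0"] - \
        expected_summary(hi, formulary)["band_fractions"]["1-4"]
    assert p5_hi >= p5_lo


def test_cooccurrence_boost_increases_ddi_prevalence(formulary):
    """Three-class toy, exact enumeration: boosting a listed pair's
    co-occurrence raises P(both dispensed)."""
    codes = {"2.8.2": -1.0, "2.9.1": -1.0, "10.1.1": -1.0}
    pair = [("2.8.2", "2.9.1")]
    base = flat_config(dict(codes))
    boosted = flat_config(dict(codes), cooccurrence_boosts={"2.8.2|2.9.1": 1.5})
    s0 = expected_summary(base, formulary, kb_pairs=pair)
    s1 = expected_summary(boosted, formulary, kb_pairs=pair)
    assert s0["method"] == s1["method"] == "exact"
    # independence benchmark for the unboosted case
    assert s0["p_ddi"] == pytest.approx(expit(-1.0) ** 2, abs=1e-12)
    assert s1["p_ddi"] > s0["p_ddi"]


def test_age_gradient_monotone_in_simulated_population(formulary):
    """With increasing age offsets the mean distinct-class count rises
    strictly across age bands (the age-graded usage pattern the
    generator is built to emulate)."""
    cfg = default_config(formulary, "2010", seed=13)
    cfg.n_practices, cfg.patients_per_practice_mean = 40, 250.0
    pats, recs, _ = simulate_population(cfg, formulary)
    from polypharm import build_exposure
    prof = build_exposure(recs, formulary, pats["patient_id"])
    means = (
        prof["n_classes"]
        .groupby(pats["age"].map(assign_age_band).to_numpy())
        .mean()
        .reindex(list(AGE_BANDS))
    )
    assert means.is_monotonic_increasing
    assert means.iloc[-1] > 2 * means.iloc[0]


def test_empty_model_recovers_practice_intercept_sd(formulary):
    """Simulate a single-class outcome with a known practice-level SD
    and no frailty; the empty-model GLMM estimate must fall within 2 SEs
    of the configured value (links the generator to the estimator)."""
    true_sd = 0.35
    cfg = flat_config({"2.4": float(logit(0.3))},
                      n_practices=100, patients_per_practice_mean=100.0,
                      practice_sd=true_sd, seed=8)
    pats, recs, _ = simulate_population(cfg, formulary)
    dispensed = pats["patient_id"].isin(set(recs["patient_id"]))
    data = pd.DataFrame({
        "y": dispensed.astype(int).to_numpy(),
        "practice_id": pats["practice_id"].to_numpy(),
    })
    fit = fit_random_intercept_logit(data, GlmmSpec("y", []))
    assert fit.converged
    assert abs(fit.sigma_u - true_sd) < 2 * fit.sigma_u_se
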