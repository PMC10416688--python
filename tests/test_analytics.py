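"""Cohort filters, rate-table invariants, and the logistic model."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from bccqa.analytics import (
    ConversionRefusedError,
    EmptyCohortError,
    SeparationError,
    build_cohort,
    cohort_frame,
    compute_rate_table,
    detect_separation,
    fit_margin_model,
    logodds_to_rate,
    model_table,
    rates_by_specialty,
    simulate_margin_cohort,
)
from bccqa.extraction import LesionExtraction


def extraction(
    rid,
    peripheral=2.0,
    deep=2.0,
    is_bcc=True,
    biopsy=False,
    specialty="plastic surgery",
    subtype="nodular",
    site="back",
    size=5.0,
):
    rec = LesionExtraction(report_id=rid, patient_id=f"pt-{rid}")
    rec.is_bcc = is_bcc
    rec.is_diagnostic_biopsy = biopsy
    rec.subtype = subtype
    rec.site = site
    rec.size_mm = size
    rec.specialty = specialty
    rec.perineural_invasion = False
    rec.lymphovascular_invasion = False
    rec.recurrent = False
    rec.peripheral_margin_mm = peripheral
    rec.peripheral_involved = None if peripheral is None else peripheral == 0
    rec.deep_margin_mm = deep
    rec.deep_involved = None if deep is None else deep == 0
    return rec


def random_extractions(rng, n):
    recs = []
    for i in range(n):
        margins = []
        for _ in range(2):
            u = rng.random()
            margins.append(0.0 if u < 0.2 else (0.5 if u < 0.3 else 2.0))
        recs.append(
            extraction(
                f"R{i}",
                peripheral=margins[0],
                deep=margins[1],
                specialty=rng.choice(["plastic surgery", "dermatology"]),
                subtype=rng.choice(["nodular", "infiltrative"]),
                site=rng.choice(["back", "nose"]),
            )
        )
    return recs


# ---------------------------------------------------------------------------
# cohort


def test_exclusion_counting():
    recs = (
        [extraction(f"A{i}") for i in range(6)]
        + [extraction(f"B{i}", biopsy=True) for i in range(3)]
        + [extraction("C0", is_bcc=False, subtype=None)]
    )
    cohort, log = build_cohort(recs)
    assert len(cohort) == 6
    assert log == {"diagnostic_biopsy": 3, "non_bcc": 1}


def test_all_biopsies_is_empty_cohort_error():
    with pytest.raises(EmptyCohortError):
        build_cohort([extraction(f"R{i}", biopsy=True) for i in range(4)])


def test_exclusions_match_generator_truth(noisy_extractions):
    recs, truths = noisy_extractions
    _, log = build_cohort(recs)
    assert log["diagnostic_biopsy"] == sum(
        t.is_bcc and t.is_diagnostic_biopsy for t in truths
    )
    assert log["non_bcc"] == sum(not t.is_bcc for t in truths)


# ---------------------------------------------------------------------------
# rate table


def brute_force_table(cohort):
    tally = {
        risk: dict(peripheral=0, deep=0, overall=0) for risk in ("low", "high", "total")
    }
    n = 0
    for r in cohort:
        if not r.assessable:
            continue
        n += 1
        p = r.peripheral.status == "involved"
        d = r.deep.status == "involved"
        for key in (r.risk, "total"):
            tally[key]["peripheral"] += p
            tally[key]["deep"] += d
            tally[key]["overall"] += p or d
    return n, tally


def test_rate_table_equals_brute_force_tally_on_random_cohorts():
    rng = np.random.default_rng(11)
    for _ in range(50):
        cohort, _ = build_cohort(random_extractions(rng, int(rng.integers(5, 50))))
        table = compute_rate_table(cohort)
        n, tally = brute_force_table(cohort)
        assert table.denominator == n
        assert table.counts == tally


def test_rate_table_invariants_and_percentages():
    rng = np.random.default_rng(12)
    cohort, _ = build_cohort(random_extractions(rng, 500))
    table = compute_rate_table(cohort)
    table.validate()
    for margin in ("peripheral", "deep", "overall"):
        assert table.percentage("low", margin) + table.percentage(
            "high", margin
        ) == pytest.approx(table.percentage("total", margin), abs=1e-12)
    assert (
        max(table.percentage("total", "peripheral"), table.percentage("total", "deep"))
        <= table.percentage("total", "overall")
        <= table.percentage("total", "peripheral") + table.percentage("total", "deep")
    )


def test_no_involvement_gives_zero_rates():
    cohort, _ = build_cohort([extraction(f"R{i}") for i in range(20)])
    table = compute_rate_table(cohort)
    assert table.percentage("total", "overall") == 0.0


def test_unassessable_records_leave_denominator():
    recs = [extraction(f"R{i}") for i in range(5)]
    recs.append(extraction("RU", peripheral=None, deep=None))  # unknown margins
    cohort, _ = build_cohort(recs)
    table = compute_rate_table(cohort)
    assert table.denominator == 5
    assert table.n_unassessable == 1


def test_single_specialty_rate_equals_total():
    cohort, _ = build_cohort(
        [extraction(f"R{i}", peripheral=0.0 if i < 2 else 2.0) for i in range(10)]
    )
    df = rates_by_specialty(cohort)
    assert len(df) == 1
    assert df.loc[0, "rate_pct"] == pytest.approx(
        compute_rate_table(cohort).percentage("total", "overall")
    )


def test_zero_involvement_specialty_reports_zero():
    recs = [extraction(f"R{i}", specialty="general surgery") for i in range(10)]
    recs += [extraction(f"S{i}", specialty="plastic surgery", peripheral=0.0) for i in range(5)]
    df = rates_by_specialty(build_cohort(recs)[0]).set_index("specialty")
    assert df.loc["general surgery", "rate_pct"] == 0.0


# ---------------------------------------------------------------------------
# logistic model


def nll_oracle(df, reference):
    """Direct numerical MLE as an independent check on the GLM fit."""
    from bccqa.analytics import _design

    X, y, terms = _design(df, reference)

    def nll(beta):
        eta = X @ beta
        return float(np.sum(np.logaddexp(0, eta)) - y @ eta)

    res = minimize(nll, np.zeros(X.shape[1]), method="BFGS", options={"gtol": 1e-10})
    return dict(zip(terms, res.x))


def test_fit_matches_direct_likelihood_optimisation():
    rng = np.random.default_rng(21)
    df = simulate_margin_cohort(
        4000,
        intercept=2.5,
        specialty_logodds={"dermatology": -0.7},
        risk_logodds=-0.5,
        specialty_weights={"plastic surgery": 0.6, "dermatology": 0.4},
        high_risk_prevalence=0.4,
        rng=rng,
    )
    fit = fit_margin_model(df)
    oracle = nll_oracle(df, "plastic surgery")
    for term, value in oracle.items():
        assert fit.params.loc[term, "coef"] == pytest.approx(value, abs=1e-5)


def test_identical_outcome_frequencies_give_or_one():
    rows = []
    for s in ("plastic surgery", "dermatology"):
        rows += [{"specialty": s, "high_risk": False, "uninvolved": v} for v in
                 [True] * 90 + [False] * 10]
    fit = fit_margin_model(pd.DataFrame(rows))
    assert fit.params.loc["specialty:dermatology", "odds_ratio"] == pytest.approx(1.0, abs=1e-8)


def test_intercept_only_reproduces_observed_frequency():
    rng = np.random.default_rng(22)
    df = pd.DataFrame(
        {
            "specialty": ["plastic surgery"] * 1000,
            "high_risk": [False] * 1000,
            "uninvolved": rng.random(1000) < 0.9,
        }
    )
    import statsmodels.api as sm

    y = df["uninvolved"].to_numpy(float)
    res = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial()).fit()
    assert abs(expit(res.params[0]) - y.mean()) < 1e-8


def test_zero_variation_specialty_is_flagged_separated():
    rng = np.random.default_rng(23)
    df = simulate_margin_cohort(
        2000,
        intercept=2.0,
        specialty_logodds={"dermatology": -0.5},
        risk_logodds=-0.3,
        specialty_weights={
            "plastic surgery": 0.5,
            "dermatology": 0.4,
            "general surgery": 0.1,
        },
        high_risk_prevalence=0.4,
        rng=rng,
    )
    df.loc[df["specialty"] == "general surgery", "uninvolved"] = True
    assert detect_separation(df) == {"general surgery": "all_uninvolved"}
    fit = fit_margin_model(df)
    assert fit.separated == {"general surgery": "all_uninvolved"}
    assert "specialty:general surgery" not in fit.params.index
    with pytest.raises(ConversionRefusedError):
        logodds_to_rate(fit, "general surgery")
    row = model_table(fit).set_index("specialty").loc["general surgery"]
    assert row["separated"] and np.isnan(row["odds_ratio"])


def test_separated_reference_is_an_error():
    df = pd.DataFrame(
        {
            "specialty": ["plastic surgery"] * 50 + ["dermatology"] * 50,
            "high_risk": [False] * 100,
            "uninvolved": [True] * 50 + [True] * 25 + [False] * 25,
        }
    )
    with pytest.raises(SeparationError):
        fit_margin_model(df, "plastic surgery")


def test_firth_fit_gives_finite_estimates_under_separation():
    rng = np.random.default_rng(24)
    df = simulate_margin_cohort(
        1000,
        intercept=2.0,
        specialty_logodds={"dermatology": -0.5, "general surgery": 0.2},
        risk_logodds=-0.3,
        specialty_weights={
            "plastic surgery": 0.5,
            "dermatology": 0.4,
            "general surgery": 0.1,
        },
        high_risk_prevalence=0.4,
        rng=rng,
    )
    df.loc[df["specialty"] == "general surgery", "uninvolved"] = True
    fit = fit_margin_model(df, method="firth")
    coef = fit.params.loc["specialty:general surgery", "coef"]
    assert np.isfinite(coef) and np.isfinite(fit.params.loc["specialty:general surgery", "se"])


def test_logodds_to_rate_identities():
    rng = np.random.default_rng(25)
    df = simulate_margin_cohort(
        30000,
        intercept=2.2,
        specialty_logodds={"general practice": -1.4},
        risk_logodds=-0.6,
        specialty_weights={"plastic surgery": 0.6, "general practice": 0.4},
        high_risk_prevalence=0.4,
        rng=rng,
    )
    fit = fit_margin_model(df)
    high = logodds_to_rate(fit, "general practice", "high")
    low = logodds_to_rate(fit, "general practice", "low")
    mixed = logodds_to_rate(fit, "general practice")
    w = fit.high_risk_prevalence
    assert mixed == pytest.approx(w * high + (1 - w) * low)
    # within 3 Monte-Carlo SEs of the generating stratum probability
    p_true = 1 - expit(2.2 - 1.4 - 0.6)
    n_stratum = int((df["specialty"] == "general practice").sum() * 0.4)
    se = 100 * np.sqrt(p_true * (1 - p_true) / n_stratum)
    assert abs(high - 100 * p_true) <= 3 * se


def test_non_significant_conversion_refused():
    rng = np.random.default_rng(26)
    df = simulate_margin_cohort(
        800,
        intercept=2.0,
        specialty_logodds={},  # no true effect
        risk_logodds=-0.3,
        specialty_weights={"plastic surgery": 0.5, "dermatology": 0.5},
        high_risk_prevalence=0.4,
        rng=rng,
    )
    fit = fit_margin_model(df)
    if fit.params.loc["specialty:dermatology", "p_value"] >= 0.05:
        with pytest.raises(ConversionRefusedError):
            logodds_to_rate(fit, "dermatology")


def test_parameter_recovery_bias_shrinks_with_n():
    truth = {"dermatology": -0.6}
    biases = []
    for n in (2000, 20000):
        rng = np.random.default_rng(27)
        errs = []
        for _ in range(20):
            df = simulate_margin_cohort(
                n,
                intercept=2.5,
                specialty_logodds=truth,
                risk_logodds=-0.5,
                specialty_weights={"plastic surgery": 0.6, "dermatology": 0.4},
                high_risk_prevalence=0.4,
                rng=rng,
            )
            fit = fit_margin_model(df)
            errs.append(fit.params.loc["specialty:dermatology", "coef"] - (-0.6))
        biases.append(abs(np.mean(errs)))
    assert biases[1] <= biases[0] + 0.02
    assert biases[1] < 0.05
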