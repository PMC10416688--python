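"""Cohort construction, stratified incomplete-excision rates, and the
specialty logistic model.

The analysable cohort is every histologically confirmed BCC treated by
excision: diagnostic biopsies and non-BCC reports are excluded (with a
per-reason exclusion log); primary, recurrent and re-excision lesions
are analysed together.  A lesion is an *incomplete excision* when either
the peripheral or the deep margin is involved (0 mm); close margins
(under 1 mm but not involved) do not count as incomplete.

Rate tables are stratified by risk (low/high) and margin (peripheral/
deep), with every percentage expressed against the whole assessable
cohort so that the low-risk and high-risk rows sum exactly to the total
row.  Lesions with both margins involved appear in both margin columns
but once in the overall column, which is why the overall rate sits
between max(peripheral, deep) and their sum.

The post-hoc model is a binomial GLM with logit link: outcome =
uninvolved margin, predictors = specialty dummies (reference specialty
omitted) plus a binary high-risk covariate.  Specialties with zero
outcome variation are *separated* — their ML coefficient is unbounded —
and are flagged and excluded from the fit rather than reported with a
meaningless odds ratio; a Jeffreys-penalised (Firth-type) fit is
available for those who want finite estimates anyway.  Fitted log odds
convert to adjusted incomplete-excision percentages via the inverse
logit, either at a fixed risk level or weighted by the cohort's observed
risk mix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm

from .classification import (
    HIGH,
    LOW,
    MarginStatus,
    RiskRuleTable,
    classify_margin,
    classify_risk,
    default_risk_rules,
)
from .extraction import LesionExtraction


class EmptyCohortError(ValueError):
    """All records were excluded; there is nothing to analyse."""


class SeparationError(RuntimeError):
    """A requested quantity is undefined because of separation."""


class ConversionRefusedError(RuntimeError):
    """Log-odds-to-rate conversion refused (non-significant or separated)."""


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortRecord:
    extraction: LesionExtraction
    peripheral: MarginStatus
    deep: MarginStatus
    risk: str  # low | high | unknown

    @property
    def incomplete(self) -> bool:
        return self.peripheral.status == "involved" or self.deep.status == "involved"

    @property
    def assessable(self) -> bool:
        return (
            self.risk in (LOW, HIGH)
            and self.peripheral.status != "unknown"
            and self.deep.status != "unknown"
        )

    @property
    def specialty(self) -> str:
        # unknown specialty pools into "other" for specialty-level analytics
        return self.extraction.specialty or "other"


def margin_status_from_extraction(
    distance_mm: float | None,
    involved,
    upper_bound_mm: float | None = None,
    inexact: bool = False,
) -> MarginStatus:
    """Bridge an extracted (distance, tri-state, bound) triple to a status."""
    if distance_mm is not None:
        return classify_margin(distance_mm, inexact=inexact)
    if upper_bound_mm is not None and upper_bound_mm <= 1.0 and involved is False:
        return classify_margin(wording="close")
    if involved is True:
        return classify_margin(wording="involved", inexact=inexact)
    if involved is False:
        return classify_margin(wording="clear", inexact=inexact)
    return MarginStatus("unknown")


def build_cohort(
    records: list[LesionExtraction],
    rules: RiskRuleTable | None = None,
) -> tuple[list[CohortRecord], dict[str, int]]:
    """Filter to the analysable cohort and classify every retained record.

    Returns (cohort, exclusion_log); the log counts exclusions by reason
    ("diagnostic_biopsy", "non_bcc").  Raises :class:`EmptyCohortError`
    when nothing survives.
    """
    rules = rules or default_risk_rules()
    cohort: list[CohortRecord] = []
    log = {"diagnostic_biopsy": 0, "non_bcc": 0}
    for rec in records:
        if not rec.is_bcc:
            log["non_bcc"] += 1
            continue
        if rec.is_diagnostic_biopsy:
            log["diagnostic_biopsy"] += 1
            continue
        cohort.append(
            CohortRecord(
                extraction=rec,
                peripheral=margin_status_from_extraction(
                    rec.peripheral_margin_mm,
                    rec.peripheral_involved,
                    rec.peripheral_upper_bound_mm,
                    "peripheral_margin_mm" in rec.inexact_fields,
                ),
                deep=margin_status_from_extraction(
                    rec.deep_margin_mm,
                    rec.deep_involved,
                    rec.deep_upper_bound_mm,
                    "deep_margin_mm" in rec.inexact_fields,
                ),
                risk=classify_risk(rec, rules),
            )
        )
    if not cohort:
        raise EmptyCohortError(
            f"no analysable records after exclusions {log}"
        )
    return cohort, log


# ---------------------------------------------------------------------------
# stratified rates


@dataclass
class StratifiedRateTable:
    """Incomplete-excision counts and whole-cohort percentages by
    risk level (rows low/high/total) and margin (peripheral/deep/overall)."""

    denominator: int
    counts: dict[str, dict[str, int]]  # risk -> {peripheral, deep, overall}
    n_unassessable: int = 0

    def percentage(self, risk: str, margin: str) -> float:
        return 100.0 * self.counts[risk][margin] / self.denominator

    def to_dataframe(self, decimals: int | None = 1) -> pd.DataFrame:
        rows = []
        for risk in (LOW, HIGH, "total"):
            row = {"risk": risk}
            for margin in ("peripheral", "deep", "overall"):
                pct = self.percentage(risk, margin)
                row[f"{margin}_pct"] = round(pct, decimals) if decimals is not None else pct
                row[f"{margin}_n"] = self.counts[risk][margin]
            rows.append(row)
        df = pd.DataFrame(rows)
        df["denominator"] = self.denominator
        return df

    def validate(self) -> None:
        for margin in ("peripheral", "deep", "overall"):
            assert (
                self.counts[LOW][margin] + self.counts[HIGH][margin]
                == self.counts["total"][margin]
            ), "risk strata must sum to the total per column"
        for risk in (LOW, HIGH, "total"):
            c = self.counts[risk]
            assert max(c["peripheral"], c["deep"]) <= c["overall"] <= (
                c["peripheral"] + c["deep"]
            ), "overall must bracket the margin columns"


def compute_rate_table(cohort: list[CohortRecord]) -> StratifiedRateTable:
    """Tally involvement per risk stratum against the whole-cohort denominator.

    Records with unknown risk or an unknown margin status are excluded
    from the denominator and reported in ``n_unassessable``.
    """
    assessable = [r for r in cohort if r.assessable]
    if not assessable:
        raise EmptyCohortError("no assessable records (all unknown risk or margins)")
    counts = {
        risk: {"peripheral": 0, "deep": 0, "overall": 0}
        for risk in (LOW, HIGH, "total")
    }
    for r in assessable:
        p_inv = r.peripheral.status == "involved"
        d_inv = r.deep.status == "involved"
        for risk in (r.risk, "total"):
            counts[risk]["peripheral"] += p_inv
            counts[risk]["deep"] += d_inv
            counts[risk]["overall"] += p_inv or d_inv
    table = StratifiedRateTable(
        denominator=len(assessable),
        counts=counts,
        n_unassessable=len(cohort) - len(assessable),
    )
    table.validate()
    return table


def rates_by_specialty(cohort: list[CohortRecord]) -> pd.DataFrame:
    """Raw incomplete rates per specialty, overall and within risk level."""
    rows = []
    assessable = [r for r in cohort if r.assessable]
    for specialty in sorted({r.specialty for r in assessable}):
        recs = [r for r in assessable if r.specialty == specialty]
        row = {
            "specialty": specialty,
            "n": len(recs),
            "n_incomplete": sum(r.incomplete for r in recs),
        }
        row["rate_pct"] = 100.0 * row["n_incomplete"] / row["n"]
        for risk in (LOW, HIGH):
            sub = [r for r in recs if r.risk == risk]
            row[f"{risk}_n"] = len(sub)
            row[f"{risk}_rate_pct"] = (
                100.0 * sum(r.incomplete for r in sub) / len(sub) if sub else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# logistic model


@dataclass
class LogisticFit:
    """Binomial-GLM fit of uninvolved margin on specialty + risk."""

    params: pd.DataFrame  # term-indexed: coef, se, odds_ratio, ci_low, ci_high, p_value
    reference: str
    separated: dict[str, str]  # specialty -> "all_uninvolved" | "all_involved"
    n_used: int
    high_risk_prevalence: float
    method: str = "mle"
    converged: bool = True

    def specialty_terms(self) -> list[str]:
        return [t for t in self.params.index if t.startswith("specialty:")]


def cohort_frame(cohort: list[CohortRecord]) -> pd.DataFrame:
    """Assessable cohort as a modelling frame (specialty, high_risk, uninvolved)."""
    rows = [
        {
            "specialty": r.specialty,
            "high_risk": r.risk == HIGH,
            "uninvolved": not r.incomplete,
        }
        for r in cohort
        if r.assessable
    ]
    return pd.DataFrame(rows)


def detect_separation(df: pd.DataFrame) -> dict[str, str]:
    """Specialties whose outcome shows zero variation."""
    out: dict[str, str] = {}
    for specialty, grp in df.groupby("specialty"):
        mean = grp["uninvolved"].mean()
        if mean == 1.0:
            out[specialty] = "all_uninvolved"
        elif mean == 0.0:
            out[specialty] = "all_involved"
    return out


def _design(df: pd.DataFrame, reference: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    specialties = sorted(s for s in df["specialty"].unique() if s != reference)
    terms = ["intercept"] + [f"specialty:{s}" for s in specialties] + ["high_risk"]
    X = np.column_stack(
        [np.ones(len(df))]
        + [(df["specialty"] == s).to_numpy(float) for s in specialties]
        + [df["high_risk"].to_numpy(float)]
    )
    y = df["uninvolved"].to_numpy(float)
    return X, y, terms


def _firth_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Jeffreys-prior penalised logistic regression (Firth bias reduction)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        W = p * (1 - p)
        XW = X * W[:, None]
        info = X.T @ XW
        info_inv = np.linalg.inv(info)
        # hat diagonal of W^1/2 X I^-1 X' W^1/2
        h = np.einsum("ij,jk,ik->i", X * np.sqrt(W)[:, None], info_inv, X * np.sqrt(W)[:, None])
        score = X.T @ (y - p + h * (0.5 - p))
        delta = info_inv @ score
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            break
    else:
        raise RuntimeError("Firth fit did not converge")
    eta = X @ beta
    p = expit(eta)
    info = X.T @ (X * (p * (1 - p))[:, None])
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se


def fit_margin_model(
    cohort,
    reference_specialty: str = "plastic surgery",
    method: str = "mle",
    alpha: float = 0.05,
    max_iter: int = 100,
) -> LogisticFit:
    """Fit the uninvolved-margin model.

    ``cohort`` is a list of :class:`CohortRecord` or an already-built
    modelling frame.  Under ``method="mle"`` separated specialties are
    excluded from the fit and reported via ``separated``; under
    ``method="firth"`` they stay in, with finite penalised estimates.
    """
    df = cohort if isinstance(cohort, pd.DataFrame) else cohort_frame(cohort)
    if df["specialty"].nunique() < 2:
        raise ValueError("need at least two specialties to model")
    if reference_specialty not in set(df["specialty"]):
        raise ValueError(f"reference specialty {reference_specialty!r} absent from cohort")

    separated = detect_separation(df)
    if reference_specialty in separated:
        raise SeparationError(
            f"reference specialty {reference_specialty!r} is separated "
            f"({separated[reference_specialty]})"
        )

    fit_df = df
    if method == "mle" and separated:
        fit_df = df[~df["specialty"].isin(separated)]
    X, y, terms = _design(fit_df, reference_specialty)

    if method == "mle":
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=max_iter)
        if not res.converged:
            raise RuntimeError(
                f"logistic fit did not converge in {max_iter} iterations; "
                f"deviance trace tail: {res.fit_history['deviance'][-5:]}"
            )
        coef, se = np.asarray(res.params), np.asarray(res.bse)
    elif method == "firth":
        coef, se = _firth_fit(X, y, max_iter=max_iter)
    else:
        raise ValueError(f"unknown method {method!r}")

    z = norm.ppf(1 - alpha / 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, coef / np.where(se > 0, se, 1.0), np.inf)
    params = pd.DataFrame(
        {
            "coef": coef,
            "se": se,
            "odds_ratio": np.exp(coef),
            "ci_low": np.exp(coef - z * se),
            "ci_high": np.exp(coef + z * se),
            "p_value": 2 * norm.sf(np.abs(wald)),
        },
        index=terms,
    )
    return LogisticFit(
        params=params,
        reference=reference_specialty,
        separated=separated,
        n_used=len(fit_df),
        high_risk_prevalence=float(df["high_risk"].mean()),
        method=method,
    )


def logodds_to_rate(
    fit: LogisticFit,
    specialty: str,
    risk: str | None = None,
    alpha: float = 0.05,
) -> float:
    """Adjusted incomplete-excision percentage for a specialty.

    ``risk`` is "low", "high", or None for the cohort-risk-mix weighted
    conversion.  Refuses (raises :class:`ConversionRefusedError`) for a
    separated specialty or one whose coefficient is not significant at
    ``alpha`` — converting an unstable log odds to a rate would lend it
    false precision.
    """
    if specialty in fit.separated:
        raise ConversionRefusedError(
            f"{specialty!r} shows complete separation ({fit.separated[specialty]}); "
            "its maximum-likelihood odds ratio is unbounded"
        )
    if specialty == fit.reference:
        spec_coef = 0.0
    else:
        term = f"specialty:{specialty}"
        if term not in fit.params.index:
            raise ValueError(f"specialty {specialty!r} not in the fitted model")
        if fit.params.loc[term, "p_value"] >= alpha:
            raise ConversionRefusedError(
                f"{specialty!r} coefficient is not significant at alpha={alpha} "
                f"(p={fit.params.loc[term, 'p_value']:.3f})"
            )
        spec_coef = fit.params.loc[term, "coef"]

    intercept = fit.params.loc["intercept", "coef"]
    risk_coef = fit.params.loc["high_risk", "coef"]

    def incomplete_pct(high: bool) -> float:
        p_uninvolved = expit(intercept + spec_coef + risk_coef * high)
        return 100.0 * (1.0 - p_uninvolved)

    if risk == "high":
        return incomplete_pct(True)
    if risk == "low":
        return incomplete_pct(False)
    if risk is None:  # cohort risk mix
        w = fit.high_risk_prevalence
        return w * incomplete_pct(True) + (1 - w) * incomplete_pct(False)
    raise ValueError(f"bad risk level {risk!r}")


def model_table(fit: LogisticFit, alpha: float = 0.05) -> pd.DataFrame:
    """Per-specialty summary: OR (CI), p, adjusted rates where convertible."""
    rows = []
    for term in fit.specialty_terms():
        specialty = term.removeprefix("specialty:")
        row = {
            "specialty": specialty,
            "odds_ratio": fit.params.loc[term, "odds_ratio"],
            "ci_low": fit.params.loc[term, "ci_low"],
            "ci_high": fit.params.loc[term, "ci_high"],
            "p_value": fit.params.loc[term, "p_value"],
            "separated": False,
        }
        try:
            row["adjusted_rate_pct"] = logodds_to_rate(fit, specialty, alpha=alpha)
            row["high_risk_rate_pct"] = logodds_to_rate(fit, specialty, "high", alpha)
            row["low_risk_rate_pct"] = logodds_to_rate(fit, specialty, "low", alpha)
        except ConversionRefusedError:
            row["adjusted_rate_pct"] = np.nan
            row["high_risk_rate_pct"] = np.nan
            row["low_risk_rate_pct"] = np.nan
        rows.append(row)
    for specialty, direction in fit.separated.items():
        rows.append(
            {
                "specialty": specialty,
                "odds_ratio": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "p_value": np.nan,
                "separated": True,
                "adjusted_rate_pct": np.nan,
                "high_risk_rate_pct": np.nan,
                "low_risk_rate_pct": np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# simulation with known generating parameters (for parameter-recovery checks)


def simulate_margin_cohort(
    n: int,
    intercept: float,
    specialty_logodds: dict[str, float],
    risk_logodds: float,
    specialty_weights: dict[str, float],
    high_risk_prevalence: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw a cohort whose uninvolved-margin outcome follows a known
    logistic model; the reference specialty is any key with log odds 0."""
    specialties = list(specialty_weights)
    w = np.asarray([specialty_weights[s] for s in specialties], float)
    idx = rng.choice(len(specialties), size=n, p=w / w.sum())
    high = rng.random(n) < high_risk_prevalence
    eta = (
        intercept
        + np.asarray([specialty_logodds.get(specialties[i], 0.0) for i in idx])
        + risk_logodds * high
    )
    uninvolved = rng.random(n) < expit(eta)
    return pd.DataFrame(
        {
            "specialty": [specialties[i] for i in idx],
            "high_risk": high,
            "uninvolved": uninvolved,
        }
    )
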