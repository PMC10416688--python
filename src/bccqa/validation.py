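"""Agreement statistics between pipeline output and reference labels.

The validation design mirrors a clinician-reference audit: for each
endpoint (completeness of excision, risk status, operating-surgeon
specialty) the pipeline's labels are cross-tabulated against a single
reference label per record, and agreement is summarised as percentage
agreement with a Wilson 95% CI and Cohen's kappa with its asymptotic
(Fleiss-Cohen-Everitt) standard error.  A seeded multinomial bootstrap
CI for kappa is available as an alternative, since agreement studies
rarely state which interval they used.

Unknown labels are carried as an explicit "unknown" category — they are
never dropped silently.  Discordant records are exported together with
the extraction evidence spans so every disagreement can be audited back
to the report text.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classification import HIGH, LOW
from .extraction import LesionExtraction
from .analytics import margin_status_from_extraction
from .classification import classify_risk, default_risk_rules

UNKNOWN_LABEL = "unknown"
ENDPOINTS = ("margin_status", "risk", "specialty")


class AlignmentError(ValueError):
    """Pipeline and reference records could not be paired by id."""


class DegenerateTableError(ValueError):
    """Kappa is undefined: chance agreement is 1 (single-label marginals)."""


@dataclass(frozen=True)
class ConfusionTable:
    labels: tuple[str, ...]
    counts: np.ndarray  # rows = reference, columns = pipeline

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def __post_init__(self) -> None:
        c = self.counts
        if c.shape != (len(self.labels), len(self.labels)):
            raise ValueError("counts must be square over the label set")
        if (c < 0).any():
            raise ValueError("counts must be nonnegative")
        if c.sum() == 0:
            raise ValueError("confusion table is empty")


@dataclass(frozen=True)
class AgreementResult:
    statistic: str  # "percent_agreement" | "cohens_kappa"
    estimate: float
    ci_low: float
    ci_high: float
    n: int
    labels: tuple[str, ...]
    p_value: float | None = None


def build_confusion(
    pipeline_labels,
    reference_labels,
    label_set: tuple[str, ...] | None = None,
) -> ConfusionTable:
    """Cross-tabulate id-aligned label sequences (reference in rows)."""
    pipeline_labels = list(pipeline_labels)
    reference_labels = list(reference_labels)
    if len(pipeline_labels) != len(reference_labels):
        raise AlignmentError(
            f"length mismatch: {len(pipeline_labels)} pipeline vs "
            f"{len(reference_labels)} reference labels"
        )
    if label_set is None:
        label_set = tuple(sorted(set(pipeline_labels) | set(reference_labels)))
    index = {lab: i for i, lab in enumerate(label_set)}
    counts = np.zeros((len(label_set), len(label_set)), dtype=np.int64)
    for ref, pipe in zip(reference_labels, pipeline_labels):
        try:
            counts[index[ref], index[pipe]] += 1
        except KeyError as err:
            raise ValueError(f"label {err.args[0]!r} outside the label set") from None
    return ConfusionTable(tuple(label_set), counts)


def wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    from scipy.stats import norm

    z = norm.ppf(0.5 + conf / 2)
    phat = k / n
    denom = 1 + z**2 / n
    centre = (phat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    # boundary counts have exact limits; also guards float jitter
    lo = 0.0 if k == 0 else max(0.0, centre - half)
    hi = 1.0 if k == n else min(1.0, centre + half)
    return min(lo, phat), max(hi, phat)


def percent_agreement(ct: ConfusionTable, conf: float = 0.95) -> AgreementResult:
    """Diagonal fraction of the table, with a Wilson CI."""
    k = int(np.trace(ct.counts))
    lo, hi = wilson_interval(k, ct.n, conf)
    return AgreementResult(
        "percent_agreement", k / ct.n, lo, hi, ct.n, ct.labels
    )


def _kappa_terms(ct: ConfusionTable) -> tuple[float, float, np.ndarray, np.ndarray, np.ndarray]:
    p = ct.counts / ct.n
    row = p.sum(axis=1)  # reference marginals
    col = p.sum(axis=0)  # pipeline marginals
    po = float(np.trace(p))
    pe = float(row @ col)
    return po, pe, p, row, col


def cohens_kappa(
    ct: ConfusionTable,
    conf: float = 0.95,
    ci_method: str = "asymptotic",
    n_boot: int = 2000,
    seed: int = 0,
) -> AgreementResult:
    """Chance-corrected agreement kappa = (po - pe) / (1 - pe).

    The default CI uses the Fleiss-Cohen-Everitt large-sample variance;
    ``ci_method="bootstrap"`` draws ``n_boot`` seeded multinomial
    resamples of the table instead.  The p-value tests kappa = 0 using
    the null-hypothesis variance.  A table whose chance agreement is 1
    raises :class:`DegenerateTableError`.
    """
    if len(ct.labels) < 2:
        raise DegenerateTableError("kappa needs at least two labels")
    po, pe, p, row, col = _kappa_terms(ct)
    if pe >= 1.0 - 1e-15:
        raise DegenerateTableError("chance agreement is 1; kappa undefined")
    kappa = (po - pe) / (1 - pe)
    n = ct.n

    from scipy.stats import norm

    z = norm.ppf(0.5 + conf / 2)
    if ci_method == "asymptotic":
        a = sum(
            p[i, i] * ((1 - pe) - (row[i] + col[i]) * (1 - po)) ** 2
            for i in range(len(ct.labels))
        )
        b = (1 - po) ** 2 * sum(
            p[i, j] * (col[i] + row[j]) ** 2
            for i in range(len(ct.labels))
            for j in range(len(ct.labels))
            if i != j
        )
        c = (po * pe - 2 * pe + po) ** 2
        var = (a + b - c) / (n * (1 - pe) ** 4)
        se = float(np.sqrt(max(var, 0.0)))
        lo, hi = kappa - z * se, kappa + z * se
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        flat = ct.counts.ravel()
        draws = rng.multinomial(n, flat / n, size=n_boot)
        stats = []
        for d in draws:
            boot = ConfusionTable(ct.labels, d.reshape(ct.counts.shape))
            po_b, pe_b, *_ = _kappa_terms(boot)
            if pe_b < 1.0 - 1e-15:
                stats.append((po_b - pe_b) / (1 - pe_b))
        lo, hi = np.percentile(stats, [100 * (0.5 - conf / 2), 100 * (0.5 + conf / 2)])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    # null-variance test of kappa = 0 (Fleiss et al.)
    var0 = (pe + pe**2 - float(sum(row * col * (row + col)))) / (n * (1 - pe) ** 2)
    p_value = (
        2 * norm.sf(abs(kappa) / np.sqrt(var0)) if var0 > 0 else (0.0 if kappa != 0 else 1.0)
    )
    return AgreementResult(
        "cohens_kappa",
        kappa,
        max(-1.0, float(lo)),
        min(1.0, float(hi)),
        n,
        ct.labels,
        p_value=float(p_value),
    )


# ---------------------------------------------------------------------------
# end-to-end validation run


def margin_label(peripheral, deep) -> str:
    """Completeness-of-excision label from two margin statuses."""
    statuses = (peripheral.status, deep.status)
    if "involved" in statuses:
        return "incomplete"
    if "unknown" in statuses:
        return UNKNOWN_LABEL
    return "complete"


def truth_endpoint_labels(truth) -> dict[str, str]:
    """Reference labels for one TruthRecord."""
    def status(mm):
        from .classification import classify_margin

        return classify_margin(mm) if mm is not None else classify_margin()

    return {
        "margin_status": margin_label(
            status(truth.peripheral_margin_mm), status(truth.deep_margin_mm)
        ),
        "risk": truth.risk or UNKNOWN_LABEL,
        "specialty": truth.specialty or UNKNOWN_LABEL,
    }


def pipeline_endpoint_labels(rec: LesionExtraction, rules=None) -> dict[str, str]:
    """Pipeline labels for one extraction."""
    peripheral = margin_status_from_extraction(
        rec.peripheral_margin_mm, rec.peripheral_involved, rec.peripheral_upper_bound_mm
    )
    deep = margin_status_from_extraction(
        rec.deep_margin_mm, rec.deep_involved, rec.deep_upper_bound_mm
    )
    try:
        risk = classify_risk(rec, rules or default_risk_rules()) if rec.is_bcc else UNKNOWN_LABEL
    except ValueError:
        risk = UNKNOWN_LABEL
    return {
        "margin_status": margin_label(peripheral, deep),
        "risk": risk,
        "specialty": rec.specialty or UNKNOWN_LABEL,
    }


@dataclass
class ValidationReport:
    results: dict[str, dict[str, AgreementResult]]  # endpoint -> statistic -> result
    discordances: list[dict] = field(default_factory=list)
    n: int = 0


def validate_run(
    pipeline_records: list[LesionExtraction],
    reference,
    endpoints: tuple[str, ...] = ENDPOINTS,
) -> ValidationReport:
    """Agreement per endpoint between pipeline output and reference.

    ``reference`` is a list of TruthRecord-like objects (or anything
    with the same fields).  Records are paired by report_id; any id
    present on one side only raises :class:`AlignmentError`.  Reports
    the reference marks as diagnostic biopsies or non-BCC are outside
    the excision QA scope and are not scored.
    """
    pipe_by_id = {r.report_id: r for r in pipeline_records}
    ref_by_id = {t.report_id: t for t in reference}
    missing = sorted(set(ref_by_id) ^ set(pipe_by_id))
    if missing or not ref_by_id:
        raise AlignmentError(f"unpaired report ids: {missing[:10]}")

    ids = [
        rid
        for rid in ref_by_id
        if ref_by_id[rid].is_bcc and not ref_by_id[rid].is_diagnostic_biopsy
    ]
    results: dict[str, dict[str, AgreementResult]] = {}
    discordances: list[dict] = []
    pipe_labels = {rid: pipeline_endpoint_labels(pipe_by_id[rid]) for rid in ids}
    ref_labels = {rid: truth_endpoint_labels(ref_by_id[rid]) for rid in ids}
    for endpoint in endpoints:
        pl = [pipe_labels[rid][endpoint] for rid in ids]
        rl = [ref_labels[rid][endpoint] for rid in ids]
        ct = build_confusion(pl, rl)
        results[endpoint] = {
            "percent_agreement": percent_agreement(ct),
            "cohens_kappa": cohens_kappa(ct),
        }
        for rid, p, r in zip(ids, pl, rl):
            if p != r:
                rec = pipe_by_id[rid]
                discordances.append(
                    {
                        "report_id": rid,
                        "endpoint": endpoint,
                        "pipeline": p,
                        "reference": r,
                        "evidence": {
                            k: {
                                "text": ev.text,
                                "section": ev.section,
                                "start": ev.start,
                                "end": ev.end,
                            }
                            for k, ev in rec.evidence.items()
                        },
                    }
                )
    return ValidationReport(results=results, discordances=discordances, n=len(ids))


# ---------------------------------------------------------------------------
# field-level accuracy against generator truth

_TRUTH_FIELDS = (
    "is_bcc",
    "is_diagnostic_biopsy",
    "subtype",
    "site",
    "size_mm",
    "peripheral_margin_mm",
    "deep_margin_mm",
    "perineural_invasion",
    "lymphovascular_invasion",
    "recurrent",
    "specialty",
)


def field_accuracy(
    extractions: list[LesionExtraction], truths
) -> tuple[float, dict[str, float]]:
    """Exact-match accuracy per truth field, plus the overall mean.

    Tri-state extraction values compare as yes/no against the boolean
    truth; unknown never matches a known truth value.
    """
    truth_by_id = {t.report_id: t for t in truths}
    per_field = {f: 0 for f in _TRUTH_FIELDS}
    n = 0
    for rec in extractions:
        truth = truth_by_id[rec.report_id]
        n += 1
        for f in _TRUTH_FIELDS:
            if getattr(rec, f) == getattr(truth, f):
                per_field[f] += 1
    if n == 0:
        raise ValueError("no records to score")
    rates = {f: per_field[f] / n for f in _TRUTH_FIELDS}
    return float(np.mean(list(rates.values()))), rates
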