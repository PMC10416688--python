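"""Synthetic BCC histopathology corpus with ground-truth sidecar.

The original audit cohort (tens of thousands of UK pathology reports) is
not shareable, so every downstream stage is exercised on a generated
corpus that emulates its essential structure: sectioned UK-style reports
with canonical subheadings, millimetre margin distances or involvement
wording, histological subtype and body-site mentions, explicitly negated
invasion findings, a requesting-clinician header carrying the surgical
specialty, plus diagnostic-biopsy and non-BCC decoy reports that the
cohort filters must exclude.

Each rendered report is paired with a :class:`TruthRecord` holding the
generating values of every endpoint, so extraction accuracy can be
measured exactly.  The truth risk label is computed by the
classification module's rule table — generator and pipeline share a
single source of truth and cannot drift.

Default rates emulate the published study conditions: per-margin
involvement probabilities conditional on risk chosen so that, with the
default feature rates (~42% high-risk lesions), the whole-cohort
peripheral/deep/overall involvement percentages land near the reported
0.9/1.2 (low), 1.7/1.7 (high) and ~5.5% overall.  Clear margins are
drawn log-uniformly — [1, 10] mm, or [0.1, 0.9] mm for the configured
fraction of close margins — rounded to 0.1 mm so the rendered text
encodes the truth value exactly.

Determinism contract: the corpus is a pure function of (config, seed);
two runs with an equal config produce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .classification import RiskRuleTable, classify_risk, default_risk_rules
from .segmentation import ReportDocument


class ConfigError(ValueError):
    """A generator configuration field is out of range."""


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class NoiseConfig:
    """Report-heterogeneity dials.

    ``negation_rate`` is the probability that an absent invasion finding
    is explicitly negated ("No perineural invasion is seen.") rather
    than simply omitted, as is common where minimum-dataset compliance
    is poor.
    """

    template_dialect_weights: dict[str, float] = field(
        default_factory=lambda: {"classic": 0.5, "compact": 0.3, "runon": 0.2}
    )
    abbreviation_rate: float = 0.3
    hedging_rate: float = 0.1
    negation_rate: float = 0.7
    unit_variant_rate: float = 0.2

    @classmethod
    def none(cls) -> "NoiseConfig":
        """The fully explicit, single-dialect rendering: no abbreviations
        or hedging, every absent invasion finding explicitly negated."""
        return cls(
            template_dialect_weights={"classic": 1.0},
            abbreviation_rate=0.0,
            hedging_rate=0.0,
            negation_rate=1.0,
            unit_variant_rate=0.0,
        )

    def validate(self) -> None:
        for name in ("abbreviation_rate", "hedging_rate", "negation_rate", "unit_variant_rate"):
            _check_prob(name, getattr(self, name))
        _check_weights("template_dialect_weights", self.template_dialect_weights)
        for d in self.template_dialect_weights:
            if d not in _DIALECTS:
                raise ConfigError(f"template_dialect_weights: unknown dialect {d!r}")


@dataclass(frozen=True)
class GeneratorConfig:
    n_patients: int = 500
    lesions_per_patient_weights: dict[int, float] = field(
        default_factory=lambda: {1: 0.40, 2: 0.25, 3: 0.15, 4: 0.10, 5: 0.10}
    )
    specialty_weights: dict[str, float] = field(
        default_factory=lambda: {
            "plastic surgery": 0.40,
            "dermatology": 0.20,
            "oral and maxillofacial surgery": 0.12,
            "general practice": 0.08,
            "ear nose and throat surgery": 0.07,
            "ophthalmology": 0.05,
            "general surgery": 0.03,
            "other": 0.05,
        }
    )
    risk_feature_rates: dict[str, float] = field(
        default_factory=lambda: {
            "aggressive_subtype": 0.15,
            "perineural_invasion": 0.02,
            "lymphovascular_invasion": 0.01,
            "high_risk_site": 0.22,
            "size_above_threshold": 0.05,
            "recurrent": 0.05,
        }
    )
    involvement_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "low": {"peripheral": 0.015, "deep": 0.020},
            "high": {"peripheral": 0.0425, "deep": 0.0425},
        }
    )
    close_margin_prob: float = 0.08
    diagnostic_biopsy_rate: float = 0.10
    non_bcc_rate: float = 0.05
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients: must be >= 1")
        _check_weights("lesions_per_patient_weights", self.lesions_per_patient_weights)
        _check_weights("specialty_weights", self.specialty_weights)
        for name, rate in self.risk_feature_rates.items():
            _check_prob(f"risk_feature_rates[{name}]", rate)
        for risk, probs in self.involvement_probs.items():
            if risk not in ("low", "high"):
                raise ConfigError(f"involvement_probs: unknown risk level {risk!r}")
            for margin, p in probs.items():
                _check_prob(f"involvement_probs[{risk}][{margin}]", p)
        for name in ("close_margin_prob", "diagnostic_biopsy_rate", "non_bcc_rate"):
            _check_prob(name, getattr(self, name))
        self.noise.validate()


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name}: probability {value} outside [0, 1]")


def _check_weights(name: str, weights: dict) -> None:
    if not weights:
        raise ConfigError(f"{name}: empty distribution")
    for k, w in weights.items():
        if w < 0:
            raise ConfigError(f"{name}[{k}]: negative weight {w}")
    if abs(sum(weights.values()) - 1.0) > 1e-9:
        raise ConfigError(f"{name}: weights sum to {sum(weights.values())}, not 1")


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class TruthRecord:
    """Generator-side ground truth for one report."""

    report_id: str
    patient_id: str
    is_bcc: bool
    is_diagnostic_biopsy: bool
    subtype: str | None
    site: str | None
    size_mm: float | None
    peripheral_margin_mm: float | None  # 0 encodes involvement
    deep_margin_mm: float | None
    perineural_invasion: bool
    lymphovascular_invasion: bool
    recurrent: bool
    specialty: str
    risk: str | None = None  # low | high | unknown; None for non-BCC

    def __post_init__(self) -> None:
        for m in (self.peripheral_margin_mm, self.deep_margin_mm):
            if m is not None and m < 0:
                raise ValueError("margin distances must be >= 0")
        if self.is_diagnostic_biopsy and (
            self.peripheral_margin_mm is not None or self.deep_margin_mm is not None
        ):
            raise ValueError("diagnostic biopsies carry no margin distances")


_NON_AGGRESSIVE = {"nodular": 0.7, "superficial": 0.3}
_AGGRESSIVE = {
    "infiltrative": 0.5,
    "morphoeic": 0.25,
    "micronodular": 0.15,
    "basosquamous": 0.10,
}
_DECOYS = (
    "seborrhoeic keratosis",
    "intradermal naevus",
    "sebaceous hyperplasia",
    "dermatofibroma",
)
_LATERAL_SITES = {
    "cheek", "ear", "eyelid", "temple", "periorbital", "shoulder",
    "arm", "forearm", "hand", "thigh", "leg", "foot",
}
_TITLES = ("Dr", "Mr", "Ms", "Mrs", "Miss", "Prof")
_SURNAMES = (
    "Jones", "Davies", "Williams", "Evans", "Thomas", "Roberts", "Lewis",
    "Hughes", "Morgan", "Griffiths", "Owen", "Rees", "Jenkins", "Price",
    "Phillips", "Morris", "James", "Edwards", "Powell", "Harris",
)
_OTHER_DEPARTMENTS = ("Vascular Surgery", "Breast Surgery", "Urology")

_SPECIALTY_FULL = {
    "plastic surgery": "Plastic Surgery",
    "oral and maxillofacial surgery": "Oral and Maxillofacial Surgery",
    "dermatology": "Dermatology",
    "ear nose and throat surgery": "Ear, Nose and Throat Surgery",
    "general practice": "General Practice",
    "ophthalmology": "Ophthalmology",
    "general surgery": "General Surgery",
}
_SPECIALTY_ABBREV = {
    "plastic surgery": "Plastics",
    "oral and maxillofacial surgery": "OMFS",
    "dermatology": "Derm",
    "ear nose and throat surgery": "ENT",
    "general practice": "GP",
    "ophthalmology": "Ophth",
    "general surgery": "Gen Surg",
}


def _choice(rng: np.random.Generator, weights: dict):
    keys = list(weights)
    p = np.asarray([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _draw_margin(rng: np.random.Generator, involved_p: float, close_p: float) -> float:
    if rng.random() < involved_p:
        return 0.0
    if rng.random() < close_p:
        return min(0.9, max(0.1, round(_log_uniform(rng, 0.1, 0.9), 1)))
    return min(10.0, max(1.0, round(_log_uniform(rng, 1.0, 10.0), 1)))


def draw_truth(
    rng: np.random.Generator,
    config: GeneratorConfig,
    report_id: str,
    patient_id: str,
    rules: RiskRuleTable | None = None,
) -> TruthRecord:
    """Sample one ground-truth lesion record."""
    rules = rules or default_risk_rules()
    rates = config.risk_feature_rates
    mask_sites = sorted(s for s, r in rules.site_regions.items() if r == "mask")
    other_sites = sorted(s for s, r in rules.site_regions.items() if r != "mask")

    is_bcc = rng.random() >= config.non_bcc_rate
    is_biopsy = rng.random() < config.diagnostic_biopsy_rate
    site = (
        mask_sites[rng.integers(len(mask_sites))]
        if rng.random() < rates["high_risk_site"]
        else other_sites[rng.integers(len(other_sites))]
    )
    specialty = _choice(rng, config.specialty_weights)

    if not is_bcc:
        return TruthRecord(
            report_id, patient_id, False, is_biopsy,
            subtype=None, site=site,
            size_mm=None if is_biopsy else float(rng.integers(3, 13)),
            peripheral_margin_mm=None, deep_margin_mm=None,
            perineural_invasion=False, lymphovascular_invasion=False,
            recurrent=False, specialty=specialty, risk=None,
        )

    aggressive = rng.random() < rates["aggressive_subtype"]
    subtype = _choice(rng, _AGGRESSIVE if aggressive else _NON_AGGRESSIVE)
    pni = rng.random() < rates["perineural_invasion"]
    lvi = rng.random() < rates["lymphovascular_invasion"]
    recurrent = rng.random() < rates["recurrent"]

    size: float | None
    if is_biopsy:
        size = None
    else:
        region = rules.site_regions[site]
        threshold = rules.size_thresholds_mm.get(region)
        if threshold is None:  # mask area: size does not change the label
            size = float(rng.integers(4, 16))
        elif rng.random() < rates["size_above_threshold"]:
            size = float(rng.integers(int(threshold), int(threshold) + 16))
        else:
            size = float(rng.integers(3, int(threshold)))

    truth = TruthRecord(
        report_id, patient_id, True, is_biopsy,
        subtype=subtype, site=site, size_mm=size,
        peripheral_margin_mm=None, deep_margin_mm=None,
        perineural_invasion=pni, lymphovascular_invasion=lvi,
        recurrent=recurrent, specialty=specialty,
    )
    truth.risk = classify_risk(truth, rules)

    if not is_biopsy:
        probs = config.involvement_probs.get(truth.risk, {"peripheral": 0.0, "deep": 0.0})
        truth.peripheral_margin_mm = _draw_margin(
            rng, probs.get("peripheral", 0.0), config.close_margin_prob
        )
        truth.deep_margin_mm = _draw_margin(
            rng, probs.get("deep", 0.0), config.close_margin_prob
        )
    return truth


# ---------------------------------------------------------------------------
# rendering

_DIALECTS = ("classic", "compact", "runon")


def _margin_sentences(
    truth: TruthRecord, hedged: bool, unit: str
) -> str:
    p, d = truth.peripheral_margin_mm, truth.deep_margin_mm
    if p is None or d is None:
        return "Margin assessment is not applicable in this diagnostic sample."
    if p == 0 and d == 0:
        return "The tumour extends to the peripheral and deep margins."
    if p == 0:
        return (
            "The tumour extends to the peripheral margin. "
            f"The deep margin is {d:.1f} {unit}."
        )
    if d == 0:
        return (
            f"The nearest peripheral margin is {p:.1f} {unit}. "
            "The tumour extends to the deep margin."
        )
    if hedged:
        return (
            "The lesion appears completely excised; the nearest peripheral "
            f"margin is approximately {p:.1f} {unit} and the deep margin is "
            f"approximately {d:.1f} {unit}."
        )
    return (
        f"The nearest peripheral margin is {p:.1f} {unit} and the deep "
        f"margin is {d:.1f} {unit}."
    )


def _conclusion_status(truth: TruthRecord) -> str:
    p, d = truth.peripheral_margin_mm, truth.deep_margin_mm
    involved = [name for name, v in (("peripheral", p), ("deep", d)) if v == 0]
    if involved:
        return f"incomplete excision at the {' and '.join(involved)} margin" + (
            "s" if len(involved) == 2 else ""
        )
    if (p is not None and p < 1) or (d is not None and d < 1):
        return "narrowly excised; see microscopy"
    return "completely excised"


def render_report(
    truth: TruthRecord, config: GeneratorConfig, rng: np.random.Generator
) -> ReportDocument:
    """Render one truth record as a free-text report.

    Every non-absent truth field is encoded exactly once; with hedging
    off the encoding is unambiguous.  Noise decisions are drawn from
    ``rng``, so rendering inside :func:`generate_corpus` stays fully
    deterministic.
    """
    noise = config.noise
    dialect = _choice(rng, noise.template_dialect_weights)
    abbrev = rng.random() < noise.abbreviation_rate
    hedged = (
        rng.random() < noise.hedging_rate
        and truth.is_bcc
        and not truth.is_diagnostic_biopsy
        and (truth.peripheral_margin_mm or 0) >= 1
        and (truth.deep_margin_mm or 0) >= 1
    )
    explicit_pni = rng.random() < noise.negation_rate
    explicit_lvi = rng.random() < noise.negation_rate
    unit = "millimetres" if rng.random() < noise.unit_variant_rate else "mm"

    clinician = (
        f"{_TITLES[rng.integers(len(_TITLES))]} "
        f"{chr(ord('A') + rng.integers(26))}. "
        f"{_SURNAMES[rng.integers(len(_SURNAMES))]}"
    )
    if truth.specialty == "other":
        dept = _OTHER_DEPARTMENTS[rng.integers(len(_OTHER_DEPARTMENTS))]
    elif abbrev:
        dept = _SPECIALTY_ABBREV[truth.specialty]
    else:
        dept = _SPECIALTY_FULL[truth.specialty]

    lat = ""
    if truth.site in _LATERAL_SITES:
        lat = ("left " if rng.random() < 0.5 else "right ")
    site_phrase = f"{lat}{truth.site}"

    clinical_parts = []
    if truth.recurrent:
        clinical_parts.append("Recurrent lesion, previously excised at this site.")
    clinical_parts.append(f"Lesion on the {site_phrase}. ?BCC.")
    clinical = " ".join(clinical_parts)

    if truth.is_diagnostic_biopsy:
        macro = f"A {rng.integers(3, 7)} mm punch biopsy of skin."
    else:
        length = int((truth.size_mm or 8) + rng.integers(4, 11))
        width = int((truth.size_mm or 8) // 2 + rng.integers(3, 8))
        macro = f"An ellipse of skin measuring {length} x {width} mm."
        if truth.size_mm is not None:
            macro += (
                " On sectioning there is a pearly nodule measuring "
                f"{truth.size_mm:g} {unit} in maximum diameter."
            )

    bcc_name = "BCC" if abbrev else "basal cell carcinoma"
    site_cap = site_phrase[0].upper() + site_phrase[1:]
    if truth.is_bcc:
        micro_parts = [f"Sections show a {truth.subtype} basal cell carcinoma."]
        if truth.perineural_invasion:
            micro_parts.append("Perineural invasion is present.")
        elif explicit_pni:
            micro_parts.append("No perineural invasion is seen.")
        if truth.lymphovascular_invasion:
            micro_parts.append("Lymphovascular invasion is identified.")
        elif explicit_lvi:
            micro_parts.append("There is no lymphovascular invasion.")
        micro_parts.append(_margin_sentences(truth, hedged, unit))
        micro = " ".join(micro_parts)
        if truth.is_diagnostic_biopsy:
            conclusion = (
                f"Punch biopsy: {truth.subtype} {bcc_name}. Margins not assessable."
            )
        else:
            conclusion = (
                f"{site_cap}, excision: {truth.subtype} {bcc_name}, "
                f"{_conclusion_status(truth)}."
            )
    else:
        decoy = _DECOYS[rng.integers(len(_DECOYS))]
        micro = (
            f"Sections show a benign {decoy}. "
            "There is no evidence of basal cell carcinoma."
        )
        if truth.is_diagnostic_biopsy:
            conclusion = f"Punch biopsy: benign {decoy}. No evidence of {bcc_name}."
        else:
            conclusion = f"{site_cap}, excision: benign {decoy}. No evidence of {bcc_name}."

    if dialect == "classic":
        header = f"Requesting clinician: {clinician} ({dept})"
        text = (
            f"{header}\n\n"
            f"CLINICAL DETAILS: {clinical}\n\n"
            f"MACROSCOPIC DESCRIPTION: {macro}\n\n"
            f"MICROSCOPIC DESCRIPTION: {micro}\n\n"
            f"CONCLUSION: {conclusion}\n"
        )
    elif dialect == "compact":
        header = f"Referring clinician: {clinician}, {dept}"
        text = (
            f"{header}\n"
            f"Clinical history: {clinical}\n"
            f"Macroscopy: {macro}\n"
            f"Microscopy: {micro}\n"
            f"Diagnosis: {conclusion}\n"
        )
    else:  # runon: a single dictated paragraph with inline headings
        header = f"Requesting clinician: {clinician} - {dept}."
        text = (
            f"{header} Clinical details: {clinical} Macroscopy: {macro} "
            f"Microscopy: {micro} Conclusion: {conclusion}\n"
        )
    return ReportDocument(
        report_id=truth.report_id,
        patient_id=truth.patient_id,
        text=text,
        header=header,
    )


# ---------------------------------------------------------------------------
# corpus


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[list[ReportDocument], list[TruthRecord]]:
    """Generate a paired (reports, truths) corpus.

    One lesion per report; a patient's lesions share a patient_id.  The
    output is a pure function of the config (including its seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rules = default_risk_rules()
    docs: list[ReportDocument] = []
    truths: list[TruthRecord] = []
    report_idx = 0
    for p in range(config.n_patients):
        patient_id = f"P{p:06d}"
        n_lesions = _choice(rng, config.lesions_per_patient_weights)
        for _ in range(n_lesions):
            report_id = f"R{report_idx:07d}"
            report_idx += 1
            truth = draw_truth(rng, config, report_id, patient_id, rules)
            docs.append(render_report(truth, config, rng))
            truths.append(truth)
    return docs, truths


def iter_corpus(config: GeneratorConfig) -> Iterator[tuple[ReportDocument, TruthRecord]]:
    """Streaming variant of :func:`generate_corpus` (same draws, same order)."""
    docs, truths = generate_corpus(config)
    yield from zip(docs, truths)


def noise_free(config: GeneratorConfig) -> GeneratorConfig:
    """Copy of ``config`` with the unambiguous rendering dialect."""
    return replace(config, noise=NoiseConfig.none())
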