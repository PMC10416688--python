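"""Rule-based extraction of audit endpoints from sectioned reports.

This is the information-extraction layer of the quality-assurance
pathway: given a sectioned histopathology report it produces one
structured :class:`LesionExtraction` holding the audit endpoints — margin
status (peripheral and deep), the fields feeding risk stratification
(subtype, site, size, invasion, recurrence), the procedure type, and the
operating-surgeon specialty read from the report header.

All patterns and lexicons live in an editable rule file
(``data/extraction_rules.yaml``); the code only supplies the matching
machinery:

* margin mentions — ordered regex inventory covering measured clearance
  ("nearest peripheral margin is 1.2 mm"), involvement wording ("extends
  to the deep margin"), generic clearance ("completely excised"), and
  bounded mentions ("less than 1 mm", recorded as an inexact interval);
* NegEx-style negation scoping — a cue negates trigger terms within the
  same clause, clauses ending at "but"/"however"/";"/sentence end;
* section-aware precedence — the conclusion outranks the clinical
  details for diagnosis (a clinical "?BCC" is a suspicion only).

Findings customarily reported only when present (perineural and
lymphovascular invasion, recurrence) default to *absent* when a
successfully sectioned report does not mention them; such fields are
listed in ``assumed_absent`` and carry no evidence span.  Every
mention-derived field records the matched text and its character offsets
into the original report for audit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import yaml

from .classification import TriState
from .segmentation import ReportDocument, SectionedReport

SPECIALTIES = (
    "plastic surgery",
    "oral and maxillofacial surgery",
    "dermatology",
    "ear nose and throat surgery",
    "general practice",
    "ophthalmology",
    "general surgery",
    "other",
)

PERIPHERAL, DEEP, UNSPECIFIED = "peripheral", "deep", "unspecified"
_MARGIN_SYNONYMS = {"lateral": PERIPHERAL, "radial": PERIPHERAL}


@dataclass(frozen=True)
class Evidence:
    """Matched text with provenance: section name + offsets into doc.text."""

    text: str
    section: str
    start: int
    end: int


@dataclass(frozen=True)
class MarginMention:
    margin: str  # peripheral | deep | unspecified
    kind: str  # distance | involved | clear | less_than
    distance_mm: float | None
    upper_bound_mm: float | None
    inexact: bool
    start: int
    end: int
    text: str


@dataclass
class LesionExtraction:
    """Structured record of everything extracted from one report."""

    report_id: str
    patient_id: str
    is_bcc: bool = False
    is_diagnostic_biopsy: bool = False
    subtype: str | None = None
    site: str | None = None
    size_mm: float | None = None
    peripheral_margin_mm: float | None = None
    peripheral_involved: TriState = None
    deep_margin_mm: float | None = None
    deep_involved: TriState = None
    peripheral_upper_bound_mm: float | None = None
    deep_upper_bound_mm: float | None = None
    perineural_invasion: TriState = None
    lymphovascular_invasion: TriState = None
    recurrent: TriState = None
    specialty: str | None = None
    inexact_fields: set = field(default_factory=set)
    conflicted_margins: set = field(default_factory=set)
    assumed_absent: set = field(default_factory=set)
    procedure_unstated: bool = False
    evidence: dict[str, Evidence] = field(default_factory=dict)


class ExtractionRules:
    """Compiled view of the YAML rule file."""

    def __init__(self, raw: dict):
        self.raw = raw
        flags = re.IGNORECASE
        self.margin_patterns = [
            (p["kind"], re.compile(p["regex"], flags)) for p in raw["margin_patterns"]
        ]
        self.hedge = re.compile(raw["hedge_cues"], flags)
        neg = raw["negation"]
        self.neg_cues = re.compile(neg["cues"], flags)
        self.clause_split = re.compile(neg["clause_splitters"], flags)
        self.sentence_split = re.compile(neg["sentence_splitters"])
        self.diagnosis_triggers = tuple(raw["diagnosis_triggers"])
        self.subtype_surfaces = [
            (surface, canon)
            for canon, surfaces in raw["subtypes"].items()
            for surface in surfaces
        ]
        self.subtype_regex = _alternation([s for s, _ in self.subtype_surfaces])
        self.subtype_map = {s.lower(): c for s, c in self.subtype_surfaces}
        self.invasion_triggers = {
            k: tuple(v) for k, v in raw["invasion_triggers"].items()
        }
        self.recurrence_triggers = tuple(raw["recurrence_triggers"])
        self.size_patterns = [re.compile(p, flags) for p in raw["size_patterns"]]
        self.procedure_diagnostic = _alternation(raw["procedure"]["diagnostic"])
        self.procedure_excision = _alternation(raw["procedure"]["excision"])
        self.site_map = {s.lower(): c for s, c in raw["sites"].items()}
        self.site_regex = _alternation(list(raw["sites"]))
        self.specialty_surfaces = sorted(
            (
                (surface.lower(), canon)
                for canon, surfaces in raw["specialties"].items()
                for surface in surfaces
            ),
            key=lambda sc: len(sc[0]),
            reverse=True,
        )
        self.specialty_regexes = [
            (re.compile(rf"\b{re.escape(s)}\b", flags), canon)
            for s, canon in self.specialty_surfaces
        ]


def _alternation(surfaces: list[str]) -> re.Pattern:
    alts = "|".join(
        re.escape(s).replace("\\ ", r"\s+").replace(" ", r"\s+")
        for s in sorted(surfaces, key=len, reverse=True)
    )
    return re.compile(rf"\b(?:{alts})\b", re.IGNORECASE)


@lru_cache(maxsize=1)
def default_rules() -> ExtractionRules:
    raw = yaml.safe_load(
        resources.files("bccqa.data").joinpath("extraction_rules.yaml").read_text()
    )
    return ExtractionRules(raw)


# ---------------------------------------------------------------------------
# margin mentions


def extract_margin_mentions(
    section_text: str, rules: ExtractionRules | None = None
) -> list[MarginMention]:
    """Find every margin mention in a stretch of text.

    Patterns run in rule-file order; a later pattern never claims
    characters already matched, so specific (typed, measured) mentions
    shadow the generic phrasing that often co-occurs in the same
    sentence.
    """
    rules = rules or default_rules()
    mentions: list[MarginMention] = []
    claimed: list[tuple[int, int]] = []

    for kind, pattern in rules.margin_patterns:
        for m in pattern.finditer(section_text):
            if any(m.start() < e and m.end() > s for s, e in claimed):
                continue
            claimed.append((m.start(), m.end()))
            groups = m.groupdict()
            margins = []
            for g in ("m1", "m2"):
                word = groups.get(g)
                if word:
                    word = word.lower()
                    margins.append(_MARGIN_SYNONYMS.get(word, word))
            if not margins:
                margins = [UNSPECIFIED]
            window = section_text[max(0, m.start() - 30) : m.end()]
            inexact = bool(rules.hedge.search(window))
            dist = float(groups["dist"]) if groups.get("dist") else None
            bound = float(groups["bound"]) if groups.get("bound") else None
            for margin in margins:
                mentions.append(
                    MarginMention(
                        margin=margin,
                        kind=kind,
                        distance_mm=dist,
                        upper_bound_mm=bound,
                        inexact=inexact or kind == "less_than",
                        start=m.start(),
                        end=m.end(),
                        text=m.group(0),
                    )
                )
    mentions.sort(key=lambda mm: mm.start)
    return mentions


def _resolve_margin(
    typed: list[MarginMention], generic: list[MarginMention]
) -> tuple[float | None, TriState, float | None, bool, bool, MarginMention | None]:
    """Fuse mentions for one margin.

    Returns (distance_mm, involved, upper_bound_mm, inexact, conflicted,
    primary_mention).  Generic mentions apply only when the margin has no
    typed mention of its own.  Contradictory statuses resolve
    pessimistically to involved and are flagged for audit.
    """
    mentions = typed if typed else generic
    if not mentions:
        return None, None, None, False, False, None

    distances = [m.distance_mm for m in mentions if m.distance_mm is not None]
    involved_claims = [m for m in mentions if m.kind == "involved"]
    clear_claims = [m for m in mentions if m.kind == "clear"]
    bounds = [m.upper_bound_mm for m in mentions if m.upper_bound_mm is not None]
    inexact = any(m.inexact for m in mentions)

    conflict = bool(involved_claims) and (
        bool(clear_claims) or any(d > 0 for d in distances)
    )
    conflict = conflict or (bool(clear_claims) and any(d == 0 for d in distances))
    conflict = conflict or len(set(distances)) > 1

    if involved_claims and conflict:
        return 0.0, True, None, inexact, True, involved_claims[0]
    if distances:
        d = min(distances)
        primary = next(m for m in mentions if m.distance_mm == d)
        return d, d == 0.0, min(bounds) if bounds else None, inexact, conflict, primary
    if involved_claims:
        return 0.0, True, None, inexact, False, involved_claims[0]
    if bounds:
        b = min(bounds)
        primary = next(m for m in mentions if m.upper_bound_mm == b)
        # "less than X mm": clearance bounded above; not involved, not clear
        return None, False if b <= 1.0 else None, b, True, conflict, primary
    if clear_claims:
        return None, False, None, inexact, conflict, clear_claims[0]
    return None, None, None, inexact, conflict, None


# ---------------------------------------------------------------------------
# negation scoping


def apply_negation_scope(
    section_text: str,
    trigger_terms: tuple[str, ...],
    rules: ExtractionRules | None = None,
) -> list[tuple[str, str, int, int]]:
    """NegEx-style polarity assignment for trigger terms.

    Returns (term, polarity, start, end) for every trigger occurrence; a
    negation cue in the same clause (clauses end at "but", "however",
    ";", or a sentence boundary) flips polarity to negative.
    """
    if not trigger_terms:
        raise ValueError("trigger_terms must be non-empty")
    rules = rules or default_rules()
    term_regex = _alternation(list(trigger_terms))

    results: list[tuple[str, str, int, int]] = []
    for sent in re.finditer(r"[^.;\n]+", section_text):
        clause_start = sent.start()
        boundaries = [m.start() for m in rules.clause_split.finditer(sent.group(0))]
        cut_points = [b + sent.start() for b in boundaries] + [sent.end()]
        for cut in cut_points:
            clause = section_text[clause_start:cut]
            negated = bool(rules.neg_cues.search(clause))
            for tm in term_regex.finditer(clause):
                results.append(
                    (
                        tm.group(0).lower(),
                        "negative" if negated else "positive",
                        clause_start + tm.start(),
                        clause_start + tm.end(),
                    )
                )
            clause_start = cut
    return results


def _tri_from_mentions(
    hits: list[tuple[str, str, int, int]]
) -> tuple[TriState, tuple[str, str, int, int] | None]:
    if not hits:
        return None, None
    positives = [h for h in hits if h[1] == "positive"]
    if positives:  # any affirmed mention wins over a negated one
        return True, positives[0]
    return False, hits[0]


# ---------------------------------------------------------------------------
# diagnosis / procedure / specialty / site / size


def detect_diagnosis(
    sr: SectionedReport, rules: ExtractionRules | None = None
) -> tuple[bool, str | None, Evidence | None]:
    """Decide BCC status and subtype with conclusion-over-clinical precedence.

    Only the conclusion and microscopic sections carry diagnoses; a
    clinical-details "?BCC" is a suspicion and never counts.  Returns
    (is_bcc, subtype, evidence); no mention anywhere yields (False, None,
    None).
    """
    rules = rules or default_rules()
    sections = sr.sections
    for name in ("conclusion", "microscopic"):
        text = sections.get(name)
        if not text:
            continue
        hits = apply_negation_scope(text, rules.diagnosis_triggers, rules)
        verdict, hit = _tri_from_mentions(hits)
        if verdict is None:
            continue
        offset = sr.section_offset(name) or 0
        ev = Evidence(text[hit[2] : hit[3]], name, offset + hit[2], offset + hit[3])
        if not verdict:
            return False, None, ev
        subtype, sub_ev = _find_subtype(sr, rules)
        return True, subtype, sub_ev or ev
    if sr.no_headings and sr.text.strip():
        hits = apply_negation_scope(sr.text, rules.diagnosis_triggers, rules)
        verdict, hit = _tri_from_mentions(hits)
        if verdict is not None:
            ev = Evidence(sr.text[hit[2] : hit[3]], "unsectioned", hit[2], hit[3])
            if verdict:
                subtype, sub_ev = _find_subtype(sr, rules)
                return True, subtype, sub_ev or ev
            return False, None, ev
    return False, None, None


def _find_subtype(
    sr: SectionedReport, rules: ExtractionRules
) -> tuple[str | None, Evidence | None]:
    sections = sr.sections
    names = ("conclusion", "microscopic") if not sr.no_headings else ()
    for name in names:
        text = sections.get(name, "")
        m = rules.subtype_regex.search(text)
        if m:
            offset = sr.section_offset(name) or 0
            return (
                rules.subtype_map[re.sub(r"\s+", " ", m.group(0).lower())],
                Evidence(m.group(0), name, offset + m.start(), offset + m.end()),
            )
    if sr.no_headings:
        m = rules.subtype_regex.search(sr.text)
        if m:
            return (
                rules.subtype_map[re.sub(r"\s+", " ", m.group(0).lower())],
                Evidence(m.group(0), "unsectioned", m.start(), m.end()),
            )
    return None, None


def detect_procedure(
    sr: SectionedReport, rules: ExtractionRules | None = None
) -> tuple[bool, bool, Evidence | None]:
    """Classify the specimen as diagnostic biopsy vs excision.

    The macroscopic description is authoritative (the clinical history
    may mention a *previous* biopsy or excision); the whole text is the
    fallback.  Returns (is_diagnostic_biopsy, unstated_warning, evidence).
    """
    rules = rules or default_rules()
    macro = sr.sections.get("macroscopic")
    search_spaces = []
    if macro:
        search_spaces.append(("macroscopic", macro, sr.section_offset("macroscopic") or 0))
    search_spaces.append(("full_text", sr.text, 0))
    for name, text, offset in search_spaces:
        m = rules.procedure_diagnostic.search(text)
        if m:
            return True, False, Evidence(m.group(0), name, offset + m.start(), offset + m.end())
        m = rules.procedure_excision.search(text)
        if m:
            return False, False, Evidence(m.group(0), name, offset + m.start(), offset + m.end())
        if macro and name == "macroscopic":
            continue  # fall through to whole text only if macro was silent
    return False, True, None


def extract_specialty(
    header: str, rules: ExtractionRules | None = None
) -> tuple[str | None, Evidence | None]:
    """Map the requesting-clinician header to a canonical specialty.

    Longest lexicon surface wins; an unmatched non-empty header maps to
    "other"; an empty header is unknown (None).
    """
    rules = rules or default_rules()
    if not header or not header.strip():
        return None, None
    for regex, canon in rules.specialty_regexes:
        m = regex.search(header)
        if m:
            return canon, Evidence(m.group(0), "header", m.start(), m.end())
    return "other", None


def _find_site(
    sr: SectionedReport, rules: ExtractionRules
) -> tuple[str | None, Evidence | None]:
    sections = sr.sections
    names = ("clinical_details", "conclusion", "macroscopic") if not sr.no_headings else ()
    for name in names:
        text = sections.get(name, "")
        m = rules.site_regex.search(text)
        if m:
            offset = sr.section_offset(name) or 0
            return (
                rules.site_map[re.sub(r"\s+", " ", m.group(0).lower())],
                Evidence(m.group(0), name, offset + m.start(), offset + m.end()),
            )
    if sr.no_headings:
        m = rules.site_regex.search(sr.text)
        if m:
            return (
                rules.site_map[re.sub(r"\s+", " ", m.group(0).lower())],
                Evidence(m.group(0), "unsectioned", m.start(), m.end()),
            )
    return None, None


def _find_size(
    sr: SectionedReport, rules: ExtractionRules
) -> tuple[float | None, Evidence | None]:
    if sr.no_headings:
        text, offset, section = sr.text, 0, "unsectioned"
    else:
        text = sr.sections.get("macroscopic", "")
        offset = sr.section_offset("macroscopic") or 0
        section = "macroscopic"
    for pattern in rules.size_patterns:
        m = pattern.search(text)
        if m:
            return (
                float(m.group("size")),
                Evidence(m.group(0), section, offset + m.start(), offset + m.end()),
            )
    return None, None


# ---------------------------------------------------------------------------
# record assembly


def extract_record(
    sr: SectionedReport,
    doc: ReportDocument,
    rules: ExtractionRules | None = None,
) -> LesionExtraction:
    """Compose all extractors into one :class:`LesionExtraction`."""
    if sr.report_id != doc.report_id:
        raise ValueError(
            f"report_id mismatch: sectioned {sr.report_id!r} vs document {doc.report_id!r}"
        )
    rules = rules or default_rules()
    rec = LesionExtraction(report_id=doc.report_id, patient_id=doc.patient_id)

    sectioned_ok = bool(sr.spans)

    rec.is_bcc, rec.subtype, diag_ev = detect_diagnosis(sr, rules)
    if diag_ev:
        rec.evidence["is_bcc"] = diag_ev
        if rec.subtype:
            rec.evidence["subtype"] = diag_ev

    rec.is_diagnostic_biopsy, rec.procedure_unstated, proc_ev = detect_procedure(sr, rules)
    if proc_ev:
        rec.evidence["is_diagnostic_biopsy"] = proc_ev

    rec.site, site_ev = _find_site(sr, rules)
    if site_ev:
        rec.evidence["site"] = site_ev
    rec.size_mm, size_ev = _find_size(sr, rules)
    if size_ev:
        rec.evidence["size_mm"] = size_ev

    # margin mentions from microscopic + conclusion
    all_mentions: list[tuple[MarginMention, str, int]] = []
    for name in ("microscopic", "conclusion"):
        text = sr.sections.get(name)
        if not text:
            continue
        offset = sr.section_offset(name) or 0
        for mm in extract_margin_mentions(text, rules):
            all_mentions.append((mm, name, offset))

    typed = {PERIPHERAL: [], DEEP: []}
    generic: list[MarginMention] = []
    where: dict[int, tuple[str, int]] = {}
    for mm, name, offset in all_mentions:
        where[id(mm)] = (name, offset)
        if mm.margin in typed:
            typed[mm.margin].append(mm)
        else:
            generic.append(mm)

    for margin, attr in ((PERIPHERAL, "peripheral"), (DEEP, "deep")):
        dist, involved, bound, inexact, conflict, primary = _resolve_margin(
            typed[margin], generic
        )
        setattr(rec, f"{attr}_margin_mm", dist)
        setattr(rec, f"{attr}_involved", involved)
        setattr(rec, f"{attr}_upper_bound_mm", bound)
        if inexact:
            rec.inexact_fields.add(f"{attr}_margin_mm")
        if conflict:
            rec.conflicted_margins.add(attr)
        if primary is not None:
            name, offset = where[id(primary)]
            rec.evidence[f"{attr}_margin_mm"] = Evidence(
                primary.text, name, offset + primary.start, offset + primary.end
            )

    # invasion / recurrence tri-states with absence-as-negative convention
    micro = sr.sections.get("microscopic", "")
    micro_offset = sr.section_offset("microscopic") or 0
    for attr, triggers in rules.invasion_triggers.items():
        hits = apply_negation_scope(micro, triggers, rules) if micro else []
        value, hit = _tri_from_mentions(hits)
        if value is None and sectioned_ok:
            value = False
            rec.assumed_absent.add(attr)
        elif hit is not None:
            rec.evidence[attr] = Evidence(
                micro[hit[2] : hit[3]], "microscopic", micro_offset + hit[2], micro_offset + hit[3]
            )
        setattr(rec, attr, value)

    clinical = sr.sections.get("clinical_details", "")
    clin_offset = sr.section_offset("clinical_details") or 0
    hits = (
        apply_negation_scope(clinical, rules.recurrence_triggers, rules)
        if clinical
        else []
    )
    rec.recurrent, hit = _tri_from_mentions(hits)
    if rec.recurrent is None and sectioned_ok:
        rec.recurrent = False
        rec.assumed_absent.add("recurrent")
    elif hit is not None:
        rec.evidence["recurrent"] = Evidence(
            clinical[hit[2] : hit[3]], "clinical_details", clin_offset + hit[2], clin_offset + hit[3]
        )

    header = doc.header
    if not header:
        # requesting-clinician line precedes the first heading
        header = doc.text[: sr.spans[0].start] if sr.spans else _header_from_text(doc.text)
    rec.specialty, spec_ev = extract_specialty(header, rules)
    if spec_ev:
        rec.evidence["specialty"] = spec_ev
    return rec


_HEADER_RE = re.compile(
    r"^(?:requesting|referring)\s+clinician.*$|^dept(?:artment)?\s*:.*$",
    re.IGNORECASE | re.MULTILINE,
)


def _header_from_text(text: str) -> str:
    m = _HEADER_RE.search(text)
    return m.group(0) if m else ""
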