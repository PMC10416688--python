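"""Sectioning of free-text histopathology reports.

UK pathology reports are written under a small set of recurring
subheadings — clinical details, macroscopic description, microscopic
description, and a conclusion/diagnosis line.  Downstream extraction is
section-aware (for example, a clinical ``?BCC`` is a suspicion, not a
diagnosis), so the first processing step maps each report onto those four
canonical sections.

Heading surface forms vary between laboratories; they are supplied as an
editable lexicon (``data/headings.yaml``) mapping canonical section names
to the surface headings observed in practice.  Matching is
case-insensitive and tolerant of trailing colons and whitespace, and a
heading is recognised either at the start of a line or inline after a
sentence boundary (some reports are dictated as a single run-on
paragraph).

Section spans are 0-based half-open character intervals into the original
text, and the segmentation is lossless: the ordered spans plus the
unassigned residue reconstruct the input exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import pandas as pd
import yaml

CANONICAL_SECTIONS = ("clinical_details", "macroscopic", "microscopic", "conclusion")


@dataclass(frozen=True)
class ReportDocument:
    """One free-text histopathology report."""

    report_id: str
    patient_id: str
    text: str
    header: str = ""  # requesting-clinician / department line

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("report_id must be non-empty")


@dataclass(frozen=True)
class SectionSpan:
    """A matched heading and the section content it opens.

    ``start`` is the offset of the heading itself, ``content_start`` the
    offset just past the heading (and its colon/whitespace), ``end`` the
    half-open end of the section content.
    """

    canonical: str
    heading: str
    start: int
    content_start: int
    end: int


@dataclass
class SectionedReport:
    report_id: str
    text: str
    spans: list[SectionSpan] = field(default_factory=list)
    no_headings: bool = False

    @property
    def sections(self) -> dict[str, str]:
        """Canonical section name -> content text.

        Repeated headings mapping to the same canonical section are
        concatenated in document order.
        """
        out: dict[str, str] = {}
        for sp in self.spans:
            content = self.text[sp.content_start : sp.end]
            if sp.canonical in out:
                out[sp.canonical] = out[sp.canonical] + "\n" + content
            else:
                out[sp.canonical] = content
        return out

    def section_offset(self, canonical: str) -> int | None:
        """Content offset of the first span for ``canonical``, if any."""
        for sp in self.spans:
            if sp.canonical == canonical:
                return sp.content_start
        return None

    @property
    def unassigned_text(self) -> str:
        pieces, pos = [], 0
        for sp in self.spans:
            if sp.start > pos:
                pieces.append(self.text[pos : sp.start])
            pos = max(pos, sp.end)
        if pos < len(self.text):
            pieces.append(self.text[pos:])
        return "".join(pieces)

    def reconstruct(self) -> str:
        """Reassemble the original text from spans + unassigned residue."""
        pieces, pos = [], 0
        for sp in self.spans:
            if sp.start > pos:
                pieces.append(self.text[pos : sp.start])
            pieces.append(self.text[sp.start : sp.end])
            pos = sp.end
        if pos < len(self.text):
            pieces.append(self.text[pos:])
        return "".join(pieces)


@lru_cache(maxsize=1)
def default_heading_lexicon() -> dict[str, tuple[str, ...]]:
    raw = yaml.safe_load(
        resources.files("bccqa.data").joinpath("headings.yaml").read_text()
    )
    return {canon: tuple(forms) for canon, forms in raw.items()}


def _heading_regex(lexicon: dict[str, tuple[str, ...]]) -> tuple[re.Pattern, dict[str, str]]:
    surface_to_canonical: dict[str, str] = {}
    for canon, forms in lexicon.items():
        if canon not in CANONICAL_SECTIONS:
            raise ValueError(f"unknown canonical section {canon!r}")
        for form in forms:
            surface_to_canonical[form.lower()] = canon
    # longest-first so "clinical history" wins over "history"
    alts = "|".join(
        re.escape(s) for s in sorted(surface_to_canonical, key=len, reverse=True)
    )
    pattern = re.compile(
        rf"(?im)"
        rf"(?:^[ \t]*(?P<line>{alts})[ \t]*:?[ \t]*)"  # heading at line start
        rf"|(?:(?<=[.?!] )(?P<inline>{alts})[ \t]*:[ \t]*)"  # inline, needs colon
    )
    return pattern, surface_to_canonical


def segment_report(
    doc: ReportDocument,
    heading_lexicon: dict[str, tuple[str, ...]] | None = None,
) -> SectionedReport:
    """Split a report into canonical sections.

    Every matched heading opens a section extending to the next matched
    heading or the end of the text.  If no heading matches, the report is
    returned whole with ``no_headings`` set (degraded, not fatal).
    """
    if heading_lexicon is None:
        heading_lexicon = default_heading_lexicon()
    if not heading_lexicon or not any(heading_lexicon.values()):
        raise ValueError("heading lexicon must cover at least one surface form")
    pattern, surface_map = _heading_regex(dict(heading_lexicon))

    text = doc.text
    matches = list(pattern.finditer(text))
    if not matches:
        return SectionedReport(doc.report_id, text, [], no_headings=True)

    spans: list[SectionSpan] = []
    for i, m in enumerate(matches):
        surface = (m.group("line") or m.group("inline")).strip().lower()
        canonical = surface_map[surface]
        end = matches[i + 1].start() if i + 1 < len(matches) else len(text)
        spans.append(
            SectionSpan(
                canonical=canonical,
                heading=text[m.start() : m.end()],
                start=m.start(),
                content_start=m.end(),
                end=end,
            )
        )
    return SectionedReport(doc.report_id, text, spans)


def sections_to_rows(sr: SectionedReport) -> dict[str, str]:
    """One tabular row per report: id + one cell per canonical section."""
    row = {"report_id": sr.report_id}
    sections = sr.sections
    for name in CANONICAL_SECTIONS:
        row[name] = sections.get(name, "").strip()
    return row


def corpus_to_table(sectioned: list[SectionedReport]) -> pd.DataFrame:
    """Stack per-report rows into a DataFrame with stable column order."""
    return pd.DataFrame(
        [sections_to_rows(sr) for sr in sectioned],
        columns=["report_id", *CANONICAL_SECTIONS],
    )
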