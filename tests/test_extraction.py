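"""Extraction rules: margin phrases, negation scope, precedence, round trip."""

import pytest

from bccqa.extraction import (
    apply_negation_scope,
    default_rules,
    detect_diagnosis,
    detect_procedure,
    extract_margin_mentions,
    extract_record,
    extract_specialty,
)
from bccqa.segmentation import ReportDocument, segment_report
from bccqa.validation import field_accuracy


def sectioned(text, rid="R1"):
    return segment_report(ReportDocument(rid, "P1", text))


# ---------------------------------------------------------------------------
# margin mentions


@pytest.mark.parametrize(
    "text, margin, kind, dist",
    [
        ("the nearest peripheral margin is 1.2 mm", "peripheral", "distance", 1.2),
        ("deep margin of excision: 3 mm", "deep", "distance", 3.0),
        ("clear of the deep margin by 0.5 mm", "deep", "distance", 0.5),
        ("the lateral margin measures 2.5 millimetres", "peripheral", "distance", 2.5),
        ("tumour extends to the deep margin", "deep", "involved", None),
        ("involves the peripheral margin", "peripheral", "involved", None),
        ("incompletely excised at the deep aspect", "deep", "involved", None),
        ("margins clear", "unspecified", "clear", None),
        ("completely excised", "unspecified", "clear", None),
        ("margins clear by 2 mm", "unspecified", "distance", 2.0),
    ],
)
def test_margin_phrase_inventory(text, margin, kind, dist):
    mentions = extract_margin_mentions(text)
    assert len(mentions) == 1
    m = mentions[0]
    assert (m.margin, m.kind, m.distance_mm) == (margin, kind, dist)


def test_less_than_pattern_yields_inexact_interval():
    (m,) = extract_margin_mentions("excision margin of less than 1 mm")
    assert m.kind == "less_than"
    assert m.upper_bound_mm == 1.0
    assert m.inexact


def test_double_margin_mention_expands():
    mentions = extract_margin_mentions("tumour extends to the peripheral and deep margins")
    assert {m.margin for m in mentions} == {"peripheral", "deep"}
    assert all(m.kind == "involved" for m in mentions)


def test_typed_mentions_shadow_generic_phrasing():
    text = (
        "The lesion appears completely excised; the nearest peripheral margin "
        "is approximately 1.2 mm and the deep margin is 3.0 mm."
    )
    mentions = extract_margin_mentions(text)
    typed = {m.margin: m for m in mentions if m.margin != "unspecified"}
    assert typed["peripheral"].distance_mm == 1.2
    assert typed["peripheral"].inexact  # "approximately"
    assert typed["deep"].distance_mm == 3.0


def test_conflicting_mentions_resolve_to_involved_with_flag():
    text = (
        "MICROSCOPY: The peripheral margin is 2.0 mm. "
        "Tumour involves the peripheral margin.\nDIAGNOSIS: BCC.\n"
    )
    rec = extract_record(sectioned(text), ReportDocument("R1", "P1", text))
    assert rec.peripheral_involved is True
    assert rec.peripheral_margin_mm == 0.0
    assert "peripheral" in rec.conflicted_margins


# ---------------------------------------------------------------------------
# negation scope


@pytest.mark.parametrize(
    "sentence, term, polarity",
    [
        ("No perineural invasion is seen.", "perineural invasion", "negative"),
        ("Perineural invasion is present.", "perineural invasion", "positive"),
        ("Perineural invasion is not seen.", "perineural invasion", "negative"),
        ("There is no evidence of lymphovascular invasion.", "lymphovascular invasion", "negative"),
    ],
)
def test_negation_polarity(sentence, term, polarity):
    hits = apply_negation_scope(sentence, (term,))
    assert [h[1] for h in hits] == [polarity]


def test_scope_terminator_splits_clauses():
    hits = apply_negation_scope(
        "no lymphovascular invasion but perineural invasion is noted",
        ("lymphovascular invasion", "perineural invasion"),
    )
    polarity = {term: pol for term, pol, *_ in hits}
    assert polarity == {
        "lymphovascular invasion": "negative",
        "perineural invasion": "positive",
    }


def test_empty_triggers_rejected():
    with pytest.raises(ValueError):
        apply_negation_scope("text", ())


# ---------------------------------------------------------------------------
# diagnosis / procedure / specialty


def test_conclusion_diagnosis_with_subtype():
    sr = sectioned("CONCLUSION: Nodular basal cell carcinoma, completely excised.\n")
    is_bcc, subtype, _ = detect_diagnosis(sr)
    assert (is_bcc, subtype) == (True, "nodular")


def test_negated_conclusion_diagnosis():
    sr = sectioned("CONCLUSION: no evidence of basal cell carcinoma.\n")
    is_bcc, subtype, _ = detect_diagnosis(sr)
    assert (is_bcc, subtype) == (False, None)


def test_clinical_suspicion_never_counts():
    sr = sectioned(
        "CLINICAL DETAILS: ?BCC.\nCONCLUSION: seborrhoeic keratosis, completely excised.\n"
    )
    is_bcc, subtype, _ = detect_diagnosis(sr)
    assert (is_bcc, subtype) == (False, None)


def test_micronodular_not_mistaken_for_nodular():
    sr = sectioned("CONCLUSION: Micronodular basal cell carcinoma.\n")
    assert detect_diagnosis(sr)[1] == "micronodular"


@pytest.mark.parametrize(
    "macro, expected",
    [
        ("A 4 mm punch biopsy of lesion.", True),
        ("An ellipse of skin, excision specimen.", False),
        ("Shave biopsy of skin.", True),
    ],
)
def test_procedure_vocabulary(macro, expected):
    sr = sectioned(f"MACROSCOPIC DESCRIPTION: {macro}\n")
    flag, warning, _ = detect_procedure(sr)
    assert flag is expected and not warning


def test_unstated_procedure_warns_and_defaults_to_excision():
    sr = sectioned("MICROSCOPY: Sections show tumour.\n")
    flag, warning, _ = detect_procedure(sr)
    assert flag is False and warning


@pytest.mark.parametrize(
    "header, expected",
    [
        ("Referring clinician: Mr A. B., OMFS", "oral and maxillofacial surgery"),
        ("Dept: Plastic Surgery", "plastic surgery"),
        ("Requesting clinician: Dr C. Jones (Plastics)", "plastic surgery"),
        ("Dr D. Evans, ENT", "ear nose and throat surgery"),
        ("Dept: Vascular surgery", "other"),
        ("", None),
    ],
)
def test_specialty_lexicon(header, expected):
    assert extract_specialty(header)[0] == expected


# ---------------------------------------------------------------------------
# whole-record extraction


def test_empty_report_yields_unknowns():
    doc = ReportDocument("R1", "P1", " ")
    rec = extract_record(segment_report(doc), doc)
    assert rec.is_bcc is False
    assert rec.perineural_invasion is None  # no sections: nothing assumed
    assert rec.peripheral_margin_mm is None and rec.peripheral_involved is None


def test_hedged_clearance_recorded_as_inexact():
    text = (
        "MICROSCOPY: Basal cell carcinoma. Margins appear clear.\n"
        "CONCLUSION: BCC.\n"
    )
    rec = extract_record(sectioned(text), ReportDocument("R1", "P1", text))
    assert rec.peripheral_involved is False and rec.deep_involved is False
    assert "peripheral_margin_mm" in rec.inexact_fields


def test_margin_tristate_invariants(clean_extractions):
    recs, _ = clean_extractions
    for rec in recs:
        for side in ("peripheral", "deep"):
            mm = getattr(rec, f"{side}_margin_mm")
            involved = getattr(rec, f"{side}_involved")
            if mm == 0:
                assert involved is True
            if mm is not None and mm >= 1:
                assert involved is False


def test_round_trip_exact_against_truth(clean_extractions):
    """Noise off: every extracted field equals the generating truth."""
    recs, truths = clean_extractions
    assert len(recs) >= 1000
    overall, per_field = field_accuracy(recs, truths)
    assert overall == 1.0, per_field


def test_noisy_corpus_accuracy_floor(noisy_extractions):
    recs, truths = noisy_extractions
    overall, per_field = field_accuracy(recs, truths)
    assert overall >= 0.98, per_field


def test_evidence_spans_rederive_values(clean_extractions, clean_corpus):
    """Re-reading an evidence span from the original text re-derives the
    same field value."""
    recs, _ = clean_extractions
    docs, _ = clean_corpus
    by_id = {d.report_id: d for d in docs}
    rules = default_rules()
    for rec in recs[:200]:
        text = by_id[rec.report_id].text
        for fieldname, ev in rec.evidence.items():
            snippet = text[ev.start : ev.end]
            assert snippet == ev.text
            if fieldname.endswith("_margin_mm"):
                value = getattr(rec, fieldname)
                mentions = extract_margin_mentions(snippet, rules)
                assert mentions, (fieldname, snippet)
                if value not in (None, 0.0):
                    assert any(m.distance_mm == value for m in mentions)
        for fieldname in ("perineural_invasion", "lymphovascular_invasion", "recurrent"):
            value = getattr(rec, fieldname)
            if value is not None and fieldname not in rec.assumed_absent:
                assert fieldname in rec.evidence
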