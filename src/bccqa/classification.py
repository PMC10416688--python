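"""Margin-status and clinicopathological risk classification.

Margin status follows the binary audit definition — *clear* at >= 1 mm of
histological clearance, *involved* at 0 mm — with margins in the open
interval (0, 1) mm reported as a distinct *close* category rather than
being folded into either side.  Close margins do not count as incomplete
excisions.

Risk stratification is the BAD adaptation of the NCCN guidance: a BCC is
high risk if it shows an aggressive growth pattern, perineural or
lymphovascular invasion, sits in the facial mask area, meets the regional
size threshold (>= 10 mm on cheek/forehead/scalp/neck, >= 20 mm on trunk
and extremities), or is a recurrence.  The rule table ships as an
editable data file (``data/risk_rules.yaml``).

Unknowns propagate: a record is *low* risk only when every trigger field
is known and negative; if nothing triggers but a trigger-relevant field
is unknown, the risk is *unknown* rather than silently low.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Optional

import yaml

CLEAR_THRESHOLD_MM = 1.0

#: tri-state fields use Optional[bool]; None means "unknown"
TriState = Optional[bool]

LOW, HIGH, UNKNOWN = "low", "high", "unknown"


@dataclass(frozen=True)
class MarginStatus:
    """Classified state of a single (peripheral or deep) margin."""

    status: str  # clear | involved | close | unknown
    distance_mm: float | None = None
    inexact: bool = False

    def __post_init__(self) -> None:
        if self.status not in ("clear", "involved", "close", "unknown"):
            raise ValueError(f"bad margin status {self.status!r}")


def classify_margin(
    distance_mm: float | None = None,
    wording: str | None = None,
    inexact: bool = False,
) -> MarginStatus:
    """Classify one margin from a measured distance and/or status wording.

    ``wording`` is the already-normalised verdict of the text ("clear",
    "involved" or "close", e.g. from a "less than 1 mm" mention).  When a
    distance and wording disagree the pessimistic reading (involved) wins;
    conflict flagging is the extractor's job.
    """
    if distance_mm is not None and distance_mm < 0:
        raise ValueError(f"negative margin distance {distance_mm}")
    if wording not in (None, "clear", "involved", "close"):
        raise ValueError(f"bad margin wording {wording!r}")

    if distance_mm is not None:
        if wording == "involved" and distance_mm > 0:
            return MarginStatus("involved", 0.0, inexact=True)
        if distance_mm == 0:
            return MarginStatus("involved", 0.0, inexact)
        if distance_mm >= CLEAR_THRESHOLD_MM:
            return MarginStatus("clear", distance_mm, inexact)
        return MarginStatus("close", distance_mm, inexact)
    if wording == "involved":
        return MarginStatus("involved", 0.0, inexact)
    if wording == "clear":
        return MarginStatus("clear", None, inexact)
    if wording == "close":
        return MarginStatus("close", None, True)
    return MarginStatus("unknown", None, inexact)


@dataclass(frozen=True)
class RiskRuleTable:
    aggressive_subtypes: frozenset[str]
    site_regions: dict[str, str]  # canonical site -> {mask, mid, low}
    size_thresholds_mm: dict[str, float | None]  # region -> threshold

    @classmethod
    def from_mapping(cls, raw: dict) -> "RiskRuleTable":
        return cls(
            aggressive_subtypes=frozenset(raw["aggressive_subtypes"]),
            site_regions=dict(raw["site_regions"]),
            size_thresholds_mm=dict(raw["size_thresholds_mm"]),
        )

    def site_region(self, site: str | None) -> str | None:
        return self.site_regions.get(site) if site else None


@lru_cache(maxsize=1)
def default_risk_rules() -> RiskRuleTable:
    raw = yaml.safe_load(
        resources.files("bccqa.data").joinpath("risk_rules.yaml").read_text()
    )
    return RiskRuleTable.from_mapping(raw)


def _tri(value) -> TriState:
    """Normalise yes/no/unknown encodings to Optional[bool]."""
    if value in (True, "yes"):
        return True
    if value in (False, "no"):
        return False
    if value in (None, "unknown"):
        return None
    raise ValueError(f"bad tri-state value {value!r}")


def classify_risk(rec, rules: RiskRuleTable | None = None) -> str:
    """Map a lesion record to {low, high, unknown}.

    ``rec`` is any object carrying ``is_bcc``, ``subtype``, ``site``,
    ``size_mm``, ``perineural_invasion``, ``lymphovascular_invasion`` and
    ``recurrent`` attributes (a TruthRecord or a LesionExtraction); the
    same rule table therefore serves as the single source of truth on the
    generator and pipeline sides.
    """
    if rules is None:
        rules = default_risk_rules()
    if not rec.is_bcc:
        raise ValueError("risk classification requires a confirmed BCC record")

    any_unknown = False

    subtype = rec.subtype
    if subtype is None:
        any_unknown = True
    elif subtype in rules.aggressive_subtypes:
        return HIGH

    for flag in (rec.perineural_invasion, rec.lymphovascular_invasion, rec.recurrent):
        t = _tri(flag)
        if t is True:
            return HIGH
        if t is None:
            any_unknown = True

    region = rules.site_region(rec.site)
    if rec.site is None or region is None:
        any_unknown = True
    else:
        threshold = rules.size_thresholds_mm.get(region)
        if threshold is None:  # mask area: site alone triggers
            return HIGH
        if rec.size_mm is None:
            any_unknown = True
        elif rec.size_mm >= threshold:
            return HIGH

    return UNKNOWN if any_unknown else LOW
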