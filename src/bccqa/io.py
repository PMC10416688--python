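"""JSON-lines / CSV / YAML serialisation for the pipeline stages."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from .extraction import Evidence, LesionExtraction
from .segmentation import ReportDocument
from .synthetic import GeneratorConfig, NoiseConfig, TruthRecord


def write_corpus_jsonl(docs: list[ReportDocument], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(
                json.dumps(
                    {"report_id": doc.report_id, "patient_id": doc.patient_id, "text": doc.text},
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_corpus_jsonl(path) -> list[ReportDocument]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                d = json.loads(line)
                docs.append(
                    ReportDocument(d["report_id"], d.get("patient_id", ""), d["text"])
                )
    return docs


def write_reports_dir(docs: list[ReportDocument], directory) -> None:
    """Optional one-file-per-report export."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        (directory / f"{doc.report_id}.txt").write_text(doc.text, encoding="utf-8")


def write_truth_jsonl(truths: list[TruthRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in truths:
            fh.write(json.dumps(dataclasses.asdict(t)) + "\n")


def read_truth_jsonl(path) -> list[TruthRecord]:
    truths = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                truths.append(TruthRecord(**json.loads(line)))
    return truths


def load_generator_config(path) -> GeneratorConfig:
    """YAML/JSON mirror of GeneratorConfig; the ``noise`` block maps to
    NoiseConfig."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if "noise" in raw:
        raw["noise"] = NoiseConfig(**raw["noise"])
    if "lesions_per_patient_weights" in raw:
        raw["lesions_per_patient_weights"] = {
            int(k): v for k, v in raw["lesions_per_patient_weights"].items()
        }
    return GeneratorConfig(**raw)


_TRISTATE_OUT = {True: "yes", False: "no", None: "unknown"}
_TRISTATE_IN = {"yes": True, "no": False, "unknown": None, "": None}

RECORD_COLUMNS = [
    "report_id", "patient_id", "is_bcc", "is_diagnostic_biopsy", "subtype",
    "site", "size_mm", "peripheral_margin_mm", "peripheral_involved",
    "deep_margin_mm", "deep_involved", "perineural_invasion",
    "lymphovascular_invasion", "recurrent", "specialty",
]


def records_to_dataframe(records: list[LesionExtraction]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {}
        for col in RECORD_COLUMNS:
            v = getattr(r, col)
            if col.endswith(("_involved", "_invasion", "recurrent")) or col in (
                "peripheral_involved", "deep_involved",
            ):
                row[col] = _TRISTATE_OUT.get(v, v)
            else:
                row[col] = v
        row["conflicted_margins"] = ";".join(sorted(r.conflicted_margins))
        rows.append(row)
    return pd.DataFrame(rows, columns=RECORD_COLUMNS + ["conflicted_margins"])


def dataframe_to_records(df: pd.DataFrame) -> list[LesionExtraction]:
    records = []
    for row in df.to_dict("records"):
        rec = LesionExtraction(
            report_id=str(row["report_id"]), patient_id=str(row["patient_id"])
        )
        rec.is_bcc = bool(row["is_bcc"])
        rec.is_diagnostic_biopsy = bool(row["is_diagnostic_biopsy"])
        for col in ("subtype", "site", "specialty"):
            v = row.get(col)
            setattr(rec, col, None if pd.isna(v) or v == "" else str(v))
        for col in ("size_mm", "peripheral_margin_mm", "deep_margin_mm"):
            v = row.get(col)
            setattr(rec, col, None if pd.isna(v) else float(v))
        for col in (
            "peripheral_involved", "deep_involved", "perineural_invasion",
            "lymphovascular_invasion", "recurrent",
        ):
            v = row.get(col)
            setattr(rec, col, _TRISTATE_IN.get("" if pd.isna(v) else str(v), None))
        cm = row.get("conflicted_margins")
        if isinstance(cm, str) and cm:
            rec.conflicted_margins = set(cm.split(";"))
        records.append(rec)
    return records


def write_evidence_jsonl(records: list[LesionExtraction], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(
                json.dumps(
                    {
                        "report_id": r.report_id,
                        "evidence": {
                            k: dataclasses.asdict(ev) for k, ev in r.evidence.items()
                        },
                        "assumed_absent": sorted(r.assumed_absent),
                    }
                )
                + "\n"
            )
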