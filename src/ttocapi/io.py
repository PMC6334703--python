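"""Project config I/O, REDCap-style data-dictionary CSV, and record export.

The project config is an original JSON/YAML schema (see
``project_to_dict``); the data dictionary follows the standard 18-column
REDCap layout, with radio/dropdown choices serialized as
``"1, Label A | 2, Label B"`` and the TTO parameters of a task instrument
carried in the Field Annotation of its indifference field as
``@TTO(l=…;t=…;step=…)``.  Completion-flag variable names and survey-queue
conditions are project-level settings and therefore live in the config,
not the dictionary — matching the REDCap convention.

Record export writes one row per respondent with columns in fixed project
order, so the CSV is identical no matter which order the randomized tasks
were completed in.  All CSVs are RFC 4180 (UTF-8, CRLF, quoted as needed).
"""

from __future__ import annotations

import csv
import json
import re
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import yaml

from .core_model import (
    FieldDef,
    FieldType,
    InstrumentDef,
    ProjectDef,
    SessionRecord,
    TTOParams,
    TTOTask,
    ValidationFormat,
    project_from_dict,
    project_to_dict,
)

__all__ = [
    "ExportError",
    "DATA_DICTIONARY_COLUMNS",
    "load_project",
    "save_project",
    "write_data_dictionary",
    "read_data_dictionary",
    "export_records",
    "write_transcript",
]


class ExportError(ValueError):
    pass


# -- project config --------------------------------------------------------

def load_project(path: Union[str, Path]) -> ProjectDef:
    """Load a project from a ``.json``/``.yaml``/``.yml`` config file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    project = project_from_dict(data)
    project.validate()
    return project


def save_project(project: ProjectDef, path: Union[str, Path]) -> None:
    path = Path(path)
    data = project_to_dict(project)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_text(
            yaml.safe_dump(data, sort_keys=False, allow_unicode=True),
            encoding="utf-8",
        )


# -- REDCap-style data dictionary -----------------------------------------

DATA_DICTIONARY_COLUMNS = (
    "Variable / Field Name",
    "Form Name",
    "Section Header",
    "Field Type",
    "Field Label",
    "Choices, Calculations, OR Slider Labels",
    "Field Note",
    "Text Validation Type OR Show Slider Number",
    "Text Validation Min",
    "Text Validation Max",
    "Identifier?",
    "Branching Logic",
    "Required Field?",
    "Custom Alignment",
    "Question Number",
    "Matrix Group Name",
    "Matrix Ranking?",
    "Field Annotation",
)

_VALIDATION_OUT = {
    ValidationFormat.INTEGER: "integer",
    ValidationFormat.NUMBER: "number",
    ValidationFormat.EMAIL: "email",
    ValidationFormat.DATE: "date_ymd",
}
_VALIDATION_IN = {v: k for k, v in _VALIDATION_OUT.items()}

_TTO_ANNOTATION_RE = re.compile(
    r"@TTO\(l=(?P<l>[\d.]+);t=(?P<t>[\d.]+);step=(?P<step>[\d.]+)\)"
)


def _choices_out(choices: Mapping[str, str]) -> str:
    return " | ".join(f"{code}, {label}" for code, label in choices.items())


def _choices_in(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.split("|"):
        code, _, label = part.strip().partition(",")
        out[code.strip()] = label.strip()
    return out


def _num_out(x: Optional[float]) -> str:
    if x is None:
        return ""
    return f"{x:g}"


def write_data_dictionary(project: ProjectDef, path: Union[str, Path]) -> None:
    """Write the project's data dictionary CSV, one row per field."""
    rows = []
    for inst in project.instruments:
        for f in inst.fields:
            annotation = ""
            if inst.tto_task is not None and f.name.endswith("_tto_indifference"):
                p = inst.tto_task.params
                annotation = (
                    f"@TTO(l={p.lead_time_l:g};t={p.disease_time_t:g};"
                    f"step={p.grid_step:g})"
                )
            choices_col = ""
            if f.field_type is FieldType.CALC:
                choices_col = f.calc_expression or ""
            elif f.choices:
                choices_col = _choices_out(f.choices)
            rows.append(
                {
                    "Variable / Field Name": f.name,
                    "Form Name": inst.name,
                    "Section Header": f.section_header,
                    "Field Type": f.field_type.value,
                    "Field Label": f.label,
                    "Choices, Calculations, OR Slider Labels": choices_col,
                    "Field Note": f.note,
                    "Text Validation Type OR Show Slider Number": (
                        _VALIDATION_OUT.get(f.validation_format, "")
                        if f.validation_format
                        else ""
                    ),
                    "Text Validation Min": _num_out(f.validation_min),
                    "Text Validation Max": _num_out(f.validation_max),
                    "Identifier?": "",
                    "Branching Logic": "",
                    "Required Field?": "y" if f.required else "",
                    "Custom Alignment": "",
                    "Question Number": "",
                    "Matrix Group Name": "",
                    "Matrix Ranking?": "",
                    "Field Annotation": annotation,
                }
            )
    _write_csv(path, DATA_DICTIONARY_COLUMNS, rows)


def _num_in(text: str) -> Optional[float]:
    return float(text) if text.strip() else None


def read_data_dictionary(
    path: Union[str, Path],
    *,
    name: str = "tto_project",
    randomization_var: str = "mod6",
    queue_conditions: Optional[Mapping[str, str]] = None,
    completion_flags: Optional[Mapping[str, str]] = None,
    labels: Optional[Mapping[str, str]] = None,
) -> ProjectDef:
    """Reconstruct a project from a data dictionary CSV.

    The dictionary carries the instrument/field layer (plus TTO parameters
    via the ``@TTO`` annotation); flag variable names, instrument labels
    and queue conditions are project-level settings supplied through the
    keyword arguments, defaulting to ``{form}_complete`` / title-cased
    names / no conditions.
    """
    queue_conditions = dict(queue_conditions or {})
    completion_flags = dict(completion_flags or {})
    labels = dict(labels or {})

    forms: dict[str, list[FieldDef]] = {}
    tto_params: dict[str, TTOParams] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            form = row["Form Name"]
            ftype = FieldType(row["Field Type"])
            choices_col = row["Choices, Calculations, OR Slider Labels"]
            vtype = row["Text Validation Type OR Show Slider Number"].strip()
            m = _TTO_ANNOTATION_RE.search(row.get("Field Annotation", ""))
            if m:
                tto_params[form] = TTOParams(
                    lead_time_l=float(m.group("l")),
                    disease_time_t=float(m.group("t")),
                    grid_step=float(m.group("step")),
                )
            forms.setdefault(form, []).append(
                FieldDef(
                    name=row["Variable / Field Name"],
                    field_type=ftype,
                    label=row["Field Label"],
                    choices=(
                        _choices_in(choices_col)
                        if ftype in (FieldType.RADIO, FieldType.DROPDOWN) and choices_col
                        else None
                    ),
                    calc_expression=choices_col if ftype is FieldType.CALC else None,
                    validation_format=_VALIDATION_IN.get(vtype),
                    validation_min=_num_in(row["Text Validation Min"]),
                    validation_max=_num_in(row["Text Validation Max"]),
                    section_header=row["Section Header"],
                    note=row["Field Note"],
                    required=row["Required Field?"].strip().lower() == "y",
                )
            )

    instruments = []
    for form, fields in forms.items():
        label = labels.get(form, "")
        tto = None
        if form in tto_params:
            tto = TTOTask(
                health_state=label or form.replace("_", " ").title(),
                params=tto_params[form],
            )
        instruments.append(
            InstrumentDef(
                name=form,
                label=label,
                fields=tuple(fields),
                completion_flag_var=completion_flags.get(form, f"{form}_complete"),
                tto_task=tto,
            )
        )
    return ProjectDef(
        name=name,
        instruments=tuple(instruments),
        randomization_var=randomization_var,
        queue_conditions=queue_conditions,
    )


# -- record export ---------------------------------------------------------

def _record_columns(
    project: ProjectDef, instruments: Sequence[InstrumentDef]
) -> list[str]:
    cols = ["record_id", project.randomization_var]
    for inst in instruments:
        for f in inst.fields:
            if f.stores_data and f.name != project.randomization_var:
                cols.append(f.name)
        cols.append(inst.completion_flag_var)
        if inst.tto_task is not None:
            cols.append(f"{inst.name}_termination")
            cols.append(f"{inst.name}_flags")
    return cols


def export_records(
    project: ProjectDef,
    records: Iterable[SessionRecord],
    path: Union[str, Path],
    *,
    instruments: Optional[Sequence[str]] = None,
) -> None:
    """Write one CSV row per record, columns in fixed project order.

    The layout never depends on the order tasks were completed in, so
    exports from differently randomized sessions align column for column.
    ``instruments`` restricts the export to named instruments (the
    per-instrument export option); ``record_id`` and the randomization
    draw are always included.  Duplicate record ids are an error.
    """
    if instruments is None:
        selected = list(project.instruments)
    else:
        selected = [project.instrument(n) for n in instruments]
    cols = _record_columns(project, selected)

    rows = []
    seen: set[str] = set()
    for rec in records:
        if rec.record_id in seen:
            raise ExportError(f"duplicate record_id {rec.record_id!r}")
        seen.add(rec.record_id)
        row: dict[str, object] = {
            "record_id": rec.record_id,
            project.randomization_var: "" if rec.mod6 is None else rec.mod6,
        }
        for inst in selected:
            for f in inst.fields:
                if f.stores_data and f.name != project.randomization_var:
                    row[f.name] = rec.field_values.get(f.name, "")
            row[inst.completion_flag_var] = rec.completion_flags.get(inst.name, 0)
            if inst.tto_task is not None:
                res = rec.utilities.get(inst.name)
                row[f"{inst.name}_termination"] = (
                    res.termination_reason.value if res else ""
                )
                row[f"{inst.name}_flags"] = ";".join(res.flags) if res else ""
        rows.append(row)
    _write_csv(path, cols, rows)


def write_transcript(
    transcript: Sequence[Mapping[str, object]], path: Union[str, Path]
) -> None:
    """Audit CSV of one interview: iteration, presented duration, choice,
    ISO-8601 UTC timestamp."""
    _write_csv(path, ("iteration", "a", "choice", "timestamp"), transcript)


def _write_csv(
    path: Union[str, Path],
    columns: Sequence[str],
    rows: Iterable[Mapping[str, object]],
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(columns))
        writer.writeheader()
        for row in rows:
            writer.writerow({c: row.get(c, "") for c in columns})
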