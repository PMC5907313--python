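"""Model-document reader/writer and deterministic result tables."""

from __future__ import annotations

import json
import os

from .document import ModelDocument
from .errors import ModelValidationError
from .mca import DEFAULT_INCREMENTS, SexComparisonTable

__all__ = ["read_model", "write_model", "write_table", "records_to_rows"]


def read_model(path) -> ModelDocument:
    """Read and fully validate a model-document JSON file."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelValidationError(f"cannot parse model file {path!r}: {exc}") from exc
    except OSError as exc:
        raise ModelValidationError(f"cannot read model file {path!r}: {exc}") from exc
    try:
        doc = ModelDocument.from_dict(data)
    except (KeyError, TypeError) as exc:
        raise ModelValidationError(
            f"model file {path!r} does not match the document schema: {exc}"
        ) from exc
    doc.validate()
    return doc


def write_model(doc: ModelDocument, path) -> None:
    text = json.dumps(doc.to_dict(), indent=1)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(text + "\n")


def _fmt(value):
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def records_to_rows(records):
    """TSV rows for a list of sensitivity records (sorted order preserved)."""
    cols = ["parameter_id", "output_id", "sex"]
    cols += [f"C_{int(p)}" for p in DEFAULT_INCREMENTS]
    cols += ["headline", "aggregate_mean", "aggregate_max", "rank"]
    rows = [cols]
    for rank, r in enumerate(records, start=1):
        row = [r.parameter_id, r.output_id, r.sex]
        row += [
            _fmt(r.per_increment[p]) if p in r.per_increment else "NA"
            for p in DEFAULT_INCREMENTS
        ]
        row += [_fmt(r.headline), _fmt(r.aggregate_mean), _fmt(r.aggregate_max), str(rank)]
        rows.append(row)
    return rows


def comparison_to_rows(table: SexComparisonTable):
    rows = [["parameter_id", "C_male", "C_female", "abs_difference", "rank"]]
    for rank, (pid, cm, cf, diff) in enumerate(table.rows, start=1):
        rows.append([pid, _fmt(cm), _fmt(cf), _fmt(diff), str(rank)])
    return rows


def write_table(rows, path, allow_empty: bool = False, json_mirror: bool = False) -> None:
    """Write rows (first row = header) as a deterministic UTF-8 TSV file.

    Floating-point cells are pre-formatted at 6 significant digits by the
    row builders; identical inputs yield byte-identical files.
    """
    body = [r for r in rows[1:]] if rows else []
    if not body and not allow_empty:
        raise ValueError("refusing to write an empty table (pass allow_empty=True)")
    text = "\n".join("\t".join(row) for row in rows) + "\n"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(text)
    if json_mirror:
        header, *data = rows
        mirror = [dict(zip(header, row)) for row in data]
        jpath = os.fspath(path) + ".json"
        with open(jpath, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(mirror, fh, indent=1)
            fh.write("\n")
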