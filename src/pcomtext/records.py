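"""Readers and writers for report, prediction and truth files.

Reports travel as UTF-8 tab-delimited text: either a table with a
``report_id[\\tpatient_id]\\ttext`` header, or headerless two-column
``report_id\\ttext`` lines. Output files carry ``#``-prefixed metadata
header lines (package version, seed, config hash) so a run can be
reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from .textprep import RawReport

__all__ = [
    "read_reports",
    "write_reports",
    "read_predictions",
    "metadata_header",
]


def read_reports(path: str | Path) -> list[RawReport]:
    """Read a report file (tab-delimited, with or without header)."""
    lines = [
        ln
        for ln in Path(path).read_text(encoding="utf-8").splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        return []
    header: list[str] | None = None
    first = lines[0].split("\t")
    if first[0].strip().lower() == "report_id":
        header = [c.strip().lower() for c in first]
        lines = lines[1:]
    reports: list[RawReport] = []
    for ln in lines:
        parts = ln.split("\t")
        if header:
            row = dict(zip(header, parts))
            reports.append(
                RawReport(
                    report_id=row.get("report_id", ""),
                    patient_id=row.get("patient_id") or None,
                    text=row.get("text", ""),
                )
            )
        else:
            rid, text = (parts + [""])[:2] if len(parts) < 2 else (parts[0], "\t".join(parts[1:]))
            reports.append(RawReport(report_id=rid, text=text))
    return reports


def write_reports(path: str | Path, reports: list[RawReport], header: str = "") -> None:
    out = [header] if header else []
    out.append("report_id\ttext")
    flat = lambda t: " ".join(t.split())  # noqa: E731 - keep records one line
    out += [f"{r.report_id}\t{flat(r.text)}" for r in reports]
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def read_predictions(path: str | Path, label_col: str = "overall_label") -> dict[str, str]:
    """Map report_id -> label from a predictions TSV."""
    lines = [
        ln
        for ln in Path(path).read_text(encoding="utf-8").splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ValueError(f"no records in {path}")
    header = lines[0].split("\t")
    try:
        id_idx = header.index("report_id")
        lab_idx = header.index(label_col)
    except ValueError as exc:
        raise ValueError(f"missing column in {path}: {exc}") from exc
    out: dict[str, str] = {}
    for ln in lines[1:]:
        parts = ln.split("\t")
        out[parts[id_idx]] = parts[lab_idx]
    return out


def metadata_header(seed: int | None, config: dict) -> str:
    """'#'-prefixed metadata lines identifying an output artifact."""
    from . import __version__

    digest = hashlib.sha1(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    return (
        f"# pcomtext {__version__}\n# seed: {seed}\n# config_hash: {digest}"
    )
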