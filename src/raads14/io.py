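"""CSV input/output and run manifests.

Responses travel as CSV with header ``subject_id,group,item_1..item_k``;
cells hold category labels or 0-3 codes (auto-detected per cell), an empty
cell is a missing answer. Score output mirrors the screen's reporting
columns. Every CLI run writes a manifest (command, parameters, seed, input
digests, version) so outputs can be reproduced byte-identically.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from typing import Optional, Sequence

from .errors import FormatError, UsageError
from .instrument import InstrumentDefinition, ResponseRecord, ScoreReport

__all__ = [
    "read_responses",
    "write_responses",
    "write_scores",
    "RunManifest",
    "write_manifest",
]

_SUBSCALE_COLUMNS = {
    "mentalizing_deficits": "mentalizing",
    "social_anxiety": "social_anxiety",
    "sensory_reactivity": "sensory",
}


def _item_columns(n: int) -> list[str]:
    return [f"item_{i}" for i in range(1, n + 1)]


def read_responses(
    path, instrument: InstrumentDefinition
) -> tuple[list[ResponseRecord], list[tuple[int, str]]]:
    """Parse a responses CSV.

    Returns ``(records, problems)`` where problems lists ``(line_number,
    message)`` for rejected rows (unknown categories, wrong cell counts);
    well-formed rows are still loaded. A malformed header raises
    :class:`FormatError` naming the missing columns.
    """
    want = ["subject_id", "group"] + _item_columns(instrument.n_items)
    records: list[ResponseRecord] = []
    problems: list[tuple[int, str]] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        missing_cols = [c for c in want if c not in header]
        if missing_cols:
            raise FormatError(f"{path}: header missing columns {missing_cols}")
        pos = {c: header.index(c) for c in want}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < len(header):
                problems.append((lineno, f"expected {len(header)} cells, got {len(row)}"))
                continue
            answers: dict[int, Optional[str]] = {}
            bad = None
            for it in instrument.items:
                cell = row[pos[f"item_{it.item_id}"]].strip()
                if cell == "":
                    answers[it.item_id] = None
                    continue
                try:
                    instrument.forward_score(cell)
                except FormatError as exc:
                    bad = str(exc)
                    break
                answers[it.item_id] = cell
            if bad is not None:
                problems.append((lineno, bad))
                continue
            records.append(
                ResponseRecord(
                    subject_id=row[pos["subject_id"]],
                    group=row[pos["group"]],
                    answers=answers,
                )
            )
    return records, problems


def write_responses(
    records: Sequence[ResponseRecord], instrument: InstrumentDefinition, path
) -> None:
    """Write records as a responses CSV (labels as stored; missing = empty)."""
    cols = ["subject_id", "group"] + _item_columns(instrument.n_items)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for rec in records:
            row = [rec.subject_id, rec.group]
            for it in instrument.items:
                ans = rec.answers.get(it.item_id)
                row.append("" if ans is None else str(ans))
            w.writerow(row)


def write_scores(reports: Sequence[ScoreReport], path) -> None:
    """Write score reports as CSV with the screen's reporting columns."""
    if not reports:
        raise UsageError("no score reports to write")
    sub_names = list(reports[0].subscale_scores)
    sub_cols = [_SUBSCALE_COLUMNS.get(s, s) for s in sub_names]
    cols = (
        ["subject_id", "group", "total"]
        + sub_cols
        + ["short_form", "screen_positive", "short_form_positive", "n_missing",
           "valid", "invalid_reason"]
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for r in reports:
            w.writerow(
                [r.subject_id, r.group, r.total]
                + [r.subscale_scores[s] for s in sub_names]
                + [
                    r.short_form,
                    r.screen_positive,
                    r.short_form_positive,
                    r.n_missing,
                    r.valid,
                    r.invalid_reason or "",
                ]
            )


@dataclass
class RunManifest:
    """Provenance of one CLI run."""

    command: str
    parameters: dict
    seed: Optional[int]
    inputs: dict = field(default_factory=dict)  # path -> sha256
    version: str = ""
    timestamp: str = ""


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path,
    command: str,
    parameters: dict,
    seed: Optional[int] = None,
    inputs: Sequence = (),
) -> RunManifest:
    from . import __version__

    manifest = RunManifest(
        command=command,
        parameters={k: v for k, v in sorted(parameters.items())},
        seed=seed,
        inputs={str(p): _sha256(p) for p in inputs},
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(asdict(manifest), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
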