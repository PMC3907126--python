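"""Likert instrument definition, scoring, and record-validity rules.

An :class:`InstrumentDefinition` describes an ordered bank of Likert items —
each with a 4-category duration response scale scored 0-3, an optional
reverse flag, and domain/subscale metadata — together with the screening
cut-offs. The bundled definition (``raads14()``) is the RAADS-14 Screen: a
14-item self-report autism-spectrum screen abridged from the 80-item
RAADS-R, with one reverse-phrased item (item 6), three subscales
(mentalizing deficits, social anxiety, sensory reactivity: 7/4/3 items),
a total-score cut-off of 14/42 and a short-form (items 1-5) cut-off of 4/15.

Scoring conventions
-------------------
* Forward items score 0 ("never true") to 3 ("true now and when I was
  young"); reverse-phrased items score ``3 - forward``.
* Missing answers score 0 by default and are counted in ``n_missing``;
  a prorated total is available as an explicit option.
* A record is invalid when more than ``max_missing`` items are missing, or
  when every answered item carries the same category while the instrument
  contains a reverse-phrased item (straight-lining).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache as _lru_cache
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import FormatError, UsageError

__all__ = [
    "GROUP_ASD",
    "GROUP_ADHD",
    "GROUP_OPD",
    "GROUP_NONPSYCH",
    "ItemDefinition",
    "InstrumentDefinition",
    "ResponseRecord",
    "ScoreReport",
    "CohortResult",
    "raads14",
    "score_item",
    "score_record",
    "validate_record",
    "batch_score",
    "score_matrix",
]

# Canonical diagnostic group labels; free labels are carried through untouched.
GROUP_ASD = "ASD"
GROUP_ADHD = "ADHD"
GROUP_OPD = "OPD"  # other psychiatric disorders (no ASD/ADHD)
GROUP_NONPSYCH = "NONPSYCH"

# RAADS-R domains and RAADS-14 subscales (plain strings so that arbitrary
# instruments/banks can use their own vocabularies).
DOMAIN_SOCIAL = "social_relatedness"
DOMAIN_CIRCUMSCRIBED = "circumscribed_interests"
DOMAIN_LANGUAGE = "language"
DOMAIN_SENSORY = "sensory_motor"

SUBSCALE_MENTALIZING = "mentalizing_deficits"
SUBSCALE_SOCIAL_ANXIETY = "social_anxiety"
SUBSCALE_SENSORY = "sensory_reactivity"

_WS = re.compile(r"\s+")


def _norm_label(label: str) -> str:
    return _WS.sub(" ", label.strip()).lower()


class ItemDefinition(BaseModel):
    """One Likert item: position, text, reverse flag and scale metadata."""

    item_id: int = Field(gt=0)
    text: str
    reversed: bool = False
    original_domain: Optional[str] = None
    subscale: Optional[str] = None
    short_form: bool = False


class InstrumentDefinition(BaseModel):
    """An ordered Likert instrument with its scoring scheme and cut-offs."""

    name: str
    items: list[ItemDefinition]
    categories: list[str]
    forward_scores: dict[str, int]
    screen_cutoff: int = 14
    short_form_cutoff: int = 4
    max_missing: int = 4

    @field_validator("items")
    @classmethod
    def _ids_contiguous(cls, items: list[ItemDefinition]) -> list[ItemDefinition]:
        ids = [it.item_id for it in items]
        if ids != list(range(1, len(items) + 1)):
            raise ValueError("item ids must be unique and contiguous from 1")
        return items

    @model_validator(mode="after")
    def _scores_bijective(self) -> "InstrumentDefinition":
        if sorted(self.forward_scores.values()) != [0, 1, 2, 3]:
            raise ValueError("forward_scores must be a bijection onto {0,1,2,3}")
        if sorted(map(_norm_label, self.forward_scores)) != sorted(
            map(_norm_label, self.categories)
        ):
            raise ValueError("forward_scores keys must match the category labels")
        return self

    # -- derived structure -------------------------------------------------

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def max_total(self) -> int:
        return 3 * self.n_items

    @property
    def max_short_form(self) -> int:
        return 3 * sum(it.short_form for it in self.items)

    @property
    def subscales(self) -> dict[str, list[int]]:
        """Subscale name -> item ids, in first-appearance order."""
        out: dict[str, list[int]] = {}
        for it in self.items:
            key = it.subscale if it.subscale is not None else "unassigned"
            out.setdefault(key, []).append(it.item_id)
        return out

    def subscale_max(self, subscale: str) -> int:
        return 3 * len(self.subscales.get(subscale, []))

    @property
    def item_by_id(self) -> dict[int, ItemDefinition]:
        return {it.item_id: it for it in self.items}

    def _norm_map(self) -> dict[str, int]:
        m = {_norm_label(k): v for k, v in self.forward_scores.items()}
        # numeric dialect: the codes 0-3 are accepted directly
        for v in range(4):
            m.setdefault(str(v), v)
        return m

    def forward_score(self, category: str) -> int:
        """Forward (unreversed) 0-3 score for a category label or 0-3 code."""
        m = self._norm_map()
        key = _norm_label(str(category))
        if key not in m:
            raise FormatError(f"unknown response category: {category!r}")
        return m[key]

    def category_for_score(self, score: int) -> str:
        """The category label whose forward score is ``score``."""
        for k, v in self.forward_scores.items():
            if v == score:
                return k
        raise UsageError(f"no category with forward score {score}")

    # -- serialization -----------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "InstrumentDefinition":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        try:
            return cls.model_validate(doc)
        except Exception as exc:  # pydantic ValidationError
            raise FormatError(f"bad instrument definition {path}: {exc}") from exc

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False, allow_unicode=True)


@dataclass
class ResponseRecord:
    """One subject's answers, keyed by item id; missing answers are absent
    keys or ``None``/empty strings."""

    subject_id: str
    group: str
    answers: dict[int, Optional[str]]
    sex: Optional[str] = None
    age: Optional[float] = None


@dataclass
class ScoreReport:
    """Scored totals, subscale sums, screen classification and validity."""

    subject_id: str
    group: str
    total: int
    subscale_scores: dict[str, int]
    short_form: int
    screen_positive: bool
    short_form_positive: bool
    n_missing: int
    valid: bool
    invalid_reason: Optional[str] = None  # "too_many_missing" | "straight_line"
    prorated_total: Optional[float] = None


@_lru_cache(maxsize=1)
def _bundled_doc() -> str:
    ref = resources.files("raads14").joinpath("data/raads14.yaml")
    return ref.read_text(encoding="utf-8")


def raads14() -> InstrumentDefinition:
    """The bundled RAADS-14 Screen definition (items, reverse flag,
    subscales, cut-offs 14 and 4). Each call returns a fresh instance."""
    return InstrumentDefinition.model_validate(yaml.safe_load(_bundled_doc()))


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def score_item(
    category: Optional[str], reversed: bool, instrument: InstrumentDefinition
) -> int:
    """Score one answer 0-3. Reverse-phrased items return ``3 - forward``;
    a missing answer scores 0 (the conservative default — callers count
    missingness separately)."""
    if _is_missing(category):
        return 0
    fwd = instrument.forward_score(category)
    return 3 - fwd if reversed else fwd


def validate_record(
    record: ResponseRecord, instrument: InstrumentDefinition
) -> tuple[bool, Optional[str]]:
    """Apply the record-validity filters.

    Returns ``(valid, reason)`` where reason is ``"too_many_missing"`` when
    more than ``max_missing`` items are unanswered, ``"straight_line"`` when
    every answered item (>= 2 of them) carries one identical category and the
    instrument has a reverse-phrased item, else ``None``.
    """
    answered = [
        record.answers[it.item_id]
        for it in instrument.items
        if not _is_missing(record.answers.get(it.item_id))
    ]
    n_missing = instrument.n_items - len(answered)
    if n_missing > instrument.max_missing:
        return False, "too_many_missing"
    has_reversed = any(it.reversed for it in instrument.items)
    if has_reversed and len(answered) >= 2:
        # compare on the forward score so label/code dialects cannot hide a
        # straight-liner
        scores = {instrument.forward_score(a) for a in answered}
        if len(scores) == 1:
            return False, "straight_line"
    return True, None


def score_record(
    record: ResponseRecord,
    instrument: InstrumentDefinition,
    missing: str = "zero",
) -> ScoreReport:
    """Score one record against the instrument.

    ``missing="zero"`` (default) scores unanswered items 0; ``"prorate"``
    additionally reports a prorated total scaled up by
    ``n_items / n_answered`` (rounded). Validity is always evaluated and
    reported; invalid records are still scored so callers can inspect them.
    """
    if missing not in ("zero", "prorate"):
        raise UsageError(f"unknown missing policy: {missing!r}")
    item_scores: dict[int, int] = {}
    n_missing = 0
    for it in instrument.items:
        ans = record.answers.get(it.item_id)
        if _is_missing(ans):
            n_missing += 1
            item_scores[it.item_id] = 0
        else:
            item_scores[it.item_id] = score_item(ans, it.reversed, instrument)

    total = sum(item_scores.values())
    sub: dict[str, int] = {}
    for name, ids in instrument.subscales.items():
        sub[name] = sum(item_scores[i] for i in ids)
    short = sum(item_scores[it.item_id] for it in instrument.items if it.short_form)

    prorated = None
    if missing == "prorate" and n_missing:
        n_ans = instrument.n_items - n_missing
        if n_ans == 0:
            raise UsageError("cannot prorate a fully missing record")
        prorated = round(total * instrument.n_items / n_ans, 1)

    valid, reason = validate_record(record, instrument)
    return ScoreReport(
        subject_id=record.subject_id,
        group=record.group,
        total=total,
        subscale_scores=sub,
        short_form=short,
        screen_positive=total >= instrument.screen_cutoff,
        short_form_positive=short >= instrument.short_form_cutoff,
        n_missing=n_missing,
        valid=valid,
        invalid_reason=reason,
        prorated_total=prorated,
    )


@dataclass
class CohortResult:
    """All score reports plus per-group summary statistics over valid records."""

    reports: list[ScoreReport]
    summary: pd.DataFrame  # index: group; columns: n, mean, sd, median, min, max
    invalid: list[ScoreReport] = field(default_factory=list)

    @property
    def valid_reports(self) -> list[ScoreReport]:
        return [r for r in self.reports if r.valid]


def batch_score(
    cohort: Sequence[ResponseRecord],
    instrument: InstrumentDefinition,
    missing: str = "zero",
) -> CohortResult:
    """Score a cohort and summarize totals per group over valid records only."""
    if len(cohort) == 0:
        raise UsageError("empty cohort")
    reports = [score_record(rec, instrument, missing=missing) for rec in cohort]
    valid = [r for r in reports if r.valid]
    invalid = [r for r in reports if not r.valid]
    if valid:
        df = pd.DataFrame({"group": [r.group for r in valid], "total": [r.total for r in valid]})
        summary = df.groupby("group")["total"].agg(
            n="count", mean="mean", sd="std", median="median", min="min", max="max"
        )
    else:
        summary = pd.DataFrame(columns=["n", "mean", "sd", "median", "min", "max"])
    return CohortResult(reports=reports, summary=summary, invalid=invalid)


def score_matrix(
    cohort: Iterable[ResponseRecord],
    instrument: InstrumentDefinition,
    valid_only: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-item score matrix (subjects x item ids) and the group labels.

    Missing answers score 0, matching :func:`score_record`'s default.
    """
    rows, groups, index = [], [], []
    for rec in cohort:
        if valid_only and not validate_record(rec, instrument)[0]:
            continue
        row = [
            score_item(rec.answers.get(it.item_id), it.reversed, instrument)
            for it in instrument.items
        ]
        rows.append(row)
        groups.append(rec.group)
        index.append(rec.subject_id)
    cols = [it.item_id for it in instrument.items]
    mat = pd.DataFrame(rows, columns=cols, index=index)
    return mat, pd.Series(groups, index=index, name="group")
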