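"""Shared domain types for the drug-labeling extraction pipeline.

The pipeline integrates four public drug-product resources (Orange Book,
Drugs@FDA, DailyMed, DrugBank) around a single identifier — the six-digit FDA
application number — and extracts twelve labeling sections that matter for
product-specific guidance assessment: boxed warning, indication, dosage and
administration, pregnancy, lactation, mechanism of action, pharmacodynamics,
and the five pharmacokinetics subsections (absorption, distribution,
metabolism, excretion, food effect — "ADMEF").

This module holds the closed vocabularies, the document/paragraph records that
every other module exchanges, text normalization, and JSON Lines
serialization.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Union


class SectionKind(str, Enum):
    """The twelve target labeling sections plus the pharmacokinetics parent.

    ``pharmacokinetics`` is extracted only so it can be split into its five
    ADMEF subsections; the remaining twelve members are the target sections.
    """

    boxed_warning = "boxed_warning"
    indication = "indication"
    dosage_admin = "dosage_admin"
    pregnancy = "pregnancy"
    lactation = "lactation"
    mechanism_of_action = "mechanism_of_action"
    pharmacodynamics = "pharmacodynamics"
    pharmacokinetics = "pharmacokinetics"
    absorption = "absorption"
    distribution = "distribution"
    metabolism = "metabolism"
    excretion = "excretion"
    food_effect = "food_effect"


#: Pharmacokinetics subsections, in ADMEF order.
ADMEF_SECTIONS: tuple[SectionKind, ...] = (
    SectionKind.absorption,
    SectionKind.distribution,
    SectionKind.metabolism,
    SectionKind.excretion,
    SectionKind.food_effect,
)

#: The 12 sections reported on (everything except the pharmacokinetics parent).
TARGET_SECTIONS: tuple[SectionKind, ...] = tuple(
    k for k in SectionKind if k is not SectionKind.pharmacokinetics
)


class SourceName(str, Enum):
    """The four data resources the pipeline integrates."""

    orange_book = "orange_book"
    drugs_at_fda = "drugs_at_fda"
    dailymed = "dailymed"
    drugbank = "drugbank"


_APP_PREFIX_RE = re.compile(r"^\s*(ANDA|NDA|A|N)\s*", re.IGNORECASE)
_DIGITS_RE = re.compile(r"[0-9]+")


@dataclass(frozen=True, order=True)
class AppNumber:
    """A six-digit, zero-padded FDA application number.

    ``app_type`` records whether the number arrived with an NDA/ANDA prefix;
    the bare six digits are what joins records across sources.
    """

    value: str
    app_type: str = "unknown"

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[0-9]{6}", self.value):
            raise ValueError(f"application number must be 6 digits, got {self.value!r}")
        if self.app_type not in ("NDA", "ANDA", "unknown"):
            raise ValueError(f"unknown application type {self.app_type!r}")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.value


def normalize_app_number(raw: str) -> AppNumber:
    """Canonicalize an application-number string to :class:`AppNumber`.

    Accepts optional ``NDA``/``ANDA``/``N``/``A`` prefixes (any case) and
    digit strings of 1–6 digits, which are left-padded with zeros. Raises
    ``ValueError`` on strings with no digits or more than six digits.
    Idempotent: feeding back ``.value`` returns an equal number (type
    ``unknown``, which compares equal on ``value``).
    """
    if raw is None:
        raise ValueError("application number is None")
    s = str(raw).strip()
    app_type = "unknown"
    m = _APP_PREFIX_RE.match(s)
    if m:
        prefix = m.group(1).upper()
        app_type = "ANDA" if prefix in ("ANDA", "A") else "NDA"
        s = s[m.end():]
    digits = "".join(_DIGITS_RE.findall(s))
    if not digits:
        raise ValueError(f"no digits in application number {raw!r}")
    if len(digits) > 6:
        raise ValueError(f"application number {raw!r} has more than 6 digits")
    return AppNumber(value=digits.zfill(6), app_type=app_type)


_HSPACE_RE = re.compile(r"[ \t\f\v]+")


def normalize_text(raw: str) -> str:
    """Whitespace-normalize label text.

    CRLF becomes LF, runs of horizontal whitespace collapse to one space,
    every line is trimmed, and runs of blank lines collapse to exactly one
    blank line (the paragraph separator). Leading/trailing blank lines are
    dropped. Idempotent.
    """
    if not raw:
        return ""
    text = raw.replace("\r\n", "\n").replace("\r", "\n")
    lines = [_HSPACE_RE.sub(" ", ln).strip() for ln in text.split("\n")]
    out: list[str] = []
    for ln in lines:
        if ln == "" and (not out or out[-1] == ""):
            continue
        out.append(ln)
    while out and out[-1] == "":
        out.pop()
    return "\n".join(out)


def split_paragraphs(text: str) -> list[str]:
    """Split normalized text into paragraphs on blank lines.

    Never returns empty paragraphs; joining the result with ``"\\n\\n"``
    round-trips to the (normalized) input.
    """
    if not text:
        return []
    return [p for p in (chunk.strip() for chunk in text.split("\n\n")) if p]


def join_paragraphs(paragraphs: Iterable[str]) -> str:
    return "\n\n".join(paragraphs)


def parse_label_date(raw: Optional[str]) -> Optional[_dt.date]:
    """Parse an effective date in SPL ``YYYYMMDD`` or ISO ``YYYY-MM-DD`` form."""
    if raw is None:
        return None
    s = str(raw).strip()
    for fmt in ("%Y%m%d", "%Y-%m-%d"):
        try:
            return _dt.datetime.strptime(s, fmt).date()
        except ValueError:
            continue
    return None


@dataclass
class LabelDocument:
    """One labeling document from one source.

    ``native_id`` is the source's own identifier (Set ID for DailyMed,
    DrugBank-ID for DrugBank, filename stem for free-text labels).
    ``sections`` stores whitespace-normalized text keyed by
    :class:`SectionKind`; an absent section is an absent key.
    """

    source: SourceName
    native_id: str
    app_numbers: list[AppNumber] = field(default_factory=list)
    effective_date: Optional[_dt.date] = None
    version: Optional[int] = None
    sections: dict[SectionKind, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.native_id:
            raise ValueError("native_id must be non-empty")

    @property
    def is_unmapped(self) -> bool:
        return not self.app_numbers

    def to_dict(self) -> dict:
        return {
            "source": self.source.value,
            "native_id": self.native_id,
            "app_numbers": [
                {"value": a.value, "app_type": a.app_type} for a in self.app_numbers
            ],
            "effective_date": self.effective_date.isoformat()
            if self.effective_date
            else None,
            "version": self.version,
            "sections": {k.value: v for k, v in self.sections.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LabelDocument":
        return cls(
            source=SourceName(d["source"]),
            native_id=d["native_id"],
            app_numbers=[
                AppNumber(a["value"], a.get("app_type", "unknown"))
                for a in d.get("app_numbers", [])
            ],
            effective_date=parse_label_date(d.get("effective_date")),
            version=d.get("version"),
            sections={SectionKind(k): v for k, v in d.get("sections", {}).items()},
        )


@dataclass
class LabeledParagraph:
    """A paragraph with a food-effect class label and its provenance."""

    text: str
    label: str  # "food_effect" | "non_food_effect"
    source: SourceName
    doc_ref: str
    annotation_method: str  # regex_title | regex_prefix | absorption_default | manual | model

    _LABELS = ("food_effect", "non_food_effect")
    _METHODS = ("regex_title", "regex_prefix", "absorption_default", "manual", "model")

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("paragraph text must be non-empty")
        if self.label not in self._LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.annotation_method not in self._METHODS:
            raise ValueError(f"unknown annotation method {self.annotation_method!r}")

    def to_dict(self) -> dict:
        return {
            "text": self.text,
            "label": self.label,
            "source": self.source.value,
            "doc_ref": self.doc_ref,
            "annotation_method": self.annotation_method,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LabeledParagraph":
        return cls(
            text=d["text"],
            label=d["label"],
            source=SourceName(d["source"]),
            doc_ref=d["doc_ref"],
            annotation_method=d["annotation_method"],
        )


@dataclass
class EvalReport:
    """Confusion counts and derived metrics, food_effect as positive class.

    When a denominator vanishes the corresponding metric is 0 and
    ``degenerate`` is set, so reports stay total.
    """

    tp: int
    fp: int
    fn: int
    precision: float = 0.0
    recall: float = 0.0
    f1: float = 0.0
    degenerate: bool = False

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "EvalReport":
        if min(tp, fp, fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        degenerate = False
        if tp + fp > 0:
            precision = tp / (tp + fp)
        else:
            precision, degenerate = 0.0, True
        if tp + fn > 0:
            recall = tp / (tp + fn)
        else:
            recall, degenerate = 0.0, True
        if precision + recall > 0:
            f1 = 2 * precision * recall / (precision + recall)
        else:
            f1, degenerate = 0.0, True
        return cls(tp, fp, fn, precision, recall, f1, degenerate)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "degenerate": self.degenerate,
        }


# --- JSON Lines serialization -------------------------------------------------

PathOrIO = Union[str, Path, IO[str]]


def _open_for(path_or_io: PathOrIO, mode: str):
    if isinstance(path_or_io, (str, Path)):
        return open(path_or_io, mode, encoding="utf-8"), True
    return path_or_io, False


def write_jsonl(records: Iterable, dest: PathOrIO) -> int:
    """Write records (objects with ``to_dict``) as JSON Lines; returns count."""
    fh, own = _open_for(dest, "w")
    n = 0
    try:
        for rec in records:
            d = rec.to_dict() if hasattr(rec, "to_dict") else rec
            fh.write(json.dumps(d, sort_keys=True, ensure_ascii=False) + "\n")
            n += 1
    finally:
        if own:
            fh.close()
    return n


def read_jsonl(src: PathOrIO, cls=None) -> Iterator:
    """Read JSON Lines; yields ``cls.from_dict`` objects when ``cls`` given."""
    fh, own = _open_for(src, "r")
    try:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            yield cls.from_dict(d) if cls is not None else d
    finally:
        if own:
            fh.close()
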