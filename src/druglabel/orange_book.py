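"""Orange Book products-file parsing.

The Orange Book (FDA's Approved Drug Products with Therapeutic Equivalence
Evaluations) products datafile is the reference list of currently valid
FDA-approved drugs. The pipeline only needs the set of distinct NDA
application numbers from it; that set anchors the Filter step of the
integration.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Union

from .core import AppNumber, normalize_app_number

logger = logging.getLogger(__name__)

#: Dialect of the publicly distributed products.txt: tilde-delimited.
DEFAULT_DELIMITER = "~"
DEFAULT_TYPE_COLUMN = "Appl_Type"
DEFAULT_NUMBER_COLUMN = "Appl_No"

_NDA_CODES = {"N", "NDA"}
_ANDA_CODES = {"A", "ANDA"}


@dataclass
class ReferenceSet:
    """Distinct NDA application numbers from one Orange Book snapshot."""

    app_numbers: set[AppNumber] = field(default_factory=set)
    source_version: str = ""

    def __contains__(self, item: AppNumber) -> bool:
        return AppNumber(item.value, "NDA") in self.app_numbers

    def __len__(self) -> int:
        return len(self.app_numbers)

    def to_dict(self) -> dict:
        return {
            "source_version": self.source_version,
            "app_numbers": sorted(a.value for a in self.app_numbers),
        }


def parse_products_file(
    stream: Union[str, Path, IO[str]],
    *,
    delimiter: str = DEFAULT_DELIMITER,
    type_column: str = DEFAULT_TYPE_COLUMN,
    number_column: str = DEFAULT_NUMBER_COLUMN,
    source_version: str = "",
) -> ReferenceSet:
    """Parse an Orange Book-style products file into a :class:`ReferenceSet`.

    Keeps NDA rows only ("N"/"NDA" application type), de-duplicated by
    application number; ANDA rows are excluded and rows with malformed
    numbers are skipped with a warning. Raises ``KeyError`` naming the
    missing column when the header lacks a required column.
    """
    if isinstance(stream, (str, Path)):
        fh: IO[str] = open(stream, "r", encoding="utf-8")
        own = True
    else:
        fh, own = stream, False
    try:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        if not header:
            logger.warning("Orange Book products file is empty")
            return ReferenceSet(source_version=source_version)
        for col in (type_column, number_column):
            if col not in header:
                raise KeyError(f"required column {col!r} missing from products file header")
        numbers: set[AppNumber] = set()
        for row in reader:
            app_type = (row.get(type_column) or "").strip().upper()
            if app_type in _ANDA_CODES:
                continue
            if app_type not in _NDA_CODES:
                logger.warning("skipping row with unrecognized application type %r", app_type)
                continue
            raw = (row.get(number_column) or "").strip()
            try:
                num = normalize_app_number(raw)
            except ValueError:
                logger.warning("skipping row with malformed application number %r", raw)
                continue
            numbers.add(AppNumber(num.value, "NDA"))
        return ReferenceSet(app_numbers=numbers, source_version=source_version)
    finally:
        if own:
            fh.close()


def parse_products_text(text: str, **kwargs) -> ReferenceSet:
    """Convenience wrapper over :func:`parse_products_file` for in-memory text."""
    return parse_products_file(io.StringIO(text), **kwargs)
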