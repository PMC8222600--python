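"""DrugBank datafile parsing.

DrugBank ships its whole dataset as one XML file of repeated ``<drug>``
elements with well-defined tag names. Eight elements are read per drug:
seven content fields mapped onto target section kinds plus the FDA
application numbers carried by the drug's products. DrugBank has no boxed
warning, dosage/administration, pregnancy, lactation or food-effect fields,
so those kinds are never emitted here.

Parsing streams drug-by-drug (``iterparse``) so memory stays proportional to
one drug element, not the file.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import IO, Iterator, Optional, Union

from lxml import etree

from .core import (
    AppNumber,
    LabelDocument,
    SectionKind,
    SourceName,
    normalize_app_number,
    normalize_text,
)

logger = logging.getLogger(__name__)

#: DrugBank tag name → section kind for the seven content elements.
DRUGBANK_FIELD_MAP: dict[str, SectionKind] = {
    "indication": SectionKind.indication,
    "mechanism-of-action": SectionKind.mechanism_of_action,
    "pharmacodynamics": SectionKind.pharmacodynamics,
    "absorption": SectionKind.absorption,
    "volume-of-distribution": SectionKind.distribution,
    "metabolism": SectionKind.metabolism,
    "route-of-elimination": SectionKind.excretion,
}

#: Tag (under product elements) carrying the eighth extracted element.
APP_NUMBER_TAG = "fda-application-number"


def _localname(el) -> str:
    return etree.QName(el).localname if isinstance(el.tag, str) else ""


def _drug_to_document(
    drug, field_map: dict[str, SectionKind]
) -> Optional[LabelDocument]:
    primary_id = None
    fallback_id = None
    sections: dict[SectionKind, str] = {}
    app_numbers: list[AppNumber] = []

    for child in drug:
        name = _localname(child)
        if name == "drugbank-id":
            if child.get("primary") in ("true", "1") and primary_id is None:
                primary_id = (child.text or "").strip()
            elif fallback_id is None:
                fallback_id = (child.text or "").strip()
        elif name in field_map:
            text = normalize_text(child.text or "")
            if text:
                sections[field_map[name]] = text
        elif name == "products":
            for el in child.iter():
                if _localname(el) == APP_NUMBER_TAG and el.text and el.text.strip():
                    try:
                        num = normalize_app_number(el.text)
                    except ValueError:
                        logger.warning("skipping malformed application number %r", el.text)
                        continue
                    if num.value not in {a.value for a in app_numbers}:
                        app_numbers.append(num)

    native_id = primary_id or fallback_id
    if not native_id:
        logger.warning("drug element without a DrugBank-ID skipped")
        return None
    return LabelDocument(
        source=SourceName.drugbank,
        native_id=native_id,
        app_numbers=app_numbers,
        sections=sections,
    )


def iter_drugbank(
    source: Union[str, Path, IO[bytes]],
    field_map: Optional[dict[str, SectionKind]] = None,
) -> Iterator[LabelDocument]:
    """Stream :class:`LabelDocument` records from a DrugBank-style datafile."""
    fmap = DRUGBANK_FIELD_MAP if field_map is None else field_map
    context = etree.iterparse(str(source) if isinstance(source, Path) else source, events=("end",))
    root = None
    for _event, el in context:
        if root is None:
            root = el.getroottree().getroot()
        if _localname(el) == "drug" and el.getparent() is root:
            doc = _drug_to_document(el, fmap)
            if doc is not None:
                yield doc
            el.clear()
            while el.getprevious() is not None:
                del el.getparent()[0]


def parse_drugbank(
    source: Union[str, Path, bytes, IO[bytes]],
    field_map: Optional[dict[str, SectionKind]] = None,
) -> list[LabelDocument]:
    """Parse a DrugBank-style XML datafile into documents, in file order."""
    if isinstance(source, bytes):
        import io

        source = io.BytesIO(source)
    elif isinstance(source, str) and "<" in source:
        import io

        source = io.BytesIO(source.encode("utf-8"))
    return list(iter_drugbank(source, field_map))
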