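"""SPL (Structured Product Labeling) XML parsing.

DailyMed distributes drug labeling as HL7 v3 SPL documents in which sections
are identified by LOINC codes. Eight of the twelve target sections carry
their own LOINC code; the five ADMEF subsections (absorption, distribution,
metabolism, excretion, food effect) do not, so the pharmacokinetics parent
section (43682-4) is extracted first and then segmented by subtitle
detection.

Element matching is namespace-agnostic (local names only) because real SPL
files vary in how they declare the HL7 namespace.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Optional, Union

from lxml import etree

from .core import (
    ADMEF_SECTIONS,
    AppNumber,
    LabelDocument,
    SectionKind,
    SourceName,
    normalize_app_number,
    normalize_text,
    parse_label_date,
)

logger = logging.getLogger(__name__)

#: LOINC code → section kind for the eight coded sections.
LOINC_SECTION_MAP: dict[str, SectionKind] = {
    "34066-1": SectionKind.boxed_warning,
    "34067-9": SectionKind.indication,
    "34068-7": SectionKind.dosage_admin,
    "42228-7": SectionKind.pregnancy,
    "77290-5": SectionKind.lactation,
    "43679-0": SectionKind.mechanism_of_action,
    "43681-6": SectionKind.pharmacodynamics,
    "43682-4": SectionKind.pharmacokinetics,
}

#: Subtitle synonyms recognized when segmenting pharmacokinetics text.
PK_SUBTITLE_SYNONYMS: dict[SectionKind, tuple[str, ...]] = {
    SectionKind.absorption: ("absorption",),
    SectionKind.distribution: ("distribution",),
    SectionKind.metabolism: ("metabolism",),
    SectionKind.excretion: ("excretion",),
    SectionKind.food_effect: (
        "food effect",
        "food effects",
        "effect of food",
        "effects of food",
    ),
}

_OUTLINE = r"(?:\d+(?:\.\d+)*\.?\s+)?"


def _compile_subtitle_patterns(
    synonyms: dict[SectionKind, tuple[str, ...]],
) -> tuple[re.Pattern, re.Pattern, dict[str, SectionKind]]:
    phrase_to_kind: dict[str, SectionKind] = {}
    phrases: list[str] = []
    for kind, names in synonyms.items():
        for name in names:
            phrase_to_kind[name.lower()] = kind
            phrases.append(re.escape(name))
    alt = "|".join(sorted(phrases, key=len, reverse=True))
    # Standalone subtitle line: just the name, optionally outline-numbered,
    # optionally followed by ':' or '-'.
    title = re.compile(rf"^{_OUTLINE}({alt})\s*[:\-]?\s*$", re.IGNORECASE)
    # Subtitle as a line/paragraph prefix with content after ':' or '-'.
    prefix = re.compile(rf"^{_OUTLINE}({alt})\s*[:\-]\s*(\S.*)$", re.IGNORECASE)
    return title, prefix, phrase_to_kind


_PK_TITLE_RE, _PK_PREFIX_RE, _PK_PHRASES = _compile_subtitle_patterns(PK_SUBTITLE_SYNONYMS)


def split_pk_subsections(
    pk_text: str,
    synonyms: Optional[dict[SectionKind, tuple[str, ...]]] = None,
) -> dict[SectionKind, str]:
    """Segment pharmacokinetics text into ADMEF subsections by subtitles.

    Subtitles are recognized in two forms: a standalone title line
    (``Absorption``) or a paragraph-leading prefix followed by ``:`` or ``-``
    (``Food Effect: ...``). Content between a subtitle and the next subtitle
    (or end of text) belongs to that subsection; content before any subtitle
    stays under ``pharmacokinetics``. Subtitle text is removed from stored
    content. Text with no subtitles yields only the ``pharmacokinetics`` key.
    """
    if synonyms is None:
        title_re, prefix_re, phrase_to_kind = _PK_TITLE_RE, _PK_PREFIX_RE, _PK_PHRASES
    else:
        title_re, prefix_re, phrase_to_kind = _compile_subtitle_patterns(synonyms)

    text = normalize_text(pk_text)
    buckets: dict[SectionKind, list[str]] = {}
    current = SectionKind.pharmacokinetics
    saw_subtitle = False
    for line in text.split("\n"):
        m = title_re.match(line)
        if m:
            current = phrase_to_kind[m.group(1).lower()]
            saw_subtitle = True
            continue
        m = prefix_re.match(line)
        if m:
            current = phrase_to_kind[m.group(1).lower()]
            saw_subtitle = True
            buckets.setdefault(current, []).append(m.group(2))
            continue
        buckets.setdefault(current, []).append(line)

    out: dict[SectionKind, str] = {}
    for kind, lines in buckets.items():
        content = normalize_text("\n".join(lines))
        if content or kind is SectionKind.pharmacokinetics:
            out[kind] = content
    if not saw_subtitle:
        return {SectionKind.pharmacokinetics: text}
    # Keep an (possibly empty) pharmacokinetics entry so callers can tell the
    # parent section was present even when everything sat under subtitles.
    out.setdefault(SectionKind.pharmacokinetics, "")
    if not out[SectionKind.pharmacokinetics] and len(out) == 1:
        out = {SectionKind.pharmacokinetics: ""}
    return out


# --- XML helpers --------------------------------------------------------------


def _local(el) -> str:
    return etree.QName(el).localname if isinstance(el.tag, str) else ""


def _iter_local(root, name: str):
    for el in root.iter():
        if isinstance(el.tag, str) and etree.QName(el).localname == name:
            yield el


def _first_local(root, name: str):
    for el in _iter_local(root, name):
        return el
    return None


def _parse_xml(xml: Union[str, bytes, Path]) -> etree._Element:
    if isinstance(xml, Path) or (
        isinstance(xml, str)
        and "<" not in xml
        and len(xml) < 4096
        and Path(xml).is_file()
    ):
        return etree.parse(str(xml)).getroot()
    if isinstance(xml, str):
        xml = xml.encode("utf-8")
    return etree.fromstring(xml)


def _section_text(section) -> str:
    """Assemble a section's text from its paragraph markup, joined by blank lines."""
    text_el = _first_local(section, "text")
    scope = text_el if text_el is not None else section
    paragraphs = ["".join(p.itertext()) for p in _iter_local(scope, "paragraph")]
    paragraphs = [normalize_text(p) for p in paragraphs]
    paragraphs = [p for p in paragraphs if p]
    if paragraphs:
        return "\n\n".join(paragraphs)
    if text_el is not None:
        return normalize_text("".join(text_el.itertext()))
    return ""


def extract_app_numbers_spl(xml: Union[str, bytes, Path, etree._Element]) -> list[AppNumber]:
    """Collect FDA application numbers from a document's approval elements.

    De-duplicated, document order preserved; empty list means the document
    cannot be mapped to an application number.
    """
    root = xml if isinstance(xml, etree._Element) else _parse_xml(xml)
    seen: dict[str, AppNumber] = {}
    for approval in _iter_local(root, "approval"):
        for id_el in _iter_local(approval, "id"):
            ext = id_el.get("extension")
            if not ext:
                continue
            try:
                num = normalize_app_number(ext)
            except ValueError:
                logger.warning("unparseable approval identifier %r", ext)
                continue
            seen.setdefault(num.value, num)
    return list(seen.values())


def parse_spl(xml: Union[str, bytes, Path]) -> LabelDocument:
    """Parse one SPL document into a :class:`LabelDocument` (source dailymed).

    Sections are populated for every LOINC-coded section found; the
    pharmacokinetics section is additionally segmented into ADMEF subsections.
    A document with no Set ID is flagged unmapped (native_id ``"unmapped"``)
    rather than dropped.
    """
    try:
        root = _parse_xml(xml)
    except etree.XMLSyntaxError as exc:
        ident = xml if isinstance(xml, (str, Path)) and "\n" not in str(xml) else "<in-memory document>"
        raise ValueError(f"malformed SPL XML in {ident}: {exc}") from exc

    set_id_el = _first_local(root, "setId")
    set_id = set_id_el.get("root") if set_id_el is not None else None
    if not set_id:
        logger.warning("SPL document has no setId; flagging as unmapped")
        set_id = "unmapped"

    version_el = _first_local(root, "versionNumber")
    version = None
    if version_el is not None and version_el.get("value"):
        try:
            version = int(version_el.get("value"))
        except ValueError:
            pass

    date = None
    for et in _iter_local(root, "effectiveTime"):
        # The document-level effectiveTime is the first one outside any section.
        inside_section = any(_local(a) == "section" for a in et.iterancestors())
        if not inside_section and et.get("value"):
            date = parse_label_date(et.get("value")[:8])
            break

    sections: dict[SectionKind, str] = {}
    for section in _iter_local(root, "section"):
        code_el = None
        for child in section:
            if isinstance(child.tag, str) and etree.QName(child).localname == "code":
                code_el = child
                break
        if code_el is None:
            continue
        kind = LOINC_SECTION_MAP.get(code_el.get("code", ""))
        if kind is None:
            continue
        text = _section_text(section)
        if kind is SectionKind.pharmacokinetics:
            sections.update(split_pk_subsections(text))
        elif text:
            sections[kind] = text

    return LabelDocument(
        source=SourceName.dailymed,
        native_id=set_id,
        app_numbers=extract_app_numbers_spl(root),
        effective_date=date,
        version=version,
        sections=sections,
    )
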