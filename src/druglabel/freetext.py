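"""Section extraction from plain-text drug labels.

Drugs@FDA distributes labeling as PDF; after PDF-to-text conversion (out of
scope here — the text is the input) the twelve target sections are located by
regex heading detection. A heading is a whole line: an optional outline
number (``12.3``), a known section title, optional trailing punctuation, and
nothing else — which keeps sentences that merely mention a section name from
opening one.

ADMEF subsection headings (absorption, distribution, ...) are only honored
inside an already-open pharmacokinetics or clinical-pharmacology region,
since words like "distribution" also occur as ordinary prose elsewhere.
"""

from __future__ import annotations

import json
import logging
import re
from importlib import resources
from pathlib import Path
from typing import Optional, Union

from .core import (
    ADMEF_SECTIONS,
    LabelDocument,
    SectionKind,
    SourceName,
    normalize_app_number,
    normalize_text,
    parse_label_date,
)
from .spl import split_pk_subsections

logger = logging.getLogger(__name__)

HeadingLexicon = dict[SectionKind, list[str]]

_TOP_LEVEL_KINDS: tuple[SectionKind, ...] = (
    SectionKind.boxed_warning,
    SectionKind.indication,
    SectionKind.dosage_admin,
    SectionKind.pregnancy,
    SectionKind.lactation,
    SectionKind.mechanism_of_action,
    SectionKind.pharmacodynamics,
    SectionKind.pharmacokinetics,
)

#: Region-opening headings that are not themselves stored sections but inside
#: which ADMEF subsection headings are honored.
_PK_REGION_ALIASES = ("clinical pharmacology",)

_OUTLINE = r"(?:\d+(?:\.\d+)*\.?\s+)?"


def load_heading_lexicon(path: Optional[Union[str, Path]] = None) -> HeadingLexicon:
    """Load the heading lexicon (the packaged default, or an override file)."""
    if path is None:
        raw = json.loads(
            resources.files("druglabel").joinpath("data/heading_lexicon.json").read_text("utf-8")
        )
    else:
        raw = json.loads(Path(path).read_text("utf-8"))
    lex = {SectionKind(k): list(v) for k, v in raw.items()}
    for kind in SectionKind:
        if not lex.get(kind):
            raise ValueError(f"heading lexicon has no pattern for {kind.value}")
    return lex


def _heading_re(phrases: list[str]) -> re.Pattern:
    alt = "|".join(re.escape(p) for p in sorted(phrases, key=len, reverse=True))
    return re.compile(rf"^{_OUTLINE}(?:{alt})\s*[:.\-]?\s*$", re.IGNORECASE)


def extract_sections_from_text(
    text: str, lexicon: Optional[HeadingLexicon] = None
) -> dict[SectionKind, str]:
    """Extract target sections from normalized free label text.

    Each section's content runs from its heading line to the next top-level
    heading (or end of text); pharmacokinetics content is further segmented
    into ADMEF subsections via :func:`~druglabel.spl.split_pk_subsections`,
    with this lexicon's ADMEF synonyms honored as subtitles. Headings are
    excluded from content. Text with no recognized headings yields ``{}``.
    """
    if lexicon is None:
        lexicon = load_heading_lexicon()
    text = normalize_text(text)
    top_res = {k: _heading_re(lexicon[k]) for k in _TOP_LEVEL_KINDS}
    cp_re = _heading_re(list(_PK_REGION_ALIASES))

    buckets: list[tuple[object, list[str]]] = []  # (kind | "cp" | None, lines)
    current: Optional[tuple[object, list[str]]] = None
    for line in text.split("\n"):
        matched = None
        for kind, rx in top_res.items():
            if rx.match(line):
                matched = kind
                break
        if matched is None and cp_re.match(line):
            matched = "cp"
        if matched is not None:
            current = (matched, [])
            buckets.append(current)
            continue
        if current is not None:
            current[1].append(line)

    pk_synonyms = {k: tuple(lexicon[k]) for k in ADMEF_SECTIONS}
    out: dict[SectionKind, str] = {}
    for kind, lines in buckets:
        content = normalize_text("\n".join(lines))
        if kind in (SectionKind.pharmacokinetics, "cp"):
            parts = split_pk_subsections(content, synonyms=pk_synonyms)
            for sub, sub_text in parts.items():
                if sub is SectionKind.pharmacokinetics:
                    if kind is SectionKind.pharmacokinetics:
                        out[sub] = (out.get(sub) or "") or sub_text
                    elif sub_text:
                        logger.debug("dropping pre-subtitle clinical pharmacology text")
                elif sub_text:
                    out[sub] = sub_text if sub not in out else out[sub] + "\n\n" + sub_text
        else:
            if content:
                out[kind] = content if kind not in out else out[kind] + "\n\n" + content
    return out


_FILENAME_RE = re.compile(r"^(?:NDA|ANDA|N|A)?(\d{1,6})_(\d{8})$", re.IGNORECASE)


def load_label_text(
    path: Union[str, Path],
    manifest: Optional[dict] = None,
    lexicon: Optional[HeadingLexicon] = None,
) -> LabelDocument:
    """Load one free-text label file into a :class:`LabelDocument`.

    Application number and effective date come from a sidecar manifest entry
    (keyed by filename) when given, else from the ``NDAnnnnnn_YYYYMMDD.txt``
    filename convention; a file with neither is kept but flagged unmapped.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    sections = extract_sections_from_text(text, lexicon=lexicon)

    app_numbers = []
    date = None
    meta = (manifest or {}).get(path.name)
    if meta:
        try:
            raw_num = meta.get("app_number")
            if raw_num:
                app_numbers = [normalize_app_number(str(raw_num))]
            date = parse_label_date(meta.get("date"))
        except ValueError:
            logger.warning("unparseable manifest metadata for %s; flagging unmapped", path.name)
            app_numbers, date = [], None
    else:
        m = _FILENAME_RE.match(path.stem)
        if m:
            prefix = path.stem[: m.start(1)]
            app_numbers = [normalize_app_number(prefix + m.group(1))]
            date = parse_label_date(m.group(2))
        else:
            logger.warning("no metadata for %s; flagging unmapped", path.name)

    return LabelDocument(
        source=SourceName.drugs_at_fda,
        native_id=path.stem,
        app_numbers=app_numbers,
        effective_date=date,
        sections=sections,
    )
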