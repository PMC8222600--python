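"""Cross-source integration: unify identifiers, filter, coverage and overlap.

Documents from DailyMed, Drugs@FDA and DrugBank are keyed by FDA application
number (a Set ID or DrugBank-ID may map to several numbers — the document
then appears under each). For every (application number, source) pair only
the latest labeling version is kept, and the table is restricted to the
Orange Book reference set of valid NDA numbers.

Two per-source statistics summarize the integrated table:

* **coverage** — the percentage of items (application numbers) carrying a
  section for which a given source provides that section, relative to the
  number of items for which *any* source provides it (for the "drug" row,
  relative to the reference-set size);
* **overlap** — how much of a source's contribution is shared: the mean of
  ``(n_i - 1) / (M_k - 1)`` over the items the source covers, where ``n_i``
  is the number of sources providing the section for item ``i`` and ``M_k``
  the number of sources providing it anywhere. A sole provider scores 0%, a
  source whose items are always also covered by every other provider scores
  100%.
"""

from __future__ import annotations

import datetime
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .core import AppNumber, LabelDocument, SectionKind, SourceName, TARGET_SECTIONS
from .orange_book import ReferenceSet

logger = logging.getLogger(__name__)

#: Labeling sources that can appear in the integrated table.
LABEL_SOURCES: tuple[SourceName, ...] = (
    SourceName.drugs_at_fda,
    SourceName.dailymed,
    SourceName.drugbank,
)

#: Row key for the whole-document ("unique drug") statistics line.
DRUG_ROW = "drug"


def unify_ids(
    docs: Iterable[LabelDocument],
) -> tuple[dict[AppNumber, list[LabelDocument]], list[LabelDocument]]:
    """Group documents by application number (one-to-many preserved).

    A document listing several numbers appears under each of them; documents
    with no number go to the ``unmapped`` bucket. Every input document lands
    in exactly one of the two return values (≥1 times in the multimap, or
    once in the bucket).
    """
    by_app: dict[AppNumber, list[LabelDocument]] = defaultdict(list)
    unmapped: list[LabelDocument] = []
    for doc in docs:
        if doc.app_numbers:
            for num in doc.app_numbers:
                by_app[AppNumber(num.value)].append(doc)
        else:
            unmapped.append(doc)
    return dict(by_app), unmapped


def filter_latest(candidates: list[LabelDocument]) -> LabelDocument:
    """Pick the latest labeling among candidates for one (app, source) pair.

    Maximum effective date wins; ties break by version number, then by
    native_id — deterministic and invariant to candidate order. A document
    without a date loses to any dated one.
    """
    if not candidates:
        raise ValueError("no candidate documents")

    def key(doc: LabelDocument):
        return (
            doc.effective_date is not None,
            doc.effective_date or datetime.date.min,
            doc.version if doc.version is not None else -1,
            doc.native_id,
        )

    return max(candidates, key=key)


@dataclass
class IntegratedTable:
    """Latest-version documents keyed by (application number, source)."""

    rows: dict[tuple[AppNumber, SourceName], LabelDocument] = field(default_factory=dict)
    reference: Optional[ReferenceSet] = None
    unmapped: list[LabelDocument] = field(default_factory=list)
    dropped_per_source: dict[SourceName, int] = field(default_factory=dict)

    @property
    def app_numbers(self) -> set[AppNumber]:
        return {app for app, _src in self.rows}

    def sources_for(self, app: AppNumber, kind: SectionKind) -> set[SourceName]:
        return {
            src
            for (a, src), doc in self.rows.items()
            if a == app and kind in doc.sections
        }


def restrict_to_reference(
    rows: dict[tuple[AppNumber, SourceName], LabelDocument],
    reference: ReferenceSet,
) -> tuple[dict[tuple[AppNumber, SourceName], LabelDocument], dict[SourceName, int]]:
    """Drop application numbers absent from the Orange Book reference.

    Raises ``ValueError`` on an empty reference (which would silently empty
    the table); returns the kept rows and per-source dropped counts.
    """
    if len(reference) == 0:
        raise ValueError("reference set is empty; refusing to drop every row")
    ref_values = {a.value for a in reference.app_numbers}
    kept: dict[tuple[AppNumber, SourceName], LabelDocument] = {}
    dropped: dict[SourceName, int] = defaultdict(int)
    for (app, src), doc in rows.items():
        if app.value in ref_values:
            kept[(app, src)] = doc
        else:
            dropped[src] += 1
    for src, n in dropped.items():
        logger.info("dropped %d %s rows outside the reference set", n, src.value)
    return kept, dict(dropped)


def build_integrated_table(
    docs: Iterable[LabelDocument], reference: ReferenceSet
) -> IntegratedTable:
    """Run unify → per-(app, source) latest-version filter → reference restriction."""
    by_app, unmapped = unify_ids(docs)
    rows: dict[tuple[AppNumber, SourceName], LabelDocument] = {}
    for app, candidates in by_app.items():
        per_source: dict[SourceName, list[LabelDocument]] = defaultdict(list)
        for doc in candidates:
            per_source[doc.source].append(doc)
        for src, cands in per_source.items():
            rows[(app, src)] = filter_latest(cands)
    kept, dropped = restrict_to_reference(rows, reference)
    return IntegratedTable(
        rows=kept, reference=reference, unmapped=unmapped, dropped_per_source=dropped
    )


def _provision(table: IntegratedTable):
    """(row key → source → set of app numbers provided). Rows: drug + 12 sections."""
    prov: dict[object, dict[SourceName, set[AppNumber]]] = {
        DRUG_ROW: defaultdict(set)
    }
    for kind in TARGET_SECTIONS:
        prov[kind] = defaultdict(set)
    for (app, src), doc in table.rows.items():
        prov[DRUG_ROW][src].add(app)
        for kind, text in doc.sections.items():
            if kind in prov and text:
                prov[kind][src].add(app)
    return prov


def coverage(table: IntegratedTable) -> pd.DataFrame:
    """Per-section, per-source coverage percentages.

    The denominator for a section is the number of distinct application
    numbers for which any source provides it; for the ``drug`` row it is the
    reference-set size. Sections nobody provides get NaN (undefined).
    """
    prov = _provision(table)
    data = {}
    denominators = {}
    for row_key, per_source in prov.items():
        union = set().union(*per_source.values()) if per_source else set()
        if row_key == DRUG_ROW and table.reference is not None:
            denom = len(table.reference)
        else:
            denom = len(union)
        name = row_key.value if isinstance(row_key, SectionKind) else row_key
        denominators[name] = denom
        data[name] = {
            src.value: (
                float("nan") if denom == 0 else 100.0 * len(per_source.get(src, set())) / denom
            )
            for src in LABEL_SOURCES
        }
    df = pd.DataFrame.from_dict(data, orient="index")
    df["denominator"] = pd.Series(denominators)
    return df


def overlap(table: IntegratedTable) -> pd.DataFrame:
    """Per-section, per-source overlap percentages.

    ``overlap(S, k) = 100 · mean over items i covered by S of
    (n_i − 1)/(M_k − 1)``; NaN when S does not provide k or when M_k ≤ 1
    (no sharing possible).
    """
    prov = _provision(table)
    data = {}
    for row_key, per_source in prov.items():
        providers = [s for s in LABEL_SOURCES if per_source.get(s)]
        m_k = len(providers)
        row = {}
        for src in LABEL_SOURCES:
            items = per_source.get(src, set())
            if not items or m_k <= 1:
                row[src.value] = float("nan")
                continue
            shares = []
            for app in items:
                n_i = sum(1 for s in providers if app in per_source[s])
                shares.append((n_i - 1) / (m_k - 1))
            row[src.value] = 100.0 * sum(shares) / len(shares)
        data[row_key.value if isinstance(row_key, SectionKind) else row_key] = row
    return pd.DataFrame.from_dict(data, orient="index")


def coverage_overlap_report(table: IntegratedTable) -> pd.DataFrame:
    """Combined report: one row per drug/section, source × {coverage, overlap} columns."""
    cov = coverage(table)
    ovl = overlap(table)
    out = pd.DataFrame(index=cov.index)
    for src in LABEL_SOURCES:
        out[f"{src.value}_coverage_pct"] = cov[src.value]
        out[f"{src.value}_overlap_pct"] = ovl[src.value]
    out["denominator"] = cov["denominator"]
    return out
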