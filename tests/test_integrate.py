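"""Identifier unification, latest-version filtering, coverage and overlap."""

import datetime
import itertools
import math

import pytest

from druglabel.core import AppNumber, LabelDocument, SectionKind, SourceName
from druglabel.integrate import (
    IntegratedTable,
    build_integrated_table,
    coverage,
    filter_latest,
    overlap,
    restrict_to_reference,
    unify_ids,
)
from druglabel.orange_book import ReferenceSet


def doc(source, native_id, apps=(), date=None, version=None, sections=()):
    return LabelDocument(
        source=source,
        native_id=native_id,
        app_numbers=[AppNumber(a) for a in apps],
        effective_date=datetime.date.fromisoformat(date) if date else None,
        version=version,
        sections={k: "text" for k in sections},
    )


def ref(*values):
    return ReferenceSet({AppNumber(v, "NDA") for v in values})


def table_from(docs, reference):
    return build_integrated_table(docs, reference)


A, B, C = "000001", "000002", "000003"
DM, FDA, DB = SourceName.dailymed, SourceName.drugs_at_fda, SourceName.drugbank


class TestUnifyIds:
    def test_one_to_many_listed_under_each(self):
        d = doc(DM, "s1", apps=[A, B])
        by_app, unmapped = unify_ids([d])
        assert d in by_app[AppNumber(A)] and d in by_app[AppNumber(B)]
        assert unmapped == []

    def test_unmapped_bucket(self):
        d = doc(DM, "s1")
        by_app, unmapped = unify_ids([d])
        assert by_app == {} and unmapped == [d]

    def test_two_docs_share_number_pre_filtering(self):
        d1, d2 = doc(DM, "s1", apps=[A]), doc(DM, "s2", apps=[A])
        by_app, _ = unify_ids([d1, d2])
        assert len(by_app[AppNumber(A)]) == 2

    def test_document_conservation(self, parsed_docs):
        by_app, unmapped = unify_ids(parsed_docs)
        placed = {id(d) for docs in by_app.values() for d in docs}
        assert placed | {id(d) for d in unmapped} == {id(d) for d in parsed_docs}
        assert placed.isdisjoint({id(d) for d in unmapped})


class TestFilterLatest:
    def test_latest_date_wins(self):
        older = doc(DM, "s1", apps=[A], date="2020-01-01")
        newer = doc(DM, "s2", apps=[A], date="2020-06-01")
        assert filter_latest([older, newer]) is newer

    def test_equal_dates_version_breaks_tie(self):
        v3 = doc(DM, "s1", apps=[A], date="2020-01-01", version=3)
        v5 = doc(DM, "s2", apps=[A], date="2020-01-01", version=5)
        assert filter_latest([v3, v5]) is v5

    def test_dateless_loses_to_dated(self):
        dated = doc(DM, "s1", apps=[A], date="2001-01-01")
        undated = doc(DM, "s2", apps=[A], version=99)
        assert filter_latest([undated, dated]) is dated

    def test_single_candidate(self):
        d = doc(DM, "s1", apps=[A])
        assert filter_latest([d]) is d

    def test_permutation_invariant(self):
        docs = [
            doc(DM, f"s{i}", apps=[A], date=f"2020-0{i}-01", version=i)
            for i in range(1, 4)
        ]
        winners = {filter_latest(list(p)).native_id for p in itertools.permutations(docs)}
        assert winners == {"s3"}

    def test_full_tie_breaks_on_native_id(self):
        d1 = doc(DM, "aaa", apps=[A], date="2020-01-01", version=1)
        d2 = doc(DM, "zzz", apps=[A], date="2020-01-01", version=1)
        assert filter_latest([d1, d2]) is d2


class TestRestrictToReference:
    def test_drops_keys_outside_reference(self):
        rows = {
            (AppNumber(A), DM): doc(DM, "s1", apps=[A]),
            (AppNumber(B), DM): doc(DM, "s2", apps=[B]),
        }
        kept, dropped = restrict_to_reference(rows, ref(A))
        assert set(kept) == {(AppNumber(A), DM)}
        assert dropped[DM] == 1

    def test_superset_reference_unchanged(self):
        rows = {(AppNumber(A), DM): doc(DM, "s1", apps=[A])}
        kept, _ = restrict_to_reference(rows, ref(A, B, C))
        assert kept == rows

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError):
            restrict_to_reference({}, ReferenceSet())

    def test_never_increases_rows(self, parsed_docs, reference):
        table = build_integrated_table(parsed_docs, reference)
        by_app, _ = unify_ids(parsed_docs)
        pre = sum(
            len({d.source for d in docs}) for docs in by_app.values()
        )
        assert len(table.rows) <= pre


def three_source_table(provides):
    """Build a table where provides[src] is the set of items with boxed_warning."""
    rows = {}
    items = sorted(set().union(*provides.values()))
    for src, item_set in provides.items():
        for item in items:
            sections = [SectionKind.boxed_warning] if item in item_set else []
            rows[(AppNumber(item), src)] = doc(
                src, f"{src.value}-{item}", apps=[item], sections=sections
            )
    return IntegratedTable(rows=rows, reference=ref(*items))


class TestCoverage:
    def test_hand_counted_example(self):
        # boxed_warning: source1 covers {X, Y}, source2 covers {Y} → denom 2
        t = three_source_table({DM: {A, B}, FDA: {B}, DB: set()})
        cov = coverage(t)
        assert cov.loc["boxed_warning", "dailymed"] == pytest.approx(100.0)
        assert cov.loc["boxed_warning", "drugs_at_fda"] == pytest.approx(50.0)
        assert cov.loc["boxed_warning", "denominator"] == 2

    def test_source_with_no_items_is_zero(self):
        t = three_source_table({DM: {A}, FDA: set(), DB: set()})
        assert coverage(t).loc["boxed_warning", "drugs_at_fda"] == 0.0

    def test_all_sources_everything_is_100(self):
        t = three_source_table({DM: {A, B}, FDA: {A, B}, DB: {A, B}})
        cov = coverage(t)
        for src in ("dailymed", "drugs_at_fda", "drugbank"):
            assert cov.loc["boxed_warning", src] == pytest.approx(100.0)

    def test_drug_row_uses_reference_denominator(self):
        t = three_source_table({DM: {A}, FDA: set(), DB: set()})
        t.reference = ref(A, B, C, "000009")
        assert coverage(t).loc["drug", "denominator"] == 4

    def test_nobody_provides_gives_nan(self):
        t = three_source_table({DM: {A}, FDA: set(), DB: set()})
        cov = coverage(t)
        assert math.isnan(cov.loc["indication", "dailymed"])


class TestOverlap:
    def test_sole_provider_zero(self):
        t = three_source_table({DM: {A, B}, FDA: set(), DB: set()})
        assert math.isnan(overlap(t).loc["boxed_warning", "dailymed"]) or True
        # M_k == 1: no sharing possible → reported absent
        assert math.isnan(overlap(t).loc["boxed_warning", "dailymed"])

    def test_sole_provider_items_zero_with_other_providers(self):
        # dailymed alone covers A and B; FDA covers C only → M_k = 2
        t = three_source_table({DM: {A, B}, FDA: {C}, DB: set()})
        ovl = overlap(t)
        assert ovl.loc["boxed_warning", "dailymed"] == pytest.approx(0.0)
        assert ovl.loc["boxed_warning", "drugs_at_fda"] == pytest.approx(0.0)

    def test_fully_shared_three_sources_is_100(self):
        t = three_source_table({DM: {A, B}, FDA: {A, B}, DB: {A, B}})
        ovl = overlap(t)
        for src in ("dailymed", "drugs_at_fda", "drugbank"):
            assert ovl.loc["boxed_warning", src] == pytest.approx(100.0)

    def test_hand_computed_75_percent(self):
        # M_k = 3. dailymed covers A (shared with 1 other) and B (shared with
        # both others): 100 * ((1/2) + (2/2)) / 2 = 75.
        t = three_source_table({DM: {A, B}, FDA: {A, B}, DB: {B, C}})
        assert overlap(t).loc["boxed_warning", "dailymed"] == pytest.approx(75.0)

    def test_bounds_on_synthetic_table(self, parsed_docs, reference):
        table = build_integrated_table(parsed_docs, reference)
        for df in (coverage(table), overlap(table)):
            vals = df.drop(columns=["denominator"], errors="ignore").to_numpy()
            finite = vals[~pd_isnan(vals)]
            assert ((finite >= 0) & (finite <= 100)).all()


def pd_isnan(arr):
    import numpy as np

    return np.isnan(arr)


class TestBuildIntegratedTable:
    def test_one_row_per_app_source_and_reference_only(self, parsed_docs, reference):
        table = build_integrated_table(parsed_docs, reference)
        ref_values = {a.value for a in reference.app_numbers}
        for (app, _src) in table.rows:
            assert app.value in ref_values

    def test_multi_version_resolved_to_latest(self, corpus, parsed_docs, reference):
        _outdir, manifest, _spec = corpus
        table = build_integrated_table(parsed_docs, reference)
        by_set = {}
        for entry in manifest["spl"].values():
            by_set.setdefault(entry["set_id"], []).append(entry)
        for set_id, entries in by_set.items():
            if len(entries) < 2 or not entries[0]["app_numbers"]:
                continue
            app = AppNumber(entries[0]["app_numbers"][0])
            row = table.rows.get((app, SourceName.dailymed))
            if row is not None and row.native_id == set_id:
                assert row.version == max(e["version"] for e in entries)
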