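"""Food-effect annotation, rule baselines, TF-IDF and classifier behavior."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from druglabel.core import LabelDocument, SectionKind, SourceName
from druglabel.foodeffect import (
    ALGORITHMS,
    FOOD_EFFECT,
    NON_FOOD_EFFECT,
    SplitSpec,
    TextClassifier,
    TrainConfig,
    annotate_absorption_paragraphs,
    build_dataset,
    cross_source_eval,
    evaluate,
    finetune_transformer,
    learning_curve,
    rule_based_1,
    rule_based_2,
    split_train_test,
    tfidf_fit,
    tfidf_transform,
    tokenize,
    train_classifier,
)
from druglabel.synthetic import generate_foodeffect_paragraphs

METHADONE = "Effect of food on the bioavailability of methadone has not been evaluated"
NALOXEGOL = "A high-fat meal increased the extent and rate of naloxegol absorption."


def absorption_doc(text):
    return LabelDocument(
        source=SourceName.dailymed,
        native_id="doc-1",
        sections={SectionKind.absorption: text},
    )


class TestAnnotation:
    def test_standalone_title_labels_next_paragraph(self):
        doc = absorption_doc("Food Effect\n\nA meal delayed Tmax.")
        (p,) = annotate_absorption_paragraphs(doc)
        assert (p.text, p.label, p.annotation_method) == (
            "A meal delayed Tmax.", FOOD_EFFECT, "regex_title",
        )

    def test_prefix_detected_and_removed(self):
        doc = absorption_doc("Effect of Food: AUC unchanged.")
        (p,) = annotate_absorption_paragraphs(doc)
        assert (p.text, p.label, p.annotation_method) == (
            "AUC unchanged.", FOOD_EFFECT, "regex_prefix",
        )

    def test_plain_absorption_paragraph_defaults_negative(self):
        doc = absorption_doc("Oral bioavailability is 60%.")
        (p,) = annotate_absorption_paragraphs(doc)
        assert (p.label, p.annotation_method) == (NON_FOOD_EFFECT, "absorption_default")

    def test_title_line_inside_paragraph(self):
        doc = absorption_doc("Food Effect\nA meal delayed Tmax.")
        (p,) = annotate_absorption_paragraphs(doc)
        assert p.text == "A meal delayed Tmax." and p.label == FOOD_EFFECT

    def test_food_effect_section_content_is_title_detected(self):
        doc = LabelDocument(
            source=SourceName.dailymed,
            native_id="doc-2",
            sections={SectionKind.food_effect: "A meal increased AUC."},
        )
        (p,) = annotate_absorption_paragraphs(doc)
        assert (p.label, p.annotation_method) == (FOOD_EFFECT, "regex_title")

    def test_methadone_sentence_not_structurally_positive(self):
        # the sentence mentions food but carries no title/prefix marker
        doc = absorption_doc(METHADONE)
        (p,) = annotate_absorption_paragraphs(doc)
        assert p.label == NON_FOOD_EFFECT

    def test_empty_document_yields_nothing(self):
        doc = LabelDocument(source=SourceName.dailymed, native_id="x")
        assert annotate_absorption_paragraphs(doc) == []


class TestRuleBaselines:
    def test_methadone_is_rule_false_positive(self):
        assert rule_based_1(METHADONE) == FOOD_EFFECT
        assert rule_based_2(METHADONE) == FOOD_EFFECT

    def test_naloxegol_is_rule_false_negative(self):
        assert rule_based_1(NALOXEGOL) == NON_FOOD_EFFECT
        assert rule_based_2(NALOXEGOL) == NON_FOOD_EFFECT

    @pytest.mark.parametrize("text", ["", "Take with water."])
    def test_plain_negatives(self, text):
        assert rule_based_1(text) == NON_FOOD_EFFECT
        assert rule_based_2(text) == NON_FOOD_EFFECT

    def test_rule2_catches_bare_keyword(self):
        assert rule_based_2("take with food") == FOOD_EFFECT
        assert rule_based_1("take with food") == NON_FOOD_EFFECT

    def test_rule1_implies_rule2_on_generated_corpus(self):
        recs = generate_foodeffect_paragraphs(120, 120, 0.3, seed=5)
        for r in recs:
            if rule_based_1(r.paragraph.text) == FOOD_EFFECT:
                assert rule_based_2(r.paragraph.text) == FOOD_EFFECT


class TestTfidf:
    def test_fit_counts(self):
        model = tfidf_fit(["food effect", "absorption rate"])
        assert model.n_docs == 2
        assert model.doc_freq["food"] == 1

    def test_term_in_every_doc_has_df_n(self):
        model = tfidf_fit(["food a", "food b", "food c"])
        assert model.doc_freq["food"] == model.n_docs == 3

    def test_duplicate_docs_count_independently(self):
        model = tfidf_fit(["food", "food"])
        assert model.n_docs == 2 and model.doc_freq["food"] == 2

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            tfidf_fit([])

    def test_hand_computed_weight(self):
        model = tfidf_fit(["food effect", "absorption rate"])
        vec = tfidf_transform(model, "food food").toarray()[0]
        expected = math.log(1 + 2) * math.log(2 / 1)
        assert vec[model.vocabulary["food"]] == pytest.approx(expected, abs=1e-12)

    def test_ubiquitous_term_weighs_zero(self):
        model = tfidf_fit(["food a", "food b"])
        vec = tfidf_transform(model, "food").toarray()[0]
        assert vec[model.vocabulary["food"]] == 0.0

    def test_absent_and_oov_terms_ignored(self):
        model = tfidf_fit(["food effect", "absorption rate"])
        vec = tfidf_transform(model, "novel words only")
        assert vec.nnz == 0

    @given(st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, data):
        """Implementation equals a direct evaluation of the formulas, 1e-12."""
        terms = ["meal", "auc", "cmax", "dose", "oral", "renal", "tmax", "fat"]
        n_docs = data.draw(st.integers(1, 5))
        corpus = [
            " ".join(data.draw(st.lists(st.sampled_from(terms), min_size=1, max_size=8)))
            for _ in range(n_docs)
        ]
        query = " ".join(data.draw(st.lists(st.sampled_from(terms), min_size=0, max_size=8)))
        model = tfidf_fit(corpus)
        vec = tfidf_transform(model, query).toarray()[0]
        toks = tokenize(query)
        for term, idx in model.vocabulary.items():
            freq = toks.count(term)
            df = sum(1 for d in corpus if term in tokenize(d))
            expected = math.log(1 + freq) * math.log(n_docs / df)
            assert vec[idx] == pytest.approx(expected, abs=1e-12)


class TestEvaluate:
    def test_closed_form(self):
        pred = [FOOD_EFFECT] * 10 + [NON_FOOD_EFFECT]
        truth = [FOOD_EFFECT] * 9 + [NON_FOOD_EFFECT, FOOD_EFFECT]
        rep = evaluate(pred, truth)
        assert (rep.tp, rep.fp, rep.fn) == (9, 1, 1)
        assert rep.precision == rep.recall == rep.f1 == pytest.approx(0.9)

    def test_perfect(self):
        labels = [FOOD_EFFECT, NON_FOOD_EFFECT] * 5
        rep = evaluate(labels, labels)
        assert rep.precision == rep.recall == rep.f1 == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate([FOOD_EFFECT], [])

    def test_matches_brute_force_on_random_vectors(self):
        rng = random.Random(123)
        labels = (FOOD_EFFECT, NON_FOOD_EFFECT)
        for _ in range(300):
            n = rng.randrange(1, 40)
            pred = [rng.choice(labels) for _ in range(n)]
            truth = [rng.choice(labels) for _ in range(n)]
            rep = evaluate(pred, truth)
            tp = sum(p == t == FOOD_EFFECT for p, t in zip(pred, truth))
            fp = sum(p == FOOD_EFFECT and t != FOOD_EFFECT for p, t in zip(pred, truth))
            fn = sum(p != FOOD_EFFECT and t == FOOD_EFFECT for p, t in zip(pred, truth))
            assert (rep.tp, rep.fp, rep.fn) == (tp, fp, fn)
            if tp + fp and tp + fn and tp:
                assert rep.f1 == pytest.approx(
                    2 * tp / (2 * tp + fp + fn)
                )


def pools(n=100, seed=0, adversarial=0.0):
    out = {}
    for offset, src in enumerate((SourceName.drugs_at_fda, SourceName.dailymed)):
        recs = generate_foodeffect_paragraphs(
            n // 2, n - n // 2, adversarial, seed=seed * 2 + offset, source=src
        )
        out[src] = [r.paragraph for r in recs]
    return out


class TestDatasetConstruction:
    def test_source_balanced_sampling(self):
        data = build_dataset(pools(100), n_per_source=10, seed=1)
        assert len(data) == 20
        per_src = {s: sum(p.source == s for p in data) for s in
                   (SourceName.drugs_at_fda, SourceName.dailymed)}
        assert set(per_src.values()) == {10}

    def test_deterministic_given_seed(self):
        a = build_dataset(pools(100), 10, seed=4)
        b = build_dataset(pools(100), 10, seed=4)
        assert [p.text for p in a] == [p.text for p in b]

    def test_insufficient_pool_names_source(self):
        with pytest.raises(ValueError, match="drugs_at_fda|dailymed"):
            build_dataset(pools(100), n_per_source=150, seed=0)

    def test_split_80_20_disjoint_exhaustive(self):
        data = build_dataset(pools(200), 100, seed=2)
        train, test = split_train_test(data, SplitSpec(seed=2))
        assert len(train) == 160 and len(test) == 40
        key = lambda p: (p.text, p.source.value, p.doc_ref)  # noqa: E731
        assert set(map(key, train)).isdisjoint(map(key, test))
        assert sorted(map(key, train + test)) == sorted(map(key, data))

    def test_split_stratified_by_source(self):
        data = build_dataset(pools(200), 100, seed=3)
        train, _test = split_train_test(data, SplitSpec(seed=3))
        for src in (SourceName.drugs_at_fda, SourceName.dailymed):
            assert sum(p.source == src for p in train) == 80

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=1.5)


class TestClassifiers:
    def test_separable_data_high_f1(self):
        recs = generate_foodeffect_paragraphs(150, 150, 0.0, seed=9)
        paras = [r.paragraph for r in recs]
        train, test = split_train_test(paras, SplitSpec(seed=9))
        for algo in ALGORITHMS:
            model = TextClassifier(algo=algo, seed=9).fit(
                [p.text for p in train], [p.label for p in train]
            )
            rep = evaluate(model.predict([p.text for p in test]),
                           [p.label for p in test])
            assert rep.f1 >= 0.95

    def test_unknown_algo_rejected(self):
        from scipy import sparse

        with pytest.raises(ValueError, match="xgboost"):
            train_classifier(sparse.eye(4).tocsr(), ["a", "b", "a", "b"], "xgboost", 0)

    def test_single_class_rejected(self):
        from scipy import sparse

        with pytest.raises(ValueError, match="single class"):
            train_classifier(sparse.eye(4).tocsr(), ["a"] * 4, "logreg", 0)

    def test_constant_features_predict_majority(self):
        import numpy as np
        from scipy import sparse

        X = sparse.csr_matrix(np.ones((10, 3)))
        y = [FOOD_EFFECT] * 7 + [NON_FOOD_EFFECT] * 3
        clf = train_classifier(X, y, "logreg", 0)
        assert list(clf.predict(X)) == [FOOD_EFFECT] * 10

    def test_training_deterministic_given_seed(self):
        recs = generate_foodeffect_paragraphs(60, 60, 0.2, seed=3)
        paras = [r.paragraph for r in recs]
        preds = []
        for _ in range(2):
            m = TextClassifier(algo="random_forest", seed=3).fit(
                [p.text for p in paras], [p.label for p in paras]
            )
            preds.append(m.predict([p.text for p in paras]))
        assert preds[0] == preds[1]


class TestCrossSourceEval:
    def test_nine_reports_in_grid_order(self):
        grid = cross_source_eval(
            {s.value: ps for s, ps in pools(120, seed=6).items()},
            algo="logreg", seed=6,
        )
        order = ("drugs_at_fda", "dailymed", "combined")
        assert list(grid) == [(a, b) for a in order for b in order]
        assert all(0 <= rep.f1 <= 1 for rep in grid.values())

    def test_combined_training_competitive_on_easy_data(self):
        grid = cross_source_eval(
            {s.value: ps for s, ps in pools(200, seed=7).items()},
            algo="logreg", seed=7,
        )
        best_single = max(grid[("drugs_at_fda", "combined")].f1,
                          grid[("dailymed", "combined")].f1)
        assert grid[("combined", "combined")].f1 >= best_single - 0.05

    def test_missing_dataset_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            cross_source_eval({"dailymed": []}, algo="logreg", seed=0)


class TestLearningCurve:
    def test_shape_and_determinism(self):
        recs = generate_foodeffect_paragraphs(80, 80, 0.1, seed=8)
        paras = [r.paragraph for r in recs]
        train, test = split_train_test(paras, SplitSpec(seed=8))
        kwargs = dict(algos=["logreg"], sizes=[20, 40, 80], seed=8, reps=1)
        a = learning_curve(train, test, **kwargs)
        b = learning_curve(train, test, **kwargs)
        assert a == b
        assert [s for s, _ in a["logreg"]] == [20, 40, 80]

    def test_oversized_request_rejected(self):
        recs = generate_foodeffect_paragraphs(10, 10, 0.0, seed=8)
        paras = [r.paragraph for r in recs]
        with pytest.raises(ValueError, match="exceeds"):
            learning_curve(paras, paras, ["logreg"], [100], seed=0)


class TestTransformerExtra:
    def test_config_defaults_match_protocol(self):
        cfg = TrainConfig()
        assert cfg.learning_rate == pytest.approx(4e-5)
        assert cfg.batch_size == 32
        assert cfg.grad_clip_norm == 1.0
        assert cfg.optimizer == "Adam"

    def test_clear_error_without_extra(self):
        try:
            import simpletransformers  # noqa: F401

            pytest.skip("optional extra installed")
        except ImportError:
            pass
        with pytest.raises(RuntimeError, match="bert"):
            finetune_transformer([])
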