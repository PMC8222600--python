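"""Food-effect paragraph labeling: annotation, baselines, TF-IDF classifiers.

A food effect is a change in a drug's pharmacokinetics caused by food intake
(delayed gastric emptying, altered gastric pH, bile flow, ...). In labeling,
food-effect content usually sits inside the absorption section, sometimes
under an explicit subtitle ("Food Effect:", "Effect of Food"), sometimes not.
Paragraphs under an explicit subtitle can be labeled mechanically by regex;
the interesting cases are the unmarked ones, which motivate treating the
problem as binary paragraph classification (Food Effect vs. Non-Food Effect)
with the paragraph as the minimum text unit.

Two rule-based baselines bracket the problem:

* rule 1 — paragraph matches ``(food effect|food effects|effect of food|
  effects of food)`` anywhere;
* rule 2 — paragraph contains the keyword ``food``.

Both have characteristic failures: "Effect of food on the bioavailability of
X has not been evaluated" is a false positive, and "A high-fat meal increased
the extent and rate of X absorption" is a false negative (no "food" keyword).

Classical classifiers (logistic regression, linear SVC, random forest) are
fed TF-IDF features computed as ``TF(t,d) = ln(1 + freq(t,d))`` and
``IDF(t,D) = ln(N / df(t))`` — natural log, no smoothing, so a term present
in every document weighs 0. The TF-IDF model is implemented here rather than
taken from a library so those exact formulas are what runs.
"""

from __future__ import annotations

import math
import random
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import sparse
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from .core import (
    EvalReport,
    LabelDocument,
    LabeledParagraph,
    SectionKind,
    SourceName,
    split_paragraphs,
)

FOOD_EFFECT = "food_effect"
NON_FOOD_EFFECT = "non_food_effect"

_FOOD_PHRASES = r"(?:food effects?|effects? of food)"

#: Standalone title line: nothing but a food-effect phrase.
TITLE_PATTERN = re.compile(rf"^{_FOOD_PHRASES}$", re.IGNORECASE)
#: Food-effect phrase as a paragraph-leading prefix, ':' or '-' terminated.
PREFIX_PATTERN = re.compile(rf"^{_FOOD_PHRASES}\s*(?::|-)\s*", re.IGNORECASE)
#: Absorption section title.
ABSORPTION_TITLE = re.compile(r"^absorption$", re.IGNORECASE)
#: Rule-based method 1: phrase anywhere in the paragraph.
RULE1_PATTERN = re.compile(_FOOD_PHRASES, re.IGNORECASE)
#: Rule-based method 2: bare keyword.
RULE2_KEYWORD = "food"


# --- Dataset construction (regex annotation) ---------------------------------


def annotate_absorption_paragraphs(doc: LabelDocument) -> list[LabeledParagraph]:
    """Label the paragraphs of a document's absorption-area content.

    Food Effect paragraphs are those (a) immediately following a standalone
    food-effect title line, or (b) opening with a food-effect prefix
    (``Food Effect: ...``) — the matched title/prefix is removed from the
    stored text. Everything already extracted into the document's
    ``food_effect`` section counts as title-detected. Remaining absorption
    paragraphs default to Non-Food Effect.
    """
    out: list[LabeledParagraph] = []

    def mk(text: str, label: str, method: str) -> LabeledParagraph:
        return LabeledParagraph(
            text=text,
            label=label,
            source=doc.source,
            doc_ref=doc.native_id,
            annotation_method=method,
        )

    fe_text = doc.sections.get(SectionKind.food_effect, "")
    for para in split_paragraphs(fe_text):
        out.append(mk(para, FOOD_EFFECT, "regex_title"))

    abs_text = doc.sections.get(SectionKind.absorption, "")
    paragraphs = split_paragraphs(abs_text)
    pending_title = False
    for para in paragraphs:
        lines = para.split("\n")
        if TITLE_PATTERN.match(para.strip()):
            # Paragraph is nothing but the title; it labels the next one.
            pending_title = True
            continue
        if pending_title:
            out.append(mk(para, FOOD_EFFECT, "regex_title"))
            pending_title = False
            continue
        if TITLE_PATTERN.match(lines[0].strip()) and len(lines) > 1:
            body = "\n".join(lines[1:]).strip()
            if body:
                out.append(mk(body, FOOD_EFFECT, "regex_title"))
            continue
        m = PREFIX_PATTERN.match(para)
        if m:
            body = para[m.end():].strip()
            if body:
                out.append(mk(body, FOOD_EFFECT, "regex_prefix"))
            continue
        out.append(mk(para, NON_FOOD_EFFECT, "absorption_default"))
    return out


def apply_manual_review(
    paragraphs: Iterable[LabeledParagraph],
    review: Optional[dict[str, str]] = None,
) -> list[LabeledParagraph]:
    """Merge a manual-review file (paragraph text → corrected label).

    The automatic annotation is manually checked in the original protocol;
    corrections are supplied as a mapping and applied with annotation method
    ``manual``. Empty/absent review leaves the input unchanged.
    """
    if not review:
        return list(paragraphs)
    out = []
    for p in paragraphs:
        corrected = review.get(p.text)
        if corrected is not None and corrected != p.label:
            out.append(
                LabeledParagraph(p.text, corrected, p.source, p.doc_ref, "manual")
            )
        else:
            out.append(p)
    return out


# --- Rule-based baselines -----------------------------------------------------


def rule_based_1(paragraph: str) -> str:
    """Food Effect iff a food-effect phrase occurs anywhere in the paragraph."""
    return FOOD_EFFECT if RULE1_PATTERN.search(paragraph) else NON_FOOD_EFFECT


def rule_based_2(paragraph: str) -> str:
    """Food Effect iff the keyword "food" occurs (case-insensitive substring)."""
    return FOOD_EFFECT if RULE2_KEYWORD in paragraph.lower() else NON_FOOD_EFFECT


# --- TF-IDF -------------------------------------------------------------------

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercase and split on non-alphanumeric runs."""
    return _TOKEN_RE.findall(text.lower())


@dataclass
class TfidfModel:
    """Fitted TF-IDF vocabulary: term → index, document frequencies, corpus size."""

    vocabulary: dict[str, int]
    doc_freq: dict[str, int]
    n_docs: int
    smooth: bool = False

    def idf(self, term: str) -> float:
        df = self.doc_freq[term]
        if self.smooth:
            return math.log((1 + self.n_docs) / (1 + df)) + 1.0
        return math.log(self.n_docs / df)


def tfidf_fit(corpus: Sequence[str], smooth: bool = False) -> TfidfModel:
    """Fit vocabulary and document frequencies over a paragraph corpus.

    Vocabulary is every token seen; ``doc_freq(t)`` counts documents
    containing ``t``; duplicate documents count separately. Raises on an
    empty corpus.
    """
    if len(corpus) == 0:
        raise ValueError("cannot fit TF-IDF on an empty corpus")
    vocabulary: dict[str, int] = {}
    doc_freq: dict[str, int] = {}
    for doc in corpus:
        for term in set(tokenize(doc)):
            if term not in vocabulary:
                vocabulary[term] = len(vocabulary)
            doc_freq[term] = doc_freq.get(term, 0) + 1
    return TfidfModel(vocabulary, doc_freq, n_docs=len(corpus), smooth=smooth)


def tfidf_transform(model: TfidfModel, paragraph: str) -> sparse.csr_matrix:
    """Weight a paragraph: ``ln(1 + freq(t,d)) · idf(t)`` per vocabulary term.

    Out-of-vocabulary tokens are ignored; with unsmoothed IDF a term present
    in every training document gets weight 0. Returns a 1×V sparse row.
    """
    counts: dict[int, int] = {}
    freqs: dict[int, str] = {}
    for tok in tokenize(paragraph):
        idx = model.vocabulary.get(tok)
        if idx is None:
            continue
        counts[idx] = counts.get(idx, 0) + 1
        freqs[idx] = tok
    cols, vals = [], []
    for idx, c in counts.items():
        w = math.log(1 + c) * model.idf(freqs[idx])
        if w != 0.0:
            cols.append(idx)
            vals.append(w)
    return sparse.csr_matrix(
        (vals, ([0] * len(cols), cols)), shape=(1, len(model.vocabulary))
    )


def tfidf_transform_corpus(model: TfidfModel, paragraphs: Sequence[str]) -> sparse.csr_matrix:
    if len(paragraphs) == 0:
        return sparse.csr_matrix((0, len(model.vocabulary)))
    return sparse.vstack([tfidf_transform(model, p) for p in paragraphs]).tocsr()


# --- Classifiers --------------------------------------------------------------

ALGORITHMS = ("logreg", "linear_svc", "random_forest")


def train_classifier(features, labels: Sequence[str], algo: str, seed: int):
    """Fit one of the three classical classifiers on TF-IDF features.

    ``algo`` ∈ {"logreg", "linear_svc", "random_forest"}; training is
    deterministic given ``seed``. Raises on a single-class training set or an
    unknown algorithm name.
    """
    labels = list(labels)
    if len(set(labels)) < 2:
        raise ValueError("training set contains a single class")
    if algo == "logreg":
        clf = LogisticRegression(max_iter=2000, random_state=seed)
    elif algo == "linear_svc":
        clf = LinearSVC(random_state=seed)
    elif algo == "random_forest":
        clf = RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
    else:
        raise ValueError(f"unknown algorithm {algo!r}; expected one of {ALGORITHMS}")
    clf.fit(features, labels)
    return clf


@dataclass
class TextClassifier:
    """TF-IDF featurizer + classical classifier over raw paragraphs."""

    algo: str
    seed: int
    smooth_idf: bool = False
    tfidf: Optional[TfidfModel] = None
    clf: object = None

    def fit(self, paragraphs: Sequence[str], labels: Sequence[str]) -> "TextClassifier":
        self.tfidf = tfidf_fit(paragraphs, smooth=self.smooth_idf)
        X = tfidf_transform_corpus(self.tfidf, paragraphs)
        self.clf = train_classifier(X, labels, self.algo, self.seed)
        return self

    def predict(self, paragraphs: Sequence[str]) -> list[str]:
        if self.tfidf is None or self.clf is None:
            raise RuntimeError("classifier is not fitted")
        X = tfidf_transform_corpus(self.tfidf, paragraphs)
        return list(self.clf.predict(X))


# --- Optional transformer fine-tuning extra -----------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Fine-tuning hyperparameters for the optional transformer classifier."""

    learning_rate: float = 4e-5
    batch_size: int = 32
    grad_clip_norm: float = 1.0
    optimizer: str = "Adam"
    num_epochs: int = 3
    max_seq_length: int = 256


def finetune_transformer(
    train: Sequence[LabeledParagraph],
    config: TrainConfig = TrainConfig(),
    model_name: str = "distilbert-base-uncased",
):
    """Fine-tune a pretrained transformer encoder for paragraph labeling.

    Optional extra: requires the ``bert`` extra (``transformers`` +
    ``simpletransformers``) and locally available pretrained weights. The
    core pipeline never calls this. Fine-tuning is stochastic; run-to-run
    reproducibility is not guaranteed.
    """
    try:
        from simpletransformers.classification import ClassificationModel  # noqa: F401
    except ImportError as exc:
        raise RuntimeError(
            "transformer fine-tuning needs the optional 'bert' extra; "
            "install with: pip install druglabel[bert] "
            "(and ensure pretrained weights for "
            f"{model_name!r} are available locally)"
        ) from exc
    import pandas as pd

    df = pd.DataFrame(
        {"text": [p.text for p in train], "labels": [int(p.label == FOOD_EFFECT) for p in train]}
    )
    model = ClassificationModel(
        "distilbert" if "distilbert" in model_name else "bert",
        model_name,
        args={
            "learning_rate": config.learning_rate,
            "train_batch_size": config.batch_size,
            "max_grad_norm": config.grad_clip_norm,
            "optimizer": "AdamW",
            "num_train_epochs": config.num_epochs,
            "max_seq_length": config.max_seq_length,
        },
        use_cuda=False,
    )
    model.train_model(df)
    return model


# --- Evaluation ---------------------------------------------------------------


def evaluate(pred: Sequence[str], truth: Sequence[str]) -> EvalReport:
    """Confusion counts and precision/recall/F1 with Food Effect positive."""
    if len(pred) != len(truth):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(truth)} truths")
    tp = fp = fn = 0
    for p, t in zip(pred, truth):
        if p == FOOD_EFFECT and t == FOOD_EFFECT:
            tp += 1
        elif p == FOOD_EFFECT and t != FOOD_EFFECT:
            fp += 1
        elif p != FOOD_EFFECT and t == FOOD_EFFECT:
            fn += 1
    return EvalReport.from_counts(tp, fp, fn)


# --- Sampling, splitting, experiment grids ------------------------------------


@dataclass
class SplitSpec:
    """Train/test split specification: 80/20 by default, stratified by source."""

    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


def build_dataset(
    pools: dict[SourceName, Sequence[LabeledParagraph]],
    n_per_source: int,
    seed: int,
) -> list[LabeledParagraph]:
    """Sample ``n_per_source`` paragraphs per source, without replacement.

    Source-balanced by design; class proportions follow the pools.
    Deterministic given ``seed``; raises naming the source whose pool is too
    small.
    """
    rng = random.Random(seed)
    out: list[LabeledParagraph] = []
    for src in sorted(pools, key=lambda s: s.value):
        pool = list(pools[src])
        if len(pool) < n_per_source:
            raise ValueError(
                f"pool for {src.value} has {len(pool)} paragraphs; {n_per_source} requested"
            )
        out.extend(rng.sample(pool, n_per_source))
    return out


def split_train_test(
    dataset: Sequence[LabeledParagraph], spec: SplitSpec
) -> tuple[list[LabeledParagraph], list[LabeledParagraph]]:
    """Random disjoint exhaustive split, stratified by source."""
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    rng = random.Random(spec.seed)
    by_source: dict[SourceName, list[LabeledParagraph]] = {}
    for p in dataset:
        by_source.setdefault(p.source, []).append(p)
    train: list[LabeledParagraph] = []
    test: list[LabeledParagraph] = []
    for src in sorted(by_source, key=lambda s: s.value):
        group = list(by_source[src])
        rng.shuffle(group)
        n_train = int(round(spec.train_fraction * len(group)))
        train.extend(group[:n_train])
        test.extend(group[n_train:])
    return train, test


def _dataset_key(p: LabeledParagraph) -> tuple[str, str, str]:
    return (p.text, p.source.value, p.doc_ref)


def cross_source_eval(
    datasets: dict[str, Sequence[LabeledParagraph]],
    algo: str,
    seed: int,
    train_fraction: float = 0.8,
) -> dict[tuple[str, str], EvalReport]:
    """3×3 train/test generalization grid across sources.

    ``datasets`` holds the two per-source paragraph sets (keys
    ``drugs_at_fda`` and ``dailymed``); each is split train/test with the
    common seed, and ``combined`` is the union of the per-source partitions —
    so no test paragraph ever appears in any training set. Returns nine
    reports keyed ``(train_name, test_name)``.
    """
    required = {"drugs_at_fda", "dailymed"}
    missing = required - set(datasets)
    if missing:
        raise ValueError(f"missing datasets: {sorted(missing)}")
    spec = SplitSpec(train_fraction=train_fraction, seed=seed)
    splits = {name: split_train_test(datasets[name], spec) for name in sorted(required)}
    trains = {name: tr for name, (tr, _te) in splits.items()}
    tests = {name: te for name, (_tr, te) in splits.items()}
    trains["combined"] = trains["drugs_at_fda"] + trains["dailymed"]
    tests["combined"] = tests["drugs_at_fda"] + tests["dailymed"]

    test_keys = {k for te in tests.values() for k in map(_dataset_key, te)}
    for name, tr in trains.items():
        leaked = test_keys & set(map(_dataset_key, tr))
        if leaked:
            raise ValueError(f"train set {name!r} overlaps evaluated test data")

    order = ("drugs_at_fda", "dailymed", "combined")
    grid: dict[tuple[str, str], EvalReport] = {}
    for tr_name in order:
        model = TextClassifier(algo=algo, seed=seed).fit(
            [p.text for p in trains[tr_name]], [p.label for p in trains[tr_name]]
        )
        for te_name in order:
            pred = model.predict([p.text for p in tests[te_name]])
            grid[(tr_name, te_name)] = evaluate(pred, [p.label for p in tests[te_name]])
    return grid


def learning_curve(
    train: Sequence[LabeledParagraph],
    test: Sequence[LabeledParagraph],
    algos: Sequence[str],
    sizes: Sequence[int],
    seed: int,
    reps: int = 1,
) -> dict[str, list[tuple[int, float]]]:
    """Mean test F1 as a function of training-set size, per algorithm.

    For each size, ``reps`` random subsamples of the training set (without
    replacement) are fitted and evaluated on the fixed test set.
    Deterministic given ``seed``; raises when a size exceeds the training
    pool.
    """
    if reps < 1:
        raise ValueError("reps must be ≥ 1")
    sizes = list(sizes)
    for s in sizes:
        if s > len(train):
            raise ValueError(f"training size {s} exceeds pool of {len(train)}")
    test_texts = [p.text for p in test]
    test_labels = [p.label for p in test]
    curves: dict[str, list[tuple[int, float]]] = {a: [] for a in algos}
    for algo in algos:
        for size in sizes:
            f1s = []
            for rep in range(reps):
                rng = random.Random(f"{seed}:{algo}:{size}:{rep}")
                sample = rng.sample(list(train), size)
                try:
                    model = TextClassifier(algo=algo, seed=seed).fit(
                        [p.text for p in sample], [p.label for p in sample]
                    )
                    pred = model.predict(test_texts)
                except ValueError:
                    continue  # single-class subsample at tiny sizes
                f1s.append(evaluate(pred, test_labels).f1)
            curves[algo].append((size, sum(f1s) / len(f1s) if f1s else float("nan")))
    return curves
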