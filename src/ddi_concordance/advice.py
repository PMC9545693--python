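"""Multi-label annotation of clinical-management advice texts.

Free-text management advice attached to a DDI is labelled with up to
nine advice categories (avoid, use with caution, space dosing times,
wash-out, monitor, adjust dose, modify administration, use alternative,
discontinue).  Small corpora are labelled manually and the labels
consumed from CSV; large corpora are labelled by one binary classifier
per category:

* pre-processing: lowercasing, drug-name blinding (every lexicon name is
  replaced by a common token, longest match first), sentence splitting,
  tokenisation on non-alphanumeric boundaries, Porter stemming;
* sentence encoding: tf-idf weights
  ``tfidf(w, s) = tf(w, s) * ln(N / (df(w) + 1))`` where ``tf`` is the
  relative frequency of the word in the sentence, ``N`` the corpus
  sentence count and ``df(w)`` the number of sentences containing ``w``;
* a linear-kernel SVM with inverse-class-frequency ("balanced") class
  weights, scored by leave-one-out cross-validation;
* threshold selection on the LOO decision scores: among operating points
  with positive predictive value at or above a floor (0.80 by default),
  the one with maximum sensitivity is kept; a category with no
  qualifying point is REJECTED — rejection is a first-class outcome.
"""
from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.svm import SVC

from ._porter import porter_stem
from .errors import DegenerateTrainingSet, IdMismatch

logger = logging.getLogger(__name__)

ADVICE_CATEGORIES: tuple[str, ...] = (
    "avoid",
    "use_with_caution",
    "space_dosing_times",
    "wash_out",
    "monitor",
    "adjust_dose",
    "modify_administration",
    "use_alternative",
    "discontinue",
)

BLIND_TOKEN = "DRUG"

_SENTENCE_SPLIT = re.compile(r"(?<=[.!?])\s+")
_TOKEN = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class BlindedSentence:
    """A pre-processed sentence: blinded text plus stemmed token roots."""

    raw_text: str
    blinded_text: str
    token_roots: tuple[str, ...]
    provenance: str | None = None


def blind_names(text: str, drug_lexicon: Iterable[str], token: str = BLIND_TOKEN) -> str:
    """Lowercase ``text`` and replace every lexicon name by ``token``.

    Longest names are replaced first so that multi-word names ("yellow
    fever vaccine") are blinded as a unit; matches respect word
    boundaries.
    """
    lowered = text.lower()
    names = sorted({n.strip().lower() for n in drug_lexicon if n.strip()}, key=len, reverse=True)
    if not names:
        return lowered
    pattern = re.compile(r"\b(?:" + "|".join(re.escape(n) for n in names) + r")\b")
    return pattern.sub(token, lowered)


def preprocess(
    text: str,
    drug_lexicon: Iterable[str] = (),
    provenance: str | None = None,
    split_sentences: bool = True,
) -> list[BlindedSentence]:
    """Blind, sentence-split, tokenise and stem a free-text description.

    Sentences that contain no alphanumeric token after stemming (for
    example a stray full stop) are dropped.  With
    ``split_sentences=False`` the whole text becomes a single unit, which
    is how pre-sentencised corpora are consumed.
    """
    blinded_full = blind_names(text, drug_lexicon)
    chunks = _SENTENCE_SPLIT.split(blinded_full) if split_sentences else [blinded_full]
    out: list[BlindedSentence] = []
    for chunk in chunks:
        chunk = chunk.strip()
        if not chunk:
            continue
        roots = tuple(porter_stem(tok) for tok in _TOKEN.findall(chunk.lower()))
        if not roots:
            continue
        out.append(
            BlindedSentence(
                raw_text=text,
                blinded_text=chunk,
                token_roots=roots,
                provenance=provenance,
            )
        )
    return out


# ---------------------------------------------------------------------------
# tf-idf
# ---------------------------------------------------------------------------

@dataclass
class TfIdfModel:
    """Corpus statistics for tf-idf sentence encoding."""

    n_sentences: int
    df: dict[str, int]
    vocabulary: dict[str, int]

    @property
    def n_features(self) -> int:
        return len(self.vocabulary)


def tfidf_fit(corpus: Sequence[BlindedSentence]) -> TfIdfModel:
    """Document frequencies and vocabulary over a sentence corpus."""
    if not corpus:
        raise ValueError("cannot fit tf-idf on an empty corpus")
    df: dict[str, int] = {}
    for sentence in corpus:
        for root in set(sentence.token_roots):
            df[root] = df.get(root, 0) + 1
    vocabulary = {root: i for i, root in enumerate(sorted(df))}
    return TfIdfModel(n_sentences=len(corpus), df=df, vocabulary=vocabulary)


def tfidf_transform(model: TfIdfModel, sentence: BlindedSentence) -> np.ndarray:
    """Weight vector ``tf(w,s) * ln(N / (df(w)+1))``; OOV words ignored."""
    roots = sentence.token_roots
    if not roots:
        raise ValueError("cannot encode a sentence with no tokens")
    vec = np.zeros(model.n_features)
    n_tokens = len(roots)
    counts: dict[str, int] = {}
    for root in roots:
        counts[root] = counts.get(root, 0) + 1
    for root, count in counts.items():
        idx = model.vocabulary.get(root)
        if idx is None:
            continue
        tf = count / n_tokens
        idf = math.log(model.n_sentences / (model.df[root] + 1))
        vec[idx] = tf * idf
    return vec


def tfidf_matrix(model: TfIdfModel, corpus: Sequence[BlindedSentence]) -> np.ndarray:
    return np.vstack([tfidf_transform(model, s) for s in corpus])


# ---------------------------------------------------------------------------
# Linear SVM, LOO-CV and threshold selection
# ---------------------------------------------------------------------------

def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    category: str | None = None,
    c: float = 1.0,
    class_weight: str | Mapping[int, float] = "balanced",
) -> SVC:
    """Soft-margin linear SVM with per-class misclassification weights.

    "balanced" weights are inversely proportional to class frequency,
    compensating for the rarity of most advice categories.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingSet(
            f"training set for {category or 'category'} contains a single class"
        )
    model = SVC(kernel="linear", C=c, class_weight=class_weight)
    model.fit(X, y)
    return model


def loocv_scores(
    X: np.ndarray,
    y: np.ndarray,
    c: float = 1.0,
    class_weight: str | Mapping[int, float] = "balanced",
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out decision scores.

    Returns ``(scores, kept_indices)``: the score for sentence *i* comes
    from a model trained on all sentences except *i*.  Folds whose
    training remainder is single-class are skipped and logged; with
    constant labels every fold degenerates and both arrays are empty.
    """
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 instances")
    scores: list[float] = []
    kept: list[int] = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_train = y[mask]
        if len(np.unique(y_train)) < 2:
            logger.debug("LOO fold %d skipped: degenerate training remainder", i)
            continue
        model = SVC(kernel="linear", C=c, class_weight=class_weight)
        model.fit(X[mask], y_train)
        scores.append(float(model.decision_function(X[i : i + 1])[0]))
        kept.append(i)
    return np.asarray(scores), np.asarray(kept, dtype=int)


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    ppv: float | None  # None when no instance is predicted positive
    sensitivity: float


@dataclass
class RocCurve:
    """Operating points from decision scores, thresholds strictly decreasing."""

    points: list[OperatingPoint]

    @classmethod
    def from_scores(cls, scores: np.ndarray, labels: np.ndarray) -> "RocCurve":
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=int)
        n_pos = int(labels.sum())
        if n_pos == 0:
            raise ValueError("ROC analysis needs at least one positive instance")
        uniq = np.unique(scores)
        thresholds = [math.inf]
        thresholds.extend(((uniq[i] + uniq[i + 1]) / 2.0 for i in range(len(uniq) - 1)))
        thresholds.append(-math.inf)
        thresholds.sort(reverse=True)
        points = []
        for t in thresholds:
            pred = scores >= t
            tp = int((pred & (labels == 1)).sum())
            fp = int((pred & (labels == 0)).sum())
            ppv = tp / (tp + fp) if (tp + fp) > 0 else None
            points.append(OperatingPoint(threshold=t, ppv=ppv, sensitivity=tp / n_pos))
        return cls(points=points)


@dataclass(frozen=True)
class ThresholdSelection:
    """Outcome of PPV-constrained threshold selection."""

    status: str  # "ACTIVE" or "REJECTED"
    threshold: float | None
    ppv: float | None
    sensitivity: float | None

    @property
    def is_active(self) -> bool:
        return self.status == "ACTIVE"


def roc_and_select_threshold(
    scores: np.ndarray,
    labels: np.ndarray,
    min_ppv: float = 0.80,
) -> tuple[ThresholdSelection, RocCurve]:
    """Pick the maximum-sensitivity operating point with PPV >= ``min_ppv``.

    Candidate thresholds are midpoints between consecutive sorted unique
    scores plus +/- infinity sentinels.  Ties on sensitivity are broken
    by higher PPV, then by higher threshold.  With no qualifying point
    the classifier is REJECTED.
    """
    roc = RocCurve.from_scores(scores, labels)
    candidates = [p for p in roc.points if p.ppv is not None and p.ppv >= min_ppv]
    if not candidates:
        return ThresholdSelection("REJECTED", None, None, None), roc
    best = max(candidates, key=lambda p: (p.sensitivity, p.ppv, p.threshold))
    return (
        ThresholdSelection("ACTIVE", best.threshold, best.ppv, best.sensitivity),
        roc,
    )


# ---------------------------------------------------------------------------
# Per-category classifiers and corpus annotation
# ---------------------------------------------------------------------------

@dataclass
class AdviceClassifier:
    """One category's trained decision function plus selection outcome."""

    category: str
    selection: ThresholdSelection
    model: SVC | None = None
    roc: RocCurve | None = None

    @property
    def is_active(self) -> bool:
        return self.selection.is_active and self.model is not None

    def scores(self, X: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise DegenerateTrainingSet(f"{self.category}: no trained model")
        return self.model.decision_function(X)

    def decide(self, X: np.ndarray) -> np.ndarray:
        if not self.is_active:
            raise ValueError(f"{self.category}: classifier is not ACTIVE")
        return self.scores(X) >= self.selection.threshold


@dataclass
class AdviceModel:
    """tf-idf encoder plus one classifier per advice category."""

    tfidf: TfIdfModel
    classifiers: dict[str, AdviceClassifier] = field(default_factory=dict)

    @property
    def active_categories(self) -> list[str]:
        return [c for c, clf in self.classifiers.items() if clf.is_active]

    def annotate(self, sentences: Sequence[BlindedSentence]) -> list[frozenset[str]]:
        return annotate_corpus(self, sentences)

    def report(self) -> dict:
        out = {}
        for cat, clf in self.classifiers.items():
            sel = clf.selection
            out[cat] = {
                "status": sel.status,
                "threshold": sel.threshold,
                "loo_ppv": sel.ppv,
                "loo_sensitivity": sel.sensitivity,
            }
        return out


def fit_advice_classifiers(
    corpus: Sequence[BlindedSentence],
    label_sets: Sequence[Iterable[str]],
    categories: Sequence[str] = ADVICE_CATEGORIES,
    min_ppv: float = 0.80,
    c: float = 1.0,
) -> AdviceModel:
    """Train, LOO-score and threshold one classifier per category.

    ``label_sets[i]`` holds the true categories of ``corpus[i]``.  A
    category with no positives (or no negatives) in the training corpus
    is marked REJECTED rather than raising.
    """
    if len(corpus) != len(label_sets):
        raise ValueError("corpus and labels must be aligned")
    tfidf = tfidf_fit(corpus)
    X = tfidf_matrix(tfidf, corpus)
    model = AdviceModel(tfidf=tfidf)
    for category in categories:
        y = np.array([1 if category in labels else 0 for labels in label_sets], dtype=int)
        if len(np.unique(y)) < 2:
            logger.warning("category %s: degenerate training set, REJECTED", category)
            model.classifiers[category] = AdviceClassifier(
                category=category,
                selection=ThresholdSelection("REJECTED", None, None, None),
            )
            continue
        scores, kept = loocv_scores(X, y, c=c)
        if len(kept) == 0 or y[kept].sum() == 0:
            # e.g. a single positive instance: its own fold degenerates and
            # the surviving scores carry no positives to anchor the ROC
            logger.warning("category %s: no scorable positives under LOO, REJECTED", category)
            model.classifiers[category] = AdviceClassifier(
                category=category,
                selection=ThresholdSelection("REJECTED", None, None, None),
            )
            continue
        selection, roc = roc_and_select_threshold(scores, y[kept], min_ppv=min_ppv)
        svc = train_classifier(X, y, category=category, c=c) if selection.is_active else None
        model.classifiers[category] = AdviceClassifier(
            category=category, selection=selection, model=svc, roc=roc
        )
    return model


def annotate_corpus(
    model: AdviceModel,
    sentences: Sequence[BlindedSentence],
) -> list[frozenset[str]]:
    """Independent binary decision per ACTIVE category for each sentence.

    Sentences with no positive decision get the empty set (no-advice).
    """
    active = [model.classifiers[c] for c in model.active_categories]
    if not active:
        raise ValueError("at least one ACTIVE classifier is required")
    X = tfidf_matrix(model.tfidf, sentences)
    decisions = {clf.category: clf.decide(X) for clf in active}
    return [
        frozenset(cat for cat, dec in decisions.items() if dec[i])
        for i in range(len(sentences))
    ]


def aggregate_advice(sentence_labels: Iterable[Iterable[str]]) -> frozenset[str]:
    """Union of the label sets of a record's sentences."""
    out: set[str] = set()
    for labels in sentence_labels:
        out.update(labels)
    return frozenset(out)


# ---------------------------------------------------------------------------
# Hold-out validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoryMetrics:
    tp: int
    fp: int
    fn: int
    ppv: float | None
    sensitivity: float | None
    f1: float | None


@dataclass
class ValidationReport:
    """Per-category PPV / sensitivity / F1 on a manually annotated hold-out."""

    metrics: dict[str, CategoryMetrics]

    def as_dict(self) -> dict:
        return {
            cat: {
                "tp": m.tp, "fp": m.fp, "fn": m.fn,
                "ppv": m.ppv, "sensitivity": m.sensitivity, "f1": m.f1,
            }
            for cat, m in self.metrics.items()
        }


def validate_holdout(
    auto_labels: Mapping[str, Iterable[str]],
    manual_labels: Mapping[str, Iterable[str]],
    categories: Sequence[str] = ADVICE_CATEGORIES,
) -> ValidationReport:
    """Compare automatic against manual labels on the same sentence ids.

    Undefined metrics (empty confusion margins) are reported as None,
    never as zero.
    """
    if set(auto_labels) != set(manual_labels):
        raise IdMismatch("automatic and manual annotation cover different sentence ids")
    metrics: dict[str, CategoryMetrics] = {}
    for category in categories:
        tp = fp = fn = 0
        for sid in auto_labels:
            predicted = category in set(auto_labels[sid])
            actual = category in set(manual_labels[sid])
            if predicted and actual:
                tp += 1
            elif predicted:
                fp += 1
            elif actual:
                fn += 1
        ppv = tp / (tp + fp) if (tp + fp) > 0 else None
        sens = tp / (tp + fn) if (tp + fn) > 0 else None
        if ppv is not None and sens is not None and (ppv + sens) > 0:
            f1 = 2 * ppv * sens / (ppv + sens)
        else:
            f1 = None
        metrics[category] = CategoryMetrics(tp=tp, fp=fp, fn=fn, ppv=ppv, sensitivity=sens, f1=f1)
    return ValidationReport(metrics=metrics)
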