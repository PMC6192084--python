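"""Case-based reasoning over labelled survey cases.

Collective knowledge is the archive of past labelled cases.  A new
record is classified by the classic retrieve/reuse/retain cycle: find
the k most similar stored cases, take the majority of their labels
(ties go to the minority class), and optionally retain the solved case.

Similarity is one minus a mixed distance: a range-normalized Euclidean
distance over numeric features blended with a Hamming mismatch fraction
over nominal features, each block weighted by its (weighted) dimension
count, so the result always lies in [0, 1] and equals 1 for identical
vectors.  No revise step is implemented — no adaptation of past
solutions is needed for a binary label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .crowd_reasoner import MAJOR, MINOR, Vote
from .errors import DomainError, RetrievalError, SchemaError
from .io_survey import (
    ABNORMAL,
    LIKERT_COLUMNS,
    NOMINAL_COLUMNS,
    NUMERIC_COLUMNS,
    SurveyDataset,
    SurveyRecord,
)

#: Default kind per survey column: Likert and numeric covariates are
#: treated as numeric; coded profile fields are nominal.
DEFAULT_KINDS = {
    **{c: "numeric" for c in LIKERT_COLUMNS},
    **{c: "numeric" for c in NUMERIC_COLUMNS},
    **{c: "nominal" for c in NOMINAL_COLUMNS},
}


@dataclass(frozen=True)
class Case:
    """A labelled past record with its cached normalized vector."""

    record: SurveyRecord
    normalized: np.ndarray = field(repr=False)

    @property
    def label(self) -> str:
        return self.record.label


@dataclass
class CaseBase:
    """Stored cases plus the normalization fitted from them.

    ``weights`` (optional, per feature) bias the similarity metric;
    the default of all ones treats every feature equally.  An optional
    crowd-knowledge bridge sets weights to association-strength
    magnitudes via :meth:`with_kb_weights`.
    """

    feature_names: list[str]
    feature_kinds: dict[str, str]
    normalization: dict[str, tuple[float, float]]
    cases: list[Case] = field(default_factory=list)
    weights: np.ndarray | None = None

    def __post_init__(self):
        self._numeric_mask = np.array(
            [self.feature_kinds[f] == "numeric" for f in self.feature_names]
        )
        if self.weights is None:
            self.weights = np.ones(len(self.feature_names))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.feature_names),):
            raise DomainError("weights must have one entry per feature")
        self._matrix = (
            np.vstack([c.normalized for c in self.cases])
            if self.cases else np.empty((0, len(self.feature_names)))
        )

    # -- construction ------------------------------------------------------

    @classmethod
    def fit(
        cls,
        dataset: SurveyDataset,
        feature_names: list[str] | None = None,
        feature_kinds: dict[str, str] | None = None,
        weights=None,
    ) -> "CaseBase":
        """Build a case base from a labelled dataset.

        Normalization ranges (min, max) are learned from the stored
        cases only; later queries are clipped into the learned range.
        """
        if not dataset.is_labelled:
            raise DomainError("case base requires a labelled dataset")
        names = list(feature_names or dataset.feature_columns)
        kinds = dict(feature_kinds or {})
        for f in names:
            kinds.setdefault(f, DEFAULT_KINDS.get(f, "numeric"))
        norm = {}
        for f in names:
            values = [r.features[f] for r in dataset.records]
            norm[f] = (float(min(values)), float(max(values)))
        base = cls(names, kinds, norm, [], weights)
        base.cases = [
            Case(r, normalize_features(base, r)) for r in dataset.records
        ]
        base._matrix = np.vstack([c.normalized for c in base.cases])
        return base

    def with_kb_weights(self, kb, target_con: str) -> "CaseBase":
        """Return a copy weighting features by |concept strength| from a
        crowd-knowledge base (features absent from the profile get a
        small floor weight so similarity stays defined)."""
        strength = kb.profile(target_con).concept_strength
        w = np.array([abs(strength.get(f, 0.0)) for f in self.feature_names])
        floor = (w[w > 0].min() if (w > 0).any() else 1.0) * 1e-3
        return CaseBase(
            self.feature_names, self.feature_kinds, self.normalization,
            list(self.cases), np.maximum(w, floor),
        )

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self):
        return iter(self.cases)


def normalize_features(case_base: CaseBase, record: SurveyRecord) -> np.ndarray:
    """Project a record onto the case base's normalized feature space.

    Numeric features map to (v - min)/(max - min) clipped into [0, 1]
    (a constant training feature maps to 0); nominal features pass
    through as their integer codes.
    """
    out = np.empty(len(case_base.feature_names))
    for i, f in enumerate(case_base.feature_names):
        if f not in record.features:
            raise SchemaError(f"record {record.record_id} lacks feature {f!r}")
        v = float(record.features[f])
        if case_base.feature_kinds[f] == "numeric":
            lo, hi = case_base.normalization[f]
            out[i] = 0.0 if hi == lo else min(1.0, max(0.0, (v - lo) / (hi - lo)))
        else:
            out[i] = v
    return out


def similarity(a, b, numeric_mask, weights=None) -> float:
    """Similarity in [0, 1] between two normalized vectors.

    distance = (W_num * euclid_norm + W_nom * hamming) / (W_num + W_nom)
    where euclid_norm is the weighted Euclidean distance over numeric
    components divided by its maximum, and hamming is the weighted
    mismatch fraction over nominal components.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    mask = np.asarray(numeric_mask, dtype=bool)
    if a.shape != b.shape or a.shape != mask.shape:
        raise DomainError("vectors and numeric mask must share one length")
    w = np.ones(a.shape) if weights is None else np.asarray(weights, dtype=float)
    w_num = float(w[mask].sum())
    w_nom = float(w[~mask].sum())
    dist = 0.0
    if w_num > 0:
        euclid = math.sqrt(float(np.sum(w[mask] * (a[mask] - b[mask]) ** 2)) / w_num)
        dist += w_num * euclid
    if w_nom > 0:
        hamming = float(np.sum(w[~mask] * (a[~mask] != b[~mask]))) / w_nom
        dist += w_nom * hamming
    total = w_num + w_nom
    if total == 0:
        raise DomainError("all feature weights are zero")
    return 1.0 - dist / total


def _similarities(case_base: CaseBase, query: np.ndarray) -> np.ndarray:
    """Vectorized similarity of a query against every stored case."""
    X = case_base._matrix
    mask = case_base._numeric_mask
    w = case_base.weights
    w_num = float(w[mask].sum())
    w_nom = float(w[~mask].sum())
    dist = np.zeros(len(X))
    if w_num > 0:
        sq = np.sum(w[mask] * (X[:, mask] - query[mask]) ** 2, axis=1)
        dist += w_num * np.sqrt(sq / w_num)
    if w_nom > 0:
        mism = np.sum(w[~mask] * (X[:, ~mask] != query[~mask]), axis=1)
        dist += w_nom * mism / w_nom
    return 1.0 - dist / (w_num + w_nom)


def retrieve_k(case_base: CaseBase, record: SurveyRecord, k: int):
    """The k most similar cases, descending; ties break on record id."""
    if len(case_base) == 0:
        raise RetrievalError("case base is empty")
    if not 1 <= k <= len(case_base):
        raise RetrievalError(f"k must be in 1..{len(case_base)}, got {k}")
    sims = _similarities(case_base, normalize_features(case_base, record))
    ids = np.array([c.record.record_id for c in case_base.cases])
    order = np.lexsort((ids, -sims))[:k]
    return [(case_base.cases[i], float(sims[i])) for i in order]


def cbr_classify(case_base: CaseBase, record: SurveyRecord, k: int = 3) -> Vote:
    """Majority label among the k nearest cases; ties go to the minority
    class, keeping the reasoner sensitive to rare abnormal cases."""
    retrieved = retrieve_k(case_base, record, k)
    minor_votes = sum(1 for case, _ in retrieved if case.label == ABNORMAL)
    return Vote("cbr", MINOR if 2 * minor_votes >= k else MAJOR)


def retain_case(case_base: CaseBase, record: SurveyRecord, refit: bool = False) -> CaseBase:
    """Return a new case base with the labelled record added.

    With ``refit`` false (default) the existing normalization is kept,
    so predictions for unrelated records are unchanged; with ``refit``
    true the (min, max) ranges are re-learned from all cases.
    """
    if record.label is None:
        raise DomainError("can only retain a labelled record")
    if refit:
        norm = {}
        for f in case_base.feature_names:
            values = [c.record.features[f] for c in case_base.cases] + [record.features[f]]
            norm[f] = (float(min(values)), float(max(values)))
    else:
        norm = dict(case_base.normalization)
    new = CaseBase(
        list(case_base.feature_names), dict(case_base.feature_kinds), norm,
        [], case_base.weights.copy(),
    )
    records = [c.record for c in case_base.cases] + [record]
    new.cases = [Case(r, normalize_features(new, r)) for r in records]
    new._matrix = np.vstack([c.normalized for c in new.cases])
    return new
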