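"""Classify a survey record from crowd knowledge alone.

Two minority-sensitive votes are derived from the knowledge base's
minority-evidence feature set J_con (typically con = the most severe
concept):

* **subjective average** — the record's association-weighted mean of its
  normalized J_con feature values is compared with the mean of the same
  score over a reference case base; strictly above the reference means
  *minor*.
* **absolute maximum** — the record is *minor* when at least ``m_min``
  J_con features sit at the extreme end of the scale (>= ``tau`` for
  positively-directed features, mirrored for negatively-directed ones).

The crowd decision is the OR of the two votes: one *minor* vote
suffices, keeping the method sensitive to the minority class.
"""

from __future__ import annotations

from dataclasses import dataclass

from .crowd_kb import CrowdKnowledgeBase
from .errors import AbstentionError, DomainError
from .io_survey import ABNORMAL, NOMINAL_COLUMNS, NORMAL, NUMERIC_COLUMNS, SurveyRecord

#: Scale bounds of the Likert items.
LIKERT_MIN, LIKERT_MAX = 1, 7

#: Survey columns that are not on the 7-point response scale; both crowd
#: votes are defined on scale positions, so these never contribute.
NON_SCALE_COLUMNS = frozenset(NOMINAL_COLUMNS) | frozenset(NUMERIC_COLUMNS)

MINOR = ABNORMAL
MAJOR = NORMAL


@dataclass(frozen=True)
class Vote:
    """One method's binary decision for one record."""

    method: str
    decision: str

    @property
    def is_minor(self) -> bool:
        return self.decision == MINOR


@dataclass(frozen=True)
class CrowdScore:
    """Continuous minority score of a record and its case-base reference."""

    record_id: int
    score: float
    reference: float


def likert_norm(value: int) -> float:
    """Map a Likert response 1..7 onto [0, 1]."""
    if not LIKERT_MIN <= value <= LIKERT_MAX:
        raise DomainError(f"Likert value {value} outside {LIKERT_MIN}..{LIKERT_MAX}")
    return (value - LIKERT_MIN) / (LIKERT_MAX - LIKERT_MIN)


def _target_profile(kb: CrowdKnowledgeBase, target_con: str):
    profile = kb.profile(target_con)
    if not profile.member_features:
        raise AbstentionError(f"concept {target_con!r} has no member features")
    return profile


def minority_score(record: SurveyRecord, kb: CrowdKnowledgeBase, target_con: str) -> float:
    """Association-weighted mean of the record's normalized J_con values.

    Weights are the magnitudes of the concept strengths; features with a
    negative direction contribute with reversed normalization
    ``1 - norm(v)`` so that low values count as minority evidence.
    Result lies in [0, 1].
    """
    profile = _target_profile(kb, target_con)
    num = 0.0
    den = 0.0
    for feature in sorted(profile.member_features):
        if feature not in record.features or feature in NON_SCALE_COLUMNS:
            continue
        alpha = profile.concept_strength[feature]
        value = likert_norm(record.features[feature])
        if alpha < 0:
            value = 1.0 - value
        num += abs(alpha) * value
        den += abs(alpha)
    if den == 0.0:
        raise AbstentionError(
            f"record {record.record_id}: no usable {target_con!r} features with weight"
        )
    return num / den


def reference_score(kb: CrowdKnowledgeBase, case_base, target_con: str) -> float:
    """Mean minority score over a reference population of cases.

    ``case_base`` is anything iterable over objects with a ``record``
    attribute or SurveyRecords directly (a CaseBase or a SurveyDataset).
    """
    scores = [
        minority_score(getattr(item, "record", item), kb, target_con)
        for item in case_base
    ]
    if not scores:
        raise AbstentionError("empty reference case base")
    return sum(scores) / len(scores)


def subjective_average_vote(
    record: SurveyRecord,
    kb: CrowdKnowledgeBase,
    case_base,
    target_con: str,
    reference: float | None = None,
) -> Vote:
    """Minor iff the record's minority score strictly exceeds the
    case-base mean (a record exactly at the reference stays major)."""
    if reference is None:
        reference = reference_score(kb, case_base, target_con)
    score = minority_score(record, kb, target_con)
    return Vote("subjective_average", MINOR if score > reference else MAJOR)


def absolute_maximum_vote(
    record: SurveyRecord,
    kb: CrowdKnowledgeBase,
    target_con: str,
    tau: int = 6,
    m_min: int = 1,
) -> Vote:
    """Minor iff >= ``m_min`` J_con features are at the scale extreme.

    Positively-directed features trigger at value >= ``tau``;
    negatively-directed features trigger at the mirrored threshold
    value <= (scale max + scale min - tau).
    """
    if not LIKERT_MIN <= tau <= LIKERT_MAX:
        raise DomainError(f"tau must be in {LIKERT_MIN}..{LIKERT_MAX}, got {tau}")
    if m_min < 1:
        raise DomainError(f"m_min must be >= 1, got {m_min}")
    profile = _target_profile(kb, target_con)
    mirrored = LIKERT_MAX + LIKERT_MIN - tau
    hits = 0
    usable = 0
    for feature in profile.member_features:
        if feature not in record.features or feature in NON_SCALE_COLUMNS:
            continue
        usable += 1
        value = record.features[feature]
        alpha = profile.concept_strength[feature]
        if (alpha >= 0 and value >= tau) or (alpha < 0 and value <= mirrored):
            hits += 1
    if usable == 0:
        raise AbstentionError(
            f"record {record.record_id}: no {target_con!r} features present"
        )
    return Vote("absolute_maximum", MINOR if hits >= m_min else MAJOR)


def crowd_classify(
    record: SurveyRecord,
    kb: CrowdKnowledgeBase,
    case_base,
    target_con: str,
    tau: int = 6,
    m_min: int = 1,
    reference: float | None = None,
) -> Vote:
    """Crowd decision: minor iff either sub-method votes minor.

    If one sub-method cannot produce a vote the other decides alone;
    if neither can, the crowd reasoner abstains.
    """
    votes = []
    try:
        votes.append(subjective_average_vote(record, kb, case_base, target_con, reference))
    except AbstentionError:
        pass
    try:
        votes.append(absolute_maximum_vote(record, kb, target_con, tau, m_min))
    except AbstentionError:
        pass
    if not votes:
        raise AbstentionError(f"record {record.record_id}: crowd reasoner abstains")
    decision = MINOR if any(v.is_minor for v in votes) else MAJOR
    return Vote("crowd", decision)
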