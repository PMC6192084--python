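"""Minority-sensitive fusion of the crowd vote and the CBR vote.

The combination rule is a one-sided OR: a record is classified into the
minority class as soon as either reasoner says so, and into the
majority class only when both agree on it.  This trades majority-class
false positives for minority-class recall, which is the desirable
direction under heavy class imbalance (missing a rare abnormal case is
costlier than flagging a normal one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .cbr_reasoner import CaseBase, cbr_classify
from .crowd_kb import CrowdKnowledgeBase
from .crowd_reasoner import (
    MAJOR,
    MINOR,
    Vote,
    crowd_classify,
    minority_score,
    reference_score,
)
from .errors import AbstentionError, PredictionError
from .io_survey import SurveyDataset, SurveyRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HybridPrediction:
    """Both component votes and the fused decision for one record."""

    record_id: int
    crowd_vote: Vote | None
    cbr_vote: Vote
    decision: str
    crowd_score: float | None = None

    def __post_init__(self):
        want_minor = (self.crowd_vote is not None and self.crowd_vote.is_minor) \
            or self.cbr_vote.is_minor
        if (self.decision == MINOR) != want_minor:
            raise PredictionError("decision inconsistent with component votes")


def combine_votes(crowd_vote: Vote | None, cbr_vote: Vote) -> str:
    """The four-row decision table: minor iff any component is minor."""
    if crowd_vote is not None and crowd_vote.is_minor:
        return MINOR
    return MINOR if cbr_vote.is_minor else MAJOR


def hybrid_classify(
    record: SurveyRecord,
    kb: CrowdKnowledgeBase,
    case_base: CaseBase,
    target_con: str,
    k: int = 3,
    tau: int = 6,
    m_min: int = 1,
    reference: float | None = None,
) -> HybridPrediction:
    """Classify one record with both reasoners and fuse the votes.

    If the crowd reasoner abstains (e.g. the target concept has no
    member features in the record), the decision degrades to CBR alone
    with a logged warning; classification stays total as long as the
    case base is non-empty.
    """
    crowd_vote: Vote | None = None
    score: float | None = None
    try:
        crowd_vote = crowd_classify(record, kb, case_base, target_con, tau, m_min, reference)
    except AbstentionError as exc:
        logger.warning("crowd reasoner abstained for record %s: %s", record.record_id, exc)
    else:
        try:
            score = minority_score(record, kb, target_con)
        except AbstentionError:
            score = None
    cbr_vote = cbr_classify(case_base, record, k)
    return HybridPrediction(
        record_id=record.record_id,
        crowd_vote=crowd_vote,
        cbr_vote=cbr_vote,
        decision=combine_votes(crowd_vote, cbr_vote),
        crowd_score=score,
    )


def classify_dataset(
    dataset: SurveyDataset,
    kb: CrowdKnowledgeBase,
    case_base: CaseBase,
    target_con: str,
    k: int = 3,
    tau: int = 6,
    m_min: int = 1,
) -> list[HybridPrediction]:
    """Batch hybrid classification; the subjective-average reference
    mean is computed once from the case base and shared."""
    try:
        reference = reference_score(kb, case_base, target_con)
    except AbstentionError:
        reference = None
    return [
        hybrid_classify(r, kb, case_base, target_con, k, tau, m_min, reference)
        for r in dataset
    ]
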