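"""Crowd-knowledge base built from word co-occurrence hit counts.

Crowd knowledge here means associations mined from open, user-generated
sources: for a class word (e.g. *depression*) qualified by degree adverbs
into severity concepts (*normal depression*, *serious depression*), a
search engine reports how often each candidate feature word co-occurs
with each degree-qualified class term.  From those hit counts this module
computes:

* the association strength between two words — a Jaccard-style ratio of
  the co-occurrence count to the union count,
      alpha = f_xy / (f_x + f_y - f_xy),
* a signed direction beta per feature (does the feature move with or
  against the class concept), inferred by correlation against labelled
  cases or supplied by configuration,
* per-concept aggregate strengths (a hit-count-weighted signed mean over
  the concept's degree levels), and
* the feature partition J_con: each feature is assigned to the concept
  with which its association is strongest (optionally requiring a
  multiplicative margin over the runner-up).

Hit counts come from search engines and routinely violate set semantics
(a co-occurrence count can exceed a single-word count); counts are
accepted as given and only non-negativity is enforced.
"""

from __future__ import annotations

import datetime
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    DomainError,
    SchemaError,
    UndefinedDirectionError,
    ValidationError,
)

#: Conventional degree-concept names, least to most severe.
CONCEPT_NAMES = ("PC", "WC", "MC", "SC")


# --------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class DegreeLevel:
    """A degree-adverb-qualified variant of the class word.

    ``index`` orders levels by severity (1 = least severe).  Each level
    doubles as a concept: the feature partition assigns features to the
    level whose qualified class term they co-occur with most strongly.
    """

    name: str
    index: int
    adverbs: tuple[str, ...] = ()

    def __post_init__(self):
        if self.index < 1:
            raise ValidationError(f"level index must be >= 1, got {self.index}")


@dataclass(frozen=True)
class ConceptSpec:
    """The class word, its severity levels, and optional synonyms."""

    class_word: str
    levels: tuple[DegreeLevel, ...]
    synonym_words: tuple[str, ...] = ()

    def __post_init__(self):
        names = [lv.name for lv in self.levels]
        if len(set(names)) != len(names):
            raise ValidationError("level names must be distinct")
        if len(self.levels) < 2:
            raise ValidationError("need at least 2 degree levels")
        if sorted(lv.index for lv in self.levels) != list(range(1, len(self.levels) + 1)):
            raise ValidationError("level indices must be consecutive 1..K")

    @property
    def level_names(self) -> list[str]:
        """Level names ordered least to most severe."""
        return [lv.name for lv in sorted(self.levels, key=lambda lv: lv.index)]


@dataclass(frozen=True)
class FrequencyRecord:
    """Hit counts for one feature word: alone and with each class level."""

    feature: str
    cooccur: dict[str, int] = field(repr=False)
    count_alone: int | None = None

    def __post_init__(self):
        if self.count_alone is not None and self.count_alone < 0:
            raise ValidationError(f"{self.feature}: negative count_alone")
        for level, c in self.cooccur.items():
            if c < 0:
                raise ValidationError(f"{self.feature}: negative count for {level!r}")


@dataclass
class FrequencyTable:
    """A collection of FrequencyRecords over a common set of levels."""

    records: list[FrequencyRecord]
    level_names: list[str]

    def __post_init__(self):
        for r in self.records:
            missing = set(self.level_names) - set(r.cooccur)
            if missing:
                raise SchemaError(f"{r.feature}: missing counts for levels {sorted(missing)}")

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def features(self) -> list[str]:
        return [r.feature for r in self.records]


@dataclass(frozen=True)
class AssociationEntry:
    """Strength and direction of one feature at one degree level."""

    feature: str
    level: str
    strength: float
    direction: int

    def __post_init__(self):
        if not 0.0 <= self.strength <= 1.0:
            raise ValidationError(f"strength must be in [0,1], got {self.strength}")
        if self.direction not in (+1, -1):
            raise ValidationError(f"direction must be +1 or -1, got {self.direction}")


@dataclass
class ConceptProfile:
    """The member features J_con of one concept with their signed strengths."""

    concept: str
    member_features: set[str]
    concept_strength: dict[str, float]


@dataclass
class CrowdKnowledgeBase:
    """Association entries plus the concept partition, with provenance."""

    concept_spec: ConceptSpec
    class_level_counts: dict[str, int]
    entries: list[AssociationEntry]
    profiles: dict[str, ConceptProfile]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        entry_features = {e.feature for e in self.entries}
        seen: set[str] = set()
        for profile in self.profiles.values():
            overlap = seen & profile.member_features
            if overlap:
                raise ValidationError(f"profiles overlap on {sorted(overlap)}")
            seen |= profile.member_features
            stray = profile.member_features - entry_features
            if stray:
                raise ValidationError(f"profile features without entries: {sorted(stray)}")

    @property
    def features(self) -> list[str]:
        return sorted({e.feature for e in self.entries})

    def profile(self, concept: str) -> ConceptProfile:
        try:
            return self.profiles[concept]
        except KeyError:
            raise DomainError(f"no profile for concept {concept!r}") from None

    def directions(self) -> dict[str, int]:
        return {e.feature: e.direction for e in self.entries}


# --------------------------------------------------------------------------
# operations

def beta_multiplier(direction: int, convention: str = "signed") -> float:
    """Direction multiplier beta.

    ``signed`` (default): -1 for negative, +1 for positive association,
    so negatively-directed features subtract from aggregate strengths.
    ``literal``: 1 for negative, 2 for positive — an alternative
    convention in which negative features merely weigh less.
    """
    if direction not in (+1, -1):
        raise DomainError(f"direction must be +1 or -1, got {direction}")
    if convention == "signed":
        return float(direction)
    if convention == "literal":
        return 2.0 if direction > 0 else 1.0
    raise DomainError(f"unknown beta convention {convention!r}")


def association_strength(f_xy: int, f_x: int, f_y: int) -> float:
    """Jaccard-style association strength between two words.

    ``f_xy / (f_x + f_y - f_xy)`` — co-occurrence hits over union hits.
    Symmetric in the two single-word counts.  Hit counts need not obey
    set semantics; the result is clipped into [0, 1].
    """
    for name, v in (("f_xy", f_xy), ("f_x", f_x), ("f_y", f_y)):
        if v < 0:
            raise DomainError(f"{name} must be non-negative, got {v}")
    denom = f_x + f_y - f_xy
    if denom <= 0:
        raise DegenerateInputError(
            f"union count f_x + f_y - f_xy = {denom} is not positive"
        )
    return min(1.0, f_xy / denom)


def infer_direction(feature_values, class_indicator) -> int:
    """Sign of the Pearson correlation between a feature and the class.

    Returns +1 for non-negative correlation, -1 otherwise.  Raises
    UndefinedDirectionError for constant input (the caller must then
    supply the direction via configuration).
    """
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(class_indicator, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("feature values and class indicator must be equal-length vectors")
    if x.size < 3:
        raise DomainError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedDirectionError("constant vector: direction undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    return +1 if r >= 0 else -1


def total_strength(entries, convention: str = "signed") -> float:
    """Direction-signed mean strength of a word over its associations.

    ``entries`` is a list of (strength, direction) pairs; the result is
    ``sum(beta * alpha) / n``, in [-1, 1] under the signed convention.
    """
    entries = list(entries)
    if not entries:
        raise DomainError("total_strength of an empty list is undefined")
    total = 0.0
    for strength, direction in entries:
        if not 0.0 <= strength <= 1.0:
            raise DomainError(f"strength must be in [0,1], got {strength}")
        total += beta_multiplier(direction, convention) * strength
    return total / len(entries)


def degree_association_strength(
    record: FrequencyRecord, level: str, class_level_count: int
) -> float:
    """Association strength of a feature with one degree-qualified class term."""
    if record.count_alone is None:
        raise DomainError(f"{record.feature}: count_alone is required")
    if level not in record.cooccur:
        raise DomainError(f"{record.feature}: no co-occurrence count for level {level!r}")
    return association_strength(record.cooccur[level], record.count_alone, class_level_count)


def concept_strength(levels, convention: str = "signed") -> float:
    """Hit-count-weighted signed mean of degree-level strengths.

    ``levels`` is a list of (class_level_count zeta, strength alpha,
    direction) triples for the degree levels belonging to one concept:
    ``sum(beta * zeta * alpha) / sum(zeta)``.
    """
    levels = list(levels)
    if not levels:
        raise DomainError("concept_strength of an empty list is undefined")
    num = 0.0
    den = 0.0
    for zeta, alpha, direction in levels:
        if zeta < 0:
            raise DomainError(f"class-level count must be non-negative, got {zeta}")
        num += beta_multiplier(direction, convention) * zeta * alpha
        den += zeta
    if den == 0:
        raise DegenerateInputError("all class-level counts are zero")
    return num / den


def assign_feature_concepts(
    strengths: dict[str, dict[str, float]],
    margin: float = 1.0,
    severity_order: list[str] | None = None,
) -> dict[str, set[str]]:
    """Partition features into concept sets J_con by strongest association.

    A feature joins J_con when its strength magnitude for ``con`` is at
    least ``margin`` times its magnitude for every other concept.  With
    margin = 1 this is an argmax; with margin > 1 a feature may qualify
    for no concept and stays unassigned.  Exact ties break toward the
    more severe concept (the last in ``severity_order``), keeping the
    partition biased toward minority evidence.
    """
    if margin < 1.0:
        raise DomainError(f"margin must be >= 1, got {margin}")
    concepts: list[str] | None = list(severity_order) if severity_order else None
    assignment: dict[str, set[str]] = {c: set() for c in concepts} if concepts else {}
    for feature, per_concept in strengths.items():
        if concepts is None:
            concepts = list(per_concept)
            assignment = {c: set() for c in concepts}
        missing = set(concepts) - set(per_concept)
        if missing:
            raise DomainError(f"{feature}: missing strengths for concepts {sorted(missing)}")
        # scan from most severe so exact ties resolve to the severe level
        winner = None
        for con in reversed(concepts):
            mag = abs(per_concept[con])
            if all(mag >= margin * abs(per_concept[o]) for o in concepts if o != con):
                winner = con
                break
        if winner is not None:
            assignment[winner].add(feature)
    return assignment


def build_kb(
    table: FrequencyTable,
    spec: ConceptSpec,
    class_level_counts: dict[str, int],
    directions: dict[str, int] | None = None,
    default_direction: int = +1,
    margin: float = 1.0,
    beta_convention: str = "signed",
    source: str | None = None,
) -> CrowdKnowledgeBase:
    """Assemble a crowd-knowledge base from a hit-count table.

    Per feature and degree level, the association strength is computed
    from the co-occurrence count, the feature's standalone count and the
    level's class-term count.  Directions come from ``directions`` (per
    feature), falling back to ``default_direction``.  Each level acts as
    a concept; features are partitioned by ``assign_feature_concepts``
    and each profile stores the direction-signed concept strength.
    Deterministic given its inputs.
    """
    level_names = spec.level_names
    missing = set(level_names) - set(class_level_counts)
    if missing:
        raise DomainError(f"missing class-level counts for levels {sorted(missing)}")
    directions = directions or {}
    entries: list[AssociationEntry] = []
    strengths: dict[str, dict[str, float]] = {}
    signed: dict[str, dict[str, float]] = {}
    for record in table:
        direction = int(directions.get(record.feature, default_direction))
        per_concept: dict[str, float] = {}
        per_signed: dict[str, float] = {}
        for level in level_names:
            try:
                alpha = degree_association_strength(
                    record, level, class_level_counts[level]
                )
            except DomainError as exc:
                raise type(exc)(f"feature {record.feature!r}: {exc}") from exc
            entries.append(AssociationEntry(record.feature, level, alpha, direction))
            per_concept[level] = alpha
            # single degree column per concept: the zeta-weighted mean collapses
            per_signed[level] = concept_strength(
                [(class_level_counts[level], alpha, direction)], beta_convention
            )
        strengths[record.feature] = per_concept
        signed[record.feature] = per_signed
    assignment = assign_feature_concepts(strengths, margin, severity_order=level_names)
    profiles = {
        con: ConceptProfile(
            concept=con,
            member_features=members,
            concept_strength={f: signed[f][con] for f in sorted(members)},
        )
        for con, members in assignment.items()
    }
    provenance = {
        "built_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "source": source or "<in-memory table>",
        "margin": margin,
        "beta_convention": beta_convention,
    }
    return CrowdKnowledgeBase(spec, dict(class_level_counts), entries, profiles, provenance)


def map_kb_features(
    kb: CrowdKnowledgeBase, mapping: dict[str, str | None], drop_unmapped: bool = True
) -> CrowdKnowledgeBase:
    """Rename KB features (e.g. associated words -> survey column names).

    Features mapping to ``None`` — words with no corresponding survey
    item — are dropped when ``drop_unmapped`` is true, else kept as-is.
    """
    def rename(f: str) -> str | None:
        if f in mapping:
            return mapping[f]
        return None if drop_unmapped else f

    entries = []
    for e in kb.entries:
        new = rename(e.feature)
        if new is not None:
            entries.append(AssociationEntry(new, e.level, e.strength, e.direction))
    profiles = {}
    for con, p in kb.profiles.items():
        members = {rename(f) for f in p.member_features} - {None}
        strength = {
            rename(f): v for f, v in p.concept_strength.items() if rename(f) is not None
        }
        profiles[con] = ConceptProfile(con, members, strength)
    provenance = {**kb.provenance, "feature_mapping": "applied"}
    return CrowdKnowledgeBase(
        kb.concept_spec, dict(kb.class_level_counts), entries, profiles, provenance
    )


# --------------------------------------------------------------------------
# persistence

def read_frequency_csv(path) -> FrequencyTable:
    """Read a hit-count table: header ``word,count_alone,<level_1>,...``."""
    frame = pd.read_csv(path)
    cols = list(frame.columns)
    if len(cols) < 3 or cols[0] not in ("word", "feature") or cols[1] != "count_alone":
        raise SchemaError(
            f"expected header 'word,count_alone,<levels...>', got {cols} in {path}"
        )
    level_names = cols[2:]
    records = []
    for row in frame.itertuples(index=False):
        row = row._asdict()
        records.append(
            FrequencyRecord(
                feature=str(row[cols[0]]),
                count_alone=int(row["count_alone"]),
                cooccur={lv: int(row[lv]) for lv in level_names},
            )
        )
    return FrequencyTable(records, level_names)


def write_frequency_csv(table: FrequencyTable, path) -> None:
    rows = [
        {"word": r.feature, "count_alone": r.count_alone,
         **{lv: r.cooccur[lv] for lv in table.level_names}}
        for r in table
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def save_kb(kb: CrowdKnowledgeBase, path) -> None:
    """Serialize a knowledge base to JSON (lossless round-trip)."""
    payload = {
        "concept_spec": {
            "class_word": kb.concept_spec.class_word,
            "synonym_words": list(kb.concept_spec.synonym_words),
            "levels": [
                {"name": lv.name, "index": lv.index, "adverbs": list(lv.adverbs)}
                for lv in kb.concept_spec.levels
            ],
        },
        "class_level_counts": kb.class_level_counts,
        "entries": [
            {"feature": e.feature, "level": e.level,
             "strength": e.strength, "direction": e.direction}
            for e in kb.entries
        ],
        "profiles": {
            con: {
                "member_features": sorted(p.member_features),
                "concept_strength": p.concept_strength,
            }
            for con, p in kb.profiles.items()
        },
        "provenance": kb.provenance,
    }
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=1)


def load_kb(path) -> CrowdKnowledgeBase:
    try:
        with open(path) as handle:
            payload = json.load(handle)
        spec = ConceptSpec(
            class_word=payload["concept_spec"]["class_word"],
            synonym_words=tuple(payload["concept_spec"]["synonym_words"]),
            levels=tuple(
                DegreeLevel(lv["name"], lv["index"], tuple(lv["adverbs"]))
                for lv in payload["concept_spec"]["levels"]
            ),
        )
        entries = [
            AssociationEntry(e["feature"], e["level"], e["strength"], e["direction"])
            for e in payload["entries"]
        ]
        profiles = {
            con: ConceptProfile(con, set(p["member_features"]), dict(p["concept_strength"]))
            for con, p in payload["profiles"].items()
        }
        return CrowdKnowledgeBase(
            spec, {k: int(v) for k, v in payload["class_level_counts"].items()},
            entries, profiles, payload.get("provenance", {}),
        )
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise SchemaError(f"malformed knowledge-base file {path}: {exc}") from exc
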