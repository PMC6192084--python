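"""Reading, validating, categorizing and splitting wellness survey data.

The survey schema is a fixed 32-column layout: demographic profile fields
(gender, age, age group, weight, solitude, hobby, location), context items
(temperature .. yellow dust), disease/symptom severities (fat .. blood
sugar) and current emotional status items (anger, stress, depression,
fatigue).  All context, disease and emotion items are 7-point Likert
responses; age and weight are numeric; the remaining profile fields are
nominal codes.

A record's class label is derived from one designated emotion item (the
stress level or the depression level): responses 1-5 are *normal*, 6 or 7
are *abnormal*.  The abnormal class is the minority in real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError, StratificationError, ValidationError

NORMAL = "normal"
ABNORMAL = "abnormal"
#: Labels ordered from majority to minority; used for monotone comparisons.
LABEL_ORDER = (NORMAL, ABNORMAL)

ID_COLUMN = "No"
NOMINAL_COLUMNS = ("P_GEN", "P_AG", "P_SOL", "P_HOB", "P_LOC")
NUMERIC_COLUMNS = ("P_AGE", "P_WEI")
LIKERT_COLUMNS = (
    "C_TEM", "C_HUM", "C_NOI", "C_ACT", "C_ILL", "C_YD",
    "D_FAT", "D_DIA", "D_HTD", "D_HL", "D_CAN", "D_SMK", "D_ACL",
    "D_INDI", "D_DEP", "D_INS", "D_COLD", "D_ALG", "D_NEU", "D_BP", "D_BS",
    "E_ANG", "E_STR", "E_DEP", "E_FTG",
)
TARGET_COLUMNS = ("E_STR", "E_DEP")
SURVEY_COLUMNS = NOMINAL_COLUMNS[:1] + NUMERIC_COLUMNS[:1] + NOMINAL_COLUMNS[1:2] \
    + NUMERIC_COLUMNS[1:] + NOMINAL_COLUMNS[2:] + LIKERT_COLUMNS
LABEL_COLUMN = "label"


def categorize_score(score: int) -> str:
    """Map a 7-point Likert response to a class label.

    Scores 1-5 are *normal*; 6 and 7 are *abnormal* (advised to consult
    a doctor).
    """
    if not isinstance(score, (int, np.integer)) or isinstance(score, bool):
        raise DomainError(f"Likert score must be an integer, got {score!r}")
    if not 1 <= score <= 7:
        raise DomainError(f"Likert score must be in 1..7, got {score}")
    return ABNORMAL if score >= 6 else NORMAL


@dataclass(frozen=True)
class SurveyRecord:
    """One respondent: an id, a feature map, and an optional class label."""

    record_id: int
    features: dict[str, int] = field(repr=False)
    label: str | None = None

    def __post_init__(self):
        if self.record_id <= 0:
            raise ValidationError(f"record_id must be positive, got {self.record_id}")
        if self.label is not None and self.label not in LABEL_ORDER:
            raise ValidationError(f"unknown label {self.label!r}")

    def raw_target(self, target_name: str) -> int:
        return self.features[target_name]


@dataclass
class SurveyDataset:
    """An ordered collection of survey records sharing one schema.

    ``target_name`` names the emotion item (E_STR or E_DEP) whose
    categorization defines the class label for this task.
    """

    records: list[SurveyRecord]
    target_name: str
    schema: list[str]

    def __post_init__(self):
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("record_ids are not unique")
        for r in self.records:
            if set(r.features) != set(self.schema):
                raise SchemaError(
                    f"record {r.record_id} does not match the dataset schema"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def feature_columns(self) -> list[str]:
        """Columns usable as predictors: everything except the two
        emotion-target items (the task's own target and its sibling, which
        would leak the label for the other task)."""
        return [c for c in self.schema if c not in TARGET_COLUMNS]

    @property
    def is_labelled(self) -> bool:
        return all(r.label is not None for r in self.records)

    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def categorize(self) -> "SurveyDataset":
        """Return a copy with each record labelled from its target item."""
        records = [
            replace(r, label=categorize_score(r.raw_target(self.target_name)))
            for r in self.records
        ]
        return SurveyDataset(records, self.target_name, list(self.schema))

    def subset(self, indices) -> "SurveyDataset":
        return SurveyDataset(
            [self.records[i] for i in indices], self.target_name, list(self.schema)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {ID_COLUMN: r.record_id, **r.features}
            if r.label is not None:
                row[LABEL_COLUMN] = r.label
            rows.append(row)
        return pd.DataFrame(rows)


def _validate_row(row_number: int, features: dict[str, int]) -> None:
    for col in LIKERT_COLUMNS:
        v = features[col]
        if not 1 <= v <= 7:
            raise ValidationError(
                f"row {row_number}: column {col} value {v} outside Likert range 1..7"
            )
    for col in SURVEY_COLUMNS:
        if features[col] < 0:
            raise ValidationError(
                f"row {row_number}: column {col} value {features[col]} is negative"
            )


def read_survey_csv(path, target_name: str = "E_DEP") -> SurveyDataset:
    """Read a survey CSV in the fixed 32-column schema.

    The header must contain every survey column (plus the ``No`` id
    column).  Likert columns are validated to integers 1-7; rows with
    missing values are rejected.  A ``label`` column, if present, is
    read back as the record label.
    """
    if target_name not in TARGET_COLUMNS:
        raise DomainError(f"target must be one of {TARGET_COLUMNS}, got {target_name!r}")
    frame = pd.read_csv(path)
    for col in (ID_COLUMN, *SURVEY_COLUMNS):
        if col not in frame.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    has_label = LABEL_COLUMN in frame.columns
    if frame[[ID_COLUMN, *SURVEY_COLUMNS]].isna().any().any():
        bad = int(frame[frame[[ID_COLUMN, *SURVEY_COLUMNS]].isna().any(axis=1)].index[0]) + 1
        raise ValidationError(f"row {bad}: missing value(s); blanks are not permitted")
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        row = row._asdict()
        try:
            features = {col: int(row[col]) for col in SURVEY_COLUMNS}
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"row {i}: non-integer value ({exc})") from exc
        _validate_row(i, features)
        label = str(row[LABEL_COLUMN]) if has_label else None
        records.append(SurveyRecord(int(row[ID_COLUMN]), features, label))
    return SurveyDataset(records, target_name, list(SURVEY_COLUMNS))


def write_survey_csv(dataset: SurveyDataset, path) -> None:
    """Write a dataset back to CSV (with a ``label`` column if labelled)."""
    dataset.to_frame().to_csv(path, index=False)


def split_stratified(
    dataset: SurveyDataset, test_fraction: float, seed: int
) -> tuple[SurveyDataset, SurveyDataset]:
    """Split into (train, test) preserving class proportions per class.

    Each class is shuffled independently with a seeded RNG and
    ``round(test_fraction * n_class)`` of its records go to the test
    part, so class proportions in each part differ from the whole by at
    most one record per class.  Reproducible for a fixed seed.
    """
    if not 0 < test_fraction < 1:
        raise DomainError(f"test_fraction must be in (0,1), got {test_fraction}")
    if not dataset.is_labelled:
        raise DomainError("dataset must be labelled before splitting")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for i, r in enumerate(dataset.records):
        by_class.setdefault(r.label, []).append(i)
    if len(by_class) < 2:
        raise StratificationError("both classes must be present to stratify")
    test_idx: list[int] = []
    train_idx: list[int] = []
    for label in sorted(by_class):
        idx = np.array(by_class[label])
        if len(idx) < 2:
            raise StratificationError(
                f"class {label!r} has {len(idx)} member(s); need at least 2"
            )
        rng.shuffle(idx)
        n_test = int(round(test_fraction * len(idx)))
        n_test = min(max(n_test, 1), len(idx) - 1)  # keep both parts non-empty per class
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    return dataset.subset(sorted(train_idx)), dataset.subset(sorted(test_idx))
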