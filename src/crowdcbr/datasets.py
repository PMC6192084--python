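"""Packaged example data: the published wellness survey sample, the
depression co-occurrence hit counts, the association-level table and
the classifier comparison tables.

All fixtures are small plain-text files shipped inside the package.
``WORD_TO_COLUMN`` bridges the two vocabularies: associated *words*
(as mined from search queries) versus survey *columns*; words with no
corresponding survey item map to ``None``.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from . import crowd_kb
from .crowd_kb import (
    ConceptSpec,
    CrowdKnowledgeBase,
    DegreeLevel,
    FrequencyTable,
    read_frequency_csv,
)
from .io_survey import SurveyDataset, read_survey_csv

#: Degree adverbs qualifying the class word, per severity group.
SLIGHT_ADVERBS = ("a little", "some", "succinct", "trifling", "light", "soft")
SERIOUS_ADVERBS = ("not a little", "severe", "grave", "deep", "intensive", "intensified")

#: Associated word -> survey column (None: no matching survey item).
WORD_TO_COLUMN: dict[str, str | None] = {
    "Temperature": "C_TEM",
    "Humidity": "C_HUM",
    "Noise": "C_NOI",
    "Illumination": "C_ILL",
    "Anger": "E_ANG",
    "Stress": "E_STR",
    "Fatigue": "E_FTG",
    "Fat": "D_FAT",
    "Diabetes": "D_DIA",
    "Heart disease": "D_HTD",
    "Hyperlipidemia": "D_HL",
    "Cancer": "D_CAN",
    "Smoking": "D_SMK",
    "Drinking": "D_ACL",
    "Indigestion": "D_INDI",
    "Insomnia": "D_INS",
    "Cold": "D_COLD",
    "Allergy": "D_ALG",
    "Neurosis": "D_NEU",
    "Blood pressure": "D_BP",
    "Blood sugar": "D_BS",
    "Wellness": None,
    "Age": "P_AGE",
    "Gender": "P_GEN",
    "Weight": "P_WEI",
    "Solitude": "P_SOL",
    "Hobby": "P_HOB",
    "Yellow dust": "C_YD",
    "Inconvenience": None,
}


def _data_path(name: str):
    return resources.files(__package__) / "data" / name


def depression_concept_spec() -> ConceptSpec:
    """Two-level severity concept for the depression class word."""
    return ConceptSpec(
        class_word="depression",
        levels=(
            DegreeLevel("normal", 1, SLIGHT_ADVERBS),
            DegreeLevel("serious", 2, SERIOUS_ADVERBS),
        ),
    )


def load_survey(target_name: str = "E_DEP") -> SurveyDataset:
    """The 100 published survey records (unlabelled; call .categorize())."""
    with resources.as_file(_data_path("table6_survey.csv")) as path:
        return read_survey_csv(path, target_name)


def load_cooccurrence() -> FrequencyTable:
    """Hit counts of 29 associated words alone and with the normal /
    serious depression class terms."""
    with resources.as_file(_data_path("table1_cooccurrence.csv")) as path:
        return read_frequency_csv(path)


def load_association_levels() -> pd.DataFrame:
    """Published association strengths per word and severity level.

    Columns: word, normal, serious, bold — ``bold`` records which level
    the source emphasised for that word ("normal", "serious" or "none").
    """
    with resources.as_file(_data_path("table2_association_levels.csv")) as path:
        return pd.read_csv(path)


def serious_words() -> list[str]:
    """Words emphasised as markers of the serious (minority) level."""
    frame = load_association_levels()
    return sorted(frame.loc[frame["bold"] == "serious", "word"])


def load_performance_table(task: str) -> pd.DataFrame:
    """Published classifier comparison for ``task`` in {stress, depression}.

    Rows per classifier: normal, serious, overall (prevalence weighted)
    and overall_norm (macro mean).
    """
    if task not in ("stress", "depression"):
        raise ValueError(f"task must be 'stress' or 'depression', got {task!r}")
    with resources.as_file(_data_path(f"performance_{task}.csv")) as path:
        return pd.read_csv(path)


def load_concept_config() -> dict:
    """Concept configuration with synthetic class-term hit counts.

    The standalone hit counts of the degree-qualified class terms
    ("normal depression", "serious depression") are not published;
    the shipped values are synthetic stand-ins of plausible magnitude,
    so downstream association strengths are illustrative, not
    reconstructions.
    """
    with resources.as_file(_data_path("depression_concepts_synthetic.json")) as path:
        with open(path) as handle:
            return json.load(handle)


def association_level_kb(target_name: str = "E_DEP", margin: float = 1.0) -> CrowdKnowledgeBase:
    """Knowledge base taken directly from the published association levels.

    Strengths are read from the association-level table (not recomputed
    from hit counts), features are renamed to survey columns, and words
    without a survey item — or clashing with the task's target columns —
    are dropped.  Directions default to +1 (all listed words describe
    burdens or symptoms; the one negatively-phrased item, wellness, has
    no survey column).
    """
    frame = load_association_levels()
    spec = depression_concept_spec()
    entries = []
    strengths: dict[str, dict[str, float]] = {}
    for row in frame.itertuples(index=False):
        column = WORD_TO_COLUMN.get(row.word)
        if column is None or column in ("E_STR", "E_DEP"):
            continue
        entries.append(crowd_kb.AssociationEntry(column, "normal", float(row.normal), +1))
        entries.append(crowd_kb.AssociationEntry(column, "serious", float(row.serious), +1))
        strengths[column] = {"normal": float(row.normal), "serious": float(row.serious)}
    assignment = crowd_kb.assign_feature_concepts(
        strengths, margin, severity_order=spec.level_names
    )
    profiles = {
        con: crowd_kb.ConceptProfile(
            con, members, {f: strengths[f][con] for f in sorted(members)}
        )
        for con, members in assignment.items()
    }
    return CrowdKnowledgeBase(
        concept_spec=spec,
        class_level_counts={"normal": 0, "serious": 0},  # not used: strengths are given
        entries=entries,
        profiles=profiles,
        provenance={"source": "published association-level table", "margin": margin},
    )
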