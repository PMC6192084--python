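"""Synthetic imbalanced survey data with known ground truth.

The generator emulates the structure of the real wellness survey: 7-point
Likert items drawn per column from the empirical distribution of the
packaged 100-record sample, a configurable majority:minority ratio
(real-data ratios are about 10.7:1 for stress and 16.9:1 for
depression), and a planted effect — minority respondents score
``effect_delta`` points higher (clipped at 7) on a designated subset of
features.  A matching hit-count table can be generated whose
co-occurrence counts make exactly the planted features come out as the
severe concept's member set, so knowledge-base construction and the
full classification pipeline are testable end to end with no external
data.

Label noise flips a record's class label (and redraws its target item
consistently) with a small probability while leaving its features at
the pattern of the true class, emulating respondents whose self-rated
severity disagrees with their symptom profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crowd_kb import FrequencyRecord, FrequencyTable
from .errors import DomainError, ValidationError
from .io_survey import (
    LIKERT_COLUMNS,
    NOMINAL_COLUMNS,
    NUMERIC_COLUMNS,
    SURVEY_COLUMNS,
    SurveyDataset,
    SurveyRecord,
    categorize_score,
)

#: Planted minority features: survey columns of the symptom words most
#: strongly tied to the severe level in the published association table.
DEFAULT_MINORITY_FEATURES = (
    "C_NOI", "D_FAT", "D_DIA", "D_SMK", "D_ACL", "D_INS", "D_ALG", "D_BP", "E_FTG",
)


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for one synthetic dataset.

    Defaults mirror the real survey: n = 334 respondents, a 10.7:1
    majority:minority ratio, a 3-point planted Likert shift and 5%
    label noise.
    """

    n: int = 334
    imbalance_ratio: float = 10.7
    target_name: str = "E_DEP"
    feature_names: tuple[str, ...] = SURVEY_COLUMNS
    minority_features: tuple[str, ...] = DEFAULT_MINORITY_FEATURES
    effect_delta: int = 3
    base_distribution: dict | None = field(default=None, hash=False)
    noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.imbalance_ratio <= 1:
            raise ValidationError(f"imbalance_ratio must exceed 1, got {self.imbalance_ratio}")
        if not 0 <= self.noise < 0.5:
            raise ValidationError(f"noise must be in [0, 0.5), got {self.noise}")
        stray = set(self.minority_features) - set(self.feature_names)
        if stray:
            raise ValidationError(f"minority_features not in feature_names: {sorted(stray)}")
        if self.n < 2:
            raise ValidationError(f"need n >= 2, got {self.n}")

    @property
    def n_minority(self) -> int:
        return int(round(self.n / (self.imbalance_ratio + 1)))


def _fixture_distributions() -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-column empirical (values, probabilities) from the packaged
    survey sample, so synthetic marginals resemble printed data."""
    from .datasets import load_survey

    frame = load_survey().to_frame()
    out = {}
    for col in SURVEY_COLUMNS:
        values, counts = np.unique(frame[col].to_numpy(), return_counts=True)
        out[col] = (values.astype(int), counts / counts.sum())
    return out


def _draw(rng, dist, size):
    values, probs = dist
    return rng.choice(values, size=size, p=probs)


def generate_survey(spec: GeneratorSpec) -> SurveyDataset:
    """Generate a labelled imbalanced survey dataset.

    Minority count is round(n / (ratio + 1)).  Minority records get
    ``effect_delta`` added (clipped to 7) on the planted Likert
    features and a target response of 6 or 7; majority records draw
    their target from the empirical distribution restricted to 1-5.
    Fully reproducible from ``spec.seed``.
    """
    n_minor = spec.n_minority
    if n_minor < 1:
        raise DomainError(
            f"imbalance ratio {spec.imbalance_ratio} yields zero minority records at n={spec.n}"
        )
    rng = np.random.default_rng(spec.seed)
    dists = spec.base_distribution or _fixture_distributions()

    is_minor = np.zeros(spec.n, dtype=bool)
    is_minor[:n_minor] = True
    rng.shuffle(is_minor)

    columns: dict[str, np.ndarray] = {}
    for col in spec.feature_names:
        if col == spec.target_name:
            continue
        dist = dists.get(col, (np.arange(1, 8), np.full(7, 1 / 7)))
        draws = _draw(rng, dist, spec.n)
        if col in spec.minority_features and col in LIKERT_COLUMNS:
            draws = np.where(is_minor, np.minimum(draws + spec.effect_delta, 7), draws)
        columns[col] = draws

    # label noise: flip class membership for the target draw only —
    # features keep the true class's pattern
    flip = rng.random(spec.n) < spec.noise
    labelled_minor = is_minor ^ flip

    t_values, t_probs = dists.get(spec.target_name, (np.arange(1, 8), np.full(7, 1 / 7)))
    low_mask = t_values <= 5
    low_values = t_values[low_mask] if low_mask.any() else np.arange(1, 6)
    low_probs = (
        t_probs[low_mask] / t_probs[low_mask].sum() if low_mask.any() else np.full(5, 0.2)
    )
    target = np.where(
        labelled_minor,
        rng.choice([6, 7], size=spec.n),
        rng.choice(low_values, size=spec.n, p=low_probs),
    )
    columns[spec.target_name] = target

    records = []
    for i in range(spec.n):
        features = {col: int(columns[col][i]) for col in spec.feature_names}
        records.append(
            SurveyRecord(
                record_id=i + 1,
                features=features,
                label=categorize_score(features[spec.target_name]),
            )
        )
    return SurveyDataset(records, spec.target_name, list(spec.feature_names))


def generate_frequency_table(
    spec: GeneratorSpec, scale: int = 1_000_000
) -> tuple[FrequencyTable, dict[str, int]]:
    """Generate a hit-count table matching the planted associations.

    Planted minority features co-occur heavily with the severe class
    term (their severe-level association strength strictly exceeds the
    normal-level one); all other features show the reverse pattern.
    Deterministic given ``spec.seed``.
    """
    if scale <= 0:
        raise DomainError(f"scale must be positive, got {scale}")
    rng = np.random.default_rng(spec.seed)
    class_level_counts = {"normal": 2 * scale, "serious": 3 * scale}
    records = []
    for feature in spec.feature_names:
        if feature == spec.target_name:
            continue
        count_alone = int(scale * (0.5 + rng.random()))
        if feature in spec.minority_features:
            hi = int(count_alone * (0.20 + 0.05 * rng.random()))
            lo = int(count_alone * (0.01 + 0.005 * rng.random()))
            cooccur = {"serious": hi, "normal": lo}
        else:
            hi = int(count_alone * (0.15 + 0.05 * rng.random()))
            lo = int(count_alone * (0.01 + 0.005 * rng.random()))
            cooccur = {"normal": hi, "serious": lo}
        records.append(FrequencyRecord(feature, cooccur, count_alone))
    return FrequencyTable(records, ["normal", "serious"]), class_level_counts


def ground_truth(spec: GeneratorSpec) -> dict:
    """Sidecar description of what was planted (for audits and tests)."""
    return {
        "n": spec.n,
        "n_minority": spec.n_minority,
        "imbalance_ratio": spec.imbalance_ratio,
        "target_name": spec.target_name,
        "minority_features": sorted(spec.minority_features),
        "effect_delta": spec.effect_delta,
        "noise": spec.noise,
        "seed": spec.seed,
    }
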