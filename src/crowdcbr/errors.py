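"""Exception hierarchy shared by all crowdcbr modules."""


class CrowdCbrError(Exception):
    """Base class for all package errors."""


class SchemaError(CrowdCbrError):
    """A file or record does not match the expected column schema."""


class ValidationError(CrowdCbrError):
    """A value violates its documented domain (e.g. Likert outside 1-7)."""


class DomainError(CrowdCbrError):
    """An argument is outside the mathematical domain of an operation."""


class DegenerateInputError(DomainError):
    """Input is formally valid but makes the operation undefined
    (zero denominator, constant vector, empty weight mass)."""


class UndefinedDirectionError(DegenerateInputError):
    """Direction of association cannot be inferred (constant vector);
    the caller must supply a direction via configuration."""


class StratificationError(CrowdCbrError):
    """A class has too few members to stratify a split."""


class RetrievalError(CrowdCbrError):
    """Case retrieval is impossible (empty case base, k too large)."""


class AbstentionError(CrowdCbrError):
    """A reasoner cannot produce a vote for this record."""


class PredictionError(CrowdCbrError):
    """No reasoner could produce a decision for a record."""
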