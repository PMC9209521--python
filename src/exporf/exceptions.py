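"""Exception hierarchy for cohort validation and pipeline contracts."""


class ExporfError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ExporfError):
    """An exposure schema is malformed, or data refer to ids/states not in it."""


class CohortValidationError(ExporfError):
    """A cohort table violates the long-format contract."""


class DuplicateRecordError(CohortValidationError):
    """The same (subject, exposure, round) appears more than once."""


class CompletenessError(CohortValidationError):
    """A subject lacks an outcome label (the cohort requires complete outcomes)."""


class StratificationError(ExporfError):
    """A class is too small to stratify the train/test split."""


class ParameterError(ExporfError):
    """A hyperparameter or configuration value is out of its valid range."""


class ContractError(ExporfError):
    """An operation was called with inputs violating its precondition."""
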