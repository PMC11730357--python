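"""Exception hierarchy shared across the package."""


class NanothermError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NanothermError):
    """A file or table does not conform to the expected layout."""


class DatasetError(NanothermError):
    """A dataset-level problem (empty table, out-of-band labels, ...)."""


class AlignmentError(NanothermError):
    """A sequence cannot be placed on, or violates, the 149-position scheme."""


class ContractError(NanothermError):
    """A caller violated an operation precondition."""


class ConfigError(NanothermError):
    """Invalid configuration (empty preference list, bad fold counts, ...)."""


class SplitError(NanothermError):
    """A stratified split is infeasible for the given class sizes."""


class ModelError(NanothermError):
    """A regressor produced unusable output (non-finite predictions, ...)."""
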