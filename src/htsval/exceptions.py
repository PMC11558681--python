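"""Exception hierarchy for htsval.

All package errors derive from :class:`HtsvalError` so callers (and the CLI)
can map error categories to exit codes.
"""


class HtsvalError(Exception):
    """Base class for all htsval errors."""


class SchemaError(HtsvalError):
    """Input table is missing a mandatory column or has an unusable dtype."""


class EmptyDatasetError(HtsvalError):
    """No parseable records remain after loading/cleaning."""


class ConfigError(HtsvalError):
    """A configuration value is outside its documented domain."""


class StratificationError(HtsvalError):
    """A stratified split cannot be built (e.g. a class stratum is empty)."""


class FeaturizationError(HtsvalError):
    """A structure could not be featurized; names the offending record."""


class DegenerateInputError(HtsvalError):
    """Inputs make the requested quantity undefined (single-class labels,
    empty target sets, constant validation labels, ...)."""
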