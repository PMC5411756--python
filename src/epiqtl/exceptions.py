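"""Exception hierarchy for epiqtl.

All package-specific failures derive from :class:`EpiqtlError` so callers
(and the CLI) can distinguish configuration/validation problems (exit code 2)
from analysis-stage failures (exit code 3).
"""


class EpiqtlError(Exception):
    """Base class for all epiqtl errors."""


class ConfigurationError(EpiqtlError):
    """A configuration value is outside its documented domain."""


class GenerationError(EpiqtlError):
    """The synthetic-data generator was asked for an impossible dataset."""


class DataConsistencyError(EpiqtlError):
    """Inputs reference ids or coordinates that do not exist or disagree."""


class UndefinedLdError(EpiqtlError):
    """LD is undefined (monomorphic genotypes or too few complete samples)."""


class AnalysisError(EpiqtlError):
    """An analysis stage cannot produce a result (e.g. no testable pairs)."""
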