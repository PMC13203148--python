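"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and subclasses) to 3.
"""


class HerdscanError(Exception):
    """Base class for all package errors."""


class ConfigError(HerdscanError):
    """Invalid configuration: bad parameter values, unknown keys, infeasible requests."""

    exit_code = 2


class InfeasibleConfigError(ConfigError):
    """A simulation/analysis request that cannot be satisfied by construction."""


class DataError(HerdscanError):
    """Invalid or inconsistent input data."""

    exit_code = 3


class FormatError(DataError):
    """Malformed file content (VCF, BED, GFF3, sample sheet)."""


class MetadataError(DataError):
    """Sample metadata does not cover, or contradicts, the genotype data."""


class InvariantError(DataError):
    """An internal data-structure invariant was violated."""


class CohortError(DataError):
    """A required sample group is empty or otherwise unusable."""


class PipelineError(HerdscanError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
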