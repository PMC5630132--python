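"""Exception hierarchy shared across the pipeline.

The CLI maps these onto distinct exit codes (config 2, input format 3,
statistical degeneracy 4), so stage code should raise the most specific
class that applies.
"""


class GeneBurdenError(Exception):
    """Base class for all package errors."""


class ConfigError(GeneBurdenError):
    """Invalid run or simulation configuration."""


class InputFormatError(GeneBurdenError):
    """Malformed or inconsistent input file content."""


class EmptyCohortError(GeneBurdenError):
    """A filter or subset left one of the case/control groups empty."""


class DegenerateDataError(GeneBurdenError):
    """Counts violate the 2x2 invariants (e.g. more observations than subjects)."""
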