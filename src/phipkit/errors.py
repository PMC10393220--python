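"""Exception hierarchy for phipkit.

Every failure mode the pipeline distinguishes gets its own class so callers
(and the CLI) can map them to exit codes and actionable messages.
"""


class PhipkitError(Exception):
    """Base class for all phipkit errors."""


class ConfigurationError(PhipkitError):
    """Invalid simulation or pipeline configuration."""


class FormatError(PhipkitError):
    """Malformed input file (bad cell value, duplicate id, unknown token)."""


class ConsistencyError(PhipkitError):
    """Cross-file inconsistency (counts/library/sample-sheet mismatch)."""


class PreconditionError(PhipkitError):
    """An operation's statistical precondition is not met
    (e.g. no mock-IP samples, reference cohort too small)."""


class LookupError_(PhipkitError):
    """Unknown gene/sample/peptide identifier."""


class AlphabetError(PhipkitError):
    """Residue outside the amino-acid alphabet."""
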