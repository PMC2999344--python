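"""Exception hierarchy.

All package errors derive from :class:`FavatError` so callers (and the CLI)
can distinguish data problems from programming errors.
"""


class FavatError(Exception):
    """Base class for all errors raised by this package."""


class MatrixError(FavatError):
    """Malformed, unknown, or unreadable substitution matrix."""


class ProfileError(FavatError):
    """Malformed profile or FASTA input."""


class AlignmentError(FavatError):
    """Invalid alignment input or malformed three-way alignment."""


class VotingError(FavatError):
    """Invalid voting input (gaps where residues are required, bad labels)."""


class SynthError(FavatError):
    """Infeasible synthetic-family configuration."""


class ConfigError(FavatError):
    """Invalid run configuration (bad threshold, missing paths, ...)."""
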