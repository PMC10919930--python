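"""Exception hierarchy shared across modules."""


class TraitscanError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(TraitscanError, ValueError):
    """Invalid simulation or pipeline configuration."""


class FormatError(TraitscanError, ValueError):
    """Malformed input file (alignment, trait table, BED, VCF, track TSV)."""


class ValidationError(TraitscanError, ValueError):
    """Input parsed but violates a domain invariant (e.g. non-positive mass)."""


class CoordinateRangeError(TraitscanError, KeyError):
    """Genomic coordinate outside the span covered by a column map."""
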