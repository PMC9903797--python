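"""Exception types shared across the pipeline stages."""


class KoscanError(Exception):
    """Base class for all pipeline errors."""


class FormatError(KoscanError):
    """A file could not be parsed in the expected format."""


class IntegrityError(KoscanError):
    """Inputs are parseable but mutually inconsistent (key mismatches, unsorted sites)."""


class ConfigurationError(KoscanError):
    """A configuration value is outside its valid domain or infeasible."""
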