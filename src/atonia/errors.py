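"""Exception hierarchy for the pipeline."""


class AtoniaError(Exception):
    """Base class for all package errors."""


class FormatError(AtoniaError, ValueError):
    """A file does not conform to the expected on-disk format."""


class IntegrityError(AtoniaError, ValueError):
    """Parsed data violate an internal consistency requirement."""


class ConfigError(AtoniaError, ValueError):
    """A run configuration is malformed or names unknown keys."""


class InsufficientDataError(AtoniaError, ValueError):
    """Too few observations for the requested computation."""


class UndefinedResultError(AtoniaError, ValueError):
    """The requested quantity is undefined on this input (e.g. a REM-A
    proportion when the hypnogram contains no REMS at all — that is not 0%)."""
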